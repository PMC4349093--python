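# Methods

## The biological setting and the estimation problem

Western corn rootworm (WCR) populations have evolved resistance to the
Cry3Bb1 Bt toxin expressed in transgenic maize. Mapping the responsible locus
is complicated by two features of the organism: severe inbreeding depression
(no inbred lines, hence no standard F2 or backcross panel) and XO sex
determination (males are hemizygous for the X). The package implements the
full inference chain for an outbred-family design: a resistant sire ×
susceptible dam single-pair cross per family, F1 sib-mating, and F2 eggs
randomized onto Bt-expressing maize (treatment) or a non-Bt isoline
(control). Viability selection on the treatment distorts genotype frequencies
at markers linked to the resistance locus; the control arm carries every
other force (drift, meiotic distortion) and serves as the reference.

## Marker classification and recoding

With biallelic SNPs, parental genotypes admit three usable configurations:

* opposite homozygotes (AA × BB): every F1 is heterozygous in known coupling
  phase; the F2 segregates 1:2:1 — a standard **F2 intercross** design, coded
  SS/RS/RR by parental origin (S = dam allele, R = sire allele);
* at least one heterozygous parent: segregation is visible in the **F1**.
  Sire-het and dam-het markers are backcross designs on that parent's
  meiosis; markers heterozygous in both parents form an intercross with
  unknown phase;
* X-linked markers with a homozygous dam and a hemizygous sire carrying the
  other allele: under XO inheritance the F2 follows a **backcross** on the F1
  female meiosis with the dam allele recurrent; hemizygous F2 males are coded
  directly from their single allele.

Progeny alleles not attributable to either parent (genotyping error) are set
missing and counted, rather than dropping individuals, keeping per-marker n
maximal. Heterozygous-dam X markers are not used. Both-parents-heterozygous
markers enter only the F1 map; the full four-allele outbred cross-type
lattice is out of scope for biallelic SNPs.

## Two-point estimation

Backcross: r̂ = recombinants/n, LOD = n_p·log10(2(1−r̂)) + n_r·log10(2r̂).
When founder phase is unknown (F1 parent maps) the recombinant count is
folded, r̂ = min(c, n−c)/n.

F2 intercross (phase known): maximum likelihood by EM over the
double-heterozygote ambiguity — the only genotype class whose recombinant
gamete count (0 or 2) is not observable. The E-step weight is
2r²/(r² + (1−r)²); convergence at |Δr| < 1e-8, at most 1000 iterations,
initialized at r = 0.25, capped at 0.5. The estimator is vectorized over all
marker pairs via the 9-cell count tables.

F2 intercross (phase unknown): the likelihood is maximized over the three
distinct phase configurations (both coupling, mixed, both repulsion — the
last being the coupling likelihood at 1−r) with a coarse grid plus local
refinement; precision ~1e-4, sufficient for grouping and ordering.

## Grouping, ordering, and the composite map

Grouping is single-linkage: two markers share a group iff connected by a
chain of pairs with LOD ≥ threshold and r̂ ≤ r_max. Single linkage is
vulnerable to chaining through rare chance links, so the pipeline scales the
LOD threshold with the number of pairs tested (χ²₁ quantile at α/n_pairs,
α = 0.0033 per design set by default to cover the five design sets × three
families of a full experiment; never below the conventional LOD 3) and uses a
conservative base r_max = 0.25. Chromosome stretches left thin by the
informativeness split can then fall apart; a rescue pass re-attaches a
smaller group to the larger group holding its tightest link, requiring at
least three qualifying links (LOD ≥ 4, r ≤ 0.35) from at least two distinct
markers so that no single chance link can fuse chromosomes. These two
thresholds trade split risk against fusion risk; fusions are the more
damaging error and the defaults favor avoiding them.

Ordering within a group is rapid chain delineation (RCD): seed with the
minimal-r pair, repeatedly append the unplaced marker with minimal r to
either chain end; ties break by marker id, preferring the right end, and the
final chain is oriented so its first marker id precedes its last. Positions
are cumulative Kosambi distances of adjacent r̂. No SARF/ripple refinement is
applied by default.

Component maps are merged through shared anchor markers. Groups connected by
≥2 shared anchors (transitively) form one composite group; the largest group
is the reference frame and every other group is rescaled onto it by monotone
piecewise-linear interpolation through the anchors it shares with an
already-rescaled group (BFS from the reference, with a cumulative-max guard
and linear extrapolation at the ends). A marker's composite position is the
mean of its rescaled positions; order is by mean position with ties broken by
reference order then marker id, re-zeroed per group. Strict mode raises on a
marker whose groups fall in different composite clusters or on a group with
fewer than two usable anchors; the pipeline uses a sanitation mode that
resolves conflicted markers by majority cluster and drops unanchorable
fragments, which is the practical choice when merging fifteen sparse
per-design component maps. This anchor-interpolation consensus deliberately
replaces graph-based consensus-map algorithms: it is deterministic, simple,
and adequate at this problem scale.

## Selection scan and threshold

One Pearson χ² test of independence per marker per family contrasts the 2×k
table of treatment vs control genotype counts (no continuity correction).
Columns with zero total are dropped and the per-test df reduced — treatment
arms often contain no susceptible homozygotes — but the familywise threshold
is computed at 2 df, the full-table df for a three-genotype marker. The
threshold is the χ² quantile at 1 − α/n over the number of tests actually
performed (α = 0.05); at 2 df this is −2·ln(α/n). Tail probabilities are
computed in log space (`chi2.logsf`), retaining two significant figures far
beyond double-precision tail underflow (χ² ≈ 223 at 2 df → p ≈ 4×10⁻⁴⁹).

The segregation-distortion scan applies a goodness-of-fit χ² of control-arm
counts against 1:2:1 (intercross) or 1:1 (X backcross), separating Cry3Bb1
selection from any transmission distortion.

The conditional epistasis scan restricts treatment survivors to those
heterozygous at ≥ a configurable fraction (default all) of their non-missing
focal-interval markers and re-tests every non-focal marker against the full
control arm, Bonferroni-corrected over tests performed. Markers linked to the
focal interval are legitimately distorted in the conditioned subset; claims
about *additional* loci concern the unlinked genome.

## Fitness, dominance, and assignment error

Because eggs are randomized into arms from one pool, final genotype
frequencies estimate viability directly: w_g = freq_trt(g)/freq_ctl(g),
rescaled by the maximum (in practice the RR class) to give
(w_SS, w_RS, w_RR ≡ 1). A zero control class is an error by default —
surfacing a data problem — with an explicit +0.5 continuity-correction
opt-in. Dominance of the susceptible allele is h_S = 1 − mean(w_RS), the
unweighted mean over families, valid when mean w_SS ≤ 0.05 (flagged
otherwise); h_S + mean(w_RS) = 1 exactly.

The Monte Carlo assignment-error routine draws a finite pool of
n_trt + n_ctl genotypes multinomially and partitions it at random into the
two arms (multivariate hypergeometric — a finite-pool partition, not two
independent multinomials, because the arms share one egg pool), recording the
per-genotype frequency difference; the per-genotype median absolute deviation
across replicates summarizes the sampling error. At 200 eggs per arm the MAD
for the heterozygote class is ≈3.4%, consistent with the normal approximation
0.6745·√(p(1−p)(1/n_t + 1/n_c)).

## Field validation

A population's resistance score is mean survivors on Bt substrate / mean
survivors on control substrate (1 = resistant, 0 = susceptible; not capped).
Plant and diet bioassays share one code path and differ only in replicate
structure (10 replicates × 30 larvae vs 12 wells × 6 plates). Scores are
regressed on candidate-marker allele frequencies by unweighted OLS
(R² = 1 − SSE/SST, two-sided t test for the slope); precision weighting is
left as future work. Repeatability uses the Poisson offset model
ln E[trt_ij] = pop_j + ln(ctl_ij), whose saturated population factor has the
closed-form MLE rate_j = Σ_i trt_ij / Σ_i ctl_ij (exploited directly and
cross-checked against an IRLS GLM in the tests). McFadden's
R² = 1 − llf/ll0 is computed on the full Poisson log-likelihood including the
ln y! terms; the constant terms do not fully cancel in the ratio, so the
convention matters and is fixed here.

## The synthetic-data generator

The simulator emulates the study design: three single-pair families from a
resistant sire × susceptible dam; founder allele frequencies drawn uniformly
inside the band where expected heterozygosity ≥ 0.25 (the informativeness
floor of the real panel), with the sire forced homozygous resistant and the
dam homozygous susceptible at the causal locus; F1 sib-mating; F2 eggs split
into arms with treatment survival proportional to causal-genotype fitness and
control retention uniform. Meiosis is a no-interference (Poisson) crossover
process — the transmitted haplotype follows a two-state Markov chain with
switch probabilities given by the inverse Haldane function — although the
estimation side reports Kosambi distances; this generator/estimator mismatch
is standard and mildly shortens estimated maps relative to a Kosambi
generator. Sex is decided by the paternal gamete (X-bearing sperm → daughter,
nullo-X → son), giving hemizygous male X calls throughout.

Genotyping noise is a symmetric per-allele flip at rate 0.02 — two
independent 2% error processes reproduce the ~96% repeat-concordance typical
of amplicon genotyping — plus missing-at-random calls at rate 0.05. Noise is
applied to F1 and F2 calls but not to the founders, whose genotypes anchor
classification and are, in practice, genotyped with replication. The default
marker panel is 9 autosomes + X with 115 markers per 230 cM group (≈1150
SNPs); per-family F1/F2 sample sizes are not dictated by the study design and
default to 200 eggs per arm, configurable. An optional second, unlinked
causal locus acts multiplicatively on fitness, supporting epistasis
experiments.

Field panels assume Hardy–Weinberg proportions within populations: causal
allele frequency q ~ Beta(a, b) (default a = b = 1, an uninformative choice
where the study reports none), marker frequency = LD·q + (1−LD)·independent
Beta draw, per-larva Bt survival = baseline·(q² + h·2q(1−q) + w_SS(1−q)²)
with baseline control survival 0.5 (a typical larval recovery rate) and
h = 0.12 (the mean heterozygote fitness scale of the cross experiment).
Reported marker frequencies are the exact generative values (n = 48
individuals is recorded as panel metadata); binomial genotyping noise at the
population level is not simulated. The generator does not attempt read-level
sequencing artifacts, family structure within field populations, or
between-generation population dynamics, so passing tests demonstrate
correctness of the inference machinery under the stated model, not robustness
to every artifact of real GBS data.

## Numerical and testing choices

* Pairwise estimation, meiosis, and the Monte Carlo routines are vectorized;
  a three-family, 1150-marker experiment builds its composite map in a few
  seconds.
* Degenerate inputs raise typed errors (`DataError`, `ExtinctionError`,
  `ConditioningError` with diagnostic counts) rather than propagating NaNs.
* Test problem sizes are scaled to the desk: scan calibration uses a
  2-autosome + X map with 200–300 eggs per arm over 100–200 seeds; fitness
  recovery uses 500 eggs per arm over 200 seeds per fitness combination
  (noise off, isolating estimator bias from genotyping error, which
  mechanically inflates w_RS by miscalling RR survivors); group-recovery and
  composite-order checks use 30–115 markers per group. The statistical
  guarantees asserted (power ≥95%, familywise error ≤5%, |bias z| ≤ 4,
  conditional-scan detection ≥90%) are properties of the method at those
  stated sizes.
* The per-family component-map pipeline leaves an occasional small fragment
  group when a design set is locally sparse and no other family anchors those
  markers; the composite map therefore reports ten major linkage groups plus,
  rarely, a residual fragment rather than forcing a fixed group count.
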