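"""Synthetic cross families and field-population panels.

Emulates the data structure of a Bt-resistance mapping study in western corn
rootworm (WCR): three single-pair families founded by a resistant sire × a
susceptible dam, F1 sib-mating, and F2 eggs split between a Cry3Bb1-expressing
treatment and a near-isoline control with genotype-dependent viability at one
(optionally two) causal resistance loci. WCR has XO sex determination: males
carry a single X, so X-linked markers are hemizygous in males and the sex of
an offspring is decided by whether the paternal gamete carries an X.

Meiosis uses a no-interference (Poisson) crossover process, so the expected
recombinant fraction between two markers d cM apart is the inverse Haldane
map function (1 − e^(−2d/100))/2. Downstream map estimation reports Kosambi
distances; the mild mismatch between the generating and reporting map
functions is standard practice and noted in the docs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import DataError, ExtinctionError
from .markers import GenotypeMatrix, HEMI, MISSING

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T"), ("C", "G")]


# ---------------------------------------------------------------------------
# configuration / domain types
# ---------------------------------------------------------------------------

@dataclass
class SimGroup:
    group_id: str
    is_x: bool
    marker_ids: list[str]
    positions_cm: np.ndarray  # nondecreasing, from 0
    alleles: list[tuple[str, str]]

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclass
class SimMap:
    """True marker map used by the simulator: linkage groups with cM positions."""

    groups: list[SimGroup]

    def __post_init__(self):
        seen: set[str] = set()
        n_x = 0
        for g in self.groups:
            g.positions_cm = np.asarray(g.positions_cm, dtype=float)
            if g.n_markers < 2:
                raise DataError(f"group {g.group_id!r} has fewer than 2 markers")
            if np.any(np.diff(g.positions_cm) < 0):
                raise DataError(f"positions not nondecreasing in group {g.group_id!r}")
            for m in g.marker_ids:
                if m in seen:
                    raise DataError(f"duplicate marker_id {m!r}")
                seen.add(m)
            n_x += int(g.is_x)
        if n_x != 1:
            raise DataError(f"exactly one X group required (found {n_x})")

    @property
    def marker_ids(self) -> list[str]:
        return [m for g in self.groups for m in g.marker_ids]

    @property
    def n_markers(self) -> int:
        return sum(g.n_markers for g in self.groups)

    def group_of(self, marker_id: str) -> SimGroup:
        for g in self.groups:
            if marker_id in g.marker_ids:
                return g
        raise KeyError(marker_id)

    def marker_table(self) -> pd.DataFrame:
        """Marker metadata in the layout :class:`~wcrmap.markers.GenotypeMatrix` expects."""
        rows = []
        for g in self.groups:
            hint = "X" if g.is_x else g.group_id
            for mid, (a1, a2) in zip(g.marker_ids, g.alleles):
                rows.append((mid, a1, a2, hint))
        return pd.DataFrame(rows, columns=["marker_id", "allele1", "allele2", "group_hint"])


def make_sim_map(n_autosomes: int = 9, markers_per_group: int = 115,
                 group_length_cm: float = 230.0, x_markers: int | None = None,
                 x_length_cm: float | None = None) -> SimMap:
    """Build an evenly spaced map: ``n_autosomes`` autosomes plus one X group.

    Defaults emulate the study panel scale: 10 groups × 115 markers ≈ 1150
    SNPs spanning ≈ 2300 cM. Allele letter pairs cycle deterministically.
    """
    groups = []
    x_markers = markers_per_group if x_markers is None else x_markers
    x_length_cm = group_length_cm if x_length_cm is None else x_length_cm
    k = 0
    for a in range(n_autosomes):
        gid = f"LG{a + 1}"
        mids = [f"M{a + 1:02d}_{j + 1:03d}" for j in range(markers_per_group)]
        pos = np.linspace(0.0, group_length_cm, markers_per_group)
        alleles = [_ALLELE_PAIRS[(k + j) % len(_ALLELE_PAIRS)] for j in range(markers_per_group)]
        k += markers_per_group
        groups.append(SimGroup(gid, False, mids, pos, alleles))
    mids = [f"MX_{j + 1:03d}" for j in range(x_markers)]
    pos = np.linspace(0.0, x_length_cm, x_markers)
    alleles = [_ALLELE_PAIRS[(k + j) % len(_ALLELE_PAIRS)] for j in range(x_markers)]
    groups.append(SimGroup("X", True, mids, pos, alleles))
    return SimMap(groups)


@dataclass
class FitnessModel:
    """Genotype relative fitness on the Bt treatment at the causal locus.

    ``w_rr`` is the reference (1). An optional second, unlinked epistatic locus
    multiplies fitness (joint survival = w1(g1) × w2(g2)).
    """

    w_ss: float
    w_rs: float
    resistance_marker_id: str
    w_rr: float = 1.0
    epistatic_marker_id: str | None = None
    epistatic_w: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.w_rr != 1.0:
            raise DataError("w_rr is the fixed reference and must equal 1")
        for w in (self.w_ss, self.w_rs, *self.epistatic_w):
            if not 0.0 <= w <= 1.0:
                raise DataError(f"fitness {w} outside [0, 1]")

    def w(self) -> np.ndarray:
        return np.array([self.w_ss, self.w_rs, self.w_rr])


@dataclass
class CrossConfig:
    """Sizes, rates, and seed for one batch of simulated families."""

    n_families: int = 3
    n_f1: int = 200
    n_f2_treatment: int = 200  # eggs placed on the Bt treatment
    n_f2_control: int = 200   # eggs placed on the isoline control
    genotyping_error_rate: float = 0.02
    missing_rate: float = 0.05
    seed: int = 0
    expected_heterozygosity_min: float = 0.25

    def __post_init__(self):
        for name in ("n_families", "n_f1", "n_f2_treatment", "n_f2_control"):
            if getattr(self, name) < 1:
                raise DataError(f"{name} must be >= 1")
        for name in ("genotyping_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise DataError(f"{name} must be in [0, 1)")
        if not 0.0 <= self.expected_heterozygosity_min <= 0.5:
            raise DataError("expected_heterozygosity_min must be in [0, 0.5]")


@dataclass
class FieldPanelConfig:
    """Generative settings for a panel of field populations with bioassays."""

    n_populations: int = 80
    beta_a: float = 1.0
    beta_b: float = 1.0
    ld: float = 1.0                 # marker–causal-locus LD coefficient
    baseline_survival: float = 0.5  # control-substrate survival per larva
    dominance_h: float = 0.12       # heterozygote fitness on Bt (field scale)
    w_ss: float = 0.0               # susceptible-homozygote survival on Bt
    plant_replicates: int = 10
    plant_larvae: int = 30
    diet_plates: int = 6
    diet_wells: int = 12
    n_individuals_genotyped: int = 48
    seed: int = 0

    def __post_init__(self):
        if self.n_populations < 2:
            raise DataError("n_populations must be >= 2")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise DataError("Beta shape parameters must be positive")
        for name in ("ld", "dominance_h", "w_ss"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise DataError(f"{name} must be in [0, 1]")
        if not 0.0 < self.baseline_survival <= 1.0:
            raise DataError("baseline_survival must be in (0, 1]")
        for name in ("plant_replicates", "plant_larvae", "diet_plates", "diet_wells"):
            if getattr(self, name) < 1:
                raise DataError(f"{name} must be >= 1")


@dataclass
class ParentGenome:
    """Phased genome of one simulated individual: per-group haplotype arrays.

    Autosomes hold shape ``(2, m)`` arrays of allele indices; the X group holds
    ``(2, m)`` for females and ``(1, m)`` for males.
    """

    sex: str  # "M" | "F"
    haplotypes: dict[str, np.ndarray]


@dataclass
class CrossFamily:
    """One simulated single-pair family with all genotyped generations.

    ``truth`` maps matrix name → noise-free calls array, and
    ``truth_causal`` maps matrix name → true causal-genotype codes (0/1/2 =
    count of resistant alleles) for survivors; both exist for testing and are
    never written to output files.
    """

    family_id: str
    parents: GenotypeMatrix
    f1: GenotypeMatrix
    f2_treatment: GenotypeMatrix
    f2_control: GenotypeMatrix
    truth: dict[str, np.ndarray] = dc_field(default_factory=dict)
    truth_causal: dict[str, np.ndarray] = dc_field(default_factory=dict)

    def to_genotype_matrix(self) -> GenotypeMatrix:
        parts = [self.parents, self.f1, self.f2_treatment, self.f2_control]
        individuals = pd.concat([p.individuals for p in parts], ignore_index=True)
        calls = np.concatenate([p.calls for p in parts], axis=0)
        return GenotypeMatrix(individuals, self.parents.markers, calls)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _adjacent_rec_fractions(positions_cm: np.ndarray) -> np.ndarray:
    """Haldane inverse of adjacent intervals: r = (1 − e^(−2d/100)) / 2."""
    d = np.diff(positions_cm)
    if np.any(d < 0):
        raise DataError("negative inter-marker distance")
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def _gametes_from_pairs(haps: np.ndarray, positions_cm: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Vectorized meiosis for k individuals at once.

    ``haps`` has shape (k, 2, m): each row is one parent's phased pair for a
    group. Under no interference the transmitted haplotype index follows a
    two-state Markov chain along the group with switch probability equal to
    the Haldane inverse of the adjacent distance.
    """
    k, _, m = haps.shape
    r_adj = _adjacent_rec_fractions(positions_cm)
    start = rng.integers(0, 2, size=k)
    if m == 1:
        idx = start[:, None]
    else:
        switches = rng.random((k, m - 1)) < r_adj[None, :]
        idx = np.empty((k, m), dtype=np.int64)
        idx[:, 0] = start
        idx[:, 1:] = (start[:, None] + np.cumsum(switches, axis=1)) % 2
    return np.take_along_axis(haps, idx[:, None, :], axis=1)[:, 0, :]


def simulate_gamete(parent: ParentGenome, sim_map: SimMap,
                    rng: np.random.Generator, include_x: bool = True) -> dict[str, np.ndarray | None]:
    """Draw one gamete: per-group haplotypes of allele indices.

    Autosomes recombine by the no-interference process. For the X group a
    female parent recombines her two X's; a male parent contributes his single
    X haplotype without recombination when ``include_x`` (an X-bearing sperm)
    and ``None`` otherwise (a nullo-X sperm, yielding an XO son).
    """
    out: dict[str, np.ndarray | None] = {}
    for g in sim_map.groups:
        haps = parent.haplotypes.get(g.group_id)
        if haps is None or haps.shape[1] != g.n_markers:
            raise DataError(f"parent haplotypes do not cover group {g.group_id!r}")
        if g.is_x and parent.sex == "M":
            out[g.group_id] = haps[0].copy() if include_x else None
        else:
            out[g.group_id] = _gametes_from_pairs(haps[None, :, :], g.positions_cm, rng)[0]
    return out


# ---------------------------------------------------------------------------
# founders and families
# ---------------------------------------------------------------------------

def _founder_freq_bounds(he_min: float) -> tuple[float, float]:
    # 2p(1-p) >= he_min  <=>  p in [(1-s)/2, (1+s)/2], s = sqrt(1-2*he_min)
    s = float(np.sqrt(1.0 - 2.0 * he_min))
    return (1.0 - s) / 2.0, (1.0 + s) / 2.0


def _draw_founders(sim_map: SimMap, fitness: FitnessModel, he_min: float,
                   rng: np.random.Generator) -> tuple[ParentGenome, ParentGenome]:
    lo, hi = _founder_freq_bounds(he_min)
    forced = {fitness.resistance_marker_id}
    if fitness.epistatic_marker_id is not None:
        forced.add(fitness.epistatic_marker_id)
    sire_h: dict[str, np.ndarray] = {}
    dam_h: dict[str, np.ndarray] = {}
    for g in sim_map.groups:
        p = rng.uniform(lo, hi, size=g.n_markers)
        n_sire = 1 if g.is_x else 2
        sire = (rng.random((n_sire, g.n_markers)) < p).astype(np.int8)
        dam = (rng.random((2, g.n_markers)) < p).astype(np.int8)
        for mid in forced & set(g.marker_ids):
            j = g.marker_ids.index(mid)
            sire[:, j] = 1  # resistant allele is index 1 (sire strain)
            dam[:, j] = 0
        sire_h[g.group_id] = sire
        dam_h[g.group_id] = dam
    return ParentGenome("M", sire_h), ParentGenome("F", dam_h)


def _offspring_batch(fathers: list[ParentGenome], mothers: list[ParentGenome],
                     father_idx: np.ndarray, mother_idx: np.ndarray,
                     sim_map: SimMap, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate k offspring; returns (calls (k, m_total, 2), sexes (k,) of 'M'/'F').

    Sex is decided by the paternal gamete: an X-bearing sperm yields a
    daughter, a nullo-X sperm a son (XO). Call slot order is (paternal,
    maternal) for autosomes; X calls are (maternal, paternal-or-HEMI).
    """
    k = len(father_idx)
    sex_is_f = rng.random(k) < 0.5
    calls = np.empty((k, sim_map.n_markers, 2), dtype=np.int8)
    col = 0
    for g in sim_map.groups:
        m = g.n_markers
        mat_haps = np.stack([mothers[i].haplotypes[g.group_id] for i in mother_idx])
        mat_gam = _gametes_from_pairs(mat_haps, g.positions_cm, rng)
        if g.is_x:
            pat_x = np.stack([fathers[i].haplotypes[g.group_id][0] for i in father_idx])
            calls[:, col:col + m, 0] = mat_gam
            calls[:, col:col + m, 1] = np.where(sex_is_f[:, None], pat_x, HEMI)
        else:
            pat_haps = np.stack([fathers[i].haplotypes[g.group_id] for i in father_idx])
            pat_gam = _gametes_from_pairs(pat_haps, g.positions_cm, rng)
            calls[:, col:col + m, 0] = pat_gam
            calls[:, col:col + m, 1] = mat_gam
        col += m
    sexes = np.where(sex_is_f, "F", "M")
    return calls, sexes


def _calls_to_parent_genomes(calls: np.ndarray, sexes: np.ndarray,
                             sim_map: SimMap) -> list[ParentGenome]:
    """Reconstruct phased ParentGenomes from offspring call arrays.

    Valid because ``_offspring_batch`` writes calls in known phase order:
    slot 0 = paternal autosomal / maternal X, slot 1 = the other.
    """
    out = []
    for i in range(calls.shape[0]):
        haps: dict[str, np.ndarray] = {}
        col = 0
        male = sexes[i] == "M"
        for g in sim_map.groups:
            m = g.n_markers
            block = calls[i, col:col + m, :]
            if g.is_x and male:
                haps[g.group_id] = block[:, 0][None, :].copy()
            else:
                haps[g.group_id] = block.T.copy()
            col += m
        out.append(ParentGenome("M" if male else "F", haps))
    return out


def _apply_noise(calls: np.ndarray, error_rate: float, missing_rate: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Symmetric per-allele flips then missing-at-random per call."""
    noisy = calls.copy()
    valid = noisy != MISSING
    valid &= noisy != HEMI
    if error_rate > 0:
        flips = (rng.random(noisy.shape) < error_rate) & valid
        noisy[flips] = 1 - noisy[flips]
    if missing_rate > 0:
        drop = rng.random(noisy.shape[:2]) < missing_rate
        noisy[drop] = MISSING
    return noisy


def _causal_codes(calls: np.ndarray, sim_map: SimMap, marker_id: str) -> np.ndarray:
    j = sim_map.marker_ids.index(marker_id)
    c = calls[:, j, :]
    codes = (c[:, 0] == 1).astype(np.int8) + ((c[:, 1] == 1) & (c[:, 1] != HEMI)).astype(np.int8)
    return codes


def simulate_cross_family(config: CrossConfig, sim_map: SimMap, fitness: FitnessModel,
                          family_id: str = "fam1",
                          rng: np.random.Generator | None = None) -> CrossFamily:
    """Simulate one resistant-sire × susceptible-dam family end to end.

    Founders are drawn with per-marker allele frequencies inside the expected-
    heterozygosity floor, with the sire forced homozygous-resistant and the dam
    homozygous-susceptible at the causal locus. F1s come from the founder
    cross; F2 eggs from random F1 sib-mating are split into treatment and
    control arms, with treatment survival proportional to the causal-genotype
    fitness. Genotyping error and missingness are applied last (to F1/F2).
    """
    causal_group = sim_map.group_of(fitness.resistance_marker_id)
    if causal_group.is_x:
        raise DataError("resistance marker must be autosomal")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sire, dam = _draw_founders(sim_map, fitness, config.expected_heterozygosity_min, rng)
    markers = sim_map.marker_table()

    # F1
    f1_calls, f1_sexes = _offspring_batch([sire], [dam],
                                          np.zeros(config.n_f1, dtype=int),
                                          np.zeros(config.n_f1, dtype=int),
                                          sim_map, rng)
    f1_genomes = _calls_to_parent_genomes(f1_calls, f1_sexes, sim_map)
    f1_males = [i for i, s in enumerate(f1_sexes) if s == "M"]
    f1_females = [i for i, s in enumerate(f1_sexes) if s == "F"]
    if not f1_males or not f1_females:
        raise ExtinctionError("F1", f"family {family_id}: F1 lacks one sex entirely")

    # F2 eggs per arm
    def _arm(n_eggs: int, arm: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        fa = rng.choice(f1_males, size=n_eggs)
        mo = rng.choice(f1_females, size=n_eggs)
        calls, sexes = _offspring_batch(f1_genomes, f1_genomes, fa, mo, sim_map, rng)
        g1 = _causal_codes(calls, sim_map, fitness.resistance_marker_id)
        w = fitness.w()[g1]
        if fitness.epistatic_marker_id is not None:
            g2 = _causal_codes(calls, sim_map, fitness.epistatic_marker_id)
            w = w * np.asarray(fitness.epistatic_w)[g2]
        if arm == "treatment":
            keep = rng.random(n_eggs) < w
        else:
            keep = np.ones(n_eggs, dtype=bool)
        if not keep.any():
            raise ExtinctionError(arm, f"family {family_id}: no survivors in {arm} arm")
        return calls[keep], sexes[keep], g1[keep]

    t_calls, t_sexes, t_causal = _arm(config.n_f2_treatment, "treatment")
    c_calls, c_sexes, c_causal = _arm(config.n_f2_control, "control")

    def _individuals(prefix: str, sexes, generation: str, arm: str) -> pd.DataFrame:
        return pd.DataFrame({
            "id": [f"{family_id}-{prefix}{i + 1:04d}" for i in range(len(sexes))],
            "family": family_id, "generation": generation, "sex": sexes, "arm": arm,
        })

    # parents (noise-free calls)
    p_calls = np.empty((2, sim_map.n_markers, 2), dtype=np.int8)
    col = 0
    for g in sim_map.groups:
        m = g.n_markers
        sh, dh = sire.haplotypes[g.group_id], dam.haplotypes[g.group_id]
        if g.is_x:
            p_calls[0, col:col + m, 0] = sh[0]
            p_calls[0, col:col + m, 1] = HEMI
        else:
            p_calls[0, col:col + m, :] = sh.T
        p_calls[1, col:col + m, :] = dh.T
        col += m
    parents = GenotypeMatrix(
        pd.DataFrame({"id": [f"{family_id}-sire", f"{family_id}-dam"],
                      "family": family_id, "generation": "P",
                      "sex": ["M", "F"], "arm": "none"}),
        markers, p_calls)

    truth = {"f1": f1_calls, "f2_treatment": t_calls, "f2_control": c_calls}
    truth_causal = {"f2_treatment": t_causal, "f2_control": c_causal}

    e, miss = config.genotyping_error_rate, config.missing_rate
    f1 = GenotypeMatrix(_individuals("F1-", f1_sexes, "F1", "none"), markers,
                        _apply_noise(f1_calls, e, miss, rng))
    f2t = GenotypeMatrix(_individuals("T", t_sexes, "F2", "treatment"), markers,
                         _apply_noise(t_calls, e, miss, rng))
    f2c = GenotypeMatrix(_individuals("C", c_sexes, "F2", "control"), markers,
                         _apply_noise(c_calls, e, miss, rng))
    return CrossFamily(family_id, parents, f1, f2t, f2c, truth, truth_causal)


def simulate_families(config: CrossConfig, sim_map: SimMap,
                      fitness: FitnessModel) -> list[CrossFamily]:
    """Simulate ``config.n_families`` independent families from one seed."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_families)
    return [
        simulate_cross_family(config, sim_map, fitness, family_id=f"fam{i + 1}",
                              rng=np.random.default_rng(s))
        for i, s in enumerate(seeds)
    ]


# ---------------------------------------------------------------------------
# field panel
# ---------------------------------------------------------------------------

def simulate_field_panel(config: FieldPanelConfig, candidate_marker_ids: list[str]
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a panel of field populations with marker frequencies and bioassays.

    Per population the causal resistance-allele frequency is q ~ Beta(a, b);
    each candidate marker's allele frequency is LD·q + (1−LD)·(independent
    Beta(a, b) draw). Assuming Hardy–Weinberg genotype proportions within each
    population, per-larva survival on Bt is
    ``baseline · (q² + h·2q(1−q) + w_SS·(1−q)²)`` and ``baseline`` on control.
    Survivor counts are binomial per replicate (plant: larvae per replicate;
    diet: wells per plate, one replicate per plate).

    Returns ``(frequency table, bioassay table)``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_populations
    q = rng.beta(config.beta_a, config.beta_b, size=n)
    pops = [f"pop{j + 1:03d}" for j in range(n)]

    freq_rows = []
    for mid in candidate_marker_ids:
        indep = rng.beta(config.beta_a, config.beta_b, size=n)
        f = config.ld * q + (1.0 - config.ld) * indep
        for j in range(n):
            freq_rows.append((pops[j], mid, float(f[j]), config.n_individuals_genotyped))
    freq = pd.DataFrame(freq_rows,
                        columns=["population_id", "marker_id", "frequency", "n_genotyped"])

    h, wss, base = config.dominance_h, config.w_ss, config.baseline_survival
    p_bt = base * (q ** 2 + h * 2 * q * (1 - q) + wss * (1 - q) ** 2)
    rows = []
    for j in range(n):
        for i in range(config.plant_replicates):
            rows.append((pops[j], "plant", i + 1,
                         int(rng.binomial(config.plant_larvae, p_bt[j])),
                         int(rng.binomial(config.plant_larvae, base)),
                         config.plant_larvae))
        for i in range(config.diet_plates):
            rows.append((pops[j], "diet", i + 1,
                         int(rng.binomial(config.diet_wells, p_bt[j])),
                         int(rng.binomial(config.diet_wells, base)),
                         config.diet_wells))
    bioassay = pd.DataFrame(rows, columns=["population_id", "assay_type", "replicate",
                                           "trt", "ctl", "n_exposed"])
    return freq, bioassay
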