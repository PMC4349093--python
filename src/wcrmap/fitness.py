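"""Relative fitness, dominance, and assignment sampling error.

Because F2 eggs are randomized into the Bt treatment and the isoline control,
both arms start from the same genotype pool and the ratio of final genotype
frequencies (treatment / control) estimates viability selection directly:

    w_g = freq_treatment(g) / freq_control(g),  rescaled so max_g w_g = 1.

With the susceptible homozygote fitness near zero, the dominance of the
susceptible allele is h_S = 1 − mean(w_RS) across families. The Monte Carlo
routine quantifies how far apart the two arms' *initial* genotype frequencies
can drift by random assignment alone: a finite egg pool is drawn
multinomially and randomly partitioned into the two arm sizes, and the
per-genotype median absolute deviation of the frequency difference is
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import DataError

GENOTYPE_ORDER = ("SS", "RS", "RR")


@dataclass
class FitnessEstimate:
    w_ss: float
    w_rs: float
    w_rr: float
    n_treatment: int
    n_control: int
    marker_id: str = ""
    family_id: str = ""
    continuity_corrected: bool = False

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w_ss, self.w_rs, self.w_rr)


@dataclass
class DominanceEstimate:
    h_s: float
    w_rs_values: list[float]
    mean_w_ss: float
    valid: bool  # False when mean w_SS > 0.05 (h_S = 1 − mean w_RS no longer exact)


@dataclass
class MCResult:
    mad: np.ndarray  # per-genotype MAD of (treatment − control) frequency
    n_reps: int
    seed: int
    genotypes: tuple[str, ...] = GENOTYPE_ORDER


def estimate_relative_fitness(treatment_counts, control_counts,
                              continuity_correction: bool = False,
                              marker_id: str = "", family_id: str = "") -> FitnessEstimate:
    """Relative fitness (w_SS, w_RS, w_RR) from survivor genotype counts.

    Per-genotype fitness is the ratio of treatment to control genotype
    frequency, rescaled by the maximum so the fittest class (expected RR)
    equals 1. A zero control class leaves the ratio undefined and raises
    :class:`DataError` unless ``continuity_correction`` adds 0.5 to every
    cell of both arms (recorded on the estimate).
    """
    t = np.asarray(treatment_counts, dtype=float)
    c = np.asarray(control_counts, dtype=float)
    if t.shape != (3,) or c.shape != (3,):
        raise DataError("genotype counts must be length-3 (SS, RS, RR)")
    if t.sum() <= 0:
        raise DataError("treatment total must be positive")
    if np.any(c <= 0):
        if not continuity_correction:
            raise DataError(
                "control genotype class with zero count: frequency ratio undefined "
                "(pass continuity_correction=True to add 0.5 to every cell)")
        t = t + 0.5
        c = c + 0.5
    ratios = (t / t.sum()) / (c / c.sum())
    w = ratios / ratios.max()
    return FitnessEstimate(float(w[0]), float(w[1]), float(w[2]),
                           int(round(np.asarray(treatment_counts, dtype=float).sum())),
                           int(round(np.asarray(control_counts, dtype=float).sum())),
                           marker_id, family_id,
                           continuity_corrected=bool(continuity_correction and np.any(
                               np.asarray(control_counts, dtype=float) <= 0)))


def estimate_dominance(estimates: list[FitnessEstimate]) -> DominanceEstimate:
    """Dominance of the susceptible allele: h_S = 1 − mean(w_RS) over families.

    The identity assumes the susceptible homozygote fitness is ~0; the
    ``valid`` flag is set False when mean w_SS exceeds 0.05. The family mean
    is unweighted.
    """
    if not estimates:
        raise DataError("at least one fitness estimate required")
    for e in estimates:
        if e.w_rr != 1.0:
            raise DataError("each estimate must be normalized with w_RR = 1")
    w_rs = [e.w_rs for e in estimates]
    mean_w_ss = float(np.mean([e.w_ss for e in estimates]))
    return DominanceEstimate(1.0 - float(np.mean(w_rs)), w_rs, mean_w_ss,
                             valid=mean_w_ss <= 0.05)


def assignment_sampling_error_mc(pool_frequencies, n_treatment: int, n_control: int,
                                 n_reps: int = 10000, seed: int = 0) -> MCResult:
    """Monte Carlo sampling error of random egg assignment into two arms.

    Each replicate draws a finite pool of ``n_treatment + n_control``
    genotypes from ``pool_frequencies`` (multinomial) and randomly partitions
    it into the two arms (multivariate hypergeometric), recording the
    per-genotype frequency difference. The per-genotype median absolute
    deviation across replicates is returned. A finite-pool partition is used —
    not two independent multinomials — because the two arms share one egg
    pool.
    """
    p = np.asarray(pool_frequencies, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
        raise DataError("pool frequencies must be nonnegative and sum to 1")
    if n_reps < 1000:
        raise DataError("n_reps must be >= 1000")
    if n_treatment < 1 or n_control < 1:
        raise DataError("arm sizes must be >= 1")
    rng = np.random.default_rng(seed)
    n_total = n_treatment + n_control
    pools = rng.multinomial(n_total, p, size=n_reps)
    diffs = np.empty((n_reps, len(p)))
    for i in range(n_reps):
        t = rng.multivariate_hypergeometric(pools[i], n_treatment)
        c = pools[i] - t
        diffs[i] = t / n_treatment - c / n_control
    mad = np.median(np.abs(diffs), axis=0)
    return MCResult(mad, n_reps, seed)
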