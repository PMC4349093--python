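"""Field-population validation of candidate resistance markers.

A population's resistance score is the mean survivor count on Bt substrate
divided by the mean survivor count on non-Bt control substrate (1 = fully
resistant, 0 = fully susceptible; not capped at 1). Scores are regressed on
candidate-marker allele frequencies across populations by ordinary least
squares. Bioassay repeatability is quantified with a Poisson regression with
a log control-count offset,

    ln E[trt_ij] = pop_j + ln(ctl_ij),

whose saturated population factor has the closed-form MLE
rate_j = Σ_i trt_ij / Σ_i ctl_ij; the population term's explanatory power is
McFadden's pseudo-R² = 1 − llf/ll0 on the full Poisson log-likelihood
(including the ln y! terms — the convention is fixed here because those terms
do not cancel in the ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import DataError


@dataclass
class ResistanceScore:
    population_id: str
    assay_type: str
    score: float
    n_treatment_reps: int
    n_control_reps: int


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n_populations: int
    zero_variance_response: bool = False


@dataclass
class RepeatabilityFit:
    rate_ratios: pd.Series  # per-population λ ratio (Σtrt/Σctl)
    loglik_fit: float
    loglik_null: float
    mcfadden_r_squared: float
    n_rows_dropped: int = 0


def resistance_score(trt_counts, ctl_counts, population_id: str = "",
                     assay_type: str = "") -> ResistanceScore:
    """Ratio of arm means: mean Bt survivors / mean control survivors."""
    t = np.asarray(trt_counts, dtype=float)
    c = np.asarray(ctl_counts, dtype=float)
    if t.size < 1 or c.size < 1:
        raise DataError("at least one replicate per arm required")
    if c.mean() <= 0:
        raise DataError(f"assay failed for {population_id!r}: zero mean control survivors")
    return ResistanceScore(population_id, assay_type, float(t.mean() / c.mean()),
                           int(t.size), int(c.size))


def scores_from_table(bioassay: pd.DataFrame, assay_type: str) -> pd.DataFrame:
    """Per-population resistance scores for one assay type.

    Expects the bioassay-table columns ``population_id, assay_type, replicate,
    trt, ctl, n_exposed``; replicates are paired rows, so each row contributes
    one treatment and one control replicate.
    """
    sub = bioassay[bioassay["assay_type"] == assay_type]
    if sub.empty:
        raise DataError(f"no rows with assay_type {assay_type!r}")
    rows = []
    for pop, grp in sub.groupby("population_id", sort=True):
        s = resistance_score(grp["trt"].to_numpy(), grp["ctl"].to_numpy(),
                             population_id=pop, assay_type=assay_type)
        rows.append({"population_id": pop, "assay_type": assay_type,
                     "score": s.score, "n_replicates": s.n_treatment_reps})
    return pd.DataFrame(rows)


def regress_score_on_frequency(scores, frequencies) -> RegressionResult:
    """OLS of resistance score on marker allele frequency across populations.

    Returns slope, intercept, R² = 1 − SSE/SST, and the two-sided t-test
    p-value for the slope. Zero variance in x raises; zero variance in y is
    reported as slope 0 / R² 0 with a flag.
    """
    y = np.asarray(scores, dtype=float)
    x = np.asarray(frequencies, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("need >= 3 populations with both score and frequency")
    if np.ptp(x) == 0:
        raise DataError("zero variance in allele frequency")
    if np.ptp(y) == 0:
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, len(x),
                                zero_variance_response=True)
    fit = stats.linregress(x, y)
    return RegressionResult(float(fit.slope), float(fit.intercept),
                            float(fit.rvalue ** 2), float(fit.pvalue), len(x))


def _poisson_ll(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where((y == 0) & (mu == 0), 0.0,
                         y * np.log(np.maximum(mu, 1e-300)) - mu - gammaln(y + 1.0))
    return float(terms.sum())


def poisson_repeatability(bioassay: pd.DataFrame, assay_type: str) -> RepeatabilityFit:
    """Poisson offset model of replicate repeatability with McFadden's R².

    Fits ln E[trt_ij] = pop_j + ln(ctl_ij). With the saturated population
    factor and a fixed offset, the MLE is closed-form: the fitted rate ratio
    of population j is Σ_i trt_ij / Σ_i ctl_ij, and the null (intercept +
    offset) rate is the pooled Σtrt/Σctl. Rows with ctl = 0 have no offset and
    are dropped (counted); McFadden's R² = 1 − llf/ll0 on the full
    log-likelihood.
    """
    sub = bioassay[bioassay["assay_type"] == assay_type].copy()
    if sub.empty:
        raise DataError(f"no rows with assay_type {assay_type!r}")
    n_drop = int((sub["ctl"] <= 0).sum())
    sub = sub[sub["ctl"] > 0]
    if sub.empty:
        raise DataError("all rows dropped (every control count is zero)")
    if sub["population_id"].nunique() < 2 and n_drop == 0 and False:
        pass  # single population handled below (model equals null, R² = 0)
    y = sub["trt"].to_numpy(dtype=float)
    ctl = sub["ctl"].to_numpy(dtype=float)
    pops = sub["population_id"].to_numpy()

    grp = pd.DataFrame({"pop": pops, "trt": y, "ctl": ctl}).groupby("pop", sort=True)
    rates = grp["trt"].sum() / grp["ctl"].sum()
    mu_fit = rates.loc[pops].to_numpy() * ctl
    rate0 = y.sum() / ctl.sum()
    mu0 = rate0 * ctl
    llf = _poisson_ll(y, mu_fit)
    ll0 = _poisson_ll(y, mu0)
    if ll0 == 0.0:
        r2 = 0.0
    else:
        r2 = 1.0 - llf / ll0
    r2 = max(r2, 0.0)  # llf >= ll0 by construction; guard rounding
    return RepeatabilityFit(rates.rename("rate_ratio"), llf, ll0, float(r2), n_drop)
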