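"""χ² machinery and the three genome scans.

The selection scan contrasts genotype counts among Bt-treatment F2 survivors
against isoline-control F2 survivors with a Pearson χ² test of independence
per marker per family, Bonferroni-corrected over all tests performed. The
segregation-distortion scan checks control-arm counts against the Mendelian
expectation (1:2:1 intercross, 1:1 X backcross). The conditional epistasis
scan restricts treatment survivors to those heterozygous across a focal
interval — holding the mapped locus constant — and re-scans the rest of the
genome for additional loci.

Tail probabilities are computed in log space so that statistics far beyond
machine-precision tails (χ² ≈ 220 at 2 df → p ≈ 4×10⁻⁴⁹) retain at least two
significant figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConditioningError, DataError
from .linkmap import LinkageMap
from .markers import MISSING, CodedMatrix


@dataclass
class ScanConfig:
    alpha: float = 0.05
    df_for_threshold: int = 2
    min_expected_count: float = 0.0  # columns with totals this low are dropped

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise DataError("alpha must be in (0, 1)")


@dataclass
class ScanTestResult:
    marker_id: str
    family_id: str
    counts: np.ndarray  # 2×k retained table (rows: treatment, control)
    chi2: float
    df: int
    p: float
    group_id: str | None = None
    position_cm: float | None = None
    significant: bool = False


@dataclass
class ScanOutput:
    results: list[ScanTestResult]
    threshold: float
    n_tests: int
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append({
                "family_id": r.family_id, "marker_id": r.marker_id,
                "group": r.group_id if r.group_id is not None else "unmapped",
                "position_cM": r.position_cm, "counts": ";".join(
                    ",".join(str(int(x)) for x in row) for row in r.counts),
                "chi2": r.chi2, "df": r.df, "p": r.p, "significant": r.significant,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# χ² primitives
# ---------------------------------------------------------------------------

def chisq_pvalue(chi2: float, df: int) -> float:
    """Upper-tail χ² probability, accurate deep into the tail (log-space)."""
    if chi2 < 0 or df < 1:
        raise DataError("chi2 must be >= 0 and df >= 1")
    if chi2 == 0:
        return 1.0
    return float(np.exp(stats.chi2.logsf(chi2, df)))


def chisq_independence(table, min_expected_count: float = 0.0) -> tuple[float, int, float]:
    """Pearson χ² test of independence on a 2×k count table.

    Columns whose total is zero (or below ``min_expected_count``) are dropped
    and the degrees of freedom reduced accordingly; no continuity correction.
    Returns ``(chi2, df, p)``.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or np.any(t < 0):
        raise DataError("table must be 2×k with nonnegative counts")
    col_tot = t.sum(axis=0)
    keep = col_tot > max(0.0, min_expected_count - 1e-12) if min_expected_count > 0 \
        else col_tot > 0
    t = t[:, keep]
    if t.shape[1] < 2:
        raise DataError("degenerate table: fewer than 2 retained columns")
    n = t.sum()
    if n <= 0:
        raise DataError("degenerate table: zero grand total")
    exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    if np.any(exp.sum(axis=1) == 0):
        raise DataError("degenerate table: empty row")
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(exp > 0, (t - exp) ** 2 / exp, 0.0)
    chi2 = float(cells.sum())
    df = t.shape[1] - 1
    return chi2, df, chisq_pvalue(chi2, df)


def bonferroni_threshold(alpha: float, n_tests: int, df: int) -> float:
    """χ² statistic threshold controlling the familywise error at ``alpha``.

    The (1 − alpha/n_tests) quantile of χ² with ``df`` degrees of freedom;
    at df = 2 this is −2·ln(alpha/n_tests).
    """
    if n_tests < 1:
        raise DataError("n_tests must be >= 1")
    if alpha / n_tests >= 1:
        raise DataError("alpha/n_tests must be < 1")
    return float(stats.chi2.isf(alpha / n_tests, df))


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def _genotype_counts(codes: np.ndarray, k_classes: int) -> np.ndarray:
    valid = codes != MISSING
    return np.bincount(codes[valid].astype(int), minlength=k_classes)[:k_classes]


def _n_classes(design: str) -> int:
    return 3 if design == "F2_intercross" else 2


def resistance_scan(entries: list[tuple[str, CodedMatrix, CodedMatrix]],
                    linkage_map: LinkageMap | None = None,
                    config: ScanConfig | None = None) -> ScanOutput:
    """Treatment-vs-control genotype-frequency scan.

    ``entries`` are ``(family_id, treatment_coded, control_coded)`` triples;
    a family may contribute several entries (e.g. its autosomal intercross
    set and its X backcross set). One test is performed per marker per entry;
    the familywise Bonferroni threshold uses the total number of tests
    actually performed, at ``config.df_for_threshold`` degrees of freedom.
    Output is ordered by map position with unmapped markers last.
    """
    config = config or ScanConfig()
    results: list[ScanTestResult] = []
    for family_id, treat, ctrl in entries:
        if treat.marker_ids != ctrl.marker_ids:
            raise DataError("treatment and control arms must share the marker set")
        k = _n_classes(treat.design)
        for j, mid in enumerate(treat.marker_ids):
            t_counts = _genotype_counts(treat.codes[:, j], k)
            c_counts = _genotype_counts(ctrl.codes[:, j], k)
            table = np.vstack([t_counts, c_counts])
            try:
                chi2, df, p = chisq_independence(table, config.min_expected_count)
            except DataError:
                continue  # no informative data at this marker
            res = ScanTestResult(mid, family_id, table, chi2, df, p)
            if linkage_map is not None:
                loc = linkage_map.position_of(mid)
                if loc is not None:
                    res.group_id, res.position_cm = loc
            results.append(res)
    n_tests = len(results)
    if n_tests == 0:
        raise DataError("no testable markers")
    threshold = bonferroni_threshold(config.alpha, n_tests, config.df_for_threshold)
    for r in results:
        r.significant = r.chi2 >= threshold
    results.sort(key=lambda r: (r.group_id is None,
                                r.group_id or "", r.position_cm or 0.0, r.marker_id))
    return ScanOutput(results, threshold, n_tests, config.alpha)


def segregation_distortion_scan(control: CodedMatrix,
                                expected: tuple[float, ...] | None = None
                                ) -> pd.DataFrame:
    """Goodness-of-fit of control-arm genotype counts to Mendelian ratios.

    Defaults: 1:2:1 for the F2 intercross design, 1:1 for the backcross.
    Markers with zero non-missing counts are skipped (reported via the
    ``skipped`` attribute on the returned frame).
    """
    if expected is None:
        expected = (1, 2, 1) if control.design == "F2_intercross" else (1, 1)
    exp = np.asarray(expected, dtype=float)
    exp = exp / exp.sum()
    k = len(exp)
    rows, skipped = [], []
    for j, mid in enumerate(control.marker_ids):
        counts = _genotype_counts(control.codes[:, j], k)
        n = counts.sum()
        if n == 0:
            skipped.append(mid)
            continue
        chi2, df, p = goodness_of_fit(counts, exp)
        rows.append({"marker_id": mid, "counts": ",".join(map(str, counts)),
                     "chi2": chi2, "df": df, "p": p})
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    return out


def goodness_of_fit(counts, expected_proportions) -> tuple[float, int, float]:
    """Pearson goodness-of-fit χ² of observed counts against expected ratios."""
    obs = np.asarray(counts, dtype=float)
    prop = np.asarray(expected_proportions, dtype=float)
    prop = prop / prop.sum()
    n = obs.sum()
    if n <= 0:
        raise DataError("zero non-missing counts")
    exp = n * prop
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    df = len(obs) - 1
    return chi2, df, chisq_pvalue(chi2, df)


def conditional_epistasis_scan(treatment: CodedMatrix, control: CodedMatrix,
                               focal_marker_ids: list[str],
                               linkage_map: LinkageMap | None = None,
                               config: ScanConfig | None = None,
                               het_fraction: float = 1.0) -> ScanOutput:
    """Scan for additional loci after conditioning on the focal interval.

    Treatment survivors heterozygous at ≥ ``het_fraction`` of their
    non-missing focal-interval markers (default: all of them) are tested
    against the full control arm at every marker outside the focal interval.
    The conditioned subset size is exposed as ``n_conditioned`` on the result.
    """
    config = config or ScanConfig()
    if treatment.design != "F2_intercross":
        raise DataError("conditioning requires intercross-coded data (RS class)")
    focal_idx = []
    for m in focal_marker_ids:
        if m not in treatment.marker_ids:
            raise DataError(f"focal marker {m!r} absent from the treatment matrix")
        focal_idx.append(treatment.marker_ids.index(m))
    focal = treatment.codes[:, focal_idx]
    non_missing = (focal != MISSING).sum(axis=1)
    het = (focal == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(non_missing > 0, het / np.maximum(non_missing, 1), np.nan)
    keep = (non_missing > 0) & (frac >= het_fraction)
    if not keep.any():
        raise ConditioningError(
            "conditioning produced an empty treatment subset",
            diagnostics={
                "n_treatment": treatment.n_individuals,
                "n_with_focal_data": int((non_missing > 0).sum()),
                "het_fraction_required": het_fraction,
                "max_het_fraction_observed": float(np.nanmax(frac)) if np.isfinite(frac).any() else 0.0,
            })
    off = [m for m in treatment.marker_ids if m not in set(focal_marker_ids)]
    sub = CodedMatrix(treatment.individuals.iloc[np.flatnonzero(keep)].reset_index(drop=True),
                      off,
                      treatment.codes[np.ix_(np.flatnonzero(keep),
                                             [treatment.marker_ids.index(m) for m in off])],
                      treatment.design)
    ctrl_off = CodedMatrix(control.individuals, off,
                           control.codes[:, [control.marker_ids.index(m) for m in off]],
                           control.design)
    out = resistance_scan([("conditioned", sub, ctrl_off)], linkage_map, config)
    out.n_conditioned = int(keep.sum())  # type: ignore[attr-defined]
    return out
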