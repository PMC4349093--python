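"""Linkage-map construction from coded progeny genotypes.

Two-point recombination fractions are estimated per design: a direct count
for backcross-coded data and maximum likelihood by EM (over the
double-heterozygote phase ambiguity) for F2-intercross data. Markers are
grouped by single-linkage chaining on (LOD, r) thresholds, ordered within a
group by rapid chain delineation (RCD: grow a chain from the tightest-linked
pair, always appending the closest unplaced marker at either end), and placed
at cumulative Kosambi positions. Per-family component maps are merged into a
composite map through shared anchor markers.

For outbred founders the linkage phase of a heterozygous parent is unknown;
``phase_known=False`` estimators maximize over phase configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import DataError
from .markers import MISSING, CodedMatrix

_LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PairwiseLinkage:
    marker_pair: tuple[str, str]
    r_hat: float
    lod: float
    n_informative: int


@dataclass
class MapGroup:
    group_id: str
    marker_ids: list[str]
    positions_cm: np.ndarray

    def __post_init__(self):
        self.positions_cm = np.asarray(self.positions_cm, dtype=float)
        if len(self.marker_ids) != len(self.positions_cm):
            raise DataError("marker/position length mismatch")
        if len(self.positions_cm) and abs(self.positions_cm[0]) > 1e-9:
            raise DataError(f"group {self.group_id!r} does not start at 0")
        if np.any(np.diff(self.positions_cm) < -1e-9):
            raise DataError(f"positions not nondecreasing in group {self.group_id!r}")

    @property
    def length_cm(self) -> float:
        return float(self.positions_cm[-1]) if len(self.positions_cm) else 0.0


@dataclass
class LinkageMap:
    groups: list[MapGroup]
    provenance: str = "unknown"

    def __post_init__(self):
        seen: set[str] = set()
        for g in self.groups:
            for m in g.marker_ids:
                if m in seen:
                    raise DataError(f"marker {m!r} appears in more than one group")
                seen.add(m)

    @property
    def n_markers(self) -> int:
        return sum(len(g.marker_ids) for g in self.groups)

    def to_frame(self) -> pd.DataFrame:
        rows = [(m, g.group_id, p, self.provenance)
                for g in self.groups for m, p in zip(g.marker_ids, g.positions_cm)]
        return pd.DataFrame(rows, columns=["marker_id", "group_id", "position_cM", "provenance"])

    def position_of(self, marker_id: str) -> tuple[str, float] | None:
        for g in self.groups:
            if marker_id in g.marker_ids:
                return g.group_id, float(g.positions_cm[g.marker_ids.index(marker_id)])
        return None


@dataclass
class MapSummary:
    n_groups: int
    n_markers: int
    span_cm: float
    mean_spacing_cm: float
    warnings: list[str] = dc_field(default_factory=list)


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def haldane_cm(r) -> float | np.ndarray:
    """Haldane map distance d = −50·ln(1−2r) cM, for r in [0, 0.5)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise DataError("recombination fraction must be in [0, 0.5)")
    d = -50.0 * np.log(1.0 - 2.0 * r)
    return float(d) if d.ndim == 0 else d


def haldane_inverse(d) -> float | np.ndarray:
    """Inverse Haldane: r = (1 − e^(−2d/100))/2 for d ≥ 0 cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise DataError("map distance must be nonnegative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


def kosambi_cm(r) -> float | np.ndarray:
    """Kosambi map distance d = 25·ln((1+2r)/(1−2r)) cM, for r in [0, 0.5)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise DataError("recombination fraction must be in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d) -> float | np.ndarray:
    """Inverse Kosambi: r = 0.5·tanh(2d/100) for d ≥ 0 cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise DataError("map distance must be nonnegative")
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# two-point estimation
# ---------------------------------------------------------------------------

def _xlogy10(n, p):
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(n > 0, n * np.log10(np.maximum(p, 1e-300)), 0.0)
    return out


def _backcross_pair(c1: np.ndarray, c2: np.ndarray, phase_known: bool):
    valid = (c1 != MISSING) & (c2 != MISSING)
    n = int(valid.sum())
    if n < 2:
        raise DataError(f"fewer than 2 informative progeny (n={n})")
    rec = int(np.sum(c1[valid] != c2[valid]))
    if not phase_known:
        rec = min(rec, n - rec)
    r = min(rec / n, 0.5)
    n_r, n_p = rec, n - rec
    lod = float(_xlogy10(n_p, 2.0 * (1.0 - r)) + _xlogy10(n_r, 2.0 * r))
    return r, max(lod, 0.0), n


# F2 intercross cell machinery. Cells are the 3×3 genotype-code table in
# row-major order (code at marker 1, code at marker 2). Known recombinant
# gamete counts per cell under coupling; cell (1,1) is phase-ambiguous.
_R_KNOWN = np.array([0, 1, 2, 1, 0, 1, 2, 1, 0], dtype=float)
_AMB = 4  # flat index of the double-heterozygote cell


def _f2_cell_probs(r, phase: str = "cc") -> np.ndarray:
    """Genotype-class probabilities for an F2 pair; shape (..., 9).

    ``phase``: 'cc' both parents coupling, 'mixed' one coupling/one repulsion,
    'rr' both repulsion (equals 'cc' at 1−r).
    """
    r = np.asarray(r, dtype=float)
    u = (1.0 - r) / 2.0
    v = r / 2.0
    if phase == "rr":
        u, v = v, u
    if phase in ("cc", "rr"):
        cells = [u * u, 2 * u * v, v * v,
                 2 * u * v, 2 * u * u + 2 * v * v, 2 * u * v,
                 v * v, 2 * u * v, u * u]
    elif phase == "mixed":
        uv = u * v
        e = u * u + v * v
        cells = [uv, e, uv,
                 e, 4 * uv, e,
                 uv, e, uv]
    else:
        raise ValueError(phase)
    return np.stack([np.broadcast_to(c, r.shape) for c in cells], axis=-1)


def _em_f2(counts9: np.ndarray, tol: float = 1e-8, max_iter: int = 1000) -> np.ndarray:
    """Vectorized phase-known (coupling) EM for F2 intercross pairs.

    ``counts9`` has shape (..., 9); returns r̂ of shape (...).
    """
    counts9 = np.asarray(counts9, dtype=float)
    n_tot = counts9.sum(axis=-1)
    if np.any(n_tot < 2):
        raise DataError("fewer than 2 informative progeny")
    s_known = counts9 @ _R_KNOWN - 0.0 * counts9[..., _AMB]
    s_known = s_known - counts9[..., _AMB] * 0.0  # cell (1,1) has R_KNOWN 0 already
    n11 = counts9[..., _AMB]
    r = np.full(n_tot.shape, 0.25)
    for _ in range(max_iter):
        w = 2.0 * r * r / (r * r + (1.0 - r) ** 2)
        r_new = (s_known + n11 * w) / (2.0 * n_tot)
        r_new = np.clip(r_new, 0.0, 0.5)
        if np.max(np.abs(r_new - r)) < tol:
            r = r_new
            break
        r = r_new
    if not np.all(np.isfinite(r)):
        raise DataError("non-finite likelihood in EM")
    return r


def _f2_loglik(counts9: np.ndarray, r, phase: str = "cc") -> np.ndarray:
    p = _f2_cell_probs(r, phase)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.where(counts9 > 0, counts9 * np.log(np.maximum(p, 1e-300)), 0.0)
    return lp.sum(axis=-1)


def _counts9(c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
    valid = (c1 != MISSING) & (c2 != MISSING)
    a, b = c1[valid], c2[valid]
    out = np.zeros(9)
    np.add.at(out, a.astype(int) * 3 + b.astype(int), 1.0)
    return out


def _f2_pair_phase_unknown(counts9: np.ndarray):
    """Maximize the pair likelihood over the three distinct phase classes."""
    best = (-np.inf, 0.25, "cc")
    grid_cc = np.linspace(0.001, 0.999, 499)
    ll = _f2_loglik(counts9, grid_cc, "cc")
    i = int(np.argmax(ll))
    r_cc = grid_cc[i]
    if ll[i] > best[0]:
        best = (ll[i], r_cc, "cc")
    grid_m = np.linspace(0.001, 0.499, 250)
    ll_m = _f2_loglik(counts9, grid_m, "mixed")
    j = int(np.argmax(ll_m))
    if ll_m[j] > best[0]:
        best = (ll_m[j], grid_m[j], "mixed")
    # local refinement
    for _ in range(3):
        ll0, r0, ph = best
        lo, hi = max(r0 - 0.002, 1e-6), min(r0 + 0.002, 0.999 if ph == "cc" else 0.499)
        grid = np.linspace(lo, hi, 41)
        llg = _f2_loglik(counts9, grid, ph)
        k = int(np.argmax(llg))
        best = (max(llg[k], ll0), grid[k] if llg[k] >= ll0 else r0, ph)
    ll_max, r_raw, ph = best
    r_hat = min(r_raw, 1.0 - r_raw) if ph == "cc" else r_raw
    ll_null = _f2_loglik(counts9, 0.5, "cc")
    lod = max((ll_max - ll_null) / _LN10, 0.0)
    return min(r_hat, 0.5), float(lod)


def estimate_rec_fraction(codes1: np.ndarray, codes2: np.ndarray,
                          design: str = "F2_intercross", phase_known: bool = True,
                          marker_pair: tuple[str, str] = ("m1", "m2"),
                          tol: float = 1e-8) -> PairwiseLinkage:
    """Two-point recombination fraction and LOD for one marker pair.

    ``design='backcross'``: direct count r̂ = recombinants/n with
    LOD = n_p·log10(2(1−r̂)) + n_r·log10(2r̂). ``design='F2_intercross'``:
    maximum likelihood by EM over the double-heterozygote phase ambiguity
    (tolerance ``tol``, at most 1000 iterations, initialized at 0.25). With
    ``phase_known=False`` the likelihood is additionally maximized over
    parental phase configurations.
    """
    c1 = np.asarray(codes1, dtype=np.int8)
    c2 = np.asarray(codes2, dtype=np.int8)
    if design == "backcross":
        r, lod, n = _backcross_pair(c1, c2, phase_known)
        return PairwiseLinkage(marker_pair, r, lod, n)
    if design != "F2_intercross":
        raise DataError(f"unknown design {design!r}")
    counts = _counts9(c1, c2)
    n = int(counts.sum())
    if n < 2:
        raise DataError(f"fewer than 2 informative progeny (n={n})")
    if phase_known:
        r = float(_em_f2(counts[None, :], tol=tol)[0])
        ll = _f2_loglik(counts, r, "cc")
        ll_null = _f2_loglik(counts, 0.5, "cc")
        lod = max(float((ll - ll_null) / _LN10), 0.0)
    else:
        r, lod = _f2_pair_phase_unknown(counts)
    return PairwiseLinkage(marker_pair, min(r, 0.5), lod, n)


# ---------------------------------------------------------------------------
# vectorized pairwise matrices
# ---------------------------------------------------------------------------

def pairwise_linkage_matrix(coded: CodedMatrix, phase_known: bool = True,
                            min_informative: int = 2):
    """All-pairs (r, LOD, n) matrices for one coded design set.

    Returns three DataFrames indexed/columned by marker_id. Pairs with fewer
    than ``min_informative`` jointly genotyped progeny get NaN.
    """
    X = coded.codes
    mids = coded.marker_ids
    m = len(mids)
    if coded.design == "backcross":
        v = (X != MISSING)
        n_mat = (v.T.astype(float) @ v.astype(float))
        # recombinant counts: codes differ among jointly valid
        a = np.where(v, X, 0).astype(float)
        eq11 = a.T @ a                       # both code 1
        ones = v.astype(float)
        n1_i = (a.T @ ones)                  # row marker code 1, col valid
        n1_j = (ones.T @ a)
        eq00 = n_mat - n1_i - n1_j + eq11
        parental = eq00 + eq11
        rec = n_mat - parental
        if not phase_known:
            rec = np.minimum(rec, n_mat - rec)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(n_mat > 0, rec / np.maximum(n_mat, 1), np.nan)
        r = np.minimum(r, 0.5)
        lod = _xlogy10(n_mat - rec, 2.0 * (1.0 - r)) + _xlogy10(rec, 2.0 * r)
        lod = np.maximum(lod, 0.0)
    elif coded.design == "F2_intercross":
        masks = [(X == k) for k in (0, 1, 2)]
        counts = np.empty((m, m, 9))
        for aa in range(3):
            Ta = masks[aa].T.astype(float)
            for bb in range(3):
                counts[:, :, aa * 3 + bb] = Ta @ masks[bb].astype(float)
        n_mat = counts.sum(axis=-1)
        flat = counts.reshape(-1, 9)
        ok = flat.sum(axis=-1) >= 2
        r = np.full(m * m, np.nan)
        lod = np.zeros(m * m)
        if phase_known:
            r[ok] = _em_f2(flat[ok])
            ll = _f2_loglik(flat[ok], r[ok], "cc")
            ll0 = _f2_loglik(flat[ok], np.full(ok.sum(), 0.5), "cc")
            lod[ok] = np.maximum((ll - ll0) / _LN10, 0.0)
        else:
            r_ok, lod_ok = _f2_phase_unknown_batch(flat[ok])
            r[ok] = r_ok
            lod[ok] = lod_ok
        r = r.reshape(m, m)
        lod = lod.reshape(m, m)
    else:
        raise DataError(f"unknown design {coded.design!r}")
    bad = n_mat < min_informative
    r = np.where(bad, np.nan, r)
    lod = np.where(bad, 0.0, lod)
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(lod, 0.0)
    to_df = lambda a: pd.DataFrame(a, index=mids, columns=mids)
    return to_df(r), to_df(lod), to_df(n_mat)


def _f2_phase_unknown_batch(counts: np.ndarray):
    """Vectorized phase-maximized F2 estimates for many pairs at once."""
    P = counts.shape[0]
    grid_cc = np.linspace(0.001, 0.999, 200)
    grid_m = np.linspace(0.001, 0.499, 100)
    ll_cc = counts @ np.log(np.maximum(_f2_cell_probs(grid_cc, "cc"), 1e-300)).T
    ll_m = counts @ np.log(np.maximum(_f2_cell_probs(grid_m, "mixed"), 1e-300)).T
    best_cc = np.argmax(ll_cc, axis=1)
    best_m = np.argmax(ll_m, axis=1)
    use_m = ll_m[np.arange(P), best_m] > ll_cc[np.arange(P), best_cc]
    r0 = np.where(use_m, grid_m[best_m], grid_cc[best_cc])
    hi_cap = np.where(use_m, 0.499, 0.999)
    phase = np.where(use_m, "mixed", "cc")
    # two local refinement rounds around the incumbent
    for width in (0.005, 0.0005):
        offs = np.linspace(-width, width, 21)
        cand = np.clip(r0[:, None] + offs[None, :], 1e-6, hi_cap[:, None])
        ll_cand = np.empty_like(cand)
        for ph in ("cc", "mixed"):
            sel = phase == ph
            if sel.any():
                probs = _f2_cell_probs(cand[sel], ph)  # (p, 21, 9)
                ll_cand[sel] = np.einsum("pc,pgc->pg", counts[sel],
                                         np.log(np.maximum(probs, 1e-300)))
        r0 = np.take_along_axis(cand, np.argmax(ll_cand, axis=1)[:, None], axis=1)[:, 0]
    ll_max = np.empty(P)
    for ph in ("cc", "mixed"):
        sel = phase == ph
        if sel.any():
            ll_max[sel] = _f2_loglik(counts[sel], r0[sel], ph)
    r_hat = np.where(phase == "cc", np.minimum(r0, 1.0 - r0), r0)
    ll_null = _f2_loglik(counts, np.full(P, 0.5), "cc")
    lod = np.maximum((ll_max - ll_null) / _LN10, 0.0)
    return np.minimum(r_hat, 0.5), lod


# ---------------------------------------------------------------------------
# grouping and ordering
# ---------------------------------------------------------------------------

def group_markers(linkages: list[PairwiseLinkage], lod_min: float = 3.0,
                  r_max: float = 0.35) -> list[list[str]]:
    """Single-linkage grouping: chains of pairs with lod ≥ lod_min and r ≤ r_max.

    Returns groups (including singletons) as sorted marker lists, ordered by
    each group's smallest marker_id.
    """
    markers: set[str] = set()
    parent: dict[str, str] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for pl in linkages:
        for mk in pl.marker_pair:
            if mk not in parent:
                parent[mk] = mk
                markers.add(mk)
    for pl in linkages:
        if pl.lod >= lod_min and pl.r_hat <= r_max and np.isfinite(pl.r_hat):
            a, b = (find(m) for m in pl.marker_pair)
            if a != b:
                # union by smaller root id keeps find deterministic
                if a < b:
                    parent[b] = a
                else:
                    parent[a] = b
    groups: dict[str, list[str]] = {}
    for mk in markers:
        groups.setdefault(find(mk), []).append(mk)
    out = [sorted(v) for v in groups.values()]
    out.sort(key=lambda g: g[0])
    return out


def suggest_grouping_lod(n_markers: int, alpha: float = 0.05) -> float:
    """Bonferroni-scaled grouping LOD for a panel of ``n_markers`` markers.

    Converts a familywise α over all marker pairs into a LOD threshold via
    the χ²₁ quantile (LOD = χ²/(2·ln10)). With hundreds of markers the
    conventional LOD 3 admits occasional false links that chain distinct
    chromosomes together under single linkage; scaling with the number of
    pairs is standard practice in linkage-mapping packages.
    """
    from scipy import stats as _stats
    n_pairs = max(n_markers * (n_markers - 1) // 2, 1)
    return float(_stats.chi2.isf(alpha / n_pairs, 1) / (2.0 * np.log(10.0)))


def linkages_from_matrices(r_df: pd.DataFrame, lod_df: pd.DataFrame,
                           n_df: pd.DataFrame) -> list[PairwiseLinkage]:
    mids = list(r_df.index)
    out = []
    r = r_df.to_numpy()
    lod = lod_df.to_numpy()
    n = n_df.to_numpy()
    for i in range(len(mids)):
        for j in range(i + 1, len(mids)):
            out.append(PairwiseLinkage((mids[i], mids[j]), float(r[i, j]),
                                       float(lod[i, j]), int(n[i, j])))
    return out


def order_rcd(marker_ids: list[str], r_matrix: pd.DataFrame
              ) -> tuple[list[str], np.ndarray]:
    """Rapid chain delineation ordering with cumulative Kosambi positions.

    Seeds the chain with the minimal-r pair, then repeatedly appends — at
    whichever chain end is closer — the unplaced marker with minimal r to that
    end. Ties break by marker_id, then by preferring the right end, so an
    all-equal r matrix yields the lexicographically smallest chain. The final
    chain is oriented so its first marker_id precedes its last.
    """
    mids = sorted(marker_ids)
    if len(mids) < 2:
        raise DataError("group size must be >= 2")
    r = r_matrix.loc[mids, mids].to_numpy()
    iu = np.triu_indices(len(mids), k=1)
    if np.any(~np.isfinite(r[iu])):
        i, j = iu[0][~np.isfinite(r[iu])][0], iu[1][~np.isfinite(r[iu])][0]
        raise DataError(f"missing pairwise estimate {mids[i]!r}–{mids[j]!r} inside a group")
    idx = {m: i for i, m in enumerate(mids)}
    # seed pair: minimal r, ties by lexicographic pair
    pairs = sorted(
        ((r[idx[a], idx[b]], a, b) for ia, a in enumerate(mids) for b in mids[ia + 1:]),
        key=lambda t: (t[0], t[1], t[2]))
    _, a, b = pairs[0]
    chain = [a, b]
    unplaced = [m for m in mids if m not in (a, b)]
    while unplaced:
        left, right = chain[0], chain[-1]
        # (r, marker, end_rank): right end preferred on ties
        cands = []
        for m in unplaced:
            cands.append((r[idx[m], idx[right]], m, 0, "R"))
            cands.append((r[idx[m], idx[left]], m, 1, "L"))
        cands.sort(key=lambda t: (t[0], t[1], t[2]))
        _, m, _, end = cands[0]
        if end == "R":
            chain.append(m)
        else:
            chain.insert(0, m)
        unplaced.remove(m)
    if chain[-1] < chain[0]:
        chain.reverse()
    adj = np.array([min(r[idx[chain[k]], idx[chain[k + 1]]], 0.4999)
                    for k in range(len(chain) - 1)])
    positions = np.concatenate([[0.0], np.cumsum(kosambi_cm(adj))])
    return chain, positions


def sarf(order: list[str], r_matrix: pd.DataFrame) -> float:
    """Sum of adjacent recombination fractions for a candidate order."""
    return float(sum(r_matrix.loc[order[k], order[k + 1]] for k in range(len(order) - 1)))


# ---------------------------------------------------------------------------
# composite map merging
# ---------------------------------------------------------------------------

def _cluster_nodes(nodes):
    """Shared-anchor counts and connected components over >=2-anchor links."""
    marker_nodes: dict[str, list[int]] = {}
    for ni, node in enumerate(nodes):
        for mk in node["markers"]:
            marker_nodes.setdefault(mk, []).append(ni)
    shared: dict[tuple[int, int], int] = {}
    for mk, nis in marker_nodes.items():
        for i in range(len(nis)):
            for j in range(i + 1, len(nis)):
                key = (min(nis[i], nis[j]), max(nis[i], nis[j]))
                shared[key] = shared.get(key, 0) + 1
    n_nodes = len(nodes)
    adjacency: dict[int, list[int]] = {i: [] for i in range(n_nodes)}
    for (i, j), c in shared.items():
        if c >= 2:
            adjacency[i].append(j)
            adjacency[j].append(i)
    comp = [-1] * n_nodes
    n_comp = 0
    for i in range(n_nodes):
        if comp[i] < 0:
            stack = [i]
            comp[i] = n_comp
            while stack:
                u = stack.pop()
                for v in adjacency[u]:
                    if comp[v] < 0:
                        comp[v] = n_comp
                        stack.append(v)
            n_comp += 1
    return marker_nodes, shared, comp, n_comp


def merge_maps(maps: list[LinkageMap], on_unresolvable: str = "error") -> LinkageMap:
    """Merge component maps sharing anchor markers into a composite map.

    Component groups are clustered into composite groups via connections of
    ≥2 shared anchors (transitively). Within each composite group the group
    with the most markers is the reference; every other group is rescaled onto
    the reference frame by monotone piecewise-linear interpolation through the
    anchors it shares with an already-rescaled group (BFS from the reference).
    A marker's merged position is the mean of its rescaled positions; final
    order sorts by merged position (ties by reference order, then marker_id)
    and is re-zeroed to the minimum.

    ``on_unresolvable='error'`` (default) raises when a marker's groups fall
    in different composite clusters, or a group shares <2 anchors with the
    rest of its cluster. ``'drop'`` instead resolves conflicted markers by
    majority cluster and drops unanchorable groups — used when merging many
    sparse per-design component maps.
    """
    if on_unresolvable not in ("error", "drop"):
        raise ValueError(on_unresolvable)
    nodes = []
    for mi, lm in enumerate(maps):
        for g in lm.groups:
            nodes.append({"key": (mi, g.group_id), "markers": list(g.marker_ids),
                          "pos": list(np.asarray(g.positions_cm, dtype=float))})

    # sanitation loop: resolve cross-cluster markers, drop unanchorable groups
    while True:
        marker_nodes, shared, comp, n_comp = _cluster_nodes(nodes)
        changed = False
        for mk, nis in marker_nodes.items():
            comps = {comp[ni] for ni in nis}
            if len(comps) > 1:
                names = [nodes[ni]["key"] for ni in nis]
                if on_unresolvable == "error":
                    raise DataError(
                        f"marker {mk!r} maps to different groups across components: {names}")
                # keep the marker only in its majority cluster (ties: the
                # cluster holding more markers overall, then lower index)
                votes: dict[int, int] = {}
                for ni in nis:
                    votes[comp[ni]] = votes.get(comp[ni], 0) + 1
                sizes = {c: sum(len(nodes[i]["markers"])
                                for i in range(len(nodes)) if comp[i] == c)
                         for c in comps}
                best = sorted(comps, key=lambda c: (-votes[c], -sizes[c], c))[0]
                for ni in nis:
                    if comp[ni] != best:
                        k = nodes[ni]["markers"].index(mk)
                        nodes[ni]["markers"].pop(k)
                        nodes[ni]["pos"].pop(k)
                        changed = True
        if changed:
            nodes = [n for n in nodes if len(n["markers"]) >= 2]
            continue
        break

    merged_groups = []
    dropped: list[tuple] = []
    for ci in range(n_comp):
        members = [i for i in range(len(nodes)) if comp[i] == ci]
        members.sort(key=lambda i: (-len(nodes[i]["markers"]), nodes[i]["key"]))
        ref = members[0]
        rescaled: dict[int, dict[str, float]] = {
            ref: dict(zip(nodes[ref]["markers"], nodes[ref]["pos"]))
        }
        frontier = [ref]
        pending = set(members[1:])
        while frontier:
            nxt = []
            for u in sorted(pending):
                src = None
                for v in frontier:
                    key = (min(u, v), max(u, v))
                    if shared.get(key, 0) >= 2:
                        src = v
                        break
                if src is None:
                    continue
                upos = dict(zip(nodes[u]["markers"], nodes[u]["pos"]))
                anchors = [m for m in nodes[u]["markers"] if m in rescaled[src]]
                order = sorted(anchors, key=lambda m: upos[m])
                xp = np.array([upos[m] for m in order])
                fp = np.array([rescaled[src][m] for m in order])
                fp = np.maximum.accumulate(fp)  # keep the mapping monotone
                rescaled[u] = {
                    m: _interp_extrap(upos[m], xp, fp) for m in nodes[u]["markers"]
                }
                pending.discard(u)
                nxt.append(u)
            if not nxt:
                break
            frontier = list(rescaled)
        if pending:
            names = [nodes[i]["key"] for i in pending]
            if on_unresolvable == "error":
                raise DataError(f"groups share fewer than 2 anchors with the rest: {names}")
            dropped.extend(names)
            members = [i for i in members if i not in pending]

        all_markers = sorted({m for i in members for m in nodes[i]["markers"]})
        ref_order = {m: k for k, m in enumerate(nodes[ref]["markers"])}
        mean_pos = {}
        for m in all_markers:
            vals = [rescaled[i][m] for i in members if m in rescaled[i]]
            mean_pos[m] = float(np.mean(vals))
        ordered = sorted(all_markers,
                         key=lambda m: (mean_pos[m], ref_order.get(m, np.inf), m))
        pos = np.array([mean_pos[m] for m in ordered])
        pos = np.maximum.accumulate(pos) - pos.min()
        merged_groups.append((ordered, pos))

    merged_groups.sort(key=lambda t: t[0][0])
    groups = [MapGroup(f"C{k + 1}", mids, pos)
              for k, (mids, pos) in enumerate(merged_groups)]
    out = LinkageMap(groups, provenance="composite")
    out.dropped_groups = dropped  # type: ignore[attr-defined]
    return out


def _interp_extrap(x: float, xp: np.ndarray, fp: np.ndarray) -> float:
    """np.interp with linear extrapolation from the edge anchor segments."""
    if len(xp) == 1:
        return float(fp[0] + (x - xp[0]))
    if x < xp[0]:
        s = _edge_slope(xp, fp, 0)
        return float(fp[0] + s * (x - xp[0]))
    if x > xp[-1]:
        s = _edge_slope(xp, fp, -1)
        return float(fp[-1] + s * (x - xp[-1]))
    return float(np.interp(x, xp, fp))


def _edge_slope(xp, fp, end) -> float:
    if end == 0:
        dx, df = xp[1] - xp[0], fp[1] - fp[0]
    else:
        dx, df = xp[-1] - xp[-2], fp[-1] - fp[-2]
    return df / dx if dx > 0 else 1.0


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def map_summary(lm: LinkageMap) -> MapSummary:
    """Group/marker counts, total span, and mean adjacent spacing (1 d.p.).

    Mean spacing = span / (n_markers − n_groups), the number of adjacent
    intervals. Groups with fewer than 2 markers contribute no interval and are
    excluded with a warning.
    """
    warnings = []
    usable = []
    for g in lm.groups:
        if len(g.marker_ids) < 2:
            warnings.append(f"group {g.group_id!r} has <2 markers; spacing undefined")
        else:
            usable.append(g)
    n_groups = len(lm.groups)
    n_markers = lm.n_markers
    span = sum(g.length_cm for g in usable)
    n_int = sum(len(g.marker_ids) for g in usable) - len(usable)
    spacing = span / n_int if n_int > 0 else float("nan")
    return MapSummary(n_groups, n_markers, round(span, 1), round(spacing, 1), warnings)


def summary_from_counts(n_markers: int, n_groups: int, span_cm: float) -> MapSummary:
    """Summary arithmetic from already-tallied counts (no per-marker data)."""
    spacing = span_cm / (n_markers - n_groups)
    return MapSummary(n_groups, n_markers, round(span_cm, 1), round(spacing, 1), [])
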