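"""Drivers wiring classification, recoding, and map construction per family.

The mapping scheme for an outbred single-pair family produces up to five
component data sets:

* control-arm F2 progeny at F2-informative markers (standard intercross),
* control-arm F2 progeny at sex-linked markers (X backcross on the F1 female
  meiosis, dam allele recurrent),
* F1 progeny at sire-heterozygous markers (backcross on the sire meiosis),
* F1 progeny at dam-heterozygous markers (backcross on the dam meiosis),
* F1 progeny at both-parents-heterozygous markers (intercross, phase unknown).

Treatment-arm F2s are never used for map construction. Component maps are
merged into a composite through anchor markers shared across families and
designs (a marker heterozygous in one family's sire may be an opposite
homozygote pair in another family, linking the components).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import linkmap, markers
from .errors import DataError
from .markers import MISSING, CodedMatrix, GenotypeMatrix
from .simcross import CrossFamily


def family_from_genotype_matrix(gm: GenotypeMatrix, family_id: str) -> CrossFamily:
    """Split a combined genotype matrix back into one family's generations."""
    fam = gm.select(family=family_id)
    if fam.n_individuals == 0:
        raise DataError(f"no individuals for family {family_id!r}")
    return CrossFamily(
        family_id,
        fam.select(generation="P"),
        fam.select(generation="F1"),
        fam.select(generation="F2", arm="treatment"),
        fam.select(generation="F2", arm="control"),
    )


def _parent_calls(family: CrossFamily) -> tuple[dict, dict]:
    """marker_id → parental genotype tuple for sire and dam."""
    parents = family.parents
    sire_row = int(np.flatnonzero((parents.individuals["sex"] == "M").to_numpy())[0])
    dam_row = int(np.flatnonzero((parents.individuals["sex"] == "F").to_numpy())[0])
    sire, dam = {}, {}
    for j, mid in enumerate(parents.marker_ids):
        sire[mid] = markers._call_tuple(parents, sire_row, j)
        dam[mid] = markers._call_tuple(parents, dam_row, j)
    return sire, dam


def classify_family(family: CrossFamily) -> pd.DataFrame:
    """Classification report (marker_id, class, cross_subtype, reason)."""
    return markers.classify_markers(family.to_genotype_matrix(), family.family_id)


def _het_het_codes(progeny: GenotypeMatrix, marker_ids: list[str]) -> CodedMatrix:
    """Code het×het markers by the count of the declared second allele (0/1/2)."""
    cols = [progeny.marker_index(m) for m in marker_ids]
    codes = np.full((progeny.n_individuals, len(cols)), MISSING, dtype=np.int8)
    for k, j in enumerate(cols):
        calls = progeny.calls[:, j]
        valid = (calls[:, 0] != MISSING) & (calls[:, 1] != markers.HEMI)
        codes[valid, k] = (calls[valid, 0] == 1).astype(np.int8) + (calls[valid, 1] == 1)
    return CodedMatrix(progeny.individuals.copy(), list(marker_ids), codes, "F2_intercross")


def recode_design_sets(family: CrossFamily) -> dict[str, CodedMatrix]:
    """Recode each mapping design's marker set from the appropriate progeny."""
    cls = classify_family(family)
    sire, dam = _parent_calls(family)
    control = family.f2_control
    f1 = family.f1
    out: dict[str, CodedMatrix] = {}

    f2_mids = list(cls.loc[cls["class"] == "F2_informative", "marker_id"])
    if f2_mids:
        out["f2_intercross"] = markers.recode_f2_intercross(
            control, f2_mids,
            {m: sire[m][0] for m in f2_mids}, {m: dam[m][0] for m in f2_mids})

    x_mids = list(cls.loc[cls["class"] == "sex_linked_F2", "marker_id"])
    if x_mids:
        out["x_backcross"] = markers.recode_x_backcross(
            control, x_mids,
            {m: dam[m][0] for m in x_mids}, {m: sire[m][0] for m in x_mids})

    f1i = cls[cls["class"] == "F1_informative"]
    sire_mids = list(f1i.loc[f1i["cross_subtype"] == "het×hom", "marker_id"])
    if sire_mids:
        out["f1_sire_backcross"] = markers.recode_backcross_one_parent(
            f1, sire_mids, {m: sire[m] for m in sire_mids},
            {m: dam[m][0] for m in sire_mids})
    dam_mids = list(f1i.loc[f1i["cross_subtype"] == "hom×het", "marker_id"])
    if dam_mids:
        out["f1_dam_backcross"] = markers.recode_backcross_one_parent(
            f1, dam_mids, {m: dam[m] for m in dam_mids},
            {m: sire[m][0] for m in dam_mids})
    hh_mids = list(f1i.loc[f1i["cross_subtype"] == "het×het", "marker_id"])
    if hh_mids:
        out["f1_intercross"] = _het_het_codes(f1, hh_mids)
    return out


def recode_scan_sets(family: CrossFamily) -> list[tuple[CodedMatrix, CodedMatrix]]:
    """(treatment, control) coded pairs for the selection scan.

    Covers F2-informative autosomal markers (SS/RS/RR) and sex-linked markers
    (recurrent/nonrecurrent), both arms.
    """
    cls = classify_family(family)
    sire, dam = _parent_calls(family)
    pairs = []
    f2_mids = list(cls.loc[cls["class"] == "F2_informative", "marker_id"])
    if f2_mids:
        s_al = {m: sire[m][0] for m in f2_mids}
        d_al = {m: dam[m][0] for m in f2_mids}
        pairs.append((markers.recode_f2_intercross(family.f2_treatment, f2_mids, s_al, d_al),
                      markers.recode_f2_intercross(family.f2_control, f2_mids, s_al, d_al)))
    x_mids = list(cls.loc[cls["class"] == "sex_linked_F2", "marker_id"])
    if x_mids:
        d_al = {m: dam[m][0] for m in x_mids}
        s_al = {m: sire[m][0] for m in x_mids}
        pairs.append((markers.recode_x_backcross(family.f2_treatment, x_mids, d_al, s_al),
                      markers.recode_x_backcross(family.f2_control, x_mids, d_al, s_al)))
    return pairs


_DESIGN_PHASE = {
    "f2_intercross": ("F2_intercross", True),
    "x_backcross": ("backcross", True),
    "f1_sire_backcross": ("backcross", False),
    "f1_dam_backcross": ("backcross", False),
    "f1_intercross": ("F2_intercross", False),
}


def _rescue_small_groups(groups: list[list[str]], r_df, lod_df,
                         rescue_lod: float = 4.0, r_max: float = 0.35) -> list[list[str]]:
    """Attach small leftover groups to their tightest-linked larger group.

    Strict (pair-count-scaled) grouping occasionally splits a chromosome where
    a design set happens to be sparse. A second, permissive pass re-attaches
    each smaller group to the group holding its minimal-r partner among links
    with lod ≥ ``rescue_lod`` and r ≤ ``r_max``; repeated until stable.
    """
    groups = [sorted(g) for g in groups]
    changed = True
    while changed:
        changed = False
        groups.sort(key=lambda g: (len(g), g[0]))
        for gi, g in enumerate(groups):
            larger = [h for h in groups if (len(h), h[0]) > (len(g), g[0])]
            if not larger:
                continue
            # a candidate must show >=3 qualifying links from >=2 distinct
            # fragment markers — one chance link must never glue chromosomes;
            # among genuine candidates the tightest (min r) wins
            candidates = []
            for h in larger:
                rv = r_df.loc[g, h].to_numpy()
                lv = lod_df.loc[g, h].to_numpy()
                ok = (lv >= rescue_lod) & (rv <= r_max) & np.isfinite(rv)
                if ok.sum() >= 3 and (ok.any(axis=1).sum() >= 2):
                    candidates.append((float(rv[ok].min()), h))
            if candidates:
                candidates.sort(key=lambda t: (t[0], t[1][0]))
                candidates[0][1].extend(g)
                candidates[0][1].sort()
                groups.pop(gi)
                changed = True
                break
    groups.sort(key=lambda g: g[0])
    return groups


def build_component_maps(family: CrossFamily, lod_min: float | None = None,
                         r_max: float = 0.25,
                         grouping_alpha: float = 0.0033) -> list[linkmap.LinkageMap]:
    """Grouped, RCD-ordered component maps for every design set of one family.

    ``lod_min=None`` scales the grouping LOD to the number of marker pairs in
    each design set (never below the conventional 3), guarding single-linkage
    grouping against chance links among many unlinked pairs. Singleton groups
    cannot be ordered and are omitted from the maps.
    """
    sets = recode_design_sets(family)
    maps = []
    for name, coded in sets.items():
        if len(coded.marker_ids) < 2:
            continue
        _, phase_known = _DESIGN_PHASE[name]
        set_lod = (max(3.0, linkmap.suggest_grouping_lod(len(coded.marker_ids),
                                                         grouping_alpha))
                   if lod_min is None else lod_min)
        r_df, lod_df, n_df = linkmap.pairwise_linkage_matrix(coded, phase_known=phase_known)
        groups = linkmap.group_markers(
            linkmap.linkages_from_matrices(r_df, lod_df, n_df), set_lod, r_max)
        groups = _rescue_small_groups(groups, r_df, lod_df)
        map_groups = []
        gi = 0
        for g in groups:
            if len(g) < 2:
                continue
            gi += 1
            order, pos = linkmap.order_rcd(g, r_df)
            map_groups.append(linkmap.MapGroup(f"G{gi}", order, pos))
        if map_groups:
            maps.append(linkmap.LinkageMap(map_groups,
                                           provenance=f"{family.family_id}/{name}"))
    return maps


def build_composite_map(families: list[CrossFamily], lod_min: float | None = None,
                        r_max: float = 0.25) -> linkmap.LinkageMap:
    """Composite map from all component maps of all families."""
    component = []
    for fam in families:
        component.extend(build_component_maps(fam, lod_min, r_max))
    if not component:
        raise DataError("no component maps could be built")
    return linkmap.merge_maps(component, on_unresolvable="drop")
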