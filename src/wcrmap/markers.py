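"""Genotype containers, marker informativeness classification, and recoding.

An outbred single-pair cross (resistant sire × susceptible dam) yields three
usable marker classes with biallelic SNPs:

* ``F1_informative`` — at least one parent heterozygous; segregation is visible
  already in the F1 (subtypes het×hom, hom×het, het×het).
* ``F2_informative`` — parents are opposite homozygotes (AA × BB); every F1 is
  heterozygous and segregation appears only in the F2 (standard intercross).
* ``sex_linked_F2`` — X-linked marker with a homozygous dam and a hemizygous
  sire carrying the other allele; under XO sex determination the F2 follows a
  backcross design driven by the F1 female meiosis, with the dam allele as the
  recurrent allele and hemizygous F2 males recoded directly.

Genotype calls are stored as allele indices into each marker's declared
biallelic pair. Diploid calls occupy two slots; hemizygous male X calls carry
the :data:`HEMI` sentinel in the second slot; missing calls carry
:data:`MISSING` in both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

#: sentinel for a missing allele slot
MISSING = -9
#: sentinel marking the unused second slot of a hemizygous (male X) call
HEMI = -1

#: coded genotype values for the F2 intercross design
SS, RS, RR = 0, 1, 2
#: coded genotype values for the X backcross design
RECURRENT, NONRECURRENT = 0, 1

GENERATIONS = ("P", "F1", "F2")
ARMS = ("treatment", "control", "none")
SEXES = ("M", "F")


@dataclass
class GenotypeMatrix:
    """Individuals × markers diploid/hemizygous genotype calls.

    Parameters
    ----------
    individuals : DataFrame with columns ``id, family, generation, sex, arm``.
    markers : DataFrame with columns ``marker_id, allele1, allele2`` and an
        optional ``group_hint`` column (``"X"`` flags sex linkage).
    calls : int8 array of shape ``(n_individuals, n_markers, 2)`` holding
        allele indices 0/1, :data:`HEMI`, or :data:`MISSING`.
    """

    individuals: pd.DataFrame
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self):
        self.individuals = self.individuals.reset_index(drop=True)
        self.markers = self.markers.reset_index(drop=True)
        n_ind, n_mark = len(self.individuals), len(self.markers)
        if self.calls.shape != (n_ind, n_mark, 2):
            raise DataError(
                f"calls shape {self.calls.shape} does not match "
                f"{n_ind} individuals × {n_mark} markers"
            )
        ids = self.individuals["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise DataError(f"duplicate individual_id {dup!r}")
        if self.markers["marker_id"].duplicated().any():
            raise DataError("duplicate marker_id")

    # -- indexing helpers -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers["marker_id"])

    def marker_index(self, marker_id: str) -> int:
        idx = self.markers.index[self.markers["marker_id"] == marker_id]
        if len(idx) == 0:
            raise KeyError(marker_id)
        return int(idx[0])

    def subset(self, mask) -> "GenotypeMatrix":
        """Row-subset by a boolean mask or index array over individuals."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            mask = np.flatnonzero(mask)
        return GenotypeMatrix(
            self.individuals.iloc[mask].reset_index(drop=True),
            self.markers,
            self.calls[mask],
        )

    def select(self, generation=None, arm=None, sex=None, family=None) -> "GenotypeMatrix":
        m = np.ones(self.n_individuals, dtype=bool)
        if generation is not None:
            m &= (self.individuals["generation"] == generation).to_numpy()
        if arm is not None:
            m &= (self.individuals["arm"] == arm).to_numpy()
        if sex is not None:
            m &= (self.individuals["sex"] == sex).to_numpy()
        if family is not None:
            m &= (self.individuals["family"] == family).to_numpy()
        return self.subset(m)

    def call_str(self, i: int, j: int) -> str:
        """Render call (i, j) as ``"A/B"``, hemizygous ``"A"``, or ``"-"``."""
        a1, a2 = self.calls[i, j]
        if a1 == MISSING:
            return "-"
        alleles = (self.markers.iloc[j]["allele1"], self.markers.iloc[j]["allele2"])
        if a2 == HEMI:
            return alleles[a1]
        return f"{alleles[a1]}/{alleles[a2]}"


@dataclass
class MarkerClass:
    """Informativeness class of one marker given the parental genotypes."""

    marker_id: str
    cls: str  # F1_informative | F2_informative | sex_linked_F2 | uninformative
    cross_subtype: str | None = None
    reason: str | None = None


@dataclass
class CodedMatrix:
    """Progeny genotypes recoded for one mapping design.

    ``codes`` is an int8 array (individuals × markers): for the F2 intercross
    design values are SS=0, RS=1, RR=2; for the backcross design
    recurrent=0, nonrecurrent=1; missing is :data:`MISSING`.
    """

    individuals: pd.DataFrame
    marker_ids: list[str]
    codes: np.ndarray
    design: str  # "F2_intercross" | "backcross"
    warning_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def column(self, marker_id: str) -> np.ndarray:
        return self.codes[:, self.marker_ids.index(marker_id)]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _norm_genotype(g):
    """Normalize a parental genotype to a tuple of allele codes.

    Accepts ``("A", "B")``, ``"A/B"``, hemizygous ``"A"`` or ``("A",)``,
    and ``None``/``"-"`` for missing.
    """
    if g is None:
        return None
    if isinstance(g, str):
        if g in ("-", ""):
            return None
        parts = g.split("/")
        return tuple(parts)
    g = tuple(g)
    return g if g else None


def classify_marker(sire_genotype, dam_genotype, is_x_linked: bool = False) -> MarkerClass | tuple:
    """Classify a marker's informativeness from the two parental genotypes.

    Returns a :class:`MarkerClass` with ``marker_id`` left empty (callers fill
    it in); raises :class:`DataError` if the parents jointly carry more than
    two alleles (violating the biallelic contract) or if ploidies are
    inconsistent with the X flag.
    """
    sire = _norm_genotype(sire_genotype)
    dam = _norm_genotype(dam_genotype)
    if sire is None or dam is None:
        return MarkerClass("", "uninformative", None, "missing parental call")

    alleles = set(sire) | set(dam)
    if len(alleles) > 2:
        raise DataError(f"more than two alleles across parents: {sorted(alleles)}")

    if is_x_linked:
        if len(sire) != 1:
            raise DataError("sire must be hemizygous at an X-linked marker")
        if len(dam) != 2:
            raise DataError("dam must be diploid at an X-linked marker")
        if dam[0] == dam[1] and sire[0] != dam[0]:
            return MarkerClass("", "sex_linked_F2", "X_backcross", None)
        if dam[0] != dam[1]:
            return MarkerClass("", "uninformative", None,
                               "heterozygous dam at X marker (not used)")
        return MarkerClass("", "uninformative", None, "no segregating X allele")

    if len(sire) != 2 or len(dam) != 2:
        raise DataError("autosomal parental genotypes must be diploid")

    sire_het = sire[0] != sire[1]
    dam_het = dam[0] != dam[1]
    if sire_het and dam_het:
        return MarkerClass("", "F1_informative", "het×het", None)
    if sire_het:
        return MarkerClass("", "F1_informative", "het×hom", None)
    if dam_het:
        return MarkerClass("", "F1_informative", "hom×het", None)
    if sire[0] != dam[0]:
        return MarkerClass("", "F2_informative", "hom×hom-opposite", None)
    return MarkerClass("", "uninformative", None, "identical homozygous parents")


def classify_markers(gm: GenotypeMatrix, family: str) -> pd.DataFrame:
    """Classify every marker of one family from its P-generation calls.

    Returns a DataFrame ``marker_id, class, cross_subtype, reason``.
    """
    parents = gm.select(generation="P", family=family)
    sires = parents.subset((parents.individuals["sex"] == "M").to_numpy())
    dams = parents.subset((parents.individuals["sex"] == "F").to_numpy())
    if sires.n_individuals != 1 or dams.n_individuals != 1:
        raise DataError(
            f"family {family!r} must have exactly one sire and one dam "
            f"(found {sires.n_individuals}/{dams.n_individuals})"
        )
    is_x = _x_flags(gm.markers)
    rows = []
    for j, mid in enumerate(gm.marker_ids):
        sire_call = _call_tuple(sires, 0, j)
        dam_call = _call_tuple(dams, 0, j)
        mc = classify_marker(sire_call, dam_call, is_x_linked=bool(is_x[j]))
        rows.append((mid, mc.cls, mc.cross_subtype, mc.reason))
    return pd.DataFrame(rows, columns=["marker_id", "class", "cross_subtype", "reason"])


def _x_flags(markers: pd.DataFrame) -> np.ndarray:
    if "group_hint" in markers.columns:
        return (markers["group_hint"].astype(str) == "X").to_numpy()
    return np.zeros(len(markers), dtype=bool)


def _call_tuple(gm: GenotypeMatrix, i: int, j: int):
    a1, a2 = gm.calls[i, j]
    if a1 == MISSING:
        return None
    alleles = (gm.markers.iloc[j]["allele1"], gm.markers.iloc[j]["allele2"])
    if a2 == HEMI:
        return (alleles[a1],)
    return (alleles[a1], alleles[a2])


# ---------------------------------------------------------------------------
# recoding
# ---------------------------------------------------------------------------

def recode_f2_intercross(progeny: GenotypeMatrix, marker_ids, sire_alleles, dam_alleles) -> CodedMatrix:
    """Recode F2 progeny at F2-informative markers into SS/RS/RR.

    ``sire_alleles``/``dam_alleles`` map marker_id → the homozygous parental
    allele (R = sire allele, S = dam allele). Alleles not attributable to
    either parent (genotyping error) are set missing and counted per marker.
    """
    cols = [progeny.marker_index(m) for m in marker_ids]
    n = progeny.n_individuals
    codes = np.full((n, len(cols)), MISSING, dtype=np.int8)
    warnings: dict[str, int] = {}
    for k, (mid, j) in enumerate(zip(marker_ids, cols)):
        row = progeny.markers.iloc[j]
        pair = (row["allele1"], row["allele2"])
        r_allele = sire_alleles[mid]
        s_allele = dam_alleles[mid]
        if r_allele == s_allele:
            raise DataError(f"marker {mid!r} is not F2-informative (R == S allele)")
        r_idx = pair.index(r_allele)
        calls = progeny.calls[:, j]
        valid = calls[:, 0] != MISSING
        if np.any(valid & (calls[:, 1] == HEMI)):
            raise DataError(f"hemizygous call at autosomal marker {mid!r}")
        n_r = (calls[:, 0] == r_idx).astype(np.int8) + (calls[:, 1] == r_idx).astype(np.int8)
        codes[valid, k] = n_r[valid]  # 0=SS, 1=RS, 2=RR
        warnings[mid] = 0  # with biallelic calls every valid call is attributable
    return CodedMatrix(progeny.individuals.copy(), list(marker_ids), codes,
                       "F2_intercross", warnings)


def recode_x_backcross(progeny: GenotypeMatrix, marker_ids, dam_alleles, sire_alleles) -> CodedMatrix:
    """Recode F2 progeny at sex-linked markers into recurrent/nonrecurrent.

    The dam (maternal) allele is the recurrent allele. Females must be diploid
    and males hemizygous at every X marker; violations raise
    :class:`DataError`.
    """
    cols = [progeny.marker_index(m) for m in marker_ids]
    n = progeny.n_individuals
    codes = np.full((n, len(cols)), MISSING, dtype=np.int8)
    is_male = (progeny.individuals["sex"] == "M").to_numpy()
    warnings: dict[str, int] = {}
    for k, (mid, j) in enumerate(zip(marker_ids, cols)):
        row = progeny.markers.iloc[j]
        pair = (row["allele1"], row["allele2"])
        rec_idx = pair.index(dam_alleles[mid])
        calls = progeny.calls[:, j]
        valid = calls[:, 0] != MISSING
        hemi = calls[:, 1] == HEMI
        if np.any(valid & ~is_male & hemi):
            raise DataError(f"hemizygous call for a female at X marker {mid!r}")
        if np.any(valid & is_male & ~hemi):
            raise DataError(f"diploid call for a male at X marker {mid!r}")
        # males: single allele decides
        male_v = valid & is_male
        codes[male_v, k] = np.where(calls[male_v, 0] == rec_idx, RECURRENT, NONRECURRENT)
        # females: homozygous-recurrent vs heterozygous
        fem_v = valid & ~is_male
        both_rec = (calls[fem_v, 0] == rec_idx) & (calls[fem_v, 1] == rec_idx)
        het = calls[fem_v, 0] != calls[fem_v, 1]
        fem_codes = np.full(both_rec.shape, MISSING, dtype=np.int8)
        fem_codes[both_rec] = RECURRENT
        fem_codes[het] = NONRECURRENT
        # homozygous for the sire allele is impossible without error -> missing
        n_bad = int(np.sum(~both_rec & ~het))
        codes[fem_v, k] = fem_codes
        warnings[mid] = n_bad
    return CodedMatrix(progeny.individuals.copy(), list(marker_ids), codes,
                       "backcross", warnings)


def recode_backcross_one_parent(progeny: GenotypeMatrix, marker_ids,
                                het_parent_genotypes, hom_parent_alleles) -> CodedMatrix:
    """Recode progeny of a het×hom marker as a backcross on the het parent.

    At a marker where one parent is heterozygous (alleles a/b) and the other
    homozygous (say a/a), progeny are a/a or a/b: the code records which allele
    the heterozygous parent transmitted (0 if the allele shared with the
    homozygous parent, 1 otherwise). Progeny calls incompatible with the
    parents (e.g. b/b) are set missing and counted.
    """
    cols = [progeny.marker_index(m) for m in marker_ids]
    n = progeny.n_individuals
    codes = np.full((n, len(cols)), MISSING, dtype=np.int8)
    warnings: dict[str, int] = {}
    for k, (mid, j) in enumerate(zip(marker_ids, cols)):
        row = progeny.markers.iloc[j]
        pair = (row["allele1"], row["allele2"])
        hom = hom_parent_alleles[mid]
        hom_idx = pair.index(hom)
        other_idx = 1 - hom_idx
        calls = progeny.calls[:, j]
        valid = calls[:, 0] != MISSING
        hom_call = valid & (calls[:, 0] == hom_idx) & (calls[:, 1] == hom_idx)
        het_call = valid & (calls[:, 0] != calls[:, 1]) & (calls[:, 1] != HEMI)
        codes[hom_call, k] = 0
        codes[het_call, k] = 1
        bad = valid & ~hom_call & ~het_call
        codes[bad, k] = MISSING
        warnings[mid] = int(bad.sum())
        del other_idx
    return CodedMatrix(progeny.individuals.copy(), list(marker_ids), codes,
                       "backcross", warnings)


# ---------------------------------------------------------------------------
# allele frequency
# ---------------------------------------------------------------------------

def estimate_allele_frequency(gm: GenotypeMatrix, marker_id: str, target_allele: str,
                              ) -> tuple[float, int]:
    """Frequency of ``target_allele`` among non-missing calls at one marker.

    Hemizygous calls contribute one allele; diploid calls two. Returns
    ``(frequency, n_genotyped)`` where ``n_genotyped`` counts individuals.
    """
    j = gm.marker_index(marker_id)
    row = gm.markers.iloc[j]
    pair = (row["allele1"], row["allele2"])
    if target_allele not in pair:
        raise DataError(f"{target_allele!r} is not an allele of {marker_id!r}")
    t_idx = pair.index(target_allele)
    calls = gm.calls[:, j]
    valid = calls[:, 0] != MISSING
    if not valid.any():
        raise DataError(f"all calls missing at {marker_id!r}")
    hemi = valid & (calls[:, 1] == HEMI)
    dip = valid & ~hemi
    n_target = int(np.sum(calls[dip, 0] == t_idx) + np.sum(calls[dip, 1] == t_idx)
                   + np.sum(calls[hemi, 0] == t_idx))
    n_total = 2 * int(dip.sum()) + int(hemi.sum())
    return n_target / n_total, int(valid.sum())
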