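"""Delimited-text formats for genotype, map, bioassay, and frequency tables.

Everything is tab-separated plain text. Files begin with comment lines:
a header recording tool version, command, seed, and config hash, and (for
genotype tables) one ``#MARKER`` line per marker declaring its biallelic pair
and optional linkage-group hint (``X`` flags sex linkage). Readers reject
malformed content with the offending location rather than coercing it.

Genotype calls are encoded ``A/B`` (diploid), ``A`` (hemizygous male X), and
``-`` (missing).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import DataError
from .linkmap import LinkageMap, MapGroup
from .markers import HEMI, MISSING, GenotypeMatrix

_META_COLS = ["individual_id", "family", "generation", "sex", "arm"]
_BIOASSAY_COLS = ["population_id", "assay_type", "replicate", "trt", "ctl", "n_exposed"]
_FREQ_COLS = ["population_id", "marker_id", "frequency", "n_genotyped"]


def config_hash(config: dict) -> str:
    """Stable 8-hex digest of a config mapping (order-insensitive)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:8]


def file_header(command: str, seed=None, cfg_hash: str = "") -> str:
    parts = [f"# wcrmap {__version__}", f"command: {command}"]
    if seed is not None:
        parts.append(f"seed: {seed}")
    if cfg_hash:
        parts.append(f"config: {cfg_hash}")
    return " | ".join(parts)


# ---------------------------------------------------------------------------
# genotype table
# ---------------------------------------------------------------------------

def write_genotype_table(gm: GenotypeMatrix, path, command: str = "",
                         seed=None, cfg_hash: str = "") -> None:
    path = Path(path)
    lines = [file_header(command or "write-genotype-table", seed, cfg_hash)]
    for _, row in gm.markers.iterrows():
        hint = row["group_hint"] if "group_hint" in gm.markers.columns and pd.notna(row.get("group_hint")) else "."
        lines.append(f"#MARKER\t{row['marker_id']}\t{row['allele1']}\t{row['allele2']}\t{hint}")
    lines.append("\t".join(_META_COLS + gm.marker_ids))
    for i in range(gm.n_individuals):
        ind = gm.individuals.iloc[i]
        cells = [str(ind["id"]), str(ind["family"]), str(ind["generation"]),
                 str(ind["sex"]), str(ind["arm"])]
        cells.extend(gm.call_str(i, j) for j in range(gm.n_markers))
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")


def read_genotype_table(path) -> GenotypeMatrix:
    path = Path(path)
    text = path.read_text().splitlines()
    marker_rows = []
    header = None
    body_start = 0
    for ln, line in enumerate(text):
        if line.startswith("#MARKER"):
            parts = line.split("\t")
            if len(parts) < 4:
                raise DataError(f"{path.name}:{ln + 1}: malformed #MARKER line")
            hint = parts[4] if len(parts) > 4 and parts[4] != "." else None
            marker_rows.append((parts[1], parts[2], parts[3], hint))
        elif line.startswith("#"):
            continue
        else:
            header = line.split("\t")
            body_start = ln + 1
            break
    if header is None:
        raise DataError(f"{path.name}: no header")
    if header[:5] != _META_COLS:
        raise DataError(f"{path.name}: header must start with {_META_COLS}")
    marker_ids = header[5:]
    declared = {m[0]: m for m in marker_rows}
    for mid in marker_ids:
        if mid not in declared:
            raise DataError(f"{path.name}: marker {mid!r} has no #MARKER declaration")
    markers_df = pd.DataFrame(
        [declared[m] for m in marker_ids],
        columns=["marker_id", "allele1", "allele2", "group_hint"])
    x_flags = (markers_df["group_hint"].astype(str) == "X").to_numpy()

    ind_rows = []
    calls = np.full((len(text) - body_start, len(marker_ids), 2), MISSING, dtype=np.int8)
    n_ind = 0
    for ln in range(body_start, len(text)):
        line = text[ln]
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 5 + len(marker_ids):
            raise DataError(f"{path.name}:{ln + 1}: expected {5 + len(marker_ids)} columns, "
                            f"found {len(parts)}")
        ind_rows.append(dict(zip(["id", "family", "generation", "sex", "arm"], parts[:5])))
        sex = parts[3]
        for j, cell in enumerate(parts[5:]):
            a = _parse_call(cell, markers_df.iloc[j], path.name, ln + 1, j)
            if a is None:
                continue
            if len(a) == 1:
                if sex != "M" or not x_flags[j]:
                    raise DataError(
                        f"{path.name}:{ln + 1}: hemizygous call {cell!r} at "
                        f"marker {marker_ids[j]!r} for a non-male or non-X marker")
                calls[n_ind, j] = (a[0], HEMI)
            else:
                if sex == "M" and x_flags[j]:
                    raise DataError(
                        f"{path.name}:{ln + 1}: diploid call {cell!r} for a male at "
                        f"X marker {marker_ids[j]!r}")
                calls[n_ind, j] = a
        n_ind += 1
    individuals = pd.DataFrame(ind_rows, columns=["id", "family", "generation", "sex", "arm"])
    return GenotypeMatrix(individuals, markers_df, calls[:n_ind])


def _parse_call(cell: str, marker_row, fname: str, line_no: int, col: int):
    if cell == "-":
        return None
    pair = (marker_row["allele1"], marker_row["allele2"])
    alleles = cell.split("/")
    if len(alleles) not in (1, 2):
        raise DataError(f"{fname}:{line_no}: malformed call {cell!r} (column {col + 6})")
    idx = []
    for a in alleles:
        if a not in pair:
            raise DataError(
                f"{fname}:{line_no}: allele {a!r} not in declared pair {pair} for "
                f"marker {marker_row['marker_id']!r} (column {col + 6})")
        idx.append(pair.index(a))
    return tuple(idx)


# ---------------------------------------------------------------------------
# map table
# ---------------------------------------------------------------------------

def write_map_table(lm: LinkageMap, path, command: str = "", seed=None,
                    cfg_hash: str = "") -> None:
    path = Path(path)
    lines = [file_header(command or "write-map-table", seed, cfg_hash),
             "\t".join(["marker_id", "group_id", "position_cM", "provenance"])]
    for g in lm.groups:
        for m, p in zip(g.marker_ids, g.positions_cm):
            lines.append(f"{m}\t{g.group_id}\t{p:.6g}\t{lm.provenance}")
    path.write_text("\n".join(lines) + "\n")


def read_map_table(path) -> LinkageMap:
    path = Path(path)
    rows = []
    header = None
    for ln, line in enumerate(path.read_text().splitlines()):
        if line.startswith("#") or not line.strip():
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            if header != ["marker_id", "group_id", "position_cM", "provenance"]:
                raise DataError(f"{path.name}: unexpected map header {header}")
            continue
        if len(parts) != 4:
            raise DataError(f"{path.name}:{ln + 1}: expected 4 columns")
        try:
            pos = float(parts[2])
        except ValueError:
            raise DataError(f"{path.name}:{ln + 1}: non-numeric position {parts[2]!r}")
        rows.append((parts[0], parts[1], pos, parts[3]))
    if header is None:
        raise DataError(f"{path.name}: no header")
    groups: dict[str, list[tuple[str, float]]] = {}
    prov = rows[0][3] if rows else "unknown"
    for mid, gid, pos, _ in rows:
        groups.setdefault(gid, []).append((mid, pos))
    map_groups = []
    for gid, items in groups.items():
        positions = np.array([p for _, p in items])
        if np.any(np.diff(positions) < 0):
            raise DataError(f"{path.name}: non-monotone positions in group {gid!r}")
        map_groups.append(MapGroup(gid, [m for m, _ in items], positions - positions[0]
                                   if len(positions) and positions[0] != 0 else positions))
    return LinkageMap(map_groups, provenance=prov)


# ---------------------------------------------------------------------------
# bioassay and frequency tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, command: str = "", seed=None,
                cfg_hash: str = "") -> None:
    """Write any tabular output with the standard comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(file_header(command or "write-table", seed, cfg_hash) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_bioassay_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _BIOASSAY_COLS if c not in df.columns]
    if missing:
        raise DataError(f"bioassay table missing columns {missing}")
    if (df["trt"] < 0).any() or (df["ctl"] < 0).any():
        raise DataError("negative survivor counts")
    if (df["trt"] > df["n_exposed"]).any() or (df["ctl"] > df["n_exposed"]).any():
        raise DataError("survivor count exceeds number exposed")
    dup = df.duplicated(subset=["population_id", "assay_type", "replicate"])
    if dup.any():
        row = df[dup].iloc[0]
        raise DataError(f"duplicate replicate {row['replicate']} for "
                        f"{row['population_id']}/{row['assay_type']}")
    return df[_BIOASSAY_COLS]


def read_frequency_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _FREQ_COLS if c not in df.columns]
    if missing:
        raise DataError(f"frequency table missing columns {missing}")
    if ((df["frequency"] < 0) | (df["frequency"] > 1)).any():
        raise DataError("allele frequency outside [0, 1]")
    return df[_FREQ_COLS]
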