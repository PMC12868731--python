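"""Readers and writers for the pipeline's tabular formats.

All tabular files are UTF-8 TSV with a header row; gene sets use the GMT
interchange format (name, description, then member genes, tab-separated).
Readers validate structure (duplicate ids, ragged rows, non-integer counts)
and report the offending line where possible; write/read round-trips are
identity on valid data.  CRLF and LF line endings parse identically.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "read_counts", "write_counts",
    "read_clinical", "write_clinical",
    "read_genus", "write_genus",
    "read_pairing", "write_pairing",
    "read_gmt", "write_gmt",
    "write_distance", "read_distance",
]


def _read_table(path, index_col: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={index_col: str})
    except pd.errors.ParserError as exc:
        raise DataError(f"{path.name}: malformed TSV ({exc})") from exc
    if df.columns[0] != index_col:
        raise DataError(
            f"{path.name}: first column must be {index_col!r}, got {df.columns[0]!r}"
        )
    df = df.set_index(index_col)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        line = int(np.where(df.index == dup)[0][1]) + 2  # header is line 1
        raise DataError(f"{path.name}: duplicate {index_col} {dup!r} at line {line}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise DataError(f"{path.name}: duplicate sample id {dup!r}")
    return df


def _validate_count_values(df: pd.DataFrame, path, kind: str) -> pd.DataFrame:
    values = df.to_numpy()
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy() & ~pd.isna(values))
    if bad.size:
        r, c = bad[0]
        raise DataError(
            f"{Path(path).name}: non-numeric {kind} count at line {r + 2}, "
            f"column {df.columns[c]!r}: {values[r, c]!r}"
        )
    arr = numeric.to_numpy(dtype=float)
    frac = np.argwhere(arr != np.floor(arr))
    if frac.size:
        r, c = frac[0]
        raise DataError(
            f"{Path(path).name}: non-integer {kind} count at line {r + 2}, "
            f"column {df.columns[c]!r}: {arr[r, c]!r}"
        )
    neg = np.argwhere(arr < 0)
    if neg.size:
        r, c = neg[0]
        raise DataError(
            f"{Path(path).name}: negative {kind} count at line {r + 2}, "
            f"column {df.columns[c]!r}"
        )
    out = numeric.astype(np.int64)
    out.index.name = df.index.name
    return out


def read_counts(path) -> pd.DataFrame:
    """Gene x sample integer count matrix (first column ``gene_id``)."""
    df = _read_table(path, "gene_id")
    return _validate_count_values(df, path, "gene")


def write_counts(counts: pd.DataFrame, path) -> None:
    out = counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_genus(path) -> pd.DataFrame:
    """Genus x sample integer count matrix (first column ``genus``)."""
    df = _read_table(path, "genus")
    return _validate_count_values(df, path, "genus")


def write_genus(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "genus"
    out.to_csv(path, sep="\t")


_CLINICAL_REQUIRED = ("time_rfs", "event_rfs", "time_os", "event_os")


def read_clinical(path) -> pd.DataFrame:
    """Per-patient survival endpoints and covariates (``patient_id`` keyed)."""
    df = _read_table(path, "patient_id")
    missing = [c for c in _CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise DataError(f"{Path(path).name}: missing clinical columns {missing}")
    for col in _CLINICAL_REQUIRED:
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in ("event_rfs", "event_os"):
        bad = ~df[col].isin([0, 1])
        if bad.any():
            line = int(np.where(bad)[0][0]) + 2
            raise DataError(f"{Path(path).name}: {col} must be 0/1 (line {line})")
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    out = clinical.copy()
    out.index.name = "patient_id"
    out.to_csv(path, sep="\t")


def read_pairing(path) -> pd.DataFrame:
    """Sample sidecar: ``sample_id, patient_id, tissue`` (+ optional group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample_id", "patient_id", "tissue"}
    if not need <= set(df.columns):
        raise DataError(
            f"{Path(path).name}: pairing needs columns {sorted(need)}"
        )
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise DataError(f"{Path(path).name}: duplicate sample_id {dup!r}")
    return df


def write_pairing(pairing: pd.DataFrame, path) -> None:
    pairing.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{Path(path).name}: GMT line {lineno} has "
                    f"{len(fields)} fields (need >= 3)"
                )
            name = fields[0]
            if name in sets:
                raise DataError(f"{Path(path).name}: duplicate gene set {name!r}")
            members = [g for g in fields[2:] if g]
            if not members:
                raise DataError(f"{Path(path).name}: gene set {name!r} is empty")
            if len(members) != len(set(members)):
                raise DataError(f"{Path(path).name}: duplicate members in {name!r}")
            sets[name] = members
    if not sets:
        raise DataError(f"{Path(path).name}: no gene sets found")
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "nbtsig") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def write_distance(dist: pd.DataFrame, path) -> None:
    out = dist.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_distance(path) -> pd.DataFrame:
    df = _read_table(path, "sample_id")
    return df.astype(float)
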