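"""TSV input/output with provenance headers and schema validation."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .exceptions import SchemaError
from .processing import SPOT_COLUMNS, ProcessedIntensityMatrix

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_json",
    "load_spot_table",
    "load_matrix",
]


def _header_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def write_tsv(
    frame: pd.DataFrame,
    path: str | Path,
    provenance: dict | None = None,
    index: bool = True,
) -> Path:
    """Write a TSV with '#'-prefixed provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(provenance))
        frame.to_csv(fh, sep="\t", index=index)
    return path


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv`, skipping provenance lines."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def load_spot_table(path: str | Path) -> pd.DataFrame:
    """Load and validate a spot-level raw intensity table.

    Requires the full spot schema, numeric non-negative intensities and no
    duplicated (sample, antibody, dilution, replicate) keys; violations
    are reported with 1-based data line numbers.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    bad = pd.to_numeric(df["intensity"], errors="coerce").isna() & df["intensity"].notna()
    bad |= df["intensity"].isna()
    if bad.any():
        lines = (df.index[bad] + 1).tolist()
        raise SchemaError(f"{path}: non-numeric intensity at data line(s) {lines[:10]}")
    df["intensity"] = pd.to_numeric(df["intensity"])
    if (df["intensity"] < 0).any():
        lines = (df.index[df["intensity"] < 0] + 1).tolist()
        raise SchemaError(f"{path}: negative intensity at data line(s) {lines[:10]}")
    key = ["sample_id", "antibody_id", "dilution_step", "technical_replicate"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        lines = (df.index[dup] + 1).tolist()
        raise SchemaError(f"{path}: duplicated spot key at data line(s) {lines[:10]}")
    return df


def load_matrix(
    path: str | Path, platform_id: str = "", method: str = ""
) -> ProcessedIntensityMatrix:
    """Load a processed intensity matrix TSV (first column sample_id)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.columns[0] != "sample_id":
        raise SchemaError(f"{path}: first column must be 'sample_id'")
    df = df.set_index("sample_id")
    values = df.apply(pd.to_numeric, errors="coerce")
    qc = pd.DataFrame("", index=values.index, columns=values.columns)
    return ProcessedIntensityMatrix(
        values=values, platform_id=platform_id, method=method, qc=qc
    )
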