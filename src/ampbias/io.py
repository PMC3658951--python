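"""Tabular interchange: validated TSV readers/writers and run configuration.

All files are tab-separated UTF-8 with a mandatory header row, '.' decimal
and '#' comment lines.  Binary chip formats are out of scope: an external
converter is expected to produce the long probe table (one row per probe
per sample) before this package is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "read_probe_table",
    "write_probe_table",
    "read_ct_table",
    "read_annotation",
    "load_config",
    "RunConfig",
]

PROBE_COLUMNS = ["sample_id", "probeset_id", "probe_id", "z", "pm"]
OPTIONAL_PROBE_COLUMNS = ["mm", "present"]
CT_COLUMNS = ["transcript_id", "amplicon_id", "start_5prime", "sample", "ct"]
ANNOTATION_COLUMNS = ["probeset_id", "probe_id", "z", "L"]


class SchemaError(ValueError):
    """Input table is missing required columns."""


def _read_tsv(path, required: list[str], label: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: {label} table is missing columns {missing}")
    return df


def read_probe_table(
    path, L: float | None = None, strict: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a long-format probe table.

    Rows with negative PM (or MM) or positions outside ``[0, L]`` are
    rejected; returns ``(valid_rows, rejected_rows)`` where the rejected
    frame carries the 1-based data line number and a reason.  With
    ``strict=True`` any rejected row raises instead.
    """
    df = _read_tsv(path, PROBE_COLUMNS, "probe")
    reasons = pd.Series("", index=df.index)
    bad = df["pm"].isna() | (df["pm"] < 0)
    reasons[bad] = "negative or missing pm"
    if "mm" in df.columns:
        bad_mm = df["mm"].notna() & (df["mm"] < 0)
        reasons[bad_mm & (reasons == "")] = "negative mm"
    out_of_range = df["z"].isna() | (df["z"] < 0)
    if L is not None:
        out_of_range |= df["z"] > L
    reasons[out_of_range & (reasons == "")] = "position outside transcript"
    rejected = df[reasons != ""].copy()
    rejected["line"] = rejected.index + 2  # 1-based, after the header row
    rejected["reason"] = reasons[reasons != ""]
    if strict and not rejected.empty:
        lines = ", ".join(str(x) for x in rejected["line"].head(10))
        raise ValueError(f"{path}: {len(rejected)} invalid rows (lines {lines} ...)")
    return df[reasons == ""].reset_index(drop=True), rejected.reset_index(drop=True)


def write_probe_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a probe table; ``meta`` becomes '#'-comment header lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in sorted((meta or {}).items()):
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_ct_table(path) -> pd.DataFrame:
    """Read a qPCR CT table (transcript_id, amplicon_id, start_5prime,
    sample, ct)."""
    df = _read_tsv(path, CT_COLUMNS, "CT")
    if df["ct"].isna().any() or not np.isfinite(df["ct"]).all():
        raise ValueError(f"{path}: CT values must be finite")
    return df


def read_annotation(path, three_prime_anchored: bool = True) -> pd.DataFrame:
    """Read a probe annotation table (probeset_id, probe_id, z, L).

    ``z`` is the distance of the probe's middle nucleotide from the 3' end.
    If the source anchors positions at the 5' end instead
    (``three_prime_anchored=False``), they are converted via ``z = L - z5``.
    """
    df = _read_tsv(path, ANNOTATION_COLUMNS, "annotation")
    if not three_prime_anchored:
        df = df.assign(z=df["L"] - df["z"])
    bad = (df["z"] < 0) | (df["z"] > df["L"])
    if bad.any():
        raise ValueError(f"{path}: {int(bad.sum())} probes positioned outside [0, L]")
    return df


_CONFIG_KEYS = {
    "probe_table",
    "annotation",
    "output_dir",
    "L",
    "a",
    "b",
    "a_grid",
    "b_grid",
    "mode",
    "p_floor",
    "method",
    "grid_step",
    "quad_step",
    "seed",
    "lowess_fraction",
    "window",
    "linkage",
    "log_level",
}

_PATH_KEYS = ("probe_table", "annotation")


@dataclass
class RunConfig:
    """Validated run configuration loaded from YAML."""

    values: dict = field(default_factory=dict)

    def get(self, key, default=None):
        return self.values.get(key, default)


def load_config(path) -> RunConfig:
    """Load a YAML config; unknown keys are rejected, referenced input paths
    must exist."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in _PATH_KEYS:
        if key in data and not Path(data[key]).exists():
            raise FileNotFoundError(f"{path}: {key} -> {data[key]} does not exist")
    return RunConfig(values=data)
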