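"""Table formats, pipeline configuration and provenance helpers.

All tables are plain CSV/TSV with a header row; the delimiter is sniffed.
Files written by the pipeline carry a leading ``# config_hash=...`` comment
so downstream stages can refuse to mix outputs from different runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "PipelineConfig",
    "read_table",
    "read_peak_integrals",
    "read_rates",
    "read_ancillary",
    "read_mas_rates",
    "write_table",
    "read_config_hash",
]

INTEGRAL_COLUMNS = (
    "residue_label",
    "field_mhz",
    "spinlock_khz",
    "delay_s",
    "integral",
    "integral_error",
)
RATE_COLUMNS = (
    "residue_label",
    "field_mhz",
    "spinlock_khz",
    "r1rho_obs",
    "r1rho_obs_error",
)
MAS_COLUMNS = ("field_mhz", "mas_khz", "spinlock_khz", "r1rho", "error")


@dataclass(frozen=True)
class PipelineConfig:
    """Run-level settings shared by the pipeline stages.

    Defaults follow standard practice for this experiment class: 2000
    Monte-Carlo replicates for decay fits and 250 for dispersion fits, a
    45-degree tilt-angle exclusion threshold, 60 kHz MAS, and a kex search
    grid of 50 log-spaced points on [1e2, 1e6] s^-1.
    """

    seed: int = 0
    decay_mc_replicates: int = 2000
    dispersion_mc_replicates: int = 250
    mc_mode: str = "gaussian"
    exclusion_threshold_deg: float = 45.0
    mas_khz: float = 60.0
    kex_grid: Tuple[float, float, int] = (1e2, 1e6, 50)
    groups: Optional[Dict[str, List[str]]] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        if "kex_grid" in data:
            data["kex_grid"] = tuple(data["kex_grid"])
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the run seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % 2**31


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return ","


def read_table(path, required: Sequence[str], numeric: Sequence[str]) -> pd.DataFrame:
    """Read a CSV/TSV table, validating columns and numeric cells.

    Raises ValueError naming the missing column or the offending row
    (1-based data row number) for non-numeric cells.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column '{col}'")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path.name}: non-numeric value in column '{col}' at row {bad[0] + 1}"
            )
        df[col] = coerced
    return df


def read_peak_integrals(path) -> pd.DataFrame:
    """Read and validate a peak-integral table.

    Columns: residue_label, field_mhz, spinlock_khz, delay_s, integral,
    integral_error. Duplicate (residue, field, lock, delay) rows are an
    error naming the first duplicated row.
    """
    df = read_table(path, INTEGRAL_COLUMNS, INTEGRAL_COLUMNS[1:])
    key = ["residue_label", "field_mhz", "spinlock_khz", "delay_s"]
    dup = df.duplicated(subset=key)
    if dup.any():
        row = int(df.index[dup][0]) + 1
        raise ValueError(f"duplicate (residue, field, lock, delay) entry at row {row}")
    return df


def read_rates(path) -> pd.DataFrame:
    return read_table(path, RATE_COLUMNS, RATE_COLUMNS[1:])


def read_ancillary(path, value_col: str) -> pd.DataFrame:
    """Read a per-residue ancillary table (offsets or R1 rates)."""
    return read_table(path, ("residue_label", value_col), (value_col,))


def read_mas_rates(path) -> pd.DataFrame:
    return read_table(path, MAS_COLUMNS, MAS_COLUMNS)


def write_table(df: pd.DataFrame, path, config_hash: str = "") -> None:
    """Write a table as CSV with an embedded config-hash comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_config_hash(path) -> str:
    """Return the embedded config hash of a pipeline output ('' if absent)."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# config_hash="):
        return first.strip().split("=", 1)[1]
    return ""
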