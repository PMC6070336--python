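"""Schema-validated CSV interchange, configuration loading, run manifests.

All tables travel as headered CSV. Units are embedded in column names
(``conc_uM``, ``time_hr``, ``distance_kb``); concentrations are µM, times
hours, distances kb.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .presets import load_config  # re-exported; config lives with the presets

__all__ = ["SCHEMAS", "SchemaError", "read_table", "write_table", "RunManifest", "load_config"]


SCHEMAS: dict[str, dict] = {
    "snapshots": {
        "required": ["strain", "condition", "green_raw", "orange_raw", "red_raw", "fsc", "ssc"],
        "numeric": ["green_raw", "orange_raw", "red_raw", "fsc", "ssc"],
    },
    "traces": {
        "required": ["cell_id", "time_hr", "green_raw", "orange_raw", "red_raw"],
        "numeric": ["time_hr", "green_raw", "orange_raw", "red_raw"],
    },
    "dose_response": {
        "required": ["condition", "ancestry", "conc_uM", "n_total", "n_green_off", "n_orange_off"],
        "numeric": ["conc_uM", "n_total", "n_green_off", "n_orange_off"],
    },
    "recovery": {
        "required": ["strain", "arm", "time_hr", "n_total", "n_full_spreading"],
        "numeric": ["time_hr", "n_total", "n_full_spreading"],
    },
    "enrichment": {
        "required": ["population", "amplicon", "assay", "ip", "input", "replicate"],
        "numeric": ["ip", "input", "replicate"],
    },
}


class SchemaError(ValueError):
    """A table failed schema validation (exit code 2 at the CLI)."""


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV table against a registered schema."""
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}; registered: {sorted(SCHEMAS)}")
    schema = SCHEMAS[schema_name]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in schema["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    for col in schema["numeric"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rows = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
            raise SchemaError(f"{path.name}: non-numeric values in column {col!r} (file rows {rows})")
        if coerced.isna().any():
            rows = (df.index[coerced.isna()] + 2).tolist()[:5]
            raise SchemaError(f"{path.name}: missing values in column {col!r} (file rows {rows})")
        df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> Path:
    """Write a table as CSV with stable float formatting (byte-reproducible)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=float_format)
    return path


@dataclass
class RunManifest:
    """Provenance record written alongside every pipeline output directory."""

    command: str
    seed: int | None = None
    config_hash: str = ""
    versions: dict = field(default_factory=dict)
    timestamp_utc: str = ""

    @classmethod
    def create(cls, command: str, seed: int | None = None, config_path: str | Path | None = None):
        import hss

        if config_path is not None:
            digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
        else:
            from importlib import resources

            digest = hashlib.sha256(
                resources.files("hss.data").joinpath("presets.yaml").read_bytes()
            ).hexdigest()
        return cls(
            command=command,
            seed=seed,
            config_hash=digest,
            versions={
                "hss": getattr(hss, "__version__", "unknown"),
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "python": platform.python_version(),
            },
            timestamp_utc=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "run_manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return path
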