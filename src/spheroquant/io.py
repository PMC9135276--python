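"""Tabular I/O, run configuration and provenance records.

The canonical tabular interchange is long-format CSV with a header
(well, condition, dose_M, replicate, value[, channel]); wide 8x12 plate
layouts are accepted through :func:`wide_plate_to_long`.  Every pipeline
run emits a JSON provenance record (config hash, seed, package versions,
timestamp) so results can be traced to their inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("spheroquant")

__all__ = [
    "RunConfig",
    "read_plate_table",
    "wide_plate_to_long",
    "write_report",
]

PLATE_COLUMNS = ["well", "condition", "dose_M", "replicate", "value"]


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run.

    ``inputs`` maps role names (e.g. ``mono_sensitive``, ``images``) to
    paths; ``params`` holds stage parameters (annulus width, edge position,
    expand/shrink px, thresholds, top_k, ...).  Paths are checked for
    existence at validation time.
    """

    inputs: dict = dc_field(default_factory=dict)
    channels: dict = dc_field(default_factory=dict)
    params: dict = dc_field(default_factory=dict)
    seed: int = 0
    outdir: str = "results"

    def validate(self) -> "RunConfig":
        for role, path in self.inputs.items():
            for p in [path] if isinstance(path, (str, Path)) else path:
                if not Path(p).exists():
                    raise FileNotFoundError(f"input {role!r}: {p} does not exist")
        ranges = {
            "edge_position": (0.0, 1.2),
            "enclosure_fraction": (0.0, 1.0),
            "expand_px": (0, 50),
            "shrink_px": (0, 50),
            "top_k": (1, 20),
        }
        for key, (lo, hi) in ranges.items():
            if key in self.params and not lo <= self.params[key] <= hi:
                raise ValueError(
                    f"parameter {key}={self.params[key]} outside [{lo}, {hi}]"
                )
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            inputs=raw.get("inputs", {}),
            channels=raw.get("channels", {}),
            params=raw.get("params", {}),
            seed=int(raw.get("seed", 0)),
            outdir=raw.get("outdir", "results"),
        ).validate()

    def digest(self) -> str:
        blob = json.dumps(
            {
                "inputs": {k: str(v) for k, v in self.inputs.items()},
                "channels": self.channels,
                "params": self.params,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_plate_table(path) -> pd.DataFrame:
    """Read and validate a long-format plate CSV.

    Requires columns well, condition, dose_M, replicate, value (an optional
    ``channel`` column is kept).  Doses are parsed as molar floats;
    duplicate (well, channel) rows are an error.
    """
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    try:
        df["dose_M"] = df["dose_M"].astype(float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: non-numeric dose_M values") from err
    df["value"] = df["value"].astype(float)
    key = ["well", "channel"] if "channel" in df.columns else ["well"]
    dups = df.duplicated(subset=key)
    if dups.any():
        raise ValueError(
            f"{path}: duplicate rows for {key}: {sorted(df.loc[dups, 'well'].unique())}"
        )
    return df


def wide_plate_to_long(
    wide: pd.DataFrame,
    condition_map: dict[str, str],
    dose_map: dict[str, float],
    replicate: int = 1,
) -> pd.DataFrame:
    """Convert an 8x12 plate layout to the canonical long format.

    ``wide`` is indexed by row letters A–H with columns 1–12;
    ``condition_map`` / ``dose_map`` assign a condition and molar dose to
    each well id (e.g. ``"A01"``).  Unmapped wells are skipped.
    """
    rows = []
    for r in wide.index:
        for c in wide.columns:
            well = f"{r}{int(c):02d}"
            if well not in condition_map:
                continue
            rows.append(
                {
                    "well": well,
                    "condition": condition_map[well],
                    "dose_M": dose_map.get(well, np.nan),
                    "replicate": replicate,
                    "value": float(wide.loc[r, c]),
                }
            )
    return pd.DataFrame(rows)


def write_report(outdir, stage: str, config: RunConfig, extra: dict | None = None) -> Path:
    """Write the JSON provenance record for one stage run."""
    import spheroquant

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {
        "stage": stage,
        "config_hash": config.digest(),
        "seed": config.seed,
        "params": config.params,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "versions": {
            "spheroquant": spheroquant.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        report.update(extra)
    path = outdir / f"{stage}_report.json"
    path.write_text(json.dumps(report, indent=2, default=str))
    logger.info("stage %s: report written to %s", stage, path)
    return path
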