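"""Reading and writing rupture datasets, run configurations and provenance.

Datasets travel as delimited text (TSV by default, delimiter sniffed on
read) with the header columns

    force_pN  rate_pNps  mode  [time_s]  [kappa_pNpnm]

plus a JSON provenance sidecar (``<path>.provenance.json``) recording the
model, seed, time step and censoring of the run that produced the file.
Run configurations round-trip through YAML or JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .simulate import RuptureDataset

__all__ = ["SchemaError", "read_ruptures", "write_ruptures", "RunConfig"]

REQUIRED_COLUMNS = ("force_pN", "rate_pNps", "mode")
_UNIT_FACTORS = {"pN": 1.0, "nN": 1000.0, "fN": 1e-3}


class SchemaError(ValueError):
    """Dataset file does not match the expected schema."""


def read_ruptures(path, force_unit: str = "pN") -> RuptureDataset:
    """Read a rupture dataset from delimited text.

    The delimiter is sniffed; required columns are force_pN, rate_pNps and
    mode.  Unknown columns are preserved in the event table.  ``force_unit``
    converts force-like columns recorded in other units to pN on input.
    """
    path = Path(path)
    if force_unit not in _UNIT_FACTORS:
        raise ValueError(f"unsupported force unit {force_unit!r}")
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise SchemaError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for col in ("force_pN", "rate_pNps"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(values.isna().to_numpy())
        if bad.size:
            lines = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
            raise SchemaError(f"non-numeric {col} on line(s) {lines}")
        df[col] = values
    factor = _UNIT_FACTORS[force_unit]
    if factor != 1.0:
        df["force_pN"] = df["force_pN"] * factor
        df["rate_pNps"] = df["rate_pNps"] * factor
        if "kappa_pNpnm" in df.columns:
            df["kappa_pNpnm"] = pd.to_numeric(df["kappa_pNpnm"]) * factor
    if "kappa_pNpnm" not in df.columns:
        df["kappa_pNpnm"] = np.where(df["mode"].astype(str) == "spring", np.nan, 0.0)
        if df["kappa_pNpnm"].isna().any():
            raise SchemaError("spring-mode events require a kappa_pNpnm column")
    if "time_s" not in df.columns:
        df["time_s"] = df["force_pN"] / df["rate_pNps"]
    if (df["force_pN"] < 0).any():
        raise SchemaError("negative rupture forces in file")
    sidecar = path.with_name(path.name + ".provenance.json")
    provenance = (
        json.loads(sidecar.read_text()) if sidecar.exists() else {"source": str(path)}
    )
    return RuptureDataset(events=df, provenance=provenance)


def write_ruptures(dataset: RuptureDataset, path, sep: str = "\t") -> Path:
    """Write a dataset as delimited text plus a JSON provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["force_pN", "time_s", "rate_pNps", "mode", "kappa_pNpnm"]
    extra = [c for c in dataset.events.columns if c not in cols]
    dataset.events[cols + extra].to_csv(path, sep=sep, index=False)
    sidecar = path.with_name(path.name + ".provenance.json")
    sidecar.write_text(json.dumps(dataset.provenance, indent=2, default=float))
    return path


@dataclass
class RunConfig:
    """Serializable description of a full simulate-and-fit run."""

    model: dict = field(default_factory=dict)      # barrier_kT, x_b_nm, D_nm2ps, T_K
    protocols: list = field(default_factory=list)  # [{mode, rate_pNps, ...}, ...]
    simulation: dict = field(default_factory=dict)  # n, dt_s, crossing, ...
    fit: dict = field(default_factory=dict)        # bounds, n_restarts, mu policy
    output: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(**data)

    def dump(self, path) -> Path:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
        path.write_text(text)
        return path

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Stable hash of the configuration for provenance records."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
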