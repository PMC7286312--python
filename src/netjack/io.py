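"""Plain-text file formats for recordings, layouts, networks, and configs.

Everything on disk is keyed by contact *label*, never by index, so files
survive channel reordering. Adjacency matrices are delimited square tables
with a label header; recordings are delimited matrices with a JSON metadata
sidecar; layouts are CSV with the fixed column set
``label,x_mm,y_mm,z_mm,soz,resected``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import BandSpec, ElectrodeLayout, FunctionalNetwork, Recording

__all__ = [
    "read_layout",
    "write_layout",
    "read_adjacency",
    "write_adjacency",
    "read_recording",
    "write_recording",
    "read_config",
    "write_config",
    "AnalysisConfig",
]

_ADJ_TOL = 1e-8


def read_layout(path: str | Path) -> ElectrodeLayout:
    """Read an electrode layout CSV, validating columns and labels."""
    table = pd.read_csv(path)
    missing = [c for c in ElectrodeLayout.COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing layout columns {missing}")
    for col in ("x_mm", "y_mm", "z_mm"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[coerced.isna()].tolist()
        if bad:
            raise ValueError(f"{path}: non-numeric {col} in row(s) {bad}")
        table[col] = coerced
    dup = table["label"].astype(str).duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: duplicate label(s) in row(s) {table.index[dup].tolist()}"
        )
    for col in ("soz", "resected"):
        table[col] = table[col].astype(int).astype(bool)
    return ElectrodeLayout(table)


def write_layout(layout: ElectrodeLayout, path: str | Path) -> None:
    out = layout.table.copy()
    out["soz"] = out["soz"].astype(int)
    out["resected"] = out["resected"].astype(int)
    out.to_csv(path, index=False)


def read_adjacency(path: str | Path) -> FunctionalNetwork:
    """Read a delimited square adjacency matrix with a label header row.

    Validates symmetry (within 1e-8), nonnegative weights, and a zero
    diagonal; an optional ``<path>.json`` sidecar restores band and window
    metadata.
    """
    table = pd.read_csv(path, index_col=0)
    labels = tuple(str(c) for c in table.columns)
    adj = table.to_numpy(dtype=float)
    if adj.shape[0] != adj.shape[1]:
        raise ValueError(f"{path}: adjacency is {adj.shape}, not square")
    asym = np.abs(adj - adj.T).max(initial=0.0)
    if asym > _ADJ_TOL:
        raise ValueError(f"{path}: asymmetric adjacency (max residual {asym:.3g})")
    if np.abs(np.diag(adj)).max(initial=0.0) > _ADJ_TOL:
        raise ValueError(f"{path}: nonzero diagonal")
    if adj.min(initial=0.0) < -_ADJ_TOL:
        raise ValueError(f"{path}: negative weights")
    adj = np.clip((adj + adj.T) / 2.0, 0.0, None)
    np.fill_diagonal(adj, 0.0)
    band = window = None
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("band"):
            band = BandSpec(**meta["band"])
        if meta.get("window"):
            window = tuple(meta["window"])
    return FunctionalNetwork(adjacency=adj, labels=labels, band=band, window=window)


def write_adjacency(net: FunctionalNetwork, path: str | Path) -> None:
    """Write adjacency as CSV (full precision) plus a JSON sidecar."""
    pd.DataFrame(net.adjacency, index=net.labels, columns=net.labels).to_csv(
        path, float_format="%.17g"
    )
    meta = {
        "band": dataclasses.asdict(net.band) if net.band else None,
        "window": list(net.window) if net.window else None,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def write_recording(rec: Recording, path: str | Path) -> None:
    """Delimited contacts x samples matrix plus a JSON metadata sidecar."""
    np.savetxt(path, rec.samples, delimiter=",", fmt="%.10g")
    meta = {"fs": rec.fs, "labels": list(rec.labels)}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_recording(path: str | Path) -> Recording:
    sidecar = Path(str(path) + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"recording sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    samples = np.atleast_2d(np.loadtxt(path, delimiter=","))
    return Recording(samples=samples, fs=float(meta["fs"]), labels=meta["labels"])


@dataclasses.dataclass
class AnalysisConfig:
    """Every tunable parameter of the pipeline, round-trippable via YAML."""

    band_name: str = "high_gamma"
    band_lo: float = 95.0
    band_hi: float = 105.0
    window_len: float = 1.0
    peri_ictal_offsets: tuple[float, ...] = (-10.0, -5.0, 0.0, 5.0, 10.0)
    removal_fractions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    n_iter: int = 1000
    seed: int = 0
    density: float | None = None
    filter_lo: float = 5.0
    filter_hi: float = 115.0
    filter_notch: float = 60.0
    ar_order: int = 1
    region_size: int = 3
    alpha: float = 0.05

    @property
    def band(self) -> BandSpec:
        return BandSpec(self.band_name, self.band_lo, self.band_hi)


def read_config(path: str | Path) -> AnalysisConfig:
    """Load an analysis config from YAML (JSON is valid YAML)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("peri_ictal_offsets", "removal_fractions"):
        if key in data:
            data[key] = tuple(data[key])
    return AnalysisConfig(**data)


def write_config(config: AnalysisConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    for key in ("peri_ictal_offsets", "removal_fractions"):
        data[key] = list(data[key])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
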