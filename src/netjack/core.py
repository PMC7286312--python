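"""Core data containers shared across the pipeline.

The unit of analysis is the electrode *contact*: a single recording site on
an implanted grid, strip, or depth electrode. A multichannel recording is a
contacts x samples matrix; a functional network is a symmetric, nonnegative,
zero-diagonal adjacency matrix whose (i, j) entry is the band-averaged
coherence between contacts i and j.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "ElectrodeLayout",
    "BandSpec",
    "FunctionalNetwork",
    "HIGH_GAMMA",
    "BETA",
]

_SYMMETRY_TOL = 1e-10


@dataclass(frozen=True)
class Recording:
    """Multichannel signal block: ``samples`` is contacts x timepoints."""

    samples: np.ndarray
    fs: float
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2:
            raise ValueError("samples must be a 2-D contacts x timepoints array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        labels = tuple(str(x) for x in self.labels)
        if len(labels) != samples.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for {samples.shape[0]} channels"
            )
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "labels", labels)

    @property
    def n_contacts(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray) -> "Recording":
        return replace(self, samples=samples)


class ElectrodeLayout:
    """Per-contact 3-D coordinates (mm) plus clinical annotations.

    ``soz`` flags contacts in the clinician-defined seizure onset zone;
    ``resected`` flags contacts overlying later-resected cortex.
    """

    COLUMNS = ("label", "x_mm", "y_mm", "z_mm", "soz", "resected")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"layout table missing columns: {missing}")
        table = table.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        table["label"] = table["label"].astype(str)
        if table["label"].duplicated().any():
            dupes = table.loc[table["label"].duplicated(), "label"].tolist()
            raise ValueError(f"duplicate contact labels: {dupes}")
        for col in ("x_mm", "y_mm", "z_mm"):
            table[col] = pd.to_numeric(table[col], errors="raise")
        table["soz"] = table["soz"].astype(bool)
        table["resected"] = table["resected"].astype(bool)
        self.table = table

    @classmethod
    def from_arrays(
        cls,
        labels: Sequence[str],
        coords: np.ndarray,
        soz: Sequence[bool] | None = None,
        resected: Sequence[bool] | None = None,
    ) -> "ElectrodeLayout":
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        n = len(labels)
        if coords.shape != (n, 3):
            raise ValueError(f"coords must be {n} x 3, got {coords.shape}")
        soz = np.zeros(n, bool) if soz is None else np.asarray(soz, bool)
        resected = (
            np.zeros(n, bool) if resected is None else np.asarray(resected, bool)
        )
        return cls(
            pd.DataFrame(
                {
                    "label": list(labels),
                    "x_mm": coords[:, 0],
                    "y_mm": coords[:, 1],
                    "z_mm": coords[:, 2],
                    "soz": soz,
                    "resected": resected,
                }
            )
        )

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElectrodeLayout):
            return NotImplemented
        return self.table.equals(other.table)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.table["label"])

    @property
    def coords(self) -> np.ndarray:
        return self.table[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)

    @property
    def soz_indices(self) -> np.ndarray:
        return np.flatnonzero(self.table["soz"].to_numpy())

    @property
    def resected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.table["resected"].to_numpy())

    def subset(self, indices: Sequence[int]) -> "ElectrodeLayout":
        """Rows at ``indices`` in the given order (original order preserved
        when indices are sorted)."""
        return ElectrodeLayout(self.table.iloc[list(indices)])

    def nearest_neighbors(self, seed: int, k: int) -> np.ndarray:
        """Indices of ``seed`` plus its ``k - 1`` nearest contacts by
        Euclidean distance; distance ties broken by lowest contact index."""
        if not 1 <= k <= len(self):
            raise ValueError(f"region size {k} out of range for {len(self)} contacts")
        d = np.linalg.norm(self.coords - self.coords[seed], axis=1)
        d[seed] = -1.0  # seed always included
        order = np.lexsort((np.arange(len(self)), d))  # stable: ties -> low index
        return np.sort(order[:k])


@dataclass(frozen=True)
class BandSpec:
    """Labeled frequency interval in Hz over which coherence is averaged."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band requires lo < hi, got [{self.lo}, {self.hi}]")


#: High-gamma band used for the primary coherence analysis.
HIGH_GAMMA = BandSpec("high_gamma", 95.0, 105.0)
#: Beta band used as the sensitivity band.
BETA = BandSpec("beta", 15.0, 25.0)


@dataclass(frozen=True)
class FunctionalNetwork:
    """Undirected weighted functional network on electrode contacts.

    Invariants enforced at construction: square adjacency, symmetry within
    1e-10, zero diagonal, nonnegative weights.
    """

    adjacency: np.ndarray
    labels: tuple[str, ...]
    band: BandSpec | None = None
    window: tuple[float, float] | None = field(default=None)  # (start s, length s)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {a.shape}")
        if not np.all(np.isfinite(a)):
            raise ValueError("adjacency contains non-finite values")
        asym = np.abs(a - a.T).max() if a.size else 0.0
        if asym > _SYMMETRY_TOL:
            raise ValueError(f"adjacency asymmetric (max |A - A.T| = {asym:.3g})")
        a = (a + a.T) / 2.0
        if np.abs(np.diag(a)).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("adjacency diagonal must be zero")
        np.fill_diagonal(a, 0.0)
        if a.min(initial=0.0) < 0:
            raise ValueError("adjacency weights must be nonnegative")
        labels = tuple(str(x) for x in self.labels)
        if len(labels) != a.shape[0]:
            raise ValueError(f"{len(labels)} labels for {a.shape[0]} nodes")
        a.setflags(write=False)
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "labels", labels)

    @property
    def n_contacts(self) -> int:
        return self.adjacency.shape[0]

    def subnetwork(self, keep: Sequence[int]) -> "FunctionalNetwork":
        """Principal submatrix on ``keep`` (original label order preserved
        when ``keep`` is sorted)."""
        keep = np.asarray(keep, dtype=int)
        return FunctionalNetwork(
            adjacency=self.adjacency[np.ix_(keep, keep)],
            labels=tuple(self.labels[i] for i in keep),
            band=self.band,
            window=self.window,
        )

    def density(self) -> float:
        """Fraction of unordered off-diagonal pairs with nonzero weight."""
        n = self.n_contacts
        if n < 2:
            return 0.0
        iu = np.triu_indices(n, k=1)
        return float(np.count_nonzero(self.adjacency[iu]) / len(iu[0]))


def warn_once(message: str) -> None:
    warnings.warn(message, stacklevel=3)
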