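"""Electrode-removal schemes for probing network robustness.

Four schemes: uniformly random removal of a fixed fraction of contacts,
deterministic removal of each contact's contiguous spatial neighborhood,
removal of exactly the seizure-onset-zone contacts, and removal of
equal-sized random sets that spare the onset zone. All schemes operate on
the adjacency matrix by deleting rows and columns, and every stochastic
scheme is reproducible from a single master seed: iteration ``i`` of a
scheme draws from an independent substream keyed by (seed, scheme, i).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import ElectrodeLayout, FunctionalNetwork

__all__ = [
    "SubsampleEnsemble",
    "remove_contacts",
    "random_subsample",
    "contiguous_subsample",
    "soz_targeted_subsample",
    "soz_sparing_subsample",
    "centroid_distance",
]

_SCHEME_CODES = {"random": 1, "contiguous": 2, "soz_targeted": 3, "soz_sparing": 4}


@dataclass(frozen=True)
class SubsampleEnsemble:
    """Retained-contact sets produced by one removal scheme."""

    scheme: str
    retained_sets: tuple[tuple[int, ...], ...]
    n_total: int
    removal_fraction: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for s in self.retained_sets:
            if len(s) < 2:
                raise ValueError("every retained set must keep >= 2 contacts")
            if any(not 0 <= i < self.n_total for i in s):
                raise ValueError("retained set indices out of range")

    @property
    def n_iter(self) -> int:
        return len(self.retained_sets)

    def removed_sets(self) -> list[tuple[int, ...]]:
        full = set(range(self.n_total))
        return [tuple(sorted(full - set(s))) for s in self.retained_sets]


def remove_contacts(
    net: FunctionalNetwork, removed: Iterable[int]
) -> FunctionalNetwork:
    """Delete the given contacts' rows and columns from the adjacency."""
    removed = set(int(i) for i in removed)
    if any(not 0 <= i < net.n_contacts for i in removed):
        raise ValueError("removed indices out of range")
    keep = [i for i in range(net.n_contacts) if i not in removed]
    if len(keep) < 2:
        raise ValueError(
            f"removing {len(removed)} of {net.n_contacts} contacts leaves "
            "fewer than 2"
        )
    return net.subnetwork(keep)


def _removal_count(n: int, fraction: float) -> int:
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    k = max(1, round(fraction * n))
    if n - k < 2:
        raise ValueError(
            f"removing {fraction:.0%} of {n} contacts would leave fewer than 2"
        )
    return k


def _iter_rng(seed: int, scheme: str, iteration: int) -> np.random.Generator:
    return np.random.default_rng([seed, _SCHEME_CODES[scheme], iteration])


def random_subsample(
    net: FunctionalNetwork,
    fraction: float,
    n_iter: int = 1000,
    seed: int = 0,
) -> SubsampleEnsemble:
    """Remove ``round(fraction * N)`` uniformly chosen contacts, repeatedly."""
    n = net.n_contacts
    k = _removal_count(n, fraction)
    retained = []
    for i in range(n_iter):
        rng = _iter_rng(seed, "random", i)
        removed = rng.choice(n, size=k, replace=False)
        retained.append(tuple(int(j) for j in range(n) if j not in set(removed.tolist())))
    return SubsampleEnsemble(
        scheme="random",
        retained_sets=tuple(retained),
        n_total=n,
        removal_fraction=fraction,
        seed=seed,
    )


def contiguous_subsample(
    net: FunctionalNetwork,
    layout: ElectrodeLayout,
    fraction: float,
) -> SubsampleEnsemble:
    """Remove each contact's spatial neighborhood in turn (deterministic).

    One removal set per seed contact: the seed plus its
    ``round(fraction * N) - 1`` nearest neighbors by Euclidean distance
    (ties to the lowest index). Produces exactly N sets.
    """
    n = net.n_contacts
    if len(layout) != n:
        raise ValueError(f"layout has {len(layout)} contacts, network has {n}")
    k = _removal_count(n, fraction)
    retained = []
    for s in range(n):
        region = set(int(i) for i in layout.nearest_neighbors(s, k))
        retained.append(tuple(i for i in range(n) if i not in region))
    return SubsampleEnsemble(
        scheme="contiguous",
        retained_sets=tuple(retained),
        n_total=n,
        removal_fraction=fraction,
    )


def soz_targeted_subsample(
    net: FunctionalNetwork, layout: ElectrodeLayout
) -> SubsampleEnsemble:
    """Remove exactly the seizure-onset-zone contacts (single set)."""
    n = net.n_contacts
    if len(layout) != n:
        raise ValueError(f"layout has {len(layout)} contacts, network has {n}")
    soz = set(int(i) for i in layout.soz_indices)
    if not soz:
        raise ValueError("layout has no seizure-onset-zone contacts")
    retained = tuple(i for i in range(n) if i not in soz)
    if len(retained) < 2:
        raise ValueError("fewer than 2 non-onset-zone contacts would remain")
    return SubsampleEnsemble(
        scheme="soz_targeted", retained_sets=(retained,), n_total=n
    )


def soz_sparing_subsample(
    net: FunctionalNetwork,
    layout: ElectrodeLayout,
    n_iter: int = 1000,
    seed: int = 0,
) -> SubsampleEnsemble:
    """Remove random non-onset-zone sets matched in size to the onset zone.

    Each iteration removes |SOZ| contacts drawn uniformly from outside the
    onset zone. When the onset zone outnumbers the remaining contacts the
    match is impossible, and the scheme degenerates to the single
    deterministic set that removes every non-onset-zone contact.
    """
    n = net.n_contacts
    if len(layout) != n:
        raise ValueError(f"layout has {len(layout)} contacts, network has {n}")
    soz = set(int(i) for i in layout.soz_indices)
    if not soz:
        raise ValueError("layout has no seizure-onset-zone contacts")
    non_soz = [i for i in range(n) if i not in soz]
    if len(non_soz) < 2:
        raise ValueError("fewer than 2 non-onset-zone contacts")
    if len(soz) > len(non_soz):
        retained = (tuple(sorted(soz)),)
    else:
        retained = []
        for i in range(n_iter):
            rng = _iter_rng(seed, "soz_sparing", i)
            removed = set(
                int(j) for j in rng.choice(non_soz, size=len(soz), replace=False)
            )
            retained.append(tuple(j for j in range(n) if j not in removed))
        retained = tuple(retained)
    return SubsampleEnsemble(
        scheme="soz_sparing", retained_sets=retained, n_total=n, seed=seed
    )


def centroid_distance(
    removed: Sequence[int], soz: Sequence[int], layout: ElectrodeLayout
) -> float:
    """Euclidean distance (mm) between set centroids."""
    removed = list(removed)
    soz = list(soz)
    if not removed or not soz:
        raise ValueError("both contact sets must be nonempty")
    coords = layout.coords
    return float(
        np.linalg.norm(coords[removed].mean(axis=0) - coords[soz].mean(axis=0))
    )
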