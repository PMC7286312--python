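"""Patient-specific confidence sets and intervals via jackknife subsampling.

Repeatedly removing a small random fraction of contacts (20% by default,
emulating minor variability in implantation strategy) and re-running the
network analysis yields, per patient:

* for nodal metrics, the **95% confidence contact set** -- the smallest
  greedy set of contacts accounting for >= 95% of the iterations'
  optimal-contact occurrences (argmax; argmin for control centrality). A
  large set means the identity of the "top" contact is fragile.
* for regional control centrality, the analogous set built from region
  *membership* occurrences, plus the ratio of its size to the region size.
* for global metrics, the **95% confidence interval** -- the central
  interval containing 95% of subsampled values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ElectrodeLayout, FunctionalNetwork
from .metrics import (
    GLOBAL_METRICS,
    NODAL_METRICS,
    NODAL_OPTIMUM_SENSE,
    regional_control_centrality,
)
from .subsample import SubsampleEnsemble, random_subsample

__all__ = [
    "ConfidenceSet",
    "ConfidenceInterval",
    "confidence_set_from_counts",
    "jackknife_nodal_confidence_set",
    "jackknife_regional_cc_confidence",
    "jackknife_global_interval",
]


@dataclass(frozen=True)
class ConfidenceSet:
    """Contacts accounting for >= ``coverage_target`` of optimum occurrences."""

    metric: str
    contacts: tuple[int, ...]
    counts: dict[int, int]
    coverage: float
    n_iter: int
    n_dropped: int
    optimum_sense: str

    @property
    def size(self) -> int:
        return len(self.contacts)


@dataclass(frozen=True)
class ConfidenceInterval:
    metric: str
    lo: float
    hi: float
    point_value: float
    n_iter: int
    n_dropped: int

    @property
    def width(self) -> float:
        return self.hi - self.lo


def _jackknife_ensemble(
    net: FunctionalNetwork, fraction: float, n_iter: int, seed: int
) -> SubsampleEnsemble:
    """Random-removal ensemble; fraction 0 degenerates to the full network."""
    if fraction == 0.0:
        full = tuple(range(net.n_contacts))
        return SubsampleEnsemble(
            scheme="random",
            retained_sets=(full,) * n_iter,
            n_total=net.n_contacts,
            removal_fraction=0.0,
            seed=seed,
        )
    return random_subsample(net, fraction, n_iter=n_iter, seed=seed)


def confidence_set_from_counts(
    counts: dict[int, int],
    *,
    coverage_target: float = 0.95,
    metric: str = "",
    n_iter: int | None = None,
    n_dropped: int = 0,
    optimum_sense: str = "max",
) -> ConfidenceSet:
    """Greedy minimal contact set covering the target occurrence fraction.

    Contacts are accumulated in descending count order (count ties broken
    by lowest contact index) until the cumulative count reaches
    ``coverage_target`` of the total.
    """
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty occurrence tally")
    order = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    acc = 0
    chosen: list[int] = []
    for contact, count in order:
        if acc >= coverage_target * total:
            break
        chosen.append(contact)
        acc += count
    return ConfidenceSet(
        metric=metric,
        contacts=tuple(sorted(chosen)),
        counts=dict(counts),
        coverage=acc / total,
        n_iter=n_iter if n_iter is not None else total,
        n_dropped=n_dropped,
        optimum_sense=optimum_sense,
    )


def jackknife_nodal_confidence_set(
    net: FunctionalNetwork,
    metric: str,
    fraction: float = 0.2,
    n_iter: int = 1000,
    seed: int = 0,
    coverage_target: float = 0.95,
) -> ConfidenceSet:
    """Confidence set for the contact with the optimal nodal metric value.

    Each iteration removes ``fraction`` of contacts at random, recomputes
    the metric on the subsample, and records which original contact attains
    the maximum (minimum for control centrality); within-iteration ties go
    to the lowest contact index. Iterations where the metric is undefined
    are dropped and the coverage denominator shrinks accordingly.
    """
    if net.n_contacts < 5:
        raise ValueError("jackknife requires >= 5 contacts")
    fn = NODAL_METRICS[metric]
    sense = NODAL_OPTIMUM_SENSE[metric]
    ensemble = _jackknife_ensemble(net, fraction, n_iter, seed)
    counts: dict[int, int] = {}
    n_dropped = 0
    for retained in ensemble.retained_sets:
        sub = net.subnetwork(retained)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vals = fn(sub)
        except ValueError:
            n_dropped += 1
            continue
        local = int(np.argmin(vals)) if sense == "min" else int(np.argmax(vals))
        winner = retained[local]
        counts[winner] = counts.get(winner, 0) + 1
    if not counts:
        raise ValueError(f"metric {metric!r} undefined on every jackknife iteration")
    return confidence_set_from_counts(
        counts,
        coverage_target=coverage_target,
        metric=metric,
        n_iter=n_iter,
        n_dropped=n_dropped,
        optimum_sense=sense,
    )


def jackknife_regional_cc_confidence(
    net: FunctionalNetwork,
    layout: ElectrodeLayout,
    region_size: int,
    fraction: float = 0.2,
    n_iter: int = 1000,
    seed: int = 0,
    coverage_target: float = 0.95,
) -> tuple[ConfidenceSet, float]:
    """Confidence set for the most synchronizing contiguous region.

    Each iteration finds the region (seed contact plus nearest neighbors,
    ``region_size`` contacts in total, typically the resected-contact
    count) whose removal most decreases synchronizability, on the
    subsampled network. Every *member* of the winning region is tallied,
    and the greedy 95% set is built from membership occurrences. Returns
    the set and the ratio of its size to ``region_size`` (1 when the same
    region wins every iteration; larger when the localization is fragile).
    """
    if net.n_contacts < 5:
        raise ValueError("jackknife requires >= 5 contacts")
    if len(layout) != net.n_contacts:
        raise ValueError("layout does not match network")
    ensemble = _jackknife_ensemble(net, fraction, n_iter, seed)
    counts: dict[int, int] = {}
    n_dropped = 0
    for retained in ensemble.retained_sets:
        if region_size > len(retained) - 2:
            raise ValueError(
                f"region_size {region_size} too large for subsamples of "
                f"{len(retained)} contacts"
            )
        sub = net.subnetwork(retained)
        sub_layout = layout.subset(retained)
        try:
            result = regional_control_centrality(sub, sub_layout, region_size)
        except ValueError:
            n_dropped += 1
            continue
        for local in result.argmin_region:
            orig = retained[local]
            counts[orig] = counts.get(orig, 0) + 1
    if not counts:
        raise ValueError("regional control centrality undefined on every iteration")
    cset = confidence_set_from_counts(
        counts,
        coverage_target=coverage_target,
        metric="regional_control_centrality",
        n_iter=n_iter,
        n_dropped=n_dropped,
        optimum_sense="min",
    )
    return cset, cset.size / region_size


def jackknife_global_interval(
    net: FunctionalNetwork,
    metric: str,
    fraction: float = 0.2,
    n_iter: int = 1000,
    seed: int = 0,
    coverage_target: float = 0.95,
) -> ConfidenceInterval:
    """Central interval containing ``coverage_target`` of subsampled values.

    Percentiles use linear interpolation between order statistics; the
    point value is the metric on the full network. A wide interval flags a
    patient whose global statistic is sensitive to the electrode sample.
    """
    if net.n_contacts < 5:
        raise ValueError("jackknife requires >= 5 contacts")
    fn = GLOBAL_METRICS[metric]
    point = fn(net)
    ensemble = _jackknife_ensemble(net, fraction, n_iter, seed)
    values = []
    n_dropped = 0
    for retained in ensemble.retained_sets:
        try:
            values.append(fn(net.subnetwork(retained)))
        except ValueError:
            n_dropped += 1
    if not values:
        raise ValueError(f"metric {metric!r} undefined on every jackknife iteration")
    tail = 100.0 * (1.0 - coverage_target) / 2.0
    lo, hi = np.percentile(values, [tail, 100.0 - tail])
    return ConfidenceInterval(
        metric=metric,
        lo=float(lo),
        hi=float(hi),
        point_value=float(point),
        n_iter=n_iter,
        n_dropped=n_dropped,
    )
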