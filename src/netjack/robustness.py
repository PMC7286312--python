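"""Reliability and agreement statistics for subsampled networks.

The central quantity is the reliability R = sigma_T^2 / (sigma_T^2 +
sigma_E^2): the fraction of total variance in a subsampled metric that is
*not* attributable to the subsampling itself. For nodal metrics the
true-score variance is the spread of the metric across contacts (averaged
over subsample iterations) and the error variance is the spread of each
contact's value across iterations (averaged over contacts). For global
metrics the true-score variance is the spread across patients. R = 1 means
subsampling adds no variance; R = 0.5 means subsampling noise equals the
true signal variance.

Agreement ``a`` compares one subsampled network against the original:
Spearman's rank correlation over the retained contacts for nodal metrics,
and the negative absolute relative difference for global metrics (0 iff
perfect agreement, increasingly negative otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ElectrodeLayout, FunctionalNetwork
from .metrics import GLOBAL_METRICS, NODAL_METRICS
from .subsample import SubsampleEnsemble, centroid_distance, random_subsample

__all__ = [
    "ReliabilityReport",
    "AgreementRecord",
    "CohortTestReport",
    "nodal_metric_ensemble",
    "global_metric_ensemble",
    "reliability_nodal",
    "reliability_global",
    "rank_stability",
    "agreement",
    "contiguous_agreement_records",
    "distance_agreement_association",
    "soz_comparison",
    "signed_relative_difference",
    "cohort_metric_comparison",
    "cohort_reliability",
    "bonferroni_alpha",
    "size_reliability_association",
]


@dataclass(frozen=True)
class ReliabilityReport:
    metric: str
    removal_fraction: float | None
    R: float
    var_true: float
    var_error: float
    n_iter: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.R <= 1.0:
            raise ValueError(f"reliability must lie in [0, 1], got {self.R}")


@dataclass(frozen=True)
class AgreementRecord:
    """One subsample's agreement with the original network."""

    metric: str
    scheme: str
    removed: tuple[int, ...]
    a: float
    centroid_distance_mm: float | None = None


@dataclass(frozen=True)
class CohortTestReport:
    """Friedman test across metrics with Sidak-adjusted post hocs."""

    statistic: float
    df: int
    pvalue: float
    alpha: float
    posthoc: pd.DataFrame | None


def nodal_metric_ensemble(
    net: FunctionalNetwork, ensemble: SubsampleEnsemble, metric: str
) -> np.ndarray:
    """Metric values per iteration, NaN-padded to the full contact set.

    Returns an (n_iter, n_contacts) array; entry (t, i) is NaN when contact
    i was removed in iteration t or the metric was undefined there (e.g.
    control centrality on a subsample with zero synchronizability).
    """
    fn = NODAL_METRICS[metric]
    out = np.full((ensemble.n_iter, net.n_contacts), np.nan)
    for t, retained in enumerate(ensemble.retained_sets):
        sub = net.subnetwork(retained)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[t, list(retained)] = fn(sub)
        except ValueError:
            continue  # undefined on this subsample; row stays NaN
    return out


def global_metric_ensemble(
    net: FunctionalNetwork, ensemble: SubsampleEnsemble, metric: str
) -> np.ndarray:
    """Global metric value per iteration (NaN where undefined)."""
    fn = GLOBAL_METRICS[metric]
    out = np.full(ensemble.n_iter, np.nan)
    for t, retained in enumerate(ensemble.retained_sets):
        try:
            out[t] = fn(net.subnetwork(retained))
        except ValueError:
            continue
    return out


def _variance_components_nodal(values: np.ndarray) -> tuple[float, float]:
    n_iter, n_contacts = values.shape
    retained_counts = np.sum(~np.isnan(values), axis=0)
    usable = retained_counts >= 2
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} contact(s) retained in < 2 iterations "
            "excluded from the error-variance average",
            stacklevel=3,
        )
    if not usable.any():
        raise ValueError("no contact retained in >= 2 iterations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_contact_var = np.nanvar(values[:, usable], axis=0, ddof=1)
        var_error = float(np.mean(per_contact_var))
        per_iter_var = np.nanvar(values, axis=1, ddof=1)
    per_iter_var = per_iter_var[~np.isnan(per_iter_var)]
    if per_iter_var.size == 0:
        raise ValueError("no iteration with >= 2 retained contacts")
    var_true = float(np.mean(per_iter_var))
    return var_true, var_error


def reliability_nodal(
    values: np.ndarray,
    metric: str = "",
    removal_fraction: float | None = None,
) -> ReliabilityReport:
    """Reliability of a nodal metric under repeated subsampling.

    ``values`` is the (n_iter, n_contacts) NaN-padded ensemble from
    :func:`nodal_metric_ensemble`. The error variance is each contact's
    variance across the iterations in which it was retained, averaged over
    contacts; the true-score variance is the across-contact variance within
    an iteration, averaged over iterations. Both use the unbiased (n-1)
    denominator.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need an (n_iter >= 2) x n_contacts array")
    var_true, var_error = _variance_components_nodal(values)
    total = var_true + var_error
    if total == 0.0:
        raise ValueError("zero total variance: reliability undefined")
    return ReliabilityReport(
        metric=metric,
        removal_fraction=removal_fraction,
        R=var_true / total,
        var_true=var_true,
        var_error=var_error,
        n_iter=values.shape[0],
    )


def reliability_global(
    values: np.ndarray,
    metric: str = "",
    removal_fraction: float | None = None,
) -> ReliabilityReport:
    """Reliability of a global metric across a patient cohort.

    ``values`` is patients x iterations. The error variance is each
    patient's variance across iterations, averaged over patients; the
    true-score variance is the across-patient variance within an iteration,
    averaged over iterations (both computed on the subsampled values, which
    avoids biasing R upward for metrics whose scale grows with network
    size).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need a (patients >= 2) x (iterations >= 2) array")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var_error = float(np.nanmean(np.nanvar(values, axis=1, ddof=1)))
        var_true = float(np.nanmean(np.nanvar(values, axis=0, ddof=1)))
    total = var_true + var_error
    if not np.isfinite(total) or total == 0.0:
        raise ValueError("zero or undefined total variance: reliability undefined")
    return ReliabilityReport(
        metric=metric,
        removal_fraction=removal_fraction,
        R=var_true / total,
        var_true=var_true,
        var_error=var_error,
        n_iter=values.shape[1],
    )


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def rank_stability(original: np.ndarray, values: np.ndarray) -> float:
    """Mean Spearman correlation between original and subsampled rankings.

    Each iteration is compared on its retained contacts only (>= 3
    required); iterations where either vector is constant have undefined
    rank correlation and are dropped with a warning.
    """
    original = np.asarray(original, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != original.size:
        raise ValueError("values must be n_iter x len(original)")
    rhos = []
    n_dropped = 0
    for row in values:
        mask = ~np.isnan(row)
        if mask.sum() < 3:
            n_dropped += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = _spearman(original[mask], row[mask])
        if np.isnan(rho):
            n_dropped += 1
            continue
        rhos.append(rho)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} iteration(s) dropped from rank stability "
            "(too few contacts or constant values)",
            stacklevel=2,
        )
    if not rhos:
        raise ValueError("no iteration yielded a defined rank correlation")
    return float(np.mean(rhos))


def agreement(original, subsampled, metric_class: str) -> float:
    """Agreement ``a`` between the original and one subsampled metric.

    Nodal: Spearman's rho between the original and subsampled vectors on
    the retained contacts (``subsampled`` may be NaN-padded to full
    length). Global: a = -|(m_new - m_old) / m_old|, which is 0 iff the
    values agree exactly.
    """
    if metric_class == "global":
        m_old = float(original)
        m_new = float(subsampled)
        if m_old == 0.0:
            raise ValueError("global agreement undefined for original value 0")
        return -abs((m_new - m_old) / m_old) + 0.0  # +0.0 avoids negative zero
    if metric_class == "nodal":
        original = np.asarray(original, dtype=float)
        subsampled = np.asarray(subsampled, dtype=float)
        if original.shape != subsampled.shape:
            raise ValueError("nodal agreement requires aligned vectors")
        mask = ~(np.isnan(original) | np.isnan(subsampled))
        if mask.sum() < 3:
            raise ValueError("nodal agreement requires >= 3 shared contacts")
        return _spearman(original[mask], subsampled[mask])
    raise ValueError(f"metric_class must be 'nodal' or 'global', got {metric_class!r}")


def contiguous_agreement_records(
    net: FunctionalNetwork,
    layout: ElectrodeLayout,
    ensemble: SubsampleEnsemble,
    metric: str,
) -> list[AgreementRecord]:
    """Agreement vs. onset-zone distance for each contiguous removal.

    For every removal set in the ensemble, computes the agreement ``a``
    with the original network and the distance between the removed-set
    centroid and the onset-zone centroid.
    """
    soz = list(layout.soz_indices)
    if not soz:
        raise ValueError("layout has no seizure-onset-zone contacts")
    if metric in GLOBAL_METRICS:
        cls, fn = "global", GLOBAL_METRICS[metric]
        original = fn(net)
    elif metric in NODAL_METRICS:
        cls, fn = "nodal", NODAL_METRICS[metric]
        original = fn(net)
    else:
        raise KeyError(f"unknown metric {metric!r}")
    records = []
    for retained, removed in zip(ensemble.retained_sets, ensemble.removed_sets()):
        sub = net.subnetwork(retained)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub_val = fn(sub)
        except ValueError:
            continue
        if cls == "nodal":
            padded = np.full(net.n_contacts, np.nan)
            padded[list(retained)] = sub_val
            a = agreement(original, padded, "nodal")
        else:
            a = agreement(original, sub_val, "global")
        records.append(
            AgreementRecord(
                metric=metric,
                scheme=ensemble.scheme,
                removed=removed,
                a=a,
                centroid_distance_mm=centroid_distance(removed, soz, layout),
            )
        )
    return records


def distance_agreement_association(records) -> tuple[float, float]:
    """Spearman's rho between removal distance and agreement, and its
    Fisher transform z = atanh(rho).

    Accepts a list of :class:`AgreementRecord` or a (distances, agreements)
    pair of sequences. |rho| = 1 has an infinite Fisher transform and is
    rejected.
    """
    if isinstance(records, tuple) and len(records) == 2:
        distances, values = (np.asarray(x, dtype=float) for x in records)
    else:
        distances = np.array([r.centroid_distance_mm for r in records], dtype=float)
        values = np.array([r.a for r in records], dtype=float)
    if distances.size < 4:
        raise ValueError("need >= 4 records with distances")
    rho = _spearman(distances, values)
    if np.isnan(rho):
        raise ValueError("rank correlation undefined (constant input)")
    if abs(rho) >= 1.0 - 1e-12:
        raise ValueError("|rho| = 1: Fisher transform is infinite")
    return rho, float(np.arctanh(rho))


def soz_comparison(
    targeted_a: float, sparing_a: np.ndarray
) -> tuple[float, float, float]:
    """Compare onset-zone-targeted vs. onset-zone-sparing agreement.

    Returns (mean sparing agreement, mean sparing - targeted, fraction of
    sparing agreements strictly greater than the targeted agreement).
    """
    sparing_a = np.asarray(sparing_a, dtype=float)
    sparing_a = sparing_a[~np.isnan(sparing_a)]
    if sparing_a.size == 0:
        raise ValueError("sparing ensemble is empty")
    mean_sparing = float(sparing_a.mean())
    percentile = float(np.mean(sparing_a > targeted_a))
    return mean_sparing, mean_sparing - targeted_a, percentile


def signed_relative_difference(original: float, subsampled: float) -> float:
    """(new - old) / old, sign preserved (unlike the agreement measure)."""
    if original == 0.0:
        raise ValueError("relative difference undefined for original value 0")
    return (subsampled - original) / original


def cohort_metric_comparison(
    values: pd.DataFrame, alpha: float = 0.05
) -> CohortTestReport:
    """Friedman test across metric columns, post hoc pairwise Sidak tests.

    ``values`` is a patients x metrics table with no missing cells. When
    the Friedman test is significant at ``alpha``, all pairwise metric
    comparisons are performed on the Friedman mean ranks (normal
    approximation) with Sidak correction for the number of pairs.
    """
    if values.isna().any().any():
        raise ValueError("metric table has missing cells")
    n, k = values.shape
    if n < 3 or k < 3:
        raise ValueError(f"need >= 3 patients and >= 3 metrics, got {n} x {k}")
    arr = values.to_numpy(dtype=float)
    stat, p = stats.friedmanchisquare(*(arr[:, j] for j in range(k)))
    posthoc = None
    if p < alpha:
        ranks = stats.rankdata(arr, axis=1)
        mean_ranks = ranks.mean(axis=0)
        se = np.sqrt(k * (k + 1) / (6.0 * n))
        m = k * (k - 1) // 2
        rows = []
        cols = list(values.columns)
        for i in range(k):
            for j in range(i + 1, k):
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p_raw = 2.0 * stats.norm.sf(abs(z))
                p_adj = 1.0 - (1.0 - p_raw) ** m
                rows.append(
                    {
                        "metric_a": cols[i],
                        "metric_b": cols[j],
                        "z": z,
                        "p_raw": p_raw,
                        "p_sidak": p_adj,
                        "significant": p_adj < alpha,
                    }
                )
        posthoc = pd.DataFrame(rows)
    return CohortTestReport(
        statistic=float(stat), df=k - 1, pvalue=float(p), alpha=alpha, posthoc=posthoc
    )


def cohort_reliability(
    cohort,
    fraction: float,
    n_iter: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Reliability of every metric on a cohort of (network, layout) pairs.

    Each patient gets an independent random-removal ensemble (substream of
    the master seed). Returns a patients x nodal-metrics table of
    per-patient reliabilities, and the cohort-level reliability of each
    global metric (true-score variance across patients). Patients where a
    nodal metric is degenerate are left as NaN in the table.
    """
    nodal_rows = []
    global_values = {name: [] for name in GLOBAL_METRICS}
    for p, (net, _layout) in enumerate(cohort):
        sub_seed = int(np.random.default_rng([seed, 7, p]).integers(2**31 - 1))
        ens = random_subsample(net, fraction, n_iter=n_iter, seed=sub_seed)
        row = {}
        for name in NODAL_METRICS:
            values = nodal_metric_ensemble(net, ens, name)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    row[name] = reliability_nodal(values, metric=name).R
            except ValueError:
                row[name] = np.nan
        nodal_rows.append(row)
        for name in GLOBAL_METRICS:
            global_values[name].append(global_metric_ensemble(net, ens, name))
    global_R = {
        name: reliability_global(np.array(vals), metric=name).R
        for name, vals in global_values.items()
    }
    return pd.DataFrame(nodal_rows), global_R


def bonferroni_alpha(family_alpha: float = 0.05, n_tests: int = 1) -> float:
    """Per-test significance level under Bonferroni correction."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return family_alpha / n_tests


def size_reliability_association(
    contact_counts: np.ndarray, reliabilities: np.ndarray
) -> tuple[float, float]:
    """Spearman correlation between implant size and reliability.

    Tests whether patients with more contacts are less vulnerable to
    incomplete sampling. Returns (rho, p).
    """
    contact_counts = np.asarray(contact_counts, dtype=float)
    reliabilities = np.asarray(reliabilities, dtype=float)
    if contact_counts.size < 4:
        raise ValueError("need >= 4 patients")
    res = stats.spearmanr(contact_counts, reliabilities)
    if np.isnan(res.statistic):
        raise ValueError("rank correlation undefined (constant input)")
    return float(res.statistic), float(res.pvalue)
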