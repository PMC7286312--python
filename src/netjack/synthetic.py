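"""Synthetic recordings, layouts, and networks with known ground truth.

Real intracranial EEG lives on clinical portals and cannot ship with the
package, so every downstream stage is exercised on simulated data whose
coupling structure is known exactly. The generative model is deliberately
minimal: contacts within a coupling block share a latent narrowband source
(bandpass-filtered Gaussian noise), contacts in different blocks have
independent sources, and each channel adds i.i.d. Gaussian sensor noise.
This reproduces the one feature the coherence pipeline depends on --
band-limited correlated activity within groups of contacts -- without
modeling seizure dynamics.

All generators are deterministic functions of their integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from scipy import signal

from .core import ElectrodeLayout, FunctionalNetwork, Recording

__all__ = [
    "SimulationTruth",
    "simulate_layout",
    "simulate_recording",
    "simulate_adjacency",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth behind a simulated recording.

    ``coupling_blocks`` partitions the contact indices into source groups;
    ``source_signals`` holds one latent trace per block (blocks x samples).
    """

    coupling_blocks: tuple[tuple[int, ...], ...]
    source_signals: np.ndarray
    soz_contacts: tuple[int, ...]
    noise_sd: float
    seed: int


def simulate_layout(
    n_rows: int,
    n_cols: int,
    spacing_mm: float = 10.0,
    n_soz: int = 1,
    seed: int = 0,
) -> ElectrodeLayout:
    """Planar grid of contacts with a contiguous seizure onset zone.

    Contacts sit on an ``n_rows`` x ``n_cols`` grid at ``spacing_mm``
    intercontact spacing (the standard clinical grid pitch is 10 mm), z = 0.
    The onset zone is a randomly seeded contact plus its ``n_soz - 1``
    nearest neighbors (distance ties to the lowest index), so it is always
    spatially contiguous. Resected flags default to the onset zone,
    emulating a resection that targeted it.
    """
    n = n_rows * n_cols
    if n_rows < 1 or n_cols < 1 or n < 4:
        raise ValueError(f"grid must have >= 4 contacts, got {n_rows} x {n_cols}")
    if not 1 <= n_soz < n:
        raise ValueError(f"n_soz must be in [1, {n - 1}], got {n_soz}")
    if spacing_mm <= 0:
        raise ValueError(f"spacing must be positive, got {spacing_mm}")
    rr, cc = np.divmod(np.arange(n), n_cols)
    coords = np.column_stack([rr * spacing_mm, cc * spacing_mm, np.zeros(n)])
    labels = [f"E{i:03d}" for i in range(n)]
    layout = ElectrodeLayout.from_arrays(labels, coords)
    rng = np.random.default_rng(seed)
    soz_seed = int(rng.integers(n))
    soz = layout.nearest_neighbors(soz_seed, n_soz)
    flags = np.zeros(n, bool)
    flags[soz] = True
    return ElectrodeLayout.from_arrays(labels, coords, soz=flags, resected=flags)


def _layout_for_n(n: int, spacing_mm: float, n_soz: int, seed: int) -> ElectrodeLayout:
    """Grid layout truncated to exactly ``n`` contacts."""
    n_cols = max(2, math.ceil(math.sqrt(n)))
    n_rows = math.ceil(n / n_cols)
    full = simulate_layout(n_rows, n_cols, spacing_mm, n_soz=1, seed=seed)
    layout = full.subset(range(n))
    rng = np.random.default_rng(seed)
    soz_seed = int(rng.integers(n))
    soz = layout.nearest_neighbors(soz_seed, n_soz)
    flags = np.zeros(n, bool)
    flags[soz] = True
    return ElectrodeLayout.from_arrays(layout.labels, layout.coords, soz=flags, resected=flags)


def simulate_recording(
    layout: ElectrodeLayout,
    *,
    n_blocks: int = 2,
    blocks: tuple[tuple[int, ...], ...] | None = None,
    band: tuple[float, float] = (95.0, 105.0),
    noise_sd: float = 0.5,
    fs: float = 512.0,
    duration: float = 1.0,
    seed: int = 0,
) -> tuple[Recording, SimulationTruth]:
    """Block-coupled narrowband recording on a layout.

    Each coupling block has one latent source: white Gaussian noise
    bandpass-filtered to ``band`` (order-4 Butterworth, zero phase) and
    standardized to unit variance. Every contact's trace is its block's
    source plus independent N(0, noise_sd^2) sensor noise, so within-block
    coherence in the band is high and between-block coherence is at chance.

    Blocks default to ``n_blocks`` contiguous index ranges of near-equal
    size. The default band matches the high-gamma analysis band and the
    default rate the 512-Hz clinical acquisition rate.
    """
    n = len(layout)
    if duration < 1.0:
        raise ValueError(f"duration must be >= 1 s, got {duration}")
    if band[1] >= fs / 2.0:
        raise ValueError(f"band upper edge {band[1]} Hz at or above Nyquist {fs / 2}")
    if not 0 < band[0] < band[1]:
        raise ValueError(f"invalid band {band}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if blocks is None:
        if not 1 <= n_blocks <= n:
            raise ValueError(f"n_blocks must be in [1, {n}]")
        edges = np.linspace(0, n, n_blocks + 1).astype(int)
        blocks = tuple(
            tuple(range(edges[b], edges[b + 1])) for b in range(n_blocks)
        )
    flat = sorted(i for blk in blocks for i in blk)
    if flat != list(range(n)):
        raise ValueError("blocks must partition the contact indices exactly once")

    n_samp = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    sos = signal.butter(4, list(band), btype="bandpass", fs=fs, output="sos")
    # Generate with padding so filter edge effects do not reach the window.
    pad = int(round(0.5 * fs))
    sources = np.empty((len(blocks), n_samp))
    for b in range(len(blocks)):
        raw = rng.standard_normal(n_samp + 2 * pad)
        filt = signal.sosfiltfilt(sos, raw)[pad : pad + n_samp]
        sources[b] = filt / filt.std()

    samples = np.empty((n, n_samp))
    for b, blk in enumerate(blocks):
        for i in blk:
            samples[i] = sources[b]
    samples += noise_sd * rng.standard_normal(samples.shape)

    rec = Recording(samples=samples, fs=fs, labels=layout.labels)
    truth = SimulationTruth(
        coupling_blocks=tuple(tuple(int(i) for i in blk) for blk in blocks),
        source_signals=sources,
        soz_contacts=tuple(int(i) for i in layout.soz_indices),
        noise_sd=float(noise_sd),
        seed=int(seed),
    )
    return rec, truth


def simulate_adjacency(
    n: int,
    model: str = "uniform_random",
    seed: int = 0,
    *,
    weight: float = 1.0,
    block_sizes: tuple[int, ...] | None = None,
    within: float = 0.6,
    between: float = 0.15,
    jitter: float = 0.1,
    strength_heterogeneity: tuple[float, float] = (0.4, 1.0),
) -> FunctionalNetwork:
    """Direct adjacency fixtures for the graph-metric stages.

    Models: ``complete`` (all off-diagonal weights equal to ``weight``),
    ``path`` (a chain 0-1-...-n-1), ``uniform_random`` (i.i.d. U(0, 1)
    weights), and ``block`` -- a stylized coherence matrix with the two
    features real functional networks show: community structure (two-level
    base weights ``within``/``between`` on a partition, plus uniform
    jitter) and heterogeneous node strength (each contact draws a coupling
    propensity u_i uniform on ``strength_heterogeneity`` and edge ij is
    scaled by sqrt(u_i u_j)).
    """
    if n < 2:
        raise ValueError(f"need >= 2 nodes, got {n}")
    labels = tuple(f"E{i:03d}" for i in range(n))
    rng = np.random.default_rng(seed)
    adj = np.zeros((n, n))
    if model == "complete":
        adj[:] = weight
    elif model == "path":
        idx = np.arange(n - 1)
        adj[idx, idx + 1] = weight
        adj[idx + 1, idx] = weight
    elif model == "uniform_random":
        iu = np.triu_indices(n, k=1)
        vals = rng.uniform(size=len(iu[0]))
        adj[iu] = vals
        adj = adj + adj.T
    elif model == "block":
        if block_sizes is None:
            block_sizes = (n - n // 2, n // 2)
        if sum(block_sizes) != n:
            raise ValueError(f"block sizes {block_sizes} do not sum to {n}")
        membership = np.repeat(np.arange(len(block_sizes)), block_sizes)
        same = membership[:, None] == membership[None, :]
        base = np.where(same, within, between)
        iu = np.triu_indices(n, k=1)
        noise = rng.uniform(0.0, jitter, size=len(iu[0]))
        propensity = rng.uniform(*strength_heterogeneity, size=n)
        scale = np.sqrt(np.outer(propensity, propensity))
        adj[iu] = (base[iu] + noise) * scale[iu]
        adj = adj + adj.T
        adj = np.clip(adj, 0.0, 1.0)
    else:
        raise ValueError(f"unknown adjacency model {model!r}")
    np.fill_diagonal(adj, 0.0)
    return FunctionalNetwork(adjacency=adj, labels=labels)


def simulate_cohort(
    n_patients: int,
    *,
    size_range: tuple[int, int] = (16, 118),
    soz_fraction: float = 0.15,
    spacing_mm: float = 10.0,
    model: str = "block",
    seed: int = 0,
    **model_params,
) -> list[tuple[FunctionalNetwork, ElectrodeLayout]]:
    """Independent patients with heterogeneous contact counts.

    Contact counts are drawn uniformly from ``size_range`` (default 16-118,
    the span observed in clinical grid implants); each patient gets a grid
    layout with a contiguous onset zone of ``soz_fraction`` of contacts
    (at least one) and a block-structured adjacency.
    """
    if n_patients < 2:
        raise ValueError(f"need >= 2 patients, got {n_patients}")
    lo, hi = size_range
    if not 4 <= lo <= hi:
        raise ValueError(f"invalid size range {size_range}")
    sizes_rng = np.random.default_rng([seed, 0])
    sizes = sizes_rng.integers(lo, hi + 1, size=n_patients)
    cohort = []
    for p, n in enumerate(sizes):
        n = int(n)
        sub_seed = int(np.random.default_rng([seed, 1, p]).integers(2**31 - 1))
        n_soz = max(1, round(soz_fraction * n))
        layout = _layout_for_n(n, spacing_mm, n_soz, seed=sub_seed)
        net = simulate_adjacency(n, model=model, seed=sub_seed, **model_params)
        cohort.append((net, layout))
    return cohort
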