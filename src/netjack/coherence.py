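"""Functional networks from band-averaged multitaper coherence.

Edges are the magnitude-squared coherence between contact pairs, estimated
with Slepian (DPSS) tapers on a short window and averaged over the frequency
bins inside a target band (high gamma 95-105 Hz by default, beta 15-25 Hz as
the sensitivity band). Coherence is phase-blind and bounded in [0, 1], which
makes the resulting adjacency matrix symmetric and nonnegative by
construction.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import windows

from .core import BandSpec, FunctionalNetwork, Recording

__all__ = [
    "multitaper_coherence_network",
    "threshold_to_density",
    "peri_ictal_windows",
    "DEFAULT_PERI_ICTAL_OFFSETS",
]

#: Window anchors relative to the earliest electrographic change (seconds).
DEFAULT_PERI_ICTAL_OFFSETS = (-10.0, -5.0, 0.0, 5.0, 10.0)


def multitaper_coherence_network(
    rec: Recording,
    window_start: float = 0.0,
    window_len: float = 1.0,
    band: BandSpec = BandSpec("high_gamma", 95.0, 105.0),
    *,
    nw: float = 2.0,
    n_tapers: int = 3,
) -> FunctionalNetwork:
    """Coherence adjacency for one window of a recording.

    Parameters
    ----------
    rec
        Preprocessed recording (contacts x timepoints).
    window_start, window_len
        Window anchor and length in seconds; the window must lie inside the
        recording.
    band
        Frequency band over which magnitude-squared coherence is averaged
        (inclusive bin bounds).
    nw, n_tapers
        Time-bandwidth product and Slepian taper count. The defaults
        (NW = 2, 3 tapers) give ~2 Hz half-bandwidth smoothing on a 1-s
        window.

    Returns
    -------
    FunctionalNetwork
        Symmetric zero-diagonal adjacency with weights in [0, 1]; entry
        (i, j) is the mean magnitude-squared coherence over in-band bins.
    """
    i0 = int(round(window_start * rec.fs))
    n_win = int(round(window_len * rec.fs))
    if n_win < 8:
        raise ValueError(f"window of {window_len} s is too short at fs={rec.fs}")
    if i0 < 0 or i0 + n_win > rec.n_samples:
        raise ValueError(
            f"window [{window_start}, {window_start + window_len}] s outside "
            f"recording of {rec.duration} s"
        )
    if band.hi >= rec.fs / 2.0:
        raise ValueError(f"band upper edge {band.hi} Hz at or above Nyquist")

    x = rec.samples[:, i0 : i0 + n_win]
    x = x - x.mean(axis=1, keepdims=True)

    tapers = windows.dpss(n_win, nw, Kmax=n_tapers)  # (K, n_win)
    freqs = np.fft.rfftfreq(n_win, d=1.0 / rec.fs)
    in_band = (freqs >= band.lo) & (freqs <= band.hi)
    if not in_band.any():
        raise ValueError(
            f"no FFT bins inside [{band.lo}, {band.hi}] Hz for a "
            f"{window_len}-s window"
        )

    # Tapered spectra restricted to in-band bins: (contacts, K, n_bins).
    spectra = np.fft.rfft(x[:, None, :] * tapers[None, :, :], axis=2)[:, :, in_band]

    # Cross-spectra averaged over tapers: (contacts, contacts, n_bins).
    sxy = np.einsum("ikf,jkf->ijf", spectra, np.conj(spectra)) / n_tapers
    auto = np.einsum("iif->if", sxy).real
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        msc = np.abs(sxy) ** 2 / denom
    msc = np.where(denom > 0, msc, 0.0)

    adj = msc.mean(axis=2)
    np.clip(adj, 0.0, 1.0, out=adj)
    adj = (adj + adj.T) / 2.0
    np.fill_diagonal(adj, 0.0)
    return FunctionalNetwork(
        adjacency=adj,
        labels=rec.labels,
        band=band,
        window=(float(window_start), float(window_len)),
    )


def threshold_to_density(
    net: FunctionalNetwork, density: float = 0.5
) -> FunctionalNetwork:
    """Zero all edges strictly below the weight achieving a target density.

    The threshold ``w`` is the smallest retained weight such that the
    fraction of nonzero unordered pairs equals ``density`` to within one
    edge; weights tied at ``w`` are retained, so heavy ties can overshoot
    the target (reported with a warning). Retained weights are unchanged.
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    n = net.n_contacts
    iu = np.triu_indices(n, k=1)
    weights = net.adjacency[iu]
    n_pairs = len(weights)
    target_edges = int(round(density * n_pairs))
    if target_edges >= np.count_nonzero(weights):
        return net  # already at or below target density
    w = np.sort(weights)[::-1][target_edges - 1] if target_edges > 0 else np.inf
    adj = np.array(net.adjacency)
    adj[adj < w] = 0.0
    out = FunctionalNetwork(adj, net.labels, band=net.band, window=net.window)
    achieved = np.count_nonzero(adj[iu])
    if abs(achieved - target_edges) > 1:
        warnings.warn(
            f"tied weights prevent density {density:.3g}: achieved "
            f"{achieved}/{n_pairs} = {achieved / n_pairs:.3g}",
            stacklevel=2,
        )
    return out


def peri_ictal_windows(
    eec_time: float,
    offsets: tuple[float, ...] = DEFAULT_PERI_ICTAL_OFFSETS,
    window_len: float = 1.0,
) -> list[tuple[float, float]]:
    """Analysis windows anchored around the earliest electrographic change.

    Each window *begins* at ``eec_time + offset``; the default offsets span
    10 s before to 10 s after the marked onset.
    """
    if eec_time < 0:
        raise ValueError(f"EEC time must be nonnegative, got {eec_time}")
    return [(float(eec_time + off), float(window_len)) for off in offsets]
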