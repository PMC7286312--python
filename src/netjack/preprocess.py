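"""Signal conditioning ahead of coherence estimation.

The pipeline applies, in order: common average re-referencing, elliptic
bandpass plus power-line notch filtering, and per-channel autoregressive
prewhitening. Each stage preserves the channel count and is deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core import Recording

__all__ = ["common_average_reference", "bandpass_and_notch", "prewhiten_ar"]


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the across-contact mean from every timepoint.

    Removes signal components common to all contacts (reference drift,
    shared environmental noise). Requires at least two contacts.
    """
    if rec.n_contacts < 2:
        raise ValueError("common average reference requires >= 2 contacts")
    return rec.with_samples(rec.samples - rec.samples.mean(axis=0, keepdims=True))


def bandpass_and_notch(
    rec: Recording,
    lo: float = 5.0,
    hi: float = 115.0,
    notch: float = 60.0,
    *,
    order: int = 4,
    rp: float = 0.5,
    rs: float = 40.0,
    notch_q: float = 30.0,
) -> Recording:
    """Elliptic bandpass [lo, hi] Hz plus an IIR notch at ``notch`` Hz.

    Both filters are applied forward-backward (zero phase). Defaults: order-4
    elliptic with 0.5 dB passband ripple and 40 dB stopband attenuation, and
    a second-order notch with quality factor 30.
    """
    nyq = rec.fs / 2.0
    if not 0 < lo < hi:
        raise ValueError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= nyq:
        raise ValueError(f"upper cutoff {hi} Hz must be below Nyquist {nyq} Hz")
    sos = signal.ellip(order, rp, rs, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.samples, axis=1)
    if notch is not None and 0 < notch < nyq:
        b, a = signal.iirnotch(notch, notch_q, fs=rec.fs)
        out = signal.filtfilt(b, a, out, axis=1)
    return rec.with_samples(out)


def prewhiten_ar(rec: Recording, order: int = 1) -> Recording:
    """Replace each channel by the residuals of an AR(``order``) fit.

    Prewhitening flattens the power spectrum, de-emphasising slow dynamics
    and reducing spurious coherence from shared low-frequency structure.
    Coefficients are estimated per channel by least squares on the lagged
    design matrix; the output has ``order`` fewer timepoints than the input.
    A constant channel yields all-zero residuals.
    """
    if order < 1:
        raise ValueError(f"AR order must be >= 1, got {order}")
    x = rec.samples
    n_t = x.shape[1]
    if n_t <= order:
        raise ValueError(f"need more than {order} timepoints, got {n_t}")
    resid = np.empty((x.shape[0], n_t - order))
    for ch in range(x.shape[0]):
        resid[ch] = _ar_residuals(x[ch], order)
    return rec.with_samples(resid)


def _ar_residuals(x: np.ndarray, order: int) -> np.ndarray:
    y = x[order:]
    design = np.column_stack([x[order - k : len(x) - k] for k in range(1, order + 1)])
    if np.ptp(x) == 0.0:
        return np.zeros_like(y)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef
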