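"""Shared zero-phase least-squares FIR band-pass filtering.

One filter implementation serves both the synthetic-signal generator and
the connectivity pipeline, so that planted band-limited components and
the band-pass stage that later analyses them agree exactly on what "in
band" means.

Design: linear-phase FIR obtained by least squares (``scipy.signal.firls``),
applied forward and backward (two-way filtering) so the net response is
zero-phase with magnitude |H(f)|^2.  Filter order follows the common
M/EEG heuristic of three cycles of the band's low edge, order = 3·fs/f_lo,
capped at one third of the signal length.  Transition widths scale with
the band edges (15% of the edge, at least 1 Hz, never past DC/Nyquist);
at these orders low-frequency bands reach >40 dB two-pass attenuation
1 Hz outside the band, while the shortest (gamma) filter trades edge
sharpness for length — see docs/methods.md for measured responses.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import signal

from .bands import Band

__all__ = ["fir_order", "design_bandpass", "filtfilt_fir", "bandpass_fir"]


def _transition_widths(f_lo: float, f_hi: float, fs: float) -> tuple[float, float]:
    # 0.5 Hz transitions keep the ramp's power mass (~tw/5 per side in
    # |H|^4 units) small next to the narrowest analysis band
    nyq = fs / 2.0
    return (min(0.5 * f_lo, 0.5), min(0.5 * (nyq - f_hi), 0.5))


def fir_order(
    f_lo: float, fs: float, n_samples: int | None = None,
    f_hi: float | None = None,
) -> int:
    """Filter order: 3 cycles of the low band edge, raised where needed.

    The EEGLAB-style rule order = 3·fs/f_lo under-resolves bands whose
    transition width is narrower than the filter's spectral resolution
    (~3.3·fs/order), producing passband errors of 10–25%; the order is
    therefore floored at 3.3·fs/min(transition widths) when the upper
    edge is known.  Always even (odd tap count), capped at one third of
    the signal length.
    """
    if f_lo <= 0:
        raise ValueError("low band edge must be positive")
    order = int(round(3.0 * fs / f_lo))
    if f_hi is not None:
        tw_lo, tw_hi = _transition_widths(f_lo, f_hi, fs)
        # the resolution floor is not pushed below 0.5 Hz transitions
        # (delta's 0.25 Hz lower skirt would triple the order for
        # sharpness outside the analysis range)
        order = max(order, int(round(3.3 * fs / max(min(tw_lo, tw_hi), 0.5))))
    if n_samples is not None:
        order = min(order, n_samples // 3)
    if order < 4:
        raise ValueError(
            f"signal too short for a band-pass at {f_lo} Hz (order {order})"
        )
    return order + (order % 2)  # even order -> odd tap count for firls


@lru_cache(maxsize=64)
def design_bandpass(
    f_lo: float, f_hi: float, fs: float, order: int, tw: float | None = None
) -> np.ndarray:
    """Least-squares linear-phase band-pass taps for ``(f_lo, f_hi)`` Hz.

    ``tw`` overrides the default edge-proportional transition widths
    (15% of the edge, at least 1 Hz).
    """
    nyq = fs / 2.0
    if not 0 < f_lo < f_hi < nyq:
        raise ValueError(f"band ({f_lo}, {f_hi}) Hz infeasible at fs={fs} Hz")
    if tw is not None:
        tw_lo = min(0.5 * f_lo, tw)
        tw_hi = min(0.5 * (nyq - f_hi), tw)
    else:
        tw_lo, tw_hi = _transition_widths(f_lo, f_hi, fs)
    # transitions are constrained as linear ramps: leaving them as
    # "don't care" gaps lets the least-squares response bulge above
    # unity just outside the passband
    bands = [0.0, f_lo - tw_lo, f_lo - tw_lo, f_lo, f_lo, f_hi,
             f_hi, f_hi + tw_hi, f_hi + tw_hi, nyq]
    desired = [0, 0, 0, 1, 1, 1, 1, 0, 0, 0]
    taps = signal.firls(order + 1, bands, desired, fs=fs)
    # very wide bands at high order make the least-squares system
    # ill-conditioned; fall back to a windowed-sinc design there
    _, h = signal.freqz(taps, worN=[0.5 * (f_lo + f_hi)], fs=fs)
    if not np.all(np.isfinite(taps)) or np.abs(taps).max() > 5.0 \
            or not 0.5 < np.abs(h[0]) < 2.0:
        taps = signal.firwin(order + 1, [f_lo, f_hi], pass_zero=False,
                             window="hamming", fs=fs)
    return taps


def filtfilt_fir(taps: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Two-way (forward-backward) FIR filtering along the last axis.

    Uses FFT convolution in 'same' mode; edge transients within one
    filter order of each end are left in place and must be discarded by
    the caller where they matter (the connectivity stage does).
    """
    x = np.asarray(x, dtype=float)
    one_d = x.ndim == 1
    x2 = np.atleast_2d(x)
    t2 = taps[np.newaxis, :]
    y = signal.fftconvolve(x2, t2, mode="same", axes=-1)
    y = signal.fftconvolve(y[:, ::-1], t2, mode="same", axes=-1)[:, ::-1]
    return y[0] if one_d else y


def bandpass_fir(ts: np.ndarray, band: Band, fs: float) -> np.ndarray:
    """Zero-phase least-squares FIR band-pass of ``ts`` (…, T) into ``band``."""
    ts = np.asarray(ts, dtype=float)
    order = fir_order(band.lo, fs, ts.shape[-1], band.hi)
    taps = design_bandpass(band.lo, band.hi, fs, order)
    return filtfilt_fir(taps, ts)
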