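"""Leakage-corrected amplitude envelope correlation (AECc).

For each frequency band and epoch, the source time-series are band-pass
filtered (two-way least-squares FIR), pairwise orthogonalized in the
time domain to remove zero-lag (spatial leakage) components, Hilbert
transformed, and the magnitudes of the analytic signals — the amplitude
envelopes — are correlated with Pearson's coefficient.  Because signal
*j* orthogonalized with respect to *i* differs from *i* orthogonalized
with respect to *j*, both directions are computed and averaged, giving
the corrected amplitude envelope correlation; the R × R matrix is
symmetrized by averaging its upper and lower triangles and averaged over
the subject's selected epochs.

Orthogonalization happens at the single-epoch level on the band-passed
real signals, before the analytic transform; a pair that is (numerically)
collinear carries only zero-lag coupling and scores 0.  The first and
last ``filter order`` samples of every envelope are discarded before
correlating, to exclude the two-pass filter's edge transients.

Summaries: whole-brain connectivity is the mean over the R(R−1)/2
distinct pairs; nodal strength is the off-diagonal row sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, ifft

from .bands import Band, BandScheme, DEFAULT_BANDS
from .filters import bandpass_fir, fir_order  # re-exported: shared FIR stage

__all__ = [
    "ConnectivityMatrix",
    "ConnectivitySummary",
    "bandpass_fir",
    "orthogonalize",
    "aecc_pair",
    "connectivity_matrix",
    "summarize_connectivity",
    "analytic_signal",
]

_DEGENERATE_REL_VAR = 1e-12


@dataclass
class ConnectivityMatrix:
    band: str
    matrix: np.ndarray  # (R, R), symmetric, zero diagonal
    n_epochs_averaged: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("connectivity matrix must be symmetric")
        self.matrix = m


@dataclass
class ConnectivitySummary:
    whole_brain: float
    nodal_strength: np.ndarray


def analytic_signal(x: np.ndarray) -> np.ndarray:
    """Analytic signal along the last axis (FFT one-sided doubling)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    X = fft(x, axis=-1)
    h = np.zeros(n)
    if n % 2 == 0:
        h[0] = h[n // 2] = 1.0
        h[1:n // 2] = 2.0
    else:
        h[0] = 1.0
        h[1:(n + 1) // 2] = 2.0
    return ifft(X * h, axis=-1)


def orthogonalize(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Remove from ``y`` its zero-lag projection onto ``x``.

    Returns ``y − (⟨y,x⟩/⟨x,x⟩)·x``; the result has zero inner product
    with ``x``.  Raises on zero-variance ``x``; a residual with variance
    below 1e-12 × var(y) indicates a pure-leakage (collinear) pair and is
    returned with a degeneracy warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = float(x @ x)
    if denom <= 0:
        raise ValueError("cannot orthogonalize against a zero signal")
    resid = y - (float(y @ x) / denom) * x
    if resid.var() <= _DEGENERATE_REL_VAR * max(y.var(), np.finfo(float).tiny):
        warnings.warn("degenerate (pure-leakage) pair: residual is numerically zero",
                      RuntimeWarning)
    return resid


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom <= 0:
        warnings.warn("constant envelope: correlation undefined, scored 0",
                      RuntimeWarning)
        return 0.0
    return float((a @ b) / denom)


def aecc_pair(x: np.ndarray, y: np.ndarray, trim: int = 0) -> float:
    """Corrected amplitude envelope correlation of two band-passed signals.

    Averages the two orthogonalization directions; a degenerate
    (collinear) direction contributes 0.  ``trim`` samples are dropped
    from both ends of every envelope before correlating.
    """
    sl = slice(trim, x.size - trim) if trim > 0 else slice(None)
    cs = []
    for ref, other in ((x, y), (y, x)):
        denom = float(ref @ ref)
        if denom <= 0:
            cs.append(0.0)
            continue
        beta = float(other @ ref) / denom
        resid = other - beta * ref
        if resid.var() <= _DEGENERATE_REL_VAR * max(other.var(), np.finfo(float).tiny):
            cs.append(0.0)
            continue
        env_ref = np.abs(analytic_signal(ref))[sl]
        env_res = np.abs(analytic_signal(resid))[sl]
        cs.append(_pearson(env_ref, env_res))
    return 0.5 * (cs[0] + cs[1])


def _aecc_matrix_epoch(Xf: np.ndarray, trim: int) -> np.ndarray:
    """All ordered-pair AECc terms for one band-passed epoch (R, T).

    Exploits linearity of the analytic transform:
    env(y − βx) = |A(y) − βA(x)|, so per reference region only O(R·T)
    work is needed instead of an analytic transform per pair.
    """
    R, T = Xf.shape
    sl = slice(trim, T - trim) if trim > 0 else slice(None)
    A = analytic_signal(Xf)
    E = np.abs(A)
    var = Xf.var(axis=1)
    dead = var <= 0
    if np.any(dead):
        warnings.warn(f"{int(dead.sum())} constant region(s): rows scored 0",
                      RuntimeWarning)
    C = np.zeros((R, R))
    for i in range(R):
        if dead[i]:
            continue
        xi = Xf[i]
        denom = float(xi @ xi)
        beta = (Xf @ xi) / denom
        resid_var = (Xf - beta[:, None] * xi).var(axis=1)
        degenerate = resid_var <= _DEGENERATE_REL_VAR * np.maximum(var, np.finfo(float).tiny)
        env_res = np.abs(A - beta[:, None] * A[i])[:, sl]
        ei = E[i, sl] - E[i, sl].mean()
        si = np.sqrt(ei @ ei)
        er = env_res - env_res.mean(axis=1, keepdims=True)
        sr = np.sqrt(np.einsum("rt,rt->r", er, er))
        with np.errstate(invalid="ignore", divide="ignore"):
            c = (er @ ei) / (sr * si)
        c[~np.isfinite(c)] = 0.0
        c[degenerate | dead] = 0.0
        C[i] = c  # row i: Pearson(env(x_i), env(x_j ⊥ x_i)) for every j
    np.fill_diagonal(C, 0.0)
    return C


def connectivity_matrix(
    eset,
    band: str | Band,
    scheme: BandScheme = DEFAULT_BANDS,
    corrected: bool = True,
) -> ConnectivityMatrix:
    """Epoch-averaged, symmetrized AECc matrix for one band.

    ``corrected=False`` skips the orthogonalization step (plain AEC),
    kept for demonstrating how much spurious zero-lag coupling the
    correction removes.
    """
    b = scheme[band] if isinstance(band, str) else band
    acc = None
    for ep in eset.epochs:
        order = fir_order(b.lo, eset.fs, ep.shape[-1], b.hi)
        Xf = bandpass_fir(ep, b, eset.fs)
        trim = min(order, (ep.shape[-1] - 2) // 2)
        if corrected:
            C = _aecc_matrix_epoch(Xf, trim)
        else:
            E = np.abs(analytic_signal(Xf))[:, trim:Xf.shape[-1] - trim]
            C = np.corrcoef(E)
            C[~np.isfinite(C)] = 0.0
        sym = 0.5 * (C + C.T)
        acc = sym if acc is None else acc + sym
    M = acc / len(eset.epochs)
    np.fill_diagonal(M, 0.0)
    return ConnectivityMatrix(band=b.name, matrix=M, n_epochs_averaged=len(eset.epochs))


def summarize_connectivity(m: ConnectivityMatrix) -> ConnectivitySummary:
    """Whole-brain mean (distinct pairs) and nodal strengths (row sums)."""
    mat = m.matrix
    iu = np.triu_indices_from(mat, k=1)
    return ConnectivitySummary(
        whole_brain=float(mat[iu].mean()),
        nodal_strength=mat.sum(axis=1),
    )
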