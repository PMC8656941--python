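"""Scalar minimum-variance beamformer.

Sensor-level recordings are projected to source space with one linear
spatial filter per source.  For lead field column *l* and broadband
(0.5–48 Hz) sensor covariance *C*, the scalar minimum-variance filter

    w = C⁻¹ l / (lᵀ C⁻¹ l)

minimises output variance subject to unit gain at the target source
(w·l = 1).  The covariance is estimated on the full recording after
band-pass filtering, and regularised as C + λ·mean(diag C)·I (λ = 0.05
by default) for finite-sample stability; lead fields are taken as given
scalar (fixed-orientation) columns — no head model is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .bands import Band
from .filters import bandpass_fir
from .synthdata import LeadFieldSet, SourceRecording

__all__ = ["BeamformerWeights", "COV_BAND", "compute_weights", "reconstruct_sources"]

COV_BAND = (0.5, 48.0)  # Hz; broadband window for covariance estimation
DEFAULT_REGULARIZATION = 0.05


@dataclass
class BeamformerWeights:
    """Spatial filters (n_sources, n_sensors) with unit gain at each source."""

    weights: np.ndarray
    regularization: float
    cov_band: tuple[float, float] = COV_BAND

    @property
    def n_sources(self) -> int:
        return self.weights.shape[0]


def compute_weights(
    sensor_data: np.ndarray,
    leads: LeadFieldSet,
    regularization: float = DEFAULT_REGULARIZATION,
    fs: float | None = None,
) -> BeamformerWeights:
    """Minimum-variance filter weights from broadband sensor covariance.

    When ``fs`` is given the data are band-passed to the 0.5–48 Hz
    covariance window first; pass ``fs=None`` for data that are already
    band-limited (e.g. analytically constructed test inputs).
    """
    X = np.asarray(sensor_data, dtype=float)
    S, T = X.shape
    if T <= S:
        raise ValueError("need more samples than sensors for a stable covariance")
    L = leads.lead_matrix
    if L.shape[0] != S:
        raise ValueError("lead field sensor count does not match data")
    if fs is not None:
        X = bandpass_fir(X, Band("broadband", *COV_BAND), fs)
    C = np.cov(X)
    lam = regularization * float(np.mean(np.diag(C)))
    C_reg = C + lam * np.eye(S)
    try:
        Cinv_L = linalg.solve(C_reg, L, assume_a="pos")
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError(
            "regularised covariance is singular; increase the regularization "
            f"fraction (currently {regularization})"
        ) from err
    gains = np.einsum("sr,sr->r", L, Cinv_L)  # lᵀ C⁻¹ l per source
    if np.any(gains <= 0):
        raise linalg.LinAlgError(
            "non-positive projected power; covariance ill-conditioned — "
            "increase the regularization fraction"
        )
    W = (Cinv_L / gains).T  # (R, S)
    return BeamformerWeights(weights=W, regularization=regularization)


def reconstruct_sources(
    sensor_data: np.ndarray,
    weights: BeamformerWeights,
    roi_names: list[str],
    fs: float,
    subject_id: str = "",
) -> SourceRecording:
    """Apply spatial filters: source r is ``weights[r] · sensor_data``."""
    X = np.asarray(sensor_data, dtype=float)
    if X.shape[0] != weights.weights.shape[1]:
        raise ValueError(
            f"sensor count mismatch: data has {X.shape[0]}, "
            f"weights expect {weights.weights.shape[1]}"
        )
    if len(roi_names) != weights.n_sources:
        raise ValueError("roi_names length must equal the number of sources")
    return SourceRecording(subject_id, fs, list(roi_names), weights.weights @ X)
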