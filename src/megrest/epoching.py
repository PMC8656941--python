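"""Epoch segmentation, quality scoring and automatic selection.

Continuous source recordings are cut into consecutive non-overlapping
candidate epochs of 16384 samples (13.1 s at 1250 Hz).  Candidates are
screened for three failure modes:

* **amplitude** — extreme values in the temporal domain (artifacts such
  as eye movements or high-frequency noise), detected as any sample
  exceeding 6 robust-z units against the per-region median/MAD of the
  whole recording;
* **ipf_outlier** — the epoch's occipital peak frequency falling outside
  median ± 3·MAD of the subject's candidate-epoch peak frequencies;
* **low_alpha** — occipital alpha1 relative power in the subject's lowest
  quartile, the signature of drowsiness / transition to early sleep.

From the survivors, the epochs with the highest combined rank of peak
frequency and occipital alpha1 power are selected (8 by default, equal
data per subject while avoiding drowsiness bias); ties break toward the
earlier start index and the selected set is returned in chronological
order.  Subjects with fewer survivors than requested are excluded with
an explicit error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .spectral import individual_peak_frequency, psd, relative_band_power
from .bands import DEFAULT_BANDS
from .synthdata import SourceRecording

__all__ = [
    "EpochQuality",
    "EpochSet",
    "SubjectExclusionError",
    "DEFAULT_EPOCH_LEN",
    "AMPLITUDE_Z_THRESHOLD",
    "segment",
    "score_epoch",
    "score_epochs",
    "select_epochs",
]

DEFAULT_EPOCH_LEN = 16384  # samples; 13.1 s at 1250 Hz
AMPLITUDE_Z_THRESHOLD = 6.0  # robust-z units
IPF_OUTLIER_MADS = 3.0
LOW_ALPHA_QUANTILE = 0.25


class SubjectExclusionError(RuntimeError):
    """Raised when a subject cannot supply the required number of clean epochs."""


@dataclass
class EpochQuality:
    max_abs_z: float
    epoch_ipf: float
    alpha1_occ_rbp: float
    rejected: bool = False
    reason: str = "none"  # amplitude | ipf_outlier | low_alpha | none


@dataclass
class EpochSet:
    subject_id: str
    fs: float
    epoch_len: int
    epochs: list[np.ndarray]
    start_indices: list[int]
    quality: list[EpochQuality] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {e.shape for e in self.epochs}
        if len(shapes) > 1:
            raise ValueError("all epochs must share one shape")

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def duration(self) -> float:
        """Epoch duration in seconds."""
        return self.epoch_len / self.fs


def segment(rec: SourceRecording, epoch_len: int = DEFAULT_EPOCH_LEN) -> EpochSet:
    """Cut a recording into consecutive non-overlapping candidate epochs.

    Windows start at sample 0; a trailing remainder shorter than one
    epoch is discarded.
    """
    if rec.n_samples < epoch_len:
        raise ValueError(
            f"recording of {rec.n_samples} samples shorter than one epoch "
            f"({epoch_len} samples)"
        )
    n = rec.n_samples // epoch_len
    starts = [k * epoch_len for k in range(n)]
    epochs = [rec.data[:, s:s + epoch_len].copy() for s in starts]
    return EpochSet(rec.subject_id, rec.fs, epoch_len, epochs, starts)


def _robust_stats(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    med = np.median(data, axis=-1)
    mad = stats.median_abs_deviation(data, axis=-1, scale="normal")
    return med, mad


def score_epoch(
    epoch: np.ndarray,
    fs: float,
    occipital_idx: Sequence[int],
    robust_loc: np.ndarray | None = None,
    robust_scale: np.ndarray | None = None,
) -> EpochQuality:
    """Quality metrics for a single epoch.

    ``robust_loc``/``robust_scale`` are the per-region median and
    normal-scaled MAD of the *whole recording*; when omitted they are
    estimated from the epoch itself.  A zero-variance region makes the
    robust z undefined and the epoch is rejected for amplitude.
    """
    if len(occipital_idx) == 0:
        raise ValueError("occipital index set must be non-empty")
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if robust_loc is None or robust_scale is None:
        robust_loc, robust_scale = _robust_stats(epoch)
    if np.any(robust_scale <= 0):
        warnings.warn("zero-variance region; epoch rejected for amplitude", RuntimeWarning)
        return EpochQuality(np.inf, np.nan, np.nan, rejected=True, reason="amplitude")
    z = np.abs(epoch - robust_loc[:, None]) / robust_scale[:, None]
    max_abs_z = float(z.max())
    pp = psd(epoch, fs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        # single-epoch periodograms need spectral smoothing before argmax
        epoch_ipf = individual_peak_frequency(pp, occipital_idx, smooth_hz=0.5)
    rbp, _ = relative_band_power(pp, DEFAULT_BANDS)
    alpha1 = float(rbp[list(occipital_idx), DEFAULT_BANDS.names.index("alpha1")].mean())
    q = EpochQuality(max_abs_z=max_abs_z, epoch_ipf=epoch_ipf, alpha1_occ_rbp=alpha1)
    if max_abs_z > AMPLITUDE_Z_THRESHOLD:
        q.rejected, q.reason = True, "amplitude"
    return q


def score_epochs(eset: EpochSet, occipital_idx: Sequence[int]) -> EpochSet:
    """Score every candidate epoch against whole-recording robust statistics."""
    whole = np.concatenate(eset.epochs, axis=-1)
    loc, scale = _robust_stats(whole)
    quality = [
        score_epoch(ep, eset.fs, occipital_idx, loc, scale) for ep in eset.epochs
    ]
    return replace(eset, quality=quality)


def select_epochs(eset: EpochSet, n_select: int = 8) -> EpochSet:
    """Reject bad candidates and keep the ``n_select`` best epochs.

    Rejection: amplitude (scored), peak-frequency outliers (outside
    median ± 3·MAD across the subject's candidates) and low occipital
    alpha1 power (below the subject's 25th percentile).  Survivors are
    ranked by the sum of ranks of epoch peak frequency and occipital
    alpha1 power; the top ``n_select`` are kept (ties to the earlier
    start index) and returned in chronological order.
    """
    if not eset.quality:
        raise ValueError("epoch set must be scored before selection")
    quality = [replace(q) for q in eset.quality]
    ipfs = np.array([q.epoch_ipf for q in quality])
    alphas = np.array([q.alpha1_occ_rbp for q in quality])

    med = np.nanmedian(ipfs)
    mad = stats.median_abs_deviation(ipfs, scale="normal", nan_policy="omit")
    lo, hi = med - IPF_OUTLIER_MADS * mad, med + IPF_OUTLIER_MADS * mad
    alpha_floor = np.nanquantile(alphas, LOW_ALPHA_QUANTILE)

    for q in quality:
        if q.rejected:
            continue
        if not (lo <= q.epoch_ipf <= hi):
            q.rejected, q.reason = True, "ipf_outlier"
        elif q.alpha1_occ_rbp < alpha_floor:
            q.rejected, q.reason = True, "low_alpha"

    survivors = [k for k, q in enumerate(quality) if not q.rejected]
    if len(survivors) < n_select:
        # the within-subject low-alpha quartile is a relative screen: when it
        # would push the pool below n_select, restore the best of the epochs
        # it removed (absolute rejections are never restored)
        restorable = sorted(
            (k for k, q in enumerate(quality) if q.reason == "low_alpha"),
            key=lambda k: -quality[k].alpha1_occ_rbp)
        for k in restorable[: n_select - len(survivors)]:
            quality[k].rejected, quality[k].reason = False, "none"
        survivors = [k for k, q in enumerate(quality) if not q.rejected]
    if len(survivors) < n_select:
        raise SubjectExclusionError(
            f"subject {eset.subject_id}: only {len(survivors)} usable epochs "
            f"(< {n_select}); subject excluded"
        )
    ipf_rank = stats.rankdata(ipfs[survivors])
    alpha_rank = stats.rankdata(alphas[survivors])
    ranksum = ipf_rank + alpha_rank
    order = sorted(
        range(len(survivors)),
        key=lambda k: (-ranksum[k], eset.start_indices[survivors[k]]),
    )
    chosen = sorted(survivors[k] for k in order[:n_select])
    return EpochSet(
        subject_id=eset.subject_id,
        fs=eset.fs,
        epoch_len=eset.epoch_len,
        epochs=[eset.epochs[k] for k in chosen],
        start_indices=[eset.start_indices[k] for k in chosen],
        quality=[quality[k] for k in chosen],
    )
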