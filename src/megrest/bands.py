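"""Canonical frequency-band scheme for resting-state M/EEG spectra.

The analysis range is 0.5–48 Hz, tiled by six contiguous bands:
delta 0.5–4, theta 4–8, alpha1 8–10, alpha2 10–13, beta 13–30 and
gamma 30–48 Hz.  A frequency that falls exactly on a shared edge is
assigned to the band whose *upper* edge it is (intervals are half-open
``(lo, hi]``); delta additionally includes its 0.5 Hz lower edge so the
bands tile the closed range exactly, with no bin counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Band", "BandScheme", "DEFAULT_BANDS"]


@dataclass(frozen=True)
class Band:
    name: str
    lo: float  # Hz
    hi: float  # Hz

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)


@dataclass(frozen=True)
class BandScheme:
    """An ordered, contiguous, non-overlapping tiling of [f_min, f_max]."""

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("band scheme must contain at least one band")
        for a, b in zip(self.bands, self.bands[1:]):
            if not np.isclose(a.hi, b.lo):
                raise ValueError(
                    f"bands must be contiguous: {a.name} ends at {a.hi} Hz "
                    f"but {b.name} starts at {b.lo} Hz"
                )
        for b in self.bands:
            if b.hi <= b.lo:
                raise ValueError(f"band {b.name} has non-positive width")

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    def __getitem__(self, key: str | int) -> Band:
        if isinstance(key, int):
            return self.bands[key]
        for b in self.bands:
            if b.name == key:
                return b
        raise KeyError(key)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    @property
    def f_min(self) -> float:
        return self.bands[0].lo

    @property
    def f_max(self) -> float:
        return self.bands[-1].hi

    def assign_bins(self, freqs: np.ndarray) -> np.ndarray:
        """Map frequency bins to band indices; -1 for out-of-range bins.

        A bin on a shared edge goes to the lower-frequency band (the band
        whose upper edge it is); the scheme's lowest edge belongs to the
        first band.
        """
        freqs = np.asarray(freqs, dtype=float)
        idx = np.full(freqs.shape, -1, dtype=int)
        for i, b in enumerate(self.bands):
            lo = b.lo
            if i == 0:
                sel = (freqs >= lo) & (freqs <= b.hi)
            else:
                sel = (freqs > lo) & (freqs <= b.hi)
            idx[sel] = i
        return idx


DEFAULT_BANDS = BandScheme(
    (
        Band("delta", 0.5, 4.0),
        Band("theta", 4.0, 8.0),
        Band("alpha1", 8.0, 10.0),
        Band("alpha2", 10.0, 13.0),
        Band("beta", 13.0, 30.0),
        Band("gamma", 30.0, 48.0),
    )
)
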