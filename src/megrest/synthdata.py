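"""Synthetic source-space MEG with planted, recoverable ground truth.

This module is the test bench for the whole pipeline: it fabricates
cohorts of source-level resting-state recordings whose spectral content,
occipital alpha peak, envelope coupling, spatial leakage, artifact and
drowsiness structure, and brain–cognition relationships are all planted
with known values, so every downstream stage can be validated against
:class:`SimTruth` without any external data.

Signal model, per region and subject
------------------------------------
Each region's signal is a sum of independent band-limited Gaussian
components, one per frequency band, built by FIR-filtering white noise
with the same filter implementation the connectivity stage uses.  Each
component is normalised to unit variance and scaled so its variance
equals the group's target power fraction for that band.  On top of this:

* occipital regions carry a narrowband oscillation at the subject's
  planted individual peak frequency (IPF), drawn per group from a normal
  distribution, replacing part of the broadband power of the alpha band
  that contains the IPF;
* planted coupling pairs share amplitude envelopes: two independent
  constant-envelope in-band carriers (frequency-modulated cosines) are
  multiplied by slowly varying positive envelopes whose underlying
  Gaussian processes are correlated at the planted strength, so the
  planted envelope correlation is known in closed form;
* artifact epochs receive ±8 robust-SD half-sine transients of 100 ms;
  drowsy epochs have all occipital alpha components halved in amplitude;
* if ``mixing_strength`` ε > 0, the channel stack is post-multiplied by
  the instantaneous symmetric nearest-neighbour operator I + εM
  (M has 1/2 on ring neighbours, zero diagonal) — a pure zero-lag
  leakage confound, exactly what orthogonalisation-based connectivity
  is designed to remove.

All randomness flows from ``SimSpec.seed`` through a documented
``SeedSequence`` splitting scheme (stage tag, then subject index), so
outputs are bit-reproducible and stages can be regenerated in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .bands import Band, BandScheme, DEFAULT_BANDS
from .filters import bandpass_fir, design_bandpass, filtfilt_fir, fir_order

__all__ = [
    "SimSpec",
    "SimTruth",
    "SourceRecording",
    "LeadFieldSet",
    "CohortTable",
    "CouplingSpec",
    "gen_source_timeseries",
    "gen_cohort_table",
    "gen_forward_model",
]

# stage tags for the seed-splitting scheme
_STAGE_SOURCES = 0
_STAGE_COHORT = 1
_STAGE_FORWARD = 2

#: fraction of the pooled occipital alpha power carried by the narrowband peak
PEAK_SHARE = 0.75

#: past ages probed by the cognitive-activity questionnaire
CAQ_PAST_AGES = (6, 12, 18, 40)

# group-level demographic defaults (oldest-old cohort; CI slightly younger,
# with proportionally fewer women)
_AGE_MEAN = {"CN": 93.0, "CI": 91.7}
_FEMALE_P = {"CN": 0.70, "CI": 0.40}
_COG_INTERCEPTS = {"MMSE": 27.0, "fluency": 30.0, "TMTB": 180.0, "CERAD": 70.0}


@dataclass(frozen=True)
class CouplingSpec:
    """A planted envelope-coupled region pair in one band.

    ``rhythm_boost`` scales the coupled component's variance relative to
    the band's calibrated share: coupled regions express a strong
    rhythm, which keeps the shared envelope from being diluted by the
    region's other-band spectral leakage.
    """

    i: int
    j: int
    strength: float  # target envelope correlation in [0, 1]
    band: str
    rhythm_boost: float = 12.0


@dataclass
class SimSpec:
    """Full description of one synthetic study.

    Defaults reproduce the study conditions this package targets: two
    groups (35 cognitively normal, 11 impaired), 80 cortical regions,
    5-minute recordings at 1250 Hz segmented into 16384-sample epochs,
    group band-power profiles that differ in theta (higher in CI) and
    beta (lower in CI), and occipital alpha peaks at 9.1 ± 0.8 Hz (CN)
    versus 8.7 ± 0.3 Hz (CI).
    """

    n_subjects_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"CN": 35, "CI": 11}
    )
    n_regions: int = 80
    fs: float = 1250.0
    duration: float = 300.0
    epoch_len: int = 16384
    band_fractions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "CN": {"delta": 0.24, "theta": 0.12, "alpha1": 0.10,
                   "alpha2": 0.11, "beta": 0.33, "gamma": 0.10},
            "CI": {"delta": 0.26, "theta": 0.18, "alpha1": 0.10,
                   "alpha2": 0.10, "beta": 0.26, "gamma": 0.10},
        }
    )
    ipf_mean: Mapping[str, float] = field(
        default_factory=lambda: {"CN": 9.1, "CI": 8.7}
    )
    ipf_sd: Mapping[str, float] = field(
        default_factory=lambda: {"CN": 0.8, "CI": 0.3}
    )
    occipital_idx: tuple[int, ...] = tuple(range(8))
    coupling_pairs: tuple[CouplingSpec, ...] = ()
    mixing_strength: float = 0.2
    artifact_rate: float = 0.10
    drowsy_rate: float = 0.10
    cognitive_effects: Mapping[str, tuple[str, float, float]] = field(
        default_factory=lambda: {
            "MMSE": ("theta_rbp", -40.0, 1.5),
            "CERAD": ("theta_rbp", -120.0, 8.0),
            "fluency": ("alpha2_rbp", 100.0, 5.0),
            "TMTB": ("beta_rbp", -600.0, 40.0),
        }
    )
    missing_rate: float = 0.05
    scheme: BandScheme = DEFAULT_BANDS
    min_epochs: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for grp, fr in self.band_fractions.items():
            if set(fr) != set(self.scheme.names):
                raise ValueError(f"group {grp}: band fractions must cover {self.scheme.names}")
            s = sum(fr.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"group {grp}: band fractions sum to {s}, not 1")
            if any(v < 0 or v > 1 for v in fr.values()):
                raise ValueError(f"group {grp}: band fractions must lie in [0, 1]")
        if self.fs <= 2 * self.scheme.f_max:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest band edge "
                f"({self.scheme.f_max} Hz)"
            )
        for name, rate in (("artifact_rate", self.artifact_rate),
                           ("drowsy_rate", self.drowsy_rate),
                           ("missing_rate", self.missing_rate)):
            if not 0 <= rate < 1:
                raise ValueError(f"{name}={rate} must lie in [0, 1)")
        if not 0 <= self.mixing_strength < 1:
            raise ValueError("mixing_strength must lie in [0, 1)")
        if max(self.occipital_idx, default=-1) >= self.n_regions:
            raise ValueError("occipital index out of range")
        for cp in self.coupling_pairs:
            if not (0 <= cp.i < self.n_regions and 0 <= cp.j < self.n_regions):
                raise ValueError(f"coupling pair ({cp.i}, {cp.j}) out of range")
            if not 0 <= cp.strength <= 1:
                raise ValueError("coupling strength must lie in [0, 1]")
            self.scheme[cp.band]  # raises KeyError for unknown band

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    @property
    def n_epochs(self) -> int:
        return self.n_samples // self.epoch_len

    @property
    def subject_ids(self) -> list[str]:
        out = []
        for grp, n in self.n_subjects_per_group.items():
            out.extend(f"{grp}{k:03d}" for k in range(n))
        return out

    def group_of(self, subject_id: str) -> str:
        for grp in self.n_subjects_per_group:
            if subject_id.startswith(grp):
                return grp
        raise KeyError(subject_id)


@dataclass
class SimTruth:
    """Planted ground truth, keyed for recovery tests.

    ``envelopes`` holds the planted slow amplitude modulators of each
    coupled pair (key ``"subject|i|j|band"`` → array (2, T)); they are
    kept in memory only and summarised, not serialised, by
    :meth:`to_json`.
    """

    band_fractions: dict
    subject_groups: dict
    ipfs: dict
    coupling: list
    artifact_epochs: dict
    drowsy_epochs: dict
    cognitive_slopes: dict
    envelopes: dict = field(default_factory=dict)

    def clean_epochs(self, subject_id: str, n_epochs: int) -> list[int]:
        bad = set(self.artifact_epochs[subject_id]) | set(self.drowsy_epochs[subject_id])
        return [e for e in range(n_epochs) if e not in bad]

    def to_json(self, path) -> None:
        payload = {
            "band_fractions": self.band_fractions,
            "subject_groups": self.subject_groups,
            "ipfs": self.ipfs,
            "coupling": self.coupling,
            "artifact_epochs": self.artifact_epochs,
            "drowsy_epochs": self.drowsy_epochs,
            "cognitive_slopes": self.cognitive_slopes,
            "envelope_keys": sorted(self.envelopes),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class SourceRecording:
    """Multichannel source-space time-series for one subject."""

    subject_id: str
    fs: float
    roi_names: list[str]
    data: np.ndarray  # (R, T)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.roi_names):
            raise ValueError("data must be (n_regions, n_samples) matching roi_names")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class LeadFieldSet:
    """Scalar (fixed-orientation) lead fields: (n_sensors, n_sources)."""

    lead_matrix: np.ndarray
    sensor_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.lead_matrix = np.asarray(self.lead_matrix, dtype=float)
        if self.lead_matrix.ndim != 2:
            raise ValueError("lead_matrix must be 2-D (sensors × sources)")
        norms = np.linalg.norm(self.lead_matrix, axis=0)
        if np.any(norms == 0):
            raise ValueError("lead field contains an all-zero column")


@dataclass
class CohortTable:
    """Per-subject demographic/cognitive variables with a missingness mask.

    ``data`` is indexed by subject id; ``mask`` is a boolean frame of the
    same shape (True = value was removed as missing); ``caq`` holds the
    raw questionnaire responses (long format: subject, activity, age,
    response with responses coded 1–5 and age ∈ {6, 12, 18, 40, 'current'}).
    """

    data: pd.DataFrame
    mask: pd.DataFrame
    caq: pd.DataFrame


# ---------------------------------------------------------------------------
# generation internals


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, tags)]))


def _unit(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return x / s if s > 0 else x


@lru_cache(maxsize=8)
def _leakage_matrix(scheme: BandScheme, fs: float, n_samples: int) -> np.ndarray:
    """L[c, b]: fraction of band-c filtered white noise measured in band b.

    White noise through the two-way FIR has power spectrum |H_c(f)|^4
    (single-pass amplitude response to the fourth).  Band-integrating
    that response over the scheme, restricted to the analysis range,
    gives the expected cross-band leakage of each generated component in
    closed form — used to calibrate component variances so *measured*
    band fractions match the planted targets despite transition-band
    leakage.
    """
    n_bands = len(scheme)
    L = np.zeros((n_bands, n_bands))
    worN = 1 << 15
    grid = np.arange(worN) * (fs / 2) / worN
    bin_of = scheme.assign_bins(grid)
    for c, band in enumerate(scheme):
        taps = design_bandpass(band.lo, band.hi, fs,
                               fir_order(band.lo, fs, n_samples, band.hi))
        _, h = signal.freqz(taps, worN=worN, fs=fs)
        p = np.abs(h) ** 4
        for b in range(n_bands):
            L[c, b] = p[bin_of == b].sum()
        L[c] /= max(L[c].sum(), np.finfo(float).tiny)
    return L


def _calibrated_variances(
    fractions: Mapping[str, float], scheme: BandScheme, fs: float, n_samples: int
) -> dict[str, float]:
    """Component variances whose *measured* band fractions hit the targets.

    Solves target = Lᵀ v for v (least squares), clipping small negative
    solutions to zero; with all-zero leakage this reduces to v = target.
    """
    L = _leakage_matrix(scheme, fs, n_samples)
    t = np.array([fractions[name] for name in scheme.names])
    v, *_ = np.linalg.lstsq(L.T, t, rcond=None)
    v = np.clip(v, 0.0, None)
    s = v.sum()
    if s > 0:
        v *= t.sum() / s
    return dict(zip(scheme.names, v))


def _slow_gaussian(rng: np.random.Generator, n: int, fs: float, cutoff: float) -> np.ndarray:
    """Unit-variance Gaussian process with ~``cutoff`` Hz bandwidth."""
    sigma = fs / (2.0 * np.pi * cutoff)
    g = gaussian_filter1d(rng.standard_normal(n), sigma, mode="wrap")
    return _unit(g)


def _carrier(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float,
    slot: int = 0,
) -> np.ndarray:
    """Constant-envelope in-band cosine carrier.

    A fixed-frequency carrier keeps |analytic(carrier · e)| ∝ e exactly
    (a drifting carrier frequency would convert the band filter's
    passband ripple into spurious envelope fluctuation, attenuating the
    planted envelope correlation).  The two members of a coupled pair
    use different frequency ``slot``s: carriers too close in frequency
    beat slowly within an epoch, and the resulting zero-lag correlation
    would make the orthogonalization step strip the shared envelope.
    """
    width = hi - lo
    base = lo + (0.3 if slot % 2 == 0 else 0.7) * width
    f_c = base + rng.uniform(-0.05, 0.05) * width
    phase = 2.0 * np.pi * f_c * np.arange(n) / fs + rng.uniform(0, 2 * np.pi)
    return np.cos(phase)


def _coupled_envelopes(
    rng: np.random.Generator, n: int, fs: float, strength: float, lo: float
) -> tuple[np.ndarray, np.ndarray]:
    """Positive slow envelopes whose correlation is the planted strength."""
    cutoff = min(0.4, lo / 4.0)
    u1 = _slow_gaussian(rng, n, fs, cutoff)
    u2 = _slow_gaussian(rng, n, fs, cutoff)
    g1 = u1
    g2 = strength * u1 + np.sqrt(max(0.0, 1.0 - strength**2)) * u2
    a = 0.45  # modulation depth; keeps clipping below ~1% so corr(e1, e2) ≈ strength
    e1 = np.clip(1.0 + a * g1, 0.05, None)
    e2 = np.clip(1.0 + a * g2, 0.05, None)
    return e1, e2


def _narrowband(
    rng: np.random.Generator, n: int, fs: float, ipf: float, band: Band
) -> np.ndarray:
    """Unit-variance narrowband noise peaked at the planted IPF.

    The peak must be spectrally sharp (~±0.6 Hz) to register as the
    occipital maximum, so its filter order is set by the needed
    transition width (~0.5 Hz), not by the band-component heuristic.
    """
    half_bw = 0.5
    order = min(int(round(3.3 * fs / 0.3)), n // 3)
    order += order % 2
    taps = design_bandpass(round(ipf - half_bw, 3), round(ipf + half_bw, 3),
                           fs, order, tw=0.3)
    return _unit(filtfilt_fir(taps, rng.standard_normal(n)))


def gen_source_timeseries(spec: SimSpec) -> tuple[list[SourceRecording], SimTruth]:
    """Generate one synthetic cohort of source recordings plus its truth."""
    if spec.n_epochs < spec.min_epochs:
        raise ValueError(
            f"duration {spec.duration}s holds only {spec.n_epochs} epochs of "
            f"{spec.epoch_len} samples; at least {spec.min_epochs} required"
        )
    T = spec.n_samples
    roi_names = [f"ROI{r:03d}" for r in range(spec.n_regions)]
    coupled_lookup = {}
    for cp in spec.coupling_pairs:
        coupled_lookup[(cp.i, cp.band)] = cp
        coupled_lookup[(cp.j, cp.band)] = cp

    truth = SimTruth(
        band_fractions={g: dict(fr) for g, fr in spec.band_fractions.items()},
        subject_groups={},
        ipfs={},
        coupling=[asdict(cp) for cp in spec.coupling_pairs],
        artifact_epochs={},
        drowsy_epochs={},
        cognitive_slopes={k: list(v) for k, v in spec.cognitive_effects.items()},
    )

    recordings = []
    for s_idx, sid in enumerate(spec.subject_ids):
        grp = spec.group_of(sid)
        rng = _rng(spec.seed, _STAGE_SOURCES, s_idx)
        fractions = spec.band_fractions[grp]
        ipf = float(np.clip(rng.normal(spec.ipf_mean[grp], spec.ipf_sd[grp]), 6.0, 12.5))
        truth.subject_groups[sid] = grp
        truth.ipfs[sid] = ipf

        art = [e for e in range(spec.n_epochs) if rng.random() < spec.artifact_rate]
        drw = [e for e in range(spec.n_epochs)
               if e not in art and rng.random() < spec.drowsy_rate]
        truth.artifact_epochs[sid] = art
        truth.drowsy_epochs[sid] = drw
        drowsy_scale = np.ones(T)
        for e in drw:
            drowsy_scale[e * spec.epoch_len:(e + 1) * spec.epoch_len] = 0.5

        # envelopes are drawn once per pair per subject
        pair_env: dict[tuple[int, int, str], tuple[np.ndarray, np.ndarray]] = {}
        for cp in spec.coupling_pairs:
            band = spec.scheme[cp.band]
            e1, e2 = _coupled_envelopes(rng, T, spec.fs, cp.strength, band.lo)
            pair_env[(cp.i, cp.j, cp.band)] = (e1, e2)
            truth.envelopes[f"{sid}|{cp.i}|{cp.j}|{cp.band}"] = np.vstack([e1, e2])

        ipf_band = spec.scheme.names[spec.scheme.assign_bins(np.array([ipf]))[0]]
        variances = _calibrated_variances(fractions, spec.scheme, spec.fs, T)
        pool_alpha = ipf_band in ("alpha1", "alpha2")
        alpha_pool = (variances.get("alpha1", 0.0) + variances.get("alpha2", 0.0)
                      if pool_alpha else variances[ipf_band])
        data = np.zeros((spec.n_regions, T))
        for r in range(spec.n_regions):
            sig = np.zeros(T)
            occipital = r in spec.occipital_idx
            for band in spec.scheme:
                var = variances[band.name]
                cp = coupled_lookup.get((r, band.name))
                # occipital alpha (incl. the IPF band) is what drowsiness damps
                occ_alpha = occipital and (band.name in ("alpha1", "alpha2")
                                           or band.name == ipf_band)
                pooled = occipital and (
                    (pool_alpha and band.name in ("alpha1", "alpha2"))
                    or band.name == ipf_band)
                if cp is not None:
                    if var <= 0:
                        continue
                    e1, e2 = pair_env[(cp.i, cp.j, cp.band)]
                    env = e1 if r == cp.i else e2
                    comp = _unit(_carrier(rng, T, spec.fs, band.lo, band.hi,
                                          slot=int(r == cp.j)) * env)
                    comp = comp * np.sqrt(var * cp.rhythm_boost)
                elif pooled:
                    # occipital: PEAK_SHARE of the (pooled) alpha power becomes
                    # a narrowband oscillation at the subject's planted IPF
                    comp = np.zeros(T)
                    if var > 0:
                        broad = _unit(bandpass_fir(rng.standard_normal(T), band, spec.fs))
                        comp = np.sqrt(var * (1 - PEAK_SHARE)) * broad
                    if band.name == ipf_band and alpha_pool > 0:
                        narrow = _narrowband(rng, T, spec.fs, ipf, band)
                        comp = comp + np.sqrt(alpha_pool * PEAK_SHARE) * narrow
                    comp = comp * drowsy_scale
                else:
                    if var <= 0:
                        continue
                    comp = _unit(bandpass_fir(rng.standard_normal(T), band, spec.fs))
                    comp = comp * np.sqrt(var)
                    if occ_alpha:
                        comp = comp * drowsy_scale
                sig += comp
            data[r] = sig

        # artifact transients: ±8 robust-SD half-sine pulses of 100 ms
        pulse_len = max(2, int(round(0.1 * spec.fs)))
        pulse = np.sin(np.pi * np.arange(pulse_len) / (pulse_len - 1))
        for e in art:
            hit = rng.choice(spec.n_regions, size=min(3, spec.n_regions), replace=False)
            for r in hit:
                pos = e * spec.epoch_len + rng.integers(0, spec.epoch_len - pulse_len)
                amp = 8.0 * data[r].std() * rng.choice([-1.0, 1.0])
                data[r, pos:pos + pulse_len] += amp * pulse

        if spec.mixing_strength > 0:
            R = spec.n_regions
            M = np.zeros((R, R))
            for r in range(R):
                M[r, (r + 1) % R] = 0.5
                M[r, (r - 1) % R] = 0.5
            data = (np.eye(R) + spec.mixing_strength * M) @ data

        recordings.append(SourceRecording(sid, spec.fs, roi_names, data))
    return recordings, truth


def gen_cohort_table(spec: SimSpec, brain_features: pd.DataFrame) -> CohortTable:
    """Build the cohort table from per-subject brain features.

    ``brain_features`` is indexed by subject id and must contain every
    feature named in ``spec.cognitive_effects`` plus a ``group`` column.
    Cognitive variables follow ``intercept + slope × feature + noise``;
    questionnaire responses are integers 1–5 at ages {6, 12, 18, 40,
    current}; missing entries are inserted at ``missing_rate`` over the
    cognitive columns, with the mask recorded.
    """
    rng = _rng(spec.seed, _STAGE_COHORT)
    if "group" not in brain_features.columns:
        raise ValueError("brain_features must carry a 'group' column")
    for var, (feat, _, _) in spec.cognitive_effects.items():
        if feat not in brain_features.columns:
            raise KeyError(
                f"cognitive effect for {var!r} names unknown brain feature {feat!r}"
            )

    subjects = list(brain_features.index)
    n = len(subjects)
    groups = brain_features["group"]
    rows: dict[str, np.ndarray] = {}
    rows["group"] = groups.to_numpy()
    rows["age"] = np.array([
        rng.normal(_AGE_MEAN.get(g, 92.5), 2.0) for g in groups])
    rows["gender"] = np.array([
        "F" if rng.random() < _FEMALE_P.get(g, 0.55) else "M" for g in groups],
        dtype=object)
    rows["education"] = np.clip(rng.normal(12.0, 3.0, n), 4, 22)

    for var, (feat, slope, noise_sd) in spec.cognitive_effects.items():
        x = brain_features[feat].to_numpy(dtype=float)
        rows[var] = (_COG_INTERCEPTS.get(var, 0.0) + slope * x
                     + rng.normal(0.0, noise_sd, n))

    # questionnaire: latent engagement per life stage, discretised to 1..5
    n_activities = 7
    caq_records = []
    ccaq = np.empty(n)
    pcaq = np.empty(n)
    for k, sid in enumerate(subjects):
        latent_past = rng.normal(3.0, 0.6)
        latent_cur = rng.normal(latent_past - 0.3, 0.4)
        resp_cur, resp_past = [], []
        for a in range(n_activities):
            for age in CAQ_PAST_AGES:
                v = int(np.clip(round(rng.normal(latent_past, 0.5)), 1, 5))
                caq_records.append((sid, f"activity{a}", str(age), v))
                resp_past.append(v)
            v = int(np.clip(round(rng.normal(latent_cur, 0.5)), 1, 5))
            caq_records.append((sid, f"activity{a}", "current", v))
            resp_cur.append(v)
        ccaq[k] = np.mean(resp_cur)
        pcaq[k] = np.mean(resp_past)
    rows["cCAQ"] = ccaq
    rows["pCAQ"] = pcaq

    data = pd.DataFrame(rows, index=pd.Index(subjects, name="subject_id"))
    cognitive_cols = ["education", *spec.cognitive_effects, "cCAQ", "pCAQ"]
    mask = pd.DataFrame(False, index=data.index, columns=data.columns)
    if spec.missing_rate > 0:
        for col in cognitive_cols:
            hit = rng.random(n) < spec.missing_rate
            mask[col] = hit
            data.loc[hit, col] = np.nan
    caq = pd.DataFrame(caq_records, columns=["subject_id", "activity", "age", "response"])
    return CohortTable(data=data, mask=mask, caq=caq)


def gen_forward_model(
    spec: SimSpec,
    n_sensors: int,
    recordings: Sequence[SourceRecording] | None = None,
    sensor_noise_sd: float = 0.1,
) -> tuple[LeadFieldSet, list[SourceRecording]]:
    """Project source recordings through a random unit-norm lead field.

    Sensor data = lead_matrix · source data + white noise.  Lead columns
    are pseudo-random and unit-normalised; a rank-deficient draw is
    regenerated (up to 5 attempts) before failing.
    """
    if n_sensors < spec.n_regions:
        raise ValueError("need at least as many sensors as sources")
    rng = _rng(spec.seed, _STAGE_FORWARD)
    for _ in range(5):
        L = rng.standard_normal((n_sensors, spec.n_regions))
        L /= np.linalg.norm(L, axis=0, keepdims=True)
        if np.linalg.matrix_rank(L) == spec.n_regions:
            break
    else:
        raise RuntimeError("could not draw a full-rank lead field")
    leads = LeadFieldSet(lead_matrix=L, sensor_noise_sd=sensor_noise_sd)
    if recordings is None:
        recordings, _ = gen_source_timeseries(spec)
    sensor_recs = []
    sensor_names = [f"MEG{s:03d}" for s in range(n_sensors)]
    for rec in recordings:
        noise = (sensor_noise_sd * rng.standard_normal((n_sensors, rec.n_samples))
                 if sensor_noise_sd > 0 else 0.0)
        sensor_recs.append(SourceRecording(
            rec.subject_id, rec.fs, sensor_names, L @ rec.data + noise))
    return leads, sensor_recs
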