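"""Generator contracts: shapes, planted spectra, cohort links, determinism."""

import numpy as np
import pandas as pd
import pytest

from megrest import (SimSpec, gen_cohort_table, gen_forward_model,
                     gen_source_timeseries)
from megrest.bands import DEFAULT_BANDS


def _uniform_fractions():
    return {"delta": 1 / 6, "theta": 1 / 6, "alpha1": 1 / 6,
            "alpha2": 1 / 6, "beta": 1 / 6, "gamma": 1 / 6}


def test_recording_shape_at_default_rates():
    """fs=1250, 300 s, 80 regions -> data 80 x 375000 (checked cheaply via
    the spec arithmetic, generated at reduced size)."""
    spec = SimSpec(seed=0)
    assert spec.n_samples == 375000
    assert spec.n_regions == 80
    small = SimSpec(n_subjects_per_group={"CN": 1, "CI": 0}, n_regions=4,
                    fs=250.0, duration=140.0, epoch_len=4096, occipital_idx=(0,),
                    seed=0)
    recs, _ = gen_source_timeseries(small)
    assert recs[0].data.shape == (4, 35000)
    assert np.all(np.isfinite(recs[0].data))


def test_single_band_spec_yields_pure_band():
    """All power planted in alpha1 -> measured alpha1 RBP near 1 everywhere.

    The ceiling is set by the FIR transition ramps (a few % of component
    power sits in the 0.5 Hz skirts outside the 2 Hz band) plus the
    rectangular-window leakage of the single-epoch periodogram, so "pure"
    means > 0.85 here rather than 1.
    """
    from megrest.spectral import psd, relative_band_power
    fr = {b: 0.0 for b in DEFAULT_BANDS.names}
    fr["alpha1"] = 1.0
    spec = SimSpec(n_subjects_per_group={"CN": 1, "CI": 0}, n_regions=3,
                   fs=250.0, duration=140.0, epoch_len=4096, occipital_idx=(0,),
                   band_fractions={"CN": fr}, ipf_mean={"CN": 9.0},
                   ipf_sd={"CN": 0.05}, mixing_strength=0.0,
                   artifact_rate=0.0, drowsy_rate=0.0, seed=3)
    recs, _ = gen_source_timeseries(spec)
    # middle epochs: the recording ends carry filter edge transients
    rbps = [relative_band_power(psd(recs[0].data[:, k * 4096:(k + 1) * 4096],
                                    250.0))[0] for k in (2, 3, 4)]
    assert np.all(np.mean(rbps, axis=0)[:, DEFAULT_BANDS.names.index("alpha1")] > 0.85)


def test_planted_theta_fraction_recovered_by_independent_periodogram():
    """Planted theta 0.40 recovered within ±0.03 by a separately coded
    averaged-periodogram estimate (plain rFFT, no package code)."""
    fr = {"delta": 0.20, "theta": 0.40, "alpha1": 0.05, "alpha2": 0.05,
          "beta": 0.20, "gamma": 0.10}
    spec = SimSpec(n_subjects_per_group={"CN": 4, "CI": 0}, n_regions=6,
                   fs=250.0, duration=280.0, epoch_len=4096,
                   occipital_idx=(0,), band_fractions={"CN": fr},
                   ipf_mean={"CN": 9.0}, ipf_sd={"CN": 0.3},
                   mixing_strength=0.0, artifact_rate=0.0, drowsy_rate=0.0,
                   seed=1)
    recs, _ = gen_source_timeseries(spec)
    thetas = []
    for rec in recs:
        for r in range(1, rec.n_regions):  # skip occipital (alpha pooling)
            x = rec.data[r]
            nseg, seglen = 17, 4096
            acc = np.zeros(seglen // 2 + 1)
            for k in range(nseg):
                seg = x[k * seglen:(k + 1) * seglen]
                seg = seg - seg.mean()
                acc += np.abs(np.fft.rfft(seg)) ** 2
            freqs = np.fft.rfftfreq(seglen, 1 / 250.0)
            keep = (freqs > 0.5) & (freqs <= 48.0) | np.isclose(freqs, 0.5)
            theta = (freqs > 4.0) & (freqs <= 8.0)
            thetas.append(acc[theta].sum() / acc[keep].sum())
    assert abs(np.mean(thetas) - 0.40) < 0.03


def test_all_band_fractions_recovered(small_spec, small_cohort):
    """Measured per-band fractions match the planted profile within ±0.03
    (non-occipital regions; occipital pools alpha into the peak)."""
    from megrest.spectral import psd, relative_band_power
    recs, truth = small_cohort
    rec = recs[0]
    non_occ = [r for r in range(rec.n_regions)
               if r not in small_spec.occipital_idx
               and r not in (4, 6)]  # coupled regions have boosted alpha2
    rbps = []
    for k in range(small_spec.n_epochs):
        ep = rec.data[non_occ, k * 4096:(k + 1) * 4096]
        if k in truth.artifact_epochs[rec.subject_id]:
            continue
        rbps.append(relative_band_power(psd(ep, small_spec.fs))[0])
    mean_rbp = np.mean(rbps, axis=(0, 1))
    planted = np.array([small_spec.band_fractions["CN"][b]
                        for b in DEFAULT_BANDS.names])
    np.testing.assert_allclose(mean_rbp, planted, atol=0.03)


def test_fixed_seed_bit_reproducible(small_spec):
    recs1, t1 = gen_source_timeseries(small_spec)
    recs2, t2 = gen_source_timeseries(small_spec)
    np.testing.assert_array_equal(recs1[0].data, recs2[0].data)
    assert t1.ipfs == t2.ipfs
    assert t1.artifact_epochs == t2.artifact_epochs


def test_spec_validation_errors():
    bad = {"CN": {b: 0.2 for b in DEFAULT_BANDS.names}}  # sums to 1.2
    with pytest.raises(ValueError, match="sum"):
        SimSpec(band_fractions=bad)
    with pytest.raises(ValueError, match="fs"):
        SimSpec(fs=90.0)
    with pytest.raises(ValueError, match="artifact_rate"):
        SimSpec(artifact_rate=1.0)
    with pytest.raises(ValueError, match="out of range"):
        SimSpec(n_regions=4, occipital_idx=(5,))
    with pytest.raises(ValueError, match="epochs"):
        gen_source_timeseries(SimSpec(
            n_subjects_per_group={"CN": 1, "CI": 0}, n_regions=2,
            duration=10.0, occipital_idx=(0,), seed=0))


# ---------------------------------------------------------------------------
# cohort table


def _features(n=60, seed=0):
    rng = np.random.default_rng(seed)
    idx = [f"CN{k:03d}" for k in range(n // 2)] + \
          [f"CI{k:03d}" for k in range(n // 2)]
    return pd.DataFrame({
        "group": ["CN"] * (n // 2) + ["CI"] * (n // 2),
        "theta_rbp": rng.normal(0.15, 0.03, n),
        "alpha2_rbp": rng.normal(0.10, 0.02, n),
        "beta_rbp": rng.normal(0.30, 0.04, n),
    }, index=pd.Index(idx, name="subject_id"))


def test_cohort_no_missingness_complete_mask():
    spec = SimSpec(missing_rate=0.0, seed=5)
    tab = gen_cohort_table(spec, _features())
    assert not tab.mask.any().any()
    assert not tab.data.drop(columns=["group", "gender"]).isna().any().any()


def test_cohort_null_slopes_uncorrelated():
    n = 100
    spec = SimSpec(missing_rate=0.0, seed=5, cognitive_effects={
        "MMSE": ("theta_rbp", 0.0, 1.0), "CERAD": ("beta_rbp", 0.0, 5.0)})
    tab = gen_cohort_table(spec, _features(n))
    for var, (feat, _, _) in spec.cognitive_effects.items():
        r = np.corrcoef(tab.data[var], _features(n)[feat])[0, 1]
        assert abs(r) < 2 / np.sqrt(n)


def test_cohort_slope_recovered_by_ols():
    """slope 1, noise sd 0.5, n=100: OLS recovers the slope within ~3 SE."""
    n = 100
    spec = SimSpec(missing_rate=0.0, seed=7, cognitive_effects={
        "MMSE": ("theta_rbp", 1.0, 0.5)})
    feats = _features(n, seed=7)
    tab = gen_cohort_table(spec, feats)
    x = feats["theta_rbp"].to_numpy()
    y = tab.data["MMSE"].to_numpy()
    X = np.column_stack([np.ones(n), x])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    sigma2 = res[0] / (n - 2)
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    assert abs(beta[1] - 1.0) < 3 * se


def test_cohort_unknown_feature_errors():
    spec = SimSpec(cognitive_effects={"MMSE": ("nope", 1.0, 1.0)})
    with pytest.raises(KeyError, match="nope"):
        gen_cohort_table(spec, _features())


def test_cohort_caq_responses_in_range():
    spec = SimSpec(missing_rate=0.0, seed=5)
    tab = gen_cohort_table(spec, _features())
    assert set(tab.caq["age"].unique()) == {"6", "12", "18", "40", "current"}
    assert tab.caq["response"].between(1, 5).all()


# ---------------------------------------------------------------------------
# forward model


def _tiny_spec(seed=0, n_regions=6):
    return SimSpec(n_subjects_per_group={"CN": 1, "CI": 0}, n_regions=n_regions,
                   fs=250.0, duration=140.0, epoch_len=4096, occipital_idx=(0,),
                   mixing_strength=0.0, artifact_rate=0.0, drowsy_rate=0.0,
                   seed=seed)


def test_forward_model_exact_when_noiseless():
    spec = _tiny_spec(2)
    recs, _ = gen_source_timeseries(spec)
    leads, sensors = gen_forward_model(spec, 6, recordings=recs,
                                       sensor_noise_sd=0.0)
    np.testing.assert_allclose(
        sensors[0].data, leads.lead_matrix @ recs[0].data, atol=1e-12)


def test_forward_model_lead_columns_unit_norm():
    spec = _tiny_spec(2)
    leads, _ = gen_forward_model(spec, 10, recordings=[], sensor_noise_sd=0.0)
    np.testing.assert_allclose(
        np.linalg.norm(leads.lead_matrix, axis=0), 1.0, atol=1e-12)


def test_forward_model_deterministic():
    spec = _tiny_spec(4)
    recs, _ = gen_source_timeseries(spec)
    l1, _ = gen_forward_model(spec, 8, recordings=recs)
    l2, _ = gen_forward_model(spec, 8, recordings=recs)
    np.testing.assert_array_equal(l1.lead_matrix, l2.lead_matrix)


def test_forward_model_requires_enough_sensors():
    with pytest.raises(ValueError, match="sensors"):
        gen_forward_model(_tiny_spec(), 3)
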