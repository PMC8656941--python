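"""ANCOVA, effect sizes, BH-FDR, Spearman grids, RSN tools, CAQ composites."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from megrest.groupstats import (ancova_group_test, bh_fdr, caq_scores,
                                cohens_d_residual, rsn_effect_contribution,
                                rsn_majority_vote, spearman_grid)

GROUP = np.array(["CN"] * 35 + ["CI"] * 11)


def _cov(rng, n=46):
    return np.column_stack([rng.normal(92, 2, n), rng.integers(0, 2, n)])


def bh_brute_force(p, q):
    """Independent step-up scan, straight from the definition."""
    m = len(p)
    order = np.argsort(p)
    kmax = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            kmax = k
    rej = np.zeros(m, dtype=bool)
    rej[order[:kmax]] = True
    return rej


# ---------------------------------------------------------------------------
# ANCOVA / effect sizes


def test_collinear_design_raises(rng):
    y = rng.standard_normal(46)
    dup = (GROUP == "CN").astype(float)[:, None]
    with pytest.raises(np.linalg.LinAlgError, match="collinear"):
        ancova_group_test(y, GROUP, dup)


def test_f_equals_squared_t_of_group_coefficient(rng):
    """Nested-model F equals the squared OLS t statistic of the group term."""
    import statsmodels.api as sm
    for _ in range(5):
        y = rng.standard_normal(46) + (GROUP == "CI") * 0.8
        cov = _cov(rng)
        res = ancova_group_test(y, GROUP, cov)
        X = np.column_stack([np.ones(46), cov, (GROUP == "CN").astype(float)])
        t = sm.OLS(y, X).fit().tvalues[-1]
        assert res.F == pytest.approx(t ** 2, rel=1e-9)
        assert res.df == (1, 42)


def test_ancova_null_calibrated(rng):
    """Type-I error 0.05 ± 0.02 over 1000 null simulations (n=46, 35/11)."""
    hits = sum(
        ancova_group_test(rng.standard_normal(46), GROUP, _cov(rng)).p < 0.05
        for _ in range(1000))
    assert abs(hits / 1000 - 0.05) <= 0.02


def test_ancova_power_matches_noncentral_f(rng):
    """Rejection rate for a unit shift tracks the closed-form noncentral-F
    power (≥ 0.8 at n=35/11)."""
    from scipy import stats
    lam = 1.0 / (1 / 35 + 1 / 11)
    power = 1 - stats.ncf.cdf(stats.f.ppf(0.95, 1, 42), 1, 42, lam)
    assert power >= 0.8
    hits = sum(
        ancova_group_test(rng.standard_normal(46) + (GROUP == "CI"),
                          GROUP, _cov(rng)).p < 0.05
        for _ in range(400))
    rate = hits / 400
    se = np.sqrt(power * (1 - power) / 400)
    assert abs(rate - power) < 4 * se


def test_cohens_d_null_and_hand_case(rng):
    y = np.r_[np.zeros(3), np.ones(3), -np.ones(3), np.zeros(3) + 1]
    g = np.array(["A"] * 6 + ["B"] * 6)
    # identical residual distributions -> d = 0
    same = np.r_[rng.standard_normal(6)]
    assert cohens_d_residual(np.r_[same, same],
                             np.array(["A"] * 6 + ["B"] * 6)) == pytest.approx(0)
    # hand case: groups {2,2,0,0} vs {1,1,-1,-1}: means 1 vs 0, pooled sd
    y = np.array([2.0, 2, 0, 0, 1, 1, -1, -1])
    g = np.array(["A"] * 4 + ["B"] * 4)
    pooled = np.sqrt((3 * np.var([2, 2, 0, 0.], ddof=1)
                      + 3 * np.var([1, 1, -1, -1.], ddof=1)) / 6)
    assert cohens_d_residual(y, g) == pytest.approx(1.0 / pooled)


def test_planted_effect_size_recovered(rng):
    """Planted standardized shift 1.15 at n=35/11: mean recovered d within
    ±0.35 over 500 simulations."""
    ds = [cohens_d_residual(rng.standard_normal(46) + (GROUP == "CN") * 1.15,
                            GROUP, _cov(rng))
          for _ in range(500)]
    assert abs(np.mean(ds) - 1.15) < 0.35


def test_zero_pooled_sd_raises():
    y = np.r_[np.ones(4), np.zeros(4)]
    g = np.array(["A"] * 4 + ["B"] * 4)
    with pytest.raises(ZeroDivisionError):
        cohens_d_residual(y, g)


# ---------------------------------------------------------------------------
# BH-FDR


def test_bh_all_ones_no_rejection():
    rej, adj = bh_fdr(np.ones(7), 0.05)
    assert not rej.any() and np.all(adj == 1.0)


def test_bh_single_p_reduces_to_raw_threshold():
    rej, adj = bh_fdr(np.array([0.01]), 0.05)
    assert rej[0] and adj[0] == pytest.approx(0.01)


def test_bh_matches_bruteforce_on_fixed_vector():
    p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.060, 0.074, 0.205,
                  0.212, 0.216, 0.222, 0.251, 0.269, 0.275, 0.34, 0.41,
                  0.57, 0.60, 0.74, 0.80])
    rej, _ = bh_fdr(p, 0.05)
    np.testing.assert_array_equal(rej, bh_brute_force(p, 0.05))


def test_bh_matches_bruteforce_and_statsmodels_randomized(rng):
    from statsmodels.stats.multitest import multipletests
    for _ in range(200):
        p = rng.random(int(rng.integers(1, 40)))
        rej, adj = bh_fdr(p, 0.05)
        np.testing.assert_array_equal(rej, bh_brute_force(p, 0.05))
        sm_rej, sm_adj, *_ = multipletests(p, 0.05, method="fdr_bh")
        np.testing.assert_array_equal(rej, sm_rej)
        np.testing.assert_allclose(adj, sm_adj, atol=1e-12)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
def test_bh_stepup_property(pvals):
    p = np.array(pvals)
    rej, adj = bh_fdr(p, 0.05)
    np.testing.assert_array_equal(rej, bh_brute_force(p, 0.05))
    assert np.all((adj >= p - 1e-12) & (adj <= 1.0))


def test_bh_rejects_bad_input():
    with pytest.raises(ValueError):
        bh_fdr(np.array([]))
    with pytest.raises(ValueError):
        bh_fdr(np.array([0.0, 0.5]))


# ---------------------------------------------------------------------------
# Spearman grid


def test_spearman_monotone_and_reversal():
    t = pd.DataFrame({"x": [1, 2, 3, 4, 5],
                      "y": np.exp([1, 2, 3, 4, 5]),
                      "z": [5, 4, 3, 2, 1]})
    g = spearman_grid(t)
    i, j, k = (g.variables.index(v) for v in ("x", "y", "z"))
    assert g.rho[i, j] == pytest.approx(1.0)
    assert g.rho[i, k] == pytest.approx(-1.0)
    np.testing.assert_allclose(np.diag(g.rho), 1.0)


def test_spearman_midranks_match_bruteforce():
    """6-point table with one tie: rho equals the explicit midrank formula."""
    x = np.array([1.0, 2, 2, 3, 4, 5])
    y = np.array([2.0, 1, 4, 3, 6, 5])
    def midranks(v):
        order = np.argsort(v)
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    rx, ry = midranks(x), midranks(y)
    expect = np.corrcoef(rx, ry)[0, 1]
    g = spearman_grid(pd.DataFrame({"x": x, "y": y}))
    assert g.rho[0, 1] == pytest.approx(expect, abs=1e-12)


def test_spearman_pairwise_deletion_and_constant_flag():
    t = pd.DataFrame({
        "a": [1.0, 2, 3, 4, 5, 6, np.nan],
        "b": [2.0, 1, 4, 3, 6, np.nan, 5],
        "c": [1.0, 1, 1, 1, 1, 1, 1],
    })
    with pytest.warns(RuntimeWarning, match="constant"):
        g = spearman_grid(t)
    assert np.isfinite(g.rho[0, 1])  # 5 complete pairs used
    assert np.isnan(g.rho[0, 2])


# ---------------------------------------------------------------------------
# RSN tools


def test_majority_vote_clear_and_tie():
    counts = pd.DataFrame(
        {"VIS": [0, 30], "SM": [10, 30], "DMN": [90, 0]},
        index=["roiA", "roiB"])
    m = rsn_majority_vote(counts)
    assert m["roiA"] == "DMN"
    assert m["roiB"] == "VIS"  # exact tie breaks by fixed network order
    assert m.attrs["ties"] == ["roiB"]


def test_majority_vote_matches_argmax_oracle(rng):
    cols = ["VIS", "SM", "DA", "VA", "FP", "DMN", "LIM"]
    counts = pd.DataFrame(rng.integers(1, 100, size=(30, 7)), columns=cols)
    m = rsn_majority_vote(counts)
    for r in range(30):
        assert m.iloc[r] == cols[int(np.argmax(counts.iloc[r].to_numpy()))]


def test_effect_contribution_hand_cases():
    rsn_map = pd.Series(["DMN", "DMN", "FP", "FP"], index=list("abcd"))
    d = np.array([2.0, 1.0, 1.0, 5.0])
    sig = np.array([True, True, True, False])
    out = rsn_effect_contribution(d, sig, rsn_map)
    assert out["DMN"] == pytest.approx(75.0)
    assert out["FP"] == pytest.approx(25.0)
    assert out.sum() == pytest.approx(100.0, abs=1e-9)
    # invariant to uniform rescaling of d
    out2 = rsn_effect_contribution(10 * d, sig, rsn_map)
    pd.testing.assert_series_equal(out, out2, check_names=False)
    # single-network case and empty set
    only = rsn_effect_contribution(d, np.array([1, 1, 0, 0], bool), rsn_map)
    assert only["DMN"] == pytest.approx(100.0)
    with pytest.warns(RuntimeWarning, match="no significant"):
        empty = rsn_effect_contribution(d, np.zeros(4, bool), rsn_map)
    assert (empty == 0).all()


# ---------------------------------------------------------------------------
# CAQ composites


def _caq(records):
    return pd.DataFrame(records, columns=["subject_id", "activity", "age",
                                          "response"])


def test_caq_constant_responses():
    rec = [("s1", "read", a, 3) for a in ("6", "12", "18", "40", "current")]
    out = caq_scores(_caq(rec))
    assert out.loc["s1", "cCAQ"] == 3.0
    assert out.loc["s1", "pCAQ"] == 3.0


def test_caq_past_mean_single_activity():
    rec = [("s1", "read", "6", 1), ("s1", "read", "12", 2),
           ("s1", "read", "18", 3), ("s1", "read", "40", 4),
           ("s1", "read", "current", 5)]
    out = caq_scores(_caq(rec))
    assert out.loc["s1", "pCAQ"] == pytest.approx(2.5)
    assert out.loc["s1", "n_past"] == 4


def test_caq_uses_exactly_the_four_past_ages():
    rec = [("s1", "read", a, 5) for a in ("6", "12", "18", "40")]
    rec += [("s1", "read", "30", 1)]  # not a probed age: ignored
    rec += [("s1", "read", "current", 2)]
    out = caq_scores(_caq(rec))
    assert out.loc["s1", "pCAQ"] == 5.0


def test_caq_missing_items_and_errors():
    rec = [("s1", "read", "6", 2), ("s1", "read", "12", np.nan),
           ("s1", "read", "18", 4), ("s1", "read", "40", np.nan),
           ("s1", "read", "current", 1)]
    out = caq_scores(_caq(rec))
    assert out.loc["s1", "pCAQ"] == pytest.approx(3.0)
    assert out.loc["s1", "n_past"] == 2
    with pytest.raises(ValueError, match="missing"):
        caq_scores(_caq([("s2", "read", "current", 3)]))
    with pytest.raises(ValueError, match="1–5"):
        caq_scores(_caq([("s3", "read", "6", 9),
                         ("s3", "read", "current", 3)]))
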