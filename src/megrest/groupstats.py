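"""Covariate-adjusted group comparisons, FDR, Spearman grids and RSN tools.

Group differences are tested by ANCOVA in a general linear model
formulation: the full model ``y ~ 1 + group + covariates`` is compared
with the reduced model without the group term by a nested-model F test
(df 1, n − k − 2 for k covariates).  Effect sizes are Cohen's d between
the two groups' residual distributions after regressing out covariates
only, with a pooled (n₁−1, n₂−1)-weighted standard deviation; the sign
convention is first-listed group minus second.  Age and gender are the
standard covariates; relative band power can be added when testing
connectivity.  Families of tests are corrected with the
Benjamini–Hochberg step-up procedure at q = 0.05.

Also here: Spearman correlation grids with pairwise deletion and FDR,
majority-vote assignment of regions to the seven canonical resting-state
networks, per-network percentage contributions of significant effect
sizes, and the cognitive-activity questionnaire composites (current
cCAQ; past pCAQ over ages 6, 12, 18 and 40).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GroupTestResult",
    "SpearmanGrid",
    "RSN_ORDER",
    "ancova_group_test",
    "cohens_d_residual",
    "bh_fdr",
    "spearman_grid",
    "rsn_majority_vote",
    "rsn_effect_contribution",
    "caq_scores",
]

RSN_ORDER = ("VIS", "SM", "DA", "VA", "FP", "DMN", "LIM")
CAQ_PAST_AGES = ("6", "12", "18", "40")


@dataclass
class GroupTestResult:
    feature_id: str
    F: float
    p: float
    cohens_d: float
    df: tuple[int, int]
    sign_convention: str = ""
    significant: bool | None = None  # set only by an explicit FDR pass


@dataclass
class SpearmanGrid:
    variables: list[str]
    rho: np.ndarray
    p: np.ndarray
    fdr_mask: np.ndarray


def _design(group: np.ndarray, covariates: np.ndarray | None, n: int):
    cols = [np.ones(n)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.extend(cov.T)
        k = cov.shape[1]
    else:
        k = 0
    X_red = np.column_stack(cols)
    X_full = np.column_stack([X_red, group])
    return X_red, X_full, k


def _as_binary_group(group) -> tuple[np.ndarray, tuple]:
    g = np.asarray(group)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {list(levels)}")
    return (g == levels[0]).astype(float), tuple(levels)


def ancova_group_test(
    y: np.ndarray,
    group,
    covariates: np.ndarray | None = None,
    feature_id: str = "",
) -> GroupTestResult:
    """Nested-model F test for a group effect, adjusting for covariates.

    Fits ``y ~ 1 + covariates + group`` and ``y ~ 1 + covariates`` with
    OLS and compares residual sums of squares:
    F = (RSS_red − RSS_full) / (RSS_full / (n − k − 2)).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    gind, levels = _as_binary_group(group)
    X_red, X_full, k = _design(gind, covariates, n)
    if n <= k + 2:
        raise ValueError(f"n={n} too small for {k} covariates plus group")
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient design: a covariate is collinear with the "
            "group indicator or another covariate"
        )
    fit_full = sm.OLS(y, X_full).fit()
    fit_red = sm.OLS(y, X_red).fit()
    df_denom = n - k - 2
    F = float((fit_red.ssr - fit_full.ssr) / (fit_full.ssr / df_denom))
    F = max(F, 0.0)
    p = float(stats.f.sf(F, 1, df_denom))
    d = cohens_d_residual(y, group, covariates)
    return GroupTestResult(
        feature_id=feature_id, F=F, p=p, cohens_d=d, df=(1, df_denom),
        sign_convention=f"{levels[0]} - {levels[1]}",
    )


def cohens_d_residual(
    y: np.ndarray, group, covariates: np.ndarray | None = None
) -> float:
    """Cohen's d between group residual distributions after covariate fit.

    Residuals come from the covariate-only model (group excluded); d is
    (mean_A − mean_B) / pooled SD with (n_A−1, n_B−1) weights, where A is
    the first-listed group level.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    gind, _ = _as_binary_group(group)
    X_red, _, _ = _design(gind, covariates, n)
    resid = sm.OLS(y, X_red).fit().resid
    a, b = resid[gind == 1.0], resid[gind == 0.0]
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled <= 0:
        raise ZeroDivisionError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up procedure.

    Returns ``(reject, p_adjusted)``: the largest k with
    p(k) ≤ k·q/m is found and all smaller ranks rejected; adjusted
    p-values are the usual step-up minima capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = q * np.arange(1, m + 1) / m
    passing = np.nonzero(ranked <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    adj = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    p_adj = np.empty(m)
    p_adj[order] = adj
    return reject, p_adj


def spearman_grid(table: pd.DataFrame, q: float = 0.05, min_pairs: int = 4) -> SpearmanGrid:
    """Spearman rank-correlation matrix with pairwise deletion and FDR.

    Correlations use midranks for ties and the t approximation for
    p-values; cells with fewer than ``min_pairs`` complete observations,
    or with a constant variable, are flagged NaN.  FDR runs over the
    unique off-diagonal pairs.
    """
    cols = list(table.columns)
    v = len(cols)
    rho = np.eye(v)
    pmat = np.zeros((v, v))
    for i in range(v):
        for j in range(i + 1, v):
            pair = table[[cols[i], cols[j]]].dropna().to_numpy(dtype=float)
            if pair.shape[0] < min_pairs:
                rho[i, j] = rho[j, i] = np.nan
                pmat[i, j] = pmat[j, i] = np.nan
                continue
            if np.ptp(pair[:, 0]) == 0 or np.ptp(pair[:, 1]) == 0:
                warnings.warn(
                    f"constant variable in pair ({cols[i]}, {cols[j]}); cell undefined",
                    RuntimeWarning,
                )
                rho[i, j] = rho[j, i] = np.nan
                pmat[i, j] = pmat[j, i] = np.nan
                continue
            r, pv = stats.spearmanr(pair[:, 0], pair[:, 1])
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = pv
    iu = np.triu_indices(v, k=1)
    flat_p = pmat[iu]
    mask = np.zeros((v, v), dtype=bool)
    ok = np.isfinite(flat_p)
    if np.any(ok):
        rej = np.zeros(flat_p.size, dtype=bool)
        rej[ok], _ = bh_fdr(np.clip(flat_p[ok], np.finfo(float).tiny, 1.0), q)
        mask[iu] = rej
        mask |= mask.T
    return SpearmanGrid(variables=cols, rho=rho, p=pmat, fdr_mask=mask)


def rsn_majority_vote(label_counts: pd.DataFrame) -> pd.Series:
    """Assign each region to the network with the maximal voxel count.

    ``label_counts`` is regions × networks (columns from the canonical
    seven RSNs); exact ties break by the fixed order VIS < SM < DA < VA <
    FP < DMN < LIM and the tied regions are reported in ``.attrs['ties']``.
    """
    unknown = set(label_counts.columns) - set(RSN_ORDER)
    if unknown:
        raise ValueError(f"unknown network labels: {sorted(unknown)}")
    counts = label_counts.reindex(columns=[c for c in RSN_ORDER if c in label_counts.columns])
    arr = counts.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("label counts must be non-negative")
    if np.any(arr.sum(axis=1) == 0):
        raise ValueError("a region has no votes for any network")
    win = arr.argmax(axis=1)  # argmax takes the first maximum = fixed order
    ties = [roi for r, roi in enumerate(counts.index)
            if (arr[r] == arr[r, win[r]]).sum() > 1]
    out = pd.Series([counts.columns[w] for w in win], index=counts.index, name="network")
    out.attrs["ties"] = ties
    return out


def rsn_effect_contribution(
    d: np.ndarray, sig_mask: np.ndarray, rsn_map: pd.Series
) -> pd.Series:
    """Percentage of total |effect size| carried by each network.

    Only regions flagged significant contribute; per network,
    Σ|d| over significant members ÷ Σ|d| over all significant regions,
    × 100.  With no significant region, all-zero with a warning.
    """
    d = np.asarray(d, dtype=float)
    sig = np.asarray(sig_mask, dtype=bool)
    if not (d.size == sig.size == len(rsn_map)):
        raise ValueError("effect sizes, mask and RSN map must align")
    networks = [n for n in RSN_ORDER if n in set(rsn_map)]
    total = np.abs(d[sig]).sum()
    if total == 0:
        warnings.warn("no significant regions: contributions are all zero",
                      RuntimeWarning)
        return pd.Series(0.0, index=pd.Index(networks, name="network"))
    vals = {
        n: 100.0 * np.abs(d[sig & (rsn_map.to_numpy() == n)]).sum() / total
        for n in networks
    }
    return pd.Series(vals, name="pct_contribution").reindex(networks)


def caq_scores(responses: pd.DataFrame) -> pd.DataFrame:
    """Cognitive-activity composites per subject.

    ``responses`` is long format (subject_id, activity, age, response)
    with responses on the 1–5 frequency scale and age one of
    {'6', '12', '18', '40', 'current'}.  cCAQ averages the current-age
    items; pCAQ averages across the four past ages.  Missing items are
    excluded from the means and the contributing item counts recorded; a
    composite with no observed items raises.
    """
    df = responses.copy()
    df["age"] = df["age"].astype(str)
    obs = df.dropna(subset=["response"])
    bad = obs[(obs["response"] < 1) | (obs["response"] > 5)]
    if len(bad):
        raise ValueError("responses must be integers on the 1–5 scale")
    out = {}
    for sid, sub in df.groupby("subject_id", sort=False):
        cur = sub.loc[sub["age"] == "current", "response"].dropna()
        past = sub.loc[sub["age"].isin(CAQ_PAST_AGES), "response"].dropna()
        if cur.empty or past.empty:
            raise ValueError(f"subject {sid}: all items missing for a composite")
        out[sid] = (cur.mean(), past.mean(), len(cur), len(past))
    res = pd.DataFrame.from_dict(
        out, orient="index", columns=["cCAQ", "pCAQ", "n_current", "n_past"]
    )
    res.index.name = "subject_id"
    return res
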