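"""Partial least squares correlation (PLSC) between brain and cognition.

Given a brain block X (subjects × p; e.g. the six whole-brain relative
band powers plus the individual peak frequency) and a cognitive block Y
(subjects × q; cognition, cognitive reserve, education and age), both
blocks are column-wise z-scored and the cross-block correlation matrix
R = XᵀY/(n−1) is decomposed by SVD, R = U S Vᵀ.  The paired columns of
U and V (brain and cognitive saliences) are orthonormal weight patterns
ordered by the covariance they capture (the singular values); latent
scores are the projections X·U and Y·V, loadings are the Pearson
correlations of the original variables with their own block's latent
scores, and r²_c is the squared correlation between the paired latent
score vectors — the share of one latent variable's variance explained
by the other.

Inference: component significance by permutation of the rows of Y
(1000 permutations by default, p = (1 + #{s*_c ≥ s_c})/(1 + N), BH-FDR
across components); loading reliability by bootstrap over subjects
(500 resamples), with components of each resample re-aligned to the
original by maximal absolute salience inner product, and the bootstrap
ratio z = loading / bootstrap SD thresholded at |z| > 3.

Missing cognitive entries are completed beforehand by 4-nearest-
neighbour imputation (Euclidean distance over z-scored mutually observed
variables).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .groupstats import bh_fdr

__all__ = [
    "PLSCInput",
    "PLSCResult",
    "impute_knn",
    "plsc_decompose",
    "plsc_permutation",
    "plsc_bootstrap",
]

#: bootstrap ratio assigned when the bootstrap SD of a loading is ~0
Z_CAP = 1e3


@dataclass
class PLSCInput:
    """Paired subject-aligned blocks with their standardization record."""

    X: np.ndarray
    Y: np.ndarray
    x_names: list[str]
    y_names: list[str]
    x_mean: np.ndarray = field(init=False)
    x_sd: np.ndarray = field(init=False)
    y_mean: np.ndarray = field(init=False)
    y_sd: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2-D (subjects × variables)")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y must have the same number of subjects")
        if self.X.shape[0] <= 2:
            raise ValueError("need more than two subjects")
        if np.isnan(self.X).any() or np.isnan(self.Y).any():
            raise ValueError("blocks must be complete; impute missing values first")
        for name, block in (("X", self.X), ("Y", self.Y)):
            sd = block.std(axis=0, ddof=1)
            if np.any(sd <= 0):
                raise ValueError(f"zero-variance column in block {name}")
        self.x_mean, self.x_sd = self.X.mean(axis=0), self.X.std(axis=0, ddof=1)
        self.y_mean, self.y_sd = self.Y.mean(axis=0), self.Y.std(axis=0, ddof=1)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def zscored(self) -> tuple[np.ndarray, np.ndarray]:
        return ((self.X - self.x_mean) / self.x_sd,
                (self.Y - self.y_mean) / self.y_sd)


@dataclass
class PLSCResult:
    singular_values: np.ndarray         # (c,), descending
    brain_saliences: np.ndarray         # (p, c)
    cognitive_saliences: np.ndarray     # (q, c)
    brain_scores: np.ndarray            # (n, c)
    cognitive_scores: np.ndarray        # (n, c)
    brain_loadings: np.ndarray          # (p, c)
    cognitive_loadings: np.ndarray      # (q, c)
    r_squared: np.ndarray               # (c,)
    perm_p: np.ndarray | None = None
    perm_p_fdr: np.ndarray | None = None
    boot_z_brain: np.ndarray | None = None
    boot_z_cognitive: np.ndarray | None = None
    reliable_brain: np.ndarray | None = None
    reliable_cognitive: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.singular_values.size


def impute_knn(table: pd.DataFrame, k: int = 4) -> pd.DataFrame:
    """Complete a table by k-nearest-neighbour imputation (default k=4).

    Distances are Euclidean over the z-scored variables both subjects
    observe (scaled up to the full variable count so subjects with few
    shared variables are not favoured); a missing cell becomes the mean
    of the k nearest subjects with that variable observed.  Distance
    ties break by row order, making the result deterministic.
    """
    df = table.astype(float)
    vals = df.to_numpy()
    n, v = vals.shape
    if not (0 < k < n):
        raise ValueError(f"k={k} must satisfy 0 < k < n={n}")
    if np.all(np.isnan(vals), axis=1).any():
        raise ValueError("a subject has no observed variables")
    col_ok = ~np.all(np.isnan(vals), axis=0)
    if not col_ok.all():
        missing_cols = [c for c, ok in zip(df.columns, col_ok) if not ok]
        raise ValueError(f"variable(s) missing for all subjects: {missing_cols}")
    mu = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0, ddof=1)
    sd[sd <= 0] = 1.0
    z = (vals - mu) / sd
    obs = ~np.isnan(vals)
    out = vals.copy()
    for i in range(n):
        miss_cols = np.nonzero(~obs[i])[0]
        if miss_cols.size == 0:
            continue
        shared = obs & obs[i]                     # (n, v) mutually observed
        diff = np.where(shared, z - z[i], 0.0)
        n_shared = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt((diff ** 2).sum(axis=1) * v / n_shared)
        dist[i] = np.inf
        dist[n_shared == 0] = np.inf
        for c in miss_cols:
            donors = np.nonzero(obs[:, c] & np.isfinite(dist))[0]
            if donors.size == 0:
                raise ValueError(
                    f"no donor for subject {df.index[i]}, variable {df.columns[c]}"
                )
            nearest = donors[np.argsort(dist[donors], kind="stable")[:k]]
            out[i, c] = vals[nearest, c].mean()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def _column_corr(block: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson correlation of every column of ``block`` with every score."""
    b = block - block.mean(axis=0)
    s = scores - scores.mean(axis=0)
    num = b.T @ s
    denom = np.outer(np.sqrt((b ** 2).sum(axis=0)), np.sqrt((s ** 2).sum(axis=0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.clip(num / denom, -1.0, 1.0)


def plsc_decompose(inp: PLSCInput) -> PLSCResult:
    """SVD of the cross-block correlation matrix; all derived quantities."""
    Xz, Yz = inp.zscored()
    n = inp.n
    Rxy = Xz.T @ Yz / (n - 1)
    U, s, Vt = np.linalg.svd(Rxy, full_matrices=False)
    V = Vt.T
    Lx = Xz @ U
    Ly = Yz @ V
    r2 = np.array([
        np.corrcoef(Lx[:, c], Ly[:, c])[0, 1] ** 2 for c in range(s.size)
    ])
    return PLSCResult(
        singular_values=s,
        brain_saliences=U,
        cognitive_saliences=V,
        brain_scores=Lx,
        cognitive_scores=Ly,
        brain_loadings=_column_corr(inp.X, Lx),
        cognitive_loadings=_column_corr(inp.Y, Ly),
        r_squared=r2,
    )


def plsc_permutation(
    inp: PLSCInput,
    n_perm: int = 1000,
    q: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Component p-values by permuting the rows of Y.

    The statistic is the rank-matched singular value (no Procrustes
    rotation); p_c = (1 + #{s*_c ≥ s_c}) / (1 + n_perm), followed by
    BH-FDR across components.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    Xz, Yz = inp.zscored()
    n = inp.n
    s_obs = np.linalg.svd(Xz.T @ Yz / (n - 1), compute_uv=False)
    count = np.zeros_like(s_obs)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        s_perm = np.linalg.svd(Xz.T @ Yz[perm] / (n - 1), compute_uv=False)
        count += s_perm >= s_obs
    p = (1.0 + count) / (1.0 + n_perm)
    _, p_fdr = bh_fdr(p, q)
    return p, p_fdr


def _align(U_ref: np.ndarray, U_boot: np.ndarray, V_boot: np.ndarray, s: np.ndarray):
    """Match bootstrap components to the originals.

    Greedy assignment by maximal |⟨u_boot, u_ref⟩|, then sign-flip both
    saliences of a pair so the brain salience correlates positively with
    its reference.
    """
    c = U_ref.shape[1]
    G = np.abs(U_boot.T @ U_ref)  # rows: boot comps, cols: ref comps
    order = np.full(c, -1)
    used = set()
    for ref in np.argsort(-s):    # strongest original components pick first
        cand = np.argsort(-G[:, ref])
        for b in cand:
            if b not in used:
                order[ref] = b
                used.add(b)
                break
    Ub = U_boot[:, order]
    Vb = V_boot[:, order]
    signs = np.sign(np.einsum("pc,pc->c", Ub, U_ref))
    signs[signs == 0] = 1.0
    return Ub * signs, Vb * signs


def plsc_bootstrap(
    inp: PLSCInput,
    n_boot: int = 500,
    z_thresh: float = 3.0,
    seed: int | np.random.Generator = 0,
) -> PLSCResult:
    """Loading reliability by subject-level bootstrap.

    Rows are resampled with replacement in pairs; each resample's
    decomposition is re-aligned to the original (order and sign) and its
    loadings collected.  The bootstrap ratio is the original loading
    divided by the bootstrap SD of that loading (capped at ±Z_CAP when
    the SD is numerically zero); |z| > ``z_thresh`` marks a reliable
    loading.  Resamples with a constant column are skipped and counted.
    """
    if n_boot < 100:
        raise ValueError("use at least 100 bootstrap resamples")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    res = plsc_decompose(inp)
    n = inp.n
    bl, cl = [], []
    skipped = 0
    while len(bl) < n_boot:
        idx = rng.integers(0, n, size=n)
        Xb, Yb = inp.X[idx], inp.Y[idx]
        if (Xb.std(axis=0) == 0).any() or (Yb.std(axis=0) == 0).any():
            skipped += 1
            if skipped > 10 * n_boot:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        bres = plsc_decompose(PLSCInput(Xb, Yb, inp.x_names, inp.y_names))
        Ub, Vb = _align(res.brain_saliences, bres.brain_saliences,
                        bres.cognitive_saliences, res.singular_values)
        Xzb = (Xb - Xb.mean(axis=0)) / Xb.std(axis=0, ddof=1)
        Yzb = (Yb - Yb.mean(axis=0)) / Yb.std(axis=0, ddof=1)
        bl.append(_column_corr(Xb, Xzb @ Ub))
        cl.append(_column_corr(Yb, Yzb @ Vb))
    if skipped:
        warnings.warn(f"skipped {skipped} degenerate bootstrap resample(s)",
                      RuntimeWarning)
    sd_b = np.std(np.stack(bl), axis=0, ddof=1)
    sd_c = np.std(np.stack(cl), axis=0, ddof=1)
    eps = 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        zb = np.where(sd_b > eps, res.brain_loadings / np.maximum(sd_b, eps),
                      np.sign(res.brain_loadings) * Z_CAP)
        zc = np.where(sd_c > eps, res.cognitive_loadings / np.maximum(sd_c, eps),
                      np.sign(res.cognitive_loadings) * Z_CAP)
    res.boot_z_brain = zb
    res.boot_z_cognitive = zc
    res.reliable_brain = np.abs(zb) > z_thresh
    res.reliable_cognitive = np.abs(zc) > z_thresh
    return res
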