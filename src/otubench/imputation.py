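"""Zero-imputation methods behind a common contract.

Every imputer returns a nonnegative matrix of the same shape as its input,
and only zero entries are eligible for replacement.  ``llsimpute``,
``scimpute`` and ``drimpute`` leave non-zero entries bit-unchanged; the two
zCompositions variants additionally apply their documented multiplicative
rescaling of the non-zero parts (which preserves the ratios between them).

Stable ids: ``llsimpute``, ``zcomp_sq``, ``zcomp_czm``, ``scimpute``,
``drimpute``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import squareform

from .containers import CountMatrix

IMPUTATION_IDS = ("llsimpute", "zcomp_sq", "zcomp_czm", "scimpute", "drimpute")

IMPUTATION_NAMES = {
    "llsimpute": "LLSimpute",
    "zcomp_sq": "zCompositions_SQ",
    "zcomp_czm": "zCompositions_CZM",
    "scimpute": "scImpute",
    "drimpute": "DrImpute",
}

#: imputed values below this are snapped back to exact zero so that denormal
#: numerical noise never counts as an imputed entry
IMPUTED_FLOOR = 1e-9


def _floor(arr: np.ndarray) -> np.ndarray:
    arr[np.abs(arr) < IMPUTED_FLOOR] = 0.0
    return arr


def _log1p_cpm(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """log1p of counts-per-million, plus the column sums for back-transform."""
    colsums = arr.sum(axis=0)
    if (colsums <= 0).any():
        raise ValueError("imputation requires positive column sums")
    return np.log1p(arr / colsums[None, :] * 1e6), colsums


def _from_log1p_cpm(values: np.ndarray, colsum: float) -> np.ndarray:
    return np.expm1(values) / 1e6 * colsum


# ---------------------------------------------------------------------------
# Local least squares


def llsimpute(matrix: CountMatrix, k: int = 10) -> CountMatrix:
    """Local-least-squares imputation borrowing from co-abundant features.

    For each feature with zeros, the samples split into the zero set ``C_i``
    and the observed set ``D_i``.  The ``k`` features nearest in Euclidean
    distance on the ``D_i`` columns form the regressor block; the
    least-squares coefficients fitted on ``D_i`` predict the ``C_i`` entries,
    clamped at zero.  Features with fewer than two observed samples are left
    untouched (recorded in provenance).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= matrix.shape[0]:
        raise ValueError("k must be smaller than the number of features")
    arr = matrix.to_numpy()
    out = arr.copy()
    skipped: list[str] = []
    zero_rows = np.flatnonzero((arr == 0).any(axis=1))
    for i in zero_rows:
        zero_cols = arr[i] == 0
        d_cols = np.flatnonzero(~zero_cols)
        c_cols = np.flatnonzero(zero_cols)
        if d_cols.size < 2:
            skipped.append(str(matrix.features[i]))
            continue
        others = np.delete(np.arange(arr.shape[0]), i)
        dists = np.linalg.norm(arr[np.ix_(others, d_cols)] - arr[i, d_cols], axis=1)
        neigh = others[np.argsort(dists, kind="stable")[:k]]
        A = arr[np.ix_(neigh, d_cols)].T          # (n-q) × K
        b = arr[i, d_cols]
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
        pred = x @ arr[np.ix_(neigh, c_cols)]
        out[i, c_cols] = np.maximum(pred, 0.0)
    return matrix.with_values(
        _floor(out),
        layer="processed",
        provenance={"imputation": "llsimpute", "k": k, "skipped_features": skipped},
    )


# ---------------------------------------------------------------------------
# zCompositions-style multiplicative replacements


def zcomp_sq(counts: CountMatrix) -> CountMatrix:
    """Square-root Bayesian-multiplicative replacement of zero counts.

    Per sample of ``D`` parts and total ``n``, each zero part is replaced by
    its posterior-expected proportion under a uniform Dirichlet prior of
    total strength ``s = sqrt(n)`` — that is ``(s/D) / (n + s)`` — and the
    non-zero proportions are multiplied by one minus the total replaced mass,
    so the composition stays closed and non-zero ratios are preserved.  The
    column is finally rescaled to its original total.
    """
    arr = counts.to_numpy()
    out = np.empty_like(arr, dtype=float)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        n = col.sum()
        if n <= 0:
            raise ValueError(f"sample {counts.samples[j]!r} has zero total")
        D = col.size
        p = col / n
        zero = col == 0
        s = np.sqrt(n)
        repl = (s / D) / (n + s)
        total_repl = zero.sum() * repl
        newp = np.where(zero, repl, p * (1.0 - total_repl))
        out[:, j] = newp * n
    return counts.with_values(out, layer="processed",
                              provenance={"imputation": "zcomp_sq"})


def zcomp_czm(counts: CountMatrix, frac: float = 0.65) -> CountMatrix:
    """Rounded-zero multiplicative replacement (CZM).

    Zero proportions are replaced by ``delta = frac / (n + 1)``, a fraction
    of the sample's detection-limit proxy ``1/(n+1)``; non-zero proportions
    are multiplied by ``1 - (#zeros) * delta`` and the column rescaled to its
    original total.

    A rounded zero sits *below* the detection limit, so the proxy is capped
    at the smallest observed positive proportion of the sample.  On integer
    counts the cap is inactive (the smallest proportion is at least ``1/n``),
    while on normalized input — where the column total is not a read count —
    it keeps the replacement on the data's own scale.
    """
    if not (0.0 < frac < 1.0):
        raise ValueError("frac must lie in (0, 1)")
    arr = counts.to_numpy()
    out = np.empty_like(arr, dtype=float)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        n = col.sum()
        if n <= 0:
            raise ValueError(f"sample {counts.samples[j]!r} has zero total")
        p = col / n
        zero = col == 0
        delta = frac * min(1.0 / (n + 1.0), p[~zero].min())
        total_repl = zero.sum() * delta
        if total_repl >= 1.0:
            raise ValueError(
                f"sample {counts.samples[j]!r} is degenerate: replacement mass "
                f"{total_repl:.3f} >= 1"
            )
        newp = np.where(zero, delta, p * (1.0 - total_repl))
        out[:, j] = newp * n
    return counts.with_values(out, layer="processed",
                              provenance={"imputation": "zcomp_czm", "frac": frac})


# ---------------------------------------------------------------------------
# scImpute-style dropout modelling


@dataclass
class DropoutModel:
    """Per-feature Gamma(dropout) + Normal(expressed) mixture diagnostics."""

    dropout_probability: pd.DataFrame  # d_ij for modelled features, else NaN
    mixing_weight: pd.Series
    skipped_features: list[str] = field(default_factory=list)


def _fit_dropout_mixture(
    x: np.ndarray, max_iter: int = 200, tol: float = 1e-6
) -> np.ndarray | None:
    """EM fit of a two-component Gamma+Normal mixture on one feature's values.

    Returns the per-sample posterior dropout probability, or None when the
    fit is degenerate (single component, non-convergent moments, or the
    "dropout" component not below the "expressed" one).  Zeros are clamped to
    a small positive value for the gamma density.  Component parameters use
    weighted moment estimates inside EM, which is robust at the small sample
    sizes typical here.
    """
    eps = 0.01
    xc = np.maximum(x, eps)
    q10 = np.quantile(x, 0.10)
    g = (x <= max(q10, 0.0)).astype(float)
    if g.sum() == 0 or g.sum() == g.size:
        return None
    for _ in range(max_iter):
        lam = g.mean()
        wg, wn = g, 1.0 - g
        if wg.sum() < 1e-12 or wn.sum() < 1e-12:
            return None
        mu_g = np.sum(wg * xc) / wg.sum()
        var_g = np.sum(wg * (xc - mu_g) ** 2) / wg.sum()
        mu_n = np.sum(wn * xc) / wn.sum()
        var_n = np.sum(wn * (xc - mu_n) ** 2) / wn.sum()
        var_g = max(var_g, 1e-6)
        sd_n = max(np.sqrt(var_n), 1e-3)
        shape = mu_g**2 / var_g
        scale = var_g / mu_g
        f_g = sstats.gamma.pdf(xc, a=shape, scale=scale)
        f_n = sstats.norm.pdf(xc, loc=mu_n, scale=sd_n)
        denom = lam * f_g + (1.0 - lam) * f_n
        denom = np.where(denom <= 0, 1e-300, denom)
        g_new = lam * f_g / denom
        if np.max(np.abs(g_new - g)) < tol:
            g = g_new
            break
        g = g_new
    if mu_n <= mu_g:  # "expressed" component must sit above the dropout one
        return None
    return g


def scimpute_like(
    counts: CountMatrix,
    t: float = 0.5,
    groups: pd.Series | None = None,
    seed: int = 0,
) -> CountMatrix:
    """Dropout-aware imputation in the style of scImpute.

    Works on log1p-CPM values.  Per feature, a Gamma(dropout)+Normal mixture
    fitted by EM yields each entry's dropout probability ``d_ij``; zero
    entries with ``d_ij > t`` are imputation candidates.  Each sample is then
    regressed (nonnegative least squares) on its similar samples — its group
    members when labels are given, otherwise clusters on the top principal
    directions — using only its reliable features (``d_ij <= t``), and the
    fitted combination predicts the candidate entries.  Non-candidate entries
    are returned bit-unchanged.
    """
    arr = counts.to_numpy()
    n_feat, n_samp = arr.shape
    if n_samp < 4:
        raise ValueError("scimpute requires at least 4 samples")
    L, colsums = _log1p_cpm(arr)

    d = np.full((n_feat, n_samp), np.nan)
    skipped: list[str] = []
    for i in range(n_feat):
        row = L[i]
        if (row == 0).all() or (row > 0).all() and np.ptp(row) < 1e-12:
            continue
        if not (row == 0).any():
            continue  # no zero entries → nothing to impute for this feature
        post = _fit_dropout_mixture(row)
        if post is None:
            skipped.append(str(counts.features[i]))
            continue
        d[i] = post

    if groups is None:
        groups = counts.groups
    if groups is not None:
        labels = groups.reindex(counts.samples).to_numpy()
    else:
        labels = _pca_partition(L, seed=seed)

    out_L = L.copy()
    candidate = (arr == 0) & (np.nan_to_num(d, nan=0.0) > t)
    reliable_mask = ~candidate  # includes unmodelled features and confident entries
    for j in range(n_samp):
        cand_feats = np.flatnonzero(candidate[:, j])
        if cand_feats.size == 0:
            continue
        similar = np.flatnonzero((labels == labels[j]) & (np.arange(n_samp) != j))
        if similar.size == 0:
            continue
        rel = np.flatnonzero(reliable_mask[:, j] & (arr[:, j] > 0))
        if rel.size < similar.size:
            continue
        A = L[np.ix_(rel, similar)]
        b = L[rel, j]
        beta, _ = nnls(A, b)
        # donors may themselves have dropped the candidate feature; predict
        # from the detected donors only, renormalizing their weights
        donor_vals = L[np.ix_(cand_feats, similar)]
        donor_det = donor_vals > 0
        w_det = donor_det @ beta
        pred = np.where(w_det > 0, (donor_vals @ beta) * (beta.sum() / np.where(w_det > 0, w_det, 1.0)), 0.0)
        out_L[cand_feats, j] = pred

    out = arr.astype(float).copy()
    changed = out_L != L
    for j in range(n_samp):
        rows = np.flatnonzero(changed[:, j])
        out[rows, j] = _from_log1p_cpm(out_L[rows, j], colsums[j])
    return counts.with_values(
        _floor(out),
        layer="processed",
        provenance={"imputation": "scimpute", "t": t, "skipped_features": skipped},
    )


def _pca_partition(L: np.ndarray, seed: int, n_components: int = 5) -> np.ndarray:
    """Fallback sample partitioning on the top principal directions."""
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    n_samp = L.shape[1]
    k = max(2, min(5, n_samp // 4))
    comps = min(n_components, n_samp - 1, L.shape[0])
    scores = PCA(n_components=comps, random_state=seed).fit_transform(L.T)
    return KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(scores)


# ---------------------------------------------------------------------------
# DrImpute-style consensus clustering


def drimpute_like(
    counts: CountMatrix,
    ks: Sequence[int] | Iterable[int] = range(10, 16),
) -> CountMatrix:
    """Consensus-clustering imputation in the style of DrImpute.

    On log1p-CPM values, for every combination of correlation metric
    (Spearman, Pearson) and cluster count ``k``, samples are clustered by
    average-linkage on the ``1 - correlation`` distance and each zero entry
    is estimated as the mean of the feature's detected (non-zero) values in
    the sample's cluster.  The final imputed value averages the estimates
    over the combinations that produced one — a cluster holding no detected
    value for the feature contributes no estimate, so entries undetected in
    every clustering (e.g. condition-wide absences) stay zero.  Non-zero
    entries are untouched.

    Correlations are computed pairwise over features detected in both
    samples: zeros are suspected dropouts, so they are not allowed to drive
    the similarity used to pick the donors.
    """
    ks = [int(k) for k in ks]
    if not ks:
        raise ValueError("ks must be non-empty")
    arr = counts.to_numpy()
    n_samp = arr.shape[1]
    L, colsums = _log1p_cpm(arr)
    zero = arr == 0
    nonzero = ~zero

    usable_ks = [k for k in ks if 2 <= k < n_samp]
    for k in set(ks) - set(usable_ks):
        warnings.warn(f"drimpute: k={k} skipped (needs 2 <= k < {n_samp} samples)")
    if not usable_ks:
        raise ValueError("drimpute: no usable cluster count k")

    est_sum = np.zeros_like(L)
    est_n = np.zeros_like(L)
    df = pd.DataFrame(np.where(nonzero, L, np.nan))
    for metric in ("spearman", "pearson"):
        corr = df.corr(method=metric, min_periods=2).to_numpy()
        corr[~np.isfinite(corr)] = 0.0
        np.fill_diagonal(corr, 1.0)
        dist = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        for k in usable_ks:
            assign = fcluster(Z, t=k, criterion="maxclust")
            for c in np.unique(assign):
                members = np.flatnonzero(assign == c)
                mask = nonzero[:, members]
                cnt = mask.sum(axis=1)
                s = (L[:, members] * mask).sum(axis=1)
                mean = np.divide(s, cnt, out=np.zeros_like(s), where=cnt > 0)
                est_sum[:, members] += mean[:, None]
                est_n[:, members] += (cnt > 0)[:, None]
    estimates = np.divide(est_sum, est_n, out=np.zeros_like(est_sum), where=est_n > 0)

    out = arr.astype(float).copy()
    for j in range(n_samp):
        rows = np.flatnonzero(zero[:, j] & (estimates[:, j] > 0))
        out[rows, j] = _from_log1p_cpm(estimates[rows, j], colsums[j])
    return counts.with_values(
        _floor(out),
        layer="processed",
        provenance={"imputation": "drimpute", "ks": usable_ks},
    )


# ---------------------------------------------------------------------------
# Dispatcher


def impute(
    counts: CountMatrix,
    method: str,
    groups: pd.Series | None = None,
    seed: int = 0,
    **params,
) -> CountMatrix:
    """Run one imputation method by its stable id."""
    if method == "llsimpute":
        return llsimpute(counts, **params)
    if method == "zcomp_sq":
        return zcomp_sq(counts)
    if method == "zcomp_czm":
        return zcomp_czm(counts, **params)
    if method == "scimpute":
        return scimpute_like(counts, groups=groups, seed=seed, **params)
    if method == "drimpute":
        return drimpute_like(counts, **params)
    raise ValueError(f"unknown imputation id {method!r}")
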