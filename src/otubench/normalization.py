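"""Library-size normalization methods for sparse count tables.

Five methods are implemented behind stable string ids:

* ``tss``   — total-sum scaling (per-sample proportions);
* ``css``   — cumulative-sum scaling with the adaptive quantile rule;
* ``tmm``   — trimmed mean of M-values (edgeR-style size factors);
* ``deseq`` — median-of-ratios size factors;
* ``gmpr``  — geometric mean of pairwise ratios, designed for zero-inflated
  tables.

All methods rescale each sample by a positive scalar, so they never create or
destroy zeros: the output zero pattern is exactly the input's.  ``cpm`` is the
counts-per-million transform used throughout the evaluation stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix

NORMALIZATION_IDS = ("tss", "css", "tmm", "deseq", "gmpr")

#: display names matching the benchmark's pipeline naming convention
NORMALIZATION_NAMES = {
    "tss": "TSS",
    "css": "CSS",
    "tmm": "edgeR",
    "deseq": "DESeq2",
    "gmpr": "GMPR",
}


@dataclass
class SizeFactors:
    """Per-sample positive scaling factors produced by a size-factor method."""

    method: str
    factors: pd.Series
    reference_sample: str | None = None

    def __post_init__(self) -> None:
        arr = self.factors.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or (arr <= 0).any():
            raise ValueError(f"{self.method}: size factors must be positive and finite")


@dataclass
class CSSStats:
    """Diagnostics of the cumulative-sum-scaling quantile selection."""

    quantiles: pd.DataFrame          # samples × levels, q_j^l
    cumulative_sums: pd.DataFrame    # samples × levels, s_j^l
    reference_quantiles: np.ndarray  # q̄^l
    deviations: np.ndarray           # d_l
    selected_level: int              # l̂ (1-based)
    scaling_constant: float          # K
    fallback_used: bool = False


@dataclass
class TMMStats:
    """Per-sample diagnostics of the trimmed-mean-of-M-values computation."""

    reference_sample: str
    m_values: dict[str, np.ndarray] = field(default_factory=dict)
    a_values: dict[str, np.ndarray] = field(default_factory=dict)
    weights: dict[str, np.ndarray] = field(default_factory=dict)
    retained: dict[str, np.ndarray] = field(default_factory=dict)  # feature indices
    trim_m: float = 0.30
    trim_a: float = 0.05


@dataclass
class GMPRStats:
    """Pairwise median count ratios behind the GMPR size factors."""

    ratios: pd.DataFrame          # r_jk; NaN where the pair shares no feature
    shared_counts: pd.DataFrame   # number of jointly nonzero features per pair


def _check_positive_columns(counts: CountMatrix) -> np.ndarray:
    arr = counts.to_numpy()
    colsums = arr.sum(axis=0)
    if (colsums == 0).any():
        bad = counts.samples[colsums == 0][0]
        raise ValueError(f"sample {bad!r} has an all-zero count column")
    return arr


def tss(counts: CountMatrix) -> CountMatrix:
    """Total-sum scaling: each column becomes its vector of proportions."""
    arr = _check_positive_columns(counts)
    out = arr / arr.sum(axis=0, keepdims=True)
    return counts.with_values(out, layer="processed", provenance={"normalization": "tss"})


def cpm(counts: CountMatrix) -> CountMatrix:
    """Counts per million: proportions scaled by 1e6."""
    arr = _check_positive_columns(counts)
    out = arr / arr.sum(axis=0, keepdims=True) * 1e6
    return counts.with_values(out, layer="processed", provenance={"normalization": "cpm"})


def css(counts: CountMatrix) -> tuple[CountMatrix, CSSStats]:
    """Cumulative-sum scaling with the adaptive quantile-instability rule.

    Per sample, ``q_j^l`` are the quantiles of the *positive* counts on a grid
    of ``m`` levels (m = number of features) and ``s_j^l`` the cumulative sum
    of counts at or below that quantile.  The shared level ``l̂`` is the
    smallest one where the median absolute deviation of the sample quantiles
    around their cross-sample median becomes unstable
    (``d_{l+1} - d_l >= 0.1 * d_l``); if the rule never fires the median level
    (0.50 quantile) is used and flagged.  Counts are scaled to
    ``K * c_ij / s_j^l̂`` with ``K`` the median of the ``s_j^l̂``.
    """
    if counts.shape[1] < 2:
        raise ValueError("css requires at least 2 samples")
    arr = _check_positive_columns(counts)
    n_feat, n_samp = arr.shape
    m = n_feat
    probs = np.arange(1, m + 1) / m
    q = np.full((n_samp, m), np.nan)
    s = np.zeros((n_samp, m))
    for j in range(n_samp):
        pos = arr[arr[:, j] > 0, j]
        q[j] = np.quantile(pos, probs)
        # cumulative sum of all counts at or below the level's quantile
        s[j] = [arr[arr[:, j] <= q[j, l], j].sum() for l in range(m)]
    q_ref = np.median(q, axis=0)
    d = np.median(np.abs(q - q_ref[None, :]), axis=0)

    selected = None
    for l in range(m - 1):
        if d[l + 1] - d[l] >= 0.1 * d[l]:
            selected = l
            break
    fallback = selected is None
    if fallback:
        selected = int(np.searchsorted(probs, 0.5))
    s_hat = s[:, selected]
    if (s_hat <= 0).any():
        raise ValueError("css: nonpositive cumulative sum at selected quantile")
    K = float(np.median(s_hat))
    out = arr / s_hat[None, :] * K
    stats = CSSStats(
        quantiles=pd.DataFrame(q, index=counts.samples, columns=probs),
        cumulative_sums=pd.DataFrame(s, index=counts.samples, columns=probs),
        reference_quantiles=q_ref,
        deviations=d,
        selected_level=selected + 1,
        scaling_constant=K,
        fallback_used=fallback,
    )
    cm = counts.with_values(out, layer="processed", provenance={"normalization": "css"})
    return cm, stats


def _tmm_reference(arr: np.ndarray) -> int:
    """Reference sample: 75th percentile of positive-count CPM closest to the mean."""
    colsums = arr.sum(axis=0)
    uq = np.array(
        [
            np.quantile(arr[arr[:, j] > 0, j] / colsums[j] * 1e6, 0.75)
            for j in range(arr.shape[1])
        ]
    )
    return int(np.argmin(np.abs(uq - uq.mean())))


def _rank_keep(values: np.ndarray, trim: float) -> np.ndarray:
    """Two-sided rank trim: keep entries whose rank lies strictly inside the
    lower and upper ``trim`` tails (edgeR's convention)."""
    n = values.size
    ranks = pd.Series(values).rank().to_numpy()
    lo = np.floor(n * trim) + 1
    hi = n + 1 - lo
    return (ranks >= lo) & (ranks <= hi)


def tmm_factors(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05,
    min_features: int = 10,
) -> tuple[SizeFactors, TMMStats]:
    """Trimmed-mean-of-M-values size factors.

    For each sample against the reference, log fold changes ``M_i`` and
    average log abundances ``A_i`` are computed on the features nonzero in
    both samples, the extreme ``M`` (30% each tail) and ``A`` (5% each tail)
    values are trimmed, and the factor is ``2**(Σ w_i M_i / Σ w_i)`` with
    delta-method inverse-variance weights.  Factors are rescaled to geometric
    mean 1.  Samples with fewer than ``min_features`` surviving features get
    factor 1 with a warning.
    """
    if counts.shape[1] < 2:
        raise ValueError("tmm requires at least 2 samples")
    arr = _check_positive_columns(counts)
    colsums = arr.sum(axis=0)
    r = _tmm_reference(arr)
    stats = TMMStats(reference_sample=str(counts.samples[r]),
                     trim_m=trim_m, trim_a=trim_a)
    factors = np.ones(arr.shape[1])
    for j in range(arr.shape[1]):
        if j == r:
            continue
        both = (arr[:, j] > 0) & (arr[:, r] > 0)
        cj, cr = arr[both, j], arr[both, r]
        pj, pr = cj / colsums[j], cr / colsums[r]
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        keep = _rank_keep(M, trim_m) & _rank_keep(A, trim_a)
        if keep.sum() < min_features:
            warnings.warn(
                f"tmm: sample {counts.samples[j]!r} retains {int(keep.sum())} "
                f"features after trimming; factor set to 1"
            )
            stats.retained[str(counts.samples[j])] = np.array([], dtype=int)
            continue
        w = 1.0 / (
            (colsums[j] - cj[keep]) / (colsums[j] * cj[keep])
            + (colsums[r] - cr[keep]) / (colsums[r] * cr[keep])
        )
        factors[j] = 2.0 ** (np.sum(w * M[keep]) / np.sum(w))
        key = str(counts.samples[j])
        stats.m_values[key] = M
        stats.a_values[key] = A
        stats.weights[key] = w
        stats.retained[key] = np.flatnonzero(both)[keep]
    factors /= np.exp(np.mean(np.log(factors)))
    sf = SizeFactors(
        method="tmm",
        factors=pd.Series(factors, index=counts.samples),
        reference_sample=str(counts.samples[r]),
    )
    return sf, stats


def deseq_factors(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    The pseudo-reference is the per-feature geometric mean across samples,
    computed on the features positive in *every* sample; each factor is the
    median of that sample's ratios to the pseudo-reference.
    """
    arr = counts.to_numpy()
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "deseq: no feature is positive in all samples; "
            "pseudo-reference alternatives are not implemented"
        )
    sub = arr[all_pos]
    geo = np.exp(np.mean(np.log(sub), axis=1))
    factors = np.median(sub / geo[:, None], axis=0)
    return SizeFactors(method="deseq", factors=pd.Series(factors, index=counts.samples))


def gmpr_factors(counts: CountMatrix) -> tuple[SizeFactors, GMPRStats]:
    """Geometric-mean-of-pairwise-ratios size factors.

    ``r_jk`` is the median of count ratios over features nonzero in both
    samples; the factor for sample ``j`` is the geometric mean of its usable
    ``r_jk`` (pairs sharing no feature are skipped and recorded).  Factors
    are rescaled to median 1, the convention of the original tool.
    """
    arr = counts.to_numpy()
    n = arr.shape[1]
    ratios = np.full((n, n), np.nan)
    shared = np.zeros((n, n), dtype=int)
    np.fill_diagonal(ratios, 1.0)
    for j in range(n):
        for k in range(n):
            if j == k:
                shared[j, k] = int(((arr[:, j] > 0)).sum())
                continue
            both = (arr[:, j] > 0) & (arr[:, k] > 0)
            shared[j, k] = int(both.sum())
            if shared[j, k] > 0:
                ratios[j, k] = float(np.median(arr[both, j] / arr[both, k]))
    factors = np.empty(n)
    for j in range(n):
        usable = np.array([k for k in range(n) if k != j and np.isfinite(ratios[j, k])])
        if usable.size == 0:
            raise ValueError(
                f"gmpr: sample {counts.samples[j]!r} shares no nonzero feature "
                "with any other sample"
            )
        factors[j] = np.exp(np.mean(np.log(ratios[j, usable])))
    factors /= np.median(factors)
    sf = SizeFactors(method="gmpr", factors=pd.Series(factors, index=counts.samples))
    idx = counts.samples
    stats = GMPRStats(
        ratios=pd.DataFrame(ratios, index=idx, columns=idx),
        shared_counts=pd.DataFrame(shared, index=idx, columns=idx),
    )
    return sf, stats


def apply_factors(counts: CountMatrix, sf: SizeFactors) -> CountMatrix:
    """Divide each sample column by its size factor."""
    factors = sf.factors.reindex(counts.samples)
    if factors.isna().any():
        raise ValueError("size factors do not cover all samples")
    out = counts.to_numpy() / factors.to_numpy()[None, :]
    return counts.with_values(
        out, layer="processed", provenance={"normalization": sf.method}
    )


def normalize(counts: CountMatrix, method: str) -> CountMatrix:
    """Run one normalization method by id and return the scaled matrix."""
    if method == "tss":
        return tss(counts)
    if method == "css":
        return css(counts)[0]
    if method == "tmm":
        sf, _ = tmm_factors(counts)
        return apply_factors(counts, sf)
    if method == "deseq":
        return apply_factors(counts, deseq_factors(counts))
    if method == "gmpr":
        sf, _ = gmpr_factors(counts)
        return apply_factors(counts, sf)
    raise ValueError(f"unknown normalization id {method!r}")
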