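"""Benchmark metrics and statistical comparisons against the ground truth.

The evaluation compares each pipeline's processed matrix with the simulator's
ground truth along five axes: total sparsity, classification of raw zeros
into biological/technical, per-sample abundance-profile error (SMAPE and
Aitchison distance on CPM-transformed data), alpha/beta diversity, and
concordance of differential-abundance calls (Jaccard index).  Improvement
over raw data is tested with one-sided paired rank tests, Benjamini–Hochberg
corrected, and accompanied by Cohen's d with conventional magnitude labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix
from .normalization import cpm

# ---------------------------------------------------------------------------
# Sparsity and zero classification


def total_sparsity(M) -> float:
    """Percentage of zero entries in a matrix (0–100)."""
    arr = M.to_numpy() if isinstance(M, (CountMatrix, pd.DataFrame)) else np.asarray(M)
    if arr.size == 0:
        raise ValueError("empty matrix")
    return 100.0 * float(np.count_nonzero(arr == 0)) / arr.size


@dataclass
class ZeroConfusion:
    """Confusion counts over the raw-zero entries.

    A raw zero is *technical* when the ground truth is positive (the species
    was present but unobserved) and *biological* otherwise.  An entry counts
    as imputed when the processed value is positive.
    """

    tp: int  # technical zeros imputed
    fp: int  # biological zeros imputed
    fn: int  # technical zeros left at zero
    tn: int  # biological zeros left at zero

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return float("nan") if denom == 0 else 100.0 * self.tp / denom

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return float("nan") if denom == 0 else 100.0 * self.tn / denom


def zero_confusion(truth, raw, processed) -> ZeroConfusion:
    """Classify every raw-zero entry by what imputation did to it."""
    t = truth.to_numpy() if isinstance(truth, CountMatrix) else np.asarray(truth)
    r = raw.to_numpy() if isinstance(raw, CountMatrix) else np.asarray(raw)
    p = processed.to_numpy() if isinstance(processed, CountMatrix) else np.asarray(processed)
    if not (t.shape == r.shape == p.shape):
        raise ValueError("matrices must share a shape")
    raw_zero = r == 0
    technical = raw_zero & (t > 0)
    biological = raw_zero & (t == 0)
    imputed = p > 0
    return ZeroConfusion(
        tp=int(np.count_nonzero(technical & imputed)),
        fp=int(np.count_nonzero(biological & imputed)),
        fn=int(np.count_nonzero(technical & ~imputed)),
        tn=int(np.count_nonzero(biological & ~imputed)),
    )


# ---------------------------------------------------------------------------
# Abundance-profile error


def smape_per_sample(x, y) -> float:
    """Symmetric mean absolute percentage error between two vectors (0–100).

    Terms where both entries are zero contribute zero (the 0/0 convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    denom = np.abs(x) + np.abs(y)
    terms = np.zeros_like(denom)
    mask = denom > 0
    terms[mask] = np.abs(x - y)[mask] / denom[mask]
    return 100.0 * float(terms.sum()) / x.size


def _apply_zero_rule(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replace zeros by half the smallest positive value across the pair."""
    pos = np.concatenate([x[x > 0], y[y > 0]])
    if pos.size == 0:
        raise ValueError("both vectors are all-zero")
    repl = 0.5 * pos.min()
    return np.where(x > 0, x, repl), np.where(y > 0, y, repl)


def aitchison_per_sample(x, y, zero_rule: str = "half_min") -> float:
    """Aitchison distance between two compositions.

    Computed as the Euclidean distance between clr-transformed vectors, which
    equals the normalized double sum over log-ratio differences.  Zeros are
    handled first: ``half_min`` replaces them by half the smallest positive
    value across the pair; ``none`` requires strictly positive input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    if zero_rule == "half_min":
        x, y = _apply_zero_rule(x, y)
    elif zero_rule == "none":
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("nonpositive entries with zero_rule='none'")
    else:
        raise ValueError(f"unknown zero_rule {zero_rule!r}")
    lx, ly = np.log(x), np.log(y)
    clr_x = lx - lx.mean()
    clr_y = ly - ly.mean()
    return float(np.linalg.norm(clr_x - clr_y))


def abundance_errors(truth: CountMatrix, other: CountMatrix) -> pd.DataFrame:
    """Per-sample SMAPE and Aitchison distance on CPM-transformed columns."""
    t = cpm(truth).to_numpy()
    o = cpm(other).to_numpy()
    rows = []
    for j, s in enumerate(truth.samples):
        rows.append(
            {
                "sample": s,
                "smape": smape_per_sample(t[:, j], o[:, j]),
                "aitchison": aitchison_per_sample(t[:, j], o[:, j]),
            }
        )
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# Alpha diversity


def alpha_indices(M: CountMatrix) -> pd.DataFrame:
    """Observed richness, Shannon entropy and Pielou evenness per sample.

    Pielou's J is the log of the order-1 Hill number (i.e. Shannon entropy H)
    over the log of the observed richness; it is undefined (NaN) for samples
    with a single detected feature.
    """
    arr = M.to_numpy()
    if (arr.sum(axis=0) <= 0).any():
        raise ValueError("alpha indices require positive column sums")
    rows = []
    for j, s in enumerate(M.samples):
        col = arr[:, j]
        s_obs = int(np.count_nonzero(col > 0))
        p = col[col > 0] / col.sum()
        H = float(-(p * np.log(p)).sum())
        J = H / np.log(s_obs) if s_obs > 1 else float("nan")
        rows.append({"sample": s, "richness": s_obs, "shannon": H, "pielou": J})
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# Rank tests, BH, effect sizes

#: Cohen's d magnitude cut-offs (lower bound on |d| → label)
MAGNITUDE_CUTOFFS = [
    (2.0, "Huge"),
    (1.2, "Very large"),
    (0.8, "Large"),
    (0.5, "Medium"),
    (0.2, "Small"),
    (0.01, "Very small"),
    (0.0, "Negligible"),
]


def magnitude_label(d: float) -> str:
    """Map |d| to its conventional magnitude label."""
    ad = abs(d)
    for cut, label in MAGNITUDE_CUTOFFS:
        if ad >= cut:
            return label
    return "Negligible"


def cohens_d(sample1, sample2) -> float:
    """Standardized mean difference with pooled standard deviation."""
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    s2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    diff = a.mean() - b.mean()
    if s2 == 0:
        return 0.0 if diff == 0 else float(np.sign(diff)) * float("inf")
    return float(diff / np.sqrt(s2))


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class TestResult:
    """Outcome of one paired improvement test."""

    statistic: float
    p_value: float
    p_adjusted: float
    cohens_d: float
    magnitude: str


def _paired_one_sided_less(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """One-sided paired rank test of H1: x tends to be smaller than y.

    Implemented as a Wilcoxon signed-rank test on the paired differences;
    degenerate all-tied inputs return p = 1.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.allclose(d, 0):
        return 0.0, 1.0
    res = sstats.wilcoxon(d, alternative="less", zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)


def alpha_error_tests(
    truth: CountMatrix,
    raw: CountMatrix,
    processed_by_pipeline: dict[str, CountMatrix],
    indices: tuple[str, ...] = ("richness", "pielou"),
) -> pd.DataFrame:
    """Test whether each pipeline's alpha-index errors beat raw data's.

    Per sample, the relative error ``|idx_proc - idx_true| / idx_true`` is
    computed; each pipeline is compared with raw by a one-sided paired rank
    test (pipeline errors smaller), BH-corrected across pipelines within each
    index, with Cohen's d and its magnitude label.
    """
    a_true = alpha_indices(truth)
    a_raw = alpha_indices(raw)
    rows = []
    for index in indices:
        truth_vals = a_true[index].to_numpy()
        raw_err = _relative_error(a_raw[index].to_numpy(), truth_vals)
        pvals, records = [], []
        for key, proc in processed_by_pipeline.items():
            proc_err = _relative_error(alpha_indices(proc)[index].to_numpy(), truth_vals)
            stat, p = _paired_one_sided_less(proc_err, raw_err)
            d = cohens_d(proc_err, raw_err) if proc_err.size >= 2 else 0.0
            pvals.append(p)
            records.append((key, stat, p, d, float(np.nanmedian(proc_err))))
        adj = benjamini_hochberg(pvals)
        for (key, stat, p, d, med), pa in zip(records, adj):
            rows.append(
                {
                    "index": index,
                    "pipeline": key,
                    "median_rel_error": med,
                    "raw_median_rel_error": float(np.nanmedian(raw_err)),
                    "statistic": stat,
                    "p_value": p,
                    "p_adjusted": pa,
                    "cohens_d": d,
                    "magnitude": magnitude_label(d),
                }
            )
    return pd.DataFrame(rows)


def _relative_error(values: np.ndarray, truth: np.ndarray) -> np.ndarray:
    out = np.full(values.shape, np.nan)
    mask = (truth != 0) & np.isfinite(values) & np.isfinite(truth)
    out[mask] = np.abs(values[mask] - truth[mask]) / np.abs(truth[mask])
    return out


def alpha_group_comparisons(
    M: CountMatrix,
    groups: pd.Series | None = None,
    alpha_level: float = 0.05,
    indices: tuple[str, ...] = ("richness", "pielou"),
) -> pd.DataFrame:
    """Directional group–group comparisons of alpha indices.

    For every ordered group pair and index, one-sided Mann–Whitney tests in
    both directions are BH-corrected within the index; the label is ``up``
    (first group larger), ``down`` or ``ns``.
    """
    groups = M.groups if groups is None else groups.reindex(M.samples)
    if groups is None:
        raise ValueError("group labels required")
    a = alpha_indices(M)
    ordered = list(dict.fromkeys(groups))
    pairs = [(g1, g2) for i, g1 in enumerate(ordered) for g2 in ordered[i + 1 :]]
    rows = []
    for index in indices:
        raw_p = []
        for g1, g2 in pairs:
            x = a.loc[groups.to_numpy() == g1, index].dropna().to_numpy()
            y = a.loc[groups.to_numpy() == g2, index].dropna().to_numpy()
            p_up = _mwu_p(x, y, "greater")
            p_down = _mwu_p(x, y, "less")
            raw_p.append((p_up, p_down))
        adj = benjamini_hochberg([p for pair in raw_p for p in pair]).reshape(-1, 2)
        for (g1, g2), (pu, pdn) in zip(pairs, adj):
            if pu < alpha_level:
                label = "up"
            elif pdn < alpha_level:
                label = "down"
            else:
                label = "ns"
            rows.append(
                {
                    "index": index,
                    "group_a": g1,
                    "group_b": g2,
                    "p_up": pu,
                    "p_down": pdn,
                    "label": label,
                }
            )
    return pd.DataFrame(rows)


def _mwu_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    if x.size == 0 or y.size == 0:
        return 1.0
    pooled = np.concatenate([x, y])
    if np.allclose(pooled, pooled[0]):
        return 1.0
    return float(sstats.mannwhitneyu(x, y, alternative=alternative).pvalue)


def comparison_disagreement(labels_a: pd.DataFrame, labels_b: pd.DataFrame) -> float:
    """Percentage of group-pair labels on which two comparison tables differ."""
    merged = labels_a.merge(
        labels_b, on=["index", "group_a", "group_b"], suffixes=("_a", "_b")
    )
    if merged.empty:
        raise ValueError("no shared comparisons")
    return 100.0 * float((merged["label_a"] != merged["label_b"]).mean())


# ---------------------------------------------------------------------------
# Beta diversity


def whittaker_matrix(M: CountMatrix) -> pd.DataFrame:
    """Pairwise Whittaker beta diversity on presence/absence.

    ``beta_w(a, b) = S_ab / ((S_a + S_b) / 2)`` where ``S_ab`` is the number
    of features present in the union of the two samples.
    """
    pres = M.to_numpy() > 0
    n = pres.shape[1]
    out = np.ones((n, n))
    richness = pres.sum(axis=0)
    for a in range(n):
        for b in range(a + 1, n):
            union = np.count_nonzero(pres[:, a] | pres[:, b])
            denom = (richness[a] + richness[b]) / 2.0
            out[a, b] = out[b, a] = union / denom
    return pd.DataFrame(out, index=M.samples, columns=M.samples)


def bray_curtis_matrix(M: CountMatrix) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarity between sample columns."""
    arr = M.to_numpy().T
    if (arr.sum(axis=1) <= 0).any():
        raise ValueError("Bray–Curtis requires positive column sums")
    d = squareform(pdist(arr, metric="braycurtis"))
    return pd.DataFrame(d, index=M.samples, columns=M.samples)


def nmds_embed(
    dist_matrix, dims: int = 2, seed: int = 0, n_restarts: int = 4
) -> tuple[pd.DataFrame, float]:
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    Iterative stress minimization with isotonic regression (scikit-learn's
    SMACOF in non-metric mode), best of ``n_restarts`` random starts,
    deterministic given the seed.  Returns the coordinates and Kruskal's
    normalized stress-1.
    """
    if isinstance(dist_matrix, pd.DataFrame):
        labels = dist_matrix.index
        D = dist_matrix.to_numpy(dtype=float)
    else:
        D = np.asarray(dist_matrix, dtype=float)
        labels = pd.RangeIndex(D.shape[0])
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", FutureWarning)
        mds = MDS(
            n_components=dims,
            metric=False,
            dissimilarity="precomputed",
            random_state=seed,
            n_init=n_restarts,
            normalized_stress=True,
            max_iter=500,
            eps=1e-9,
        )
        coords = mds.fit_transform(D)
    cols = [f"NMDS{i + 1}" for i in range(dims)]
    return pd.DataFrame(coords, index=labels, columns=cols), float(mds.stress_)


# ---------------------------------------------------------------------------
# Differential abundance


def da_features(
    M: CountMatrix,
    groups: pd.Series | None = None,
    alpha_level: float = 0.05,
) -> dict[tuple[str, str], set[str]]:
    """Differentially abundant features per condition pair.

    Per feature, a two-sided Mann–Whitney U test between the two groups;
    BH correction across features within the pair; features with adjusted
    p < ``alpha_level`` are returned.  Features all-zero in both groups are
    excluded from testing.
    """
    groups = M.groups if groups is None else groups.reindex(M.samples)
    if groups is None:
        raise ValueError("group labels required")
    arr = M.to_numpy()
    glabels = groups.to_numpy()
    ordered = list(dict.fromkeys(glabels))
    for g in ordered:
        if (glabels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    out: dict[tuple[str, str], set[str]] = {}
    for i, g1 in enumerate(ordered):
        for g2 in ordered[i + 1 :]:
            cols1 = glabels == g1
            cols2 = glabels == g2
            sub1, sub2 = arr[:, cols1], arr[:, cols2]
            testable = ~((sub1 == 0).all(axis=1) & (sub2 == 0).all(axis=1))
            idx = np.flatnonzero(testable)
            pvals = np.array([_mwu_p_two_sided(sub1[i_], sub2[i_]) for i_ in idx])
            hits: set[str] = set()
            if pvals.size:
                adj = benjamini_hochberg(pvals)
                hits = {str(M.features[i_]) for i_, pa in zip(idx, adj) if pa < alpha_level}
            out[(g1, g2)] = hits
    return out


def _mwu_p_two_sided(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    if np.allclose(pooled, pooled[0]):
        return 1.0
    return float(sstats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def jaccard(A, B) -> float:
    """Intersection-over-union of two sets; two empty sets count as 1."""
    A, B = set(A), set(B)
    union = A | B
    if not union:
        return 1.0
    return len(A & B) / len(union)


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class EvalReport:
    """Tidy per-metric tables plus a JSON-able summary."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(outdir / f"{name}.tsv", sep="\t")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, outdir: str | Path) -> "EvalReport":
        outdir = Path(outdir)
        tables = {
            p.stem: pd.read_csv(p, sep="\t", index_col=0)
            for p in sorted(outdir.glob("*.tsv"))
        }
        with open(outdir / "summary.json") as fh:
            summary = json.load(fh)
        return cls(tables=tables, summary=summary)


def evaluate_all(
    truth: CountMatrix,
    raw: CountMatrix,
    processed_by_pipeline: dict[str, CountMatrix],
    seed: int = 0,
    alpha_level: float = 0.05,
    with_beta: bool = True,
) -> EvalReport:
    """Run the full metric suite for every pipeline.

    Produces tidy tables: sparsity, zero-classification, abundance error
    (median per-sample SMAPE/Aitchison), alpha-index error tests, group-pair
    disagreement, beta-diversity summaries (matrix deviations from truth and
    NMDS stress) and differential-abundance Jaccard concordance.
    """
    report = EvalReport()
    truth_sp = total_sparsity(truth)
    raw_sp = total_sparsity(raw)

    # sparsity + zero classification
    rows = []
    for key, proc in processed_by_pipeline.items():
        conf = zero_confusion(truth, raw, proc)
        rows.append(
            {
                "pipeline": key,
                "sparsity": total_sparsity(proc),
                "truth_sparsity": truth_sp,
                "raw_sparsity": raw_sp,
                "tp": conf.tp,
                "fp": conf.fp,
                "fn": conf.fn,
                "tn": conf.tn,
                "sensitivity": conf.sensitivity,
                "specificity": conf.specificity,
            }
        )
    report.tables["sparsity_confusion"] = pd.DataFrame(rows).set_index("pipeline")

    # abundance-profile errors
    raw_err = abundance_errors(truth, raw)
    rows = []
    wil_p = {"smape": [], "aitchison": []}
    keys = list(processed_by_pipeline)
    per_pipe_err = {}
    for key in keys:
        err = abundance_errors(truth, processed_by_pipeline[key])
        per_pipe_err[key] = err
        entry = {"pipeline": key}
        for metric in ("smape", "aitchison"):
            stat, p = _paired_one_sided_less(
                err[metric].to_numpy(), raw_err[metric].to_numpy()
            )
            entry[f"median_{metric}"] = float(err[metric].median())
            entry[f"raw_median_{metric}"] = float(raw_err[metric].median())
            entry[f"{metric}_p_value"] = p
            entry[f"{metric}_cohens_d"] = cohens_d(
                err[metric].to_numpy(), raw_err[metric].to_numpy()
            )
            wil_p[metric].append(p)
        rows.append(entry)
    abundance = pd.DataFrame(rows).set_index("pipeline")
    for metric in ("smape", "aitchison"):
        abundance[f"{metric}_p_adjusted"] = benjamini_hochberg(wil_p[metric])
        abundance[f"{metric}_magnitude"] = [
            magnitude_label(d) for d in abundance[f"{metric}_cohens_d"]
        ]
    report.tables["abundance_error"] = abundance

    # alpha diversity
    report.tables["alpha_error_tests"] = alpha_error_tests(
        truth, raw, processed_by_pipeline
    )
    truth_labels = alpha_group_comparisons(truth, alpha_level=alpha_level)
    rows = []
    for key, proc in processed_by_pipeline.items():
        lab = alpha_group_comparisons(proc, alpha_level=alpha_level)
        rows.append(
            {
                "pipeline": key,
                "disagreement_pct": comparison_disagreement(lab, truth_labels),
            }
        )
    raw_lab = alpha_group_comparisons(raw, alpha_level=alpha_level)
    report.summary["raw_alpha_disagreement_pct"] = comparison_disagreement(
        raw_lab, truth_labels
    )
    report.tables["alpha_group_disagreement"] = pd.DataFrame(rows).set_index("pipeline")

    # beta diversity
    if with_beta:
        bc_truth = bray_curtis_matrix(truth)
        wh_truth = whittaker_matrix(truth)
        rows = []
        for key, proc in processed_by_pipeline.items():
            bc = bray_curtis_matrix(proc)
            wh = whittaker_matrix(proc)
            _, stress = nmds_embed(bc, seed=seed, n_restarts=2)
            rows.append(
                {
                    "pipeline": key,
                    "braycurtis_mad_vs_truth": float(
                        np.abs(bc.to_numpy() - bc_truth.to_numpy()).mean()
                    ),
                    "whittaker_mad_vs_truth": float(
                        np.abs(wh.to_numpy() - wh_truth.to_numpy()).mean()
                    ),
                    "nmds_stress": stress,
                }
            )
        report.tables["beta_diversity"] = pd.DataFrame(rows).set_index("pipeline")

    # differential abundance
    truth_da = da_features(truth, alpha_level=alpha_level)
    raw_da = da_features(raw, alpha_level=alpha_level)
    raw_jac = np.array([jaccard(truth_da[p], raw_da[p]) for p in truth_da])
    rows = []
    for key, proc in processed_by_pipeline.items():
        proc_da = da_features(proc, alpha_level=alpha_level)
        jac = np.array([jaccard(truth_da[p], proc_da[p]) for p in truth_da])
        # improvement = larger Jaccard, so test raw < pipeline
        stat, p = _paired_one_sided_less(raw_jac, jac)
        rows.append(
            {
                "pipeline": key,
                "median_jaccard": float(np.median(jac)),
                "raw_median_jaccard": float(np.median(raw_jac)),
                "p_value": p,
                "cohens_d": cohens_d(jac, raw_jac),
            }
        )
    da = pd.DataFrame(rows).set_index("pipeline")
    da["p_adjusted"] = benjamini_hochberg(da["p_value"].to_numpy())
    da["magnitude"] = [magnitude_label(d) for d in da["cohens_d"]]
    report.tables["da_concordance"] = da

    report.summary.update(
        {
            "truth_sparsity": truth_sp,
            "raw_sparsity": raw_sp,
            "n_pipelines": len(processed_by_pipeline),
            "raw_median_smape": float(raw_err["smape"].median()),
            "raw_median_aitchison": float(raw_err["aitchison"].median()),
            "raw_median_jaccard": float(np.median(raw_jac)),
            "seed": seed,
            "alpha_level": alpha_level,
        }
    )
    return report
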