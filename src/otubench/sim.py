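"""Synthetic 16S count-data generator with paired ground truth.

The simulator follows a two-step scheme.  Step one draws, for every sample,
pre-sequencing feature abundances from a gamma law whose mean is the
condition-specific intensity ``phi`` and whose squared coefficient of
variation is the feature variability ``v`` — this models biological
variability between replicates of a condition, and its output is the ground
truth.  Step two models the sequencing process as sampling *without
replacement*: the abundances are discretized into a finite community pool and
``N_j`` reads are drawn from it via a multivariate hypergeometric draw,
producing the raw integer count table.  Sampling can only lose features, so
raw sparsity is at least ground-truth sparsity; the gap is made of *technical*
zeros (present but unobserved species), while features with ``phi = 0`` are
*biological* (structural) zeros in both layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix

#: floor applied to the squared CV of features with positive intensity but
#: nonpositive declared variability; keeps the gamma draw well defined while
#: making it effectively deterministic at the mean.
VARIABILITY_FLOOR = 1e-6


@dataclass
class SimulationPreset:
    """Parameters of one simulated experiment.

    Parameters
    ----------
    condition_intensities
        Mapping condition id → vector ``phi`` of nonnegative mean relative
        intensities, one entry per feature.  Zeros mark species absent from
        that condition (structural zeros).
    variability
        Per-feature nonnegative dispersion ``v`` (the squared coefficient of
        variation of the gamma draw).
    replicates_per_condition
        Biological replicates simulated per condition (>= 2).
    depth_range
        ``(min, max)`` sequencing depth; each sample's depth is drawn
        uniformly on this integer range.
    pool_scale
        Size ``P`` of the discretized community pool sampled without
        replacement; defaults to ten times the maximum depth.
    seed
        Seed for all randomness of the run.
    feature_ids, condition_order
        Optional explicit identifiers; generated when omitted.
    """

    condition_intensities: dict[str, np.ndarray]
    variability: np.ndarray
    replicates_per_condition: int
    depth_range: tuple[int, int]
    pool_scale: int | None = None
    seed: int = 0
    feature_ids: list[str] | None = None
    condition_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.condition_intensities = {
            c: np.asarray(phi, dtype=float)
            for c, phi in self.condition_intensities.items()
        }
        self.variability = np.asarray(self.variability, dtype=float)
        if not self.condition_order:
            self.condition_order = list(self.condition_intensities)
        n_feat = {phi.size for phi in self.condition_intensities.values()}
        if len(n_feat) != 1:
            raise ValueError("condition intensity vectors differ in length")
        (self.n_features,) = n_feat
        if self.variability.size != self.n_features:
            raise ValueError("variability length does not match feature count")
        for c, phi in self.condition_intensities.items():
            if (phi < 0).any():
                raise ValueError(f"negative intensity in condition {c!r}")
            if not (phi > 0).any():
                raise ValueError(f"condition {c!r} has no present feature")
        if self.replicates_per_condition < 2:
            raise ValueError("replicates_per_condition must be >= 2")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ValueError("depth_range must satisfy 0 < min <= max")
        if self.pool_scale is None:
            self.pool_scale = 10 * int(hi)
        if self.pool_scale < hi:
            raise ValueError("pool_scale must be >= max depth")
        if self.feature_ids is None:
            width = len(str(self.n_features))
            self.feature_ids = [f"ASV{i + 1:0{width}d}" for i in range(self.n_features)]

    @property
    def n_samples(self) -> int:
        return len(self.condition_order) * self.replicates_per_condition

    def sample_ids(self) -> list[str]:
        return [
            f"{c}_r{r + 1}"
            for c in self.condition_order
            for r in range(self.replicates_per_condition)
        ]

    def sample_groups(self) -> pd.Series:
        return pd.Series(
            {
                f"{c}_r{r + 1}": c
                for c in self.condition_order
                for r in range(self.replicates_per_condition)
            }
        ).reindex(self.sample_ids())


@dataclass
class SimulatedDataset:
    """Paired ground-truth / raw output of one simulator run."""

    ground_truth: CountMatrix
    raw: CountMatrix
    depths: pd.Series
    structural_zero_mask: pd.DataFrame

    def technical_zero_mask(self) -> pd.DataFrame:
        """Entries present in the ground truth but lost by sequencing."""
        return (self.raw.values == 0) & ~self.structural_zero_mask


def gamma_abundances(preset: SimulationPreset, rng: np.random.Generator) -> np.ndarray:
    """Step one: per-replicate abundances from a gamma law.

    For feature ``i`` in condition ``c`` the draw has mean ``phi_i(c)`` and
    squared CV ``v_i`` (shape ``1/v_i``, scale ``phi_i * v_i``).  Features
    with ``phi_i(c) = 0`` are exactly zero in every replicate.
    """
    v = np.where(preset.variability > 0, preset.variability, VARIABILITY_FLOOR)
    cols = []
    for c in preset.condition_order:
        phi = preset.condition_intensities[c]
        shape = 1.0 / v
        for _ in range(preset.replicates_per_condition):
            draw = rng.gamma(shape=shape, scale=phi * v)
            draw[phi == 0] = 0.0
            cols.append(draw)
    return np.column_stack(cols)


def mhg_draw(
    pool_counts: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``depth`` reads without replacement from an integer pool.

    Implemented as sequential univariate hypergeometric conditioning, which
    is exact: category ``i`` is drawn against the remaining pool, and the
    remaining sample size is reduced accordingly.
    """
    pool = np.asarray(pool_counts, dtype=np.int64)
    if (pool < 0).any():
        raise ValueError("pool counts must be nonnegative")
    total = int(pool.sum())
    depth = int(depth)
    if depth > total:
        raise ValueError(
            f"requested depth {depth} exceeds pool total {total}; "
            "preset is inconsistent (increase pool_scale)"
        )
    out = np.zeros_like(pool)
    remaining_total = total
    remaining_draw = depth
    for i, ngood in enumerate(pool):
        if remaining_draw == 0:
            break
        nbad = remaining_total - ngood
        if nbad == 0:
            x = remaining_draw
        elif ngood == 0:
            x = 0
        else:
            x = int(rng.hypergeometric(ngood, nbad, remaining_draw))
        out[i] = x
        remaining_draw -= x
        remaining_total -= int(ngood)
    return out


def _largest_remainder_pool(abundances: np.ndarray, pool_total: int) -> np.ndarray:
    """Discretize a nonnegative vector into integers summing to ``pool_total``.

    Proportional shares are floored and the leftover units are assigned to the
    largest fractional remainders (ties broken by index).  Entries that are
    exactly zero never receive pool mass.
    """
    total = abundances.sum()
    if total <= 0:
        raise ValueError("all-zero abundance column")
    shares = abundances * (pool_total / total)
    base = np.floor(shares).astype(np.int64)
    leftover = pool_total - int(base.sum())
    if leftover > 0:
        remainders = shares - base
        remainders[abundances == 0] = -1.0  # structural zeros get nothing
        order = np.argsort(-remainders, kind="stable")
        base[order[:leftover]] += 1
    return base


def simulate_dataset(
    preset: SimulationPreset, seed: int | None = None
) -> SimulatedDataset:
    """Run the two-step simulator and return paired ground-truth/raw tables.

    Deterministic given the seed: depths and the step-one abundances use the
    dataset stream, while each sample's without-replacement draw uses a
    substream derived from ``seed + sample index``, so per-sample work is
    reproducible regardless of evaluation order.
    """
    seed = preset.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    abundances = gamma_abundances(preset, rng)
    sample_ids = preset.sample_ids()
    lo, hi = preset.depth_range
    depths = rng.integers(lo, hi + 1, size=len(sample_ids))

    raw = np.zeros_like(abundances, dtype=np.int64)
    for j in range(abundances.shape[1]):
        pool = _largest_remainder_pool(abundances[:, j], preset.pool_scale)
        sub_rng = np.random.default_rng(seed + j)
        raw[:, j] = mhg_draw(pool, int(depths[j]), sub_rng)

    groups = preset.sample_groups()
    truth_df = pd.DataFrame(abundances, index=preset.feature_ids, columns=sample_ids)
    raw_df = pd.DataFrame(raw, index=preset.feature_ids, columns=sample_ids)
    prov = {"simulator": "otubench.sim", "seed": seed}
    return SimulatedDataset(
        ground_truth=CountMatrix(truth_df, groups=groups, layer="ground_truth",
                                 provenance=dict(prov)),
        raw=CountMatrix(raw_df, groups=groups, layer="raw", provenance=dict(prov)),
        depths=pd.Series(depths, index=sample_ids, name="depth"),
        structural_zero_mask=truth_df == 0,
    )


# ---------------------------------------------------------------------------
# Preset construction


def random_preset(
    n_conditions: int,
    n_features: int,
    structural_zero_frac: float,
    variability: float | np.ndarray,
    depth_range: tuple[int, int],
    replicates_per_condition: int = 10,
    pool_scale: int | None = None,
    intensity_sigma: float = 1.5,
    effect_sigma: float = 0.4,
    seed: int = 0,
) -> SimulationPreset:
    """Build a preset with lognormal feature intensities and random structure.

    Each feature gets a base intensity from a lognormal law (``sigma``
    controls the skew of the community profile, i.e. how many rare species
    there are).  Per condition, features are independently absent with
    probability ``structural_zero_frac`` and present features get a mild
    condition-specific lognormal fold effect, which makes conditions
    genuinely differentially abundant.
    """
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=intensity_sigma, size=n_features)
    intensities: dict[str, np.ndarray] = {}
    for c in range(n_conditions):
        present = rng.random(n_features) >= structural_zero_frac
        if not present.any():
            present[np.argmax(base)] = True
        effect = rng.lognormal(mean=0.0, sigma=effect_sigma, size=n_features)
        intensities[f"G{c + 1}"] = np.where(present, base * effect, 0.0)
    v = np.broadcast_to(np.asarray(variability, dtype=float), (n_features,)).copy()
    return SimulationPreset(
        condition_intensities=intensities,
        variability=v,
        replicates_per_condition=replicates_per_condition,
        depth_range=depth_range,
        pool_scale=pool_scale,
        seed=seed,
    )


def builtin_presets() -> dict[str, SimulationPreset]:
    """Three reduced-scale presets mirroring the benchmark's scenario contrasts.

    * ``scenario1`` — moderate sparsity, low biological variability
      (target raw sparsity band 60–80%).
    * ``scenario2`` — low sparsity, high biological variability.
    * ``scenario3`` — high sparsity, high sequencing depth
      (target raw sparsity band 88–96%).

    All presets use 10 replicates per condition.
    """
    return {
        "scenario1": random_preset(
            n_conditions=8,
            n_features=300,
            structural_zero_frac=0.55,
            variability=0.25,
            depth_range=(5_000, 20_000),
            intensity_sigma=2.5,
            seed=101,
        ),
        "scenario2": random_preset(
            n_conditions=8,
            n_features=300,
            structural_zero_frac=0.40,
            variability=4.0,
            depth_range=(3_000, 10_000),
            seed=202,
        ),
        "scenario3": random_preset(
            n_conditions=8,
            n_features=400,
            structural_zero_frac=0.90,
            variability=1.0,
            depth_range=(30_000, 100_000),
            intensity_sigma=3.0,
            seed=303,
        ),
    }
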