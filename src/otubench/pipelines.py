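"""Enumeration and execution of the preprocessing pipelines.

With the default five normalization and five imputation methods the registry
holds exactly 35 pipelines: 5 normalization-only, 5 imputation-only and the
25 normalization→imputation combinations, in that order.  Execution order is
always normalization first, then imputation.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import pandas as pd

from . import imputation, normalization
from .containers import CountMatrix


@dataclass(frozen=True)
class PipelineSpec:
    """One preprocessing pipeline: optional normalization, optional imputation."""

    normalization: str | None
    imputation: str | None

    def __post_init__(self) -> None:
        if self.normalization is None and self.imputation is None:
            raise ValueError("a pipeline needs at least one stage")
        if (
            self.normalization is not None
            and self.normalization not in normalization.NORMALIZATION_IDS
        ):
            raise ValueError(f"unknown normalization id {self.normalization!r}")
        if (
            self.imputation is not None
            and self.imputation not in imputation.IMPUTATION_IDS
        ):
            raise ValueError(f"unknown imputation id {self.imputation!r}")

    @property
    def name(self) -> str:
        parts = []
        if self.normalization is not None:
            parts.append(normalization.NORMALIZATION_NAMES[self.normalization])
        if self.imputation is not None:
            parts.append(imputation.IMPUTATION_NAMES[self.imputation])
        return " + ".join(parts)

    @property
    def key(self) -> str:
        """Machine id, e.g. ``gmpr+scimpute``."""
        parts = [p for p in (self.normalization, self.imputation) if p is not None]
        return "+".join(parts)


def build_registry(
    norm_ids=normalization.NORMALIZATION_IDS,
    imp_ids=imputation.IMPUTATION_IDS,
) -> list[PipelineSpec]:
    """All normalization-only, imputation-only and combined pipelines."""
    norm_ids = list(norm_ids)
    imp_ids = list(imp_ids)
    if not norm_ids or not imp_ids:
        raise ValueError("both method id lists must be non-empty")
    for n in norm_ids:
        if n not in normalization.NORMALIZATION_IDS:
            raise ValueError(f"unknown normalization id {n!r}")
    for i in imp_ids:
        if i not in imputation.IMPUTATION_IDS:
            raise ValueError(f"unknown imputation id {i!r}")
    registry = [PipelineSpec(n, None) for n in norm_ids]
    registry += [PipelineSpec(None, i) for i in imp_ids]
    registry += [PipelineSpec(n, i) for n in norm_ids for i in imp_ids]
    return registry


def parse_pipeline(key: str) -> PipelineSpec:
    """Parse a machine id like ``"gmpr+scimpute"``, ``"tss"`` or ``"drimpute"``."""
    parts = [p.strip() for p in key.split("+") if p.strip()]
    norm = imp = None
    for p in parts:
        if p in normalization.NORMALIZATION_IDS:
            if norm is not None:
                raise ValueError(f"pipeline {key!r} names two normalizations")
            norm = p
        elif p in imputation.IMPUTATION_IDS:
            if imp is not None:
                raise ValueError(f"pipeline {key!r} names two imputations")
            imp = p
        else:
            raise ValueError(f"unknown method id {p!r} in pipeline {key!r}")
    return PipelineSpec(norm, imp)


def run_pipeline(
    raw: CountMatrix,
    spec: PipelineSpec,
    seed: int = 0,
    method_params: dict | None = None,
) -> CountMatrix:
    """Execute one pipeline on a raw count matrix.

    ``method_params`` maps a method id to its keyword overrides (e.g.
    ``{"llsimpute": {"k": 10}}``).  The output layer is ``processed`` and
    provenance records the pipeline, parameters, seed and wall time.
    """
    if raw.layer != "raw":
        raise ValueError(f"run_pipeline expects a raw-layer matrix, got {raw.layer!r}")
    method_params = method_params or {}
    t0 = time.perf_counter()
    current = raw
    try:
        if spec.normalization is not None:
            current = normalization.normalize(current, spec.normalization)
        if spec.imputation is not None:
            # imputers require a raw-or-processed matrix; keep group labels
            current = imputation.impute(
                current.with_values(current.values, layer=current.layer),
                spec.imputation,
                groups=raw.groups,
                seed=seed,
                **method_params.get(spec.imputation, {}),
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline {spec.name!r} failed: {exc}") from exc
    prov = {
        "pipeline": spec.key,
        "pipeline_name": spec.name,
        "seed": seed,
        "params": method_params,
        "wall_time_s": round(time.perf_counter() - t0, 6),
    }
    return current.with_values(current.values, layer="processed", provenance=prov)


def run_all(
    raw: CountMatrix,
    registry: list[PipelineSpec] | None = None,
    seed: int = 0,
    method_params: dict | None = None,
) -> dict[str, CountMatrix]:
    """Run every pipeline in the registry; returns key → processed matrix."""
    registry = build_registry() if registry is None else registry
    return {
        spec.key: run_pipeline(raw, spec, seed=seed, method_params=method_params)
        for spec in registry
    }
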