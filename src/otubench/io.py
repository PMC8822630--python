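"""Readers and writers for the benchmark's tabular formats.

Counts travel as dense TSV (features in rows, samples in columns, '.'
decimal, no quoting) or as MatrixMarket triplets with two companion id
files; metadata is a two-column TSV (sample_id, group).  Configuration is a
YAML document whose unknown keys are rejected (fail fast).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as scipy_io
from scipy import sparse

from .containers import CountMatrix
from .sim import SimulatedDataset, SimulationPreset

log = logging.getLogger("otubench")


def read_counts(path: str | Path, layer: str = "raw") -> CountMatrix:
    """Read a dense counts TSV (or a MatrixMarket ``.mtx`` triplet).

    For ``.mtx`` input, feature and sample ids are read from sibling files
    ``<stem>.features.txt`` and ``<stem>.samples.txt`` (one id per line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".mtx":
        mat = scipy_io.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        features = (path.parent / f"{path.stem}.features.txt").read_text().split()
        samples = (path.parent / f"{path.stem}.samples.txt").read_text().split()
        df = pd.DataFrame(np.asarray(mat), index=features, columns=samples)
    else:
        if path.stat().st_size == 0:
            raise ValueError(f"{path}: empty file")
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except pd.errors.ParserError as exc:
            raise ValueError(f"{path}: malformed TSV ({exc})") from exc
        if df.shape[1] == 0:
            raise ValueError(f"{path}: no sample columns")
        non_numeric = df.columns[
            [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
        ]
        if len(non_numeric):
            raise ValueError(f"{path}: non-numeric entries in columns {list(non_numeric)}")
    arr = df.to_numpy(dtype=float)
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"{path}: negative value at feature {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return CountMatrix(df, layer=layer)


def write_counts(cm: CountMatrix, path: str | Path, sparse_fmt: bool = False) -> None:
    """Write a count matrix as dense TSV or MatrixMarket triplet."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if sparse_fmt or path.suffix == ".mtx":
        scipy_io.mmwrite(path, sparse.coo_matrix(cm.to_numpy()))
        (path.parent / f"{path.stem}.features.txt").write_text(
            "\n".join(map(str, cm.features)) + "\n"
        )
        (path.parent / f"{path.stem}.samples.txt").write_text(
            "\n".join(map(str, cm.samples)) + "\n"
        )
    else:
        cm.values.to_csv(path, sep="\t", float_format=None)


def read_metadata(path: str | Path, samples: pd.Index | None = None) -> pd.Series:
    """Read the sample→group TSV; optionally validate against a sample index."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, group)")
    sid, grp = df.columns[:2]
    if df[sid].duplicated().any():
        dupes = df[sid][df[sid].duplicated()].tolist()
        raise ValueError(f"{path}: duplicated sample ids {dupes}")
    mapping = pd.Series(df[grp].to_numpy(), index=df[sid].to_numpy(), name="group")
    if samples is not None:
        missing = samples.difference(mapping.index)
        extra = mapping.index.difference(samples)
        if len(missing) or len(extra):
            raise ValueError(
                f"{path}: metadata does not match counts "
                f"(missing: {list(missing)}, extra: {list(extra)})"
            )
        mapping = mapping.reindex(samples)
    return mapping


def write_metadata(groups: pd.Series, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"sample_id": groups.index, "group": groups.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write a simulated dataset: two counts layers, metadata and depths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(dataset.ground_truth, outdir / "ground_truth.tsv")
    write_counts(dataset.raw, outdir / "raw.tsv")
    write_metadata(dataset.raw.groups, outdir / "metadata.tsv")
    dataset.depths.rename_axis("sample_id").to_frame().to_csv(
        outdir / "depths.tsv", sep="\t"
    )


def read_dataset(outdir: str | Path) -> SimulatedDataset:
    """Read back a dataset written by :func:`write_dataset`."""
    outdir = Path(outdir)
    truth = read_counts(outdir / "ground_truth.tsv", layer="ground_truth")
    raw = read_counts(outdir / "raw.tsv", layer="raw")
    groups = read_metadata(outdir / "metadata.tsv", samples=raw.samples)
    truth.groups = groups.copy()
    raw.groups = groups.copy()
    depths = pd.read_csv(outdir / "depths.tsv", sep="\t", index_col=0)["depth"]
    return SimulatedDataset(
        ground_truth=truth,
        raw=raw,
        depths=depths,
        structural_zero_mask=truth.values == 0,
    )


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class BenchmarkConfig:
    """One benchmark run: preset, method sets, parameters, seed, output."""

    preset: str | SimulationPreset
    seed: int
    outdir: str
    normalization_ids: list[str] = field(default_factory=lambda: list(
        ("tss", "css", "tmm", "deseq", "gmpr")))
    imputation_ids: list[str] = field(default_factory=lambda: list(
        ("llsimpute", "zcomp_sq", "zcomp_czm", "scimpute", "drimpute")))
    method_params: dict = field(default_factory=dict)
    alpha_level: float = 0.05
    with_beta: bool = True


_CONFIG_KEYS = {
    "preset", "seed", "outdir", "normalization_ids", "imputation_ids",
    "method_params", "alpha_level", "with_beta",
}


def read_config(path: str | Path) -> BenchmarkConfig:
    """Parse a YAML benchmark config; unknown keys are errors."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for req in ("preset", "seed", "outdir"):
        if req not in data:
            raise ValueError(f"{path}: missing required key {req!r}")
    if isinstance(data["preset"], dict):
        # inline preset: keyword arguments of sim.random_preset
        from .sim import random_preset

        spec = dict(data["preset"])
        spec["depth_range"] = tuple(spec.get("depth_range", (5_000, 20_000)))
        data = dict(data, preset=random_preset(**spec))
    return BenchmarkConfig(**data)


def setup_logging(verbose: bool = False, logfile: str | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )
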