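"""In-memory containers shared by all stages of the benchmark.

The central object is :class:`CountMatrix`, a thin wrapper around a
feature-by-sample :class:`pandas.DataFrame` carrying sample→group labels and a
layer tag saying where in the workflow the matrix sits (``ground_truth``,
``raw`` or ``processed``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

LAYERS = ("ground_truth", "raw", "processed")


@dataclass
class CountMatrix:
    """A feature×sample nonnegative matrix with identifiers and group labels.

    Parameters
    ----------
    values
        DataFrame with feature ids as index and sample ids as columns.
        Entries must be nonnegative and finite.
    groups
        Optional mapping sample id → experimental condition.  When present it
        must cover exactly the matrix's samples.
    layer
        One of ``ground_truth``, ``raw``, ``processed``.
    provenance
        Free-form record of how the matrix was produced (method ids,
        parameters, seed).  Propagated, never interpreted.
    """

    values: pd.DataFrame
    groups: pd.Series | None = None
    layer: str = "raw"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        arr = self.values.to_numpy()
        if arr.size == 0:
            raise ValueError("empty count matrix")
        if not np.all(np.isfinite(arr)):
            raise ValueError("count matrix contains non-finite entries")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative entry at feature {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        if self.values.index.has_duplicates:
            raise ValueError("duplicated feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicated sample ids")
        if self.groups is not None:
            if not isinstance(self.groups, pd.Series):
                self.groups = pd.Series(dict(self.groups))
            missing = self.values.columns.difference(self.groups.index)
            extra = self.groups.index.difference(self.values.columns)
            if len(missing) or len(extra):
                raise ValueError(
                    f"group labels do not match samples "
                    f"(missing: {list(missing)}, extra: {list(extra)})"
                )
            self.groups = self.groups.reindex(self.values.columns)

    # -- convenience accessors -------------------------------------------------

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def with_values(
        self,
        values: np.ndarray | pd.DataFrame,
        layer: str | None = None,
        provenance: Mapping | None = None,
    ) -> "CountMatrix":
        """Return a copy carrying new values (ids and groups preserved)."""
        if isinstance(values, np.ndarray):
            values = pd.DataFrame(
                values, index=self.values.index, columns=self.values.columns
            )
        prov = dict(self.provenance)
        if provenance:
            prov.update(provenance)
        return CountMatrix(
            values=values,
            groups=None if self.groups is None else self.groups.copy(),
            layer=self.layer if layer is None else layer,
            provenance=prov,
        )

    def sparsity(self) -> float:
        """Percentage of zero entries (0–100)."""
        arr = self.to_numpy()
        return 100.0 * float(np.count_nonzero(arr == 0)) / arr.size
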