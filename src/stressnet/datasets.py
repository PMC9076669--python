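"""Core in-memory containers.

Two containers flow through the pipeline:

* :class:`CountMatrix` — a gene x sample matrix of raw RNA-seq counts with a
  per-sample binary condition label (0 = non-stress, 1 = stress) and an
  optional study id, the input to differential-expression selection.
* :class:`DiscreteDataset` — a variable x sample table of small integer state
  codes (three expression levels per gene plus, optionally, the binary
  condition variable), the input to Bayesian-network structure learning.

Both are thin, validated wrappers around pandas objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

CONDITION_VAR = "condition"


@dataclass
class CountMatrix:
    """Gene x sample nonnegative integer counts with per-sample condition labels.

    Parameters
    ----------
    counts : DataFrame
        Genes as rows, samples as columns; nonnegative integers.
    condition : Series
        Binary (0/1) label per sample, indexed by sample id, aligned with
        the columns of ``counts``.
    study : Series, optional
        Study id per sample (for multi-study inputs).
    """

    counts: pd.DataFrame
    condition: pd.Series
    study: pd.Series | None = None

    def __post_init__(self):
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids: {dups}")
        vals = c.to_numpy()
        if vals.size and (not np.issubdtype(vals.dtype, np.number)):
            raise DataError("counts must be numeric")
        if vals.size and ((vals < 0).any() or np.any(vals != np.floor(vals))):
            raise DataError("counts must be nonnegative integers")
        self.condition = self.condition.reindex(c.columns)
        if self.condition.isna().any():
            missing = self.condition.index[self.condition.isna()].tolist()
            raise DataError(f"samples without condition label: {missing}")
        if not set(np.unique(self.condition.to_numpy())) <= {0, 1}:
            raise DataError("condition labels must be binary 0/1")
        if self.study is not None:
            self.study = self.study.reindex(c.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, genes) -> "CountMatrix":
        missing = [g for g in genes if g not in self.counts.index]
        if missing:
            raise DataError(f"genes not present: {missing}")
        return CountMatrix(self.counts.loc[list(genes)], self.condition, self.study)


@dataclass
class DiscreteDataset:
    """Variables x samples categorical data for structure learning.

    ``data`` holds integer state codes (variable rows, sample columns);
    ``arities`` the per-variable number of states; ``labels`` the ordered
    state labels per variable; ``cutpoints`` the quantile cutpoints used
    during discretization (empty for variables that were born discrete).
    """

    data: pd.DataFrame
    arities: dict[str, int]
    labels: dict[str, list[str]]
    cutpoints: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise DataError("duplicate variable names")
        if self.data.columns.has_duplicates:
            raise DataError("duplicate sample ids")
        for v in self.data.index:
            if v not in self.arities:
                raise DataError(f"variable '{v}' missing an arity")
            r = self.arities[v]
            if r < 2:
                raise DataError(f"variable '{v}' has arity {r} < 2")
            col = self.data.loc[v].to_numpy()
            if col.size and (col.min() < 0 or col.max() >= r):
                raise DataError(f"variable '{v}' has codes outside [0, {r})")

    @property
    def variables(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def codes(self) -> np.ndarray:
        """Variable x sample integer array (C-contiguous, small ints)."""
        return np.ascontiguousarray(self.data.to_numpy(dtype=np.int64))

    def drop_variable(self, name: str) -> "DiscreteDataset":
        if name not in self.data.index:
            raise DataError(f"variable '{name}' not in dataset")
        return DiscreteDataset(
            self.data.drop(index=name),
            {k: v for k, v in self.arities.items() if k != name},
            {k: v for k, v in self.labels.items() if k != name},
            {k: v for k, v in self.cutpoints.items() if k != name},
        )
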