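"""Quantile discretization of expression values into ordinal categories.

Each gene's expression vector — pooled across all samples of all studies —
is cut at its empirical k/n_bins quantiles (linear-interpolation, "type 7")
into ``n_bins`` ordered categories (low / medium / high for the default 3).
Intervals are closed on the right at each cutpoint: a value equal to a
cutpoint falls in the lower bin. The binary condition variable is appended
afterwards, untouched by discretization.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datasets import CONDITION_VAR, DiscreteDataset
from .errors import ConfigError, DataError

log = logging.getLogger(__name__)

_TERTILE_LABELS = ["low", "medium", "high"]


def _bin_labels(n_bins: int) -> list[str]:
    if n_bins == 3:
        return list(_TERTILE_LABELS)
    return [f"bin{i}" for i in range(n_bins)]


def discretize_quantile(values, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Cut a real vector at its k/n_bins quantiles into ordinal codes.

    Returns ``(codes, cutpoints)``. Value v gets the largest bin b with
    v > cutpoints[b-1]; v <= cutpoints[0] goes to bin 0 (ties at a cutpoint
    go to the lower bin). Warns when the number of distinct values is below
    ``n_bins`` (degenerate, possibly empty, bins).
    """
    v = np.asarray(values, dtype=float)
    if n_bins < 2:
        raise ConfigError("n_bins must be >= 2")
    if v.size < n_bins:
        raise ConfigError("need at least n_bins values")
    n_distinct = len(np.unique(v))
    if n_distinct < n_bins:
        warnings.warn(
            f"only {n_distinct} distinct values for {n_bins} bins; "
            "some bins will be degenerate",
            UserWarning,
            stacklevel=2,
        )
    cuts = np.quantile(v, np.arange(1, n_bins) / n_bins, method="linear")
    codes = np.searchsorted(cuts, v, side="left")
    return codes.astype(np.int64), cuts


def build_discrete_dataset(matrices, genes, n_bins: int = 3) -> DiscreteDataset:
    """Discretize selected genes over the pooled samples of one or more studies.

    Parameters
    ----------
    matrices : DataFrame or list of DataFrames
        Gene x sample real-valued expression (e.g. log-CPM), one per study.
        Sample ids must be disjoint across studies.
    genes : ordered list of gene names to keep (must be present everywhere).
    n_bins : number of expression categories.
    """
    if isinstance(matrices, pd.DataFrame):
        matrices = [matrices]
    for m in matrices:
        for g in genes:
            if g not in m.index:
                raise DataError(f"gene '{g}' missing from an input study")
    pooled = pd.concat([m.loc[list(genes)] for m in matrices], axis=1)
    if pooled.columns.has_duplicates:
        dups = pooled.columns[pooled.columns.duplicated()].unique().tolist()
        raise DataError(f"sample ids shared across studies: {dups}")
    codes = np.empty((len(genes), pooled.shape[1]), dtype=np.int64)
    cutpoints: dict[str, list[float]] = {}
    for i, g in enumerate(genes):
        c, cuts = discretize_quantile(pooled.loc[g].to_numpy(), n_bins)
        ties = np.isin(pooled.loc[g].to_numpy(), cuts).sum()
        if ties:
            log.info("gene %s: %d values tie with a cutpoint (sent to lower bin)", g, ties)
        codes[i] = c
        cutpoints[g] = [float(x) for x in cuts]
    labels = _bin_labels(n_bins)
    return DiscreteDataset(
        data=pd.DataFrame(codes, index=list(genes), columns=pooled.columns),
        arities={g: n_bins for g in genes},
        labels={g: list(labels) for g in genes},
        cutpoints=cutpoints,
    )


def append_condition(ds: DiscreteDataset, labels) -> DiscreteDataset:
    """Append the binary condition variable (0 non-stress, 1 stress)."""
    lab = np.asarray(labels)
    if lab.shape[0] != ds.n_samples:
        raise DataError(
            f"condition length {lab.shape[0]} != sample count {ds.n_samples}"
        )
    if not set(np.unique(lab)) <= {0, 1}:
        raise DataError("condition labels must be binary 0/1")
    if CONDITION_VAR in ds.data.index:
        raise DataError("dataset already has a condition variable")
    data = pd.concat(
        [ds.data, pd.DataFrame([lab.astype(np.int64)], index=[CONDITION_VAR],
                               columns=ds.data.columns)]
    )
    return DiscreteDataset(
        data=data,
        arities={**ds.arities, CONDITION_VAR: 2},
        labels={**ds.labels, CONDITION_VAR: ["0", "1"]},
        cutpoints=dict(ds.cutpoints),
    )


class QuantileDiscretizer(TransformerMixin, BaseEstimator):
    """Per-feature quantile discretizer (samples x features orientation).

    ``fit`` learns cutpoints at the k/n_bins empirical quantiles of each
    column; ``transform`` maps values to ordinal codes with right-closed
    intervals at each cutpoint. ``fit_transform`` on the pooled data is the
    pipeline's discretization step.

    Attributes
    ----------
    cutpoints_ : array of shape (n_features, n_bins - 1).
    """

    def __init__(self, n_bins: int = 3):
        self.n_bins = n_bins

    def fit(self, X, y=None):
        X = self._as_array(X)
        cuts = []
        for j in range(X.shape[1]):
            _, c = discretize_quantile(X[:, j], self.n_bins)
            cuts.append(c)
        self.cutpoints_ = np.vstack(cuts)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "cutpoints_")
        was_df = isinstance(X, pd.DataFrame)
        idx = X.index if was_df else None
        cols = X.columns if was_df else None
        X = self._as_array(X)
        out = np.empty(X.shape, dtype=np.int64)
        for j in range(X.shape[1]):
            out[:, j] = np.searchsorted(self.cutpoints_[j], X[:, j], side="left")
        if was_df:
            return pd.DataFrame(out, index=idx, columns=cols)
        return out

    @staticmethod
    def _as_array(X):
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float)
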