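"""Differential-expression gene selection and cross-study intersection.

Per study: filter low-count genes, log-CPM transform, fit a two-group linear
model per gene, shrink the residual variances with an empirical-Bayes prior
(moderated t-statistics in the limma style), adjust p-values by
Benjamini-Hochberg, and keep genes below a significance cutoff. The two
studies' gene lists are then intersected, so only genes responsive in both
experiments survive.

The empirical-Bayes step moment-matches the per-gene residual variances
``s_g^2`` (on ``d = n - 2`` degrees of freedom) to a scaled-F model with
prior degrees of freedom ``d0`` and prior variance ``s0^2``; the posterior
variance is ``(d0*s0^2 + d*s_g^2) / (d0 + d)`` and the moderated t uses
``d + d0`` degrees of freedom.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import norm, t as t_dist
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .datasets import CountMatrix
from .errors import ConfigError, DataError

log = logging.getLogger(__name__)


def filter_low_counts(cm: CountMatrix, min_cpm: float, min_samples: int) -> CountMatrix:
    """Keep genes with CPM > ``min_cpm`` in at least ``min_samples`` samples.

    Library sizes are the column sums of the input matrix. The sample set is
    unchanged; the result may have zero genes.
    """
    if min_samples > len(cm.samples):
        raise ConfigError("min_samples exceeds the number of samples")
    lib = cm.library_sizes.to_numpy(dtype=float)
    if (lib == 0).any():
        raise DataError("sample with zero library size")
    cpm = cm.counts.to_numpy(dtype=float) / lib * 1e6
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    return CountMatrix(cm.counts.loc[keep], cm.condition, cm.study)


def log_cpm(cm: CountMatrix, prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a prior count to damp zeros.

    Entry = log2((count + prior) / (library_size + 2*prior) * 1e6).
    """
    if prior_count < 0:
        raise ConfigError("prior_count must be >= 0")
    lib = cm.library_sizes.to_numpy(dtype=float)
    if (lib == 0).any():
        zeros = [s for s, v in zip(cm.samples, lib) if v == 0]
        raise DataError(f"zero library size in samples: {zeros}")
    vals = (cm.counts.to_numpy(dtype=float) + prior_count) / (
        lib + 2.0 * prior_count
    ) * 1e6
    with np.errstate(divide="ignore"):
        out = np.log2(vals)
    return pd.DataFrame(out, index=cm.counts.index, columns=cm.counts.columns)


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve polygamma(1, x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return np.inf
    # Smyth's starting value: trigamma(x) ~ 1/x for large x, ~1/x^2 for small.
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def _fit_f_dist_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-match log residual variances to a scaled F prior (d0, s0^2)."""
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        log.warning("too few positive residual variances; using complete shrinkage")
        m = float(np.log(s2[ok]).mean()) if ok.any() else 0.0
        return np.inf, float(np.exp(m))
    z = np.log(s2[ok])
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    target = evar - float(polygamma(1, d / 2.0))
    if target <= 0:
        # variances are under-dispersed relative to chi-square: infinite prior df
        log.info("moment system has no finite solution; d0 set to +inf")
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(target)
    s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def fit_moderated_t(
    logmat: pd.DataFrame,
    condition,
    d0: float | None = None,
    s0_squared: float | None = None,
) -> pd.DataFrame:
    """Per-gene two-group moderated t-statistics.

    Parameters
    ----------
    logmat : DataFrame
        Genes x samples log-expression.
    condition : sequence of 0/1
        Group label per sample (aligned with columns).
    d0, s0_squared : optional
        Override the empirical-Bayes prior; ``d0=0`` gives the ordinary
        pooled-variance two-sample t.

    Returns
    -------
    DataFrame indexed by gene with columns ``log2fc`` (group 1 minus group
    0), ``s2``, ``s2_post``, ``t``, ``pvalue``, ``adj_pvalue``, and the
    fitted prior in ``attrs`` (``d0``, ``s0_squared``).
    """
    cond = np.asarray(condition)
    if cond.shape[0] != logmat.shape[1]:
        raise DataError("condition length does not match sample count")
    g0 = cond == 0
    g1 = cond == 1
    n0, n1 = int(g0.sum()), int(g1.sum())
    if n0 < 2 or n1 < 2:
        raise DataError("each condition group needs >= 2 samples")
    x = logmat.to_numpy(dtype=float)
    m0 = x[:, g0].mean(axis=1)
    m1 = x[:, g1].mean(axis=1)
    beta = m1 - m0
    rss = ((x[:, g0] - m0[:, None]) ** 2).sum(axis=1) + (
        (x[:, g1] - m1[:, None]) ** 2
    ).sum(axis=1)
    d = n0 + n1 - 2
    s2 = rss / d
    if d0 is None:
        d0, s0_squared = _fit_f_dist_prior(s2, d)
    elif s0_squared is None:
        s0_squared = 0.0 if d0 == 0 else float(np.exp(np.log(s2[s2 > 0]).mean()))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_squared)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_squared + d * s2) / (d0 + d)
        df_total = d + d0
    se = np.sqrt(s2_post * (1.0 / n0 + 1.0 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.where(beta == 0, 0.0, np.inf * np.sign(beta)))
    if np.isinf(df_total):
        pvals = 2.0 * norm.sf(np.abs(tstat))
    else:
        pvals = 2.0 * t_dist.sf(np.abs(tstat), df_total)
    stats = pd.DataFrame(
        {
            "log2fc": beta,
            "s2": s2,
            "s2_post": s2_post,
            "t": tstat,
            "pvalue": pvals,
            "adj_pvalue": adjust_bh(list(pvals)),
        },
        index=logmat.index,
    )
    stats.attrs["d0"] = float(d0)
    stats.attrs["s0_squared"] = float(s0_squared)
    stats.attrs["df_residual"] = float(d)
    return stats


def adjust_bh(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DataError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def top_genes(stats: pd.DataFrame, alpha: float = 0.05, max_n: int | None = None) -> list[str]:
    """Genes with BH-adjusted p <= alpha, ordered by ascending raw p."""
    if stats.empty:
        raise DataError("empty gene statistics")
    hits = stats[stats["adj_pvalue"] <= alpha]
    hits = hits.sort_values("pvalue", kind="stable")
    out = list(hits.index)
    if max_n is not None:
        out = out[:max_n]
    return out


def intersect_gene_lists(list_a, list_b) -> list[str]:
    """Set intersection, ordered by the first list's order."""
    in_b = set(list_b)
    return [g for g in list_a if g in in_b]


class ModeratedTSelector(BaseEstimator):
    """Empirical-Bayes differential-expression gene selector.

    A scikit-learn style feature selector: ``fit(X, y)`` with ``X`` a
    samples x genes count matrix (DataFrame or array) and ``y`` the binary
    condition, then ``transform(X)`` keeps only the selected genes.

    Parameters
    ----------
    min_cpm, min_samples : low-count filter (CPM > min_cpm in >= min_samples
        samples).
    prior_count : pseudo-count for the log-CPM transform.
    alpha : BH-adjusted significance cutoff.
    max_n : optional cap on the number of selected genes.

    Attributes
    ----------
    stats_ : per-gene statistics table (post-filter genes).
    selected_genes_ : ordered list of selected gene names.
    support_ : boolean mask over the input genes.
    d0_, s0_squared_ : fitted empirical-Bayes prior.
    """

    def __init__(self, min_cpm=0.5, min_samples=2, prior_count=0.5, alpha=0.05, max_n=None):
        self.min_cpm = min_cpm
        self.min_samples = min_samples
        self.prior_count = prior_count
        self.alpha = alpha
        self.max_n = max_n

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            genes = list(X.columns)
            counts = X.to_numpy().T
            samples = list(X.index)
        else:
            X = np.asarray(X)
            genes = [f"g{i}" for i in range(X.shape[1])]
            counts = X.T
            samples = [f"s{i}" for i in range(X.shape[0])]
        cm = CountMatrix(
            pd.DataFrame(counts, index=genes, columns=samples),
            pd.Series(np.asarray(y), index=samples),
        )
        filtered = filter_low_counts(cm, self.min_cpm, self.min_samples)
        logmat = log_cpm(filtered, self.prior_count)
        self.stats_ = fit_moderated_t(logmat, filtered.condition.to_numpy())
        self.d0_ = self.stats_.attrs["d0"]
        self.s0_squared_ = self.stats_.attrs["s0_squared"]
        self.selected_genes_ = top_genes(self.stats_, self.alpha, self.max_n)
        sel = set(self.selected_genes_)
        self.feature_names_in_ = np.asarray(genes, dtype=object)
        self.support_ = np.array([g in sel for g in genes])
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_
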