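"""Between-library normalization and expression filtering.

Implements trimmed-mean-of-M-values (TMM) normalization factors,
effective library sizes, counts-per-million (CPM) and the low-expression
filter used ahead of model fitting.

The central object is :class:`TMMNormalizer`, a scikit-learn style
transformer whose samples are sequencing libraries and whose features are
genes (``X`` has shape ``(n_libraries, n_genes)``).  The module-level
functions :func:`tmm_factors`, :func:`cpm` and
:func:`filter_low_expression` are thin wrappers operating on the
genes x libraries ``DataFrame`` convention used by the file formats.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "TMMNormalizer",
    "tmm_factors",
    "cpm",
    "filter_low_expression",
    "validate_counts",
]


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate a genes x libraries count matrix.

    Requires non-negative integer-valued entries, unique gene and library
    identifiers and at least one library with a positive total.
    """
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate gene identifier: {dup!r}")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()][0]
        raise ValueError(f"duplicate library identifier: {dup!r}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("count matrix must be numeric")
    if (values < 0).any():
        g, k = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at gene {counts.index[g]!r}, library {counts.columns[k]!r}"
        )
    if np.any(values != np.floor(values)):
        g, k = np.argwhere(values != np.floor(values))[0]
        raise ValueError(
            f"non-integer count at gene {counts.index[g]!r}, library {counts.columns[k]!r}"
        )
    if not (values.sum(axis=0) > 0).any():
        raise ValueError("no library has a positive total count")
    return counts


def _pairwise_tmm(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one library against the reference library.

    Genes with a zero count in either library are excluded; the M
    (log-ratio) and A (average log-abundance) values are double-trimmed and
    the surviving log-ratios averaged with inverse delta-method-variance
    (precision) weights.  Returns the factor on the natural scale.
    """
    pos = (obs > 0) & (ref > 0)
    obs = obs[pos].astype(float)
    ref = ref[pos].astype(float)
    if obs.size == 0:
        warnings.warn("no gene expressed in both libraries; TMM factor set to 1")
        return 1.0
    p_obs = obs / lib_obs
    p_ref = ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method variance of M; weights are its inverse
    v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        warnings.warn("all genes trimmed in TMM estimation; factor set to 1")
        return 1.0
    # zero-variance guard (v can vanish only if obs==lib_obs and ref==lib_ref)
    v = np.maximum(v, 1e-12)
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0**f)


class TMMNormalizer(BaseEstimator, TransformerMixin):
    """Trimmed-mean-of-M-values normalization.

    Corrects between-library comparisons for RNA composition differences:
    for each library a scaling factor is estimated as the weighted trimmed
    mean of gene-wise log-ratios against a reference library, so that the
    bulk of genes (assumed unchanged) has a log-ratio centred on zero.
    Factors are renormalized to geometric mean one, and the effective
    library size is the raw total multiplied by the factor.

    Parameters
    ----------
    trim_m : float, default 0.30
        Two-sided trim proportion applied to the M (log-ratio) values.
    trim_a : float, default 0.05
        Two-sided trim proportion applied to the A (abundance) values.
    ref_library : int or str, optional
        Reference library (positional index, or column label when the
        input is a DataFrame).  By default the library whose upper
        quartile of scaled counts is closest to the mean upper quartile.

    Attributes
    ----------
    factors_ : ndarray of shape (n_libraries,)
        TMM factors, geometric mean 1.
    library_sizes_ : ndarray of shape (n_libraries,)
        Raw library totals.
    effective_library_sizes_ : ndarray of shape (n_libraries,)
        ``library_sizes_ * factors_``.
    ref_index_ : int
        Positional index of the reference library used.
    """

    def __init__(self, trim_m: float = 0.30, trim_a: float = 0.05, ref_library=None):
        self.trim_m = trim_m
        self.trim_a = trim_a
        self.ref_library = ref_library

    def _validate_x(self, X):
        if isinstance(X, pd.DataFrame):
            self.library_ids_ = np.asarray(X.index)
            X = X.to_numpy()
        else:
            X = np.asarray(X)
            self.library_ids_ = np.arange(X.shape[0])
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (libraries x genes)")
        if (X < 0).any():
            raise ValueError("counts must be non-negative")
        return X.astype(float)

    def fit(self, X, y=None):
        """Estimate TMM factors from a libraries x genes count matrix."""
        for name in ("trim_m", "trim_a"):
            t = getattr(self, name)
            if not 0 <= t < 0.5:
                raise ValueError(f"{name} must be in [0, 0.5); got {t}")
        X = self._validate_x(X)
        lib_sizes = X.sum(axis=1)
        if (lib_sizes == 0).any():
            bad = self.library_ids_[np.argmax(lib_sizes == 0)]
            raise ValueError(f"library {bad!r} has zero total count")

        if self.ref_library is None:
            uq = np.quantile(X / lib_sizes[:, None], 0.75, axis=1)
            ref = int(np.argmin(np.abs(uq - uq.mean())))
        else:
            matches = np.nonzero(self.library_ids_ == self.ref_library)[0]
            if matches.size:
                ref = int(matches[0])
            elif isinstance(self.ref_library, (int, np.integer)):
                ref = int(self.ref_library)
            else:
                raise ValueError(f"reference library {self.ref_library!r} not found")

        factors = np.array(
            [
                _pairwise_tmm(
                    X[k], X[ref], lib_sizes[k], lib_sizes[ref], self.trim_m, self.trim_a
                )
                for k in range(X.shape[0])
            ]
        )
        factors = factors / np.exp(np.mean(np.log(factors)))
        self.ref_index_ = ref
        self.factors_ = factors
        self.library_sizes_ = lib_sizes
        self.effective_library_sizes_ = lib_sizes * factors
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, prior_count: float = 0.0):
        """Return CPM computed against the fitted effective library sizes.

        ``X`` must have the same library order as the matrix passed to
        :meth:`fit`; the per-library totals are re-derived from the fitted
        raw sizes so that counts and normalization stay consistent.
        """
        if not hasattr(self, "factors_"):
            raise ValueError("TMMNormalizer is not fitted")
        index = columns = None
        if isinstance(X, pd.DataFrame):
            index, columns = X.index, X.columns
            X = X.to_numpy()
        X = np.asarray(X, dtype=float)
        eff = self.effective_library_sizes_
        if X.shape[0] != eff.size:
            raise ValueError("library dimension does not match the fitted normalizer")
        if prior_count < 0:
            raise ValueError("prior_count must be non-negative")
        prior_k = prior_count * eff / eff.mean()
        out = (X + prior_k[:, None]) / (eff + prior_k)[:, None] * 1e6
        if index is not None:
            return pd.DataFrame(out, index=index, columns=columns)
        return out

    def factors_frame(self) -> pd.DataFrame:
        """Fitted factors as a tidy table (library_id, tmm_factor, effective size)."""
        if not hasattr(self, "factors_"):
            raise ValueError("TMMNormalizer is not fitted")
        return pd.DataFrame(
            {
                "library_id": self.library_ids_,
                "tmm_factor": self.factors_,
                "effective_library_size": self.effective_library_sizes_,
            }
        )


def tmm_factors(
    counts: pd.DataFrame,
    ref_library=None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.DataFrame:
    """TMM factors for a genes x libraries count matrix.

    Returns a DataFrame with columns ``library_id``, ``tmm_factor`` and
    ``effective_library_size`` (geometric mean of factors is 1).
    """
    validate_counts(counts)
    norm = TMMNormalizer(trim_m=trim_m, trim_a=trim_a, ref_library=ref_library)
    norm.fit(counts.T)
    return norm.factors_frame()


def _effective_sizes(counts: pd.DataFrame, norm: pd.DataFrame) -> np.ndarray:
    norm = norm.set_index("library_id")
    missing = [c for c in counts.columns if c not in norm.index]
    if missing:
        raise ValueError(f"normalization factors missing for libraries: {missing}")
    return norm.loc[counts.columns, "effective_library_size"].to_numpy(float)


def cpm(
    counts: pd.DataFrame, norm: pd.DataFrame, prior_count: float = 0.0
) -> pd.DataFrame:
    """Counts per million against TMM-effective library sizes.

    ``cpm_gk = (y_gk + p_k) / (effective_size_k + p_k) * 1e6`` with the
    prior scaled per library as ``p_k = prior_count * eff_k / mean(eff)``
    (zero prior gives plain CPM).
    """
    if prior_count < 0:
        raise ValueError("prior_count must be non-negative")
    eff = _effective_sizes(counts, norm)
    prior_k = prior_count * eff / eff.mean()
    values = (counts.to_numpy(float) + prior_k) / (eff + prior_k) * 1e6
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def filter_low_expression(
    counts: pd.DataFrame, norm: pd.DataFrame, min_avg_cpm: float = 1.0
) -> pd.Series:
    """Boolean gene mask retaining genes with mean CPM >= ``min_avg_cpm``.

    Genes whose average CPM across all libraries falls below the threshold
    are flagged for exclusion before model fitting; the threshold itself is
    retained (only strictly lower averages are excluded).
    """
    mean_cpm = cpm(counts, norm).mean(axis=1)
    return mean_cpm >= min_avg_cpm
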