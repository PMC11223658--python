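"""Expression filtering, normalization and embedding.

Two low-expression filters are implemented, mirroring the two analysis arms:

* the differential-expression filter keeps genes with a mean of at least one
  read count per sample (total >= n samples) *and* at most 1/3 of samples at
  zero (stated for 30-sample strata as "zero in more than 10 of 30 removed");
* the co-expression filter removes genes with zero TPM in more than 1/3 of
  the samples of any brain-region group (stated for 60-sample groups as
  "more than 20 of 60").

Cutoffs scale proportionally with stratum size and the strict inequalities
are kept exactly as stated, so a gene with zeros exactly at the cutoff is
retained.

The estimator classes follow scikit-learn conventions and operate on
samples x genes arrays (samples as rows); the module-level functions wrap
them for the genes x samples :class:`~nestnet.matrix.ExpressionMatrix`
orientation used elsewhere.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .errors import FormatError, InvalidConfigError
from .matrix import ExpressionMatrix


# ---------------------------------------------------------------------------
# estimators (samples x genes orientation)
# ---------------------------------------------------------------------------

class LowCountFilter(BaseEstimator, TransformerMixin):
    """Drop genes with low total counts or too many zero-count samples.

    A gene is kept iff total counts >= ``min_mean_count * n_samples`` and the
    number of zero-count samples is <= ``max_zero_fraction * n_samples``
    (strictly-more-than-the-cutoff removes).
    """

    def __init__(self, min_mean_count: float = 1.0, max_zero_fraction: float = 10 / 30):
        self.min_mean_count = min_mean_count
        self.max_zero_fraction = max_zero_fraction

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise FormatError("expected a 2-D samples x genes array")
        n = X.shape[0]
        totals = X.sum(axis=0)
        zeros = (X == 0).sum(axis=0)
        low_total = totals < self.min_mean_count * n
        too_many_zeros = zeros > self.max_zero_fraction * n
        self.support_ = ~(low_total | too_many_zeros)
        self.reasons_ = np.where(
            low_total, "low_total", np.where(too_many_zeros, "too_many_zeros", "kept")
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]


class ZeroFractionFilter(BaseEstimator, TransformerMixin):
    """Drop genes with zero expression in more than a fraction of any group.

    ``fit`` accepts ``groups`` (per-sample labels, e.g. brain region); a gene
    is removed if its zero count exceeds ``max_zero_fraction * group size``
    in *any* group.
    """

    def __init__(self, max_zero_fraction: float = 20 / 60):
        self.max_zero_fraction = max_zero_fraction

    def fit(self, X, y=None, groups: Sequence | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise FormatError("expected a 2-D samples x genes array")
        if groups is None:
            groups = np.zeros(X.shape[0], dtype=int)
        groups = np.asarray(groups)
        if len(groups) != X.shape[0]:
            raise FormatError("groups length must equal the number of samples")
        keep = np.ones(X.shape[1], dtype=bool)
        for g in pd.unique(groups):
            sub = X[groups == g]
            zeros = (sub == 0).sum(axis=0)
            keep &= zeros <= self.max_zero_fraction * sub.shape[0]
        self.support_ = keep
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]


class MedianOfRatiosNormalizer(BaseEstimator, TransformerMixin):
    """Median-of-ratios library-size normalization for count data.

    ``fit`` learns a per-gene reference (geometric mean across the fitted
    samples, restricted to genes nonzero in all of them); ``transform``
    computes one size factor per sample — the median over reference genes of
    count/reference — and divides the sample's counts by it.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise FormatError("median-of-ratios needs at least two samples")
        usable = (X > 0).all(axis=0)
        if not usable.any():
            raise FormatError("no gene is expressed in all samples; cannot form a reference")
        self.reference_mask_ = usable
        self.reference_ = np.exp(np.log(X[:, usable]).mean(axis=0))
        return self

    def size_factors(self, X) -> np.ndarray:
        check_is_fitted(self, "reference_")
        X = np.asarray(X, dtype=float)
        ratios = X[:, self.reference_mask_] / self.reference_
        return np.median(ratios, axis=1)

    def transform(self, X):
        factors = self.size_factors(X)
        if isinstance(X, pd.DataFrame):
            return X.div(factors, axis=0)
        return np.asarray(X, dtype=float) / factors[:, None]


class Log2Transformer(BaseEstimator, TransformerMixin):
    """x -> log2(x + pseudocount); stateless, kept for pipeline composition."""

    def __init__(self, pseudocount: float = 1.0):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        arr = np.asarray(X, dtype=float)
        if (arr + self.pseudocount <= 0).any():
            raise InvalidConfigError(
                "log2 transform undefined: value + pseudocount <= 0 encountered"
            )
        out = np.log2(arr + self.pseudocount)
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


# ---------------------------------------------------------------------------
# ExpressionMatrix-oriented wrappers
# ---------------------------------------------------------------------------

def filter_deg_genes(
    m: ExpressionMatrix,
    sample_ids: Sequence[str] | None = None,
    min_mean_count: float = 1.0,
    max_zero_fraction: float = 10 / 30,
    return_report: bool = False,
):
    """Apply the differential-expression low-count filter within a stratum."""
    if m.scale != "counts":
        raise FormatError(f"DEG filter requires counts, got scale {m.scale!r}")
    sub = m if sample_ids is None else m.subset_samples(sample_ids)
    f = LowCountFilter(min_mean_count, max_zero_fraction).fit(sub.data.T.to_numpy())
    out = ExpressionMatrix(sub.data.loc[f.support_], "counts")
    if return_report:
        report = pd.DataFrame({"gene_id": sub.gene_ids, "reason": f.reasons_})
        return out, report
    return out


def filter_wgcna_genes(
    m: ExpressionMatrix,
    regions: Sequence[str],
    max_zero_fraction: float = 20 / 60,
) -> ExpressionMatrix:
    """Remove genes with TPM=0 in more than the cutoff fraction of any region group."""
    if m.scale != "tpm":
        raise FormatError(f"co-expression filter requires tpm, got scale {m.scale!r}")
    regions = list(regions)
    if len(regions) != m.n_samples:
        raise FormatError("regions must provide one label per sample")
    if any(pd.isna(r) or r == "" for r in regions):
        raise FormatError("missing region label(s)")
    f = ZeroFractionFilter(max_zero_fraction).fit(m.data.T.to_numpy(), groups=regions)
    return ExpressionMatrix(m.data.loc[f.support_], "tpm")


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(TPM + pseudocount); returns a log2tpm-tagged matrix."""
    if m.scale != "tpm":
        raise FormatError(f"log2 transform expects tpm, got scale {m.scale!r}")
    out = Log2Transformer(pseudocount).transform(m.data)
    return ExpressionMatrix(out, "log2tpm")


def median_of_ratios_normalize(m: ExpressionMatrix) -> tuple[ExpressionMatrix, pd.Series]:
    """Median-of-ratios normalization; returns (normalized matrix, size factors)."""
    if m.scale != "counts":
        raise FormatError(f"median-of-ratios expects counts, got scale {m.scale!r}")
    norm = MedianOfRatiosNormalizer().fit(m.data.T.to_numpy())
    factors = pd.Series(norm.size_factors(m.data.T.to_numpy()), index=m.sample_ids,
                        name="size_factor")
    data = m.data.div(factors, axis=1)
    return ExpressionMatrix(data, "counts"), factors


def pca_embed(m: ExpressionMatrix, n_components: int = 2):
    """PCA over samples (genes as features, per-gene centering).

    Returns ``(coordinates, variance_fractions, degenerate)`` where
    coordinates is a samples x components DataFrame. ``degenerate`` is True
    when total variance is zero (all samples identical), in which case the
    coordinates are all zero and fractions are 0.
    """
    if m.n_samples < 2:
        raise FormatError("PCA needs at least two samples")
    if n_components > min(m.n_samples, m.n_genes):
        raise InvalidConfigError(
            f"n_components={n_components} exceeds min(n_samples, n_genes)="
            f"{min(m.n_samples, m.n_genes)}"
        )
    X = m.values.T  # samples x genes
    if np.allclose(X, X[0]):
        coords = pd.DataFrame(
            np.zeros((m.n_samples, n_components)),
            index=m.sample_ids,
            columns=[f"PC{i+1}" for i in range(n_components)],
        )
        return coords, np.zeros(n_components), True
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    coords = pd.DataFrame(coords, index=m.sample_ids,
                          columns=[f"PC{i+1}" for i in range(n_components)])
    return coords, pca.explained_variance_ratio_, False
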