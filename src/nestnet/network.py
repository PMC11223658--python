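"""Signed-hybrid weighted co-expression networks and module detection.

The network is built from a gene-gene correlation matrix (biweight
midcorrelation by default, Pearson optionally), soft-thresholded on the
positive side only (negative correlations map to adjacency 0 — the
"signed hybrid" convention), turned into a topological overlap similarity,
and clustered by average-linkage hierarchical clustering with a static cut.

Module eigengenes are the first principal component of the gene-standardized
module submatrix, with the sign fixed so that the mean correlation between
the eigengene and the member genes is nonnegative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import FormatError, InvalidConfigError
from .matrix import ExpressionMatrix

UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def _bicor_weights(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene biweight-midcovariance vectors, unit-normalized.

    Rows with zero MAD but nonzero variance fall back to Pearson-style
    centering (mean/SD), matching common practice; constant rows become zero
    vectors and are reported by the caller as undefined correlations.
    """
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (X - med) / (9.0 * mad)
    w = np.square(1.0 - np.square(u)) * (np.abs(u) < 1.0)
    a = w * (X - med)

    constant = X.std(axis=1) == 0
    fallback = (mad.ravel() == 0) & ~constant
    if fallback.any():
        a[fallback] = X[fallback] - X[fallback].mean(axis=1, keepdims=True)
    a[constant] = 0.0

    norms = np.sqrt(np.square(a).sum(axis=1))
    nz = norms > 0
    a[nz] /= norms[nz, None]
    return a, constant


def bicor(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Biweight midcorrelation matrix of the rows of ``X`` (genes x samples).

    Uses the standard 9-MAD tuning constant. Returns ``(C, constant_mask)``;
    rows flagged constant have all off-diagonal correlations set to 0.
    """
    X = np.asarray(X, dtype=float)
    a, constant = _bicor_weights(X)
    C = a @ a.T
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    return C, constant


def pearson_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation matrix of the rows of ``X``; constants -> 0."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1)
    constant = sd == 0
    Z = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.square(Z).sum(axis=1))
    nz = norms > 0
    Z[nz] /= norms[nz, None]
    Z[~nz] = 0.0
    C = Z @ Z.T
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    return C, constant


@dataclass
class CorrelationMatrix:
    gene_ids: list[str]
    values: np.ndarray
    method: str
    constant_genes: list[str] = field(default_factory=list)


def correlation_matrix(m: ExpressionMatrix, method: str = "bicor") -> CorrelationMatrix:
    """Gene-gene correlation matrix (``bicor`` or ``pearson``)."""
    if m.n_samples < 3:
        raise FormatError("correlation needs at least 3 samples")
    if method == "bicor":
        C, constant = bicor(m.values)
    elif method == "pearson":
        C, constant = pearson_rows(m.values)
    else:
        raise InvalidConfigError(f"unknown correlation method {method!r}")
    constant_genes = [g for g, c in zip(m.gene_ids, constant) if c]
    if constant_genes:
        warnings.warn(
            f"{len(constant_genes)} constant gene(s); their correlations are set to 0",
            stacklevel=2,
        )
    return CorrelationMatrix(m.gene_ids, C, method, constant_genes)


# ---------------------------------------------------------------------------
# adjacency and topological overlap
# ---------------------------------------------------------------------------

@dataclass
class AdjacencyMatrix:
    gene_ids: list[str]
    values: np.ndarray  # zero diagonal
    soft_power: int


def signed_hybrid_adjacency(c: CorrelationMatrix, beta: int = 6) -> AdjacencyMatrix:
    """a_ij = max(cor_ij, 0)^beta with a zero diagonal."""
    if beta < 1:
        raise InvalidConfigError(f"soft power must be >= 1, got {beta}")
    A = np.power(np.clip(c.values, 0.0, None), beta)
    np.fill_diagonal(A, 0.0)
    return AdjacencyMatrix(c.gene_ids, A, beta)


def tom_similarity(a: AdjacencyMatrix) -> np.ndarray:
    """Topological overlap: TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)."""
    A = a.values
    if (A < 0).any() or (A > 1).any():
        raise FormatError("adjacency values must lie in [0, 1]")
    k = A.sum(axis=1)
    shared = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (shared + A) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

@dataclass
class ModulePartition:
    """Gene -> module labels with a reserved 'unassigned' label."""

    labels: pd.Series  # index: gene ids, values: module labels

    @property
    def gene_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def modules(self) -> list[str]:
        sizes = self.module_sizes
        return [m for m in sizes.index if m != UNASSIGNED]

    @property
    def module_sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.labels.index, "module": self.labels.to_numpy()})


def detect_modules(
    tom: np.ndarray,
    gene_ids: list[str],
    min_module_size: int = 30,
    cut_height: float = 0.99,
) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Clusters smaller than ``min_module_size`` are pooled into 'unassigned'.
    Labels are canonical: modules sorted by (size desc, smallest member gene
    id) and named M1, M2, ..., so the partition is invariant to gene input
    order.
    """
    if not 0.0 < cut_height < 1.0:
        raise InvalidConfigError(f"cut_height must be in (0, 1), got {cut_height}")
    n = len(gene_ids)
    if tom.shape != (n, n):
        raise FormatError("TOM shape does not match gene list")
    dist = 1.0 - tom
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")

    labels = pd.Series([UNASSIGNED] * n, index=gene_ids, dtype=object)
    clusters = []
    for cid in np.unique(raw):
        members = [gene_ids[i] for i in np.flatnonzero(raw == cid)]
        if len(members) >= min_module_size:
            clusters.append(members)
    clusters.sort(key=lambda ms: (-len(ms), min(ms)))
    for rank, members in enumerate(clusters, start=1):
        labels.loc[members] = f"M{rank}"
    return ModulePartition(labels)


# ---------------------------------------------------------------------------
# eigengenes and module membership
# ---------------------------------------------------------------------------

@dataclass
class ModuleEigengene:
    module: str
    scores: pd.Series  # per-sample, unit norm
    variance_explained: float
    sign_flipped: bool = False
    degenerate: bool = False


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = X.std(axis=1)
    constant = sd == 0
    Z = X - X.mean(axis=1, keepdims=True)
    Z[constant] = 0.0
    Z[~constant] /= sd[~constant, None]
    return Z, constant


def module_eigengene(
    m: ExpressionMatrix,
    part: ModulePartition,
    module: str,
    sample_ids: list[str] | None = None,
) -> ModuleEigengene:
    """First principal component of the gene-standardized module submatrix.

    The per-sample score vector has unit norm; the sign is fixed so the mean
    correlation between the eigengene and the member genes is nonnegative.
    A single-gene module degenerates to the standardized gene itself.
    """
    genes = part.members(module)
    if not genes:
        raise InvalidConfigError(f"module {module!r} has no members")
    sub = m.subset_genes(genes)
    if sample_ids is not None:
        sub = sub.subset_samples(sample_ids)
    Z, constant = _standardize_rows(sub.values)
    if constant.any():
        warnings.warn(
            f"module {module}: {int(constant.sum())} constant gene(s) contribute zero rows",
            stacklevel=2,
        )
    samples = sub.sample_ids
    if len(genes) == 1:
        v = Z[0]
        norm = np.linalg.norm(v)
        v = v / norm if norm > 0 else v
        return ModuleEigengene(module, pd.Series(v, index=samples), 1.0, degenerate=True)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    v = Vt[0]
    var_exp = float(S[0] ** 2 / np.square(S).sum()) if S.sum() > 0 else 0.0
    # mean gene-eigengene correlation has the sign of mean(U[:, 0])
    flipped = bool(U[:, 0].mean() < 0)
    if flipped:
        v = -v
    return ModuleEigengene(module, pd.Series(v, index=samples), var_exp, sign_flipped=flipped)


def module_membership(
    m: ExpressionMatrix, me: ModuleEigengene, gene: str
) -> float:
    """Pearson correlation between one gene's expression and the eigengene."""
    x = m.data.loc[gene, me.scores.index].to_numpy(dtype=float)
    if x.std() == 0 or me.scores.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, me.scores.to_numpy())[0, 1])


def module_membership_all(m: ExpressionMatrix, me: ModuleEigengene,
                          genes: list[str] | None = None) -> pd.Series:
    """Vectorized module membership for many genes; constants map to NaN."""
    genes = genes if genes is not None else m.gene_ids
    X = m.data.loc[genes, me.scores.index].to_numpy(dtype=float)
    Z, constant = _standardize_rows(X)
    y = me.scores.to_numpy()
    ys = y.std()
    if ys == 0:
        return pd.Series(np.nan, index=genes)
    yz = (y - y.mean()) / ys
    mm = (Z @ yz) / len(y)
    mm[constant] = np.nan
    return pd.Series(np.clip(mm, -1.0, 1.0), index=genes)


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class CoexpressionModules(ClusterMixin, BaseEstimator):
    """Signed-hybrid weighted co-expression module detection.

    scikit-learn style clusterer over genes. ``fit`` expects a samples x
    genes DataFrame (or array) of log2-scale expression; fitted attributes:

    - ``labels_``: per-gene module labels ('unassigned' for leftovers)
    - ``partition_``: the :class:`ModulePartition`
    - ``eigengenes_``: samples x modules DataFrame of eigengene scores
    - ``variance_explained_``: per-module fraction
    """

    def __init__(
        self,
        correlation: str = "bicor",
        beta: int = 6,
        cut_height: float = 0.99,
        min_module_size: int = 30,
        merge_height: float | None = None,
    ):
        self.correlation = correlation
        self.beta = beta
        self.cut_height = cut_height
        self.min_module_size = min_module_size
        self.merge_height = merge_height

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            gene_ids = list(X.columns)
            sample_ids = list(X.index)
            data = X.T.astype(float)
        else:
            X = np.asarray(X, dtype=float)
            gene_ids = [f"g{i}" for i in range(X.shape[1])]
            sample_ids = [f"s{i}" for i in range(X.shape[0])]
            data = pd.DataFrame(X.T, index=gene_ids, columns=sample_ids)
        m = ExpressionMatrix(data, "log2tpm")
        corr = correlation_matrix(m, self.correlation)
        adj = signed_hybrid_adjacency(corr, self.beta)
        tom = tom_similarity(adj)
        part = detect_modules(tom, gene_ids, self.min_module_size, self.cut_height)
        if self.merge_height is not None:
            part = self._merge_close_modules(m, part)
        self.partition_ = part
        self.labels_ = part.labels.loc[gene_ids].to_numpy()
        mes, var_exp = {}, {}
        for mod in part.modules:
            me = module_eigengene(m, part, mod)
            mes[mod] = me.scores
            var_exp[mod] = me.variance_explained
        self.eigengenes_ = pd.DataFrame(mes, index=sample_ids)
        self.variance_explained_ = pd.Series(var_exp, dtype=float)
        return self

    def _merge_close_modules(self, m: ExpressionMatrix, part: ModulePartition) -> ModulePartition:
        """Merge modules whose eigengenes are closer than merge_height (1 - cor)."""
        mods = part.modules
        if len(mods) < 2:
            return part
        ME = np.vstack([module_eigengene(m, part, mod).scores.to_numpy() for mod in mods])
        C, _ = pearson_rows(ME)
        d = np.clip(1.0 - C, 0.0, None)
        np.fill_diagonal(d, 0.0)
        Z = linkage(squareform((d + d.T) / 2, checks=False), method="average")
        raw = fcluster(Z, t=self.merge_height, criterion="distance")
        labels = part.labels.copy()
        merged: list[list[str]] = []
        for cid in np.unique(raw):
            group = [mods[i] for i in np.flatnonzero(raw == cid)]
            members: list[str] = []
            for g in group:
                members.extend(part.members(g))
            merged.append(members)
        merged.sort(key=lambda ms: (-len(ms), min(ms)))
        for rank, members in enumerate(merged, start=1):
            labels.loc[members] = f"M{rank}"
        return ModulePartition(labels)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
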