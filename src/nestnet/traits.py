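"""Module-behavior correlation, gene significance, and hub-gene selection.

A module whose eigengene correlates significantly (raw two-sided P < 0.05
from the t distribution with n-2 df) with a nesting-action frequency within
the nesting (E) group is a "nesting behavior frequency" (NBF) module. Hub
genes of a module are genes with |module membership| > 0.8 and |gene
significance| above a family-specific threshold — the empirical top-1%
quantile of |GS| within that module family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidConfigError
from .matrix import ExpressionMatrix
from .network import ModuleEigengene, _standardize_rows

MM_THRESHOLD = 0.8
GS_QUANTILE = 0.99


@dataclass
class TraitVector:
    """A trait over a sample subset: a frequency, or a 0/1 nesting state
    (``binary=True``, e.g. nesting=1 for E, 0 for the reference group)."""

    name: str
    values: pd.Series  # index: sample ids
    binary: bool = False

    def __post_init__(self) -> None:
        if self.binary:
            uniq = set(pd.unique(self.values))
            if not uniq <= {0, 1}:
                raise InvalidConfigError(f"binary trait {self.name!r} has values {uniq}")
            if len(uniq) < 2:
                raise InvalidConfigError(
                    f"binary trait {self.name!r} contains a single class"
                )


@dataclass
class NBFResult:
    module: str
    trait: str
    r: float
    p: float
    significant: bool
    n: int
    undefined: bool = False


def pearson_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided P (t distribution, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise InvalidConfigError(f"need >= 4 observations for a correlation test, got {n}")
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def nbf_correlation(me: ModuleEigengene, trait: TraitVector,
                    alpha: float = 0.05) -> NBFResult:
    """Correlate one module eigengene with one action frequency."""
    common = [s for s in me.scores.index if s in trait.values.index]
    x = me.scores.loc[common].to_numpy(dtype=float)
    y = trait.values.loc[common].to_numpy(dtype=float)
    r, p = pearson_test(x, y)
    if np.isnan(r):
        return NBFResult(me.module, trait.name, r, p, False, len(common), undefined=True)
    return NBFResult(me.module, trait.name, r, p, bool(p < alpha), len(common))


def gene_significance(
    m: ExpressionMatrix, trait: TraitVector, genes: list[str] | None = None
) -> pd.Series:
    """Pearson correlation of each gene with the trait (binary traits as 0/1).

    Constant genes yield NaN.
    """
    genes = genes if genes is not None else m.gene_ids
    samples = [s for s in m.sample_ids if s in trait.values.index]
    X = m.data.loc[genes, samples].to_numpy(dtype=float)
    y = trait.values.loc[samples].to_numpy(dtype=float)
    if y.std() == 0:
        return pd.Series(np.nan, index=genes)
    Z, constant = _standardize_rows(X)
    yz = (y - y.mean()) / y.std()
    gs = (Z @ yz) / len(y)
    gs[constant] = np.nan
    return pd.Series(np.clip(gs, -1.0, 1.0), index=genes, name=f"GS_{trait.name}")


def gs_quantile_threshold(gs_values, q: float = GS_QUANTILE) -> float:
    """Empirical q-quantile of |GS| over a module family (linear interpolation)."""
    vals = np.abs(np.asarray(list(gs_values), dtype=float))
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise InvalidConfigError("empty gene-significance family")
    return float(np.quantile(vals, q, method="linear"))


def select_hub_genes(
    mm: pd.Series,
    gs: pd.Series,
    mm_threshold: float = MM_THRESHOLD,
    gs_threshold: float = 0.0,
    module: str | None = None,
) -> pd.DataFrame:
    """Hub genes: |MM| > mm_threshold AND |GS| > gs_threshold (strict).

    Genes with missing MM or GS are skipped (flagged in the ``skipped``
    column of the returned frame). Sorted by |GS| descending.
    """
    if not (0.0 <= mm_threshold <= 1.0 and 0.0 <= gs_threshold <= 1.0):
        raise InvalidConfigError("hub thresholds must lie in [0, 1]")
    genes = mm.index.intersection(gs.index)
    df = pd.DataFrame({"MM": mm.loc[genes], "GS": gs.loc[genes]})
    df.index.name = "gene_id"
    df["skipped"] = df["MM"].isna() | df["GS"].isna()
    df["is_hub"] = (
        ~df["skipped"]
        & (df["MM"].abs() > mm_threshold)
        & (df["GS"].abs() > gs_threshold)
    )
    if module is not None:
        df.insert(0, "module", module)
    return df.sort_values("GS", key=lambda s: s.abs(), ascending=False, na_position="last")


def nbf_scan(
    eigengenes: pd.DataFrame,
    frequencies: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All module x trait NBF correlations on one sample subset.

    ``eigengenes``: samples x modules; ``frequencies``: samples x actions.
    """
    rows = []
    common = eigengenes.index.intersection(frequencies.index)
    for module in eigengenes.columns:
        for trait_name in frequencies.columns:
            x = eigengenes.loc[common, module].to_numpy(dtype=float)
            y = frequencies.loc[common, trait_name].to_numpy(dtype=float)
            r, p = pearson_test(x, y)
            rows.append({
                "module": module, "trait": trait_name, "r": r, "p": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
                "n": len(common),
            })
    return pd.DataFrame(rows)
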