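"""Custom neural-function over-representation tests.

Genes are mapped to three categories — neuron projection, in situ
neurogenesis, other neurogenesis — plus the derived composite
"neurogenesis". Because axon/dendrite projection is developmentally part of
neurogenesis, a neuron-projection gene also counts as a neurogenesis gene,
but neurogenesis genes do not count as neuron-projection genes.

Over-representation of a gene list in a category is assessed with a
one-tailed (greater) Fisher exact test against the expressed-gene background
of the relevant brain region. Per-list tests are reported unadjusted
(significant at raw P < 0.05); when scanning all modules, BH adjustment is
applied across modules within each category family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .errors import FormatError, InvalidConfigError
from .connectivity import bh_adjust
from .network import ModulePartition

PRIMARY_CATEGORIES = ("neuron_projection", "in_situ_neurogenesis", "other_neurogenesis")
COMPOSITE = "neurogenesis"
ALL_CATEGORIES = PRIMARY_CATEGORIES + (COMPOSITE,)


@dataclass
class CategoryMap:
    """Gene -> category membership with the derived neurogenesis composite."""

    memberships: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat in PRIMARY_CATEGORIES:
            self.memberships.setdefault(cat, set())

    def genes_in(self, category: str) -> set[str]:
        if category in PRIMARY_CATEGORIES:
            return set(self.memberships[category])
        if category == COMPOSITE:
            # hierarchy rule: neuron projection counts toward neurogenesis,
            # but not the other way around
            return (
                self.memberships["in_situ_neurogenesis"]
                | self.memberships["other_neurogenesis"]
                | self.memberships["neuron_projection"]
            )
        raise InvalidConfigError(f"unknown category {category!r}")

    def categories_of(self, gene: str) -> set[str]:
        out = {c for c in PRIMARY_CATEGORIES if gene in self.memberships[c]}
        if out:  # any primary membership implies the neurogenesis composite
            out.add(COMPOSITE)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "category": c}
            for c in PRIMARY_CATEGORIES
            for g in sorted(self.memberships[c])
        ]
        return pd.DataFrame(rows, columns=["gene_id", "category"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class EnrichmentResult:
    label: str
    category: str
    k: int  # list genes in the category
    K: int  # list size
    n: int  # background genes in the category
    N: int  # background size
    p: float
    adj_p: float | None = None
    significant: bool = False


def load_category_map(path: str | Path) -> CategoryMap:
    """Read a two-column TSV (gene_id, category); empty files yield an empty map."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return CategoryMap()
    if list(df.columns[:2]) != ["gene_id", "category"]:
        raise FormatError(
            f"{path}: expected columns gene_id, category; got {list(df.columns)}"
        )
    cmap = CategoryMap()
    for i, row in df.iterrows():
        cat = row["category"]
        if cat not in PRIMARY_CATEGORIES:
            raise FormatError(
                f"{path}: row {i + 2}: unknown category {cat!r} for gene {row['gene_id']!r}"
            )
        cmap.memberships[cat].add(row["gene_id"])
    return cmap


def fisher_one_tailed(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric P of drawing >= k category genes.

    2x2 table: (k, K-k) over (n-k, N-K-(n-k)); P = sum_{i>=k} P(X=i) with
    X ~ Hypergeom(N, n, K).
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise InvalidConfigError(f"inconsistent contingency counts k={k}, K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, n, K))


def over_representation_test(
    gene_list,
    category: str,
    background,
    category_map: CategoryMap,
    label: str = "",
    alpha: float = 0.05,
) -> EnrichmentResult:
    """One-tailed Fisher exact test of a gene list against the background."""
    gene_list = set(gene_list)
    background = set(background)
    offenders = sorted(gene_list - background)
    if offenders:
        raise InvalidConfigError(
            f"gene list is not a subset of the background; offenders: {offenders[:10]}"
        )
    cat_genes = category_map.genes_in(category) & background
    k = len(gene_list & cat_genes)
    K = len(gene_list)
    n = len(cat_genes)
    N = len(background)
    p = fisher_one_tailed(k, K, n, N)
    return EnrichmentResult(label, category, k, K, n, N, p, significant=bool(p < alpha))


def module_over_representation(
    part: ModulePartition,
    category_map: CategoryMap,
    background,
    categories=("neuron_projection", COMPOSITE),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-module over-representation with BH across modules within each category."""
    background = set(background)
    rows: list[EnrichmentResult] = []
    for category in categories:
        fam: list[EnrichmentResult] = []
        for module in part.modules:
            members = set(part.members(module)) & background
            fam.append(over_representation_test(
                members, category, background, category_map, label=module, alpha=alpha
            ))
        if fam:
            adj = bh_adjust([r.p for r in fam])
            for r, a in zip(fam, adj):
                r.adj_p = float(a)
                r.significant = bool(a < alpha)
        rows.extend(fam)
    df = pd.DataFrame([vars(r) for r in rows])
    return df.rename(columns={"label": "module"})
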