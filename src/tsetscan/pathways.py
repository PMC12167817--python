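"""Functional-category "completeness" over a coregulated gene set.

Given a KEGG-Mapper-style catalog (category -> gene set, against a
reference genome annotation) and the set of genes selected as coregulated
with the core complex, completeness of a category is the percentage of its
genes that fall in the selected set.  Categories are ranked by decreasing
completeness.  This is a descriptive statistic, not an enrichment test: no
p-values are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .census import detection_percentage
from .errors import InputIntegrityError, UndefinedDenominatorError

DEFAULT_MIN_SIZE = 5
DEFAULT_EXCLUDED = frozenset({"Enzymes"})


@dataclass
class PathwayCatalog:
    """Category membership plus the reference gene universe.

    A gene may belong to several categories (functional hierarchies
    overlap); completeness is computed per category so this introduces no
    double counting.
    """

    categories: dict[str, frozenset[str]]
    reference_universe: frozenset[str]

    def __post_init__(self) -> None:
        stray = {
            g for genes in self.categories.values() for g in genes
        } - set(self.reference_universe)
        if stray:
            raise InputIntegrityError(
                f"category genes outside the reference universe: {sorted(stray)[:5]}"
            )


def completeness(
    category_genes: frozenset[str] | set[str], selected_genes: set[str]
) -> tuple[int, int, int]:
    """(n_coregulated, n_total, percent) for one category.

    ``percent`` is round-half-up of ``100 * |category & selected| / |category|``
    (e.g. 106 of 153 -> 69, 13 of 15 -> 87).
    """
    n_total = len(category_genes)
    if n_total == 0:
        raise UndefinedDenominatorError("completeness of an empty category")
    n_coreg = len(set(category_genes) & selected_genes)
    return n_coreg, n_total, detection_percentage(n_coreg, n_total)


def filter_categories(
    catalog: PathwayCatalog,
    min_size: int = DEFAULT_MIN_SIZE,
    excluded_names: frozenset[str] | set[str] = DEFAULT_EXCLUDED,
) -> PathwayCatalog:
    """Drop excluded categories and those with fewer than ``min_size`` genes.

    "Fewer than 5" is read strictly: size 4 is dropped, size 5 is kept.
    The reference universe is unchanged.
    """
    kept = {
        name: genes
        for name, genes in catalog.categories.items()
        if name not in excluded_names and len(genes) >= min_size
    }
    return PathwayCatalog(categories=kept, reference_universe=catalog.reference_universe)


def completeness_table(
    catalog: PathwayCatalog, selected_genes: set[str]
) -> pd.DataFrame:
    """Completeness of every catalog category, ranked.

    Selected genes absent from the reference universe are ignored with a
    warning (guards against annotation-version drift between the selection
    and the catalog).
    """
    stray = selected_genes - set(catalog.reference_universe)
    if stray:
        warnings.warn(
            f"{len(stray)} selected genes absent from the reference universe "
            "were ignored",
            stacklevel=2,
        )
        selected_genes = selected_genes & set(catalog.reference_universe)
    rows = []
    for name, genes in catalog.categories.items():
        n_coreg, n_total, percent = completeness(genes, selected_genes)
        rows.append(
            {
                "category": name,
                "n_coregulated": n_coreg,
                "n_total": n_total,
                "percent": percent,
            }
        )
    table = pd.DataFrame(rows, columns=["category", "n_coregulated", "n_total", "percent"])
    return rank_categories(table)


def rank_categories(rows: pd.DataFrame) -> pd.DataFrame:
    """Order rows by completeness, deterministically.

    Descending percent; ties broken by larger category first, then by
    category name.  Rank 1 is the most complete category.
    """
    if rows.empty:
        out = rows.copy()
        out["rank"] = pd.Series(dtype=int)
        return out
    out = rows.sort_values(
        by=["percent", "n_total", "category"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["rank"] = range(1, len(out) + 1)
    return out
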