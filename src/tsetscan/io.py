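"""Readers and writers for the pipeline's delimited-text dialects.

All tables are UTF-8 delimited text with a mandatory header row; the
delimiter is auto-detected from the extension (``.csv`` -> comma, anything
else -> tab).  Gene x sample matrices carry gene ids in the first column;
empty cells mean "not evaluated".
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .coregulation import CoreSubunitSet, ExpressionDataset
from .errors import InputIntegrityError
from .ocean import SAMPLE_KEY
from .pathways import PathwayCatalog

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _sep(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _to_bool(series: pd.Series) -> pd.Series:
    def conv(v: object) -> bool:
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        if s in _TRUE:
            return True
        if s in _FALSE:
            return False
        raise InputIntegrityError(f"cannot parse boolean value {v!r}")

    return series.map(conv)


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep=_sep(path), index=index)


def read_manifest(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=_sep(path), dtype=str)
    required = {"library_id", "species", "taxon_group", "lineage", "data_type"}
    missing = required - set(frame.columns)
    if missing:
        raise InputIntegrityError(f"manifest missing columns: {sorted(missing)}")
    return frame


def read_detections(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=_sep(path), dtype=str)
    required = {"library_id", "panel", "subunit", "detected", "validated"}
    missing = required - set(frame.columns)
    if missing:
        raise InputIntegrityError(f"detection table missing columns: {sorted(missing)}")
    frame["detected"] = _to_bool(frame["detected"])
    frame["validated"] = _to_bool(frame["validated"])
    return frame


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Genes x samples matrix; first column is the gene id."""
    frame = pd.read_csv(path, sep=_sep(path), index_col=0)
    return frame.astype(float)


def read_platform_manifest(path: str | Path) -> dict[str, str]:
    """Two columns: sample_id, platform."""
    frame = pd.read_csv(path, sep=_sep(path), dtype=str)
    if not {"sample_id", "platform"} <= set(frame.columns):
        raise InputIntegrityError("platform manifest needs sample_id and platform")
    if frame["sample_id"].duplicated().any():
        raise InputIntegrityError("duplicate sample_id in platform manifest")
    return dict(zip(frame["sample_id"], frame["platform"]))


def split_by_platform(
    matrix: pd.DataFrame, sample_platform: dict[str, str]
) -> list[ExpressionDataset]:
    """Split a fused matrix into per-platform datasets.

    Genes entirely missing on a platform are dropped from that platform's
    dataset (they were not evaluated there).
    """
    unknown = set(matrix.columns) - set(sample_platform)
    if unknown:
        raise InputIntegrityError(f"samples without a platform: {sorted(unknown)[:5]}")
    datasets = []
    platforms = sorted(set(sample_platform[c] for c in matrix.columns))
    for platform in platforms:
        cols = [c for c in matrix.columns if sample_platform[c] == platform]
        block = matrix[cols]
        block = block.dropna(how="all")
        datasets.append(ExpressionDataset(platform=platform, values=block))
    return datasets


def read_core_set(path: str | Path) -> CoreSubunitSet:
    """Core set as JSON: {"members": {role: gene}, "excluded_paralogues": [...]}."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return CoreSubunitSet(
        members=dict(raw["members"]),
        excluded_paralogues=frozenset(raw.get("excluded_paralogues", [])),
    )


def read_catalog(
    path: str | Path, universe_path: str | Path | None = None
) -> PathwayCatalog:
    """Catalog as two-column text (gene, category) or KEGG-Mapper-like JSON.

    For the two-column form the reference universe defaults to the union of
    listed genes unless a one-column universe file is given.
    """
    if str(path).lower().endswith(".json"):
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        categories = {k: frozenset(v) for k, v in raw["categories"].items()}
        universe = frozenset(
            raw.get("reference_universe")
            or {g for genes in categories.values() for g in genes}
        )
        return PathwayCatalog(categories=categories, reference_universe=universe)
    frame = pd.read_csv(path, sep=_sep(path), dtype=str)
    if not {"gene", "category"} <= set(frame.columns):
        raise InputIntegrityError("catalog needs gene and category columns")
    categories = {
        str(name): frozenset(sub["gene"])
        for name, sub in frame.groupby("category", sort=True)
    }
    if universe_path is not None:
        uni = pd.read_csv(universe_path, sep=_sep(universe_path), dtype=str)
        universe = frozenset(uni.iloc[:, 0])
    else:
        universe = frozenset(frame["gene"])
    return PathwayCatalog(categories=categories, reference_universe=universe)


def write_catalog(catalog: PathwayCatalog, path: str | Path) -> None:
    rows = [
        {"gene": g, "category": name}
        for name, genes in catalog.categories.items()
        for g in sorted(genes)
    ]
    write_table(pd.DataFrame(rows, columns=["gene", "category"]), path)


def read_gene_list(path: str | Path) -> set[str]:
    """Plain one-column id list (header optional: 'gene' is recognized)."""
    with open(path, encoding="utf-8") as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if ids and ids[0].lower() == "gene":
        ids = ids[1:]
    return set(ids)


def read_abundance(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=_sep(path))
    required = {"transcript_id", "subunit", "taxon", *SAMPLE_KEY, "abundance"}
    missing = required - set(frame.columns)
    if missing:
        raise InputIntegrityError(f"abundance table missing columns: {sorted(missing)}")
    frame["abundance"] = frame["abundance"].astype(float)
    return frame


def read_group_totals(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=_sep(path))
    missing = {*SAMPLE_KEY, "group_total"} - set(frame.columns)
    if missing:
        raise InputIntegrityError(f"group totals missing columns: {sorted(missing)}")
    frame["group_total"] = frame["group_total"].astype(float)
    return frame


def read_env(path: str | Path) -> pd.DataFrame:
    """Environmental table, returned indexed by the sample key."""
    frame = pd.read_csv(path, sep=_sep(path))
    missing = set(SAMPLE_KEY) - set(frame.columns)
    if missing:
        raise InputIntegrityError(f"env table missing columns: {sorted(missing)}")
    return frame.set_index(SAMPLE_KEY).astype(float)
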