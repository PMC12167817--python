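"""Percentile-rank expression fusion and core-gene coregulation scoring.

The expression substrate is a meta-dataset fused from heterogeneous
platforms (RNA-seq relative abundances and microarray fold-changes).  Raw
values are never compared across platforms: each sample (column) is
independently transformed to percentile ranks on a 0-100 scale, where 100
is the most highly expressed gene in that sample and 0 the lowest.  Genes
not evaluated on a platform stay missing (NaN) for all of its samples so
that absence never biases a correlation.

Coregulation with the complex is then scored per gene as the mean Pearson
correlation between rank profiles over the samples shared with each member
of a small "core" gene set — Pearson on ranks, i.e. a Spearman-type
statistic.  Two ranking orientations are provided:

* ``per_sample`` (default): genes are ranked within each sample, and the
  correlation is taken across samples between two genes' rank profiles;
* ``per_gene``: textbook Spearman, each gene's profile is ranked across the
  shared samples before the Pearson step.

Missing values are handled pairwise-complete; a correlation over fewer
than ``min_overlap`` shared samples, or with a constant profile on the
overlap, is undefined (NaN) rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, EmptyRankError, InputIntegrityError

RNASEQ = "rnaseq_abundance"
MICROARRAY = "microarray_foldchange"


@dataclass
class ExpressionDataset:
    """A gene x sample matrix from one platform; NaN marks 'not evaluated'."""

    platform: str
    values: pd.DataFrame  # genes in rows, samples in columns; NaN = missing

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise InputIntegrityError("duplicate sample ids within a dataset")
        if self.values.index.duplicated().any():
            raise InputIntegrityError("duplicate gene ids within a dataset")


@dataclass
class RankedExpressionMatrix:
    """Fused, per-sample percentile-ranked matrix (NaN = missing).

    ``raw`` keeps the fused untransformed values for the per-gene
    (textbook Spearman) correlation mode.
    """

    ranks: pd.DataFrame
    raw: pd.DataFrame
    sample_platform: dict[str, str]

    @property
    def genes(self) -> pd.Index:
        return self.ranks.index

    @property
    def samples(self) -> pd.Index:
        return self.ranks.columns


@dataclass
class CoreSubunitSet:
    """The core gene set the coregulation score is taken against.

    Defaults are the four central TSET subunit genes of the
    Phaeodactylum tricornutum version-3 annotation; the two paralogues with
    limited coregulation to the rest of the complex are excluded.
    """

    members: dict[str, str] = field(
        default_factory=lambda: {
            "TCUP": "Phatr3_J43047",
            "TPLATE": "Phatr3_J54511",
            "TSPOON": "Phatr3_J54718",
            "TTRAY": "Phatr3_J46356",
        }
    )
    excluded_paralogues: frozenset[str] = frozenset(
        {"Phatr3_J43761", "Phatr3_J14536"}
    )

    def __post_init__(self) -> None:
        if not self.members:
            raise ConfigurationError("core set must have at least one member")
        if set(self.members.values()) & self.excluded_paralogues:
            raise ConfigurationError("core members overlap excluded paralogues")


def percentile_rank(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rank a vector to [0, 100], averaging ties, preserving NaN.

    Non-missing entries receive average ranks 1..n rescaled as
    ``100*(rank-1)/(n-1)``; an all-tied (or singleton) vector maps to 50.
    """
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n == 0:
        raise EmptyRankError("cannot rank an all-missing vector")
    out = np.full(x.shape, np.nan)
    if n == 1:
        out[obs] = 50.0
        return out
    r = stats.rankdata(x[obs], method="average")
    out[obs] = 100.0 * (r - 1.0) / (n - 1.0)
    return out


def fuse_platforms(datasets: list[ExpressionDataset]) -> RankedExpressionMatrix:
    """Fuse platform matrices on the union of genes and rank each sample.

    Sample axes are concatenated (ids must be globally unique); a gene
    absent from a platform is missing for all of that platform's samples.
    """
    if not datasets:
        raise ConfigurationError("need at least one dataset to fuse")
    all_samples = [s for d in datasets for s in d.values.columns]
    if len(all_samples) != len(set(all_samples)):
        raise InputIntegrityError("duplicate sample ids across platforms")
    genes: list[str] = []
    seen: set[str] = set()
    for d in datasets:
        for g in d.values.index:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    raw = pd.concat(
        [d.values.reindex(index=genes) for d in datasets], axis=1
    )
    ranks = raw.copy()
    for col in ranks.columns:
        ranks[col] = percentile_rank(raw[col].to_numpy())
    sample_platform = {
        s: d.platform for d in datasets for s in d.values.columns
    }
    return RankedExpressionMatrix(ranks=ranks, raw=raw, sample_platform=sample_platform)


def _masked_pearson(x: np.ndarray, y: np.ndarray, min_overlap: int) -> tuple[float, int]:
    both = ~np.isnan(x) & ~np.isnan(y)
    n = int(both.sum())
    if n < max(min_overlap, 2):
        return np.nan, n
    xs, ys = x[both], y[both]
    if np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
        return np.nan, n  # constant profile: correlation undefined, not 0
    # symmetric formula: cov/sqrt(varx*vary) is bit-identical under swap,
    # unlike np.corrcoef whose normalization order depends on the argument order
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    return r, n


def pairwise_corr(
    ranked: RankedExpressionMatrix,
    gene_a: str,
    gene_b: str,
    min_overlap: int = 10,
    mode: str = "per_sample",
) -> tuple[float, int]:
    """Correlation between two genes' profiles over their shared samples.

    Returns ``(r, n_shared)``; ``r`` is NaN when undefined.  In
    ``per_sample`` mode the profiles are the fused per-sample ranks; in
    ``per_gene`` mode the raw profiles are re-ranked across the shared
    samples (textbook Spearman).
    """
    for g in (gene_a, gene_b):
        if g not in ranked.genes:
            raise KeyError(f"unknown gene id: {g}")
    if mode == "per_sample":
        x = ranked.ranks.loc[gene_a].to_numpy(dtype=float)
        y = ranked.ranks.loc[gene_b].to_numpy(dtype=float)
        return _masked_pearson(x, y, min_overlap)
    if mode == "per_gene":
        x = ranked.raw.loc[gene_a].to_numpy(dtype=float)
        y = ranked.raw.loc[gene_b].to_numpy(dtype=float)
        both = ~np.isnan(x) & ~np.isnan(y)
        n = int(both.sum())
        if n < max(min_overlap, 2):
            return np.nan, n
        xs = stats.rankdata(x[both], method="average")
        ys = stats.rankdata(y[both], method="average")
        if np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
            return np.nan, n
        return float(np.corrcoef(xs, ys)[0, 1]), n
    raise ConfigurationError(f"unknown mode {mode!r}")


def core_score(
    ranked: RankedExpressionMatrix,
    gene: str,
    core: CoreSubunitSet | None = None,
    min_overlap: int = 10,
    mode: str = "per_sample",
) -> tuple[float, int]:
    """Mean correlation of one gene to the defined core members.

    Undefined member correlations are skipped (not zero-imputed); with no
    defined member the score itself is NaN and the gene should be flagged,
    never silently dropped.  Returns ``(mean_r, n_defined_members)``.
    """
    core = core or CoreSubunitSet()
    rs = []
    for member in core.members.values():
        if member not in ranked.genes:
            continue
        r, _ = pairwise_corr(ranked, gene, member, min_overlap=min_overlap, mode=mode)
        if not np.isnan(r):
            rs.append(r)
    if not rs:
        return np.nan, 0
    return float(np.mean(rs)), len(rs)


def coregulation_table(
    ranked: RankedExpressionMatrix,
    core: CoreSubunitSet | None = None,
    min_overlap: int = 10,
    threshold: float = 0.5,
    mode: str = "per_sample",
) -> pd.DataFrame:
    """Score every gene in the matrix against the core set.

    Columns: one ``r_<role>`` and ``n_<role>`` per core member, plus
    ``mean_core_r``, ``n_core_members`` and the boolean ``selected``
    (``mean_core_r`` strictly above ``threshold``).
    """
    core = core or CoreSubunitSet()
    missing_core = [g for g in core.members.values() if g not in ranked.genes]
    if missing_core:
        raise InputIntegrityError(f"core genes absent from matrix: {missing_core}")
    out = pd.DataFrame(index=ranked.genes.copy())
    member_rs = []
    for role, member in core.members.items():
        rs = np.empty(len(ranked.genes))
        ns = np.empty(len(ranked.genes), dtype=int)
        for i, g in enumerate(ranked.genes):
            rs[i], ns[i] = pairwise_corr(
                ranked, g, member, min_overlap=min_overlap, mode=mode
            )
        out[f"r_{role}"] = rs
        out[f"n_{role}"] = ns
        member_rs.append(rs)
    stacked = np.vstack(member_rs)
    defined = ~np.isnan(stacked)
    n_def = defined.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_r = np.where(n_def > 0, np.nanmean(stacked, axis=0), np.nan)
    out["mean_core_r"] = mean_r
    out["n_core_members"] = n_def
    out["selected"] = (mean_r > threshold) & (n_def > 0)
    return out


def threshold_select(table: pd.DataFrame, threshold: float = 0.5) -> set[str]:
    """Genes whose defined mean core correlation strictly exceeds the threshold."""
    if table.empty:
        return set()
    m = table["mean_core_r"]
    keep = m.notna() & (m > threshold)
    return set(table.index[keep])
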