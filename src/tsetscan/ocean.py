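"""Environmental metatranscriptome analysis of complex-subunit transcripts.

Operates on long-format station abundance exports: one row per transcript
with a subunit assignment, a taxon annotation, a sample key (station, depth
layer, size fraction) and an abundance expressed as a fraction of total
reads in the sample.  The analysis chain is:

1. restrict to the taxon of interest (default diatoms, "Bacillariophyta");
2. normalize each abundance by the group's total abundance in the same
   sample, removing the ecological-preference signal of the group itself;
3. summarize per station (mean of surface and DCM layers) and per subunit;
4. correlate normalized subunit abundances with environmental covariates
   (textbook Spearman, pairwise-complete);
5. impute missing covariates by regularized iterative PCA and decompose the
   (covariates + total abundance) table by PCA.

Samples from different size fractions are never pooled; analyses run per
fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import ConfigurationError, InputIntegrityError

SAMPLE_KEY = ["station", "depth_layer", "size_fraction"]
DEPTH_LAYERS = ("SRF", "DCM")
DEFAULT_SIZE_FRACTION = "0.8-2000um"
DEFAULT_TAXON = "Bacillariophyta"


def taxon_filter(
    records: pd.DataFrame, target_taxon: str = DEFAULT_TAXON
) -> pd.DataFrame:
    """Keep records whose taxon annotation exactly matches the target."""
    kept = records[records["taxon"] == target_taxon].copy()
    n_removed = len(records) - len(kept)
    if kept.empty:
        warnings.warn(f"no records annotated as {target_taxon!r}", stacklevel=2)
    elif n_removed:
        warnings.warn(
            f"taxon filter removed {n_removed} of {len(records)} records",
            stacklevel=2,
        )
    return kept


def normalize_by_group_total(
    records: pd.DataFrame, group_totals: pd.DataFrame
) -> pd.DataFrame:
    """Divide each abundance by the taxon-group total of its sample.

    ``group_totals`` has the sample key columns plus ``group_total`` (the
    summed fraction-of-total-reads of all the group's transcripts in that
    sample).  Samples without a group total are skipped with a warning; a
    zero total alongside a nonzero abundance is an inconsistency error.
    Adds a ``normalized`` column.
    """
    gt = group_totals.set_index(SAMPLE_KEY)["group_total"]
    if gt.index.duplicated().any():
        raise InputIntegrityError("duplicate sample keys in group totals")
    keys = pd.MultiIndex.from_frame(records[SAMPLE_KEY])
    totals = gt.reindex(keys).to_numpy(dtype=float)
    missing = np.isnan(totals)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} records in samples without a group total "
            "were skipped",
            stacklevel=2,
        )
    ab = records["abundance"].to_numpy(dtype=float)
    bad = (totals == 0) & (ab > 0) & ~missing
    if bad.any():
        raise InputIntegrityError(
            "zero group total in a sample with nonzero abundance"
        )
    out = records.loc[~missing].copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = ab[~missing] / totals[~missing]
    out["normalized"] = np.where(ab[~missing] == 0, 0.0, norm)
    return out


def station_mean(srf: float | None, dcm: float | None) -> float:
    """Mean of the available depth layers; a single layer stands alone."""
    vals = [v for v in (srf, dcm) if v is not None and not np.isnan(v)]
    if not vals:
        raise ConfigurationError("station_mean needs at least one layer")
    return float(np.mean(vals))


def station_summary(
    records: pd.DataFrame, panel: tuple[str, ...] | list[str] | None = None
) -> pd.DataFrame:
    """Per-station totals and subunit presence.

    ``normalized_total`` is the sum of normalized abundances over the panel
    subunits within a layer, averaged over the layers available at the
    station.  ``present_<subunit>`` is True iff any transcript of that
    subunit was detected at the station in any layer.
    """
    if "normalized" not in records.columns:
        raise InputIntegrityError("records must be normalized first")
    if panel is None:
        panel = tuple(sorted(records["subunit"].unique()))
    rec = records[records["subunit"].isin(set(panel))]
    layer_tot = (
        rec.groupby(["station", "depth_layer"])["normalized"].sum().rename("total")
    )
    per_station = layer_tot.groupby("station").mean()
    rows = []
    for station, total in per_station.items():
        row: dict[str, object] = {"station": station, "normalized_total": total}
        at_station = rec[rec["station"] == station]
        for s in panel:
            row[f"present_{s}"] = bool((at_station["subunit"] == s).any())
        rows.append(row)
    return pd.DataFrame(rows)


def abundance_by_sample(
    records: pd.DataFrame, panel: tuple[str, ...] | list[str]
) -> pd.DataFrame:
    """Pivot normalized abundances to a sample x subunit matrix.

    Samples are all (station, depth, fraction) keys present in the records;
    a subunit undetected in a sample contributes 0 there.  A subunit never
    detected anywhere yields an all-zero column, which downstream
    correlation reports as undefined (blank).
    """
    wide = records.pivot_table(
        index=SAMPLE_KEY,
        columns="subunit",
        values="normalized",
        aggfunc="sum",
        fill_value=0.0,
    )
    return wide.reindex(columns=list(panel), fill_value=0.0)


def env_correlate(
    abundances: pd.DataFrame,
    env: pd.DataFrame,
    min_overlap: int = 5,
) -> pd.DataFrame:
    """Spearman correlation of each subunit column with each covariate.

    Both tables are indexed by sample key; only samples present in both are
    used, pairwise-complete over missing covariate values.  Cells with
    fewer than ``min_overlap`` paired values, or with a constant variable
    on the overlap (e.g. a never-detected subunit), are NaN.
    """
    joined_idx = abundances.index.intersection(env.index)
    ab = abundances.loc[joined_idx]
    ev = env.loc[joined_idx]
    out = pd.DataFrame(
        index=pd.Index(ab.columns, name="subunit"),
        columns=pd.Index(ev.columns, name="covariate"),
        dtype=float,
    )
    for sub in ab.columns:
        x = ab[sub].to_numpy(dtype=float)
        for cov in ev.columns:
            y = ev[cov].to_numpy(dtype=float)
            both = ~np.isnan(x) & ~np.isnan(y)
            n = int(both.sum())
            if n < max(min_overlap, 2):
                continue
            xs, ys = x[both], y[both]
            if np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
                continue
            rho = stats.spearmanr(xs, ys).statistic
            out.loc[sub, cov] = float(rho)
    return out


@dataclass
class PCAResult:
    """Loadings (variables x components), scores (samples x components),
    explained-variance fractions, and the imputed standardized table."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    imputed: pd.DataFrame
    n_iterations: int


def _regularized_svd_impute(
    z: np.ndarray, mask: np.ndarray, k: int, max_iter: int, tol: float
) -> tuple[np.ndarray, int]:
    """EM-style iterative SVD imputation with eigenvalue shrinkage.

    ``mask`` is True where values are missing; missing entries start at 0
    (the column mean on the standardized scale) and are refilled from a
    rank-``k`` reconstruction whose singular values are shrunk by the mean
    residual eigenvalue, damping overfit to noise.
    """
    z = z.copy()
    z[mask] = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        if k < len(s):
            sigma2 = float(np.mean(s[k:] ** 2))
        else:
            sigma2 = 0.0
        s_shrunk = np.where(s[:k] > 0, np.maximum(s[:k] - sigma2 / np.maximum(s[:k], 1e-12), 0.0), 0.0)
        recon = (u[:, :k] * s_shrunk) @ vt[:k]
        delta = np.max(np.abs(recon[mask] - z[mask])) if mask.any() else 0.0
        z[mask] = recon[mask]
        if delta < tol:
            break
    return z, it


def impute_and_pca(
    table: pd.DataFrame,
    n_components: int = 3,
    n_impute_components: int = 2,
    seed: int | None = 0,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> PCAResult:
    """Impute missing covariates, standardize, and decompose by PCA.

    ``table`` is samples x variables (environmental covariates plus the
    complex's total normalized abundance).  Variables are centered and
    scaled to unit variance using their observed values; missing entries
    are filled by regularized iterative PCA imputation with
    ``n_impute_components`` components; a complete table passes through
    unchanged.  Columns that are entirely missing are dropped with a
    warning.
    """
    tab = table.astype(float)
    all_missing = tab.columns[tab.isna().all()]
    if len(all_missing):
        warnings.warn(
            f"dropping entirely-missing columns: {list(all_missing)}", stacklevel=2
        )
        tab = tab.drop(columns=list(all_missing))
    mu = tab.mean(skipna=True)
    sd = tab.std(skipna=True, ddof=0)
    if (sd == 0).any():
        constant = list(tab.columns[(sd == 0).to_numpy()])
        warnings.warn(f"dropping constant columns: {constant}", stacklevel=2)
        tab = tab.drop(columns=constant)
        mu = mu.drop(constant)
        sd = sd.drop(constant)
    z = ((tab - mu) / sd).to_numpy()
    mask = np.isnan(z)
    n_complete = int((~np.isnan(z).any(axis=1)).sum())
    if n_complete < n_components + 1:
        raise ConfigurationError(
            f"need at least {n_components + 1} complete-enough samples, "
            f"have {n_complete}"
        )
    n_iter = 0
    if mask.any():
        z, n_iter = _regularized_svd_impute(
            z, mask, k=min(n_impute_components, min(z.shape) - 1), max_iter=max_iter, tol=tol
        )
    imputed = pd.DataFrame(z, index=tab.index, columns=tab.columns)
    n_components = min(n_components, min(z.shape))
    pca = PCA(n_components=n_components, random_state=seed)
    scores = pca.fit_transform(z)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        loadings=pd.DataFrame(pca.components_.T, index=tab.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=tab.index, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        imputed=imputed,
        n_iterations=n_iter,
    )


def subunit_ratio(
    records: pd.DataFrame,
    numerator_subunit: str = "TCUP",
    denominator_subunit: str = "AP2mu",
) -> pd.Series:
    """Per-station ratio of two subunits' normalized abundances.

    Each subunit's per-station value is its layer-summed normalized
    abundance averaged over the available depth layers.  Stations where the
    denominator is absent or zero get NaN (undefined), never infinity.
    """
    if "normalized" not in records.columns:
        raise InputIntegrityError("records must be normalized first")

    def per_station(subunit: str) -> pd.Series:
        rec = records[records["subunit"] == subunit]
        if rec.empty:
            return pd.Series(dtype=float)
        layer = rec.groupby(["station", "depth_layer"])["normalized"].sum()
        return layer.groupby("station").mean()

    num = per_station(numerator_subunit)
    den = per_station(denominator_subunit)
    stations = num.index.union(den.index)
    num = num.reindex(stations, fill_value=0.0)
    den = den.reindex(stations)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    ratio[den.isna() | (den == 0)] = np.nan
    ratio.name = f"{numerator_subunit}:{denominator_subunit}"
    return ratio
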