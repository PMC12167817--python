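"""Ocean stage: taxon filtering, group-total normalization, station
summaries, environmental correlation, imputation+PCA and subunit ratios."""

import numpy as np
import pandas as pd
import pytest

from tsetscan import (
    TSET_PANEL,
    abundance_by_sample,
    env_correlate,
    impute_and_pca,
    normalize_by_group_total,
    station_mean,
    station_summary,
    subunit_ratio,
    taxon_filter,
)
from tsetscan.errors import ConfigurationError, InputIntegrityError
from tsetscan.ocean import SAMPLE_KEY
from tsetscan.simulate import OceanConfig, gen_stations


def _rec(subunit, station, layer, abundance, taxon="Bacillariophyta"):
    return {
        "transcript_id": f"{subunit}_{station}_{layer}",
        "subunit": subunit,
        "taxon": taxon,
        "station": station,
        "depth_layer": layer,
        "size_fraction": "0.8-2000um",
        "abundance": abundance,
    }


def _totals(entries):
    return pd.DataFrame(
        [
            {"station": s, "depth_layer": l, "size_fraction": "0.8-2000um",
             "group_total": t}
            for s, l, t in entries
        ]
    )


def test_taxon_filter_exact_match():
    records = pd.DataFrame(
        [_rec("TCUP", f"S{i}", "SRF", 1e-4) for i in range(10)]
        + [_rec("TCUP", f"S{i}", "SRF", 1e-4, taxon="Haptophyta") for i in range(5)]
    )
    with pytest.warns(UserWarning, match="removed 5"):
        kept = taxon_filter(records)
    assert len(kept) == 10
    assert (kept["taxon"] == "Bacillariophyta").all()


def test_taxon_filter_empty_warns():
    records = pd.DataFrame([_rec("TCUP", "S1", "SRF", 1e-4, taxon="Haptophyta")])
    with pytest.warns(UserWarning, match="no records"):
        assert taxon_filter(records).empty


def test_normalization_division_and_zero():
    records = pd.DataFrame(
        [_rec("TCUP", "S1", "SRF", 0.002), _rec("TPLATE", "S1", "SRF", 0.0)]
    )
    out = normalize_by_group_total(records, _totals([("S1", "SRF", 0.5)]))
    np.testing.assert_allclose(out["normalized"].to_numpy(), [0.004, 0.0])


def test_normalization_conservation_on_random_fixture():
    # per sample: sum(normalized) == sum(raw) / group_total, exactly
    rng = np.random.default_rng(11)
    rows, totals = [], []
    for i in range(15):
        station, layer = f"S{i // 2}", ("SRF" if i % 2 else "DCM")
        total = rng.uniform(0.1, 0.9)
        totals.append((station, layer, total))
        for s in TSET_PANEL[:4]:
            rows.append(_rec(s, station, layer, rng.uniform(0, 1e-3)))
    records = pd.DataFrame(rows)
    out = normalize_by_group_total(records, _totals(totals))
    gt = _totals(totals).set_index(SAMPLE_KEY)["group_total"]
    for key, sub in out.groupby(SAMPLE_KEY):
        assert sub["normalized"].sum() == pytest.approx(
            sub["abundance"].sum() / gt.loc[key], rel=1e-12
        )


def test_normalization_zero_total_with_abundance_raises():
    records = pd.DataFrame([_rec("TCUP", "S1", "SRF", 0.002)])
    with pytest.raises(InputIntegrityError):
        normalize_by_group_total(records, _totals([("S1", "SRF", 0.0)]))


def test_normalization_skips_samples_without_totals():
    records = pd.DataFrame(
        [_rec("TCUP", "S1", "SRF", 0.002), _rec("TCUP", "S2", "SRF", 0.001)]
    )
    with pytest.warns(UserWarning, match="skipped"):
        out = normalize_by_group_total(records, _totals([("S1", "SRF", 0.5)]))
    assert list(out["station"]) == ["S1"]


def test_normalization_scale_invariance():
    records = pd.DataFrame(
        [_rec("TCUP", "S1", "SRF", 0.002), _rec("TPLATE", "S1", "SRF", 0.003)]
    )
    a = normalize_by_group_total(records, _totals([("S1", "SRF", 0.5)]))
    scaled = records.copy()
    scaled["abundance"] *= 7.0
    b = normalize_by_group_total(scaled, _totals([("S1", "SRF", 3.5)]))
    np.testing.assert_allclose(
        a["normalized"].to_numpy(), b["normalized"].to_numpy()
    )


def test_station_mean_rules():
    assert station_mean(2e-3, 1e-3) == pytest.approx(1.5e-3)
    assert station_mean(2e-3, None) == pytest.approx(2e-3)
    assert station_mean(None, 1e-3) == pytest.approx(1e-3)
    with pytest.raises(ConfigurationError):
        station_mean(None, None)


def test_station_summary_matches_hand_means():
    rng = np.random.default_rng(5)
    rows, totals, expected = [], [], {}
    for i in range(20):
        station = f"S{i:02d}"
        layers = ["SRF", "DCM"] if i % 3 else ["SRF"]  # some single-layer stations
        layer_sums = []
        for layer in layers:
            totals.append((station, layer, 0.5))
            layer_sum = 0.0
            for s in ("TCUP", "TPLATE"):
                ab = rng.uniform(0, 1e-3)
                rows.append(_rec(s, station, layer, ab))
                layer_sum += ab / 0.5
            layer_sums.append(layer_sum)
        expected[station] = float(np.mean(layer_sums))
    out = normalize_by_group_total(pd.DataFrame(rows), _totals(totals))
    summary = station_summary(out, ("TCUP", "TPLATE", "TSAUCER")).set_index("station")
    for station, value in expected.items():
        assert summary.loc[station, "normalized_total"] == pytest.approx(value)
        assert summary.loc[station, "present_TCUP"]
        assert not summary.loc[station, "present_TSAUCER"]


def test_station_summary_requires_normalized():
    with pytest.raises(InputIntegrityError):
        station_summary(pd.DataFrame([_rec("TCUP", "S1", "SRF", 1e-4)]))


def _env_frame(rows):
    return pd.DataFrame(rows).set_index(SAMPLE_KEY)


def test_env_correlate_perfect_monotone():
    rows, env_rows = [], []
    for i in range(12):
        station = f"S{i:02d}"
        rows.append(_rec("TCUP", station, "SRF", (i + 1) * 1e-4))
        env_rows.append(
            {"station": station, "depth_layer": "SRF",
             "size_fraction": "0.8-2000um", "temperature": 30.0 - i}
        )
    norm = normalize_by_group_total(
        pd.DataFrame(rows), _totals([(f"S{i:02d}", "SRF", 0.5) for i in range(12)])
    )
    wide = abundance_by_sample(norm, ("TCUP", "TSAUCER"))
    corr = env_correlate(wide, _env_frame(env_rows), min_overlap=5)
    assert corr.loc["TCUP", "temperature"] == pytest.approx(-1.0)
    assert np.isnan(corr.loc["TSAUCER", "temperature"])  # never detected -> blank


def test_env_correlate_bounds_and_permutation_invariance():
    cfg = OceanConfig(n_stations=25)
    records, totals, env = gen_stations(cfg, seed=9)
    with pytest.warns(UserWarning):
        norm = normalize_by_group_total(taxon_filter(records), totals)
    wide = abundance_by_sample(norm, TSET_PANEL)
    env_idx = env.set_index(SAMPLE_KEY)
    corr = env_correlate(wide, env_idx)
    defined = corr.to_numpy()[~np.isnan(corr.to_numpy())]
    assert ((defined >= -1.0) & (defined <= 1.0)).all()
    perm = np.random.default_rng(2).permutation(len(wide))
    corr_perm = env_correlate(wide.iloc[perm], env_idx)
    pd.testing.assert_frame_equal(corr, corr_perm)


def test_impute_and_pca_complete_table_identity():
    rng = np.random.default_rng(4)
    table = pd.DataFrame(
        rng.standard_normal((30, 5)), columns=[f"v{i}" for i in range(5)]
    )
    res = impute_and_pca(table, n_components=5, seed=0)
    standardized = (table - table.mean()) / table.std(ddof=0)
    pd.testing.assert_frame_equal(res.imputed, standardized)
    assert res.n_iterations == 0
    assert res.explained_variance_ratio.sum() == pytest.approx(1.0)
    gram = res.scores.to_numpy().T @ res.scores.to_numpy()
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8  # component scores orthogonal


def test_impute_and_pca_duplicate_column_gets_equal_loadings():
    rng = np.random.default_rng(6)
    table = pd.DataFrame(
        rng.standard_normal((40, 3)), columns=["v0", "v1", "v2"]
    )
    table["v2"] = table["v0"] * 2.0 + 1.0  # same variable after standardization
    res = impute_and_pca(table, n_components=3, seed=0)
    # equality holds on every component carrying variance; the null
    # component's direction is arbitrary for an exactly rank-deficient table
    informative = res.explained_variance_ratio > 1e-12
    np.testing.assert_allclose(
        res.loadings.loc["v0"].to_numpy()[informative],
        res.loadings.loc["v2"].to_numpy()[informative],
        atol=1e-10,
    )


def test_impute_and_pca_drops_all_missing_column():
    rng = np.random.default_rng(8)
    table = pd.DataFrame(
        rng.standard_normal((20, 3)), columns=["v0", "v1", "v2"]
    )
    table["dead"] = np.nan
    with pytest.warns(UserWarning, match="entirely-missing"):
        res = impute_and_pca(table, n_components=2, seed=0)
    assert "dead" not in res.loadings.index


def test_impute_and_pca_recovers_structure_under_masking():
    rng = np.random.default_rng(12)
    scores = rng.standard_normal(60)
    loadings = rng.uniform(0.5, 1.0, 6)
    table = pd.DataFrame(
        np.outer(scores, loadings) + 0.1 * rng.standard_normal((60, 6)),
        columns=[f"v{i}" for i in range(6)],
    )
    full = impute_and_pca(table, n_components=3, seed=0)
    masked = table.copy()
    mask = rng.random(table.shape) < 0.10
    masked = masked.mask(pd.DataFrame(mask, columns=table.columns))
    imput = impute_and_pca(masked, n_components=3, seed=0)
    gap = abs(
        full.explained_variance_ratio[0] - imput.explained_variance_ratio[0]
    )
    assert gap < 0.05


def test_subunit_ratio_division_and_zero_handling():
    rows = [
        _rec("TCUP", "S1", "SRF", 1e-4),
        _rec("AP2mu", "S1", "SRF", 2e-4),
        _rec("AP2mu", "S2", "SRF", 3e-4),  # TCUP absent at S2
        _rec("TCUP", "S3", "SRF", 1e-4),  # AP2mu absent at S3
    ]
    norm = normalize_by_group_total(
        pd.DataFrame(rows),
        _totals([("S1", "SRF", 0.5), ("S2", "SRF", 0.5), ("S3", "SRF", 0.5)]),
    )
    ratio = subunit_ratio(norm)
    assert ratio["S1"] == pytest.approx(0.5)
    assert ratio["S2"] == 0.0
    assert np.isnan(ratio["S3"])


def test_subunit_ratio_below_one_on_planted_fixture():
    """AP2mu is planted to outnumber TCUP, so every defined station ratio
    is below 1."""
    records, totals, _ = gen_stations(OceanConfig(), seed=3)
    with pytest.warns(UserWarning):
        norm = normalize_by_group_total(taxon_filter(records), totals)
    ratio = subunit_ratio(norm).dropna()
    assert len(ratio) == 60
    assert (ratio < 1.0).all()
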