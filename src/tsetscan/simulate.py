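"""Seed-reproducible synthetic inputs for every pipeline stage.

Each generator plants a known structure so recovery can be tested without
any downloaded data:

* ``gen_detection_table`` — Bernoulli subunit detections per library at
  group-specific rates, with a configurable fraction of libraries failing
  the two-AP1-subunit gate;
* ``gen_expression`` — a single latent expression program shared by a
  planted gene module (which contains the core subunit genes), observed on
  two platforms through strictly increasing distortions, with missing data;
* ``gen_pathways`` — a category catalog in which one category is seeded
  with planted-module genes;
* ``gen_stations`` — station/depth transcript abundances with a planted
  negative temperature association on the softplus scale, plus group
  totals so normalization is exercised, and a partially missing
  environmental table.

Realism is limited to the statistical structure the analyses assume; no
attempt is made to match real taxonomic compositions or expression
distributions.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .census import AP1_PANEL, TSET_PANEL
from .coregulation import MICROARRAY, RNASEQ, CoreSubunitSet, ExpressionDataset
from .errors import ConfigurationError
from .ocean import DEFAULT_SIZE_FRACTION, DEPTH_LAYERS
from .pathways import PathwayCatalog

DISTORTIONS = {
    "identity": lambda x: x,
    "cbrt": np.cbrt,
    "scaled_exp": lambda x: np.exp(x / 2.0),
}


@dataclass
class CensusGroupConfig:
    name: str
    n_libraries: int
    detection_prob: dict[str, float] | float = 0.5
    ap1_dropout: float = 0.0

    def prob(self, subunit: str) -> float:
        if isinstance(self.detection_prob, dict):
            return self.detection_prob.get(subunit, 0.0)
        return self.detection_prob


@dataclass
class CensusConfig:
    groups: list[CensusGroupConfig] = field(
        default_factory=lambda: [
            CensusGroupConfig("Diatoms", 40, {s: p for s, p in zip(
                TSET_PANEL, (0.75, 0.2, 0.8, 0.0, 0.6, 0.55))}, ap1_dropout=0.1),
            CensusGroupConfig("Oomycetes", 25, {s: p for s, p in zip(
                TSET_PANEL, (0.6, 0.1, 0.7, 0.04, 0.5, 0.4))}, ap1_dropout=0.15),
            CensusGroupConfig("Haptophytes", 20, {s: p for s, p in zip(
                TSET_PANEL, (0.65, 0.05, 0.3, 0.0, 0.25, 0.2))}, ap1_dropout=0.1),
        ]
    )


@dataclass
class PlatformConfig:
    platform: str
    n_samples: int
    distortion: str = "identity"
    missing_rate: float = 0.1
    absent_gene_fraction: float = 0.0


@dataclass
class ExpressionConfig:
    n_genes: int = 200
    module_size: int = 20
    latent_loading: float = 0.9
    noise_sd: float = 0.3
    platforms: list[PlatformConfig] = field(
        default_factory=lambda: [
            PlatformConfig(RNASEQ, 30, "identity", 0.1),
            PlatformConfig(MICROARRAY, 30, "cbrt", 0.1),
        ]
    )


@dataclass
class PathwayConfig:
    n_categories: int = 10
    size_range: tuple[int, int] = (5, 30)
    planted_category: str = "Membrane trafficking"
    planted_fraction: float = 0.8


@dataclass
class OceanConfig:
    n_stations: int = 60
    env_means: dict[str, float] = field(
        default_factory=lambda: {
            "temperature": 15.0, "oxygen": 220.0, "nitrate": 5.0,
            "phosphate": 0.5, "silicate": 10.0, "salinity": 35.0,
            "density": 1025.0, "par": 30.0,
        }
    )
    env_sds: dict[str, float] = field(
        default_factory=lambda: {
            "temperature": 8.0, "oxygen": 40.0, "nitrate": 3.0,
            "phosphate": 0.3, "silicate": 6.0, "salinity": 1.5,
            "density": 2.0, "par": 15.0,
        }
    )
    abundance_temperature_slope: float = 0.05
    noise_sd: float = 0.3
    intercept: float = -8.2
    ap2mu_offset: float = 1.4  # AP2mu typically outnumbers TCUP
    detection_floor: dict[str, float] = field(
        default_factory=lambda: {"TSAUCER": np.inf}
    )
    missing_env_rate: float = 0.1
    size_fraction: str = DEFAULT_SIZE_FRACTION
    n_offtarget_per_sample: int = 1


@dataclass
class SimConfig:
    seed: int = 0
    census: CensusConfig = field(default_factory=CensusConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    pathway: PathwayConfig = field(default_factory=PathwayConfig)
    ocean: OceanConfig = field(default_factory=OceanConfig)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        if "census" in raw:
            cfg.census = CensusConfig(
                groups=[CensusGroupConfig(**g) for g in raw["census"]["groups"]]
            )
        if "expression" in raw:
            e = dict(raw["expression"])
            plats = e.pop("platforms", None)
            cfg.expression = ExpressionConfig(**e)
            if plats is not None:
                cfg.expression.platforms = [PlatformConfig(**p) for p in plats]
        if "pathway" in raw:
            p = dict(raw["pathway"])
            if "size_range" in p:
                p["size_range"] = tuple(p["size_range"])
            cfg.pathway = PathwayConfig(**p)
        if "ocean" in raw:
            cfg.ocean = OceanConfig(**raw["ocean"])
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _validate_probs(*probs: float) -> None:
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"probability {p} outside [0, 1]")


def gen_detection_table(
    config: CensusConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a library manifest and a long-format detection table.

    AP1 control detections are drawn so that a fraction ``ap1_dropout`` of
    each group's libraries carries fewer than two AP1 subunits (and hence
    fails the gate); target-panel detections are independent Bernoulli at
    the group's per-subunit probabilities.  All emitted detections are
    validated.
    """
    rng = np.random.default_rng(seed)
    manifest_rows, det_rows = [], []
    for group in config.groups:
        _validate_probs(group.ap1_dropout, *(group.prob(s) for s in TSET_PANEL))
        for i in range(group.n_libraries):
            lib = f"{group.name}_{i:03d}"
            manifest_rows.append(
                {
                    "library_id": lib,
                    "species": f"{group.name}_sp{i:03d}",
                    "taxon_group": group.name,
                    "lineage": f"Eukaryota;{group.name}",
                    "data_type": "genome" if i % 2 == 0 else "transcriptome",
                }
            )
            if rng.random() < group.ap1_dropout:
                n_ap1 = int(rng.integers(0, 2))  # 0 or 1: fails the gate
            else:
                n_ap1 = int(rng.integers(2, len(AP1_PANEL) + 1))
            for s in rng.choice(AP1_PANEL, size=n_ap1, replace=False):
                det_rows.append(
                    {"library_id": lib, "panel": "AP1", "subunit": str(s),
                     "detected": True, "validated": True}
                )
            for s in TSET_PANEL:
                if rng.random() < group.prob(s):
                    det_rows.append(
                        {"library_id": lib, "panel": "TSET", "subunit": s,
                         "detected": True, "validated": True}
                    )
    manifest = pd.DataFrame(manifest_rows)
    detections = pd.DataFrame(
        det_rows, columns=["library_id", "panel", "subunit", "detected", "validated"]
    )
    return manifest, detections


def gen_expression(
    config: ExpressionConfig, seed: int, core: CoreSubunitSet | None = None
) -> tuple[list[ExpressionDataset], list[str]]:
    """Simulate multi-platform expression data with a planted module.

    A latent factor is drawn per sample; planted-module genes load on it
    with ``latent_loading`` plus Gaussian noise, background genes are pure
    noise.  The core subunit gene ids are the first module members.  Each
    platform applies its own strictly increasing distortion and missing
    mask; a platform may also lack a fraction of the background genes
    entirely.  Returns the datasets and the planted gene ids.
    """
    core = core or CoreSubunitSet()
    core_ids = list(core.members.values())
    if config.module_size < len(core_ids):
        raise ConfigurationError(
            f"module_size {config.module_size} smaller than core set {len(core_ids)}"
        )
    if config.module_size > config.n_genes:
        raise ConfigurationError("module_size exceeds n_genes")
    rng = np.random.default_rng(seed)
    n_extra = config.n_genes - len(core_ids)
    genes = core_ids + [f"gene_{i:05d}" for i in range(n_extra)]
    planted = genes[: config.module_size]

    n_total = sum(p.n_samples for p in config.platforms)
    factor = rng.standard_normal(n_total)
    values = rng.standard_normal((config.n_genes, n_total))
    values[: config.module_size] = (
        config.latent_loading * factor
        + config.noise_sd * rng.standard_normal((config.module_size, n_total))
    )

    datasets = []
    start = 0
    for p in config.platforms:
        _validate_probs(p.missing_rate, p.absent_gene_fraction)
        if p.distortion not in DISTORTIONS:
            raise ConfigurationError(f"unknown distortion {p.distortion!r}")
        cols = [f"{p.platform}_s{start + j:03d}" for j in range(p.n_samples)]
        block = DISTORTIONS[p.distortion](values[:, start : start + p.n_samples].copy())
        block[rng.random(block.shape) < p.missing_rate] = np.nan
        frame = pd.DataFrame(block, index=genes, columns=cols)
        if p.absent_gene_fraction > 0:
            background = [g for g in genes if g not in planted]
            n_absent = int(round(p.absent_gene_fraction * len(background)))
            absent = rng.choice(background, size=n_absent, replace=False)
            frame = frame.drop(index=list(absent))
        datasets.append(ExpressionDataset(platform=p.platform, values=frame))
        start += p.n_samples
    return datasets, planted


def gen_pathways(
    config: PathwayConfig,
    planted_genes: list[str],
    all_genes: list[str],
    seed: int,
) -> PathwayCatalog:
    """Simulate a category catalog with one planted-enriched category.

    The planted category draws ``planted_fraction`` of its members from the
    planted gene module and the rest from background; all other categories
    sample uniformly from background genes.
    """
    rng = np.random.default_rng(seed)
    lo, hi = config.size_range
    if lo < 1 or hi < lo:
        raise ConfigurationError(f"bad size_range {config.size_range}")
    background = [g for g in all_genes if g not in set(planted_genes)]
    categories: dict[str, frozenset[str]] = {}

    # planted category: size capped so the module can supply its share
    if config.planted_fraction > 0:
        max_size = int(len(planted_genes) / config.planted_fraction)
        if max_size < lo:
            raise ConfigurationError(
                "planted_fraction * minimum category size exceeds the planted module"
            )
    else:
        max_size = hi
    size = min(int(rng.integers(lo, hi + 1)), max_size)
    n_from_module = int(round(config.planted_fraction * size))
    members = list(rng.choice(planted_genes, size=n_from_module, replace=False))
    members += list(rng.choice(background, size=size - n_from_module, replace=False))
    categories[config.planted_category] = frozenset(members)

    for i in range(config.n_categories - 1):
        size = int(rng.integers(lo, hi + 1))
        categories[f"category_{i + 1:02d}"] = frozenset(
            rng.choice(background, size=min(size, len(background)), replace=False)
        )
    return PathwayCatalog(
        categories=categories, reference_universe=frozenset(all_genes)
    )


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(np.minimum(x, 30.0))) + np.maximum(x - 30.0, 0.0)


def gen_stations(
    config: OceanConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate station abundance records, group totals and an env table.

    Normalized subunit abundance at a sample is
    ``softplus(intercept + offset_subunit - slope * temperature + noise)``;
    subunits whose draw falls below their detection floor are not emitted
    (by default TSAUCER's floor is infinite, so it is never detected).
    Abundances are generated on the normalized scale and back-multiplied by
    sampled diatom group totals, so group-total normalization recovers them
    exactly.  Returns ``(records, group_totals, env)``.
    """
    _validate_probs(config.missing_env_rate)
    rng = np.random.default_rng(seed)
    subunits = list(TSET_PANEL) + ["AP2mu"]
    offsets = {s: 0.0 for s in TSET_PANEL}
    offsets["AP2mu"] = config.ap2mu_offset
    rec_rows, total_rows, env_rows = [], [], []
    for i in range(config.n_stations):
        station = f"TARA_{i + 1:03d}"
        temp_base = rng.normal(
            config.env_means["temperature"], config.env_sds["temperature"]
        )
        for layer in DEPTH_LAYERS:
            temp = temp_base + rng.normal(0.0, 0.5)
            env_row: dict[str, object] = {
                "station": station,
                "depth_layer": layer,
                "size_fraction": config.size_fraction,
                "temperature": temp,
            }
            for name, mean in config.env_means.items():
                if name == "temperature":
                    continue
                env_row[name] = rng.normal(mean, config.env_sds[name])
            env_rows.append(env_row)

            group_total = rng.uniform(0.2, 0.6)
            total_rows.append(
                {
                    "station": station,
                    "depth_layer": layer,
                    "size_fraction": config.size_fraction,
                    "group_total": group_total,
                }
            )
            for s in subunits:
                eta = (
                    config.intercept
                    + offsets[s]
                    - config.abundance_temperature_slope * temp
                    + rng.normal(0.0, config.noise_sd)
                )
                normalized = float(_softplus(np.array(eta)))
                if normalized < config.detection_floor.get(s, 0.0):
                    continue
                rec_rows.append(
                    {
                        "transcript_id": f"{s}_{station}_{layer}",
                        "subunit": s,
                        "taxon": "Bacillariophyta",
                        "station": station,
                        "depth_layer": layer,
                        "size_fraction": config.size_fraction,
                        "abundance": normalized * group_total,
                    }
                )
            for j in range(config.n_offtarget_per_sample):
                rec_rows.append(
                    {
                        "transcript_id": f"other_{station}_{layer}_{j}",
                        "subunit": "TCUP",
                        "taxon": "Haptophyta",
                        "station": station,
                        "depth_layer": layer,
                        "size_fraction": config.size_fraction,
                        "abundance": float(rng.uniform(0.0, 1e-3)),
                    }
                )
    records = pd.DataFrame(rec_rows)
    group_totals = pd.DataFrame(total_rows)
    env = pd.DataFrame(env_rows)
    env_cols = [c for c in env.columns if c not in ("station", "depth_layer", "size_fraction")]
    mask = rng.random((len(env), len(env_cols))) < config.missing_env_rate
    env[env_cols] = env[env_cols].mask(mask)
    return records, group_totals, env
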