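"""Synthetic-data generator emulating the statistical structure of the field study.

Generates: (i) a source training library — three isotopically distinct
classes (bacteria, fungi, plants) in 5-dimensional centred δ13C eAA space,
class sizes mirroring the study's training data (bacteria 26, fungi 39,
plants 59); (ii) consumer communities whose centred profiles are convex
mixtures of the source class means plus residual noise at known true
proportions p*; (iii) δ15N Glu/Phe pairs forward-simulated at known trophic
positions; (iv) community size/density tables spanning meso- and macrofauna
body-mass ranges.

All randomness flows from one seed through fixed-key `SeedSequence` streams,
so each component regenerates independently and identically for the same
config.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .csia_io import DEFAULT_EAA, AAProfile
from .energyflux import IndividualRecord
from .fingerprint import CLASSES, SourceLibrary
from .trophic import TPConstants

__all__ = ["SynthConfig", "scenario", "gen_sources", "gen_consumers",
           "gen_nitrogen", "gen_community", "gen_dataset"]

_STREAMS = {"sources": 0, "consumers": 1, "nitrogen": 2, "community": 3}

#: Centred class-mean fingerprints (per mil, sum 0 over Ile, Leu, Phe, Thr,
#: Val). Pairwise separations 5.5–8.4 ‰ against within-class SD 1 ‰, i.e.
#: >= 4 within-class SDs — well-separated clusters, the regime the
#: fingerprinting approach assumes.
DEFAULT_SOURCE_MEANS = {
    "bacteria": np.array([2.0, -1.0, -4.0, 4.0, -1.0]),
    "fungi": np.array([-2.0, 2.5, -3.5, 5.0, -2.0]),
    "plants": np.array([0.5, -3.0, 2.0, 3.0, -2.5]),
}

#: Study-like true proportion vectors (bacteria, fungi, plants).
TRUE_P = {
    "fungal": np.array([0.085, 0.730, 0.185]),
    "chilopoda": np.array([0.22, 0.40, 0.38]),
    "balanced": np.array([1 / 3, 1 / 3, 1 / 3]),
}


def _default_consumer_groups():
    p = TRUE_P["fungal"]
    groups = {}
    for taxon in ("Collembola", "Lumbricidae", "Isopoda"):
        groups[taxon] = {"p": p.copy(), "n": 10, "residual_sd": 1.0,
                         "taxon_group": taxon, "region": "central",
                         "forest_type": "Beech150"}
    return groups


def _default_nitrogen_groups():
    # trophic positions at study-like group means
    return {
        "Lumbricidae": {"tp": 2.69, "n": 10, "noise_sd": 0.5,
                        "baseline_phe": -5.0, "context": "beech"},
        "Collembola": {"tp": 3.05, "n": 10, "noise_sd": 0.5,
                       "baseline_phe": -5.0, "context": "beech"},
        "Isopoda": {"tp": 3.72, "n": 10, "noise_sd": 0.5,
                    "baseline_phe": -5.0, "context": "beech"},
    }


def _default_community():
    # per group: median body length (mm), geometric SD, per-size-class
    # density range (ind/m²) and number of size classes, so that summed
    # group densities land in field-realistic ranges (earthworms tens per
    # m², microarthropods tens of thousands per m²); macrofauna and
    # mesofauna body-mass scales differ by >> 1 order of magnitude
    return {
        "Lumbricidae": {"median_length": 60.0, "gsd": 1.4,
                        "density_range": (1.0, 5.0), "n": 20},
        "Diplopoda": {"median_length": 20.0, "gsd": 1.4,
                      "density_range": (0.7, 3.3), "n": 15},
        "Isopoda": {"median_length": 8.0, "gsd": 1.4,
                    "density_range": (0.7, 5.3), "n": 15},
        "Chilopoda": {"median_length": 25.0, "gsd": 1.4,
                      "density_range": (0.5, 4.0), "n": 10},
        "Collembola": {"median_length": 1.2, "gsd": 1.5,
                       "density_range": (330.0, 1700.0), "n": 30},
        "Oribatida": {"median_length": 0.6, "gsd": 1.5,
                      "density_range": (670.0, 3300.0), "n": 30},
        "Mesostigmata": {"median_length": 0.8, "gsd": 1.5,
                         "density_range": (50.0, 250.0), "n": 20},
    }


@dataclass
class SynthConfig:
    """Full parameterisation of one synthetic dataset."""

    seed: int = 0
    eaa_order: tuple[str, ...] = DEFAULT_EAA
    source_means: dict[str, np.ndarray] = field(
        default_factory=lambda: {k: v.copy()
                                 for k, v in DEFAULT_SOURCE_MEANS.items()})
    source_sds: dict[str, np.ndarray] = field(
        default_factory=lambda: {k: np.ones(5) for k in CLASSES})
    source_counts: dict[str, int] = field(
        default_factory=lambda: {"bacteria": 26, "fungi": 39, "plants": 59})
    consumer_groups: dict[str, dict] = field(
        default_factory=_default_consumer_groups)
    nitrogen_groups: dict[str, dict] = field(
        default_factory=_default_nitrogen_groups)
    community: dict[str, dict] = field(default_factory=_default_community)
    tp_constants: TPConstants = field(default_factory=TPConstants)
    d13c_baseline: float = -25.0   # bulk offset added to centred fingerprints

    def __post_init__(self) -> None:
        for g, cfg in self.consumer_groups.items():
            p = np.asarray(cfg["p"], dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"group {g!r}: true p must lie on the simplex")
            cfg["p"] = p
        for g, cfg in self.nitrogen_groups.items():
            if cfg["tp"] < 1.0:
                raise ValueError(f"group {g!r}: true TP must be >= 1")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed,
                                   spawn_key=(_STREAMS[stream],)))


def scenario(name: str = "default", seed: int = 0, **overrides) -> SynthConfig:
    """Named study-like scenarios.

    ``default`` (= ``fungal``): 3 detritivore strata × 10 consumers at the
    fungal-dominated community-mean proportions. ``chilopoda``: predator-like
    plant-shifted mixture. ``balanced``: uniform proportions. ``hard``:
    overlapping source classes (within-class SD 3 ‰) for robustness tests.
    """
    cfg = SynthConfig(seed=seed, **overrides)
    key = "fungal" if name == "default" else name
    if key == "hard":
        cfg.source_sds = {k: np.full(5, 3.0) for k in CLASSES}
        key = "fungal"
    if key not in TRUE_P:
        raise ValueError(f"unknown scenario {name!r}")
    for g in cfg.consumer_groups.values():
        g["p"] = TRUE_P[key].copy()
    return cfg


def gen_sources(config: SynthConfig) -> SourceLibrary:
    """Draw the source training library: per class, n independent normal
    draws per eAA around the class-mean fingerprint."""
    rng = config.rng("sources")
    samples = {}
    for k in CLASSES:
        n = config.source_counts[k]
        mean = np.asarray(config.source_means[k], dtype=float)
        sd = np.asarray(config.source_sds[k], dtype=float)
        samples[k] = mean + rng.standard_normal((n, mean.size)) * sd
    return SourceLibrary.from_raw(samples, config.eaa_order, centre=True)


def gen_consumers(config: SynthConfig,
                  library: SourceLibrary) -> list[AAProfile]:
    """Consumers as convex mixtures of the library's centred class means.

    Each consumer's raw δ13C = Σ_k p*_k·(centred class mean) + bulk baseline
    offset + per-eAA residual noise; mean-centring downstream recovers the
    mixture plus (projected) noise.
    """
    rng = config.rng("consumers")
    means = library.means()
    profiles: list[AAProfile] = []
    for group, cfg in config.consumer_groups.items():
        mix = cfg["p"] @ means
        for i in range(cfg["n"]):
            offset = config.d13c_baseline + rng.normal(0.0, 1.0)
            noise = rng.standard_normal(mix.size) * cfg["residual_sd"]
            vec = mix + offset + noise
            profiles.append(AAProfile(
                sample_id=f"{group}_{i:03d}",
                taxon_group=cfg.get("taxon_group", group),
                region=cfg.get("region", "central"),
                forest_type=cfg.get("forest_type", "Beech150"),
                d13c=dict(zip(config.eaa_order, vec.tolist()))))
    return profiles


def gen_nitrogen(config: SynthConfig) -> pd.DataFrame:
    """δ15N Glu/Phe pairs forward-simulated at each group's true trophic
    position: Phe = baseline + noise; Glu = Phe + β + (TP*−1)·TDF + noise."""
    rng = config.rng("nitrogen")
    tdf, _ = config.tp_constants.tdf
    rows = []
    for group, cfg in config.nitrogen_groups.items():
        beta, _ = config.tp_constants.beta_for(cfg["context"])
        for i in range(cfg["n"]):
            phe = cfg["baseline_phe"] + rng.normal(0.0, cfg["noise_sd"])
            glu = phe + beta + (cfg["tp"] - 1.0) * tdf \
                + rng.normal(0.0, cfg["noise_sd"])
            rows.append({"sample_id": f"{group}_{i:03d}", "taxon_group": group,
                         "context": cfg["context"], "d15n_glu": glu,
                         "d15n_phe": phe, "true_tp": cfg["tp"]})
    return pd.DataFrame(rows)


def gen_community(config: SynthConfig) -> list[IndividualRecord]:
    """Community size/density table: log-normal body lengths, uniform
    densities within each group's configured range."""
    rng = config.rng("community")
    records: list[IndividualRecord] = []
    for group, cfg in config.community.items():
        sigma = np.log(cfg["gsd"]) if cfg["gsd"] > 1.0 else 0.0
        lo, hi = cfg["density_range"]
        for i in range(cfg["n"]):
            length = float(np.exp(np.log(cfg["median_length"])
                                  + sigma * rng.standard_normal()))
            density = float(rng.uniform(lo, hi))
            records.append(IndividualRecord(
                taxon_group=group, body_length=length, density=density,
                site=f"site_{i % 4}", region="central",
                forest_type="Beech150"))
    return records


def gen_dataset(config: SynthConfig) -> dict:
    """Generate every component of one synthetic study in one call."""
    library = gen_sources(config)
    consumers = gen_consumers(config, library)
    nitrogen = gen_nitrogen(config)
    # attach δ15N pairs to the matching consumer profiles where ids align
    by_id = {p.sample_id: p for p in consumers}
    for _, row in nitrogen.iterrows():
        prof = by_id.get(row["sample_id"])
        if prof is not None:
            prof.d15n["Glu"] = float(row["d15n_glu"])
            prof.d15n["Phe"] = float(row["d15n_phe"])
    return {"config": config, "library": library, "consumers": consumers,
            "nitrogen": nitrogen, "community": gen_community(config)}


def config_to_dict(config: SynthConfig) -> dict:
    """JSON-serialisable view of a config (for run manifests)."""
    def conv(x):
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items()}
        if isinstance(x, tuple):
            return list(x)
        if dataclasses.is_dataclass(x):
            return conv(dataclasses.asdict(x))
        return x
    return conv(dataclasses.asdict(config))
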