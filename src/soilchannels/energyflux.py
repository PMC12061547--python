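"""Energy fluxes from basal resources to soil animal communities.

The chain: individual body length/width → fresh body mass via group-specific
log-log regressions → community biomass per m² → community metabolic rate X
via the mass- and temperature-dependent regression

    ln I = ln i0 + a·ln M − E/(k·T)          [I in J/h, M in mg, T in K]

→ assimilation efficiencies e_a per basal resource from food nitrogen
content via the logit-linear model

    logit(e_a) = 0.471 · foodN% − 2.097

temperature-corrected with an Arrhenius shift on the logit scale (activation
energy 0.164 eV, reference 20 °C) → per-channel energy fluxes

    F_k = (X / e_a,k) · p_k

where p is the mixing-model proportion vector; predator fluxes are further
multiplied by the carnivore assimilation efficiency 0.91. F_k is the energy
input (J h⁻¹ m⁻²) a community must draw from channel k to cover the share
of its metabolism attributed to that channel.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .fingerprint import CLASSES

__all__ = [
    "BOLTZMANN_EV",
    "PREDATOR_GROUPS",
    "IndividualRecord",
    "MassRegression",
    "MetabolicParams",
    "EfficiencyParams",
    "FluxResult",
    "body_mass",
    "community_biomass",
    "community_metabolism",
    "assimilation_efficiency",
    "channel_fluxes",
    "check_efficiency_calibration",
    "load_constants",
    "read_community",
]

logger = logging.getLogger(__name__)

#: Boltzmann constant in eV per kelvin.
BOLTZMANN_EV = 8.62e-5

#: Groups that reach basal resources through prey, not by direct feeding.
PREDATOR_GROUPS = frozenset({"Chilopoda", "Mesostigmata"})


@dataclass
class IndividualRecord:
    """One measured individual (or size class) with its field density."""

    taxon_group: str
    body_length: float            # mm
    density: float                # individuals per m²
    body_width: float | None = None   # mm, optional per regression form
    site: str = ""
    region: str = ""
    forest_type: str = ""

    def __post_init__(self) -> None:
        if self.body_length <= 0 or self.density <= 0:
            raise ValueError("length and density must be > 0")
        if self.body_width is not None and self.body_width <= 0:
            raise ValueError("width must be > 0 when given")


@dataclass
class MassRegression:
    """Log-log length(–width)–mass power laws per taxon group.

    ``coefficients[group] = {"intercept": a, "length_exp": b, "width_exp": c}``
    encode ln M = a + b·ln L + c·ln W with M in mg fresh weight and L, W in
    mm; ``width_exp`` absent or zero means a length-only form.
    """

    coefficients: dict[str, dict[str, float]]

    def predict(self, group: str, length: float, width: float | None = None) -> float:
        if group not in self.coefficients:
            raise KeyError(f"no mass regression for taxon group {group!r}")
        c = self.coefficients[group]
        ln_m = c["intercept"] + c["length_exp"] * math.log(length)
        w_exp = c.get("width_exp", 0.0)
        if w_exp:
            if width is None:
                raise ValueError(f"{group}: regression needs body width")
            ln_m += w_exp * math.log(width)
        return math.exp(ln_m)


@dataclass
class MetabolicParams:
    """Mass- and temperature-scaling of individual metabolic rate per group.

    ``params[group] = {"ln_i0": ..., "mass_exp": a, "activation_e": E}`` with
    E in eV; ``temperatures`` maps region to mean °C measured 10 cm above
    ground (northern 10.3, central 9.3, southern 8.6).
    """

    params: dict[str, dict[str, float]]
    temperatures: dict[str, float] = field(default_factory=lambda: {
        "northern": 10.3, "central": 9.3, "southern": 8.6})

    def __post_init__(self) -> None:
        for g, c in self.params.items():
            if not 0.0 < c["mass_exp"] < 1.5:
                raise ValueError(f"{g}: mass exponent outside (0, 1.5)")
            if not 0.0 <= c["activation_e"] <= 2.0:
                raise ValueError(f"{g}: activation energy outside [0, 2] eV")
        for r, t in self.temperatures.items():
            if not -10.0 < t < 40.0:
                raise ValueError(f"{r}: temperature {t} °C implausible")

    def individual_rate(self, group: str, mass_mg: float, region: str) -> float:
        """Metabolic rate I (J/h) of one individual of the given fresh mass."""
        if mass_mg <= 0:
            raise ValueError("mass must be > 0")
        if group not in self.params:
            raise KeyError(f"no metabolic parameters for {group!r}")
        if region not in self.temperatures:
            raise KeyError(f"no temperature for region {region!r}")
        c = self.params[group]
        t_k = self.temperatures[region] + 273.15
        return math.exp(c["ln_i0"] + c["mass_exp"] * math.log(mass_mg)
                        - c["activation_e"] / (BOLTZMANN_EV * t_k))


@dataclass
class EfficiencyParams:
    """Assimilation-efficiency model constants.

    The logit-linear slope/intercept act on food nitrogen content (%); the
    temperature correction shifts the logit by
    ``activation_e·(T − T_ref_arrhenius)/(k·T·T_ref_arrhenius)`` (both in K).
    ``reference_temperature`` is the cross-region mean (9.4 °C) the study
    evaluates efficiencies at.
    """

    slope: float = 0.471                 # per %N, logit scale
    intercept: float = -2.097            # logit scale
    source_n: dict[str, float] = field(default_factory=lambda: {
        "bacteria": 7.07, "fungi": 3.14, "plants": 1.30})
    reference_temperature: float = 9.4   # °C
    activation_e: float = 0.164          # eV
    arrhenius_ref_temperature: float = 20.0  # °C
    carnivore_ea: float = 0.91


@dataclass
class FluxResult:
    """Per taxon-group × stratum energy budget."""

    taxon_group: str
    stratum: str
    biomass_mg_m2: float
    metabolism_j_h_m2: float
    efficiencies: dict[str, float]
    fluxes: dict[str, float]          # J h⁻¹ m⁻² per source class
    is_predator: bool

    @property
    def total_flux(self) -> float:
        return sum(self.fluxes.values())


def body_mass(record: IndividualRecord, reg: MassRegression) -> float:
    """Fresh body mass (mg) of one individual from its linear dimensions."""
    return reg.predict(record.taxon_group, record.body_length, record.body_width)


def community_biomass(individuals: list[IndividualRecord],
                      reg: MassRegression) -> dict[str, float]:
    """Σ mass·density per taxon group: mg fresh weight per m²."""
    out: dict[str, float] = {}
    for rec in individuals:
        out[rec.taxon_group] = out.get(rec.taxon_group, 0.0) + \
            body_mass(rec, reg) * rec.density
    return out


def community_metabolism(individuals: list[IndividualRecord],
                         masses: list[float], params: MetabolicParams,
                         region: str) -> dict[str, float]:
    """Community metabolic rate X (J h⁻¹ m⁻²) per taxon group.

    Each individual's rate is evaluated at its own body mass and the
    region's mean temperature, then scaled by its field density and summed
    within the group.
    """
    if len(individuals) != len(masses):
        raise ValueError("individuals and masses must align")
    out: dict[str, float] = {}
    for rec, m in zip(individuals, masses):
        rate = params.individual_rate(rec.taxon_group, m, region)
        out[rec.taxon_group] = out.get(rec.taxon_group, 0.0) + rate * rec.density
    return out


def assimilation_efficiency(food_n: float, params: EfficiencyParams,
                            temperature: float | None = None) -> float:
    """Assimilation efficiency in (0, 1) from food nitrogen content (%).

    ``temperature`` in °C defaults to the study's cross-region mean;
    ``temperature=None`` with ``params.activation_e = 0`` recovers the raw
    (uncorrected) logit-linear model.
    """
    if food_n <= 0:
        raise ValueError("food nitrogen content must be > 0 %")
    logit = params.slope * food_n + params.intercept
    t = params.reference_temperature if temperature is None else temperature
    t_k = t + 273.15
    t0_k = params.arrhenius_ref_temperature + 273.15
    logit += params.activation_e * (t_k - t0_k) / (BOLTZMANN_EV * t_k * t0_k)
    return 1.0 / (1.0 + math.exp(-logit))


def check_efficiency_calibration(params: EfficiencyParams,
                                 expected: dict[str, float] | None = None) -> bool:
    """Start-up guard: the configured temperature correction must reproduce
    the calibrated efficiency triple (fungi 0.30, plants 0.15, bacteria 0.73)
    from the configured N concentrations at the reference temperature.
    Returns True when it does; warns and returns False otherwise."""
    expected = expected or {"bacteria": 0.73, "fungi": 0.30, "plants": 0.15}
    ok = True
    for k, target in expected.items():
        got = round(assimilation_efficiency(params.source_n[k], params), 2)
        if got != target:
            logger.warning(
                "efficiency calibration check failed for %s: got %.2f, "
                "expected %.2f — check the temperature-correction constants",
                k, got, target)
            ok = False
    return ok


def channel_fluxes(metabolism: float, efficiencies: dict[str, float],
                   proportions: np.ndarray, taxon_group: str = "",
                   stratum: str = "", biomass: float = float("nan"),
                   is_predator: bool | None = None,
                   carnivore_ea: float = 0.91) -> FluxResult:
    """Per-channel energy fluxes F_k = (X / e_a,k) · p_k (J h⁻¹ m⁻²).

    ``proportions`` is the (bacteria, fungi, plants) simplex vector from the
    mixing model. Predator groups' fluxes are scaled by the carnivore
    assimilation efficiency, applied uniformly so the total scales by the
    same factor.
    """
    p = np.asarray(proportions, dtype=float)
    if p.shape != (len(CLASSES),) or np.any(p < -1e-9) or abs(p.sum() - 1) > 1e-9:
        raise ValueError("proportions must lie on the 3-simplex")
    if is_predator is None:
        is_predator = taxon_group in PREDATOR_GROUPS
    fluxes = {}
    for k, label in enumerate(CLASSES):
        ea = efficiencies[label]
        if not 0.0 < ea <= 1.0:
            raise ValueError(f"e_a[{label}] must be in (0, 1], got {ea}")
        f = metabolism / ea * max(p[k], 0.0)
        if is_predator:
            f *= carnivore_ea
        fluxes[label] = f
    return FluxResult(taxon_group=taxon_group, stratum=stratum,
                      biomass_mg_m2=biomass, metabolism_j_h_m2=metabolism,
                      efficiencies=dict(efficiencies), fluxes=fluxes,
                      is_predator=is_predator)


# ---------------------------------------------------------------------------
# constants file and community CSV
# ---------------------------------------------------------------------------

def load_constants(path=None) -> tuple[MassRegression, MetabolicParams,
                                       EfficiencyParams]:
    """Load the versioned constants JSON (packaged defaults when no path)."""
    if path is None:
        text = resources.files("soilchannels.data").joinpath(
            "constants.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    obj = json.loads(text)
    mass = MassRegression(obj["mass_regressions"])
    metab = MetabolicParams(obj["metabolic_params"],
                            temperatures=obj.get("temperatures",
                                                 MetabolicParams({}).temperatures))
    eff_obj = obj.get("efficiency", {})
    eff = EfficiencyParams(**eff_obj)
    return mass, metab, eff


def read_community(path) -> list[IndividualRecord]:
    """Read a community table CSV: site, taxon_group, length_mm, width_mm
    (optional), density_ind_m2, and optional region/forest_type columns."""
    df = pd.read_csv(path)
    for col in ("taxon_group", "length_mm", "density_ind_m2"):
        if col not in df.columns:
            raise ValueError(f"community CSV missing column {col!r}")
    records = []
    for _, row in df.iterrows():
        width = row.get("width_mm")
        records.append(IndividualRecord(
            taxon_group=str(row["taxon_group"]),
            body_length=float(row["length_mm"]),
            body_width=float(width) if pd.notna(width) else None,
            density=float(row["density_ind_m2"]),
            site=str(row.get("site", "")),
            region=str(row.get("region", "")),
            forest_type=str(row.get("forest_type", ""))))
    return records
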