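"""Data model and measurement post-processing for compound-specific amino-acid isotope data.

Holds the per-sample container (:class:`AAProfile`), CSV reading/writing, and
the corrections applied before any statistics: mass-balance correction of
δ13C for carbon added during derivatisation, normalisation of δ15N from the
reference-gas scale to atmospheric N2, and per-sample mean-centring of the
essential-amino-acid (eAA) δ13C profile.

δ13C values are per mil vs VPDB; δ15N values are per mil vs atmospheric N2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AA_CODES",
    "DEFAULT_EAA",
    "TAXON_GROUPS",
    "REGIONS",
    "FOREST_TYPES",
    "AAProfile",
    "DerivatisationSpec",
    "ScaleCalibration",
    "SchemaError",
    "IsotopeParseError",
    "read_profiles",
    "write_profiles",
    "correct_derivatisation",
    "normalise_d15n",
    "mean_centre",
]

#: Amino acids with reliable δ13C in the workflow, 3-letter codes.
AA_CODES = ("Ala", "Asx", "Glu", "Ile", "Leu", "Phe", "Pro", "Ser", "Thr", "Val")

#: Essential amino acids used for fingerprinting and mixing.
DEFAULT_EAA = ("Ile", "Leu", "Phe", "Thr", "Val")

TAXON_GROUPS = (
    "Lumbricidae",
    "Oribatida",
    "Diplopoda",
    "Collembola",
    "Chilopoda",
    "Mesostigmata",
    "Isopoda",
    "litter",
)
REGIONS = ("northern", "central", "southern")
FOREST_TYPES = ("Beech150", "Beech70", "Beech30", "Coniferous")

#: Plausibility windows (per mil); violations warn, they do not raise.
D13C_WINDOW = (-60.0, 10.0)
D15N_WINDOW = (-30.0, 40.0)


class SchemaError(ValueError):
    """A required column is missing or a categorical value is unknown."""


class IsotopeParseError(ValueError):
    """A cell that should hold a per-mil value could not be parsed."""


@dataclass
class AAProfile:
    """One sample's amino-acid isotope values with its grouping labels.

    Missing amino acids are absent keys in ``d13c``/``d15n`` — never zeros.
    Replicate SDs (from collapsing triplicate measurements) live in
    ``replicate_sd`` keyed like ``d13c``.
    """

    sample_id: str
    taxon_group: str
    region: str
    forest_type: str
    d13c: dict[str, float] = field(default_factory=dict)
    d15n: dict[str, float] = field(default_factory=dict)
    replicate_sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.taxon_group not in TAXON_GROUPS:
            raise SchemaError(f"unknown taxon_group {self.taxon_group!r}")
        if self.region not in REGIONS:
            raise SchemaError(f"unknown region {self.region!r}")
        if self.forest_type not in FOREST_TYPES:
            raise SchemaError(f"unknown forest_type {self.forest_type!r}")
        for aa, v in self.d13c.items():
            if not D13C_WINDOW[0] < v < D13C_WINDOW[1]:
                warnings.warn(
                    f"{self.sample_id}: δ13C[{aa}] = {v}‰ outside plausibility "
                    f"window {D13C_WINDOW}", stacklevel=2)
        for aa, v in self.d15n.items():
            if not D15N_WINDOW[0] < v < D15N_WINDOW[1]:
                warnings.warn(
                    f"{self.sample_id}: δ15N[{aa}] = {v}‰ outside plausibility "
                    f"window {D15N_WINDOW}", stacklevel=2)

    def eaa_vector(self, eaa_set: tuple[str, ...] = DEFAULT_EAA) -> np.ndarray:
        """Raw δ13C values in the order of ``eaa_set``; error if any is absent."""
        missing = [aa for aa in eaa_set if aa not in self.d13c]
        if missing:
            raise KeyError(
                f"{self.sample_id}: missing eAA δ13C values: {', '.join(missing)}")
        return np.array([self.d13c[aa] for aa in eaa_set], dtype=float)


@dataclass
class DerivatisationSpec:
    """Carbon counts and reagent δ13C for the mass-balance derivatisation correction.

    ``entries`` maps amino-acid code to ``(n_aa, n_total, d13c_added)`` where
    ``n_aa`` is the carbon count of the free amino acid, ``n_total`` of the
    derivatised compound, and ``d13c_added`` the per-mil value of the carbon
    added by the reagents.
    """

    entries: dict[str, tuple[int, int, float]]

    def __post_init__(self) -> None:
        for aa, (n_aa, n_total, _) in self.entries.items():
            if not (n_total > n_aa >= 2):
                raise ValueError(
                    f"{aa}: require n_total > n_aa >= 2, got "
                    f"n_total={n_total}, n_aa={n_aa}")

    @classmethod
    def from_json_dict(cls, obj: dict) -> "DerivatisationSpec":
        return cls({aa: (int(v["n_aa"]), int(v["n_total"]), float(v["d13c_added"]))
                    for aa, v in obj.items()})


@dataclass
class ScaleCalibration:
    """Linear δ15N scale from reference-gas values to atmospheric N2.

    Fitted by ordinary least squares of the known (vs air) values of
    co-derivatised standard amino acids on their measured (vs reference gas)
    values.
    """

    slope: float | None = None
    intercept: float | None = None
    residual_sd: float | None = None

    @classmethod
    def fit(cls, measured, known) -> "ScaleCalibration":
        measured = np.asarray(measured, dtype=float)
        known = np.asarray(known, dtype=float)
        if measured.size < 2:
            raise ValueError("need at least 2 calibration pairs")
        slope, intercept = np.polyfit(measured, known, 1)
        if not (np.isfinite(slope) and slope > 0):
            raise ValueError(f"calibration slope must be finite and > 0, got {slope}")
        resid = known - (slope * measured + intercept)
        dof = max(measured.size - 2, 1)
        return cls(float(slope), float(intercept),
                   float(np.sqrt(np.sum(resid ** 2) / dof)))

    @property
    def fitted(self) -> bool:
        return self.slope is not None


def correct_derivatisation(d13c_derivatised: float, aa: str,
                           spec: DerivatisationSpec) -> float:
    """Mass-balance correction removing the reagent carbon from a derivatised δ13C.

    δ13C_AA = (n_total·δ_derivatised − (n_total − n_aa)·δ_added) / n_aa.
    Linear in the measured value with slope n_total/n_aa; a reagent carbon
    isotopically identical to the measured compound leaves the value unchanged.
    """
    if aa not in spec.entries:
        raise KeyError(f"no derivatisation entry for amino acid {aa!r}")
    n_aa, n_total, d_added = spec.entries[aa]
    return (n_total * d13c_derivatised - (n_total - n_aa) * d_added) / n_aa


def normalise_d15n(measured: float, calib: ScaleCalibration) -> float:
    """Map a δ15N measured vs reference gas onto the atmospheric-N2 scale."""
    if not calib.fitted:
        raise RuntimeError("ScaleCalibration not fitted; call ScaleCalibration.fit")
    return calib.slope * measured + calib.intercept


def mean_centre(profile: AAProfile | np.ndarray,
                eaa_set: tuple[str, ...] = DEFAULT_EAA) -> np.ndarray:
    """Centre a sample's eAA δ13C values on their own mean.

    Removes the bulk-carbon offset so that only the relative eAA pattern
    (the fingerprint) remains; the output sums to zero.
    """
    if isinstance(profile, AAProfile):
        vec = profile.eaa_vector(eaa_set)
    else:
        vec = np.asarray(profile, dtype=float)
        if vec.shape != (len(eaa_set),):
            raise ValueError(
                f"expected vector of length {len(eaa_set)}, got shape {vec.shape}")
    return vec - vec.mean()


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_REQUIRED = ("sample_id", "taxon_group", "region", "forest_type")


def _collapse_replicates(df: pd.DataFrame, value_cols: list[str]) -> pd.DataFrame:
    """Collapse repeated sample_id rows (triplicate measurements) to mean,
    recording the per-AA SD in companion ``sd_<col>`` columns."""
    meta = df.groupby("sample_id", sort=False).first()[list(_REQUIRED[1:])]
    means = df.groupby("sample_id", sort=False)[value_cols].mean()
    sds = df.groupby("sample_id", sort=False)[value_cols].std(ddof=1)
    out = pd.concat([meta, means], axis=1).reset_index()
    for c in value_cols:
        out[f"sd_{c}"] = sds[c].to_numpy()
    return out


def read_profiles(path, schema: dict[str, str] | None = None,
                  collapse_replicates: bool = True) -> list[AAProfile]:
    """Read sample profiles from a CSV file.

    The expected layout is one row per sample (or per replicate measurement,
    collapsed to mean ± SD when ``collapse_replicates``): label columns
    ``sample_id, taxon_group, region, forest_type``, one δ13C column per
    amino acid named by its 3-letter code, and optional ``d15n_<AA>`` columns.
    ``schema`` optionally maps expected column names to the names actually in
    the file. Empty cells become absent keys.
    """
    df = pd.read_csv(path, dtype=str)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    for col in _REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")

    aa_cols = [c for c in df.columns if c in AA_CODES]
    d15n_cols = [c for c in df.columns if c.startswith("d15n_")]
    value_cols = aa_cols + d15n_cols

    for col in value_cols:
        for i, raw in enumerate(df[col]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
                continue
            try:
                float(raw)
            except (TypeError, ValueError):
                raise IsotopeParseError(
                    f"non-numeric value {raw!r} in column {col!r}, row {i + 2} "
                    f"(counting the header as row 1)") from None
        df[col] = pd.to_numeric(df[col])

    if collapse_replicates and df["sample_id"].duplicated().any():
        df = _collapse_replicates(df, value_cols)

    profiles: list[AAProfile] = []
    for _, row in df.iterrows():
        d13c = {aa: float(row[aa]) for aa in aa_cols if pd.notna(row.get(aa))}
        d15n = {c[len("d15n_"):]: float(row[c]) for c in d15n_cols
                if pd.notna(row.get(c))}
        rep = {}
        for c in value_cols:
            sd_col = f"sd_{c}"
            if sd_col in row.index and pd.notna(row[sd_col]):
                rep[c] = float(row[sd_col])
        profiles.append(AAProfile(
            sample_id=str(row["sample_id"]),
            taxon_group=str(row["taxon_group"]),
            region=str(row["region"]),
            forest_type=str(row["forest_type"]),
            d13c=d13c, d15n=d15n, replicate_sd=rep))
    return profiles


def write_profiles(profiles: list[AAProfile], path) -> None:
    """Write profiles to CSV in the layout :func:`read_profiles` consumes.

    Numeric fields are written at full repr precision so a read-back
    round-trip reproduces them bit-identically.
    """
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "sample_id": p.sample_id, "taxon_group": p.taxon_group,
            "region": p.region, "forest_type": p.forest_type}
        for aa in AA_CODES:
            if aa in p.d13c:
                row[aa] = repr(p.d13c[aa])
        for aa, v in p.d15n.items():
            row[f"d15n_{aa}"] = repr(v)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
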