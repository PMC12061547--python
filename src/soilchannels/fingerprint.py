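"""δ13C essential-amino-acid fingerprinting by linear discriminant analysis.

Bacteria, fungi and plants build essential amino acids through
lineage-specific enzymatic pathways, leaving distinct multivariate δ13C
patterns. An LDA trained on source samples of the three classes projects
consumers into a 2-D discriminant space where each consumer community is
classified to the nearest class centroid.

Directions are normalised in the pooled within-class scatter metric
(w' Sw w = 1), the convention of classical discriminant analysis, so that
within-class dispersion is isotropic in discriminant space and Euclidean
centroid distance is the natural classification rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.stats import chi2

from .csia_io import DEFAULT_EAA, AAProfile, mean_centre

__all__ = [
    "CLASSES",
    "SourceLibrary",
    "LDAModel",
    "fit_lda",
    "project",
    "classify",
    "confidence_ellipse",
]

logger = logging.getLogger(__name__)

#: Fixed class order; also the deterministic tie-break order.
CLASSES = ("bacteria", "fungi", "plants")


@dataclass
class SourceLibrary:
    """Centred δ13C eAA training vectors for the three basal-resource classes.

    ``samples`` maps class label to an (n_k, d) array of per-sample centred
    vectors, all sharing ``eaa_order``.
    """

    samples: dict[str, np.ndarray]
    eaa_order: tuple[str, ...] = DEFAULT_EAA

    def __post_init__(self) -> None:
        d = len(self.eaa_order)
        for k in CLASSES:
            if k not in self.samples:
                raise ValueError(f"source library missing class {k!r}")
            arr = np.asarray(self.samples[k], dtype=float)
            if arr.ndim != 2 or arr.shape[1] != d:
                raise ValueError(
                    f"class {k!r}: expected (n, {d}) array, got {arr.shape}")
            if arr.shape[0] < 2:
                raise ValueError(f"class {k!r}: need >= 2 samples, got {arr.shape[0]}")
            self.samples[k] = arr

    @classmethod
    def from_raw(cls, raw: dict[str, np.ndarray],
                 eaa_order: tuple[str, ...] = DEFAULT_EAA,
                 centre: bool = True) -> "SourceLibrary":
        """Build a library from raw δ13C vectors, mean-centring each sample."""
        samples = {}
        for k, arr in raw.items():
            arr = np.asarray(arr, dtype=float)
            if centre:
                arr = arr - arr.mean(axis=1, keepdims=True)
            samples[k] = arr
        return cls(samples, eaa_order)

    def means(self) -> np.ndarray:
        """(K, d) class means μ_k, rows in CLASSES order."""
        return np.vstack([self.samples[k].mean(axis=0) for k in CLASSES])

    def sds(self) -> np.ndarray:
        """(K, d) per-eAA within-class sample SDs σ_k, rows in CLASSES order."""
        return np.vstack([self.samples[k].std(axis=0, ddof=1) for k in CLASSES])

    def counts(self) -> dict[str, int]:
        return {k: self.samples[k].shape[0] for k in CLASSES}


@dataclass
class LDAModel:
    """Fitted discriminant model: directions, eigenvalues, class centroids."""

    directions: np.ndarray        # (d, m) columns are discriminant axes
    eigenvalues: np.ndarray       # (m,) descending, >= 0
    centroids: dict[str, np.ndarray]   # class -> (m,) coordinates
    eaa_order: tuple[str, ...]
    class_means: dict[str, np.ndarray]  # class -> (d,) input-space mean

    @property
    def n_axes(self) -> int:
        return self.directions.shape[1]

    def to_json(self) -> str:
        return json.dumps({
            "directions": self.directions.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "centroids": {k: v.tolist() for k, v in self.centroids.items()},
            "eaa_order": list(self.eaa_order),
            "class_means": {k: v.tolist() for k, v in self.class_means.items()},
        })

    @classmethod
    def from_json(cls, s: str) -> "LDAModel":
        obj = json.loads(s)
        return cls(
            directions=np.array(obj["directions"]),
            eigenvalues=np.array(obj["eigenvalues"]),
            centroids={k: np.array(v) for k, v in obj["centroids"].items()},
            eaa_order=tuple(obj["eaa_order"]),
            class_means={k: np.array(v) for k, v in obj["class_means"].items()},
        )


def _scatter_matrices(library: SourceLibrary) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within-class covariance Sw and between-class scatter Sb."""
    d = len(library.eaa_order)
    grand = np.vstack([library.samples[k] for k in CLASSES]).mean(axis=0)
    sw = np.zeros((d, d))
    sb = np.zeros((d, d))
    n_total = 0
    for k in CLASSES:
        x = library.samples[k]
        n_k = x.shape[0]
        mu_k = x.mean(axis=0)
        dev = x - mu_k
        sw += dev.T @ dev
        diff = (mu_k - grand)[:, None]
        sb += n_k * (diff @ diff.T)
        n_total += n_k
    sw /= n_total - len(CLASSES)   # pooled covariance
    return sw, sb


def fit_lda(library: SourceLibrary, regularise: bool = True) -> LDAModel:
    """Fit the discriminant axes from a source library.

    Solves the generalized eigenproblem Sb w = λ Sw w; eigenvectors come out
    Sw-orthonormal and are sorted by descending eigenvalue. At most K−1 = 2
    axes carry signal for 3 classes. A singular within-class scatter is
    ridge-regularised (λ_ridge = 1e-8·trace) when ``regularise`` is on,
    otherwise raises.
    """
    sw, sb = _scatter_matrices(library)
    d = sw.shape[0]
    cond = np.linalg.cond(sw)
    if not np.isfinite(cond) or cond > 1e12:
        if not regularise:
            raise np.linalg.LinAlgError(
                f"within-class scatter is singular (cond={cond:.3g}); "
                "enable regularise=True to ridge-regularise")
        ridge = 1e-8 * np.trace(sw)
        if ridge <= 0:
            ridge = 1e-12
        logger.warning("singular within-class scatter; adding ridge %.3g", ridge)
        sw = sw + ridge * np.eye(d)

    eigval, eigvec = linalg.eigh(sb, sw)   # ascending; eigvec' Sw eigvec = I
    order = np.argsort(eigval)[::-1]
    n_axes = min(len(CLASSES) - 1, d)
    eigval = np.clip(eigval[order][:n_axes], 0.0, None)
    directions = eigvec[:, order][:, :n_axes]

    class_means = {k: library.samples[k].mean(axis=0) for k in CLASSES}
    centroids = {k: class_means[k] @ directions for k in CLASSES}
    return LDAModel(directions=directions, eigenvalues=eigval,
                    centroids=centroids, eaa_order=library.eaa_order,
                    class_means=class_means)


def project(model: LDAModel, centred_profile: np.ndarray) -> np.ndarray:
    """Project a centred eAA vector onto the discriminant axes."""
    v = np.asarray(centred_profile, dtype=float)
    d = model.directions.shape[0]
    if v.shape != (d,):
        raise ValueError(f"expected vector of length {d}, got shape {v.shape}")
    return v @ model.directions


def classify(model: LDAModel,
             centred_profile: np.ndarray) -> tuple[str, dict[str, float]]:
    """Assign the nearest class centroid in discriminant space.

    Returns the label and the Euclidean distances to all class centroids.
    Exact ties break deterministically in CLASSES order
    (bacteria < fungi < plants).
    """
    z = project(model, centred_profile)
    distances = {k: float(np.linalg.norm(z - model.centroids[k])) for k in CLASSES}
    label = min(CLASSES, key=lambda k: (distances[k], CLASSES.index(k)))
    return label, distances


def classify_profiles(model: LDAModel, profiles: list[AAProfile]):
    """Project and classify a batch of profiles; returns a tidy DataFrame."""
    import pandas as pd

    rows = []
    for p in profiles:
        v = mean_centre(p, model.eaa_order)
        z = project(model, v)
        label, dist = classify(model, v)
        rows.append({
            "sample_id": p.sample_id, "taxon_group": p.taxon_group,
            "region": p.region, "forest_type": p.forest_type,
            "LD1": z[0], "LD2": z[1] if len(z) > 1 else np.nan,
            "assigned_class": label,
            **{f"dist_{k}": dist[k] for k in CLASSES}})
    return pd.DataFrame(rows)


def confidence_ellipse(model: LDAModel, library: SourceLibrary, class_label: str,
                       level: float = 0.75) -> dict:
    """Confidence ellipse of a class's projected training points.

    From the 2-D sample covariance of the projections, scaled by the
    chi-square(2) quantile at ``level``. Returns centre, semi-axis lengths
    (descending) and the angle of the major axis in radians.
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class {class_label!r}")
    pts = library.samples[class_label] @ model.directions
    if pts.shape[0] < 3:
        raise ValueError(
            f"need >= 3 projected points for an ellipse, got {pts.shape[0]}")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must be in [0, 1)")
    cov = np.cov(pts, rowvar=False)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = chi2.ppf(level, df=2) if level > 0 else 0.0
    axes = np.sqrt(np.clip(eigval, 0, None) * scale)
    angle = float(np.arctan2(eigvec[1, 0], eigvec[0, 0]))
    return {"centre": pts.mean(axis=0), "axes": axes, "angle": angle}
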