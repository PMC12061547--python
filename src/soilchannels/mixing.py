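"""Bayesian mixing model for basal-resource proportions from δ13C eAA fingerprints.

Each consumer community's mean-centred δ13C eAA vector is modelled as a
convex mixture of the three source-class means (bacteria, fungi, plants):

    y_ja ~ Normal( Σ_k p_k μ_ka ,  Σ_k p_k² σ_ka² + σ_res,a² )

with a Dirichlet prior on the proportion simplex p. The first variance term
is process error inherited from source variability; σ_res is an optional
per-eAA residual term with a half-normal prior. Strata (e.g. taxon group, or
taxon group × forest type) are fitted independently.

Sampling is adaptive random-walk Metropolis in isometric log-ratio (ilr)
coordinates — the orthonormal bijection between the open simplex and R²,
which removes the sum-to-one constraint. Convergence is monitored with the
Gelman–Rubin potential-scale-reduction statistic per proportion parameter,
with the acceptance threshold R-hat < 1.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import helmert
from scipy.special import xlogy

from .fingerprint import CLASSES, SourceLibrary

__all__ = [
    "MixingModelSpec",
    "MixingPosterior",
    "ilr",
    "ilr_inv",
    "log_posterior",
    "run_mcmc",
    "gelman_rubin",
    "summarise",
    "map_estimate",
    "build_mixing_spec",
]

logger = logging.getLogger(__name__)

_K = len(CLASSES)
#: Orthonormal ilr contrast basis, rows sum to zero (Helmert sub-matrix).
_ILR_BASIS = helmert(_K)          # (K-1, K)


def ilr(p: np.ndarray) -> np.ndarray:
    """Isometric log-ratio transform of simplex points; p strictly positive.

    Accepts a (K,) point or an (n, K) array of points.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("ilr requires strictly positive components")
    return np.log(p) @ _ILR_BASIS.T


def ilr_inv(z: np.ndarray) -> np.ndarray:
    """Inverse ilr: map R^(K-1) coordinates back onto the open simplex."""
    z = np.asarray(z, dtype=float)
    x = z @ _ILR_BASIS
    x = x - x.max(axis=-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class MixingModelSpec:
    """Inputs of one mixing-model run.

    ``source_means``/``source_sds`` are (K, d) in CLASSES order over the
    ``eaa_order`` amino acids; ``consumers`` maps stratum label to an (n, d)
    array of mean-centred consumer vectors.
    """

    source_means: np.ndarray
    source_sds: np.ndarray
    consumers: dict[str, np.ndarray]
    eaa_order: tuple[str, ...]
    prior_alpha: np.ndarray = field(default_factory=lambda: np.ones(_K))
    residual_error: bool = True
    sigma_res: float = 0.0            # fixed residual SD when residual_error is off
    sigma_res_scale: float = 5.0      # half-normal prior scale (per mil)

    def __post_init__(self) -> None:
        self.source_means = np.asarray(self.source_means, dtype=float)
        self.source_sds = np.asarray(self.source_sds, dtype=float)
        self.prior_alpha = np.asarray(self.prior_alpha, dtype=float)
        d = len(self.eaa_order)
        if self.source_means.shape != (_K, d) or self.source_sds.shape != (_K, d):
            raise ValueError(f"source summaries must be ({_K}, {d}) arrays")
        if np.any(self.prior_alpha <= 0):
            raise ValueError("Dirichlet concentration parameters must be > 0")
        for s, arr in self.consumers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != d:
                raise ValueError(f"stratum {s!r}: consumer array must be (n, {d})")
            if np.any(~np.isfinite(arr)):
                raise ValueError(f"stratum {s!r}: non-finite consumer values")
            self.consumers[s] = arr


@dataclass
class MixingPosterior:
    """Post-burn-in draws and diagnostics, per stratum.

    ``draws[stratum]`` has shape (n_chains, n_kept, K) on the simplex;
    ``rhat[stratum]`` holds the Gelman–Rubin statistic per proportion.
    """

    draws: dict[str, np.ndarray]
    rhat: dict[str, np.ndarray]
    converged: dict[str, bool]
    rhat_threshold: float
    sigma_res_draws: dict[str, np.ndarray] | None = None
    seed: int | None = None

    def pooled(self, stratum: str) -> np.ndarray:
        """All chains' draws stacked: (n_chains·n_kept, K)."""
        return self.draws[stratum].reshape(-1, _K)


def _log_prior(p: np.ndarray, alpha: np.ndarray) -> float:
    """Unnormalised Dirichlet log density; xlogy gives 0·log(0) = 0 at α=1."""
    return float(np.sum(xlogy(alpha - 1.0, p)))


def _loglik(p: np.ndarray, sigma2_res, y: np.ndarray,
            mu: np.ndarray, sig2: np.ndarray) -> float:
    """Gaussian mixture-mean likelihood summed over consumers and eAAs."""
    m = p @ mu
    v = (p * p) @ sig2 + sigma2_res
    if np.any(v <= 0):
        return -np.inf
    r = y - m
    n = y.shape[0]
    return float(-0.5 * (np.sum(r * r / v) + n * np.sum(np.log(2.0 * np.pi * v))))


def log_posterior(p: np.ndarray, spec: MixingModelSpec, stratum: str,
                  sigma_res: float | np.ndarray | None = None) -> float:
    """Unnormalised log posterior density of a simplex point for one stratum.

    With no consumers in the stratum this reduces to the (flat, for
    Dirichlet(1,1,1)) prior. Raises for points off the simplex.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (_K,) or np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"p must lie on the {_K}-simplex, got {p}")
    p = np.clip(p, 0.0, None)
    if sigma_res is None:
        sigma_res = spec.sigma_res
    sigma2 = np.asarray(sigma_res, dtype=float) ** 2
    y = spec.consumers.get(stratum)
    lp = _log_prior(p, spec.prior_alpha)
    if y is not None and y.shape[0] > 0:
        lp += _loglik(p, sigma2, y, spec.source_means, spec.source_sds ** 2)
    return lp


def gelman_rubin(chains: np.ndarray) -> float:
    """Gelman–Rubin potential scale reduction R-hat for one parameter.

    ``chains`` is (m, n): m >= 2 chains of equal post-burn-in length n.
    R-hat = sqrt(((n−1)/n·W + B/n)/W) with W the mean within-chain variance
    and B = n·Var(chain means). Degenerate cases: W = 0 with between-chain
    spread gives +inf; chains that are all one identical constant give 1.0.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length, shape (m, n)")
    m, n = chains.shape
    if n < 2:
        raise ValueError("chains must have length >= 2")
    w = chains.var(axis=1, ddof=1).mean()
    b_over_n = chains.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return np.inf if b_over_n > 0 else 1.0
    return float(np.sqrt(((n - 1) / n * w + b_over_n) / w))


def _run_chain(y, mu, sig2, alpha, residual_error, sigma_res_fixed,
               sigma_res_scale, n_iter, burn_in, rng):
    """One adaptive random-walk Metropolis chain in ilr (+ log σ_res) space.

    Proposal scale adapts toward 20–50% acceptance during burn-in only, so
    the post-burn-in kernel is fixed and detailed balance holds for the
    retained draws. Returns (p draws, σ_res draws) post burn-in.
    """
    d = mu.shape[1]
    dim = (_K - 1) + (d if residual_error else 0)
    has_data = y is not None and y.shape[0] > 0

    # overdispersed start: random Dirichlet point
    p0 = rng.dirichlet(np.ones(_K))
    theta = np.empty(dim)
    theta[: _K - 1] = ilr(np.clip(p0, 1e-6, None) / np.clip(p0, 1e-6, None).sum())
    if residual_error:
        theta[_K - 1:] = np.log(rng.uniform(0.5, 2.0, size=d))

    def target(th):
        p = ilr_inv(th[: _K - 1])
        lp = float(np.sum(xlogy(alpha - 1.0, p))) + float(np.sum(np.log(p)))
        if residual_error:
            sig = np.exp(th[_K - 1:])
            # half-normal prior on σ plus the log|dσ/du| Jacobian
            lp += float(-0.5 * np.sum((sig / sigma_res_scale) ** 2)
                        + np.sum(np.log(sig)))
            s2 = sig ** 2
        else:
            s2 = sigma_res_fixed ** 2
        if has_data:
            lp += _loglik(p, s2, y, mu, sig2)
        return lp, p

    lp_cur, p_cur = target(theta)
    # blocks updated Metropolis-within-Gibbs: ilr coordinates, then (when
    # sampled) the log residual SDs, each with its own adapted scale
    blocks = [np.arange(_K - 1)]
    if residual_error:
        blocks.append(np.arange(_K - 1, dim))
    scales = [0.5] * len(blocks)
    shape = np.ones(dim)           # per-component proposal shape
    steps = rng.standard_normal((n_iter, dim))
    log_u = np.log(rng.uniform(size=(n_iter, len(blocks))))

    n_keep = n_iter - burn_in
    p_out = np.empty((n_keep, _K))
    sig_out = np.empty((n_keep, d)) if residual_error else None
    history = np.empty((burn_in, dim))
    accepted = np.zeros(len(blocks))
    window = 0
    for t in range(n_iter):
        for b, idx in enumerate(blocks):
            prop = theta.copy()
            prop[idx] += scales[b] * shape[idx] * steps[t, idx]
            lp_prop, p_prop = target(prop)
            if log_u[t, b] < lp_prop - lp_cur:
                theta, lp_cur, p_cur = prop, lp_prop, p_prop
                accepted[b] += 1
        window += 1
        if t < burn_in:
            history[t] = theta
            if window == 50:
                for b in range(len(blocks)):
                    rate = accepted[b] / window
                    scales[b] = float(np.clip(
                        scales[b] * np.exp(rate - 0.3), 1e-3, 10.0))
                accepted[:] = 0
                window = 0
            # reshape proposals to the posterior's per-component spread
            if t >= 500 and (t + 1) % 500 == 0:
                est = np.clip(history[t - 499:t + 1].std(axis=0), 1e-3, None)
                for idx in blocks:
                    shape[idx] = est[idx] / est[idx].mean()
        if t == burn_in - 1:       # freeze adaptation
            accepted[:] = 0
            window = 0
        if t >= burn_in:
            j = t - burn_in
            p_out[j] = p_cur
            if residual_error:
                sig_out[j] = np.exp(theta[_K - 1:])
    return p_out, sig_out


def run_mcmc(spec: MixingModelSpec, n_iter: int = 10_000, burn_in: int = 5_000,
             n_chains: int = 3, seed: int = 0) -> MixingPosterior:
    """Sample the mixing posterior for every stratum.

    Runs ``n_chains`` independent chains (seeded seed, seed+1, ...) of
    ``n_iter`` iterations each, discarding ``burn_in``; R-hat is computed per
    proportion parameter from the retained draws. Non-convergence is flagged
    in the result, never raised.
    """
    if burn_in >= n_iter:
        raise ValueError("burn_in must be < n_iter")
    if n_chains < 2:
        raise ValueError("need >= 2 chains for the Gelman-Rubin diagnostic")

    mu = spec.source_means
    sig2 = spec.source_sds ** 2
    draws: dict[str, np.ndarray] = {}
    rhat: dict[str, np.ndarray] = {}
    converged: dict[str, bool] = {}
    sig_draws: dict[str, np.ndarray] = {}
    threshold = 1.05

    for si, stratum in enumerate(spec.consumers):
        y = spec.consumers[stratum]
        chain_p = []
        chain_s = []
        for c in range(n_chains):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed + c, spawn_key=(si,)))
            p_out, s_out = _run_chain(
                y, mu, sig2, spec.prior_alpha, spec.residual_error,
                spec.sigma_res, spec.sigma_res_scale, n_iter, burn_in, rng)
            chain_p.append(p_out)
            if s_out is not None:
                chain_s.append(s_out)
        draws[stratum] = np.stack(chain_p)              # (m, n_keep, K)
        if chain_s:
            sig_draws[stratum] = np.stack(chain_s)
        rh = np.array([gelman_rubin(draws[stratum][:, :, k]) for k in range(_K)])
        rhat[stratum] = rh
        converged[stratum] = bool(np.all(rh < threshold))
        if not converged[stratum]:
            logger.warning("stratum %r: R-hat %s >= %.2f, flagged non-converged",
                           stratum, np.round(rh, 3), threshold)

    return MixingPosterior(draws=draws, rhat=rhat, converged=converged,
                           rhat_threshold=threshold,
                           sigma_res_draws=sig_draws or None, seed=seed)


def summarise(posterior: MixingPosterior) -> pd.DataFrame:
    """Posterior summary table: mean, SD and 95% credible interval per
    proportion per stratum, with the convergence diagnostics."""
    rows = []
    for stratum, arr in posterior.draws.items():
        if arr.size == 0:
            raise ValueError(f"stratum {stratum!r}: no draws to summarise")
        pooled = arr.reshape(-1, _K)
        q = np.percentile(pooled, [2.5, 50.0, 97.5], axis=0)
        for k, label in enumerate(CLASSES):
            rows.append({
                "stratum": stratum, "source": label,
                "mean": pooled[:, k].mean(), "sd": pooled[:, k].std(ddof=1),
                "q2.5": q[0, k], "q50": q[1, k], "q97.5": q[2, k],
                "rhat": posterior.rhat[stratum][k],
                "converged": posterior.converged[stratum]})
    return pd.DataFrame(rows)


def map_estimate(posterior: MixingPosterior, spec: MixingModelSpec,
                 stratum: str) -> np.ndarray:
    """The retained draw with the highest log posterior (sampled-mode estimate).

    When the residual SD was sampled, the density is evaluated at each draw's
    own σ_res so the comparison matches the sampler's target.
    """
    pooled = posterior.pooled(stratum)
    if posterior.sigma_res_draws and stratum in posterior.sigma_res_draws:
        sig = posterior.sigma_res_draws[stratum].reshape(pooled.shape[0], -1)
        lps = np.array([log_posterior(p, spec, stratum, sigma_res=s)
                        for p, s in zip(pooled, sig)])
    else:
        lps = np.array([log_posterior(p, spec, stratum) for p in pooled])
    return pooled[int(np.argmax(lps))]


def build_mixing_spec(profiles, library: SourceLibrary,
                      scheme: str = "taxon_group", **kwargs) -> MixingModelSpec:
    """Group consumer profiles into strata and assemble a model spec.

    ``scheme`` is one of ``taxon_group``, ``taxon_group_x_forest``,
    ``taxon_group_x_region``; profiles are mean-centred on the library's eAA
    order. Extra keyword arguments pass through to :class:`MixingModelSpec`.
    """
    from .csia_io import mean_centre

    def key(p):
        if scheme == "taxon_group":
            return p.taxon_group
        if scheme == "taxon_group_x_forest":
            return f"{p.taxon_group}|{p.forest_type}"
        if scheme == "taxon_group_x_region":
            return f"{p.taxon_group}|{p.region}"
        raise ValueError(f"unknown stratum scheme {scheme!r}")

    strata: dict[str, list[np.ndarray]] = {}
    for p in profiles:
        strata.setdefault(key(p), []).append(mean_centre(p, library.eaa_order))
    consumers = {s: np.vstack(v) for s, v in strata.items()}
    return MixingModelSpec(
        source_means=library.means(), source_sds=library.sds(),
        consumers=consumers, eaa_order=library.eaa_order, **kwargs)
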