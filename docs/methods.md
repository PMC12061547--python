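# Methods notes

This note documents the models implemented in `soilchannels`, the defaults
and why they were chosen, the numerical choices that matter, and what the
synthetic-data generator does and does not emulate.

## Measurement post-processing (`csia_io`)

Gas-chromatography CSIA measures amino acids after derivatisation, which
adds reagent carbon of known isotopic composition. The mass-balance
correction

    δ13C_AA = (n_total·δ_derivatised − (n_total − n_aa)·δ_added) / n_aa

removes it; it is linear in the measured value with slope `n_total/n_aa`
and leaves the value unchanged when the reagent carbon is isotopically
identical. Reagent δ13C values and carbon counts are lab-specific and are
therefore config inputs (`DerivatisationSpec`), not built-in constants.

δ15N is measured against a reference gas and mapped to the atmospheric-N2
scale by an OLS line fitted through co-derivatised standards of known
composition (≥ 2 standards; the fit stores its residual SD as a
quality measure).

Mean-centring subtracts each sample's own mean over the configured
essential-AA set (default Ile, Leu, Phe, Thr, Val), removing bulk trophic
and baseline offsets so only the relative fingerprint pattern remains.
Missing amino acids stay missing — any operation that needs them fails
loudly listing the absent codes; silent imputation would corrupt
fingerprints. Replicate measurements (the usual triplicates) collapse to
mean ± SD at read time, with the SD retained per amino acid.

## Fingerprinting (`fingerprint`)

The LDA solves the generalized symmetric eigenproblem `Sb·w = λ·Sw·w` with
`Sw` the pooled within-class covariance and `Sb` the between-class scatter.
Eigenvectors come out Sw-orthonormal (`wᵀSw w = 1`), so within-class
dispersion is isotropic in discriminant space and the nearest-centroid rule
under plain Euclidean distance is the natural classifier. Three classes
yield at most two axes; eigenvalues are clipped at zero and sorted.

Because per-sample centring places all vectors on a sum-zero subspace, `Sw`
is always singular in the ambient 5-D space. The fit detects condition
numbers above 1e12 and adds a ridge of `1e-8·trace(Sw)` with a logged
warning (disable with `regularise=False` to get a hard error instead). The
signal directions are unaffected; the null direction receives a ≈ 0
eigenvalue and is never selected.

Centring is applied to both the source library and the consumers
(`SourceLibrary.from_raw(..., centre=True)` is the default). Whether the
original workflow centred sources per sample or per batch is ambiguous;
per-sample centring makes multi-laboratory source data comparable, which is
the point of fingerprinting, and the switch records the choice.

Exact centroid-distance ties break deterministically in the fixed class
order bacteria < fungi < plants. Confidence ellipses scale the 2-D sample
covariance of a class's projections by the χ²₂ quantile at the requested
level (the conventional 75% level gives semi-axes √(λᵢ·2.773)).

## Mixing model (`mixing`)

Each stratum (taxon group, optionally × forest type or × region) is fitted
independently. The observed data are the centred consumer vectors y_j; the
likelihood treats each eAA as Gaussian around the proportion-weighted
source means with variance composed of *process error* (source variability
scaled by p²) and an optional per-eAA *residual error*:

    y_ja ~ Normal( Σ_k p_k μ_ka ,  Σ_k p_k² σ_ka² + σ_res,a² )

- Prior on p: Dirichlet(1, 1, 1) by default (configurable).
- Prior on σ_res,a: half-normal with scale 5 ‰ (configurable); set
  `residual_error=False` to fix σ_res at a given value instead.
- Independent per-stratum fits replace a hierarchical covariate model: the
  hierarchical interaction structure is exactly the part that tends not to
  converge on small strata, and independent fits reproduce per-factor
  summaries at desk scale.

### Sampler

Random-walk Metropolis in isometric log-ratio (ilr) coordinates, the
orthonormal bijection between the open simplex and R²; the ilr basis is the
Helmert sub-matrix (`scipy.linalg.helmert`). The change of variables
carries the Jacobian `Σ_k ln p_k` (up to a constant), so a flat Dirichlet
prior on the simplex is exactly preserved — a prior-only run returns
marginal means of 1/3, which the tests verify. Sampled residual SDs move on
the log scale with the matching `+ln σ` Jacobian.

Updates are Metropolis-within-Gibbs in two blocks (ilr coordinates; log
residual SDs), each with its own scalar scale adapted every 50 iterations
toward the 20–50% acceptance window, plus a per-component proposal shape
re-estimated every 500 burn-in iterations from the recent sample spread.
All adaptation freezes at the end of burn-in, so the retained draws come
from a fixed, detailed-balance-satisfying kernel. Chains start from
independent random Dirichlet points (overdispersed starts, which makes the
Gelman–Rubin diagnostic meaningful). Chain c of a run with seed s uses seed
s + c; defaults are 3 chains × 10,000 iterations with 5,000 burn-in.

### Diagnostics

The Gelman–Rubin statistic is computed per proportion parameter in its
plain (non-split) form `R̂ = sqrt(((n−1)/n·W + B/n)/W)`; the convergence
threshold is 1.05. Degenerate cases: zero within-chain variance with
between-chain spread reports +inf; identical constant chains report 1.0.
Non-convergence is flagged in the results (and by CLI exit code 3), never
raised, mirroring how such runs are handled in practice (refit or report).

The posterior mode reported by `map_estimate` is the retained draw with the
highest log posterior; tests verify it lands within one 0.02 grid step of a
brute-force simplex grid search of the same density, and that posterior
means match grid-integration expectations.

## Trophic positions (`trophic`)

    TP = 1 + (δ15N_Glu − δ15N_Phe − β) / TDF

β is the Glu−Phe spacing of the primary producer (beech litter 8.77 ± 1.17
‰; spruce needles 7.84 ± 1.00 ‰) and TDF = 7.60 ± 1.20 ‰ per trophic step.
The sign convention is fixed by the producer identity: litter with
Glu−Phe = β must give TP = 1. Coniferous sites use the spruce baseline, all
beech age classes the beech baseline; predators are assigned by their
site's forest type since a finer diet-weighted baseline is not identifiable
from these data.

Uncertainty is propagated to first order:

    TP_sd = sqrt(σ_Glu² + σ_Phe² + σ_β² + ((Glu−Phe−β)/TDF)²·σ_TDF²) / TDF

**Known limitation.** The delta method linearises 1/TDF. With the published
σ_TDF (CV ≈ 16%) the true (Monte-Carlo) SD exceeds the first-order value by
≈ 8–10% at one trophic step and more at higher TP; agreement is within 5%
once the TDF CV is ≲ 7%, and exact (to MC error) when only measurement and
β noise act. `propagate_tp_sd_mc` provides the Monte-Carlo mode for users
who want the unlinearised value; the tests pin both behaviours.

## Energy fluxes (`energyflux`)

Fresh body masses come from group-specific log-log power laws
`ln M = a + b·ln L (+ c·ln W)` (mg from mm). Individual metabolic rate uses
the mass- and temperature-scaling `ln I = ln i0 + a·ln M − E/(kT)` with k =
8.62×10⁻⁵ eV K⁻¹ and region mean temperatures (northern 10.3, central 9.3,
southern 8.6 °C). Community metabolism X sums I·density within a group. The
regression coefficients are deliberately config data in a versioned JSON
(`src/soilchannels/data/constants.json`): the defaults use the overall
phylogenetically corrected invertebrate regression (ln i0 = 23.055,
a = 0.695, E = 0.686 eV) for every group and order-of-magnitude length–mass
laws; studies with taxon-specific coefficients should override the file,
and nothing downstream depends on the defaults beyond positivity and
monotonicity.

Assimilation efficiency is logit-linear in food nitrogen content with a
temperature correction applied as an additive Arrhenius shift on the logit
scale:

    logit(e_a) = 0.471·N% − 2.097 + E_a·(T − T0)/(k·T·T0)

with E_a = 0.164 eV and T0 = 293.15 K. At the cross-region mean temperature
of 9.4 °C this yields e_a = 0.30 (fungi, N = 3.14%), 0.15 (plants, 1.30%)
and 0.73 (bacteria, 7.07%); `check_efficiency_calibration` verifies this
triple at pipeline start-up and warns if the configured correction breaks
it, which guards any re-transcription of the correction constants.

Channel fluxes are `F_k = (X / e_a,k) · p_k` — the energy input a community
must draw from channel k to cover the share of its metabolism attributed to
that channel by the mixing proportions. Dividing by e_a (rather than
multiplying) is required for the units to come out as an input flux:
ingested energy must exceed metabolism by the inverse efficiency. Predator
groups (Chilopoda, Mesostigmata) reach basal resources through prey, so
each of their channel fluxes is additionally multiplied by the carnivore
assimilation efficiency 0.91; the scaling is uniform across channels, so
predator totals are exactly 0.91× the detritivore formula. Predation losses
are not modelled: fluxes quantify basal-channel inputs, not a balanced
food-web flux network.

## Synthetic data (`synthgen`)

The generator emulates the statistical structure the analysis assumes:

- **Sources**: three classes at fixed centred mean fingerprints with
  within-class SD 1 ‰ per eAA; pairwise mean separations 5.5–8.4 ‰ (≥ 4
  within-class SDs), the well-separated regime in which fingerprinting is
  meaningful; class sizes 26/39/59 (bacteria/fungi/plants) as in typical
  training libraries. A `hard` scenario with SD 3 ‰ provides overlapping
  classes for robustness testing.
- **Consumers**: centred profiles are convex mixtures of the library's
  centred class means plus i.i.d. per-eAA residual noise (default 1 ‰) and
  a random bulk offset removed again by centring. Default scenario: three
  detritivore strata × 10 communities at fungal-dominated true proportions
  (0.085, 0.730, 0.185); a Chilopoda-like plant-shifted scenario (0.22,
  0.40, 0.38) and a uniform scenario cover the other observed regimes.
- **Nitrogen**: δ15N_Phe = baseline + noise and δ15N_Glu = δ15N_Phe + β +
  (TP*−1)·TDF + noise, so the trophic equation inverts exactly at zero
  noise. Default true TPs sit at group-typical values (2.69, 3.05, 3.72).
- **Community tables**: log-normal body lengths per group (meso- vs
  macrofauna separated by well over an order of magnitude in mass) and
  uniform per-size-class densities chosen so group totals land in
  field-realistic ranges (earthworms tens per m², microarthropods tens of
  thousands per m²).

All randomness flows from a single seed through fixed-key `SeedSequence`
streams, so components regenerate independently and identically.

What the generator does **not** emulate: correlated measurement error
across amino acids within a chromatogram, batch/drift effects, source-class
covariance structure (classes are axis-aligned Gaussians), diet-tissue
fractionation deviations, and spatial autocorrelation between sites.
Passing tests therefore demonstrate correctness of the estimators under
the model's own assumptions — identifiability, calibration and coverage at
realistic noise levels — not robustness to every field artefact. One known
mild misspecification is deliberate: centring projects the consumers'
residual noise onto the sum-zero subspace, while the fitted model assumes
independent residuals plus process error, making posterior intervals
slightly conservative.

## Problem sizes and numerics

Default analyses run 3 chains × 10,000 iterations on strata of ~10
consumers in 5-D eAA space, which completes in seconds per stratum; the
parameter-recovery studies in the tests use 20 replicates per scenario at
those same settings. Tolerances: simplex closure 1e-9; eigenvalue clipping
at 0; LDA ridge 1e-8·trace; proposal scales clipped to [1e-3, 10];
plausibility screens δ13C (−60, +10) ‰ and δ15N (−30, +40) ‰ warn rather
than fail. Ties in classification break by fixed class order. Empty strata
reduce the posterior to its prior; empty inputs yield empty outputs rather
than errors wherever a sensible empty result exists.
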