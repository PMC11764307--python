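# Methods

`mmlsdm` selects feature subsets and model families for gridded species
distribution data by minimum message length (the Wallace–Freeman 1987
approximation, MML87), with AIC, AICc and BIC as competitors. This note
records the models, the priors, the numerical choices, what the synthetic
generators emulate, and the design decisions that were genuinely open.

## Data model

The survey window is a rectangular lattice of square cells (default 50×25
unit cells, area |A| = 1250, mirroring a 1000×500 m plot divided into
20 m cells). Environmental covariates are piecewise constant per cell.
Species data enter in one of three views derived from a point pattern:
the pattern itself (for point-process families), per-cell counts, or
per-cell binary occupancy. Cells are half-open squares, so aggregation is
a true partition: counts always sum to the number of points.

## Model families

All trends are log-linear (logit-linear for occupancy) in a feature
subset with an intercept, coefficients estimated by maximum
(pseudo)likelihood:

- **IPPP** — inhomogeneous Poisson point process with intensity
  ln λ(u) = θᵀS(u). Because covariates are per-cell constants, the
  discretized likelihood ℓ(θ) = Σᵢ ln λ(xᵢ) − Σ_c λ_c a_c is exactly a
  Poisson regression of cell counts with offset ln a_c (the one
  -quadrature-point-per-cell Berman–Turner device), solved by Fisher
  scoring with step halving (gradient tolerance 1e-8, 100-iteration cap).
  Expected information F = Σ_c s_c s_cᵀ λ̂_c a_c.
- **Poisson / negative-binomial count regressions** — per-cell counts,
  log link, offset ln a_c. NB2 (variance μ + αμ²) is fitted by
  alternating Fisher scoring in the coefficients with a bounded
  one-dimensional ML update of ln α; the reported log-likelihood is the
  ML log-likelihood, as standard NB GLM software returns. The *reported
  dispersion statistic* — the quantity carrying the prior in the message
  length — is the Pearson chi-square over the residual degrees of
  freedom, X²/(n−p), a quasi-likelihood variance-inflation estimate (≈1
  under equidispersion). For its coding curvature the statistic is mapped
  to the NB2 size through the variance identity at the mean fitted value.
  A plug-in variant that also evaluates the likelihood at the mapped size
  exists behind `dispersion_method="pearson_plugin"`; it is not the
  default because the Pearson statistic is noise-dominated at the small
  cell means typical here (≈0.4), and its likelihood can fall below
  Poisson's even on clearly overdispersed data.
- **Logistic occupancy regression** — Bernoulli ML with logit link;
  F = Σ_c s_c s_cᵀ p̂_c(1−p̂_c). Diverging coefficients (|β| > 10³) are
  reported as separation.
- **Hardcore process** — exclusion radius estimated by its ML value, the
  minimum pairwise distance r̂; trend coefficients by maximum
  pseudolikelihood, where a quadrature cell contributes zero conditional
  intensity if its center lies within r̂ of a point outside that cell.
  The information entry for r is the curvature of a quadratic fit to the
  pseudolikelihood profiled over a 41-point geometric grid in
  [r̂/2, r̂] (the grid size is exposed as `n_profile`).

## Message lengths

A model's two-part message length in nats is

I = ln(K+1) + ln C(K, D) + Σᵢ[½ln 2π + ln 10 + θᵢ²/200] [+ ln μ + x/μ]
    + ½ln|F| + (D_c/2)(ln κ_{D_c} + 1) − ℓ

- The discrete prior codes the subset size uniformly over 0..K, then the
  subset uniformly among C(K, D) of that size. D here counts *selected
  features* only.
- Each coefficient has an independent N(0, 10²) prior, appropriate for
  standardized covariates. The extra positive parameter — NB dispersion
  statistic or hardcore radius — carries an exponential prior with mean
  equal to the mean cell count (NB) or |A|/n (hardcore; a square-root
  variant `sqrt_mu=True` reads the per-point square's edge length
  instead).
- The Fisher/lattice dimension D_c counts *all* continuous parameters:
  intercept, coefficients, and the extra parameter when present. Keeping
  the two counts separate honors both roles the dimension plays.
- κ_D is the optimal-quantizing-lattice constant. The default evaluates
  the asymptotic form (D/2)(ln κ_D + 1) ≈ −(D/2)ln 2π + ½ln(Dπ) + γ for
  every D, uniformly; `lattice_mode="exact_small"` substitutes the
  tabulated κ₁ = 1/12, κ₂ ≈ 0.080, κ₃ ≈ 0.079 below dimension 4 for
  sensitivity checks.
- Model-family indicator bits cost 0 by default (equal family priors, a
  cost common to every candidate); `family_cost_nats` adds ln(#families)
  for strictly decodable multi-family messages.
- |F| is computed from the eigenvalues of the symmetrized information;
  an eigenvalue at or below 1e-10 is reported as singular information
  rather than silently producing −∞.
- The extra parameter's information entry (NB dispersion curvature by
  finite differences, hardcore radius curvature from the smoothed
  profile) is floored at the squared inverse of its prior mean. This is
  the MML87 small-information correction: when the likelihood is locally
  flat — e.g. the dispersion statistic sits at the equidispersion
  boundary — the parameter's statement precision is bounded by the
  prior's width, so the parameter costs about its prior length and can
  never *shorten* the message through a vanishing half-log-determinant.
  (With an arbitrary tiny floor, an uninformative parameter would
  subsidize its family by −½ln(floor) nats and the NB family could beat
  Poisson on exactly Poisson data.)

Two codes for the same event may be mixed: I₃ = −ln((e^{−I₁}+e^{−I₂})/2),
computed by log-sum-exp and clamped at min(I₁,I₂) against rounding; the
mixture never costs more than one bit over the better code.

## Selection

Candidates are all nonempty subsets of the K-feature pool (2^K − 1), plus
the intercept-only model under MML, whose discrete prior codes D = 0
explicitly; classical criteria exclude it, following the convention that
their competitions start at one feature. AIC = −2ℓ + 2k,
AICc = AIC + 2k(k+1)/(n−k−1), BIC = −2ℓ + k ln n, with k counting all
free continuous parameters (intercept and dispersion/radius included; a
features-only variant is config-exposed) and n the number of points for
pattern-based families and of cells otherwise (also config-exposed — the
criteria's n is genuinely ambiguous for point processes).

The MML search walks subset sizes instead of enumerating: start at
⌊K/2⌋, evaluate the per-size minima there and at both neighbors, walk in
the improving direction while the next size *strictly* improves (plateaus
halt), clamped to [0, K] (or [1, K] when the intercept-only model is
excluded). Each visited size is minimized over all C(K, k) subsets, so
the walk is exact whenever per-size minima are unimodal in size — the
regime the discrete prior's U-shaped cost induces in practice. Ties break
deterministically: smaller size, then lexicographic subset order, then
family declaration order.

## Synthetic generators and what they do (not) show

Covariate fields are Gaussian-kernel-smoothed white noise (length-scale 3
cells), standardized, then rotated to principal-component scores — a
stand-in for PCA-transformed soil chemistry maps. PCA sign ambiguity is
removed by flipping each loading vector so its largest-magnitude entry is
positive. The generating intensity uses the first four components, each
weighted by the reciprocal of its standard deviation so all contribute
equally, with intercept −3: on the default grid this yields roughly
450–500 expected points, matching the reference design's scale. Test
patterns are generated independently from the same intensity and thinned
with the same retention as training (whether the original protocol
thinned its test patterns is not stated; thinning both keeps train and
test scales comparable).

The misspecification protocol generates from components 5–8 inside an
8-component candidate pool and aggregates to counts or occupancy. Counts
aggregated from a pure IPPP with per-cell-constant covariates are exactly
Poisson, so the negative binomial could never be the better family; the
protocol therefore uses a Cox (doubly stochastic) generator: each cell's
intensity is multiplied by an iid Gamma(1/a, a) effect, making cell
counts negative binomial with size 1/a. The default mixing variance
a = 1 (size 1) is the classic strongly aggregated regime for tree
counts; at the cell means here it produces Pearson dispersion statistics
around 1.3–1.6 — overdispersion that is unmistakable at n = 1250 yet
"not large" in absolute terms. Smaller mixing (a ≈ 0.25) leaves a
non-negligible fraction of realizations effectively equidispersed, in
which case message length and BIC correctly prefer Poisson — those runs
probe the generator, not the selector.

Because the real soil covariates differ from these synthetic fields, the
simulations validate *method properties* (exact subset recovery, family
discrimination, search-vs-enumeration agreement), not any particular
predictive log-likelihood value; reference log-likelihood tables tied to
the real tree-census data are out of scope.

Seed management: one master seed spawns per-trial substreams
(SeedSequence over [seed, trial, attempt]), so trials are independent and
individually replayable; a degenerate trial (constant occupancy, failed
fit) is rerun on the next substream and logged, never dropped — averages
are always over the configured number of valid trials.

## Problem sizes

The shipped protocols run at 20–50 trials on the 1250-cell grid: the
feature-selection study at K = 8 (and a hardest cell at K = 12 with
retention 0.5), the misspecification studies at 50 trials. A single
Poisson-family fit costs well under a millisecond, an NB fit a few
milliseconds, so a full 50-trial two-family study completes in about two
minutes on one core.

## Known limitations

- The hardcore radius information entry rests on a smoothed profile of a
  non-smooth pseudolikelihood; its magnitude (and hence a fraction of a
  nat of the hardcore message) depends on the profile window, which is
  why the window is config-exposed and floored rather than trusted
  blindly.
- Whether the hardcore's extra coded parameter is the radius itself or
  its prior's hyperparameter is ambiguous in the source formulation; the
  radius reading is implemented.
- The NB dispersion statistic is coded with an exponential prior whose
  mean is the mean cell count; for very sparse patterns (mean count ≪
  dispersion statistic) this prior is informative and slightly penalizes
  the NB family.
- Point estimation is maximum likelihood throughout; MML-optimal point
  estimates for point processes are deliberately not attempted.
- Only log-linear trends are supported; no splines or quadratic terms.
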