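# Methods

## The model

`dynsrm` fits social relations models (SRMs) to *clustered longitudinal
round-robin* data: within each family (cluster) k, every pair of members is
observed interacting in both directions over a sequence of snapshots, and
members are distinguished by role — mother (M), father (F), younger child
(S1), older child (S2).  The directed response of actor i towards partner j
at snapshot t decomposes as

    y*_tijk = mu_ij + f_k + a_ik + p_jk + d_ijk + e_tijk

with a dyad-type mean `mu_ij` (optionally `mu_ij + beta1_ij t` with a linear
snapshot trend), a family effect `f_k ~ N(0, sigma2_f)`, bivariate
role-specific actor/partner effects `(a_ik, p_ik) ~ N2(0, Sigma_ap[i])`
whose correlation is the *generalised reciprocity*, and bivariate
relationship effects `(d_ijk, d_jik) ~ N2(0, Sigma_d[ij])` whose correlation
is the *dyadic reciprocity*.  The time-varying residual pair of an
undirected dyad follows a first-order vector autoregression

    e_t = Phi e_{t-1} + eta_t,   Phi = [[phi1_ij, phi2_ij],
                                        [phi2_ji, phi1_ji]],

where `phi1` captures persistence in an individual's own deviations and
`phi2` the *proximal trigger* of the partner's previous deviation.
Innovations `eta_t ~ N2(0, Sigma_eta[ij])` and the first snapshot's residual
pair has its own free covariance `Sigma_e1[ij]`.  Stationarity of `Phi` is
*not* imposed during estimation; it is required only where a stationary
quantity is requested (stationary simulator starts, extended VPCs), and
nonstationary posterior draws are excluded there with a reported count.

For ordinal responses with C categories the continuous `y*` is latent and
observed through thresholds `tau_0 = -inf < tau_1 < ... < tau_{C-1} <
tau_C = inf` with `y = c <=> y* in [tau_{c-1}, tau_c)`.  Identification
fixes `tau_1 = 0` and the innovation and first-snapshot variances to 1
(ordered probit).  Binary data are the C = 2 special case.

An equivalent *response-form* parameterisation puts the lag structure on
the responses, `y*_t = theta~ + Phi y*_{t-1} + eta_t`, with transformed
intercept and effects `x~_ij = (1 - phi1_ij) x_ij - phi2_ij x_ji`.  The
`reparam` module implements both forms, and their joint densities agree to
machine precision (this is an acceptance-tested invariant); all reported
parameters are the unconditional ones.

## Estimation

A blocked Gibbs sampler, written for this package:

* **Latent responses** (ordinal, and any missing records): each latent has
  a Gaussian full conditional (its own transition density, its successor's,
  and the same-snapshot partner coupling) truncated to the observed
  category's interval.  Latents are updated in four conditionally
  independent colours — snapshot parity x direction — so one colour is one
  vectorised truncated-normal draw.  Missing responses are imputed
  untruncated rather than dropped, consistent with pair-completion at the
  data stage.
* **Linear predictor components**: per undirected-dyad instance the
  quasi-differenced observations give bivariate Gaussian sufficient
  statistics for the pair (theta_ij, theta_ji); means, family effects,
  actor/partner pairs (cycled role by role; two individuals of one role
  never share a dyad, so each role block vectorises across families) and
  relationship pairs are conjugate Gaussian draws.
* **Phi blocks**: given residuals, each undirected dyad type's 2x2
  coefficient matrix is a multivariate regression with known error
  covariance — a conjugate 4-dimensional Gaussian (2-dimensional for the
  AR-only variant).
* **Variance components**: conjugate Wishart draws for the 2x2 precision
  blocks and a conjugate Gamma draw for the family precision.  Identified
  correlations (ordinal innovation and first-snapshot blocks) use
  random-walk Metropolis on the Fisher-z (atanh) scale — the same transform
  that keeps these correlations in (-1, 1) in generic Gibbs
  implementations — with step sizes adapted towards ~44% acceptance during
  the adaptation phase.
* **Thresholds**: conditional on the latents and the Exp(1) gap priors,
  interior thresholds are *uniform* on the feasible interval between the
  adjacent latent order statistics (the two neighbouring gap densities
  cancel) and the top threshold follows a truncated exponential, so the
  conditional draws preserve ordering by construction.  Because those
  feasible windows shrink like 1/n, conditional draws alone mix very
  slowly; each sweep therefore adds a joint threshold-latent
  Metropolis move that proposes `tau_c -> tau_c + delta` together with a
  piecewise-linear remapping of every latent (stretching the two adjacent
  intervals, or shifting the upper tail), accepted with the exact ratio
  including the transformation Jacobian.  This move makes O(1) jumps of
  the threshold scale possible and is what keeps the desk-scale chain
  lengths below honest mixing requirements.

### Priors

Weakly informative defaults standard for this model class: N(0, precision
0.001) for fixed-part coefficients (means, trend slopes, and the AR/cross-
lag coefficients), Exp(1) for threshold gaps, Wishart(I2, 2) for 2x2
precision blocks, Gamma(0.001, 0.001) for the family precision, and a
Normal prior on the atanh-transformed identified correlations.  For that
last prior two conventions circulate — precision 0.001 (diffuse) and
variance 0.001 (which shrinks correlations to ~0 and is most plausibly a
transcription slip in accounts of this model).  The default is precision
0.001; `FitConfig(strict_correlation_prior=True)` selects variance
0.001 for exact comparability with reports that used it.

Continuous-model innovation and first-snapshot covariances get the same
Wishart treatment as the other 2x2 blocks; the tanh device is used only
where a variance is pinned to 1.

### Chain settings

`FitConfig` defaults are desk-scale (4 chains, 1,000 adaptation / 2,000
burn-in sweeps... the shipped defaults are 500/1,000/2,500 monitored with
thinning 5) and are meant for exploration; the named preset
`longrun_chain_config()` (5 chains, 200,000 burn-in, 50,000 monitored storing
every 10th) reproduces the long-run regime a production analysis of ~200
families would use.  Convergence is assessed with the classic (non-split)
Gelman–Rubin PSRF and an initial-monotone-sequence ESS; the default pass
thresholds are PSRF within 0.05 of 1 and ESS >= 1,500, both configurable,
with a split-PSRF variant by flag.

### Degenerate and special cases

* **Cross-sectional reduction.** With one snapshot per dyad and no
  dynamics, a continuous model cannot separate the relationship effect
  from a pair-level residual — the classic confounding of relationship and
  error in single-occasion SRMs.  The sampler detects this case, drops the
  explicit relationship effects, and reports the pair residual block *as*
  the relationship covariance, which is exactly the cross-sectional SRM.
  Ordinal single-snapshot fits keep both blocks (the residual variance is
  pinned to 1 there) and the relationship/residual split is then partly
  prior-driven — a property of the model, not of this implementation.
* **Empty blocks** (e.g. a dyad type absent from every family) fall back
  to prior draws; prior draws of unidentified correlations are clipped to
  |rho| <= 0.999999 to keep the working matrices invertible.
* The diffuse Gamma(0.001, 0.001) family precision can underflow double
  precision in prior-only runs; draws are floored at 1e-290.
* Truncated-normal draws with vanishing interval mass return the
  conditional mean clipped to the interval.

## The simulator

`simulate_dataset` emulates the design of an intensive family-interaction
study: K families (default 200); composition mix 156:65:1:1 over
{M,F,S1,S2}, {M,S1,S2}, {M,F,S1}, {M,F,S2} (a cohort of ~223 families of
which 65 lack a participating father and 2 lack a child); per-undirected-
dyad durations equal to the 15-snapshot maximum with probability 0.293 and
otherwise uniform on 3..12, giving mean 9.7; a 4-category ordinal response;
and 1% missingness injected completely at random at the undirected-dyad ×
snapshot level so both directions are always missing together (the
both-or-neither rule holds by construction).  The `paper-like` preset uses
reported point estimates of this model class for the dynamics (phi1 in
[0.07, 0.24], phi2 in [-0.05, 0.10]) and innovation correlations (up to
0.33), observed dyad-type means mapped to the latent scale, and variance
components chosen so relationship shares dominate family shares; the
`headline` preset flattens the dynamics to phi1 = 0.2, phi2 = 0.1,
rho_eta = 0.2 for recovery benchmarking.  Thresholds (0, 2, 4) make one
latent unit half a threshold gap.

What the simulator does **not** emulate: rater disagreement and
double-coding, non-random missingness mechanisms, duration-by-dyad-type
differences, age/sex covariate structure, and any departure from
(multivariate) normality of the effects.  Passing recovery tests therefore
show that the estimator inverts its own generative model at realistic
sizes and magnitudes — not that real interaction data meet these
assumptions.

## Evaluation battery

`dynsrm.evaluation` (run by `scripts/acceptance.py` and the acceptance
tests) checks, at desk-scale problem sizes chosen to run on one CPU in
minutes:

1. identification constraints hold *exactly* in every stored draw of an
   ordinal fit (K = 20, T = 5);
2. residual-form and response-form joint log-densities agree within 1e-8
   over 100 random parameter sets;
3. the discrete-Lyapunov stationary covariance matches the empirical
   covariance of ~10^6 simulated VAR(1) steps within 2% (normalised by the
   dominant entry);
4. the empirical covariance of 2,000 simulated families matches the
   implied marginal covariance entrywise within Monte-Carlo error (>= 99%
   of entries inside 3 SEs, none beyond 6);
5. with effects and dynamics disabled the fitter agrees with an
   independent maximum-likelihood ordered probit within 3 combined
   standard errors (n = 2,000);
6. continuous T = 1 fits (K = 500) recover every generating variance
   component and reciprocity correlation within 3 posterior SDs;
7. across 20 replicate ordinal AR+cross-lag fits (K = 100, mean T ~ 9.7),
   95% credible intervals cover the generating phi1, phi2 and innovation
   correlations at >= 80%, with pooled |bias| <= 0.05 per coefficient
   class;
8. variance-share and extended-VPC chains sum to 1 per draw exactly, and a
   parameter's contrast with itself is identically zero.

## Design choices and limitations

* Trend slopes default to one per undirected dyad (shared by both
  directions), with `trend_scope="directed"` available; nothing in the
  model forces either convention.
* Draws serialise to a plain CSV with JSON metadata header — lossless
  (17 significant digits, round-trip parsing) and self-describing.
* Category labels need not be contiguous on input;
  `relabel_categories` maps the used labels onto 1..C and keeps the
  original coding as metadata, since thresholds are defined per gap
  between *used* categories.
* First-order dynamics only; higher-order lags, random (family- or
  dyad-varying) phi coefficients, growth-curve/ALT extensions, covariates
  beyond the linear trend, and non-probit links are out of scope.
* Single-site latent updates plus the threshold moves mix well at the
  tested sizes, but very long series or C >> 4 categories may still need
  the long-run chain preset.
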