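# Methods

`hpdyn` implements the analysis chain used in live-cell single-molecule
tracking studies of heterochromatin-associated proteins (HP1-family readers
such as Swi6 and Chp2, and their partners Epe1, Mit1, Clr3, in fission
yeast): photoactivated single molecules are localized frame by frame
(40 ms exposure), linked into trajectories, classified into diffusive
mobility states, and the state-transition kinetics, chromatin-bound
residence times and spatial organization are quantified.  This note
records the models, the parameters that matter, and the design choices
made where the methods literature leaves them open.

## Trajectory model and simulator (`simulate`)

Motion is modeled as K-state Brownian diffusion: a hidden mobility state
`z_t` switches between frames with a per-frame transition matrix `T`, and
the true displacement per coordinate over one frame is
`N(0, 2 D_z dt)` with `dt = 0.04 s`.  Observed positions add independent
localization noise `N(0, sigma_loc^2)` per coordinate
(`sigma_loc = 0.02 um` by default, typical of PAmCherry in yeast).
Defaults mirror the measured regime of a chromatin reader: `D =
(0.007, 0.13) um^2/s` with ~92.5% of steps in the slow state.

Design choices the underlying experiments do not constrain:

- **Confinement.** The nucleus is a circle of radius 1 um (configurable;
  `R_nuc=None` disables confinement).  Steps that would exit are
  rejection-resampled, which preserves the Gaussian step distribution in
  the interior; localization noise is likewise resampled at the boundary so
  every confined localization lies inside its ROI exactly.  Real nuclear
  boundaries are neither hard nor perfectly circular; trajectories near the
  rim are therefore only qualitatively realistic.
- **Photobleaching.** Track lengths are geometric (per-frame bleaching
  probability `p_bleach`, default 0.05), conditioned on the 2-frame minimum
  a displacement requires and capped at `max_len`.
- **Initialization.** Initial states are drawn from the stationary
  distribution of `T`, matching the equilibrium assumption the rate
  inference makes downstream.
- **Seeding.** Every generator consumes a single integer seed through
  numpy's `default_rng`; outputs record it.

The generator emulates state-switching diffusion, confinement, blur and
bleaching, but not photoactivation duty cycles, gap frames, out-of-focus
loss, anisotropic nuclei or chromatin substructure.  Passing recovery tests
on these data therefore demonstrates correctness of the estimators under
the model's own assumptions, not robustness to every artifact of real
movies.

Time-lapse dwell data use the experimental scheme directly: fixed
integration time `tau_int = 0.2 s`, variable dark delays, survival per
frame `exp(-k_diss tau_TL) exp(-k_bleach tau_int)`, emitted as geometric
frame counts.

## Mobility-state inference (`statehmm`)

A finite-K Bayesian HMM over steps: emission per coordinate is
`N(0, s_k^2)` with `s_k^2 = 2 D_k dt + 2 sigma_loc^2`; a Gibbs sampler
alternates forward-filtering backward-sampling of step labels (numba
kernel), conjugate inverse-gamma updates of `s_k^2`, and Dirichlet updates
of the transition rows (concentration 1).  The variance prior is a weak,
data-scaled inverse-gamma (shape 2, scale set to half the mean squared
displacement).  Reported quantities: `D_k = max(0, (s_k^2/2 -
sigma_loc^2)/dt)` (posterior mean and s.d.), weight fractions `pi_k` as the
posterior-mean fraction of assigned steps (the stationary distribution of
the posterior-mean `T` is reported alongside in the diagnostics for
comparison), and the posterior-mean per-frame transition matrix.

Numerical conventions: states are relabeled in ascending `D` every sweep,
so fixed-seed runs are bit-identical and label switching cannot scramble
summaries; the `-2 sigma_loc^2` blur correction is clipped at `D = 0`;
the anti-correlation that localization noise induces between consecutive
steps is deliberately ignored (each step treated independently), a known
approximation shared with the per-step state models this follows — it
inflates apparent `D` of truly immobile molecules by at most
`sigma_loc^2/dt`, which the blur correction removes on average.  Chains
default to 1200 sweeps with 300 burn-in; convergence is monitored with a
split-chain R-hat on each state variance (threshold 1.1) and flagged, not
silently accepted.  Near-identical state variances trigger a merge warning.

The state count is chosen by fitting each candidate K and minimizing
`BIC = -2 log p(steps | posterior means) + n_params ln(n_steps)`, with the
marginal step likelihood from the forward pass; ties break toward smaller
K.  With well-separated states (>= 3x in D) and >= 1e4 steps this
reliably selects the generative K; heavily overlapping states are merged
by construction, which is the desired behaviour for mobility analysis.

Occupancy recovery is assessed against the realized ground-truth step
fractions of the simulated dataset rather than the generative weights: a
dataset of ~500 tracks carries only ~500 independent state sojourns, so
its realized occupancy fluctuates around the generative value with s.d.
~1% — an order of magnitude above the posterior s.d. of the assignment
fractions.  Generative-value consistency is checked separately at the
sojourn-level standard error.

## Rate-constant inference (`bsl`)

The per-frame transition matrix aggregates many fine-grained binding and
unbinding events.  Continuous-time rate constants `k_ij` are inferred with
a Bayesian Synthetic Likelihood sampler: the 40-ms frame is divided into
100 fine steps (`delta_t = 4e-4 s`); M = 1e4 molecules are partitioned
across states by the equilibrium proportions (multinomial) and evolved
with per-fine-step transition probabilities `k_ij delta_t`; the summary
statistic is the per-frame transition count matrix.  2000 simulated
summaries per likelihood evaluation define a multivariate Gaussian
(covariance regularized by `1e-6 tr(C)/d · I`) evaluated at the observed
summary (`M pi_i T_ij`).  Metropolis-Hastings proposals multiply rates by
`exp(s T)` with `T ~ Student-t(10)`: a random rate (`s = 0.02`), all rates
(`s = 0.02/N^2`), or a random opposing pair (`s = 0.01`), the move type
chosen uniformly.  The prior is Jeffreys (`1/rate` per rate); its ratio
cancels the proposal Jacobian exactly, so the chain is a symmetric random
walk in log-rate space and the acceptance ratio reduces to the likelihood
ratio.  Chains default to 5e4 proposals, 20% burn-in, thinning 10; the
chain starts at the matrix logarithm of `T` (negative off-diagonal entries
clamped to 1e-3 /s).  Reported: posterior means and 95% highest-density
intervals; acceptance below 1% is flagged.

Because each molecule evolves independently with the fine-step matrix
`P_delta = I + Q delta_t`, the count matrix after 100 steps is exactly
multinomial with row probabilities `P_delta^100`; the default simulator
draws from this composite law directly (the literal step-by-step walk is
retained as `method="stepwise"` and tested to agree in distribution).
This is an exact algebraic collapse, not an approximation, and makes a
5e4-step chain run in about a minute.

Identifiability: the information in the summary is set by the expected
per-frame transition count `M pi_i T_ij`.  Below roughly 50-100 expected
events the posterior is wide and right-skewed, and its *mean* can sit tens
of percent from the matrix-logarithm point value even though the HDI covers
it; oracle-agreement checks therefore use systems with per-frame
probabilities >= 0.02 (the published matrices have >= ~75 expected events),
and coverage — not point agreement — is asserted in the weakly identified
regime.

## Dwell-time analysis (`dwell`)

Residence times are `tau_measured = (n - 1) tau_TL` for a molecule
detected in n consecutive frames.  The apparent decay rate at each
interval is fitted from the dwell-time distribution: with frame-quantized
data the empirical distribution decays by a constant survival factor p per
interval, so the decay-rate estimator is `k_app = -ln(p_hat)/tau_TL` with
`p_hat = 1 - 1/mean(n - 1 | n >= 2)` (the geometric MLE; standard error by
the delta method).  This estimator is unbiased for arbitrarily coarse
`tau_TL`, whereas the naive continuous-exponential MLE `1/mean(tau)`
underestimates the rate by ~`k tau_TL/2` (12% at `k = 0.26 /s`,
`tau_TL = 1 s`); the naive form is available as `method="mean"` for
comparison.  Single-frame observations carry no dwell information and are
excluded.

True dissociation and photobleaching separate through
`k_app tau_TL = k_diss tau_TL + k_bleach tau_int`: a weighted
least-squares regression (statsmodels WLS, weights from the per-interval
standard errors) gives `k_diss` from the slope and `k_bleach` from the
intercept.  A non-positive slope or strongly negative intercept is flagged
on the result rather than silently returned.  `mean_dwell = 1/k_diss` by
definition.

Stationary dwells are extracted from tracking data as maximal runs of
consecutive frames within `r_stat` (default `3 sigma_loc`) of the run's
first localization, with no gap closing.

## Spatial statistics (`ripley`)

`K(r) = lambda^-1 sum_i sum_{j != i} w_ij I(r_ij < r)/n` with the strict
inequality (many packages use `<=`; with continuous coordinates the two
differ only on ties), `lambda = n/area`, and the nucleus approximated as a
circle.  `w_ij` is the isotropic edge correction: the inverse of the
fraction of the circle of radius `r_ij` centred at point i lying inside
the ROI (closed form for a circular window).  `H(r) = sqrt(K/pi) - r`.
Cells are combined by a mean weighted with the per-cell fit density,
weights normalized to 1.  The default grid is 40 radii from 0.025 to
1.0 um; radii beyond the ROI diameter are flagged unreliable.

Because consecutive localizations of one trajectory are intrinsically
correlated, raw H overstates clustering.  The null model resamples
trajectory-matched replicates: same track count, lengths and ROIs, step
lengths drawn from the empirical step-length distribution, directions
uniform, boundary-leaving steps redrawn, starts uniform in the ROI.
`H_norm = H_data - mean(H_sim)` with the 2.5/97.5% envelope of the
simulated H reported so alternative normalizations can be re-derived.

Heatmaps are rendered from localizations (each contributing a
unit-integral Gaussian, width 0.04 um, on a 0.02-um grid, globally
normalized to max 1) rather than by summing fitted camera pixels — a
deliberate adaptation, since raw frames are out of scope here.

## Pipeline (`pipeline`, `cli`)

Stages run in order (simulate/load, states, rates, dwell, ripley,
heatmap); each stage derives its RNG seed deterministically from the root
seed and the stage label, so a rerun with the same config and seed is
byte-identical.  Outputs are CSV/JSON with unit-annotated keys and carry a
sha-256 config hash in their headers; a manifest records versions, seeds,
files and wall times.  Nucleus masks are circles only — a documented
simplification matching the clustering analysis; segmentation from
autofluorescence is out of scope.

## Problem sizes used in the checks

The shipped consistency checks run at desk scale, chosen as the smallest
sizes at which the targeted standard errors are meaningful: ~1e4 steps
(≈520 tracks) for state recovery, 1e4 molecules per delay and five delays
for dwell recovery, M = 1e4 molecules / 2000 simulations / 2e4-5e4
proposals for rate inference, and 100 repetitions of 500-point patterns
for the edge-correction calibration.

## Known limitations

- The HMM assumes free diffusion between frames; confinement biases the
  fast-state D downward near the boundary (a few percent at
  `D = 0.13 um^2/s` in a 1-um nucleus), so model-matched recovery checks
  run unconfined.
- Weight fractions and the stationary distribution of `T` agree only if
  the data are at equilibrium; both are reported.
- The BSL posterior mean is a biased point estimate in the low-information
  regime (see above); the HDI is the honest summary there.
- Dwell-run detection has no gap closing and a hard `r_stat` threshold;
  blinking fluorophores would fragment dwells and inflate rates.
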