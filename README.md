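# hpdyn

Single-molecule tracking analysis of heterochromatin protein dynamics in
living cells.

HP1-family proteins (Swi6 and Chp2 in fission yeast) and their partners
(Epe1, Mit1, Clr3) bind H3K9-methylated chromatin transiently, on the
milliseconds-to-seconds scale.  Photoactivated single-molecule tracking
resolves this as a small number of *mobility states* — subpopulations of
molecules sharing a diffusion coefficient — switching within individual
trajectories.  `hpdyn` implements the quantitative chain from trajectories
to kinetics for this kind of experiment:

- **Simulation** of K-state Brownian trajectories with per-frame Markov
  switching, confinement in a ~1 μm circular nucleus, localization error,
  geometric photobleaching, and time-lapse dwell acquisition — so every
  estimator is testable without raw movies.
- **Mobility-state inference**: a Bayesian hidden Markov model over steps
  (Gibbs sampler with forward-filtering backward-sampling) giving the
  state count K (by BIC), diffusion coefficients *D_k*, weight fractions
  *π_k*, and the per-frame transition matrix *T*.  The per-step emission is
  Normal(0, 2·D_k·Δt + 2·σ_loc²) per coordinate, Δt = 40 ms.
- **Rate constants** k_ij (s⁻¹) from *T* by Bayesian Synthetic Likelihood:
  the frame is divided into 100 fine steps (δt = 4×10⁻⁴ s), molecule
  populations are evolved stochastically, and a Metropolis–Hastings chain
  with multiplicative Student-t(10) proposals and a Jeffreys 1/rate prior
  samples the posterior; reported as posterior means with 95% HDIs.
- **Photobleaching-corrected residence times** from time-lapse imaging:
  dwell distributions at several intervals τ_TL give apparent rates that
  separate via k_app·τ_TL = k_diss·τ_TL + k_bleaching·τ_int; the mean
  chromatin-bound dwell time is 1/k_diss.
- **Spatial clustering** per mobility state via Ripley's
  K(r) = λ⁻¹ ΣᵢΣ_{j≠i} I(r_ij<r)/n and H(r) = √(K/π) − r with isotropic
  edge correction on the circular nucleus and trajectory-matched
  resampling normalization, plus reconstructed localization heatmaps.

See `docs/methods.md` for the models, defaults and design decisions.

## Worked example

Infer the dissociation rate of a slow-binding factor from its per-frame
transition matrix (slow→fast 0.8%, fast→slow 21% per 40 ms):

```python
import numpy as np
from hpdyn import ObservedTransitions, BslConfig, infer_rate_constants, mean_dwell_time

obs = ObservedTransitions(T_frame=np.array([[0.992, 0.008], [0.21, 0.79]]),
                          dt_exp=0.04)
post = infer_rate_constants(obs, BslConfig(seed=1))
k = post.rate(0, 1)                 # slow -> fast = dissociation
lo, hi = post.hdi(0, 1)
print(f"k_diss = {k:.3f} /s  (95% HDI {lo:.3f}-{hi:.3f}); "
      f"mean dwell {mean_dwell_time(k):.2f} s")
```

```
k_diss = 0.216 /s  (95% HDI 0.174-0.262); mean dwell 4.62 s
```

The posterior mean sits at the continuous-time rate embedded in the
two-significant-figure transition probabilities (the matrix logarithm of
this matrix gives 0.226 s⁻¹); its reciprocal is the mean time a molecule
stays chromatin-bound.  A full simulate → infer-states → infer-rates →
dwell → Ripley run:

```
hpdyn pipeline --seed 7 --out-dir out/
hpdyn simulate --seed 7 --n-tracks 1000 --out out/traj.csv
hpdyn infer-states --trajectories out/traj.csv --k 2 --seed 1 --out out/model.json
```

`infer-states` prints the per-state summary; for the simulated set above
(generated at D = 0.007/0.13 μm²/s, 92.5% slow, confined in a 1-μm
nucleus):

```
 state  D_um2_s  D_sd_um2_s       pi   P_to_0   P_to_1
     0 0.006379    0.000134 0.924405 0.989021 0.010979
     1 0.118215    0.003757 0.075595 0.130192 0.869808
```

(diffusion coefficients in μm²/s, fractions and per-frame transition
probabilities dimensionless; the fast-state D reads a few percent low
because confinement truncates the longest steps — see
`docs/methods.md`).

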