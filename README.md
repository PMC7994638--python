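# pigmove

Behavioral-state segmentation of GPS telemetry and state-specific resource
selection for wild pigs (*Sus scrofa*) — or any terrestrial animal tracked
at regular fix intervals.

Wildlife managers targeting an invasive generalist need to know not just
*where* animals are, but *what they are doing there*: resting and foraging
sites (close-contact, disease-relevant behavior) call for different
interventions than travel corridors. `pigmove` implements the full analysis
chain for that question:

1. **Movement HMMs.** Cleaned hourly GPS tracks are summarized as step
   lengths `ℓ_t` and turning angles `φ_t`, modelled by a K-state hidden
   Markov model with gamma step emissions (mean `μ_k`, SD `σ_k`),
   wrapped-Cauchy turn emissions (angular mean `μφ_k`, concentration
   `ρ_k`), and hour-of-day entering the transition probabilities through a
   multinomial logit with a first-order cosinor:

   `η_ij(h) = β0_ij + βc_ij cos(2πh/24) + βs_ij sin(2πh/24)`,
   `Γ_ij(h) = exp(η_ij) / (1 + Σ_{j'≠i} exp(η_ij'))`.

   Models with 2 and 3 states are fitted by maximum likelihood from 25
   random starting-value sets, compared by AIC, and decoded with the
   Viterbi algorithm.  States sorted by ascending `μ_k` are interpreted as
   resting, foraging, and traveling.
2. **Second-order RSF** (home-range placement): logistic regression of
   systematic 90-m grid points inside each individual's 95% fixed-kernel
   home range (used) against grid points across the buffered study-area
   MCP (available).
3. **Third-order RSF** (behavior-specific, within home range): logistic
   GLMM with a per-animal random intercept contrasting the GPS fixes
   decoded to each behavioral state against home-range grid points, fitted
   by adaptive Gauss–Hermite quadrature.

Covariates are Euclidean distances to land-cover classes and linear
features plus percent canopy cover, standardized before fitting and
screened at Pearson |r| > 0.6; coefficients are reported as odds ratios
per 100 m (distances) or per 10 percentage points (canopy) with Wald 95%
CIs, and discrimination as rank-based AUC.

A synthetic-data module generates landscapes, tracks, and selection point
patterns with known parameters, so the entire pipeline is testable without
field data.

## Worked example

Simulate eight females' low-forage-season tracks from the default
generating parameters and refit:

```python
import numpy as np
from pigmove import synthetic, MovementHMM

params = synthetic.default_hmm_params("female", "low_forage")
rng = np.random.default_rng(7)
series = [
    synthetic.simulate_track(params, 1000, rng=rng, animal_id=f"F{i:02d}")[2]
    for i in range(8)
]
model = MovementHMM(series, n_states=3, transition_covariate="none")
res = model.fit(n_starts=10, seed=1)
print(res.summary())
```

```
Movement HMM: 3 states, transition covariate = none
log-likelihood = -48757.243   AIC = 97554.486   k = 20
n steps = 8000, n bursts = 8, starts = 10 (9 converged)

state  mean step (m)  SD step (m)  turn mean (rad)  concentration
    1         11.677        7.523            3.138          0.806
    2         38.534       23.642            3.138          0.591
    3        241.945      218.580            0.008          0.854

initial distribution: 0.753 0.048 0.199
transition matrix at hour 0:
  0.798 0.092 0.111
  0.105 0.811 0.085
  0.104 0.102 0.794
```

The three fitted states recover the generating values (gamma means
11.4 / 37.7 / 244.3 m; stay probability 0.8): a short-step state with
turning concentrated at π (resting — jitter around one spot), an
intermediate state also reversal-dominated (foraging), and a long-step
state moving straight ahead (traveling).  `res.decode()` then labels every
step; here 2,785 / 2,658 / 2,557 of the 8,000 steps decode to states
1/2/3.

The full model grid — 8 HMMs, 4 second-order GLMs, 12 third-order GLMMs
for a two-sex, two-season study — runs from one config:

```sh
pigmove run-all --seed 11 --out runs/demo
```

## Layout

- `pigmove.tracks` — fix parsing, cleaning (duplicates, 48-h acclimation,
  mortality), regularization into bursts, step/turn/hour derivation
- `pigmove.hmm` — `MovementHMM` / `HMMResults`, likelihood kernels
  (numba), multi-start fitting, AIC selection, Viterbi decoding
- `pigmove.homerange` — MCP, buffering, href kernel density, isopleths,
  systematic grid sampling
- `pigmove.landscape` — ASCII-grid rasters, distance layers, covariate
  extraction, standardization, collinearity screening
- `pigmove.rsf` — used–available GLM and random-intercept GLMM, odds
  reports, AUC
- `pigmove.synthetic` — landscape/track/selection generators
- `pigmove.pipeline` / `pigmove.cli` — orchestration and command line
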