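# icnet — time-varying interaction networks from quantitative DNA time series

`icnet` reconstructs **time-varying interspecific interaction networks** from
high-frequency, quantitative community time series (e.g. daily DNA
metabarcoding of environmental samples with internal-standard spike-ins) and
computes the network properties that link community diversity to the capacity
of species for interspecific interaction.

It is written for community ecologists and microbial-ecology groups who have
(or want to simulate) abundance time series for tens to hundreds of
coexisting taxa and ask: *who interacts with whom, how strongly, how does
that change through time, and what does it imply for diversity and
stability?*

## The analysis chain

1. **Calibration** (`icnet.calibration`). Internal-standard DNAs of known
   copy number are spiked into every sample; the per-sample through-origin
   regression `reads = slope × copies` converts read counts of every taxon
   into estimated copies/µl.
2. **Preparation** (`icnet.prep`). Taxa are filtered for prevalence,
   abundance and temporal information; series are z-scored; daily diversity
   S, total DNA, and per-taxon coefficients of variation are computed.
3. **Causality screen** (`icnet.edm`). Convergent cross-mapping (CCM) with
   amplitude-adjusted surrogate significance and a cross-map lag criterion
   detects directed causal links between taxa: a cause leaves a recoverable,
   convergent signature in the delay embedding of its effect.
4. **Interaction strengths** (`icnet.smap`). For each effect taxon, a
   multivariate regularized S-map — a locally weighted ridge regression in
   state space, with air temperature and a linear trend as covariates —
   yields the time-varying Jacobian entries IS_{i→j}(t), the interaction
   strength of taxon *i* on taxon *j* at time *t*.
5. **Network properties** (`icnet.network`). Per plot and day:

   - diversity **S** (taxa present), link count **N_link**,
   - mean interaction capacity **IC = 2·ΣΣ_{i≠j}|IS_{i→j}|/S**
     (the summed strength a species gives and receives),
   - mean strength per link **IS_link**, connectance **C = N_link/S²**,
   - dynamic stability (modulus of the dominant eigenvalue of the day's
     interaction matrix; > 1 ⇒ perturbations amplify).

   These satisfy the identity **S = IC / (2 · IS_link · C)** whenever links
   exist. If IS_link converges to a system constant at high diversity, that
   identity becomes a prediction of the maximum supportable diversity,
   **S_max = IC / (2 · IS_conv · C)** — so diversity can be understood
   through what controls interaction capacity and connectance (for
   example temperature and total abundance, probed by `driver_analysis`).

A fully tested **synthetic community simulator** (`icnet.simulate`) —
a temperature-forced multispecies Ricker map with closed-form Jacobians,
plus a multinomial sequencing observation model with internal standards —
provides ground truth for every stage.

## Worked example

Simulate a two-species oscillating community with known coupling, then
reconstruct it:

```python
import numpy as np
from icnet import (SimulationConfig, simulate_community,
                   InteractionNetworkModel, SmapConfig)

A = np.array([[2.5, 0.3],      # A[i, j]: per-capita effect of j on i
              [0.4, 2.5]])     # (positive = suppressive); diagonal = self-regulation
config = SimulationConfig(
    n_species=2, n_steps=200, interaction_matrix=A,
    growth_rates=np.array([2.5, 2.5]), process_noise_sd=0.01,
    temperature_sensitivity=np.zeros(2), seed=11,
    initial_abundance=np.array([1.0, 1.1]))
truth = simulate_community(config)       # trajectories + exact Jacobians

model = InteractionNetworkModel(
    truth.abundances,
    smap_config=SmapConfig(include_temperature_trend=False),  # no forcing here
    E=2)
res = model.fit(seed=1)
print(res.summary())
```

```
Interaction network reconstruction
==================================================
Taxa analysed:          2
Plots x days:           1 x 200
Directed pairs tested:  2
Significant links:      2 (alpha = 0.05)
Snapshots (plot x day): 199
Mean S:                 2.00
Mean IC:                0.7563
Mean IS_link:           0.3781
Mean connectance C:     0.5000
Mean stability |λ_max|: 1.4342 (unstable days: 98/199)
Identity S=IC/(2·IS·C): max rel err 0.00e+00
```

Both directed links are recovered (`res.links_table` shows cross-map skill
ρ ≈ 0.997 with surrogate p = 0 for each), the daily interaction strengths in
`res.tensor` track the analytic Jacobian of the simulator, and every daily
snapshot satisfies the diversity identity exactly. The mean dominant
eigenvalue above 1 says this oscillating community amplifies small
perturbations on about half of the days — fluctuation-driven dynamics, not a
steady state.

Continue with:

```python
res.snapshots            # per-day S, N_link, IC, IS_link, C, stability
res.converged_is()       # system's converged mean interaction strength
res.predict_smax()       # maximum-diversity prediction from IC, C
res.shuffle_control()    # negative control on time-shuffled series
res.save("output/")      # CSV/JSON artifacts + reproducibility manifest
```

A `icnet` command-line tool wraps the same stages
(`icnet simulate | calibrate | ccm | props | shuffle-control | drivers`).

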