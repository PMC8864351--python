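# Methods

This note documents the models and estimators implemented in `icnet`, the
defaults and why they were chosen, what the synthetic data do and do not
emulate, and the numerical conventions.

## 1. Quantitative calibration with internal standards

Each sequencing sample contains spiked standard DNAs spanning a copy-number
gradient (default five standards, 10–6250 copies/µl). The calibration model
is a through-origin linear regression per sample,

    reads_s = slope_sample × copies_s ,

fitted by least squares: `slope = Σ(reads·copies) / Σ(copies²)`, with the
uncentered R² as the fit diagnostic. The intercept is fixed at zero because
a sample with zero template yields zero expected reads; an intercept would
absorb index-hopping/contamination, which is outside this model. Taxon
reads are converted as `copies = reads / slope`. QC: curves with all-zero
standard reads or nonpositive slope are flagged and their samples propagate
as missing values (no imputation) — downstream embedding handles gaps by
masking. Unweighted OLS is used; no saturation handling.

Properties that follow (and are tested): exact round-trip recovery in the
noise-free limit, invariance to per-sample depth rescaling, and
preservation of within-sample abundance ranking.

## 2. Synthetic communities

The simulator is a discrete-time Ricker map with temperature forcing:

    x_i(t+1) = x_i(t) · exp( r_i + b_i·T_t − Σ_j A_ij x_j(t) + ε_it ),
    ε_it ~ Normal(0, σ_p).

This form was chosen because it is the standard nonlinear, state-dependent
multispecies map and its Jacobian is closed-form,

    J(t)_ij = exp(g_i(t)) · (δ_ij − x_i(t) A_ij),   g_i = r_i + b_i T_t − Σ_j A_ij x_j + ε_it,

which provides the exact ground truth that S-map coefficients are supposed
to track. Temperature enters linearly in the exponent so that "net
interactions" after accounting for a shared linear temperature effect are
well defined. Sign convention: `A[i, j] > 0` means taxon j suppresses
taxon i; self-regulation therefore requires a nonnegative diagonal.
Species below 10⁻¹² are clamped to zero and stay extinct (no immigration);
trajectories exceeding 10¹² raise an "unstable parameterization" error
naming the offending step.

The observation model emulates quantitative amplicon sequencing: per
sample, an amplification-efficiency slope drawn once (lognormal, CV
configurable, default 0.3), total depth drawn negative-binomial (mean
50 000, dispersion 0.1), and reads allocated multinomially across taxa and
standards in proportion to copies × slope. The full monitored design —
122 daily samples × 5 plots × 2 filter types = 1220 samples — is the
default grid of `observe_reads`. A `sampling="expected"` mode returns
expected (fractional) reads, i.e. the deep-sequencing, noise-free limit
used by the exact round-trip tests. Not emulated: PCR chimeras, taxonomy,
primer bias (it is absorbed into the per-taxon efficiency), or
compositional interactions between markers — so passing tests validate the
calibration arithmetic and sampling noise handling, not wet-lab biases.

**Reference test systems.** Two-species Ricker with r = 2.5,
A = [[2.5, 0.3], [0.4, 2.5]], process noise 0.01, n = 200: the
period-doubling (oscillatory) regime, where the Jacobian varies strongly
in time yet the local-linear S-map approximation holds; at stronger chaos
(r ≥ 2.7) local linearization degrades and Jacobian recovery is unstable
across seeds, which is a property of the estimator worth knowing, not a
bug. For causality benchmarks, coupled logistic maps
x(t+1) = x(r_x − r_x x − β y) with distinct growth rates (3.6–3.9) keep
the maps desynchronized so that the coupling support is the unambiguous
ground truth.

## 3. Embedding, simplex projection, CCM

Delay embedding uses lag τ = 1 day (the sampling resolution; no evidence
supports another lag at daily grain) and a configurable Theiler window
(default 0). Rows touching missing values are masked, never dropped
silently. Simplex projection predicts one step ahead from the E+1 nearest
embedded neighbours with weights exp(−d/d₁) (uniform fallback when d₁ = 0,
neighbour ties broken toward the earlier time index); the embedding
dimension is the smallest E whose leave-one-out skill comes within 10⁻³ of
the best over 1..E_max, so flat skill profiles do not inflate E.

CCM cross-maps the cause from the effect's embedding: library subsets of
increasing size L are drawn (20 draws per size, averaged), and the skill
profile ρ(L) should rise ("converge") for a genuine cause. Significance
combines three conditions:

1. **Surrogate exceedance.** p = fraction of surrogate causes whose skill
   at the largest library exceeds the observed ρ_max; requires p < α
   (default α = 0.05, no multiple-testing correction by default;
   Benjamini–Hochberg can be applied across pairs by the caller). The
   p-value uses a single statistic deliberately: an intersection rule
   ("surrogate beats the observation on convergence *and* ρ_max") is
   anti-conservative, because jointly exceeding two statistics is rarer
   than exceeding one, inflating type-I error beyond α. Extra requirements
   are instead applied as separate conditions, which only reduce
   rejections.
2. **Convergence.** ρ_max − ρ_min > 0.
3. **Cross-map lag.** Cross-map skill is profiled over prediction lags
   tp ∈ {−3..3}; the best skill at tp ≤ 0 must come within 0.05 of the
   best overall. Rationale: a cause precedes its signature in the effect,
   so skill should peak at a non-positive lag. Under strong unidirectional
   forcing the driven variable genuinely encodes the driver and the naive
   reverse test fires (its skill peaks at *positive* lags, by 0.25–0.31 in
   the logistic benchmark); under tight bidirectional coupling the profile
   is nearly flat (gaps ≤ 0.002) and the peak location is noise — hence a
   tolerance rather than a strict argmax. The condition is config-exposed
   (`require_nonpositive_lag`).

Surrogates default to amplitude-adjusted phase randomization (AAFT):
plain phase randomization preserves the spectrum but Gaussianizes the
marginal, which measurably inflates type-I error for skewed series;
rank-remapping onto the observed values fixes the marginal. Plain
phase-randomized and circular time-shift surrogates remain options.

Measured operating characteristics on the coupled-logistic benchmark
(coupling 0.3, n = 400, E = 2): true-direction detection 50/50, reverse
direction 0/200, independent-noise pairs ≈ 4–8% at α = 5%, shuffled-series
screens ≈ 5%. Known limitation: synchronized or phase-locked oscillators
(e.g. equal-growth-rate coupled Ricker communities) cross-map each other
almost perfectly in every direction, so CCM over-detects links there; no
cross-mapping method distinguishes synchrony from causality.

## 4. Multivariate regularized S-map

For each effect taxon, the predictors are its own lag plus its significant
causes, and (by default) the standardized air-temperature series and a
linear time trend as covariates — "net" interactions after removing the
shared seasonal forcing. (Alternative reading — detrending each series by
temperature before fitting — is available via preprocessing, but
covariate-inclusion is the default.) For target time t* the model solves a
weighted ridge regression predicting effect(t+1) with weights
w(t) = exp(−θ·d(x_t, x_t*)/d̄) over the cause coordinates, d̄ the mean
distance. The coefficient row at t* is the local Jacobian estimate
IS_{i→j}(t*) on the standardized scale (no back-transformation; network
properties use absolute standardized strengths; note that standardization
is a similarity transform of the coefficient matrix, so eigenvalues — and
hence dynamic stability — are unaffected by it).

Numerical conventions: coefficients at t* are fitted on *all* observations
(the target row carries the maximal weight 1), so θ = 0, λ = 0 reproduces
the global least-squares solution exactly; the leave-one-out forecast used
for skill and hyperparameter selection refits with the target row's weight
zeroed. The intercept is unpenalized (a no-intercept mode matches the
textbook ridge closed form exactly). θ and λ default to leave-one-out-RMSE
selection over θ ∈ {0, 0.1, 0.3, 1, 2, 4, 8} and λ ∈ {0, 10⁻³, 10⁻²,
10⁻¹, 1}; ridge (L2) is the regularizer. Models with (number of
predictors)² exceeding the usable series length are flagged in a
reliability report; p ≥ n with λ = 0 is an error.

## 5. Network properties and the diversity identity

Per (plot, day): S counts taxa with positive estimated abundance that day
(switchable to the filtered-set definition); links are off-diagonal fitted
entries with |IS| > 0 among present taxa. IC = 2·ΣΣ_{i≠j}|IS|/S,
IS_link = ΣΣ|IS|/N_link, C = N_link/S². Self-loops are excluded from
N_link, IC and IS_link but the diagonal (self-regulation) is kept in the
stability matrix, since intraspecific terms are part of the community
Jacobian; both choices are flags. With those definitions

    S = IC / (2 · IS_link · C)

is an algebraic identity whenever N_link > 0 (verified to 10⁻¹⁰ on random
tensors); its value is as a decomposition: with IS_link pinned at a
system's converged value, S_max = IC/(2·IS_conv·C). The converged mean
strength is system-specific — `estimate_converged_is` takes the mean
IS_link over high-diversity snapshots (S above its 0.75 quantile); the
constant 0.03 built into `HypothesisParams` is a rice-paddy-scale default
and must be re-estimated for any other system, including synthetic ones.

Dynamic stability is the modulus of the dominant eigenvalue of the day's
raw S-map coefficient matrix (no rescaling), restricted to present taxa;
values above 1 mean perturbations amplify in discrete time. On linear
stochastic benchmarks the end-to-end estimate matches |λ_max(A)| to
within OLS sampling error (≈ 0.03 at n = 2000).

The shuffle control re-runs the whole screen on independently
time-permuted series: link counts should drop to the α-budget, and do
(≈ 5% of pairs). The driver analysis applies the same CCM + S-map
machinery to (temperature, total DNA) → (IC, C, S) per plot, emitting
time-varying effect coefficients; snapshot correlations across
(plot × day) points use nonparametric (Spearman) correlation. No outlier
removal is performed anywhere.

## 6. Problem sizes and scope of validation

The validation suite and `scripts/acceptance.py` use: 122-day × 5-plot ×
2-filter design emulation (1220 samples); 100 random tensors for the
identity; n = 500 linear systems for estimator equivalence and recovery;
the n = 200 two-species Ricker for Jacobian tracking; 50 + 200 + 200
replicates of coupled-logistic / noise pairs for CCM operating
characteristics; n = 2000 for stability recovery; and a 5-species
logistic chain with 10 shuffles (200 shuffled pair tests) for the
negative control. These sizes give Monte-Carlo error comfortably below
the tolerances tested while keeping a full run in minutes on one core.

What passing does **not** show: robustness to observation noise levels far
above the simulated ones, to strong synchrony (see §3), to series much
shorter than ~100 points, or to the wet-lab biases excluded from the
observation model. Those are the user's responsibility to assess on real
data — the reliability flags, shuffle control and surrogate machinery are
the in-package tools for doing so.
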