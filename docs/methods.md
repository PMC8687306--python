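# Methods

This note documents the modelling assumptions, parameter conventions,
numerical choices and known limitations of `fluctid`. It complements the
README, which states the estimation problem and the objective function.

## Stochastic and deterministic semantics

A `ReactionNetwork` is a list of mass-action reactions over integer copy
numbers. The stochastic semantics is the continuous-time Markov jump
process with combinatorial mass-action propensities (zeroth order: k;
first order: k·x; heterodimeric binding A+B: k·x_A·x_B; homodimerisation
2A: k·x_A(x_A−1)/2, implemented for completeness though no built-in model
uses it). Trajectories are simulated with the exact Gillespie Direct
Method — no tau-leaping or other approximation — because the method's
signal *is* the exact fluctuation statistics. The value reported at a
grid time t_i is the state immediately after the last event at or before
t_i; event draws never depend on the sampling grid, so refining the grid
and sub-sampling reproduces a coarse series exactly for the same seed.
The inner event loop is compiled with numba.

The deterministic semantics is the mass-action rate equation
dx/dt = Σ_j k_j ∏_i x_i^{s_ij}/s_ij! · (p_j − s_j), integrated with
LSODA at relative tolerance 1e-8 (absolute 1e-10). Steady states are
computed as roots of the rate equations and verified to a residual norm
of 1e-10. Copy numbers are used as given — the Epo model's nominal
concentrations are treated directly as molecule counts, since no volume
conversion is specified for it; real-valued initial conditions are kept
exactly on the ODE side and rounded to integers (with a warning) only for
stochastic simulation.

Every source of randomness descends from one root seed through
`numpy.random.SeedSequence` sub-streams, one per (dataset, ensemble
member, noise draw), so whole studies are bit-reproducible and
parallelisable.

## Built-in models

* **Immigration-death** ∅→X (θ1), X→∅ (θ2·x); defaults (θ1, θ2) = (1, 0.1),
  x0 = 10 (the steady state θ1/θ2). The stationary law is Poisson(θ1/θ2);
  the autocorrelation decays as exp(−θ2·Δ).
* **Gene expression**: ∅→mRNA (k_r), mRNA→mRNA+Pro (k_p·mRNA), mRNA→∅
  (γ_r·mRNA), Pro→∅ (γ_p·Pro); defaults k_r = 20, k_p = 10, γ_r = 1.2,
  γ_p = 0.7, starting at the rounded deterministic steady state
  (k_r/γ_r, k_p·k_r/(γ_r·γ_p)) = (16.7, 238.1).
* **Epo receptor**: ligand binding (k_on, dissociation constant k_D, i.e.
  unbinding at k_on·k_D), receptor turnover (synthesis at the constant
  rate k_t·B_max, degradation k_t), complex internalisation (k_e),
  recycling (k_ex) and two degradation routes (k_di intracellular, k_de
  extracellular); read-outs y1 = scale·(Epo + Epo_e), y2 = scale·EpoEpoR.
  Nominal parameters (B_max, k_on, k_D, scale, Epo(0)) =
  (170, 0.017, 13.2, 9.12, 300) and (k_t, k_e, k_ex, k_di, k_de) =
  (0.17, 0.3, 0.087, 0.065, 0.15), with EpoR(0) = B_max and all complex /
  degraded species starting at 0.

The Epo model's non-identifiability is an exact scaling symmetry: with
c = B_max/170, the map k_on → k_on/c, k_D → c·k_D, scale → scale/c,
Epo(0) → c·Epo(0) leaves both read-outs invariant. The package uses this
closed form as an independent cross-check of the scan-based manifold
estimate in its test suite; the scan is the general-purpose tool.

## The fluctuation measures

**D_diff** is the mean *absolute* consecutive difference of the centered
series, (1/(n−1)) Σ|ν_i − ν_{i−1}|. Without absolute values the sum
telescopes to (ν_n − ν_1)/(n−1), which measures nothing about fluctuation
magnitude; the telescoping variant is available (`absolute=False`) purely
for comparison. D_diff is nonnegative, absolutely homogeneous and
invariant under constant shifts, so with sample-mean centering the
centering constant is immaterial.

**D_act** uses the autocorrelation estimator
R̂(k) = Σ_{i≤n−k}(x_i−μ)(x_{i+k}−μ) / ((n−k)·σ²) with the sample mean and
the 1/n sample variance applied at every lag (a single σ², so R̂(0) = 1).
The autocorrelation time is the linearly interpolated lag at which R̂
first drops below a level l (default 0.6), scaled by Δt. Lags run to
n−2 by default; if R̂ never crosses l the measure is undefined and
returns NaN, which the objective treats as a failed evaluation. D_act is
defined for univariate series only. Finite-series autocorrelation
estimates are biased low, so D_act on short windows sits somewhat below
the infinite-sample value −ln(l)/θ2 of an exponentially correlated
process.

## Mean-field centering

Two modes. *Steady-state mode* subtracts the per-observable sample mean
ν̄ — appropriate for stationary recordings with no trusted initial
condition, and the mode in which ν̄ also supplies the steady-state
estimate entering ρ. *Transient mode* subtracts the ODE solution at the
candidate parameter point, computed from the model's initial condition;
along the manifold this trajectory is (by construction) the same for all
candidates, so centering does not itself discriminate. A known initial
condition takes precedence over ν̄. Simulated ensemble members are
centered the same way as the data (their own sample means in steady-state
mode; the candidate's ODE trajectory in transient mode).

## The objective and its optimisation

F(θ) = Σ_obs (D(ν) − (1/M) Σ_j D(H^(j)))², summed over observable
channels for multivariate data. The objective is stochastic: each
evaluation draws a fresh M-member ensemble from a per-evaluation seed
(common random numbers are deliberately not used; the studies re-simulate
per evaluation). Measurement noise of known amplitude is applied to the
simulations exactly as to the data (additive N(0, σ), or proportional
N(0, σ·|y|)); with unknown amplitude, σ joins the search vector.
Evaluations that fail — event-cap overruns from runaway parameter
proposals (cap 10^7 events per trajectory inside the objective, 10^8 for
direct simulation), manifold evaluations outside the scanned hull, or
autocorrelation times undefined for more than half the ensemble — return
a large finite penalty (10^6 × max(ΣD(ν)², 10⁻³)) so swarm search remains
well-defined.

The optimiser is a global-best particle swarm: inertia 0.7, cognitive and
social coefficients 1.5, particles initialised uniformly in the box with
zero velocity, reflecting boundary handling, every evaluation seeded from
a deterministic stream. Study defaults follow the reference study settings
(10 particles, 25 generations; 20 particles, 100 iterations for the 2-D
(θ, σ) search) with search ranges [0, 1] for θ2, ([0, 1], [0.001, 1]) for
(θ, σ), [0.1, 100] for k_r and [100, 1000] for B_max. Because the
objective is noisy, the returned global best is the best *observed*
evaluation; no re-evaluation or averaging is applied, matching the
studies' original procedure.

## Manifold estimation by scanning

`estimate_rho_by_scan` fixes the free parameter at each grid value and
refits the dependent parameters (in log space, Levenberg–Marquardt) so the
deterministic observables match a reference trajectory computed at the
nominal point, with residuals scaled per observable by its maximum
magnitude. Fits continue from the previous grid point's solution, with up
to four randomised restarts; a grid point whose scaled RMS residual
exceeds 1e-4 is flagged off-manifold. Fitted points are interpolated with
a monotone piecewise cubic (PCHIP; linear for two-point grids) and
evaluation is restricted to the scanned hull. The Epo scan uses 19
log-spaced points on [100, 1000] by default and recovers the nominal
dependent parameters at B_max = 170 to well under 0.1%.

## Quantile-scan confidence intervals

For a grid of free-parameter values, M simulations per point give an
empirical distribution of the measure; the bracketed interval is the set
of grid values whose 10–90% quantile band contains the data's measure,
with endpoints refined by linear interpolation and grid-edge endpoints
flagged open. By construction the bracket attains ~80% coverage of the
true parameter when the band is evaluated at the truth; replication
experiments with the stationary immigration-death design measure
coverage 0.796 ± 0.015, i.e. the construction is calibrated at its
nominal level.

## Recovery studies

`run_recovery_study` simulates independent datasets at the truth,
estimates the free parameter per dataset, derives the paired parameters
through ρ, and reports per-parameter means and the average relative error
(mean over datasets of 100·|estimate − truth|/truth). Per-dataset
estimator failures are recorded, never dropped silently. Design choices
mirroring the reference studies:

* Immigration-death: 100 samples, Δt = 0.5, data started at x0 = 10;
  θ2 free; ρ and the derived θ1 use each dataset's own sample mean ν̄
  (dataset-specific, since the steady state is treated as unknown).
* Gene expression: 50 samples, Δt = 0.3; ρ maps k_r to
  k_p = γ_r·γ_p·Pro^s/k_r with Pro^s from the protein sample mean
  (steady-state mode) or from a deterministic least-squares fit of the
  product k_r·k_p on the induction transient from (mRNA, Pro) = (0, 0)
  (perturbation mode — the transient's starting state is this package's
  assumption, as induction from zero is the standard perturbation).
  By default both mRNA and protein *fluctuations* enter the measure
  (means subtracted, so the deterministic information in the mRNA level
  is unused). This choice is deliberate: with the protein channel alone
  the measure is a mean of 49 increments whose sampling coefficient of
  variation (≥11%) passes through a response curve of elasticity
  |d ln D/d ln k_r| ≈ 0.22, giving an irreducible per-dataset spread of
  roughly 50–100% and a right-skewed, range-limited estimate
  distribution; the two-channel measure brings the average relative error
  to ~20%. The protein-only variant remains available
  (`observed="pro"`) and its behaviour is a useful illustration of how
  inter-sample spacing and channel choice bound what the measure can
  resolve.
* Epo receptor: 160 samples, Δt = 0.1, bivariate (y1, y2) by default
  (y1-only supported); transient-mode centering; B_max free along the
  scan-estimated manifold; noise scenarios as configured.

## Problem sizes and runtime

The full reference studies use 50 datasets and M = 200 simulations per
objective evaluation. The bundled test-suite and acceptance-script runs
use 8–30 datasets and M = 40–200 with correspondingly reduced swarm
sizes, chosen so the whole pipeline completes in minutes on one core;
means over replicate datasets are then accurate to a few percent
(standard errors are reported alongside in the result tables). All sizes
are recorded in the outputs.

## What the synthetic data does and does not emulate

All study inputs are generated by the package's own exact simulator at
the nominal parameter values, with Gaussian measurement noise overlaid
on the (scaled) observables — matching how the original studies produced
their inputs. This validates the estimation machinery end to end, but it
shares the generator's assumptions with the estimator: mass-action
kinetics, constant rates, perfectly equal sampling intervals,
homoscedastic Gaussian noise, and intrinsic noise as the only source of
biological variability. Passing tests therefore demonstrate correct
recovery *within* this model class, not robustness to model
misspecification, extrinsic cell-to-cell variability, non-Gaussian or
autocorrelated measurement error, or unequal sampling.

## Known limitations

* The measures presume the inter-sample interval is shorter than the
  system's autocorrelation time but long enough for several events;
  outside that window the objective flattens and the non-identifiability
  persists (the coarse-sampling regime is directly reproducible with the
  scan tools).
* With unknown noise amplitude the objective has a compensation valley —
  larger σ trades off against lower rates — so only a bounded region,
  not a point, is identified; σ estimates are strongly biased upward.
* High measurement noise biases the estimates themselves (no bias
  correction is implemented).
* Only 1-D non-identifiability manifolds are supported.
* D_act requires stationarity and a univariate channel, and inherits the
  small-sample bias of autocorrelation estimation.
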