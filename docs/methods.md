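# Methods

`causalflow` asks a single scientific question: can the effect of stimulating
one unit of a neural circuit be predicted from directed functional
connectivity inferred while the circuit is *not* being stimulated?  The
package implements both sides of that question — a causal-flow estimator for
resting activity, and an interventional-connectivity measure for
perturbation sessions — plus a fully specified ground-truth simulator on
which the prediction can be validated, and the information-theoretic
estimators it is compared against.

## Causal flow (CF)

For units $i, j$ with activity $x_i(t)$, the delay (Takens) embedding of
unit $i$ is

$$X_i(t) = \big(x_i(t),\, x_i(t-\tau),\, \dots,\, x_i(t-(d-1)\tau)\big),$$

with dimension $d$ and delay step $\tau$ (samples).  Convergent
cross-mapping scores the directed influence $j \to i$ by how well unit $i$'s
embedding reconstructs unit $j$'s series: if $j$ drives $i$, then $i$'s
attractor contains a signature of $j$'s state.  Reconstruction uses simplex
projection — for each held-out time $t$, the $k = d+1$ nearest library
neighbors of $X_i(t)$, with weights $\exp(-\delta/\delta_{\min})$ on their
distances, vote on the value of $x_j$ at the neighbors' time indices — and
skill is the Pearson correlation $\rho$ between predictions and held-out
truth, reported as the Fisher transform $z = \operatorname{arctanh}(\rho)$
(clipped at $|\rho| = 1 - 10^{-12}$).  The CF matrix stores
$F_{ij} = z(\rho(X_j \mid X_i))$ with **rows = targets (reconstructors)**
and **columns = sources**; column $j$ is the CF vector $f^{(j)}$.

Cross-validation uses contiguous-block $K$-fold ($K=5$) with a Theiler
exclusion window of $(d-1)\tau$ samples between the held-out block and the
library, so temporal autocorrelation cannot masquerade as predictive skill.
Predictions from all folds are pooled into a single $\rho$.  Neighbor ties
are broken by earlier time index; a constant unit is flagged missing (with a
warning) rather than failing the whole matrix.

Hyperparameters: `select_hyperparameters` scans $d \in \{2..10\}$,
$\tau \in \{1..8\}$ and returns the smallest $(d, \tau)$ whose median
cross-map skill over a probe pair set is within 0.02 z-units of the grid
maximum (accuracy plateaus once the attractor is unfolded).  For the
simulator experiments the package uses fixed $d=8$, $\tau=8$ on 0.1-t.u.
bins: the embedding window $(d-1)\tau \cdot 0.1 = 5.6$ t.u. then spans about
one characteristic period of the chaotic driver (~6.1 t.u.), the standard
prescription for oscillatory flows, and was confirmed against the
known-coupling pair before any validation experiment was run.

## Twin-surrogate significance

The null model for a CF entry must preserve the reconstructor's dynamics
while destroying its causal alignment with the source.  Twin surrogates do
this by re-threading the observed trajectory: states whose recurrence
neighborhoods coincide ("twins") are dynamically interchangeable, and a
surrogate walks the trajectory forward, at each visit to a twin class of
size $n$ retaining its own successor with probability $(n-1)/n$ and
otherwise jumping to one of its $n-1$ twins, continuing from the twin's
successor.  Each surrogate starts at a uniformly random state and has the
original length; all surrogate values occur in the original series.

Twin detection works on the max-norm recurrence structure of the embedded
trajectory at a radius equal to the 0.1 quantile of all pairwise state
distances.  Two corrections, standard in recurrence analysis of finely
sampled flows, are applied before comparing neighbor sets: (1) the
tangential (Theiler) band of $(d-1)\tau$ samples around each compared state
is excluded — consecutive samples are trivially recurrent, and without the
correction the only "twins" are adjacent samples, making every surrogate a
pure time shift; (2) a pair must be mutual neighbors and temporally distant,
and their remaining neighbor sets may differ in at most 2% of columns
(exact agreement is the tolerance-zero limit).  Twin classes are the
connected components of this relation.

Significance of $F_{ij}$: recompute the cross-map with the reconstructor
(target $i$) series replaced by each of $n_s = 99$ of its surrogates (same
$d$, $\tau$, folds), then $p = (1 + \#\{F^{\text{surr}} \ge F\})/(1 + n_s)$,
one-sided, add-one; significant when $p < \alpha = 0.05$.  No
multiple-comparison correction is applied by default (per-pair reporting); a
Benjamini–Hochberg flag exists.  The test is calibrated — on independent
white-noise ensembles the false-positive rate stays at the nominal level —
but its *power* on phase-coherent oscillators is intrinsically limited:
twins share oscillation phase, so surrogates retain the phase relation to
any rhythmic source and the null spans the oscillation-autocorrelation
range.  Detection therefore requires amplitude-level skill, not merely
rhythm-level skill; see Limitations.

## Interventional connectivity (IC)

A perturbation session stimulates one source unit with an additive pulse of
strength $S$ (default 10, comparable to the saturation drive of the rate
units) for 100 ms, repeated over 40 trials with jittered onsets and
inter-trial gaps of at least 10 pulse durations.  For each target, activity
is summed in the 200 ms window before pulse onset and the 200 ms window
after pulse offset (the stimulation interval itself is excluded), one scalar
per trial per side.  $S_{ij} \in [0, 1]$ is the two-sample
Kolmogorov–Smirnov statistic between the pre and post distributions —
a rank-based measure, invariant under monotone transforms of the activity,
well-defined for discrete spike counts.  Significance uses a within-trial
label permutation (999 permutations, add-one p) rather than the asymptotic
KS law, which is anticonservative under ties.  Column $j$ of the IC matrix
is the perturbation vector $s^{(j)}$.

## Ground-truth simulator

The network has 103 nodes in two subnetworks with strictly feed-forward
coupling between them:

* **X** — three coordinates of a Roessler system,
  $\tau_0 \dot x_1 = -x_2 - x_3$, $\tau_0 \dot x_2 = x_1 + \alpha x_2$,
  $\tau_0 \dot x_3 = \beta + x_3(x_1 - \gamma)$, with the canonical chaotic
  constants $\alpha = \beta = 0.2$, $\gamma = 5.7$;
* **Y** — 100 rate units,
  $\tau_0 \dot y = -\lambda y + 10 \tanh(J_{YX} x + J_{YY} y + I)$, with
  $J_{YX} = g \cdot \mathbf{1}$ (every rate unit receives the summed
  driver, $g = 0.1$), $J_{YY} \sim \mathcal N(0, g_r)$ i.i.d.
  ($g_r = 0.05$), $\lambda = 1$, $I = 0$.

There is no feedback from Y to X: the asymmetry every inference stage is
validated against.  Defaults: $\tau_0 = 1$ time unit, $dt = 0.01$,
a 2,000-sample transient discarded, 20,000 samples retained.  The package's
time convention maps 1 time unit to 100 ms, so $dt$ is 1 ms, the analysis
bin 10 ms, the pulse one $\tau_0$, and the IC windows two $\tau_0$ — the
pulse displaces a stimulated unit by a finite fraction of its dynamic range,
as micro-stimulation does relative to cortical population time constants.

Integration is fixed-step RK4 (deterministic, adequate for this non-stiff
system); identical parameters including the seed give bit-identical output,
and a zero-strength pulse reproduces the unperturbed trajectory exactly.
Halving $dt$ changes trajectories by under $10^{-4}$ RMS over short
horizons; over the full duration the comparison is dominated by chaotic
amplification of integrator error at the driver's Lyapunov rate
(~0.07/t.u.), which no integrator can evade.  An overflow guard at
$|x| > 10^6$ raises a named divergence error (reachable e.g. at
$\alpha \ge 0.6$).

The base network is deterministic.  Two noise mechanisms are available and
off by default: `sigma_dyn` adds private dynamical noise to the Y units
inside the integration (Euler–Maruyama term), and `inject_noise` adds
*observational* noise at an exact SNR, defined as
$10 \log_{10}(\sigma_{\text{signal}}/\sigma_{\text{noise}})$ dB per unit,
in private (i.i.d. per unit) or shared (one scalar realization scaled into
all units — a common input) mode.  The realized noise is rescaled so the
measured SNR equals the request exactly.  A softplus-Poisson observation
layer (`poissonify`) emulates electrode spike counts when a count-valued
pipeline is wanted.

## The validation experiment

`run_ground_truth_experiment` reproduces the full protocol for one seed:
simulate the resting network; subsample 10 units (all three driver
coordinates plus seven random rate units — sparse electrode sampling);
compute CF on 10 ms-binned resting activity; re-simulate the same network
(same weights and initial conditions) once per subsampled unit with the
pulse protocol (40 trials, 650 t.u. sessions) and compute IC; correlate CF
with IC over all ordered pairs where both are defined (90 pairs), and
likewise for any requested baseline estimator.  `scripts/acceptance.py`
averages these correlations over 4 independent replicates.

At these study conditions the three within-driver pairs are mutually
near-deterministic: their cross-validated $\rho \approx 0.999$ maps to
Fisher $z \approx 3$–4, and their Granger log error ratios are similarly
extreme, while their IC is also the largest.  These high-leverage pairs pull
the pooled Pearson correlations of *all* estimators upward, so the absolute
correlation values depend strongly on the (here fully declared) simulator
parameters; the robust finding is the ordering — CF correlates with IC more
strongly than univariate Granger causality, which beats the remaining
estimators.

## Baselines

All five information-based estimators score source → target influence with
the package-wide matrix orientation and, where requested, a circular
time-shift surrogate null (99 shifts) in place of the twin-surrogate test:

* **GC** — univariate Granger causality,
  $\ln(\text{RSS}_{\text{restricted}}/\text{RSS}_{\text{full}})$ from OLS
  autoregressions (BIC order selection over 1..10; F-test p-value; ridge
  fallback with a warning on rank deficiency);
* **MGC** — conditional GC, the source's lags added to a model already
  containing every other unit's lags;
* **EGC** — extended GC: the same error-ratio improvement from local linear
  fits inside phase-space neighborhoods (10% nearest states, 30 anchors) of
  the joint delay embedding;
* **NGC** — RBF autoregression (20 k-means centers on the lag vectors,
  width = median inter-center distance); the full feature set extends the
  restricted one so the score is nonnegative up to noise;
* **TE** — transfer entropy in bits: plug-in estimate over equal-occupancy
  bins (4 per variable), minus the mean of 20 circularly time-shifted source
  surrogates as bias correction; an undersampling guard rejects
  $n_{\text{bins}}^{2k+1} > T/5$.

## Evaluation statistics

* **Gini coefficient** of a nonnegative vector,
  $G = \sum_{a,b} |v_a - v_b| / (2 m^2 \bar v)$ (population form, computed
  via the sorted-rank identity): 0 for uniform vectors, 0.5 for exponential
  samples; quantifies how hierarchical a CF or perturbation vector is.
  Negative CF entries are floored at zero with a warning.
* **Spatial footprint**: pair values binned by source–target Euclidean
  distance on the array geometry (mean ± s.e.m. per bin; empty bins stay
  missing).  The default synthetic geometry places units on a 10×10 grid
  minus corners (the 96-channel footprint).
* **Distance residualization**: bin-mean detrending (assumption-free;
  residuals have zero mean within each distance bin); with a single-bin
  geometry, the global mean is removed, with a warning.
* **Prediction tests**: pooled Pearson $r$ between CF and IC over shared
  ordered pairs, pooled and per-source linear regressions, and Welch
  t-tests comparing IC across CF-significant vs -nonsignificant pairs (and
  CF across IC groups) — Welch because group sizes differ strongly.  With a
  geometry, all statistics are recomputed on residuals.
* **Hierarchy PCA**: PCA of the CF column vectors followed by 2-means on the
  leading scores recovers the driver/driven partition from sparse samples;
  degenerate (identical-column) inputs are flagged with a NaN silhouette.

## Numerical and design choices

* Half-open windows $[t_0, t_1)$ and 0-based sample indices everywhere.
* $\rho$ clipped before arctanh; zero-variance predictions score $\rho = 0$.
* Simplex weights with exact-match handling when the nearest distance is 0.
* Add-one (pseudocount) empirical p-values throughout; surrogate/permutation
  counts are chosen so the minimum attainable p-value is below $\alpha$
  (requesting otherwise is an error).
* Per-surrogate and per-unit RNG streams are spawned from a single seed;
  every stage is bit-reproducible under its seed.
* Problem sizes used in the shipped tests and acceptance script (10
  subsampled units, 2,000 analysis samples, 40 trials, 99 surrogates, 4
  replicates) are the package's declared desk-scale study conditions.

## What the simulator does and does not emulate

The generator reproduces the features the method claims to handle: a
low-dimensional chaotic driver, a heterogeneous driven population, strictly
one-way macro-coupling, controlled private/shared observation noise, pulse
interventions with pre/post windows, and optional Poisson spike counts.  It
does not emulate biophysical spiking dynamics, synaptic transmission delays,
non-stationarity (arousal drift), stimulation artifacts, or electrode
cross-talk.  Passing validation here therefore demonstrates correctness of
the estimators and the internal consistency of the prediction claim under
these idealized conditions — not performance on cortical recordings.

## Limitations

* Twin-surrogate power is limited on phase-coherent oscillators (see above):
  true couplings whose cross-map skill is only rhythm-level can fail to
  reach significance, and per-unit skill varies with the random recurrent
  weights, so single-pair directionality detection is not guaranteed in
  every network realization.
* CCM assumes stationary, deterministic-skeleton dynamics; for
  stochastic-linear systems (white-noise drivers) the cross-map convention
  is not meaningful, which is why the convention fixture is a coupled
  logistic-map pair.
* With strong unidirectional coupling some network realizations enter
  partial generalized synchronization, where the reverse direction also
  gains skill; the significance contrast, not the raw CF value, carries the
  directional claim.
* MGC on near-deterministic ensembles conditions away almost all predictive
  improvement and can anticorrelate with IC; this mirrors its failure in the
  comparison study rather than an implementation defect.
* On heavily oversampled series (integration-grid resolution) the twin
  relation chains into a single component and `find_twins` raises the
  degenerate-partition error; bin to the analysis resolution (`bin(0.1)`)
  before surrogate testing.
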