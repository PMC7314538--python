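# Methods

This note documents the models, parameter choices, and numerical decisions
behind `gpstop`, and what the synthetic-data results do and do not show
about real recordings.

## Task model and outcome taxonomy

A trial is: Center In → variable hold (uniform 0.5–1.25 s) → Go cue
(50 ms tone) → Center Out within the 0.8 s RT limit → Side In within the
0.5 s MT limit. On Stop trials a Stop cue (125 ms noise) follows the Go cue
at a stop-signal delay drawn uniformly from 0.1–0.25 s; reward then requires
holding the center port for a total of 0.8 s after Go-cue onset. Outcomes
are exhaustive and mutually exclusive: `correct_go`, `rt_limit_error`
(no Center Out within 0.8 s), `wrong_choice`, `mt_limit_error`,
`successful_stop`, `failed_stop`; exits before the Go cue are `aborted` and
excluded everywhere. Failed stops with RT > 0.5 s are excluded from neural
analyses (treated as hold failures after successful stopping), but kept in
behavioral summaries. Classification depends only on time differences, so
it is invariant to session-clock offsets.

## Race model of the synthetic behavior

Each trial races a Go process against (on Stop-scheduled trials) a Stop
process. Finishing times are shifted log-normal,
`T = shift + scale·exp(σZ)`: positive support, right skew like empirical RT
distributions, and a closed-form median (`shift + scale`) that makes
calibration exact. Defaults (σ = 0.6, shift = 0.1 s for the Go process):

| condition, direction | latent median | calibration target (observed) |
|---|---|---|
| No-Stop, either | 0.251 s | 251 ms |
| Maybe-Stop context, unslowed direction | 0.264 s | 264 ms |
| Maybe-Stop context, slowed direction | 0.416 s | 385 ms |

The slowed latent median exceeds its observed target because the observed
median is computed over *correct* trials: the 0.8 s RT limit censors the
right tail, and Stop-scheduled trials whose Go process finishes before the
Stop cue re-enter the Go pool as fast trials. 0.416 s was solved by
simulation so the observed correct-trial median equals 385 ms under default
task timing (the censoring bias at 251 ms is < 1 ms, so the No-Stop scale
needs no correction).

The Stop process (shift 0.03 s, median 0.19 s from Stop-cue onset, σ = 0.4)
gives roughly balanced successful/failed stops across the SSD range. A
Stop-scheduled trial is converted to a plain Go trial when the Go finishing
time precedes the SSD (no Stop cue is shown); a Stop trial whose Go process
would finish after the 0.8 s hold requirement is a successful stop
regardless of the Stop process. Failed-stop RTs are therefore a
race-censored (fast) subsample of the Go distribution — the left-shift the
test suite checks. Wrong choices occur with probability 0.10 on
Maybe-Stop-direction cues and 0.02 otherwise (errors concentrate under
proactive inhibition); movement times are shifted log-normal with median
0.25 s, producing occasional MT-limit errors. A `proactive_rt_shift`
additive knob (default 0) and a `hold_lapse_prob` for late hold failures
(default 0) are exposed but not part of the calibrated defaults.

## Population surrogate

Each of N = 376 units fires as an inhomogeneous Poisson process with rate

```
r_n(t) = max(0, b_n + w_init,n · L_I(t) + w_sel,n · L_S(t) + ε_n(trial))
```

* `b_n` ~ Gamma(shape 4, mean 28 Hz): tonically active, across-unit mean
  ≈ 28 spikes/s.
* Loadings `w_init`, `w_sel` ~ N(0, 5 Hz): signed, so the population mixes
  movement-related increases and decreases with no net direction bias.
* `L_I` (initiation latent) sits at the per-condition pre-Go offset during
  the hold (ramped on over 100 ms after Center In), then rises linearly to
  1 at movement onset at the trial's own Go-process speed — so fast-Go
  (failed-stop) trials have travelled farther by the time of the Stop cue,
  the race-model signature in state space. On successful stops the ramp
  freezes when the Stop process wins and decays (τ = 150 ms); after Side In
  latents relax with τ = 200 ms.
* `L_S` (selection latent) ramps similarly toward +1 (contra) or −1 (ipsi
  or wrong choices).
* Pre-Go offsets (initiation, selection): (0, 0) for No-Stop,
  (−0.4, −0.5) for Maybe-Stop-contra, (−0.4, +0.5) for Maybe-Stop-ipsi, in
  latent units where the full Go→Center-Out excursion is 1. No recorded-data
  effect magnitude exists to calibrate against, so these were fixed once at values
  that make the planted ground truth unambiguous at the reduced population
  sizes used in the test suite; they are deliberately larger than the
  subtle shifts a 376-unit recorded population resolves.
* `ε_n(trial)` ~ N(0, 2 Hz), constant within a trial: slow excitability
  fluctuations beyond Poisson variability.

Spikes are drawn per 2 ms bin (piecewise-constant intensity) and jittered
uniformly within the bin; inter-trial intervals fire at baseline. What this
generator does **not** emulate: biophysical spiking statistics (refractory
periods, bursting), correlated noise between simultaneously recorded units,
drift/instability, cell-type heterogeneity, or LFP. Passing tests therefore
demonstrate that the *analysis* recovers planted low-dimensional structure
under Poisson noise at calibrated rates — not that real pallidal data
contain such structure.

## Rate estimation and alignment

Rates are sums of unit-mass Gaussian kernels (σ = 30 ms) on a 2 ms grid
whose samples sit at integer multiples of the step. Spikes are deposited
with first-order (linear) interpolation onto the grid and convolved with a
discrete Gaussian truncated at ±5σ; the grid is padded by 5σ beyond the
session span and cropped, so no edge renormalization is needed and the
integral of the rate equals the spike count. Z-scoring uses the session
mean and the population-formula SD (ddof = 0, fixed for determinism); units
with no spikes or zero variance are dropped with a log entry. Event windows
are closed intervals, so a 500 ms window at 2 ms yields 251 samples; trials
whose window leaves the session are dropped with a log entry.

Single-cell statistics: unpaired two-sample t-tests on per-trial 50 ms-bin
mean Z rates (bins tile the window from its left edge; the trials being
independent sets, a paired test is not applicable); population per-bin
fractions are compared with the binomial critical fraction at chance level
α = 0.05, without and with Bonferroni correction across bins. Peak
deflection is the maximum |Z| within ±250 ms; alignments are compared
across the population with Wilcoxon signed-rank tests.

## State space and axes

The population matrix uses correct No-Stop contra and ipsi trials
(configurable), averaged around Center Out. PCA is computed by SVD of the
column-centered matrix; each component's sign is fixed so its
largest-magnitude unit weight is positive (axis definitions are
sign-invariant, but stored scores must be deterministic). K = 10 components
by default.

Axis anchors: the Go-cue anchor `a0` and Center-Out anchor `a1` are
single-time-point means at t = 0 of the cue- and movement-aligned
trajectories, averaged over the two movement directions, using the same
trial set that built the matrix; the Selection anchors are full-window
(±250 ms) trajectory means. Scaled coordinates are affine:
`a0 → 0, a1 → 1` (Initiation) and `m_ipsi → −1, m_contra → +1` (Selection),
exact at the anchors by construction for every fitted model. Projections of
any aligned activity subtract the stored column means and apply **W**;
difference vectors skip the centering (it cancels). "Distance travelled" is
an axis coordinate minus its value at the alignment event. The
full-dimensional variant replaces **W** with the identity, so the same
anchoring, scaling and test code runs in the N-D rate space.

## Permutation machinery

One shuffle set is drawn per unit (independent across units, preserving
per-condition trial counts) and reused across time points, preserving the
temporal smoothness of each surrogate trajectory. Surrogate separations are
reconstructed through the weights, `Δx(t,k) = Σ_n Δr(t,n)·w(n,k)`, at a
4 ms statistic cadence anchored at the alignment event; the Euclidean
statistic is `√Σ_k Δx²` (one-tailed), axis statistics are signed scaled
coordinates (two-tailed). P-values use the add-one estimator
`(1 + #extreme)/(1 + n_shuffles)`, which never returns 0; two-tailed tests
take absolute deviations about the mean of the pooled
(surrogates + observed) set — pooling keeps the estimator exactly
exchangeable, so null p-values are exactly uniform (verified by simulation:
type-I ≈ 0.05 and Kolmogorov–Smirnov uniformity over 500 null datasets at
500 shuffles). Pointwise masks are displayed at per-bin p < 0.05 with no
correction across bins; epoch tests (window-averaged state, e.g. −100–0 ms
pre-Go) are reported singly. Default 10 000 shuffles; the test suite and
examples use 150–1000 for runtime.

## Simulation sizes used by the test suite

Structural and statistical properties are exercised on reduced sessions —
typically 60–80 units, 160–200 trials, 1–2 s inter-trial intervals, 300–500
shuffles — with default noise, effect sizes and task timing. Axis-recovery
checks (planted loading directions, cosine ≥ 0.8 over 20 seeds; pre-Go
offset sign detection in ≥ 90% of seeds) use 80 units and 200 trials.
Behavioral calibration pools correct-trial RTs over 8–16 full-size default
sessions, mirroring the multi-session design the published medians
summarize. The acceptance script generates one full default session
(376 units) for the firing-rate calibration.

## Known limitations

* Axis anchors are single-time-point means; at few-unit/few-trial scales
  the Initiation-direction estimate is noticeably noisier than the
  Selection direction (a ±10 ms anchor-widening option exists).
* RT matching is greedy nearest-neighbour without replacement (20 ms
  tolerance, ≥10 pairs, post-match rank-sum balance check); with strong
  proactive slowing the distributions overlap only partially and small
  sessions can legitimately fail to match.
* Multi-session pooling (units recorded in different sessions with
  different trial sets) is supported by the per-unit shuffle machinery but
  the pipeline operates on one session at a time.
* No SSRT estimation, no sequential (post-trial) adjustment analyses, no
  single-trial latent inference, and no plotting beyond optional exports.
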