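# gpstop

State-space analysis of globus pallidus (GPe) population activity in the rat
stop-signal task — a tested, reusable implementation of the full pipeline
from spike trains and trial events to Initiation/Selection-axis statistics
and trial-shuffle permutation tests, together with a synthetic-session
generator (race-model behavior plus latent-factor Poisson spiking) that
provides ground truth for every downstream stage.

## The scientific problem

In a stop-signal task a rat holds its nose in a center port, receives a Go
cue instructing a leftward or rightward movement (RT limit 800 ms, MT limit
500 ms), and on some trials must cancel the movement when a Stop cue follows
after a short stop-signal delay (SSD, 100–250 ms). Three start ports signal
different stop probabilities, so the animal can *proactively* restrain a
specific action: contra reaction times slow selectively (median ≈251 ms when
no Stop cue can occur vs ≈385 ms when it might), the behavioral signature of
selective proactive inhibition.

The package asks how that covert restraint is implemented in pallidal
population dynamics:

1. **Rates.** Each unit's spike train is convolved with a Gaussian kernel
   (σ = 30 ms) and Z-scored by its session-wide mean and SD.
2. **State space.** Condition-averaged Z rates in a 500 ms window around
   movement onset (Center Out), contra then ipsi, form the population
   matrix **R** (T·C × N with T = 251 timepoints at 2 ms, C = 2). After
   column centering, PCA by SVD gives weights **W** and scores
   **S** = **R W**; the first K = 10 PCs define the state space.
3. **Axes.** The *Initiation Axis* joins the mean position at the Go cue
   (scaled coordinate 0) to the mean position at Center Out (coordinate 1):
   progression toward movement. The *Selection Axis* joins the ipsi (−1)
   and contra (+1) trajectory means: bias between the two actions. A
   no-PCA variant defines the same axes in the full N-dimensional space.
4. **Permutation tests.** To test whether two trial conditions occupy
   different state-space positions, trial labels are shuffled per neuron
   (preserving counts) and the separation is reconstructed from the
   shuffled condition-mean rate differences through the weights,
   Δx(t,k) = Σₙ Δr(t,n)·w(n,k) — a one-tailed test on the 10-D Euclidean
   distance and two-tailed tests on the signed axis coordinates, pointwise
   (4 ms bins) or on window-averaged epochs (e.g. −100–0 ms before the Go
   cue), with add-one p-values.

The synthetic generator races a shifted-lognormal Go process against a Stop
process (the first to finish decides the outcome; Stop-scheduled trials
whose Go process finishes before the Stop cue are emitted as Go trials) and
drives an inhomogeneous-Poisson population (N = 376 units, mean ≈28 Hz) with
two planted latents — initiation and selection — including per-condition
pre-Go state offsets, so axis recovery and every permutation test can be
scored against known ground truth.

## Worked example

```bash
python examples/01_generate_session.py
```

prints, for one default synthetic session:

```
323 trials, 54 Stop-scheduled (1 converted to Go trials by fast Go finishes)
outcomes: {'correct_go': 254, 'failed_stop': 25, 'wrong_choice': 12, 'successful_stop': 28, 'rt_limit_error': 4}
median correct RT [no_stop]: contra=251 ms, ipsi=240 ms
median correct RT [maybe_stop_contra]: contra=380 ms, ipsi=258 ms
proactive-inhibition screen (one-tailed rank-sum): p=1.53e-04, include=True
```

— contra RTs slow by >100 ms when a contra Stop cue may occur while ipsi
RTs are essentially unchanged, so the session passes the selective
proactive-inhibition screen. Continuing with the neural analyses
(`examples/03_state_space_axes.py`, `examples/04_permutation_tests.py`):

```
state at Go cue [no_stop]:           initiation=-0.00, selection=-0.05
state at Go cue [maybe_stop_contra]: initiation=-0.26, selection=-0.85
pre-Go cue (-100-0 ms), Maybe-Stop-contra vs No-Stop (n=54 vs 59):
  euclidean_10d     observed=+1.671  p=0.0010 (one-tailed)
  initiation_coord  observed=-0.272  p=0.0010 (two-tailed)
  selection_coord   observed=-0.762  p=0.0010 (two-tailed)
```

Under proactive inhibition the pre-Go population state sits significantly
*below* 0 on the Initiation Axis (farther from movement onset) and on the
ipsi side of the Selection Axis (biased against the restrained action) —
the planted generator offsets, recovered through the full pipeline.

The remaining examples cover single-cell statistics (`02`), and the
end-to-end report with the Stop-trial race analysis (`05`). The same
pipeline runs from the shell over CSV sessions:

```bash
gpstop generate --seed 3 -o session/
gpstop analyze --seed 3 --events session/events.csv --spikes session/spikes.csv -o out/
gpstop report out/report.json
```

## Layout

```
src/gpstop/
  params.py      task timing, race-model and population parameters (+ YAML I/O)
  synth.py       behavior generation, latent time courses, Poisson spiking
  behavior.py    outcome classification, inclusion screen, RT matching/splits
  rates.py       kernel smoothing, Z-scoring, event alignment, single-cell stats
  statespace.py  population matrix, PCA, Initiation/Selection axes, projections
  permstats.py   label shuffles, surrogate Δx reconstruction, p-values
  pipeline.py    end-to-end orchestration and JSON/CSV reports
  cli.py         thin click front end (generate / analyze / report)
docs/methods.md  model assumptions, parameter choices, limitations
examples/        one narrative script per capability
```
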