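# saccvis

Tools for studying when high-speed finite motion stops being visible — and
how that limit tracks the kinematics of saccadic eye movements.

When a stimulus sweeps across the visual field fast enough, observers no
longer see motion: they see the stimulus jump from its start to its end
point, exactly as the world appears to do during a saccade (saccadic
omission). `saccvis` implements the computational machinery for
psychophysics experiments probing this transition:

* **Stimulus kinematics** tied to the saccadic *main sequence*
  (`v_p = c·A/D_sac` with `c = 1.64`, `D_sac = 2.7·A + 23 ms`): condition
  grids over amplitude × relative speed, gamma-shaped saccadic velocity
  profiles, arc trajectories with static endpoints, and motion-absent twin
  stimuli.
* **An early-vision model** — spatiotemporal Gaussian/gamma filtering of the
  stimulus trajectory, Naka-Rushton normalization, max readout, Minkowski
  evidence pooling, report sampling, and population position decoding, with
  ocular drift and amplitude-dependent response noise.
* **Psychometric analysis**: Gumbel (log-Weibull) maximum-likelihood fits
  on log10 stimulus scales (`Ψ(x) = γ + (1−γ−λ)(1−e^{−10^{β(x−θ)}})`),
  orthogonal polynomial/Helmert contrasts, d′ and Naka-Rushton detection
  thresholds, retinal- vs spatial-direction threshold–kinematics
  correlations, and BIC-based Bayes-factor model comparison.
* **Saccade analysis**: adaptive velocity-threshold detection
  (median + 5 median-based SDs, ≥ 8 ms, 10-ms merging), trial filters, and
  main-sequence fitting (`v_p = v0(1−e^{−A/a0})`, `D = d0 + c·A`).
* **Synthetic data** with known ground truth for every pipeline stage.

The fitting components are scikit-learn style estimators
(`GumbelPsychometric`, `NakaRushtonSensitivity`, `MainSequenceFitter`,
`SaccadeDetector`) and compose with sklearn tooling.

## Worked example

Thresholds of a synthetic observer whose visibility limit sits at 53% of
saccadic peak velocity, recovered from binomial 2AFC data:

```python
>>> import numpy as np, pandas as pd, saccvis as sv
>>> sv.expected_peak_velocity(8.0)          # dva/s, main-sequence law
294.1704035874439
>>> cond = sv.make_condition(8.0, 0.5)      # 8 dva at half peak velocity
>>> (round(cond.v, 1), round(cond.D_ms, 1), round(cond.D_rel, 2))
(147.1, 54.4, 1.22)

>>> v_rels = np.array([0.25, 1/3, 0.5, 2/3, 0.8, 1.0, 1.25])
>>> spec = sv.SyntheticObserverSpec(threshold_ratio=0.53, lapse=0.02,
...                                 n_trials=120, seed=7)
>>> conditions = pd.DataFrame({"amplitude_dva": np.full(7, 8.0), "v_rel": v_rels})
>>> trials, truth = sv.make_observer_trials(spec, conditions)
>>> trials[["v_rel", "v", "n_correct", "n_total"]]
      v_rel           v  n_correct  n_total
0  0.250000   73.542601        117      120
1  0.333333   98.056801        116      120
2  0.500000  147.085202        101      120
3  0.666667  196.113602         71      120
4  0.800000  235.336323         74      120
5  1.000000  294.170404         58      120
6  1.250000  367.713004         56      120

>>> est = sv.GumbelPsychometric(lapse=0.02, decreasing=True).fit(
...     trials.v, trials.n_correct / trials.n_total, trials.n_total)
>>> round(est.threshold_, 1)                # dva/s, back on the speed scale
153.2
>>> round(est.threshold_ / sv.expected_peak_velocity(8.0), 3)
0.521
```

Performance falls from near-ceiling at a quarter of saccadic peak velocity
to chance near 1.25·v_p; the fitted Gumbel threshold (the speed yielding
81.6% correct) recovers the generative ratio 0.53 to within sampling error.

The early-vision model runs the same condition logic end to end:

```python
>>> from saccvis import ModelParams, run_model_experiment
>>> res = run_model_experiment(amplitudes=(4, 8, 12), endpoint_durations=(0, 200),
...                            params=ModelParams(dx=0.1, dt=2.0, runs_per_condition=50),
...                            seed=1)
```

`res["conditions"]` holds evidence and simulated proportion correct per
condition; `res["thresholds"]` the fitted relative-speed threshold per
amplitude × endpoint cell. With 200-ms static endpoints the thresholds
collapse across amplitudes (coefficient of variation ≈ 0.05 vs ≈ 0.15 at
0 ms) — the model's account of why visibility follows the main sequence
only when the stimulus rests at its endpoints.

## Command line

```bash
saccvis condition-table --check      # emit the 5×7 design grid; verify it
saccvis synth-observer trials.csv --seed 3
saccvis fit trials.csv --out fits.json
saccvis contrasts fits.json
saccvis synth-traces trace.csv --seed 4
saccvis detect-saccades trace.csv --out events.csv
saccvis model-run outdir/ --seed 1
```

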