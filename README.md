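# resilnet

Cross-species analysis of stress resilience, as a tested Python pipeline
running on synthetic data with ground truth.

Resilience — maintaining mental health despite stressor exposure — can be
operationalized in parallel in humans and mice. In humans, the
stressor-reactivity (SR) proxy is the residual of regressing mental-health
problems (GHQ) on life-event exposure: positive residuals mean
worse-than-expected outcomes, i.e. lower resilience. In mice, the
social-interaction (SI) score after chronic social defeat,
`100 × dwell(aggressor)/dwell(empty)`, classifies animals as resilient
(> 100) or nonresilient (< 100). This package implements the
neurophysiology analyses that link those scores to circuit activity:

**Mouse arm** — two-photon calcium-imaging processing for V1 layer-II/III
microcircuits: ΔF/F against a quiescent 10-s baseline, windowed-median
detrending, repeated Gaussian smoothing + zero-phase high-pass, transient
detection at mean + 2.5 SD with derivative criteria and exponential decay
fits, binarized activity rasters; activity frequency, amplitude and
inter-event-interval (IEI) statistics with two-sided Kolmogorov–Smirnov
group comparisons; pairwise-correlation connectivity maps; and orientation
tuning from randomized drifting-grating schedules, summarized by the
circular variance

```
CV = 1 − |Σ_k r_k·exp(i·2θ_k)| / Σ_k r_k
```

**Human arm** — SR-proxy scoring with the participant exclusion ledger;
emotional-Flanker reaction-time contrasts (the 2×2 double difference);
Morlet/multitaper time–frequency interaction maps with band-restricted
min/max extraction; γ-burst detection by learned-dictionary matched
filtering (40–80 Hz FIR, 30 atoms via sparse coding with a correntropy
loss, per-trial adaptive threshold) with burst-IEI statistics; and
Bayesian linear regressions `y ~ N(α + Σβᵢxᵢ, σ²)` with weakly
informative priors, 94% HDIs, R-hat convergence checks and LOO-CV model
comparison (lower = better).

All inputs are produced by seeded generators (`resilnet.synthdata`) that
emulate the data structure the analyses assume — sparse GCaMP6f-like
transients at 30.8 Hz whose rate/amplitude/tuning differ by group, 1/f
background with planted 60-Hz bursts, cohort and predictor tables with
known coefficients — so every estimator is tested against ground truth.

## Worked example

```python
from resilnet import pipeline

report = pipeline.run(pipeline.PipelineConfig(arm="both", seed=7))

mouse, human = report["mouse"], report["human"]
print(mouse["median_frequency_per_min"])
print(mouse["group_tests"]["ks_frequency_resilient_vs_nonresilient"])
print(human["roster"]["behavioral_n"], human["roster"]["electrophys_n"])
print(human["burst_iei"]["median_iei_s"])
print(human["bayes"]["winning_model"], human["bayes"]["m5_coefficients"])
```

prints (≈ 7 s on one core):

```
{'resilient': 1.0, 'nonresilient': 1.8, 'nonstressed': 1.2}
{'D': 0.6778, 'p': 5.32e-21}
117 103
{'resilient': 0.996, 'nonresilient': 0.634}
m5 {'ifg_tri_min': -0.486, 'v2_max': 0.431}
```

Reading the output: detected activity frequencies recover the planted
group difference (nonresilient somata ~1.8 events/min vs resilient ~1.0;
the pooled KS test rejects decisively at 90 somata/group). The exclusion
ledger reproduces 121 → 117 behavioral → 103 electrophysiological
subjects. Simulated resilient subjects (lower burst rate) show longer
γ-burst IEIs. The Bayesian model comparison selects the combined model
(minimum-β + maximum-γ predictors), and its posterior means recover the
generating coefficients (−0.5, 0.4) to ≈ 0.01.

The same stages are exposed individually (`resilnet.imaging`,
`.microcircuit`, `.tuning`, `.spectral`, `.scores`, `.bayes`) and as a CLI:

```bash
resilnet simulate --what traces --seed 3 --out traces.csv
resilnet detect traces.csv --out events.csv
resilnet run --arm both --seed 7 --out out/
```

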