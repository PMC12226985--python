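# neurofragility

Interictal neural-fragility analysis of stereo-EEG (SEEG) for seizure-onset-zone
(SOZ) localization and surgical-outcome statistics in drug-resistant epilepsy.

Clinically, the SOZ is delineated by capturing seizures during days or weeks of
intracranial monitoring — impossible for patients who rarely seize. This
package implements an *interictal* alternative: treat short windows of
seizure-free SEEG as a discrete-time linear network

```
x(t+1) = A x(t) + ε(t)
```

estimate each 250 ms window's operator `A` by Tikhonov-regularized dynamic
mode decomposition (DMD), and ask, for every channel `k`: what is the smallest
structured perturbation `Δ = γ e_kᵀ` (a change to node `k`'s couplings) that
moves an eigenvalue of `A` onto the unit circle — i.e. tips the network from
stable into seizure-like instability? The minimum norm

```
f_k(A) = min_{ω ∈ [0, π]}  min { ‖γ‖₂ :  det(A + γ e_kᵀ − e^{iω} I) = 0 }
```

is the channel's **neural fragility**: the less interference a node needs to
destabilize the network, the more fragile (epileptogenic) it is. Per-window
normalization `(max_k f − f_k)/max_k f` yields channels × time heatmaps in
[0, 1] where high values mark fragile channels. A random forest over
per-channel heatmap statistics predicts SOZ channels under
leave-one-patient-out cross-validation, and cohort statistics (paired
SOZ-vs-NSOZ t-tests by outcome group, a logistic regression of surgical
failure on concordance metrics and clinical covariates, Engel-group
summaries) quantify whether interictal fragility tracks treatment success.

Because raw clinical SEEG cannot be redistributed, the package ships a
**verified synthetic cohort generator**: stochastic linear networks with a
designated near-critical fragile node subset (construction is re-drawn until
the planted nodes are provably the most fragile under the package's own
fragility computation), emitted as EDF recordings with channel annotations
and cohort outcome tables.

## Worked example

```python
from neurofragility import SimulationConfig, simulate_recording
from neurofragility.pipeline import analyze_patient, fragility_pair

cfg = SimulationConfig(n_channels=8, duration_s=10.0, fragile_set=(0, 1), seed=0)
rec, ann = simulate_recording(cfg)          # 8-channel, 10 s, 2 kHz snapshot
result = analyze_patient(rec, ann)          # 500 Hz, 0.1-30 Hz, 78 windows
print(result.features["mean"].sort_values(ascending=False).round(3).to_string())
soz, nsoz = fragility_pair(result)
print(f"mean SOZ fragility = {soz:.3f}, mean NSOZ fragility = {nsoz:.3f}")
```

prints

```
channel
CH02    0.770
CH01    0.754
CH05    0.675
CH04    0.660
CH08    0.594
CH06    0.398
CH03    0.237
CH07    0.207
mean SOZ fragility = 0.762, mean NSOZ fragility = 0.462
```

The two planted fragile channels (CH01, CH02 — the simulated seizure onset
zone) rank first in channel-mean normalized fragility, and the SOZ mean is
well above the non-SOZ mean: the interictal recording alone localizes the
planted epileptogenic nodes.

The same flow is available from the shell:

```sh
neurofragility simulate --out-dir cohort/ --n-patients 30 --seed 0
neurofragility cohort cohort/ --out results/ --seed 0
neurofragility stats --metrics results/metrics.csv --cohort cohort/cohort.csv \
    --pairs results/fragility_pairs.csv --out stats/
```

`cohort` runs every patient, cross-validates the SOZ classifier and writes
heatmaps, per-patient precision/recall against both the clinician-read SOZ
(SOZE) and the treatment-target set (SOZC), and the statistics report;
`stats` re-runs only the cohort statistics from tabulated per-patient values.

## Layout

- `io_formats` — EDF recordings (read via mne, written by a built-in 16-bit
  writer), annotation/cohort CSVs, lossless fragility containers.
- `preprocess` — polyphase resampling to 500 Hz, zero-phase Butterworth
  bandpass (0.1-30 Hz), bad-channel rules, sliding-window planning.
- `dynamics` — per-window regularized DMD operator estimation.
- `fragility` — closed-form minimum structured perturbations, heatmaps.
- `soz_classifier` — channel features, LOPO random forest, precision/recall.
- `cohort_stats` — paired t-tests, logistic outcome model, Engel summaries.
- `synthetic_data` — verified fragile-network simulator and cohort generator.
- `pipeline` / `cli` — orchestration and the `neurofragility` command.

See `docs/methods.md` for the model, its assumptions, parameter choices and
known limitations.
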