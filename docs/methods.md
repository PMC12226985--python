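# Methods

## Model

Interictal SEEG is modeled piecewise: within each short window the
multichannel signal is treated as one realization of a stable stochastic
linear network

x(t+1) = A x(t) + ε(t),   ε(t) ~ iid noise,

where x stacks the retained channels (microvolts) and `A` is the window's
state-transition operator in the observed channel basis, so row/column `k`
corresponds to a named channel. The epileptological premise is that focal
seizures arise from a small set of *fragile* nodes that hold the network
close to instability: between seizures the network returns to baseline after
perturbations (all eigenvalues of `A` inside the unit circle), and a seizure
corresponds to an eigenvalue crossing onto the unit circle.

### Operator estimation

Each window's operator is the Tikhonov-regularized least-squares (DMD)
solution. With snapshot pairs X₁ = X[:, :-1], X₂ = X[:, 1:] and the economy
SVD X₁ = U Σ Vᵀ:

A = X₂ V diag(σᵢ / (σᵢ² + λ)) Uᵀ,   λ = 0.05 by default.

λ = 0 reduces to the plain pseudo-inverse and recovers the generating
operator exactly on noise-free identifiable trajectories (tested to 1e-8);
the regularized operator's Frobenius norm is non-increasing in λ (tested).
Rank is capped at min(N, m−1) with a 1e-12 relative singular-value cutoff;
the rank actually used and the residual norm are recorded per window. With
the default windowing (125 snapshots at 500 Hz) the estimate is
well-conditioned up to ~100 channels; beyond m−1 = 124 channels the problem
is rank-deficient and the recorded rank makes that auditable.

### Neural fragility

For a stable `A`, the fragility of node `k` is the smallest 2-norm
single-column perturbation Δ = γ e_kᵀ (default; single-row available) that
places an eigenvalue at λ = e^{iω} on the unit circle. By the matrix
determinant lemma this is the linear constraint wᵀγ = −1 with
wᵀ = e_kᵀ (A − λI)⁻¹; over real γ the stacked system
[Im wᵀ; Re wᵀ] γ = (0, −1) has the closed-form minimum-norm solution
γ = Cᵀ(CCᵀ)⁻¹(0, −1), ‖γ‖² = ‖Im w‖² / (‖Im w‖²‖Re w‖² − (Im w·Re w)²),
degenerating to γ = −Re w / ‖Re w‖² for real λ. A parallel-Im/Re (singular
CCᵀ) direction is infeasible and that grid point is skipped. The node's
fragility is the minimum over a frequency grid ω ∈ [0, π] (51 uniform
points; conjugate symmetry makes the half-circle sufficient, and grid
refinement to 501 points changes values by < 5%, both tested). Closed-form
optimality is verified against an independent least-squares min-norm oracle
and random feasible competitors, with eigenvalue-placement residuals below
1e-6.

Column mode perturbs a node's *outgoing* couplings, the convention of the
structured-fragility literature this analysis follows; row mode is provided
behind a flag.

### Heatmaps and normalization

Raw fragility (channels × windows) is normalized per window-column as
(max − f)/max, so values lie in [0, 1], each column's minimum is 0, and
*high* values mark fragile channels. A window whose estimated operator is
already unstable (spectral radius ≥ 1) gets raw fragility 0 for every node —
the zero perturbation destabilizes — and normalizes to an all-zero column
with a warning; such windows are counted in diagnostics rather than dropped,
keeping the map rectangular. Whether raw or normalized values feed
downstream analysis is an interpretive choice; this package uses normalized
values for features and patient-level summaries because they are comparable
across windows and montages.

## Preprocessing

Recordings are resampled to 500 Hz (polyphase, anti-aliased), bandpass
filtered 0.1–30 Hz with a 4th-order Butterworth applied forward-backward
(zero-phase; filter family/order are this package's choice — flat passband,
standard in iEEG pipelines), and cut into 250 ms windows with 125 ms
overlap. At 500 Hz the overlap is 62.5 samples; the hop is fixed at
win_len − floor(62.5) = 63 samples so window counts are deterministic
(10 s → 78 windows). Windows are half-open `[start, start+win_len)` with
0-based indexing; a trailing partial window is discarded.

Bad channels are the union of manual flags and two automatic rules:
flatline (variance < 1e-12 µV²) and amplitude outlier (robust SD, 1.4826 ×
MAD, above 5 × the cross-channel median robust SD). Screening runs on the
**as-recorded broadband signal, before resampling and filtering**: the
0.1–30 Hz restriction concentrates the physiological power of near-critical
channels and would push exactly the channels of interest past the outlier
threshold (measured 12.5× worst case on filtered synthetic data vs 4.2× on
raw). No notch filtering, re-referencing (an optional common-average flag
exists, off by default) or artifact-epoch rejection is applied.

## SOZ classification

Each retained channel is summarized by seven montage-length-invariant
statistics of its normalized fragility time course: mean, SD, median, 10th
and 90th percentiles, the fraction of windows in the recording's top decile
of normalized fragility, and the window count. A 500-tree random forest
(sqrt-features, balanced class weights, fixed seed) is trained on
clinician-read SOZ (SOZE) labels under leave-one-patient-out
cross-validation — per-patient feature rows never inform their own
prediction — and channels with out-of-fold P(SOZ) ≥ 0.5 are called SOZ.
Predictions are scored against SOZE and against the treatment-target set
SOZC by precision and recall; zero-denominator metrics are reported as
undefined, never as 0. The feature set, the LOPO scheme, the forest
hyperparameters and the 0.5 threshold are this package's design choices;
all are configurable.

## Cohort statistics

Per patient, mean normalized fragility over SOZE channels and over non-SOZE
channels form one pair; two-sided paired t-tests compare them within the
successful (Engel I) and failed (Engel II–IV) outcome groups. The logistic
outcome model regresses binary failure (Engel > 1) on the four concordance
metrics, RFTC and resective-surgery flags, the MRI lesional flag, and
clinical complexity entered as a single ordinal covariate (a ~30-patient
cohort cannot support dummy coding); negative coefficients on concordance
metrics therefore mean higher concordance associates with seizure freedom.
Fits are plain maximum likelihood with Wald standard errors and 95% CIs;
complete or quasi-complete separation is detected (exploding coefficients or
a perfect fitted split) and flagged in the result rather than silently
diverging — at small n with strong effects the flagged coefficient
magnitudes are boundary artifacts, not estimates. An ordinal-outcome variant
is out of scope. Engel-group summaries report min/quartiles/median/max per
metric with linear interpolation between order statistics; empty groups emit
a count-0 row. No multiple-testing correction is applied. Type-I error of
both tests is verified at the nominal 5% level by null simulation, and
logistic CI coverage by parameter-recovery simulation (true coefficient
−2.0, n = 500, ≥ 90% coverage over 100 replicates).

## Synthetic data

The generator emulates the study conditions: N-channel interictal SEEG at
2 kHz (clinical acquisitions are 2–4 kHz), ~10-minute default snapshots, a
designated fragile subset near instability, and a cohort with a 22:8
success:failure outcome mix. The generating operator is
A = B + c·u_F u_Fᵀ — a random stable base B rescaled to spectral radius 0.7
plus rank-one column loadings on the normalized indicator u_F of the fragile
set F, with c bisected so the spectral radius is 0.95 ± 1e-6. Construction
is **verified**: the package's own fragility computation must rank every
node in F strictly more fragile than every node outside F, else a new
sub-seed is drawn (≤ 20 attempts, then error). Unverified ground truth never
reaches tests — this verification is load-bearing; without it the planted
ranking fails for a substantial fraction of draws. Innovations are iid
Gaussian (1 µV default; the noise model is a package choice), a 2 s burn-in
is discarded, and divergence aborts with an error. noise_sd = 0 is allowed
as a degenerate noise-free control.

Success-profile patients have fragile_set ⊆ SOZE ⊆ SOZC and Engel 1;
failure-profile patients have a fixed mislocalization fraction (default 0.5)
of fragile nodes excluded from both SOZE and SOZC and replaced by
non-fragile channels, with Engel drawn from {2, 3, 4}. Treatment-flag
probabilities default to the 30-patient study mix (27 RFTC, 5 LITT, 11
resections, 2 RNS); the MRI lesional flag and CC class are drawn from
configurable categoricals. All draws descend from one seed via spawned
sub-streams, making cohorts byte-reproducible.

What the simulator does *not* emulate: interictal epileptiform discharges
and other transients, 1/f spectra, line noise, volume conduction, nonlinear
or non-stationary dynamics, electrode geometry. Passing tests therefore
demonstrate that the pipeline recovers planted linear-network fragility
structure under realistic sampling and preprocessing — not that it localizes
SOZ in real clinical recordings.

## Numerical choices and degenerate inputs

- Frequency grid endpoints ω = 0, π are included; λ numerically equal to an
  eigenvalue of `A` skips that grid point.
- Effectively-real w (‖Im w‖² ≤ 1e-12 × scale) uses the single-constraint
  formula; singular CCᵀ marks infeasibility.
- All-zero snapshot windows yield the zero operator (fragility handled by the
  unstable/zero-column conventions).
- EDF is written with an integer symmetric physical range so the 8-character
  header fields are exact and round-trips are bounded by half of one 16-bit
  step; non-integer-second recordings are written as a single EDF record.
- Quantiles interpolate linearly between order statistics everywhere.
- Problem sizes in the test suite and acceptance script (10–60 s snapshots,
  5–30 patients, 8–12 channels) are scaled down from the ~10-minute,
  30-patient study setting; the windowing, rates and all thresholds are
  unchanged, and the statistics are computed by the same code paths.

## Known limitations

- The linear time-invariant-per-window model ignores cross-window coupling;
  no smoothing of operators across windows is attempted.
- Fragility magnitudes depend on the estimated operator's conditioning;
  only within-window *rankings* (and their normalization) are used
  downstream, which is also why per-window normalization is the default.
- At cohort sizes around 30 with strong concordance effects the logistic
  model can separate; results then carry a flag and should be read as sign
  information only.
- The 0.1 Hz highpass edge has a ~4 s time constant; the first and last few
  seconds of zero-phase-filtered snapshots carry low-frequency transients.
  Long snapshots make this negligible; very short ones (< ~10 s) do not.
- Gamma-band and high-frequency-oscillation analysis is explicitly out of
  scope; the pipeline is band-limited to 0.1–30 Hz.
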