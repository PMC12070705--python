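# Methods

This note documents the models, conventions and numerical choices behind
`ppgbp`, and what its synthetic experiments do and do not demonstrate.

## Synthetic record model

No public recordings exist for this protocol, so the package ships a
generator whose outputs carry exact ground truth. Each PPG beat is the
sum of two Gaussian lobes,

    w(t) = A_s exp(−(t − c_s T)² / 2σ_s²) + A_d exp(−(t − c_d T)² / 2σ_d²),

with T the beat period, centers c_s = 0.16 T and c_d = 0.46 T, widths
0.075 T and 0.09 T (fractions of the period so the pulse shape — and the
visibility of the dicrotic notch, the local minimum between the lobes —
is heart-rate invariant), and A_d/A_s ≈ 0.25–0.70 across subjects. Beats
are rendered at continuous onset times (onsets are not sample-aligned),
so per-beat sampling phase dithers naturally and averaged timing
features are not biased by the 2 ms grid. The ECG channel is a train of
narrow Gaussian R-waves, each preceding its beat's systolic peak by the
subject's pulse transit time (PTT, R-peak → PPG peak, 0.25 ± 0.035 s).
Ground-truth fiducials (feet, peaks, notches, R-peaks) are extrema of
the pristine composite signal, located before drift, mains interference
(50 Hz, amplitude 0.02 a.u.) and white noise (30 dB SNR) are added.

Subject physiology is drawn from configured demographic distributions
(heart rate 83.2 ± 12.6 bpm; see `defaults.yaml`); per-subject
generators are spawned from `SeedSequence(root).spawn(n)`, so any
subject is reproducible independently of cohort size.

**Generative blood-pressure law.** SBP = a₀ + a₁/PTT + a₂·AI + ε and
DBP = b₀ + b₁/PTT + b₂·AI + ε, with AI the augmentation index of the
rendered template and ε Gaussian (σ = 2 mmHg by default). Coefficients
(27 mmHg·s and 3 mmHg for SBP; 20 and 1.5 for DBP) are calibrated so the
cohort reproduces the demographic means and spreads (SBP 121.7 ± 15.1,
DBP 75.4 ± 11.2 mmHg) under the configured PTT and AI distributions.
The law asserts no physiology beyond the inverse PTT–BP relation; its
purpose is a known, recoverable signal.

**Phase presets.** Smoking phases raise heart rate (during: +12 bpm,
matching the observed 44 → 50 pulses per 30 s), deepen slow amplitude
modulation, add baseline drift, relocate the notch later in the beat
(+0.02 T during; no quantitative magnitude is established for this
effect, the default is arbitrary), and shorten PTT (−25 ms during,
decaying over the after-intervals), which is what moves pressure under
the law. Each window also receives nuisance jitter around its preset
(heart rate 3 bpm, PTT 6 ms, modulation 0.07, drift 0.05): resting
recordings are not identical minute to minute, and without this spread
every post-smoking window would be wholly outside the training
distribution of a "before"-fitted model.

**What the generator does not emulate:** respiration coupling, motion
artifacts beyond additive drift, arrhythmia, reflected-wave physiology,
sensor nonlinearity. Passing tests therefore demonstrate the pipeline's
internal correctness and its behaviour under the stated statistical
structure, not clinical accuracy on real recordings.

## Conditioning

Butterworth filters (order 4), designed as second-order sections because
a 0.05 Hz corner at 500 Hz sampling is numerically stiff in
transfer-function form, applied forward–backward so fiducial timing is
not shifted. Records that end mid-beat excite a large low-frequency
transient at the record edges; filtering uses even-symmetric padding of
3 s to keep it small. Normalization to [0, 1] is the exact min–max map
and is applied after filtering, before detection; a constant signal is a
hard error rather than silent zeros. PSD uses Welch with 4-s segments.
The residual of a 50 Hz tone after the PPG band-pass alone is ≈1.7%
(order-4 zero-phase design); the dedicated 48–52 Hz band-stop brings the
mains rejection beyond 20 dB.

## Fiducial detection

Systolic peaks: prominence-gated local maxima with a 0.25 s refractory
distance. On a [0, 1]-normalized PPG a systolic peak has prominence near
the full range while even a strong diastolic wave stays below ≈0.45; the
default gate of 0.5 separates them across the configured amplitude
range. Feet are minima between consecutive peaks (the beat foot, not the
post-notch trough). The dicrotic notch is located through the first
derivative: by default its minus-to-plus zero crossing strictly inside
(peak, next foot) — the inter-wave local minimum; the alternate rule
(the derivative's interior maximum, i.e. the steepest diastolic rise,
the classic surrogate when the notch is a mere inflection) is available
as `detection.notch_method: derivative_peak`. Beats without a qualifying
extremum keep the notch unset; nothing is fabricated. Outlier beats are
removed when their nearest peak spacing or systolic amplitude leaves
median ± 3 robust scale units; the scale is 1.4826·MAD floored at the
measurement resolution (one sample period / 1% of the median amplitude),
because a clean record's beat-to-beat spread is quantization-dominated
and its raw MAD is vanishingly small. Using the *nearest* peak spacing
keeps the gate idempotent after removals.

## Features

Sixteen per-beat families: systolic/diastolic amplitudes (Da measured at
the diastolic peak after the notch — the landmark is not standardized
elsewhere), systolic/diastolic areas (trapezoidal, above the beat foot,
foot→notch and notch→next foot), inflection-point area ratio IPA=SA/DA,
systolic/diastolic times, pulse interval, stiffness index sa/DT,
peak-to-peak interval and pulse rate 60/PPI, width at half the systolic
amplitude (first half-level crossings on each side of the peak, linearly
interpolated), augmentation index sa/Da, heart rate 60/T_PP from the
enclosing R-R interval, and PTT to foot and to peak. The stiffness index
and the "systolic amplitude to diastolic time ratio" share one
definition and enter the registry once (the alias exists in the `full`
preset). Each family is summarized by mean, sample SD, bias-corrected
skewness and Pearson (non-excess) kurtosis — conventions pinned in
configuration for bit-reproducibility; an (effectively) constant series
gets 0 for the shape statistics with a log note. With the PPG Shannon
energy entropy E = −Σ y² ln y² (0·ln 0 = 0; inputs held in [−1, 1] by
prior scaling) the default registry has exactly 65 named features.
Zero-crossing rates (sign-change semantics, count{yₙ·yₙ₋₁<0}/(N−1); the
literal negative-fraction form count{yₙ<0}/N is a config switch) are
computed on the zero-mean band-passed signals — on a [0, 1]-normalized
trace they would be identically zero — and live in the `full` preset
together with the derivative entropies.

## Cohort table, expansion, split

Windows become rows (subject, habit, phase, provenance, SBP/DBP
references, features). Row-level outlier removal flags any feature
outside median ± 3 scale units; the per-column scale is the MAD-based
robust sigma with a sample-std floor capped at 10 robust sigmas (the
floor protects quantization-clumped columns, the cap prevents mass
corruption from inflating its own gate); flagging more than half the
table is a hard error. With 65 heterogeneous, partly heavy-tailed
columns this any-column rule is conservative: it removes roughly a
quarter to a third of perfectly clean synthetic windows, which the
expansion stage re-densifies.

Expansion sorts rows by reference DBP (ties by subject id), fits one
cubic spline per numeric column over normalized row rank, and evaluates
all splines on an evenly spaced grid of the target size (870 by
default). Measured rows are preserved exactly where ranks coincide;
interpolated rows are flagged as such. Columns whose interpolant leaves
the measured envelope by more than 5% of its range are logged and
recorded in `table.attrs`. The split draws the test partition as
round-half-up of n·0.15 (870 → 739 train + 131 test) from a seeded
permutation.

**Leakage caveat.** Expanding before splitting places interpolated
neighbours of training rows in the test set, and all expanded rows lie
on a one-dimensional curve through feature space. Held-out RMSE under
this protocol is therefore optimistic by construction — sub-mmHg values
for a law with 2 mmHg noise are a property of the protocol, not of the
regressor. The statistically safer `split_before_expand` mode is a
config switch; the default reproduces the expand-then-split protocol.

## Reduction and regression

Features are standardized (training statistics only, constant columns
dropped) and decomposed by PCA; 12 components are retained by default,
or the minimal k reaching a cumulative explained-variance threshold.
Component signs are pinned (largest-magnitude loading positive) for
determinism. Because principal components have no original-variable
names, a loading-based ranking of original features across the retained
components is exposed for reporting a named reduced set.

Each target gets its own Gaussian process with a fixed-form kernel —
Matérn 5/2 for SBP, exponential (Matérn 1/2) for DBP — a constant prior
at the training-target mean, and observation-noise jitter 10⁻⁴ (zero
yields exact interpolation; conflicting duplicates then raise with
guidance). Reduced scores are rescaled to a common standard deviation of
0.07 so the length-scale grid [0.01, 0.5] spans correlation lengths from
well below one feature's spread to several times it; σ is chosen by
5-fold seeded cross-validation minimizing mean RMSE, ties toward the
smaller σ. Note that CV selection is predictively consistent but is not
a length-scale *identifier*: on data simulated from a known GP the
CV-optimal σ sits systematically above the generating value, because
smoother posteriors predict noisy draws better.

The held-out evaluation uses the expanded-split model (protocol
fidelity). Phase application — predicting the during/after windows from
a "before"-trained model — instead refits on the measured (unexpanded)
training-phase rows: a GP fitted on the rank curve is unconstrained off
that curve, exactly where other phases live. The during-phase SBP rise
survives this transfer in attenuated form (stationary kernels revert
toward the prior mean out of distribution); at n = 84 the predicted
during-minus-before SBP delta was positive in 7 of 8 generator seeds
(mean ≈ +4 mmHg against ≈ +13 mmHg generated), so the directional check
pools three seeded cohorts.

## Reporting

Phase summaries give mean, SD, and the mean absolute difference from
each subject's own "before" prediction (the MAE baseline — defined here
explicitly since phase-wise MAE has no standard referent), per target
and phase; subjects without a baseline are excluded and logged.
Trajectories enumerate the protocol interval order with missing
intervals as explicit NaNs. Report generation is pure: identical inputs
produce byte-identical CSV.

## Problem sizes

Default experiments use 84 subjects × 30-s windows at 500 Hz (the
protocol's cohort and window), expansion to 870 rows, a 25-point σ grid
and 5-fold CV; the test suite's recovery and directional checks run the
full chain at these sizes.

## Known limitations

Two-Gaussian beats lack a true reflected-wave mechanism, so the
augmentation index is a geometric, not hemodynamic, quantity; the foot
of a beat sits in a nearly flat valley and carries tens-of-samples
localization uncertainty (PTT-to-foot is accordingly noisier than
PTT-to-peak); the generative BP law is linear in 1/PTT and AI, so
nonlinear-recovery behaviour is untested; and all accuracy statements
are conditional on the generator's assumptions.
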