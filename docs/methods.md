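# Methods

This note records the models, the numerical choices, and what the synthetic
cohort does and does not emulate.

## Acquisition model

One "block" per arm: after three maximal voluntary contraction (MVC)
calibration bursts and a short rest lead-in, six trials of 15 s task /
25 s rest. During the task the subject performs intermittent isometric
elbow flexions to 30% of mean MVC, one lift every 2 s (a 0.5 Hz auditory
cue in 2/4 time; the cue-to-lift mapping is not standardised anywhere, so
the lifts-per-trial count — 7 by default for a 15 s window — is a config
parameter). Signals: 5-channel sEMG at 1,925.9 Hz, dynamometer force at
10 Hz (the segmentation clock), and 24-channel dual-wavelength fNIRS at
10 Hz with 30 mm source–detector spacing.

## sEMG preprocessing

Zero-phase (forward–backward) filtering throughout: 4th-order Butterworth
band-pass 20–450 Hz, linear detrend, full-wave rectification, 4th-order
Butterworth low-pass at 5 Hz. Zero-phase filtering is a deliberate choice —
it keeps the envelope aligned with the force trace, which defines lift
boundaries. Segmentation: baseline = median force over rest; onset = force
rising past baseline + 5% of target; each lift is padded by two force
samples (0.2 s) before onset and ends at return to baseline. A lift is
excluded when it lasts over 3 s or when its plateau (mean force over
samples above 50% of target) deviates from target by more than 15%; both
the onset threshold and the plateau definition are conventions fixed here
because no standard pins them down. Amplitude normalization is min–max per
muscle over the whole block (not per lift), so between-lift amplitude
differences survive; time normalization resamples each lift to q = 50
points by linear interpolation.

## MCR-ALS synergy decomposition

The decomposition unit is a single lift (5×50). Initial base vectors are
pure columns chosen by SIMPLISMA purity (std/(mean + offset), offset = 5%
of the largest column mean), each pick down-weighted by its projection onto
previous picks; the alternating solves are exact non-negative least squares
(unconstrained solve first, active-set NNLS only for violating columns —
identical solution, much faster); convergence when the relative VAF change
drops below 1e-8 (max 500 iterations). No randomness, hence bit-identical
reruns — the reason this family of algorithms is preferred over
random-restart NMF for clinical indices. On exit V columns are rescaled to
unit norm with the scale absorbed into T, making the cosine (C_V) and
Pearson (SSI) indices scale-free. VAF = 1 − ‖X−VT‖²/‖X−mean(X)‖² with the
column-mean centring matrix. The synergy count is the smallest n at which a
strict majority of subjects in *both* groups exceeds VAF 0.80; with one
synergy the indices need no cross-lift column matching (multi-synergy
matching is out of scope).

Baselines: per control subject, unit-normalised per-lift V (and unit-energy
T) are averaged over retained lifts; the across-subject mean is
renormalised. Baselines are built separately per hand (dominant /
non-dominant), and a patient's affected arm is compared against the
non-dominant baseline.

## fNIRS chain

OD = −ln(I/Ī) with the temporal mean as pseudo-baseline; a true-baseline
mismatch only shifts OD by a per-channel constant, which the band-pass and
the GLM intercept absorb. Motion artifacts: multilevel DWT (Daubechies-5,
5 levels, symmetric extension); any detail level whose coefficient kurtosis
(Pearson convention, normal = 3) exceeds 3.3 has its largest-magnitude
coefficients zeroed — kurtosis recomputed over the surviving coefficients —
until tame. Note that finite-sample kurtosis noise makes occasional
single-coefficient edits on perfectly Gaussian data unavoidable (~1% mean
energy change at typical block lengths); the spike-suppression tests bound
this. Band-pass: zero-phase 3rd-order Butterworth 0.01–0.08 Hz (≥ 40 dB at
the ~1 Hz cardiac line, < 3 dB at the 0.025 Hz task fundamental). MBLL: a
2×2 linear solve per sample with tabulated extinction coefficients at
830/704 nm and DPF 6.0 for both wavelengths; these constants are exposed in
config, and because the simulator uses the exact same forward model, no
analysis result depends on the specific table. HbR is computed but feeds
nothing downstream; analyses use HbO only. GLM: task boxcar convolved with
the canonical double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6),
band-passed identically to the data so OLS stays unbiased inside the
analysis band, plus intercept.

## Laterality

The default region map (3 regions × 2 hemispheres × 4 channels, channel i
mirroring i+12) is a declared stand-in — real montages should supply their
own YAML, since true optode coordinates are study hardware. Orientation
normalization mirrors every affected hemisphere onto the right (patients:
lesion side; controls: the hemisphere contralateral to the non-dominant
arm). LI is computed with contralateral/ipsilateral resolved relative to
the *moving arm*; the alternative gloss (contralesional regardless of arm)
is not encoded because it contradicts the formula for affected-arm blocks.
LI is reported raw; with mixed-sign βs it can leave [−1, 1] and is flagged
rather than clipped, and a vanishing denominator marks the value missing.

## Statistics

Gate: Shapiro–Wilk per sample and one Levene across samples, each at
α = 0.05; all must pass for the parametric branch. Samples below n = 3
force the nonparametric branch. Note the gate's joint pass rate on truly
normal data is ≈ 0.95³ ≈ 86% by construction. Scheirer–Ray–Hare: mid-ranks
over all N observations, two-way ANOVA sums of squares on ranks,
H = SS_effect/(SS_total/(N−1)) against χ² at the effect's df; mid-ranking
already deflates the total rank variance under ties, so no separate tie
correction is applied. In unbalanced designs the interaction SS
(cells − A − B) is the classical approximation.

## Regression

The 21 predictors: {LI_PMC, LI_M1, LI_S1, SSI, C_V, C_T} × {affected,
unaffected}, six unaffected/affected ratios, age, days post stroke, and
F_r = MVC_unaffected/MVC_affected. The ratio direction follows the explicit
published equation (unaffected over affected) and is a config switch.
Models are fitted on patients only and applied out-of-sample to controls
(whose days-post-stroke is 0 and whose dominant/non-dominant arms play the
unaffected/affected roles). The exhaustive search enumerates subsets in
lexicographic order, fits by least squares on the complete-case rows
(listwise deletion computed once, so all 5985 models compete on identical
rows), ranks by adjusted R², and breaks ties by enumeration order; the
winner is refitted with full OLS inference (coefficient t-tests, model
F-test, standardized βs). No multiple-testing correction is applied across
the 5985 fits; the winning model's p-values are therefore optimistic and
should be read as descriptive.

## Synthetic cohort

The generator is the package's test bed, not a biophysical simulator. What
it emulates: the paradigm's timing and rates; trapezoid force lifts peaking
near target with configurable jitter (5% sd default, so the 15% exclusion
rule fires occasionally, as in practice); sEMG as a planted per-lift
envelope (synergy weight × bell profile) amplitude-modulating a 20–450 Hz
Gaussian carrier plus background noise; fNIRS as planted β × HRF responses
buried in cardiac (1 Hz), respiratory (0.3 Hz), Mayer-wave (0.1 Hz)
oscillations, linear drift, white noise and Poisson spike artifacts, pushed
through the exact inverse MBLL to intensities.

Severity maps (declared, not estimated): each patient draws a latent
severity ~ Uniform(0.1, 0.9). The affected arm's synergy vector is a
normalized mixture (1−m)·V_healthy + m·V_abnormal with m = severity plus
subject noise, where V_abnormal raises anterior-deltoid and brachioradialis
weights; the unaffected arm gets a mild baseline involvement
(0.15 + 0.25·severity plus noise). Per-lift vectors jitter with an sd that
grows with severity (driving SSI down); time profiles skew with severity
(driving C_T down); MVC on the affected side shrinks by 45%·severity;
planted hemodynamic responses shrink contralaterally and grow ipsilaterally
with severity, strongest in PMC, so the implied LI decreases strictly with
severity. Every index family carries its own independent subject-level
noise — without that, all indices would be monotone transforms of one
latent severity and no selection or recovery question would be well-posed.
The true FMul is θ0 + θ1·C_V_af + θ2·LI_PMC_un + θ3·F_r + θ4·C_V_r + ε
with θ = (60, 40, 28, −10, −40) and ε sd 2.0 by default, rounded and
clipped to [10, 66]; θ was chosen so the raw score spans the scale over the
severity range while staying ~2.5 sd inside the clip bounds (clipping would
otherwise corrupt the planted linearity), with clinically signed weights
(closeness and laterality positive, asymmetry ratios negative).

One non-obvious generator decision: the simulated sEMG block includes the
paradigm's three MVC bursts, which drive all five muscles to a common
ceiling. Per-muscle block min–max normalization then rescales every channel
by the same constant, so the planted synergy *direction* survives
preprocessing — without a common normalization reference the per-muscle
min–max would whiten away exactly the quantity the synergy indices measure.
The MVC bursts are themselves rejected from the lift pool by the 15% force
rule, exercising the exclusion logic in every simulated session.

What the generator does not emulate: motor-unit physiology, electrode
crosstalk, optode coupling and scalp physiology differences, motion
kinematics, HbR dynamics beyond a fixed −0.3 coupling, learning or fatigue
across trials. Passing recovery tests therefore demonstrates that the
pipeline's inference is correct under its own forward model, not that the
indices are valid biomarkers in real cohorts.

## Problem sizes

Default study-scale conditions are 15 patients + 15 controls, 6 trials per
block. The test suite and worked examples run reduced cohorts (2–4
subjects, 1–3 trials) and implied-feature cohorts (30 patients, indices
taken from ground truth rather than simulated signals) where the property
under test does not require full signal simulation; the per-lift
decomposition, filters and statistics are identical at every scale.

## Known limitations

* K = 1 synergy only; multi-synergy index matching across lifts is not
  implemented (the count-selection rule is, and flags when n > 1 would be
  needed).
* The SRH interaction term uses the balanced-design decomposition; strongly
  unbalanced tables should be interpreted with care.
* The default region map is positional, not anatomical.
* SNIRF import is not implemented; the documented CSV layout is the
  interchange format.
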