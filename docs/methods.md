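# Methods

This note documents the models, defaults and numerical choices behind
`fogdetect`, and what the synthetic experiments do and do not demonstrate.

## Synthetic cohort model

The generator (`fogdetect.synth`) produces multi-modal recordings whose
statistical and spectral structure carries exactly the contrasts the
detection pipeline relies on. It is a signal-level emulation, not a
biomechanical gait model.

**Episodes.** FOG onsets follow a homogeneous Poisson process (default 2
episodes/min) with a 2-s refractory gap between episodes; arrivals that
cannot fit (overlap, gap violation, or overrun of the task end) are thinned.
Durations are log-normal with median 8 s and shape σ = 1.2, clipped to
[1, 200] s. These defaults place roughly half the episodes under 10 s and
about a fifth under the 3-s exclusion threshold, matching the clinical
picture of many short freezes with an occasional very long one.

**Inertial signals** (100 Hz native). Walking is a per-subject gait
fundamental drawn from U(1, 2.5) Hz plus two harmonics with amplitudes
(1, 0.5, 0.25) and random phases per channel; even at the fastest gait the
locomotion band (0.5–3 Hz) holds ≥ 70 % of the 0.5–16 Hz power. FOG segments
replace this with a single tremor oscillation at the subject's freeze
frequency, drawn from U(4, 7) Hz, scaled by the FOG amplitude ratio
(default 0.5) — reduced movement intensity with power concentrated in the
freeze band. White noise (σ = 0.1) is added throughout. Wrist channels swing
at the gait frequency during walking; during FOG each subject is randomly
(once) assigned either *attenuation* (arm swing reduced to 15 %) or
*trembling* (freeze-band oscillation), reflecting the heterogeneity of upper
limb behaviour during freezing.

**EEG** (1000 Hz native, 28 electrodes including the ocular channel IO).
Each electrode carries pink (1/f-amplitude) noise; fronto-central and
centro-parietal sites (Fz, Cz, Pz, FC1/2, C3/4, CP1/2) additionally carry
band-limited oscillators (delta 2.5 Hz, theta 6 Hz, alpha 10 Hz, beta1
16 Hz, beta2 25 Hz). Inside episodes the oscillator powers are multiplied by
configurable band shifts (default: theta ×2.0, beta1/beta2 ×1.6, delta ×0.7,
alpha ×1.0), emulating the fronto-central rhythm changes associated with
freezing.

**Skin conductance** (100 Hz native). Conductance is a tonic level
(1.5–3 µS baseline) with a monotone drift of 0.3–0.6 µS per task plus a very
small slow oscillation, and phasic responses modelled as exponential pulses
(rise 0.3 s, decay 2 s, peak 0.3 µS) initiated within the 2 s preceding each
episode onset — anticipatory arousal. The channel is stored as galvanic
resistance (reciprocal of conductance), as a resistance front-end would
deliver it. The paper literature gives no quantitative SC morphology during
FOG, so the phasic timing is a modelling choice, not a claim.

Everything is reproducible: all draws derive from `(seed, subject_index)`,
and per-subject quantities (gait/freeze frequency, wrist style) are drawn
once and shared across that subject's tasks.

**What passing tests show — and not.** The synthetic regimes switch
instantaneously, the tremor is a pure tone, and noise is stationary; real
FOG has gradual onsets, broadband tremor, artefacts and annotation jitter.
High end-to-end scores on this cohort therefore validate the *pipeline
mechanics* (no leakage, correct labelling, features that capture the
intended contrasts), not clinical-grade performance.

## Preprocessing

Order per modality: standardize → filter → resample to 500 Hz. Filtering at
the native rate avoids interpolation artefacts entering band-power features;
resampling uses a polyphase band-limited method because all rate ratios are
exactly rational (100→500, 1000→500).

* All filters are applied **zero-phase** (forward–backward `sosfiltfilt`):
  the analysis is offline and window labels must not be shifted against the
  video-derived annotations. Stated filter orders are implemented literally
  as the digital design orders of each pass.
* Inertial: 4th-order Butterworth high-pass at 0.5 Hz + 5th-order Butterworth
  low-pass at 16 Hz, after z-scoring each channel.
* EEG: longitudinal bipolar montage first (18 derivations; the default
  montage covers temporal and parasagittal chains, the midline, and
  fronto-central/centro-parietal pairs — it is configurable and should be
  reported with results), then z-score per derivation, then 5th-order
  high-pass at 1.6 Hz + 6th-order low-pass at 30 Hz, Chebyshev type I with
  **0.1 dB passband ripple**. The ripple is deliberately small: zero-phase
  application squares the magnitude response, so a 0.5 dB design would lose
  up to ~21 % of passband amplitude at ripple minima across the cascade,
  versus ~4.5 % at 0.1 dB.
* Skin conductance is **exempt from z-scoring**: its features rely on the
  physical phasic/tonic morphology (e.g. the tonic slope in µS/s), which
  standardization would destroy. Pipeline: reciprocal → 5th-order Butterworth
  low-pass at 2 Hz → transient suppression → phasic split (SCR = 5th-order
  Butterworth high-pass at 0.5 Hz, SCL = SC − SCR, additive by
  construction). Transients are detected as first-difference outliers
  (> 5 × the MAD scale, lasting < 0.5 s) and replaced by a centred 4-s
  moving average; detection thresholds are heuristic because no published
  criterion exists.
* A note on the phasic split: since the 2-Hz low-pass confines any fast bump
  to [0, 2] Hz and the 0.5-Hz high-pass claims only the upper part of that
  range, at most ~70–75 % of an exponential bump's energy can ever appear in
  SCR. "Predominantly phasic" is the correct expectation for sharp
  responses; a 50/50 split is normal for slower ones.

## Windowing and labelling

3-s windows, 90 % overlap (0.3-s step), grid anchored at t = 0 of each task.
A window is FOG when **strictly more than half** of it lies inside episodes;
the exact 50 % tie breaks to non-FOG (conservative toward the negative
class). Sample membership uses half-open intervals [start, end) to avoid
double counting. Episodes shorter than 3 s are excluded before labelling —
they are below the post-smoothing time resolution — and windows straddling
an excluded episode are labelled against the filtered annotation set.

## Feature battery and its calibration

All frequency-domain features are computed from a Welch PSD (1-s Hann
segments, 50 % overlap → 1 Hz resolution on a 3-s window). Band powers are
trapezoidal integrals with interpolated band edges. Spectral moments
(mean/median/dominant frequency, skewness, kurtosis, entropy) are taken on
the power-normalized spectral distribution; entropy is normalized by
log(bin count) into [0, 1]. Peaks are local maxima with prominence
≥ 0.1 × the window standard deviation. A window whose locomotion-band power
vanishes yields a +inf freeze index, which normalization clips to 1.

The per-sensor column totals are a published contract (186 / 168 / 1107 /
39) whose itemization is partly ambiguous; the registry resolves the
ambiguities as follows and emits a machine-readable feature dictionary so
the calibration is auditable:

* **Tibial inertial (186)** — 17 frequency + 14 time features per axis ×
  3 axes × 2 sensors. The per-axis "axes correlation" slot holds one of the
  three pairwise Pearson correlations (x↔(x,y), y↔(y,z), z↔(z,x)).
* **Wrist inertial (168)** — per sensor: the Euclidean magnitude stream gets
  24 frequency (including sixteen 1-Hz band powers, locomotion/freeze band
  powers and the 9–12 / 13–16 Hz bands) + 3 time features; each component
  gets 7 frequency + 12 time features; 2 × (27 + 3 × 19) = 168.
* **EEG (1107)** — 16 frequency (including the five band powers bounded by
  the 1.6–30 Hz filter: delta 1.6–4, theta 4–8, alpha 8–13, beta1 13–20,
  beta2 20–30 Hz) + 3 time features per bipolar channel (19 × 18 = 342),
  plus magnitude squared coherence averaged within each band for all 153
  channel pairs (765). MSC uses the same Welch segmentation; with five
  averaged segments its null bias is ≈ 0.2, so only band coherences well
  above that are meaningful on 3-s windows.
* **Skin conductance (39)** — phasic: 10 frequency + 9 time; first and
  second central-difference derivatives of the phasic component: 8 time
  each; tonic: 3 frequency + least-squares slope.

The freeze ratio is implemented as the bounded variant
P(3–8)/P(0.5–8) ∈ [0, 1]; outputs state this definition.

Range normalization (min–max onto [0, 1]) is always fitted on training rows
only and applied to held-out rows with clipping — normalizing over all data
would leak test information into the leave-one-subject-out design. Columns
constant on the fitting rows are dropped with a warning.

## Selection

Point-biserial correlation of each column with the 0/1 label; p-values from
the exact t-transform with n − 2 degrees of freedom (windows are treated as
independent for selection despite the 90 % overlap, as the original design
does implicitly). The threshold is read as **absolute** correlation —
strongly negative features (locomotion band power, RMS) are retained.
Redundancy pruning is greedy in descending |r| with name-based tie-breaking:
the strongest candidate claims and removes everything correlated with it at
|r| ≥ 0.86, so the retained set never contains a redundant pair and the
result is invariant to column order. In the subject-independent design,
selection defaults to per-outer-fold fitting (never on the test subject); a
`selection_scope="all"` flag reproduces the variant where selection is run
once on the pooled cohort.

## Modeling

SVM kernels map to their usual parameterization (kernel scale s enters as
γ = 1/s²; polynomial kernels use coef0 = 1). kNN supports cityblock,
euclidean and squared-euclidean metrics (the latter two are rank-equivalent
by monotonicity) and equal / inverse / squared-inverse distance weights.
Continuous grid ranges are sampled at 5 log-spaced points over [0.1, 100]
and neighbour counts at {1, 5, 15, 45, 90, 180} (`full_grid`); a reduced
preset (`small_grid`: three SVM cells, two kNN cells) is used where the data
are strongly separated and the full grid adds nothing but runtime — the
acceptance run and the end-to-end tests use it, on a default cohort of
8 subjects × 2 tasks × 120 s (~6 250 windows).

Inner-fold aggregation uses the mean F-score across inner folds; the model
choice rule takes the cell that maximizes both accuracy and F-score when one
exists, otherwise the maximum F-score, with lexicographic tie-breaking. When
an inner validation subject lacks both classes it is excluded with a
warning. If no feature passes selection in a fold (as happens under label
permutation), the fold predicts the training majority class rather than
erroring — this keeps the permutation control meaningful. Class imbalance is
reported but not reweighted. Per-fold hyperparameter choice is the default
reading of the nested design; the modal configuration across folds is
available from the fold results for comparison.

A leakage audit records the row indices used by every fitting step
(normalization, selection, grid search, final fit) and asserts that no test
row appears in any of them.

## Evaluation

Metrics follow the standard confusion-count definitions; undefined metrics
(zero denominator) are reported as NaN, never coerced to 0. Majority voting
uses a centred 5-window span; at stream edges the vote shrinks to the
available neighbours, and an even-count tie keeps the original prediction
(a constant stream is always a fixed point). An episode counts as detected
when at least one smoothed FOG window overlaps it — the weakest defensible
criterion given the ~4-s smoothing resolution; the required overlap fraction
is configurable. Detection uses post-smoothing predictions by default.

## Known limitations

* The synthetic data omit EEG blink/EMG artefacts (artefact removal is out
  of scope), annotation jitter, sensor drift and non-stationary noise.
* Selection treats overlapping windows as independent, inflating effective
  sample size; p-values are anti-conservative by design fidelity.
* The 18-pair bipolar montage is a documented default, not a canonical
  standard, because the electrode set does not match the classical
  double-banana exactly.
* Episode-level detection with an any-overlap rule is generous for long
  episodes; stricter overlap fractions are available via configuration.
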