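# Methods

## Problem and architecture

Eight-class combined motor imagery assigns one class to every subset of
{left hand, feet, right hand} imagined simultaneously (rest = empty set).
Indexing the classes as a 3-bit engagement vector (left hand the least
significant bit) reproduces the conventional listing order rest, left hand,
feet, left hand + feet, right hand, both hands, right hand + feet, both
hands + feet, and this bit order is used everywhere: module order, feature
block order, class indices.

The multilabel decoders replace the 8-class problem by three binary CSP
problems, one per body part:

- **MC2CMI** — per part, class 1 = the 4 classes engaging it, class 2 = the
  4 that do not; trained on all eight classes.
- **MC2SMI** — per part, class 1 = that part's single MI, class 2 = rest;
  combined-MI trials are never used for fitting. Training vectors for all
  eight classes are synthesized by superposition (below).

Each module contributes 2m = 6 log-variance features (m = 3 filter pairs);
the concatenated 18-dim vectors feed one 8-class shared-covariance LDA.
The PW (28 pairwise members) and OVA (8 one-vs-rest members) baselines use
the identical CSP feature pipeline per member with a 2-class LDA each.

## CSP conventions

- Per-trial covariances are trace-normalized (`EEᵀ/trace(EEᵀ)`); class
  covariances are arithmetic means over trials.
- The generalized eigenproblem Σ̄₁w = λΣ̄₂w is solved after symmetrization
  and a relative ridge of 1e-8·trace/C on each matrix. The ridge matters
  because common-average-referenced data is rank-deficient by exactly one
  dimension (the all-ones direction).
- Eigenvalues are sorted descending; ties keep their stable order. Filters
  are scaled so wᵀ(Σ̄₁+Σ̄₂)w = 1 and signed so the largest-magnitude
  coefficient is positive — both conventions are mathematically arbitrary
  and exist to make results reproducible.
- Patterns are stored as A = W⁻¹ (so W·A = I). Under Y = WᵀE the scalp
  pattern of filter j is row j of A; `CSPModel.pattern(j)` returns that row.
- Log-variance features floor each projected variance at 1e-12 of the
  trial's total projected variance before the log: the CAR null direction
  projects every trial to exactly zero power, and when its (λ = 1)
  eigenvalue falls among the selected extremes the feature would otherwise
  be −∞. The floor preserves the per-block identity Σexp(v) = 1 to < 1e-11.

## MC2SMI feature synthesis

For class y and module p, the 6-dim block of a synthesized training vector
is copied from a randomly drawn donor trial: a single-MI trial of part p if
y engages p, else a rest trial. Donors are drawn without replacement until
the pool is exhausted, then reshuffled (seeded). Forty vectors per class
(mirroring the real class size) are synthesized; raising this to 120
changed benchmark accuracy by < 1 pp, so the default stands. Sharing one
rest donor across the non-engaged modules of a vector (preserving
cross-block correlations where possible) was also evaluated and did not
help, so blocks are drawn independently.

## LDA

Class-conditional Gaussians with per-class means and the pooled within-class
covariance (scatter / (n − K)), plus a relative ridge of 1e-6·trace/d:
CSP features become nearly collinear when classes separate sharply. Priors
are empirical unless given; OVA members deliberately keep the empirical
1/8 vs 7/8 priors so their posteriors reflect the class imbalance. The
decision rule is maximum posterior, i.e. minimum expected 0–1 cost.

## Preprocessing

Fifth-order Butterworth band-pass 8–30 Hz, applied zero-phase
(forward–backward; the analysis is offline and zero-phase preserves ERD
timing — the −3 dB band edges hold for the single-pass design). Filtering
happens on the continuous recording before epoching when possible; on
pre-epoched input 0.5 s reflection padding limits edge transients. Common
average reference follows, then a 3-s analysis window starting 0.5 s after
the cue (0.5–3.5 s).

## Synthetic sessions

The generator emulates the acquisition: 26 electrodes over the sensorimotor
cortex at 256 Hz; 12-s trials (6-s cue, 6-s pause); 4 runs × 10 trials per
class in randomized order (320 trials); a 4-s lead-in precedes the first
cue. Three oscillatory sources sit at the canonical locations (left hand →
C4, feet → Cz, right hand → C3) and project to the montage through a
Gaussian kernel of head-plane distance (width 0.25 head radii, column
maxima normalized to 1). Each source is the sum of mu (11 Hz, 2 µV RMS) and
beta (21 Hz, 1 µV RMS) components realized as narrowband-filtered white
noise (±1.5 Hz, new phase every session) — pure sinusoids would make the
trial covariances rank-deficient and CSP degenerate. Background noise is
independent per-channel 1/f noise (8 µV RMS broadband) plus a small common
1/f component (30%), the latter removed exactly by CAR.

During the cue window an engaged source's amplitude drops to (1 − d) of
baseline (default d = 0.6, i.e. −84% band power); non-engaged sources of
non-rest trials rise to (1 + g) (surround ERS; default g = 0). Transitions
are smoothed with a 250-ms ramp, mimicking gradual ERD onset. Amplitudes
revert to baseline during the pause, so the 2 s before each cue serve as
the ERD reference period.

**What the defaults represent.** They were chosen once so that the default
benchmark (20 seeded sessions, 10-fold cross-validation) operates in the
regime the method was designed for: MC2CMI accuracy mid-range rather than
saturated (84.9% mean), every method clearly above the 22.5% chance bound,
the multilabel methods ahead of PW/OVA, and MC2SMI within 10 points of
MC2CMI — the near-equivalence of the two is the regime of interest, since
MC2SMI is MC2CMI's cheap-calibration variant.

Two generator effects discovered while choosing the defaults are worth
recording. First, surround ERS (g > 0) systematically penalizes MC2SMI:
with g > 0 each single-MI-vs-rest CSP module keys on *all three* sources
(the non-engaged ones rise during a single MI), so features no longer
superpose across modules; at g = 0.25 the MC2CMI−MC2SMI gap is 20–30
points at any SNR. The default g = 0 is the pure-superposition regime.
Second, task-independent background rhythms (available via
`n_background_sources`) widen the gap further: they correlate the three
modules' feature blocks within a trial, and MC2SMI's synthesis — which
assembles blocks from independent donor trials — cannot represent that
correlation. Both effects are real limitations of superposition-based
training, not artifacts, and both knobs remain available for robustness
studies.

**What the generator does not emulate:** volume conduction through a
3-D head model, EOG/EMG artifacts, non-stationary drifts, inter-subject
variability, or the attentional/fatigue effects that dominate real MI
performance. Passing benchmarks here show the decoders are implemented
correctly and behave as designed under their own model assumptions; they do
not predict accuracy on real recordings.

## Diagnostics

ERD/ERS% uses the classical band-power convention 100·(A − R)/R with the
reference window [−2, 0) s before the cue (the tail of the preceding
pause); the window is a parameter. Band power is the squared band-passed
signal smoothed by a 250-ms moving average. The square law links the
generator to the measurement: amplitude suppression d yields a plateau of
100·((1−d)² − 1), i.e. −75% for d = 0.5. Verification runs use a focal
source footprint (spread 0.15) because with the default 0.25 the feet
source leaks ≈ 7.7% of its power into C4 and shifts the theoretical
plateau to −69.6%; the law under test is the amplitude–power relation, not
the leakage. Spectra are Welch periodograms (1-s segments, 50% overlap),
reported as amplitude; discriminability is the squared point-biserial
correlation (r²) between a feature and the binary condition.

## Evaluation

A seeded stratified plan partitions each class's trials into 10 folds of 4
test trials per class (32 test / 288 training trials per fold at full
session size); the same plan and the same band-passed data are shared by
all methods, and every method is re-fitted from scratch inside each fold.
ROC/AUC is one-vs-rest on the pooled held-out scores (AUC = normalized
Mann–Whitney U, ties half-credit). Method comparisons use the two-sided
Wilcoxon rank-sum test on fold accuracies — exact null for combined
samples ≤ 20 without ties, normal approximation with tie correction
otherwise. The chance level is the binomial inverse-CDF bound: the smallest
k with CDF(k; n, 1/K) ≥ 1 − α, as a percentage of n.

Problem sizes used by the shipped verification runs: the decoding benchmark
is 20 sessions of 320 trials (tests) or 10 sessions (acceptance script);
unit tests use 80-trial single-run sessions. PW ties are broken by the
summed LDA posterior over the tied classes (deterministic); pure majority
voting alone would be ambiguous.

## Known limitations

- The synthetic benchmark's absolute accuracies are not comparable to any
  real-subject numbers; only orderings and invariances are meaningful.
- MC2SMI's synthesis assumes cross-module feature independence; the
  generator options that break it (g > 0, background rhythms) degrade it
  by design (see above).
- The EDF importer matches channels by name against the built-in montage
  and drops the rest; montages other than the 26-channel layout require
  constructing a `Montage` explicitly.
- No artifact handling: the package expects cleaned, continuous or epoched
  EEG.
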