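# Methods

This note documents the models, numerical choices and limitations of
`qeegpod`: what the synthetic EEG emulates, how each qEEG feature is
defined where the clinical literature leaves details open, and what
passing the test suite does and does not establish about real
recordings.

## The synthetic EEG model

A subject's EEG is modelled as a stationary Gaussian process with a
piecewise power-law spectrum on 0.5–40 Hz (the analysis band). The
spectrum is parameterized the way clinical tables report it:

- **band fractions** — shares of power in delta/theta/alpha/beta over
  a normalization range (default: the band union, 1–30 Hz for
  published-table profiles; sums within 10⁻³ are accepted as printed
  rounding and renormalized exactly);
- **`subdelta_mass`** — the share of *total* power lying below the
  normalization range (flat-shaped over [0.5, lo));
- **`in_band_tilt`** — a power-law exponent `S(f) ∝ f^t` applied
  within each band without moving the band masses;
- **`amplitude_scale`** — the RMS amplitude in µV.

Synthesis shapes white Gaussian noise in the frequency domain by
√S(f) (equivalent to summing zero-phase band-filtered noise
components, with exact expected power per band and no inter-band
leakage) and then pins the realized RMS of each channel to
`amplitude_scale`. Channels are independent realizations: every
implemented feature is a per-channel quantity averaged across
channels, so spatial covariance would not change any of them.

Cohorts draw per-subject profiles around a group mean:
logistic-normal jitter on the band fractions (additive Gaussian noise
on log-fractions, renormalized — keeps fractions on the simplex) and a
mean-one log-normal multiplier on the amplitude. The dispersion values
for the study-emulation scenarios are inverted from the published SEM
columns by the delta method (`scenarios.fraction_dispersion`,
`scenarios.amplitude_dispersion`). Per-subject randomness derives from
the cohort seed via `numpy.random.SeedSequence(seed, spawn_key=(group,
subject))`, so a single subject can be regenerated in isolation and
the dataset is bit-reproducible.

### Why `subdelta_mass` exists

The published group tables are internally inconsistent if band
fractions are taken as a complete description: for the delirium arm,
cumulative power at 8 Hz is 80.29 + 9.85 = 90.1% of the band union,
yet the printed SEF95 is 7.58 Hz — impossible unless substantial power
lies *outside* (below) the fraction-normalization range. Sub-delta
slow activity is exactly what heavy sedation produces, so the model
exposes it as a free parameter: included in SEF/entropy/aEEG physics,
excluded from fraction normalization. Calibrating the delirium SEF95
requires ≈60% of total power below 1 Hz.

The same diagnosis applies to the printed RAV values: both arms' RAVs
(24.92%, 33.38%) exceed the largest 6–14/1–20 Hz power ratio their own
printed band fractions permit under *any* within-band shape (the
sub-delta component lies below 1 Hz and cannot help). RAV calibration
therefore raises an explicit infeasibility error at those targets,
reporting the attainable range; the tilt calibration is exercised and
tested at attainable targets instead.

## Calibration

`calibrate_profile` solves one scalar parameter by bracketed root
finding (Brent; `xtol=1e-12`):

- **SEF95** → `subdelta_mass` (monotone decreasing in SEF95);
- **RAV** → `in_band_tilt` (bracket located by a sign-change scan over
  t ∈ [−12, 12], since the map is not monotone);
- **aEEG upper limit** → `amplitude_scale`.

By default the objective is the feature of the **expected extractor
PSD**, not of the ideal spectrum: the profile spectrum multiplied by
the zero-phase band-pass power transfer (`|H|⁴` for
forward–backward Butterworth filtering) and convolved with the Hann
taper's spectral window, evaluated on the extractor's periodogram
grid. This matters: the 0.5 Hz high-pass attenuates the sub-delta
component enough to shift recovered SEF95 by several tenths of a Hz
if calibration ignores it. Ideal-spectrum ("theoretical") features
remain available (`theoretical_sef`, `theoretical_rav`,
`theoretical_band_fractions`) and are what the closed-form unit tests
check (flat spectrum → SEF95 = 38.025 Hz, RAV = 8/19, etc.).

The aEEG envelope percentile of band-weighted Gaussian noise has no
closed form, but it is exactly linear in amplitude, so the aEEG
reference value is computed once per spectral shape by running the
full chain on three fixed-seed unit-amplitude 120 s syntheses and the
amplitude is rescaled analytically. This makes amplitude calibration
deterministic and exact up to the (small, seed-averaged) reference
noise.

## Feature-extraction choices

Where the clinical sources do not state an algorithm, the following
conventions are fixed and exposed in `FeatureConfig`:

- **Band-pass** 0.5–40 Hz, 4th-order Butterworth, zero-phase
  (`sosfiltfilt`) so the aEEG envelope sees no phase distortion. The
  acquisition hardware band (0.1–40 Hz) is not re-applied; the
  analysis band governs the features. The doubled response gives
  ≈ −28 dB at 60 Hz (mains).
- **Epochs**: 8 s Hann windows, 50% overlap (0.125 Hz grid),
  per-epoch periodograms averaged per channel. 4 s epochs (0.25 Hz)
  are a configurable alternative but smear enough delta power across
  the 4 Hz edge (the taper main lobe is ±0.5 Hz) to bias the delta
  fraction of a strongly slowed spectrum by ~1.7 points; at 8 s the
  bias is ~0.8 points, a better resolution/variance trade-off at the
  2-minute recording lengths used here.
- **Artifact screening** masks (never edits) epochs whose any-channel
  peak-to-peak exceeds 200 µV or whose all-channel peak-to-peak is
  below 0.1 µV, standing in for the visual screening of clinical
  practice.
- **Band integrals** are trapezoidal on the PSD grid with linear
  interpolation at band edges; **SEF** interpolates the cumulative
  power linearly between grid points (removes grid-resolution bias).
- **Spectral entropy** is the normalized Shannon entropy × 100 over
  0.5–40 Hz. Proprietary monitor entropies (the "40–50 under
  sedation" scale) involve undisclosed weighting and time-domain
  components; absolute agreement with them is out of scope, and the
  package's SE is used for bounds, invariances and relative
  comparisons only.
- **aEEG** is a documented stand-in for vendor cerebral-function-
  monitor algorithms: 2nd-order Butterworth 2–15 Hz (zero-phase), a
  linear-in-f gain (the classic ~12 dB/decade rising response)
  normalized to 1 at 10 Hz, peak-to-peak amplitude per 0.5 s window,
  15 s moving-average smoothing, 10th/90th envelope percentiles as
  the lower/upper limits. Every constant is configurable.
- **RAV** is implemented exactly as defined — a band-power ratio over
  a 2-minute window — despite "variability" in its name; a
  time-course-variability alternative is out of scope.
- **Montage**: features are computed on the 8 listed referential
  channels; `EEGRecording.pick` supports derived montages but no
  bipolar re-referencing is applied by default, since every reported
  quantity is an 8-channel average.

## Statistics

Welch's t is computed from summaries (`t = Δm/√(sem₁²+sem₂²)`,
Welch–Satterthwaite df), and the raw-sample route is *defined* as the
summary route applied to computed summaries, so the two agree exactly.
The Fisher two-sided p sums hypergeometric point probabilities ≤ the
observed one (the standard small-p rule, with a 1+1e-7 relative guard
against floating-point ties); both chi-square variants (with/without
Yates) are always reported because published papers rarely state
which was used. No multiplicity correction is applied by default
(matching how such tables are printed); Holm adjustment is available
on the results object. Sample-size planning implements
unpooled-normal, pooled-normal and arcsine (Cohen's h) formulas —
for the 35% vs 5% planning scenario these give 24, 22 and 12 per
group respectively; no attempt is made to reverse-engineer which
tool produced any particular published planning number.

## Problem sizes and determinism

Recovery tests and the acceptance script use 120 s, 256 Hz, 8-channel
recordings at the published group sizes (10/14/22/24) — about 90
syntheses plus extractions, a few tens of seconds on one CPU.
Acceptance cohorts are generated with zero between-subject dispersion:
they measure generator↔extractor calibration fidelity; sampling
variability at the published SEMs is exercised separately by the
study-emulation scenarios. All randomness flows from explicit seeds;
identical configuration yields byte-identical outputs.

## What passing does not show

The generator produces stationary, Gaussian, spatially independent,
artifact-free signals. Real sedated-ICU EEG is none of these: it has
nonstationary sedation depth, inter-channel correlation, occasional
artifacts, and non-Gaussian graphoelements. Consequently the tests
demonstrate that the *pipeline* is correct and self-consistent (it
recovers known spectral truth at stated tolerances and reproduces the
published arithmetic and effect directions under calibrated
simulation), not that the biomarkers would achieve any particular
discrimination on new patients. Quantities requiring the original
recordings — ventilation hours, length of stay, the reported ROC
(78% sensitivity / 50% specificity) — are explicitly out of scope, as
are burst-suppression detection and sleep–wake cycling, which the
generator does not simulate. aEEG *lower* limits of Gaussian
surrogates sit closer to the upper limit than published values (real
EEG's envelope is wider-tailed); only the upper limit is calibrated.
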