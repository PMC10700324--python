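# Methods

This note records the modeling choices behind the package: what the
pipeline computes, what the synthetic cohorts do and do not emulate, the
numerical conventions, and the places where the procedure was genuinely
underdetermined and a choice had to be made.

## The CorrTF feature

For ROI mean series `x` (output role) and `y` (input role), both of
length `T` sampled at TR seconds, the per-bin feature is the one-sided
DFT magnitude ratio `|X_k| / |Y_k|`. The scalar connection value is the
mean of these ratios over the bins with `0.01 ≤ f_k ≤ 0.08` Hz (the DC
bin is always excluded; at T = 130, TR = 3 s this is 28 bins). Median
and maximum reductions are available (`aggregation`), but the band mean
is the default: the feature is used as one number per directed pair, and
the mean is the least structured reduction.

**Direction convention.** The denominator region is the input: matrix
entry `(i, j)` is `|F(region_i)| / |F(region_j)|`, the connection
directed *j → i*, and summaries count region `j` as the source. The
defining ratio as printed is ambiguous between the two readings; the
input-in-the-denominator reading is the one consistent with the
transfer-function identity `H = Y/X` and with describing connections as
"directed from" the denominator region.

**Denominator regularization.** Bins where `|Y_k|` falls below
`eps_rel × max in-band |Y_k|` (default `eps_rel = 1e-12`) are *excluded*
from the band mean rather than clipped: clipping a near-zero denominator
produces a huge but meaningless ratio, and inflating the mean with it
would make the feature noise-dominated. After band-pass filtering real
in-band bins essentially never trip this guard; it exists for degenerate
inputs (a region with no in-band power raises a degenerate-connection
error naming the pair).

**No windowing or detrending.** The series are band-pass filtered and
nothing else; a taper would change the statistic being studied.

Per-bin identities used as test oracles: self-ratio ≡ 1; scale law
`CorrTF(c·x, x) = |c|`; reciprocity `ratio_{i→j}(f) · ratio_{j→i}(f) = 1`
at every bin valid in both directions; and full equivalence with a naive
O(T²) direct-summation DFT implementation.

## Signal preparation

Inputs are assumed fully preprocessed upstream (slice timing, motion
correction, MNI normalization, smoothing); this package only discards
the first 10 volumes (magnetization equilibrium), averages voxel
intensities per atlas label (label integers = 1-based region indices;
mismatched grids are an error, never silently resampled), and band-pass
filters each series to 0.01–0.08 Hz.

The filter is a zero-phase forward–backward Butterworth of order 4
(effective order 8), with odd-reflection edge padding. The filter family
and order are not dictated by the analysis being reproduced — only the
band is — so a standard rs-fMRI choice was made and left configurable.
Contract (verified in tests): a 0.04 Hz sinusoid is retained within 10%,
DC and 0.15 Hz components are attenuated by more than 20 dB, the
operation is linear, and the passband has zero phase shift.

## Longitudinal screening

Per group and connection, the subjects × visits value matrix is tested
with two paired t-tests (baseline→visit 1, visit 1→visit 2) and a
one-way ANOVA across visits; significance requires all three p < α
(default 0.05, two-sided, uncorrected across the 13,340 connections —
deliberately mirroring the screening character of the reference
procedure; `correction: bh` is available). Paired tests are the default
because the same subjects are measured at every visit; an unpaired
variant is selectable. Degenerate connections (zero-variance
differences) are reported with a flag, never dropped, so bookkeeping
identities over the full connection set always hold.

**Normalization axis — a deliberate deviation.** The reference
procedure normalizes "the data" to unit sum of squares without stating
the axis. Two readings exist:

* *per connection*: each visit's cross-subject vector scaled to unit
  norm. Because connectivity features are positive with mean well above
  their cross-subject spread, this normalization removes almost exactly
  the across-the-board shift between visits that a longitudinal effect
  produces. Measured on synthetic cohorts it drives the power against
  planted effects to zero and makes the paired t strongly conservative
  (type-I ≈ 0.01–0.03 at α = 0.05). It cannot be what a procedure that
  *found* hundreds of longitudinal connections used.
* *per subject*: each subject-visit's whole connection profile scaled to
  unit norm. This removes global scale differences between subjects and
  scanning sessions — the usual motivation for sum-of-squares
  standardization — while leaving each connection's cross-subject mean
  shift intact. Measured type-I error of the single paired t is
  0.046 ± 0.003 on 4,000 independent null connections, and planted
  effects are recovered with the expected power.

The package defaults to the per-subject axis (`stats.normalize:
per_subject`); `per_connection` and `none` are selectable. One caveat of
profile normalization: a very strong change concentrated on few
connections leaks into all others through the shared norm. The effect
shrinks as 1/(number of connections) and is negligible at the 13,340
connections of the full parcellation, but in heavily reduced test
problems (tens of regions) it measurably inflates the null rate — the
package's own Monte-Carlo experiments therefore use ≥ 50 regions.

Sign patterns: `positive_to_negative` for t₁ > 0 > t₂, and so on; an
exact zero takes the partner's sign, a double zero is classified
`same_sign_positive` by convention.

## Synthetic cohorts

The generator emulates exactly the features the analysis consumes:

* **Band-limited signal.** Each region's latent series is a sum of
  K = 5 equal-amplitude sinusoids with frequencies drawn uniformly among
  the DFT-bin frequencies inside 0.01–0.08 Hz, random phases, normalized
  to unit SD. Drawing *bin* frequencies makes every series band-limited
  by construction (zero leakage), which is what the ≥ 95% in-band-power
  invariant requires even for draws at the band edge; continuously drawn
  frequencies leak several percent of their power outside the band at
  130 samples.
* **Within-subject stability, between-visit noise.** A subject's latent
  oscillators are drawn once and reused at every visit; white Gaussian
  noise (default SD 1.0 against the unit-SD latent) is redrawn per
  visit. Under no effects the visits are exchangeable, which underwrites
  the type-I experiments.
* **Directed effects.** An effect adds `gain_v × latent_source` into the
  target region at visit v — coupling of latent (noise-free) signals, so
  the injected connectivity change is controlled and monotone in the
  gain (verified by a Monte-Carlo oracle on the generator itself).

Defaults reproduce the target study design: groups NC 29 / EMCI 23 /
LMCI 24 / AD 23, three visits, 116 × 130 at TR = 3 s. The shipped
default study plants effects from one characteristic source region per
disease group (a vermis region for EMCI, a cerebellar hemisphere region
for LMCI, a temporal-pole region for AD) with gains (0, 0.5, 0.2) — a
rise then partial fall, the positive→negative temporal pattern — and
none in NC. The gain magnitude was chosen once so that the default run
yields significant sets of the same order as a real study (tens to ~150
per group) rather than saturating the matrix.

**What the generator does not emulate** — and hence what passing tests
do *not* establish about real data: hemodynamic response shapes, 1/f
spectral structure, head motion, physiological (cardiac/respiratory)
aliasing, spatial autocorrelation between neighboring regions, and
between-subject clinical heterogeneity. The Monte-Carlo calibration and
power results are statements about the procedure under the stated
generative model, not about effect sizes in patients.

The tiny labeled-volume fixtures (disjoint voxel blocks carrying known
series) exist to test NIfTI ingestion and ROI averaging exactly; they
are synthetic stand-ins, not atlas data.

## Region table and networks

The packaged table lists the 116 AAL regions in the standard ordering
(90 paired cerebral regions, odd = left / even = right; 18 cerebellar
hemisphere regions; 8 midline vermis regions) with abbreviations and a
six-network assignment (SMC, EAN, VC, Cereb, DMN, SN). No authoritative
per-region table exists for this exact six-network scheme; the shipped
mapping honors every attribution stated alongside the reference analysis
(all cerebellum and vermis regions → Cereb; calcarine → VC; paracentral
lobule, Heschl, superior parietal, superior temporal → SMC; hippocampus
and middle temporal pole → SN; superior temporal pole → EAN; gyrus
rectus → DMN) and fills the remaining regions from conventional AAL
groupings. It is a documented reconstruction: any analysis that depends
on the exact membership should supply an override file (YAML or TSV,
keyed by index or abbreviation), which is applied and re-validated at
load time.

Percentage contribution uses *distinct regions* touched by significant
connections as the denominator by default; counting endpoints with
multiplicity is available (`denominator="endpoints"`) because the
phrase "contributed regions" admits both readings. An empty significant
set yields zero counts and percentages, not an error — a group with no
longitudinal change is a data outcome.

## Determinism and problem sizes

All randomness flows from explicit integer seeds through NumPy
`SeedSequence` spawning, so cohorts are bit-reproducible and pipeline
reruns produce byte-identical CSVs (fixed float formatting). The full
default study (297 subject-visits, 116 regions, both arms, four groups)
runs in well under a minute on one CPU; the package's Monte-Carlo
experiments use 80 replicate null cohorts of 50 regions (2,000
independent connections via disjoint region pairs) for type-I
calibration and 200 replicate 116-region cohorts at n = 25 for power,
sizes chosen to give binomial standard errors below half a percentage
point on the reported rates.

## Known limitations

* The scalar reduction of the per-frequency ratio (band mean) and the
  filter family/order are documented choices, not recoverable facts;
  results at other settings are available through the config but are
  not the defaults.
* No covariate adjustment (age, sex), no mixed-effects or trajectory
  modeling, no multiple-comparison correction by default, no dynamic
  (sliding-window) connectivity — all outside the reproduced procedure.
* CorrTF values are ratios of spectral magnitudes; their cross-subject
  distributions are right-skewed with occasional large values, and the
  paired t-test on their differences is accordingly slightly
  conservative (measured rejection ≈ 0.046 at α = 0.05). The intersection
  rule compounds three such tests, so its empirical false-positive rate
  on null cohorts is well below 1%.
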