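# Methods

`cpmon` analyses continuous pressure-monitoring (CPM) recordings from bed
sensing mats: grids of interface pressures (mmHg) sampled at 1 Hz from a
mattress-sized array. The pipeline detects large-scale postural changes,
characterises the pressure borne at the buttock/sacral region during each
static posture, and stratifies each posture's pressure–time exposure into
four risk categories. A synthetic session generator with exact ground truth
stands in for clinical recordings, which are not publicly available.

## Mat geometry and data model

The default profile (`MatGeometry.foresite_pt()`) models a 762 × 1880 mm
sensing area at 15.9 mm pitch sampled at 1 Hz, realised as a 48 × 118 grid
(5664 sensels). The commercial device this emulates quotes 5556 cells — a
count no integer row × column factorisation of the stated area and pitch
reproduces — so the grid is plain configuration, and the package never
hard-codes a cell count. Rows run across the mat width, columns along the
head-to-foot axis, 0-based; cell (r, c) is centred at
((r + 0.5)·pitch, (c + 0.5)·pitch). Timestamps are seconds from the first
frame; all segment intervals are half-open `[start, end)`, and the
monitoring length counts the final frame's dwell (T = n/rate).

Two interchangeable on-disk formats sit behind `read_sequence` /
`write_sequence`: a long-format CSV (`t_s,row,col,pressure_mmHg`) with a
YAML metadata sidecar, and an HDF5 container (one 3-D array plus
attributes). CSV serialisation uses `%.17g` so round-trips are bit-faithful;
the CSV suits short recordings and inspection, HDF5 suits multi-hour
sessions (an 8-h default-geometry session is ~160 M CSV rows).
Validation checks non-negative finite pressures, grid shape, strictly
increasing timestamps, and sampling uniformity within a ±10 % jitter
tolerance, reporting each violation with the offending frame.

## Posture-change detection

Three channels are derived per frame: centre of pressure (COP) in both
planar axes — the pressure-weighted centroid over cells above a 5 mmHg
floor — and the contact area, the total area of cells above 20 mmHg. The
COP floor and contact threshold are deliberately distinct parameters: the
floor only suppresses near-zero cells that would drag the centroid, while
20 mmHg is the conventional loaded-contact criterion.

Each channel is moving-average smoothed (default 11 s), differentiated by
central differences, and robust-z-scored over the recording using
median/MAD. A channel whose derivative has zero MAD but non-zero variance
(noise-free recordings: the derivative is zero except at isolated events)
falls back to the SD scale; a truly constant channel contributes nothing.
The per-frame movement signal is the Euclidean norm of the three z-scored
derivatives — scale-free across channels with different units.

Changes are detected where the combined signal exceeds
`median + k·MAD` (default `k = 12`). Contiguous supra-threshold runs merge
into one candidate at the run's peak (earliest frame on ties), and
candidates are accepted greedily in descending amplitude subject to a
minimum separation (default 60 s), so two true events closer than the
separation merge into one — documented behaviour, not a bug.

The threshold multiplier was calibrated on the generator, not on any
clinical data: across seeded five-posture sessions with inter-posture
shifts ≥ 6 sensels, within-posture micro-movement peaks at roughly 8×
the combined signal's MAD (the norm of three correlated z-scores has
heavier tails than its MAD suggests), while genuine postural changes exceed
60×. `k = 12` sits in that gap with margin on both sides; at `k = 6` the
threshold lands inside the micro-movement band and false positives appear
in about half of runs. Both `k` and the window are configuration.

Recordings shorter than twice the smoothing window are rejected rather than
silently segmented. No pre-filter for alternating-mattress interference is
applied by default; the generator's alternating mode exists to stress the
detector, and its slow (≥ minutes) modulation is largely absorbed by the
MAD normalisation.

Segmentation partitions `[0, T)` at the detected instants; durations sum to
T exactly. Movement features: posture count, monitoring hours,
`frequency_per_hour` (posture count ÷ hours by default — the convention
that reproduces the published per-patient extremes 1.17/h = 17 postures /
14.5 h and 0.06/h = 1 posture / 16 h; a `transitions` basis, change count ÷
hours, is available), intervals between changes, and the fraction of the
period spent in postures held longer than 2 h.

## Buttock ROI and pressure signatures

For each static posture a fixed window of 30 sensels along the body axis ×
20 across the width (47.7 × 31.8 cm at 15.9 mm pitch) is centred on the
segment's median COP, rounded to the nearest sensel, with even-extent
convention `centre − ⌊e/2⌋ … centre + ⌈e/2⌉ − 1`; windows overhanging the
mat are shifted minimally to fit and flagged. The window is fixed per
posture (median COP) rather than tracked per frame, matching the static-
posture reading and avoiding gradient artefacts from a moving window.

Inside the window, per frame:

* **peak pressure** — maximum sensel pressure, mmHg;
* **peak pressure index (PPI)** — mean of the 10 highest pressures, mmHg;
* **peak pressure gradient (PPG)** — maximum |Δp| over diagonally adjacent
  sensel pairs, both diagonal orientations, divided by the diagonal spacing
  √2 · pitch = 2.2486 cm, in mmHg/cm. Using both orientations is
  direction-symmetric and never smaller than either single diagonal. The
  diagonal definition is blind to perfect checkerboard patterns (diagonal
  neighbours share parity) — an accepted property of the definition.

Per-posture descriptors are the mean and sample SD (n−1) of each per-frame
series, plus the posture duration in hours. All signatures are homogeneous
of degree 1 in pressure, and peak ≥ PPI ≥ window mean on every frame; both
properties are enforced by tests against brute-force oracles.

## Sigmoid pressure–time exposure

Tissue tolerates high pressure briefly and lower pressure longer; the
boundary between tolerable and damaging exposure is conventionally drawn as
a sigmoid in the (duration, pressure) plane. Three ordered logistic-decay
curves

    B_k(t) = F_k + (S_k − F_k) / (1 + exp(α (t − t₀)))

split the plane into low / moderate / high / very-high exposure, where the
category of a point is the number of curves its magnitude strictly exceeds
at its duration. Starting pressures S_k default to 25/35/45 mmHg/cm for PPG
and 70/90/110 mmHg for PPI ("starting pressure" is read as the
short-exposure boundary value; the published PPG values are printed in
mmHg, but the quantity's unit is mmHg/cm and they are treated as such).
The remaining parameters — floor fraction F_k/S_k = 0.4, steepness
α = 2 h⁻¹, inflection t₀ = 2 h — are engineering defaults chosen to give
clinically plausible decay over the 0–12 h range; the source analysis calls
its thresholds arbitrary and does not publish a functional form, so no
physiological validity is claimed and every parameter is configuration.
With shared α, t₀ and floor fraction the three curves never cross.

Two attribution modes exist because "proportion of time in each exposure
category" admits both readings. `posture` (default) accrues each posture's
whole duration to the category of its (duration, mean magnitude) point —
one marker per posture against the curves. `resolved` partitions each
posture's timeline at the analytic crossing times
`t*_k = t₀ + ln((S_k−F_k)/(m−F_k) − 1)/α`, so a long posture accrues
lower-category time early and higher-category time once the curves decay
below its magnitude. Fractions are normalised by total monitoring hours and
sum to 1 in both modes; the resolved mode is verified against a 1-second
brute-force categorisation scan.

## Synthetic sessions

The generator emulates exactly the structure the analysis assumes, with
known ground truth:

* **Body templates** — each posture is a set of Gaussian loading sites
  (amplitude mmHg, SD in sensels), exactly one flagged pelvic. The four
  built-in templates (supine, both laterals, high sitting) are fixed
  documented constants on the 48 × 118 grid, not fitted to any subject;
  pelvic amplitudes 110–130 mmHg dominate the other sites, as buttock
  loading dominates in lying postures.
* **Schedule** — postures with dwell times (minimum 60 s) and whole-body
  COP offsets; changes are linear cross-fades (default 10 s) so the
  derivative detector sees a finite-width pulse like a real turning event.
  Transition samples belong to the following posture (half-open
  convention).
* **Micro-movement** — a mean-reverting AR(1) walk of the whole-body
  position (stationary SD `jitter_sd_sensels`, default 0.2). A pure random
  walk at that step size would drift ~12 sensels per hour — a posture
  change, not micro-movement — so mean reversion keeps the wander bounded
  while preserving its low-frequency character.
* **Sensor noise** — i.i.d. Gaussian, default SD 2 mmHg, truncated at
  0 mmHg since pressures are non-negative. Truncation biases near-zero
  cells upward by at most ~0.8·SD (the folded-Gaussian mean at zero
  signal); loaded-region signatures are unaffected.
* **Alternating mattress (optional)** — multiplicative modulation
  `1 ± depth·sin(2πt/period)` with opposite sign on odd/even column
  stripes; defaults 600 s and 0.15, chosen to stress detection rather than
  to model any product.

Identical seeds give identical sessions. The ground-truth log carries the
true change instants, per-posture pelvic centres, and noise-free PPG/PPI
oracles computed from the static render in an ROI centred on the true
pelvic site.

No noise or movement statistics are published for the real device, so
these defaults are stress-test choices, not estimates; the generator also
has no tissue mechanics and no shear. Passing recovery tests therefore
demonstrates correctness of the algorithmic chain under the stated model,
not clinical performance on real mats.

## Cohort fixtures and reporting

The study cohort's two published tables are packaged as CSV fixtures with
SHA-256 checksums fixed at build time; `load_fixture` fails loudly on any
edit. Reported summaries use linear-interpolation quartiles at 1-based
position `1 + (n−1)q` — the convention that reproduces the published IQRs
8.7 (post lengths), 4 (pre posture counts) and 10 (post posture counts)
from the 17-patient table. Display rounding matches the source: frequencies
2 d.p., hours 1 d.p., mean BMI to the nearest integer (27 kg/m²).

Three published numbers are irreproducible from the tables under any
standard convention and are recorded as errata rather than targets: the
pre-length IQR printed as 13 (linear-interpolation value: 20), the BMI
range printed as 15.10–46.5 (the table's maximum is 46.7), and the
pre-length range printed as 9–45.3 (the table contains a 51 h entry).
The published cohort-level exposure percentages require the raw
recordings, which are not public, and are out of scope.

`compare_pre_post` joins per-patient analysis outputs across phases with
explicit gaps for missing phases; pooled exposure fractions are
monitoring-hour-weighted means within each phase, so they sum to 1.

## Problem sizes and numerical choices

The repository's analysis drivers and tests run on deliberately compact
sessions: detector-recovery batteries use five-posture sessions of 10 min
per posture (3 000 frames), and the end-to-end check uses one 8-h
four-posture session (28 800 frames, run through the HDF5 path). Frame
stacks are rendered and stored in float32; COP/area channels accumulate in
float64. Quartiles use NumPy's linear interpolation; sample SDs use the
n−1 denominator and require ≥ 2 frames per segment; peak-acceptance ties
break toward the earlier time; sub-threshold detection on a flat signal
yields zero changes and a single posture spanning the recording.

## Known limitations

* Posture *identity* (supine vs lateral) is not classified — only change
  instants and static intervals.
* Seated/wheelchair data and shear effects are out of scope.
* The ROI is a fixed rectangle anchored on the COP; no anatomical
  recognition is attempted, and for unusual postures the pelvic region can
  sit off-centre in the window.
* Exposure-category boundaries are configurable defaults, not validated
  injury thresholds; between-cohort comparisons should hold them fixed.
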