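# Methods

This note records the scientific and numerical choices behind `synergia`:
what each stage computes, which parameters matter, what the synthetic-data
generator does and does not emulate, and where the design was genuinely
open.

## Signal conditioning

Raw surface EMG (13 lower-limb muscles, 1000 Hz, 30 s trials) is turned into
the activation matrix V in four steps.

**Filtering.** Each channel is high-pass filtered at 50 Hz, full-wave
rectified, and low-pass filtered at 20 Hz to form the linear envelope. Both
filters are Butterworth run forward-backward (zero phase). "4th-order
zero-phase" is read here as a 2nd-order design applied bidirectionally,
which squares the magnitude response to effective 4th order — the common
convention in the EMG literature. The alternative reading (a 4th-order
design run bidirectionally, effective 8th order) steepens the transition
bands but changes none of the downstream logic; the cut-offs are exposed as
`hp_cutoff` / `lp_cutoff` in `RunConfig`.

**Positivity.** After filtering, negative values are set to zero and zero
entries are floored to the smallest non-zero value of that channel in that
trial (per-channel scope keeps muscles independent; the floor only matters
in the far tails). The factorization requires a nonnegative V, and strictly
positive entries avoid absorbing zeros in the multiplicative updates.

**Amplitude normalization** is per muscle, dividing both of a participant's
trials by that muscle's maximum over their concatenation, so each muscle's
global maximum is exactly 1. Per-muscle (rather than one global) scaling is
the standard choice for this normalization lineage; it makes module weights
comparable across muscles with different absolute signal amplitudes. The
operation is idempotent.

**Time normalization.** Each gait cycle is resampled to 200 points — 100
spanning stance (touchdown to lift-off) and 100 spanning swing (lift-off to
next touchdown) — by piecewise-linear interpolation on the 1000 Hz grid
(monotone and artifact-free; the resampling method is not dictated by the
analysis). The stance grid includes both of its endpoints; the swing grid
stops short of the next touchdown so the cycle boundary sample is not
duplicated. Thirty cycles give n = 6000 columns. The conditioning order is
filter → amplitude-normalize → time-normalize; amplitude normalization
commutes with linear resampling only up to interpolation error at the
per-muscle maximum, which is negligible at these sampling rates.

A cycle-times table of k rows (touchdown + stance duration per cycle)
defines only k−1 complete cycles, because the last swing ends at a
touchdown the table does not list. `time_normalize` therefore requires
n_cycles + 1 touchdowns and reports the number of complete cycles found when
there are too few; the synthetic generator emits n_cycles + 1 rows so the
pipeline can cut exactly the requested number of cycles.

## Factorization

V ≈ W·H is fit by the squared-error ("Gaussian") multiplicative updates,
H first, then W against the updated H, with denominators floored at 1e-12.
W and H are initialized i.i.d. uniform on (0, 1] — strictly positive, since
a zero entry would be fixed forever under multiplicative updates. R² between
V and W·H is evaluated once per iteration after both updates; iteration
stops when the spread (max − min) of the last 20 R² values falls below
0.01 % of the current R², read as a *relative* tolerance — at the R² ≈ 0.9–1
levels typical here, the relative and absolute readings nearly coincide.
`max_iter` defaults to 1000 and is a safety net; the window rule normally
fires within a couple of hundred iterations. The squared reconstruction
error is non-increasing across iterations (a known property of these
updates, asserted numerically in the tests), and results are bit-reproducible
for a fixed seed.

Each rank r = 1…10 is fit from 10 restarts, restart j seeded with
master + j, keeping the highest-R² solution. Outputs are the raw
factorization results: no post-hoc normalization of W columns or H rows is
applied, and the synergy order is whatever the factorization produced —
factors are identifiable only up to permutation and positive rescaling, so
all comparisons against ground truth are made after greedy best-cosine
matching of module columns (adequate for r ≤ 10).

## Model-order selection

The best-of-restarts R² values across ranks form a rising, saturating
curve. A line is fitted by OLS to the current curve and the mean squared
residual computed; while it is ≥ 10⁻⁵ (strict less-than stops, as the
threshold is a printed constant) and more than two points remain, the
lowest-rank point is dropped. The selected order is the first rank of the
terminal segment — the point where the curve becomes linear, i.e., where
additional synergies stop improving reconstruction beyond a linear trend.
OLS residuals are invariant to adding a constant to the whole curve, so the
selection depends only on curvature, not on the absolute R² level.

## Synergy classification

Primitives are averaged pointwise across the cycles of the trial (200-point
mean cycle). Major peaks are counted on a 5-point moving-average smoothed
copy with a prominence floor of 10 % of the primitive's maximum and a
minimum separation of 25 points (12.5 % of the cycle); "single peak" has no
canonical quantitative definition, so both parameters are exposed as
configuration. One major peak ⇒ fundamental, two or more ⇒ combined. The
cycle start is a true physical boundary (touchdown), so no circular wrap is
applied, and a monotone primitive peaking at the boundary counts as
single-peaked. Fundamental synergies are labeled by the quadrant of their
peak: points [0, 50) weight acceptance, [50, 100) propulsion, [100, 150)
early swing, [150, 200) late swing; combined synergies are labeled `none`.

## Gait parameters

Contact time is the stance duration; cycle duration is the interval between
successive touchdowns; swing is their difference. Cadence counts both feet:
steps/min = 2 × 60 / cycle duration in seconds — the 2× convention is the
one consistent with ~163 steps/min at ~740 ms cycles, whereas a per-foot
count would give ~81. The strike index projects the center of pressure at
impact onto the heel→toe axis and divides by foot length, clamping to
[0, 1]; values below 0.333 are classified rearfoot, the boundary itself
midfoot-forefoot (strict less-than).

## Synthetic-data generator

The generator runs the analysis model backwards so that ground truth is
known exactly.

- **Primitives:** single Gaussian bumps on the 200-point cycle, peak 1,
  σ = 13 points (FWHM ≈ 15 % of the cycle — a width that makes generated
  primitives unambiguous single peaks without being impulse-like). For
  r = 4 the centers sit at points 25, 75, 125, 175, the middles of the four
  functional quadrants.
- **Modules:** for the default 13-muscle rank-4 truth, each synergy weights
  its functional muscle group — glutei + knee extensors (weight acceptance),
  plantar flexors PL/GM/GL/SO (propulsion), dorsiflexors (early swing),
  knee flexors + dorsiflexors (late swing) — with random magnitudes in
  [0.6, 1.0] against a [0.02, 0.15] background on the remaining muscles.
- **Cycles:** contact ~ N(288, 42²) ms and swing ~ N(452, 45²) ms, truncated
  at zero by redraw; these defaults are the cohort statistics the analysis
  is meant to operate on.
- **Envelope:** per sample, the primitives are linearly time-warped onto the
  drawn stance/swing durations (stance → template points 0–99, swing →
  100–199), combined through the modules, and multiplied by
  1 + noise (truncated Gaussian, clipped at 0, relative sd `noise_sd`,
  default 0.1) — multiplicative so nonnegativity is preserved.
- **Carrier:** each raw channel is the envelope times an independent
  zero-mean unit-RMS Gaussian carrier band-limited to 20–450 Hz — a simple,
  spectrally plausible surrogate for the interference pattern of real EMG
  whose rectified, low-passed version approximates the envelope (scaled by
  E|N(0,1)| = √(2/π)). A `carrier="constant"` mode replaces it by 1 for
  degenerate-case tests.
- **Metadata:** heights, masses, ages and speeds from the cohort's normal
  statistics; strike index from a Beta distribution moment-matched to mean
  0.152, sd 0.195.

What the generator does **not** emulate: electrode crosstalk, motion
artifacts, inter-cycle correlation of noise, non-Gaussian interference
statistics, amplitude drift, or any biophysical motor-unit structure. Raw
amplitudes are arbitrary units by design (no SNR statistics of real
recordings are modeled). Passing tests therefore demonstrate that the
pipeline is a correct implementation of the analysis and that it recovers
planted low-rank structure under realistic timing and moderate noise — not
that real recordings satisfy the rank-4 model.

## Problem sizes in the tests and acceptance script

The unit and property tests use single trials of 8–30 cycles and small
random matrices. The ground-truth recovery check runs 20 seeded replicates
of 15-cycle trials (V is 13 × 3000) through the full chain — conditioning,
10-rank sweep with 10 restarts, order selection — which keeps the whole
suite at a few minutes on one CPU while leaving the per-replicate selection
problem statistically equivalent to the 30-cycle case (the R²-vs-rank curve
is driven by the per-cycle structure, which is identical). The acceptance
script additionally runs a 5-participant × 2-trial cohort at the full 30
cycles and a 135-row metadata table. The factorization oracle check uses a
6 × 40 matrix at rank 2, where a 1000-restart exhaustive baseline is
computable in seconds.

## Known limitations

- The order-selection procedure assumes the R²-vs-rank curve is evaluated
  at ranks 1…10 with best-of-10 restarts; far noisier curves (few restarts)
  can shift the selected order by ±1.
- Peak counting is threshold-based; primitives with genuinely ambiguous
  secondary activity near the 10 % prominence floor flip between
  fundamental and combined under small perturbations.
- The strike index is computed from supplied heel/toe/COP geometry; no
  plantar-pressure image processing is included, and touchdown/lift-off
  detection is out of scope — cycle-times tables are inputs.
- `normalize_amplitude` assumes the trials passed together belong to the
  same participant; it does not check identity.
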