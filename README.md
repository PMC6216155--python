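# synergia

Muscle-synergy extraction from surface EMG of human treadmill running.

During locomotion the central nervous system is thought to coordinate the
many muscles of the lower limb through a small set of shared commands —
*muscle synergies*. `synergia` implements the standard factorization-based
analysis of this idea for running: it conditions multi-channel surface EMG
into nonnegative activation profiles, decomposes them by non-negative matrix
factorization (NMF), chooses the number of synergies from the shape of the
reconstruction-quality curve, classifies each synergy functionally, and
summarizes the gait cycle. It is written for movement scientists who want a
tested, scriptable version of this pipeline, and it ships a synthetic-data
generator with known ground truth so every stage can be validated without
access to recorded data.

## The model

The conditioned EMG of m = 13 muscles over n time points is collected in a
nonnegative matrix **V** (m × n) and factorized as

    V ≈ V_R = W · H,    W ∈ ℝ₊^{m×r},  H ∈ ℝ₊^{r×n}

where the columns of **W** are *motor modules* (time-invariant muscle
weightings) and the rows of **H** are *motor primitives* (time-dependent
activation coefficients). The factors are fit by the classical Gaussian
multiplicative updates

    H ← H ∘ (WᵀV) ⊘ (WᵀW H),    W ← W ∘ (V Hᵀ) ⊘ (W H Hᵀ)

(the W update uses the freshly updated H), iterated until the coefficient of
determination R² between V and W·H changes by less than 0.01 % over the last
20 iterations. Each rank r = 1…10 is fit from 10 random restarts and the
best solution kept; the *minimum number of synergies* is then chosen by
repeatedly fitting a line to the R²-vs-rank curve and dropping its first
point until the mean squared residual falls below 10⁻⁵ — the rank at which
the curve becomes linear.

Upstream of the factorization, each raw EMG channel (1000 Hz) is high-pass
filtered at 50 Hz, full-wave rectified and low-pass filtered at 20 Hz (both
zero-phase Butterworth), floored to strictly positive values, normalized per
muscle to the participant's maximum across both trials, and each gait cycle
is time-normalized to 200 points (100 stance + 100 swing). Downstream, a
synergy whose cycle-averaged primitive has a single major peak is
*fundamental* and labeled by the cycle quadrant of that peak
(weight acceptance, propulsion, early swing, late swing); multi-peaked
primitives are *combined*. Gait summaries report contact and swing times and
cadence (2 steps per one-limb cycle), and the strike index — heel-to-center-
of-pressure distance at impact over foot length, < 0.333 meaning rearfoot
strike.

## Worked example

```python
import numpy as np
from synergia import (make_ground_truth, synthesize_trial, preprocess_participant,
                      rank_sweep, select_order, classify_synergies, summarize_cycles)

gt = make_ground_truth(seed=1, noise_sd=0.1)            # 4 known synergies
trial, cycles, _ = synthesize_trial(gt, n_cycles=30)    # 30 s raw trial at 1000 Hz

(V,) = preprocess_participant([trial], [cycles], n_cycles=30)
print("V:", V.values.shape)                             # 13 muscles x 6000 points

curve, best = rank_sweep(V.values, r_max=10, restarts=10, seed=42)
rank = select_order(curve)
syn = best[rank - 1]
print("selected rank:", rank, " R2: %.3f" % syn.r_squared)

for c in classify_synergies(syn.H):
    print(f"synergy {c.index + 1}: {c.kind}, peak at {c.peak_location}, {c.phase_label}")

g = summarize_cycles(cycles)
print(f"contact {g.contact_mean:.0f} ms, swing {g.swing_mean:.0f} ms, "
      f"cadence {g.cadence_mean:.0f} steps/min")
```

prints

```
V: (13, 6000)
selected rank: 4  R2: 0.974
synergy 1: fundamental, peak at 75, propulsion
synergy 2: fundamental, peak at 175, late-swing
synergy 3: fundamental, peak at 127, early-swing
synergy 4: fundamental, peak at 24, weight-acceptance
contact 290 ms, swing 460 ms, cadence 161 steps/min
```

The generator planted four single-peaked synergies; the pipeline conditions
the raw trial into the 13 × 6000 matrix V, selects exactly four synergies
(R² = 0.974), recovers one fundamental synergy per functional phase of the
gait cycle, and the cycle table reproduces the generator's contact/swing
statistics. Factorizations are identifiable only up to permutation and
scaling, so the synergy order is arbitrary.

The same analysis is available from the shell over deposited-style file
trees (`RAW_EMG_P0026_02.dat`, `CYCLE_TIMES_P0026_02.dat`, ...):

```sh
synergia simulate --participants 5 --cycles 30 --rank 4 --noise 0.1 --seed 1 --out data/
synergia run --input data/ --out results/ --seed 1
```

which writes `FILT_EMG_*`, `SYNS_H_*`/`SYNS_W_*` files, a per-trial
`report.tsv` and a cohort `summary.json`.

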