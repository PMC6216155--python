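"""Classification of extracted synergies and functional phase labeling.

A synergy whose cycle-averaged motor primitive shows a single major
activation peak is *fundamental*; one blending two or more fundamental
patterns — two or more major peaks — is *combined*. Fundamental synergies
are given a functional label by the quadrant of the 200-point gait cycle in
which their peak falls: weight acceptance (early stance), propulsion (late
stance), early swing, late swing. Combined synergies are labeled ``none``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .preprocess import POINTS_PER_CYCLE

#: Peak detection: a local maximum counts as a major peak when its prominence
#: exceeds this fraction of the primitive's maximum ...
PROMINENCE_FRACTION = 0.10
#: ... and it is at least this many points (12.5% of the cycle) from the
#: nearest other accepted peak.
MIN_PEAK_SEPARATION = 25
#: Moving-average width applied before peak counting.
SMOOTH_WINDOW = 5

PHASE_LABELS = ("weight-acceptance", "propulsion", "early-swing", "late-swing")

FUNDAMENTAL = "fundamental"
COMBINED = "combined"


@dataclass
class ClassifiedSynergy:
    index: int
    mean_primitive: np.ndarray      # cycle-averaged activation, 200 points
    kind: str                       # "fundamental" | "combined"
    peak_count: int
    peak_location: int              # index of the highest major peak
    phase_label: str = "none"


def mean_cycle(primitive: np.ndarray,
               points_per_cycle: int = POINTS_PER_CYCLE) -> np.ndarray:
    """Average a primitive row over its gait cycles (pointwise mean)."""
    p = np.asarray(primitive, dtype=float)
    if p.ndim != 1:
        raise ValueError("primitive must be 1-D")
    if len(p) % points_per_cycle != 0:
        raise ValueError(
            f"length {len(p)} is not a multiple of {points_per_cycle} points/cycle"
        )
    return p.reshape(-1, points_per_cycle).mean(axis=0)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: len(x)]


def classify_primitive(mean_primitive: np.ndarray,
                       prominence_fraction: float = PROMINENCE_FRACTION,
                       min_separation: int = MIN_PEAK_SEPARATION,
                       smooth_window: int = SMOOTH_WINDOW
                       ) -> tuple[str, int, int]:
    """Count major activation peaks; return (kind, peak_count, peak_location).

    Peaks are detected on the lightly smoothed cycle-averaged primitive with
    a prominence floor of ``prominence_fraction`` of its maximum and a
    minimum mutual separation of ``min_separation`` points. One peak makes
    the synergy fundamental, two or more make it combined. The gait-cycle
    start is a true boundary (touchdown), so no circular wrap is applied; a
    maximum sitting on the boundary of a monotone primitive still counts as
    its single peak.
    """
    p = np.asarray(mean_primitive, dtype=float)
    if np.any(p < 0):
        raise ValueError("primitive must be nonnegative")
    if np.ptp(p) == 0:
        raise ValueError("constant primitive: no peaks definable")
    s = _smooth(p, smooth_window)
    floor = prominence_fraction * s.max()
    peaks, props = find_peaks(s, prominence=floor, distance=min_separation)
    if len(peaks) == 0:
        # monotone or boundary-peaked primitive: the global maximum is the peak
        peaks = np.array([int(np.argmax(s))])
        heights = s[peaks]
    else:
        heights = s[peaks]
    loc = int(peaks[int(np.argmax(heights))])
    count = int(len(peaks))
    kind = FUNDAMENTAL if count == 1 else COMBINED
    return kind, count, loc


def label_synergies(classified: Sequence[ClassifiedSynergy],
                    points_per_cycle: int = POINTS_PER_CYCLE
                    ) -> list[ClassifiedSynergy]:
    """Assign functional phase labels by peak-location quadrant.

    Quadrants of the 200-point cycle map to weight-acceptance [0, 50),
    propulsion [50, 100), early-swing [100, 150) and late-swing [150, 200).
    Only fundamental synergies receive a label; combined ones get ``none``.
    """
    quarter = points_per_cycle // 4
    out = []
    for c in classified:
        if c.kind == FUNDAMENTAL:
            q = min(c.peak_location // quarter, 3)
            out.append(replace(c, phase_label=PHASE_LABELS[q]))
        else:
            out.append(replace(c, phase_label="none"))
    return out


def classify_synergies(H: np.ndarray,
                       points_per_cycle: int = POINTS_PER_CYCLE,
                       **peak_kw) -> list[ClassifiedSynergy]:
    """Cycle-average, classify and label every primitive row of H."""
    H = np.asarray(H, dtype=float)
    classified = []
    for i, row in enumerate(H):
        mp = mean_cycle(row, points_per_cycle)
        kind, count, loc = classify_primitive(mp, **peak_kw)
        classified.append(ClassifiedSynergy(index=i, mean_primitive=mp,
                                            kind=kind, peak_count=count,
                                            peak_location=loc))
    return label_synergies(classified, points_per_cycle)
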