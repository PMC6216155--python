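"""Gait-cycle summary statistics and the strike index.

Contact (stance) time, swing time and cadence are derived from the per-trial
cycle-times tables: the cycle duration is the interval between successive
touchdowns, swing is cycle minus contact, and cadence counts both feet —
steps/min = 2 x 60 / cycle duration in seconds (each one-limb gait cycle
contains two steps; this convention reproduces ~163 steps/min from ~740 ms
cycles).

The strike index characterizes the foot-strike pattern: the distance from
the heel to the center of pressure at impact, relative to total foot length,
so it ranges from 0 (heel strike) to 1 (toe strike). A value below 0.333 —
the rear third of the foot — denotes a rearfoot strike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import CycleTimes, ValidationError

#: Strike-index boundary of the rearfoot third (strict less-than).
REARFOOT_THRESHOLD = 0.333
REARFOOT = "rearfoot"
MIDFOOT_FOREFOOT = "midfoot-forefoot"


@dataclass
class GaitSummary:
    """Mean ± SD of contact/swing times (ms) and cadence (steps/min)."""

    contact_mean: float
    contact_sd: float
    swing_mean: float
    swing_sd: float
    cadence_mean: float
    cadence_sd: float
    n_cycles: int


def summarize_cycles(ct: CycleTimes) -> GaitSummary:
    """Contact, swing and cadence statistics over the complete cycles of a trial."""
    if ct.n_cycles < 2:
        raise ValidationError(
            f"need at least 2 touchdowns to measure a cycle, got {ct.n_cycles}"
        )
    cycle_s = np.diff(ct.touchdown)             # one-limb cycle durations
    contact_s = ct.stance_duration[:len(cycle_s)]
    swing_s = cycle_s - contact_s
    cadence = 2.0 * 60.0 / cycle_s              # both feet: 2 steps per cycle
    ddof = 1 if len(cycle_s) > 1 else 0
    return GaitSummary(
        contact_mean=float(np.mean(contact_s) * 1e3),
        contact_sd=float(np.std(contact_s, ddof=ddof) * 1e3),
        swing_mean=float(np.mean(swing_s) * 1e3),
        swing_sd=float(np.std(swing_s, ddof=ddof) * 1e3),
        cadence_mean=float(np.mean(cadence)),
        cadence_sd=float(np.std(cadence, ddof=ddof)),
        n_cycles=int(len(cycle_s)),
    )


def strike_index(heel: np.ndarray, toe: np.ndarray,
                 cop_at_impact: np.ndarray) -> float:
    """Heel-to-COP distance at impact over foot length, clamped to [0, 1].

    The center of pressure is projected onto the heel→toe axis; off-axis
    components are discarded (the index is one-dimensional along the foot).
    """
    heel = np.asarray(heel, dtype=float)
    toe = np.asarray(toe, dtype=float)
    cop = np.asarray(cop_at_impact, dtype=float)
    axis = toe - heel
    length_sq = float(axis @ axis)
    if length_sq == 0.0:
        raise ValueError("zero foot length: heel and toe coincide")
    si = float((cop - heel) @ axis) / length_sq
    return float(np.clip(si, 0.0, 1.0))


def foot_strike_class(si: float) -> str:
    """Rearfoot for si < 0.333, midfoot-forefoot otherwise."""
    if not 0.0 <= si <= 1.0:
        raise ValueError(f"strike index {si} outside [0, 1]")
    return REARFOOT if si < REARFOOT_THRESHOLD else MIDFOOT_FOREFOOT
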