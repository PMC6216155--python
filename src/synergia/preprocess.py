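"""EMG conditioning: linear envelopes, amplitude and time normalization.

The conditioning chain turns a raw trial plus its gait-cycle breakdown into
the nonnegative activation matrix V handed to the factorization:

1. high-pass filter at 50 Hz (movement-artifact removal), full-wave
   rectification, low-pass filter at 20 Hz (linear envelope) — both filters
   zero-phase Butterworth, a 2nd-order design run forward-backward so the
   effective magnitude response is 4th order;
2. negative values clipped to zero and zero entries floored to the smallest
   non-zero value of the channel, so V is strictly positive;
3. per muscle, amplitude-normalized to the participant's maximum activation
   across both trials;
4. each gait cycle time-normalized to 200 points — 100 for stance, 100 for
   swing — and cycles concatenated column-wise, so 30 cycles give
   n = 6000 columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io_formats import MUSCLES, CycleTimes, ValidationError

#: Default sampling rate of the EMG system, Hz.
FS_DEFAULT = 1000.0
#: High-pass cut-off, Hz.
HP_CUTOFF = 50.0
#: Low-pass (linear envelope) cut-off, Hz.
LP_CUTOFF = 20.0
#: Time-normalization grid: points assigned to stance and to swing.
POINTS_STANCE = 100
POINTS_SWING = 100
POINTS_PER_CYCLE = POINTS_STANCE + POINTS_SWING

_MIN_SAMPLES = 100  # filter warm-up floor


@dataclass
class EnvelopeMatrix:
    """The m x n conditioned activation matrix V (m muscles, n = cycles*200)."""

    values: np.ndarray
    muscle_order: tuple[str, ...] = MUSCLES
    cycles: int = 0
    points_per_cycle: int = POINTS_PER_CYCLE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m, n = self.values.shape
        if m != len(self.muscle_order):
            raise ValidationError(f"{m} rows but {len(self.muscle_order)} muscle names")
        if self.cycles and n != self.cycles * self.points_per_cycle:
            raise ValidationError(
                f"{n} columns != {self.cycles} cycles x {self.points_per_cycle} points"
            )
        if np.any(self.values < 0):
            raise ValidationError("activation matrix must be nonnegative")

    @property
    def n_muscles(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.values.shape[1]


def make_envelope(series: np.ndarray, fs: float = FS_DEFAULT,
                  hp_cutoff: float = HP_CUTOFF,
                  lp_cutoff: float = LP_CUTOFF) -> np.ndarray:
    """Linear envelope of one raw EMG channel.

    Zero-phase high-pass at ``hp_cutoff`` -> full-wave rectification ->
    zero-phase low-pass at ``lp_cutoff``; negatives set to 0, then zeros set
    to the smallest non-zero value of the series (the matrix entering the
    factorization must be strictly positive). Output has the input's length.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if len(x) < _MIN_SAMPLES:
        raise ValueError(
            f"series of {len(x)} samples is shorter than the filter warm-up "
            f"({_MIN_SAMPLES} samples)"
        )
    if np.isnan(x).any():
        raise ValueError("series contains NaN")
    sos_hp = signal.butter(2, hp_cutoff, btype="highpass", fs=fs, output="sos")
    sos_lp = signal.butter(2, lp_cutoff, btype="lowpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos_hp, x)
    y = np.abs(y)
    y = signal.sosfiltfilt(sos_lp, y)
    y[y < 0] = 0.0
    nonzero = y[y > 0]
    if nonzero.size == 0:
        # identically-zero input: floor everything at a tiny positive value
        y[:] = np.finfo(float).tiny
    else:
        y[y == 0] = nonzero.min()
    return y


def make_envelopes(channels: np.ndarray, fs: float = FS_DEFAULT, **kw) -> np.ndarray:
    """Apply :func:`make_envelope` row-wise to an (m, T) channel matrix."""
    channels = np.asarray(channels, dtype=float)
    return np.vstack([make_envelope(row, fs=fs, **kw) for row in channels])


def normalize_amplitude(trials: list[np.ndarray]) -> list[np.ndarray]:
    """Normalize each muscle to its maximum across both trials of a participant.

    ``trials`` holds one (m, T_i) envelope matrix per trial, rows in the same
    muscle order. Every muscle row of every trial is divided by that muscle's
    maximum over the concatenation of the trials, so the per-muscle global
    maximum becomes exactly 1. Idempotent.
    """
    if not trials:
        raise ValueError("no trials given")
    m = trials[0].shape[0]
    if any(t.shape[0] != m for t in trials):
        raise ValueError("all trials must have the same muscle set")
    maxima = np.max(np.hstack([np.max(t, axis=1, keepdims=True) for t in trials]),
                    axis=1)
    out = []
    scale = maxima.copy()
    tiny = np.finfo(float).tiny * 1e3
    flat = scale <= tiny
    if flat.any():
        warnings.warn(
            f"channel(s) {np.nonzero(flat)[0].tolist()} are at the zero floor; "
            "left unscaled", RuntimeWarning)
        scale[flat] = 1.0
    for t in trials:
        out.append(t / scale[:, None])
    return out


def time_normalize(envelopes: np.ndarray, ct: CycleTimes,
                   fs: float = FS_DEFAULT, n_cycles: int = 30,
                   t0: float = 0.0,
                   points_stance: int = POINTS_STANCE,
                   points_swing: int = POINTS_SWING) -> EnvelopeMatrix:
    """Resample each gait cycle to a fixed grid and concatenate.

    For cycle k, the stance interval (touchdown -> touchdown + stance
    duration) is resampled to ``points_stance`` points and the swing interval
    (stance end -> next touchdown) to ``points_swing`` points, by linear
    interpolation on the sample grid. The stance grid includes both of its
    endpoints; the swing grid starts at the stance end and stops short of the
    next touchdown so that the cycle boundary sample is not duplicated.

    ``envelopes`` is (m, T) with samples at ``t0 + i/fs``. Uses the first
    ``n_cycles`` complete cycles of ``ct``.
    """
    env = np.asarray(envelopes, dtype=float)
    if env.ndim == 1:
        env = env[None, :]
    m, T = env.shape
    if ct.n_complete_cycles < n_cycles:
        raise ValidationError(
            f"need {n_cycles} complete gait cycles but the cycle table defines "
            f"only {ct.n_complete_cycles}"
        )
    t = t0 + np.arange(T) / fs
    last_needed = ct.touchdown[n_cycles]
    if last_needed > t[-1] + 0.5 / fs:
        raise ValidationError(
            f"cycle table extends to {last_needed:.3f} s but the recording "
            f"ends at {t[-1]:.3f} s"
        )
    ppc = points_stance + points_swing
    out = np.empty((m, n_cycles * ppc), dtype=float)
    for k in range(n_cycles):
        td = ct.touchdown[k]
        st_end = td + ct.stance_duration[k]
        next_td = ct.touchdown[k + 1]
        grid_st = np.linspace(td, st_end, points_stance)
        grid_sw = st_end + (next_td - st_end) * np.arange(points_swing) / points_swing
        grid = np.concatenate([grid_st, grid_sw])
        for i in range(m):
            out[i, k * ppc:(k + 1) * ppc] = np.interp(grid, t, env[i])
    return EnvelopeMatrix(out, muscle_order=tuple(MUSCLES[:m]) if m == len(MUSCLES)
                          else tuple(f"ch{i}" for i in range(m)),
                          cycles=n_cycles, points_per_cycle=ppc)


def preprocess_participant(raw_trials, cycle_tables, fs: float = FS_DEFAULT,
                           n_cycles: int = 30) -> list[EnvelopeMatrix]:
    """Full conditioning for the trials of one participant.

    Envelopes are computed per trial, amplitude is normalized jointly across
    the trials (per muscle), then each trial is time-normalized against its
    own cycle table.
    """
    envs = [make_envelopes(rt.channel_matrix(), fs=fs) for rt in raw_trials]
    envs = normalize_amplitude(envs)
    out = []
    for env, rt, ct in zip(envs, raw_trials, cycle_tables):
        out.append(time_normalize(env, ct, fs=fs, n_cycles=n_cycles,
                                  t0=float(rt.time[0])))
    return out
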