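"""Synthetic running-EMG generator with known synergy ground truth.

Every downstream stage is testable without the recorded cohort: trials are
built from known nonnegative modules and primitives, so rank selection,
factor recovery, envelope conditioning and gait summaries can all be checked
against the generating truth.

The generative model mirrors the analysis model read backwards. A set of r
motor primitives — single Gaussian bumps on the 200-point normalized gait
cycle, peak 1, centered in the weight-acceptance, propulsion, early-swing
and late-swing quadrants for the default r = 4 — is combined with a
nonnegative module matrix weighting the muscle groups engaged in each phase
(knee extensors + glutei; plantar flexors; dorsiflexors; knee flexors +
dorsiflexors). Per-cycle contact and swing durations are drawn from the
cohort's running statistics (contact 288 ± 42 ms, swing 452 ± 45 ms), the
primitives are time-warped onto each drawn cycle, multiplied by the modules
and by multiplicative truncated-Gaussian envelope noise, and the resulting
envelope amplitude-modulates a zero-mean band-limited (20-450 Hz) Gaussian
carrier to give a raw-EMG-like signed signal at 1000 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .io_formats import MUSCLES, CycleTimes, ParticipantRecord, RawEmgTrial

#: Cohort gait statistics used as generator defaults: contact and swing
#: duration mean/sd in milliseconds.
CYCLE_MODEL_DEFAULT: dict[str, float] = {
    "contact_mean": 288.0, "contact_sd": 42.0,
    "swing_mean": 452.0, "swing_sd": 45.0,
}

#: Gaussian primitive width: sigma as a fraction of the 200-point cycle.
PRIMITIVE_SIGMA_FRACTION = 0.065   # FWHM ~= 15 % of the cycle

#: Muscles dominating each of the four functional phases (generator truth):
#: weight acceptance (glutei + knee extensors), propulsion (plantar
#: flexors), early swing (foot dorsiflexors), late swing (knee flexors +
#: dorsiflexors).
PHASE_MUSCLE_GROUPS: tuple[tuple[str, ...], ...] = (
    ("ME", "MA", "RF", "VM", "VL"),
    ("PL", "GM", "GL", "SO"),
    ("TA", "FL"),
    ("ST", "BF", "TA"),
)

_CARRIER_BAND = (20.0, 450.0)     # Hz


@dataclass
class SyntheticGroundTruth:
    """Generating modules, primitive templates and trial-model parameters."""

    W_true: np.ndarray             # (m, r) nonnegative module weights
    H_true: np.ndarray             # (r, 200) unit-peak primitive templates
    noise_sd: float                # relative envelope noise
    cycle_model: dict[str, float]  # contact/swing mean and sd, ms
    seed: int | None = None

    def __post_init__(self) -> None:
        self.W_true = np.asarray(self.W_true, dtype=float)
        self.H_true = np.asarray(self.H_true, dtype=float)
        if np.any(self.W_true < 0) or np.any(self.H_true < 0):
            raise ValueError("ground-truth factors must be nonnegative")
        if self.W_true.shape[1] != self.H_true.shape[0]:
            raise ValueError("W_true and H_true rank mismatch")
        if self.W_true.shape[1] > self.W_true.shape[0]:
            raise ValueError("rank r cannot exceed the muscle count m")
        peaks = self.H_true.max(axis=1)
        if not np.allclose(peaks, 1.0):
            raise ValueError("primitive templates must peak at 1")

    @property
    def m(self) -> int:
        return self.W_true.shape[0]

    @property
    def r(self) -> int:
        return self.W_true.shape[1]


def make_ground_truth(m: int = 13, r: int = 4, seed: int | None = None,
                      noise_sd: float = 0.1,
                      cycle_model: dict[str, float] | None = None
                      ) -> SyntheticGroundTruth:
    """Draw a ground-truth synergy set of rank r for m muscles.

    Primitive bump centers are spread evenly so that for the default r = 4
    they fall in the middle of the four functional quadrants of the cycle
    (points 25, 75, 125, 175). For r = 4 and the 13-muscle set, each module
    weights its phase's muscle group (see :data:`PHASE_MUSCLE_GROUPS`) with
    random magnitudes in [0.6, 1.0] and the remaining muscles in
    [0.02, 0.15]; for other shapes a random disjoint muscle subset per
    synergy plays the major role.
    """
    if not 1 <= r <= m:
        raise ValueError(f"rank r={r} must satisfy 1 <= r <= m={m}")
    rng = np.random.default_rng(seed)
    ppc = 200
    centers = (np.arange(r) + 0.5) * ppc / r
    sigma = PRIMITIVE_SIGMA_FRACTION * ppc
    x = np.arange(ppc)
    H = np.exp(-((x[None, :] - centers[:, None]) ** 2) / (2 * sigma ** 2))
    H /= H.max(axis=1, keepdims=True)

    W = rng.uniform(0.02, 0.15, size=(m, r))
    if r == 4 and m == len(MUSCLES):
        groups = [[MUSCLES.index(name) for name in g] for g in PHASE_MUSCLE_GROUPS]
    else:
        order = rng.permutation(m)
        size = max(1, m // r)
        groups = [order[j * size:(j + 1) * size].tolist() or
                  [int(order[j % m])] for j in range(r)]
    for j, idx in enumerate(groups):
        W[idx, j] = rng.uniform(0.6, 1.0, size=len(idx))
    return SyntheticGroundTruth(W_true=W, H_true=H, noise_sd=noise_sd,
                                cycle_model=dict(cycle_model or CYCLE_MODEL_DEFAULT),
                                seed=seed)


def _draw_positive(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Truncated-normal draw: redraw until strictly positive."""
    while True:
        v = rng.normal(mean, sd)
        if v > 0:
            return v


def synthesize_trial(gt: SyntheticGroundTruth, n_cycles: int = 30,
                     fs: float = 1000.0, duration: float = 30.0,
                     participant_id: str = "P0001", trial_no: int = 1,
                     carrier: str = "bandlimited"
                     ) -> tuple[RawEmgTrial, CycleTimes, np.ndarray]:
    """Build one raw-EMG-like trial plus its cycle table and true envelope.

    Cycle durations are drawn from ``gt.cycle_model`` (truncated at zero and
    redrawn, never emitted nonpositive) until the recording duration is
    covered; the per-sample envelope is W_true times the per-cycle
    time-warped primitives, times multiplicative truncated-Gaussian noise of
    relative sd ``gt.noise_sd`` (clipped at 0). With ``carrier="bandlimited"``
    each raw channel is the envelope multiplied by an independent zero-mean
    band-limited (20-450 Hz) unit-RMS Gaussian carrier; ``carrier="constant"``
    uses 1 instead, so the rectified raw signal equals the envelope exactly.

    The returned cycle table lists ``n_cycles + 1`` rows so that exactly
    ``n_cycles`` complete cycles (including the last swing end) are defined.
    Returns ``(trial, cycle_times, envelope)`` with ``envelope`` the noisy
    modulating envelope on the (m, duration*fs) sample grid. Everything is
    reproducible from ``gt.seed``.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if carrier not in ("bandlimited", "constant"):
        raise ValueError(f"unknown carrier kind {carrier!r}")
    rng = np.random.default_rng(
        None if gt.seed is None else (gt.seed * 1000003 + trial_no) % 2**31)
    n_samples = int(round(duration * fs))
    cm = gt.cycle_model
    touchdowns = [0.0]
    stances = []
    while touchdowns[-1] < duration or len(stances) < n_cycles + 1:
        contact = _draw_positive(rng, cm["contact_mean"], cm["contact_sd"]) / 1e3
        swing = _draw_positive(rng, cm["swing_mean"], cm["swing_sd"]) / 1e3
        stances.append(contact)
        touchdowns.append(touchdowns[-1] + contact + swing)

    # map every sample to a position on the 200-point template axis:
    # stance -> [0, 100), swing -> [100, 200)
    t = np.arange(n_samples) / fs
    phase = np.empty(n_samples)
    td = np.asarray(touchdowns)
    idx = np.clip(np.searchsorted(td, t, side="right") - 1, 0, len(stances) - 1)
    t_in = t - td[idx]
    contact_k = np.asarray(stances)[idx]
    cycle_k = np.diff(td)[idx]
    in_stance = t_in < contact_k
    phase[in_stance] = 100.0 * t_in[in_stance] / contact_k[in_stance]
    sw = ~in_stance
    phase[sw] = 100.0 + 100.0 * (t_in[sw] - contact_k[sw]) / (cycle_k[sw] - contact_k[sw])
    phase = np.clip(phase, 0.0, 200.0 - 1e-9)

    xtpl = np.arange(200)
    h_warp = np.vstack([np.interp(phase, xtpl, row) for row in gt.H_true])
    envelope = gt.W_true @ h_warp
    if gt.noise_sd > 0:
        mult = np.clip(1.0 + gt.noise_sd * rng.standard_normal(envelope.shape),
                       0.0, None)
        envelope = envelope * mult

    if carrier == "constant":
        raw = envelope.copy()
    else:
        sos = signal.butter(2, _CARRIER_BAND, btype="bandpass", fs=fs,
                            output="sos")
        raw = np.empty_like(envelope)
        for i in range(envelope.shape[0]):
            c = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
            c /= np.sqrt(np.mean(c ** 2))
            raw[i] = envelope[i] * c

    data = pd.DataFrame({"time": t})
    for i, name in enumerate(MUSCLES[: gt.m]):
        data[name] = raw[i]
    trial = RawEmgTrial(data, participant_id, trial_no)
    ct = CycleTimes(td[: n_cycles + 1], np.asarray(stances)[: n_cycles + 1])
    return trial, ct, envelope


def make_metadata(n_participants: int, seed: int | None = None
                  ) -> list[ParticipantRecord]:
    """Draw a plausible participants table.

    Heights ~ N(175, 9) cm, masses ~ N(69, 11) kg, ages ~ N(30, 5) y,
    speeds ~ N(2.65, 0.31) m/s (all truncated to positive), sex M with the
    cohort's 78/135 proportion, speed type PR/FX equiprobable, and strike
    index beta-distributed with moments matched to mean 0.152, sd 0.195.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    rng = np.random.default_rng(seed)
    # Beta(a, b) with mean .152 and sd .195
    mu, var = 0.152, 0.195 ** 2
    k = mu * (1 - mu) / var - 1
    a, b = mu * k, (1 - mu) * k
    records = []
    for i in range(n_participants):
        si = float(np.clip(rng.beta(a, b), 1e-3, 1.0 - 1e-3))
        records.append(ParticipantRecord(
            code=f"P{i + 1:04d}",
            sex="M" if rng.random() < 78 / 135 else "F",
            speed=round(_draw_positive(rng, 2.65, 0.31), 2),
            speed_type="PR" if rng.random() < 0.5 else "FX",
            age=float(int(np.clip(rng.normal(30, 5), 18, 45))),
            height=round(_draw_positive(rng, 175, 9), 1),
            mass=round(_draw_positive(rng, 69, 11), 1),
            si=si,
        ))
    return records


def make_cop_trace(foot_length: float, si_true: float,
                   seed: int | None = None
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Foot geometry whose strike index is ``si_true`` by construction.

    Places a randomly positioned and oriented foot of the given length in
    the plane and puts the center of pressure at impact at ``si_true`` of
    the way from heel to toe, plus a small off-axis (mediolateral) offset
    that projection onto the foot axis removes. Returns (heel, toe, cop).
    """
    if foot_length <= 0:
        raise ValueError("foot_length must be positive")
    if not 0.0 <= si_true <= 1.0:
        raise ValueError("si_true must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    heel = rng.uniform(-1.0, 1.0, size=2)
    theta = rng.uniform(0, 2 * np.pi)
    u = np.array([np.cos(theta), np.sin(theta)])
    n_perp = np.array([-u[1], u[0]])
    toe = heel + foot_length * u
    lateral = rng.uniform(-0.05, 0.05) * foot_length
    cop = heel + si_true * foot_length * u + lateral * n_perp
    return heel, toe, cop


def match_synergies(W_est: np.ndarray, W_true: np.ndarray
                    ) -> tuple[list[int], np.ndarray]:
    """Greedy best-cosine pairing of estimated to true module columns.

    Factorizations are identifiable only up to permutation and positive
    scaling, so recovered synergies are compared after pairing each true
    column with its most-similar unclaimed estimated column (greedy on the
    cosine-similarity matrix; adequate for r <= 10). Returns the estimated
    column index matched to each true column and the matched cosines.
    """
    W_est = np.asarray(W_est, dtype=float)
    W_true = np.asarray(W_true, dtype=float)
    if W_est.shape != W_true.shape:
        raise ValueError("module matrices must have equal shapes")
    norm_e = np.linalg.norm(W_est, axis=0)
    norm_t = np.linalg.norm(W_true, axis=0)
    sim = (W_true.T @ W_est) / np.outer(np.maximum(norm_t, 1e-300),
                                        np.maximum(norm_e, 1e-300))
    r = sim.shape[0]
    perm = [-1] * r
    cos = np.zeros(r)
    pairs = sorted(((sim[i, j], i, j) for i in range(r) for j in range(r)),
                   reverse=True)
    used_t, used_e = set(), set()
    for s, i, j in pairs:
        if i not in used_t and j not in used_e:
            perm[i] = j
            cos[i] = s
            used_t.add(i)
            used_e.add(j)
    return perm, cos
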