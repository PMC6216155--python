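"""Readers and writers for the deposited-style ASCII file conventions.

The data set stores every artifact as a whitespace-delimited ASCII table
whose filename encodes its kind, participant and trial, e.g.
``RAW_EMG_P0026_02`` (raw EMG of participant 26, second trial),
``CYCLE_TIMES_P0026_02`` (gait-cycle breakdown), ``SYNS_H_P0026_02`` /
``SYNS_W_P0026_02`` (motor primitives / motor modules) and the cohort-wide
``participants_data.dat``.

On write this module emits tab-delimited tables with a header row and
9-significant-digit floats; on read any whitespace is accepted.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: The 13 recorded ipsilateral (right-side) lower-limb muscles, in the fixed
#: order used throughout: gluteus medius, gluteus maximus, tensor fasciae
#: latae, rectus femoris, vastus medialis, vastus lateralis, semitendinosus,
#: biceps femoris (long head), tibialis anterior, peroneus longus,
#: gastrocnemius medialis, gastrocnemius lateralis, soleus.
MUSCLES: tuple[str, ...] = (
    "ME", "MA", "FL", "RF", "VM", "VL", "ST",
    "BF", "TA", "PL", "GM", "GL", "SO",
)

#: Float serialization: 9 significant digits.
FLOAT_FMT = "%.9g"

_TRIAL_NAME_RE = re.compile(
    r"^(?P<prefix>[A-Z][A-Z_]*?)_(?P<participant>P\d{4})_(?P<trial>\d{2})$"
)


class FormatError(ValueError):
    """A file does not follow the expected column layout or naming."""


class ParseError(ValueError):
    """A cell could not be parsed as the expected type."""


class ValidationError(ValueError):
    """A parsed table violates a domain invariant."""


# ---------------------------------------------------------------------------
# Trial naming

def parse_trial_name(name: str) -> tuple[str, str, int]:
    """Split ``PREFIX_Pxxxx_yy`` into (prefix, participant_id, trial_no).

    ``name`` may carry a file extension, which is ignored.
    """
    stem = name.rsplit("/", 1)[-1]
    stem = stem.split(".", 1)[0]
    m = _TRIAL_NAME_RE.match(stem)
    if m is None:
        raise FormatError(
            f"file name {name!r} does not match the PREFIX_Pxxxx_yy convention"
        )
    return m["prefix"], m["participant"], int(m["trial"])


def make_trial_name(prefix: str, participant_id: str, trial_no: int) -> str:
    """Inverse of :func:`parse_trial_name` (no extension)."""
    if not re.fullmatch(r"P\d{4}", participant_id):
        raise FormatError(f"participant id {participant_id!r} is not like 'P0026'")
    return f"{prefix}_{participant_id}_{trial_no:02d}"


# ---------------------------------------------------------------------------
# Domain types

@dataclass
class RawEmgTrial:
    """One recorded trial: a time column plus 13 EMG channels at 1000 Hz.

    ``data`` holds 14 columns — ``time`` in seconds at 1 ms steps followed by
    the muscles in :data:`MUSCLES` order — and 30000 rows for a canonical
    30 s acquisition. Channel values are signed raw EMG in arbitrary units.
    """

    data: pd.DataFrame
    participant_id: str
    trial_no: int

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if cols[0] != "time":
            raise FormatError("first column must be 'time'")
        missing = [m for m in MUSCLES if m not in cols]
        if missing:
            raise FormatError(f"missing muscle column(s): {', '.join(missing)}")
        extra = [c for c in cols[1:] if c not in MUSCLES]
        if extra:
            raise FormatError(f"unexpected column(s): {', '.join(extra)}")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def channel_matrix(self) -> np.ndarray:
        """Channels as an (13, n_samples) array in :data:`MUSCLES` order."""
        return self.data.loc[:, list(MUSCLES)].to_numpy().T

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy()


@dataclass
class CycleTimes:
    """Per-gait-cycle touchdown instants and stance durations, in seconds.

    A table of k rows defines k-1 *complete* cycles: the swing phase of the
    last listed cycle ends at a touchdown that is not in the table.
    """

    touchdown: np.ndarray
    stance_duration: np.ndarray

    def __post_init__(self) -> None:
        self.touchdown = np.asarray(self.touchdown, dtype=float)
        self.stance_duration = np.asarray(self.stance_duration, dtype=float)
        if self.touchdown.shape != self.stance_duration.shape or self.touchdown.ndim != 1:
            raise ValidationError("touchdown and stance_duration must be equal-length 1-D")
        if np.any(np.diff(self.touchdown) <= 0):
            raise ValidationError("touchdown times must be strictly increasing")
        if np.any(self.stance_duration <= 0):
            raise ValidationError("stance durations must be positive")
        cycle = np.diff(self.touchdown)
        if np.any(self.stance_duration[:-1] >= cycle):
            k = int(np.nonzero(self.stance_duration[:-1] >= cycle)[0][0])
            raise ValidationError(
                f"stance duration of cycle {k} is not shorter than the cycle itself"
            )

    @property
    def n_cycles(self) -> int:
        """Number of listed cycles (rows)."""
        return len(self.touchdown)

    @property
    def n_complete_cycles(self) -> int:
        """Number of cycles whose swing end (next touchdown) is known."""
        return max(len(self.touchdown) - 1, 0)


@dataclass
class ParticipantRecord:
    """One row of the participants metadata table.

    ``si`` is the strike index — heel-to-center-of-pressure distance at
    impact over foot length, in [0, 1] — and may be missing (None); in the
    cohort it was unavailable for participants P0015 through P0032.
    """

    code: str
    sex: str
    speed: float          # m/s
    speed_type: str       # "PR" preferred / "FX" fixed
    age: float            # years
    height: float         # cm
    mass: float           # kg
    si: float | None = None

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValidationError(f"{self.code}: speed must be positive")
        if self.si is not None and not (0.0 <= self.si <= 1.0):
            raise ValidationError(
                f"{self.code}: strike index {self.si} outside [0, 1]"
            )


# ---------------------------------------------------------------------------
# Raw EMG files

def read_raw_emg(path: str | Path) -> RawEmgTrial:
    """Read a ``RAW_EMG_Pxxxx_yy`` file (header row + 14 columns)."""
    path = Path(path)
    _, participant, trial = parse_trial_name(path.name)
    df = pd.read_csv(path, sep=r"\s+")
    cols = list(df.columns)
    if cols and cols[0] != "time":
        # deposited files name the first column arbitrarily; it is the time axis
        df = df.rename(columns={cols[0]: "time"})
        cols = list(df.columns)
    missing = [m for m in MUSCLES if m not in cols]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {', '.join(missing)}")
    extra = [c for c in cols if c != "time" and c not in MUSCLES]
    if extra:
        raise FormatError(f"{path.name}: unexpected column(s) {', '.join(extra)}")
    for c in cols:
        if not pd.api.types.is_numeric_dtype(df[c]):
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()]
            row = int(bad[0]) if len(bad) else -1
            raise ParseError(f"{path.name}: non-numeric value in column {c!r}, row {row}")
    return RawEmgTrial(df.loc[:, ["time", *MUSCLES]], participant, trial)


def write_raw_emg(trial: RawEmgTrial, directory: str | Path) -> Path:
    directory = Path(directory)
    name = make_trial_name("RAW_EMG", trial.participant_id, trial.trial_no)
    path = directory / f"{name}.dat"
    trial.data.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# Cycle-times files

def read_cycle_times(path: str | Path) -> CycleTimes:
    """Read a ``CYCLE_TIMES_Pxxxx_yy`` file: touchdown + stance columns."""
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    # tolerate a header row of labels
    if not pd.api.types.is_numeric_dtype(df.iloc[:, 0]):
        df = pd.read_csv(path, sep=r"\s+", comment="#")
    if df.shape[1] != 2:
        raise FormatError(f"{path.name}: expected 2 columns, found {df.shape[1]}")
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy()
    if np.isnan(arr).any():
        r, c = map(int, np.argwhere(np.isnan(arr))[0])
        raise ParseError(f"{path.name}: non-numeric value at row {r}, column {c}")
    return CycleTimes(arr[:, 0], arr[:, 1])


def write_cycle_times(ct: CycleTimes, directory: str | Path,
                      participant_id: str, trial_no: int) -> Path:
    directory = Path(directory)
    name = make_trial_name("CYCLE_TIMES", participant_id, trial_no)
    path = directory / f"{name}.dat"
    df = pd.DataFrame({"touchdown": ct.touchdown, "stance": ct.stance_duration})
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# Participants metadata

_PARTICIPANT_COLUMNS = ["Code", "Sex", "Speed", "Type", "Age", "Height", "Mass", "SI"]


def read_participants(path: str | Path) -> list[ParticipantRecord]:
    """Read ``participants_data.dat``; missing SI ('' or 'NA') is tolerated."""
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"], keep_default_na=True)
    missing = [c for c in _PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {', '.join(missing)}")
    records = []
    for _, row in df.iterrows():
        si = row["SI"]
        si = None if (si is None or (isinstance(si, float) and math.isnan(si))) else float(si)
        records.append(ParticipantRecord(
            code=str(row["Code"]), sex=str(row["Sex"]), speed=float(row["Speed"]),
            speed_type=str(row["Type"]), age=float(row["Age"]),
            height=float(row["Height"]), mass=float(row["Mass"]), si=si,
        ))
    return records


def write_participants(records: Sequence[ParticipantRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [(r.code, r.sex, r.speed, r.speed_type, r.age, r.height, r.mass,
          "NA" if r.si is None else FLOAT_FMT % r.si) for r in records],
        columns=_PARTICIPANT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# Synergy files (motor primitives H, motor modules W)

def write_synergies(syn, directory: str | Path, trial_id: str) -> tuple[Path, Path]:
    """Write a factorization result as SYNS_H_* / SYNS_W_* files.

    The primitives file has r rows named Syn1..Synr and n columns (one per
    time-normalized point); the modules file has 13 muscle-named rows and r
    synergy-named columns. ``trial_id`` is e.g. ``"P0026_02"``.
    ``syn`` needs ``W`` (m x r) and ``H`` (r x n) attributes.
    """
    directory = Path(directory)
    W = np.asarray(syn.W, dtype=float)
    H = np.asarray(syn.H, dtype=float)
    r = H.shape[0]
    if W.shape != (len(MUSCLES), r):
        raise FormatError(
            f"modules matrix has shape {W.shape}, expected ({len(MUSCLES)}, {r})"
        )
    syn_names = [f"Syn{i + 1}" for i in range(r)]
    h_path = directory / f"SYNS_H_{trial_id}.dat"
    w_path = directory / f"SYNS_W_{trial_id}.dat"
    h_df = pd.DataFrame(H, index=syn_names,
                        columns=[f"t{j + 1}" for j in range(H.shape[1])])
    h_df.to_csv(h_path, sep="\t", float_format=FLOAT_FMT, index_label="Syn")
    w_df = pd.DataFrame(W, index=list(MUSCLES), columns=syn_names)
    w_df.to_csv(w_path, sep="\t", float_format=FLOAT_FMT, index_label="Muscle")
    return h_path, w_path


def read_synergies(h_path: str | Path, w_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read back (W, H) written by :func:`write_synergies`."""
    h_df = pd.read_csv(h_path, sep=r"\s+", index_col=0)
    w_df = pd.read_csv(w_path, sep=r"\s+", index_col=0)
    if list(w_df.index) != list(MUSCLES):
        raise FormatError(f"{Path(w_path).name}: module rows are not the 13 muscles")
    return w_df.to_numpy(dtype=float), h_df.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Filtered (conditioned, time-normalized) EMG files

def write_filt_emg(values: np.ndarray, directory: str | Path,
                   participant_id: str, trial_no: int) -> Path:
    """Write a conditioned activation matrix (13 x n) as a FILT_EMG_* file.

    Stored with time-normalized points as rows and muscle-named columns.
    """
    directory = Path(directory)
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(MUSCLES):
        raise FormatError(f"expected {len(MUSCLES)} muscle rows, got {values.shape[0]}")
    name = make_trial_name("FILT_EMG", participant_id, trial_no)
    path = directory / f"{name}.dat"
    pd.DataFrame(values.T, columns=list(MUSCLES)).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def read_filt_emg(path: str | Path) -> np.ndarray:
    """Read a FILT_EMG_* file back to a (13, n) array."""
    df = pd.read_csv(path, sep=r"\s+")
    missing = [m for m in MUSCLES if m not in df.columns]
    if missing:
        raise FormatError(f"{Path(path).name}: missing column(s) {', '.join(missing)}")
    return df.loc[:, list(MUSCLES)].to_numpy(dtype=float).T
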