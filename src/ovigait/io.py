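"""Reading and writing force-platform recordings, session manifests and tidy tables.

File dialect
------------
A recording is a two-column UTF-8 CSV with header ``time_s,force_N`` holding one
uniformly sampled vertical ground-reaction-force trace (compressive load positive,
newtons).  The time column may be omitted, in which case the sampling rate must be
supplied (the reference platform samples at 50 Hz).  A session manifest is a CSV with
one row per acquisition file::

    file,animal_id,limb,day_postop,body_weight_kg,session_id,group

Limb labels follow the operated-side convention used in quadruped lameness studies:
``IH``/``IF`` ipsilateral (operated-side) hind/fore limb, ``CH``/``CF`` contralateral
hind/fore limb.  Control animals keep the same labels with ``group = "control"``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Closed set of limb labels.
LIMBS = ("IH", "IF", "CH", "CF")
#: Study arm of an animal.
GROUPS = ("operated", "control")
#: Default acquisition rate of the reference pressure platform (Hz).
DEFAULT_SAMPLING_RATE = 50.0

#: Maximum relative deviation of a time step from the median step before the
#: grid is rejected as irregular.
_MAX_STEP_DEVIATION = 0.01


@dataclass(frozen=True)
class ForceRecording:
    """One platform acquisition: a vertical GRF trace plus session metadata.

    Forces are in newtons, sampled uniformly at ``sampling_rate`` Hz.
    ``day_postop`` is days since surgery (for control animals it is simply the
    measurement day of the session).
    """

    forces: np.ndarray
    sampling_rate: float
    animal_id: str
    limb: str
    day_postop: int
    body_weight: float
    session_id: str
    group: str = "operated"

    def __post_init__(self) -> None:
        forces = np.asarray(self.forces, dtype=float)
        object.__setattr__(self, "forces", forces)
        if forces.ndim != 1 or forces.size < 2:
            raise ValidationError("a recording needs at least 2 samples")
        if not np.all(np.isfinite(forces)):
            raise ValidationError("force trace contains non-finite values")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be positive")
        if self.limb not in LIMBS:
            raise ValidationError(f"limb must be one of {LIMBS}, got {self.limb!r}")
        if not self.body_weight > 0:
            raise ValidationError("body_weight must be positive (kg)")
        if self.day_postop < 0:
            raise ValidationError("day_postop must be >= 0")
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def n_samples(self) -> int:
        return int(self.forces.size)

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds (first sample at t = 0)."""
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class ManifestEntry:
    """One manifest row tying an acquisition file to its session metadata."""

    file: str
    animal_id: str
    limb: str
    day_postop: int
    body_weight: float
    session_id: str
    group: str = "operated"

    def __post_init__(self) -> None:
        if self.limb not in LIMBS:
            raise ValidationError(f"limb must be one of {LIMBS}, got {self.limb!r}")
        if not self.body_weight > 0:
            raise ValidationError(
                f"body_weight must be positive, got {self.body_weight} "
                f"for {self.animal_id}/{self.session_id}"
            )
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}")


_MANIFEST_COLUMNS = [
    "file",
    "animal_id",
    "limb",
    "day_postop",
    "body_weight_kg",
    "session_id",
    "group",
]


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read a session manifest CSV and validate its schema and uniqueness."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"animal_id": str, "session_id": str})
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns and c != "group"]
    if missing:
        raise FormatError(f"manifest {path} is missing columns {missing}")
    if "group" not in df.columns:
        df["group"] = "operated"
    entries = [
        ManifestEntry(
            file=str(row.file),
            animal_id=str(row.animal_id),
            limb=str(row.limb),
            day_postop=int(row.day_postop),
            body_weight=float(row.body_weight_kg),
            session_id=str(row.session_id),
            group=str(row.group),
        )
        for row in df.itertuples()
    ]
    keys = [(e.animal_id, e.session_id, e.limb) for e in entries]
    if len(set(keys)) != len(keys):
        raise ValidationError("manifest has duplicate (animal_id, session_id, limb) keys")
    return entries


def write_manifest(entries: Sequence[ManifestEntry], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "file": e.file,
                "animal_id": e.animal_id,
                "limb": e.limb,
                "day_postop": e.day_postop,
                "body_weight_kg": e.body_weight,
                "session_id": e.session_id,
                "group": e.group,
            }
            for e in entries
        ],
        columns=_MANIFEST_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_force_recording(
    path: str | Path,
    manifest_entry: ManifestEntry | None = None,
    sampling_rate: float | None = None,
    **metadata,
) -> ForceRecording:
    """Read a recording CSV, inferring the sampling rate from the time column.

    The sampling rate is ``1 / median(dt)``; any step deviating from the median by
    more than 1% rejects the file as irregular, naming the first offending row.
    If the file has no time column, ``sampling_rate`` (or the platform default of
    50 Hz) is used.  Session metadata comes from ``manifest_entry`` or keyword
    overrides.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "force_N" not in df.columns:
        raise FormatError(f"{path}: expected a 'force_N' column, found {list(df.columns)}")
    forces = df["force_N"].to_numpy(dtype=float)

    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        # a bad step dt[i] implicates its second timestamp: data row i+1,
        # file row i+3 (header line + 1-based numbering)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 3
            raise FormatError(f"{path}: time not strictly increasing at row {row}")
        step = float(np.median(dt))
        dev = np.abs(dt - step) / step
        if np.any(dev > _MAX_STEP_DEVIATION):
            row = int(np.argmax(dev > _MAX_STEP_DEVIATION)) + 3
            raise FormatError(
                f"{path}: irregular sampling at row {row} "
                f"(step deviates >{_MAX_STEP_DEVIATION:.0%} from median {step:g} s)"
            )
        fs = 1.0 / step
    else:
        fs = sampling_rate if sampling_rate is not None else DEFAULT_SAMPLING_RATE

    meta = {}
    if manifest_entry is not None:
        meta = {
            "animal_id": manifest_entry.animal_id,
            "limb": manifest_entry.limb,
            "day_postop": manifest_entry.day_postop,
            "body_weight": manifest_entry.body_weight,
            "session_id": manifest_entry.session_id,
            "group": manifest_entry.group,
        }
    meta.update(metadata)
    return ForceRecording(forces=forces, sampling_rate=fs, **meta)


def write_force_recording(recording: ForceRecording, path: str | Path) -> None:
    """Write a recording as a two-column time/force CSV (value round-trip exact)."""
    df = pd.DataFrame({"time_s": recording.time, "force_N": recording.forces})
    # 17 significant digits: float64 values survive the text round trip exactly
    df.to_csv(path, index=False, float_format="%.17g")


def write_tidy_table(records: "pd.DataFrame | Iterable", path: str | Path) -> None:
    """Write a homogeneous result collection as a tidy CSV.

    Accepts a DataFrame or an iterable of dataclass instances / mappings.  The
    column order of the first record is kept, so identical input yields
    byte-identical output.  An empty collection is an error rather than an empty
    file.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        for rec in records:
            if dataclasses.is_dataclass(rec):
                rows.append(dataclasses.asdict(rec))
            else:
                rows.append(dict(rec))
        df = pd.DataFrame(rows)
    if df.empty:
        raise ValidationError("refusing to write an empty result table")
    df.to_csv(path, index=False)
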