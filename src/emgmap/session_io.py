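"""Protocol-aware multichannel sEMG session model and CSV interchange.

A *session* is one participant's set of labeled, fixed-rate multichannel
segments following the two-paddle compression protocol: three rest controls
(``C1``, ``C2``, ``C3``) and eight 15-second compressions (four views per
paddle).  Sessions are serialized to plain CSV in either a *long* layout
(one sample per row) or a *wide* layout (one column per channel), both
carrying the sampling rate in a ``# fs_hz=`` header line.
"""

from __future__ import annotations

import enum
import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Muscle",
    "Side",
    "ChannelId",
    "ALL_CHANNELS",
    "SegmentLabel",
    "SegmentRole",
    "segment_role",
    "Segment",
    "Session",
    "Cohort",
    "ValidationError",
    "read_session",
    "write_session",
    "read_cohort",
    "write_cohort",
    "CONTROL_LABELS",
    "COMPRESSION_LABELS",
    "DEFAULT_FS_HZ",
    "NOMINAL_CONTROL_S",
    "NOMINAL_COMPRESSION_S",
]

#: Vendor-default sampling rate; stored per session, never hard-coded downstream.
DEFAULT_FS_HZ = 1925.925

NOMINAL_CONTROL_S = 120.0
NOMINAL_COMPRESSION_S = 15.0
#: Hard floor for compression duration: edge trimming needs >= 3 s of margin.
MIN_COMPRESSION_S = 5.0
DURATION_TOLERANCE = 0.10


class ValidationError(ValueError):
    """A session violates a structural invariant of the protocol."""


class Muscle(str, enum.Enum):
    STERNOCLEIDOMASTOID = "sternocleidomastoid"
    TRAPEZIUS_UPPER = "trapezius_upper"
    DELTOID = "deltoid"
    INFRASPINATUS = "infraspinatus"
    TERES_MAJOR = "teres_major"
    SERRATUS_ANTERIOR = "serratus_anterior"
    EXTERNAL_OBLIQUE = "external_oblique"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True, order=True)
class ChannelId:
    """One recorded muscle: a (muscle, body side) pair, e.g. ``deltoid_left``."""

    muscle: Muscle
    side: Side

    def __str__(self) -> str:
        return f"{self.muscle.value}_{self.side.value}"

    @classmethod
    def parse(cls, text: str) -> "ChannelId":
        stem, _, side = text.rpartition("_")
        try:
            return cls(Muscle(stem), Side(side))
        except ValueError:
            raise ValidationError(f"unknown channel id: {text!r}") from None


#: Canonical channel order: the 7 muscles in anatomical listing order, left then right.
ALL_CHANNELS: tuple[ChannelId, ...] = tuple(
    ChannelId(m, s) for m in Muscle for s in Side
)
assert len(ALL_CHANNELS) == 14
_CHANNEL_RANK = {c: i for i, c in enumerate(ALL_CHANNELS)}


class SegmentLabel(str, enum.Enum):
    C1 = "C1"
    C2 = "C2"
    F_RCC = "F_RCC"
    F_LCC = "F_LCC"
    F_LMLO = "F_LMLO"
    F_RMLO = "F_RMLO"
    C3 = "C3"
    C_RCC = "C_RCC"
    C_LCC = "C_LCC"
    C_LMLO = "C_LMLO"
    C_RMLO = "C_RMLO"


CONTROL_LABELS = (SegmentLabel.C1, SegmentLabel.C2, SegmentLabel.C3)
COMPRESSION_LABELS = tuple(
    lab for lab in SegmentLabel if lab not in CONTROL_LABELS
)


@dataclass(frozen=True)
class SegmentRole:
    """Decomposition of a segment label into protocol semantics."""

    kind: str                       # "control" | "compression"
    paddle: str | None              # "F" | "C" | None
    side: str | None                # "L" | "R" | None
    view: str | None                # "CC" | "MLO" | None
    reference_control: SegmentLabel


def segment_role(label: SegmentLabel) -> SegmentRole:
    """Classify a label and name the control segment it is normalized against.

    Flat-paddle compressions reference ``C2``, curved-paddle compressions
    reference ``C3``; controls reference themselves.  (Normalization
    additionally substitutes C2's scale for C1 so the two rest states stay
    comparable; that is a preprocessing rule, not part of the role.)
    """
    label = SegmentLabel(label)
    if label in CONTROL_LABELS:
        return SegmentRole("control", None, None, None, label)
    paddle, _, rest = label.value.partition("_")
    side, view = rest[0], rest[1:]
    ref = SegmentLabel.C2 if paddle == "F" else SegmentLabel.C3
    return SegmentRole("compression", paddle, side, view, ref)


@dataclass
class Segment:
    """A labeled block of samples, shaped ``(n_channels, n_samples)``, in mV."""

    label: SegmentLabel
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.label = SegmentLabel(self.label)
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValidationError(
                f"segment {self.label.value}: samples must be 2-D "
                f"(channels x time), got shape {self.samples.shape}"
            )
        if not self.fs > 0:
            raise ValidationError(f"segment {self.label.value}: fs must be > 0")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Segment":
        return Segment(self.label, self.samples.copy(), self.fs)


@dataclass
class Session:
    """One participant's ordered map of protocol segments."""

    participant_id: str
    segments: dict[SegmentLabel, Segment]
    channel_order: tuple[ChannelId, ...]

    def __post_init__(self) -> None:
        self.channel_order = tuple(self.channel_order)

    @property
    def fs(self) -> float:
        return next(iter(self.segments.values())).fs

    def validate(
        self,
        nominal_control_s: float = NOMINAL_CONTROL_S,
        nominal_compression_s: float = NOMINAL_COMPRESSION_S,
        check_durations: bool = True,
        require_reference_controls: bool = True,
    ) -> "Session":
        """Check structural invariants; returns self so calls can be chained.

        Duration deviations beyond +/-10% of nominal warn; compressions
        shorter than 5 s are a hard error because edge trimming would leave
        too little signal.
        """
        if not self.segments:
            raise ValidationError("session has no segments")
        if len(set(self.channel_order)) != len(self.channel_order):
            raise ValidationError("duplicate channels in channel_order")
        n_ch = len(self.channel_order)
        fs0 = self.fs
        for lab, seg in self.segments.items():
            if SegmentLabel(lab) is not seg.label:
                raise ValidationError(f"segment keyed {lab} carries label {seg.label}")
            if seg.n_channels != n_ch:
                raise ValidationError(
                    f"segment {seg.label.value}: {seg.n_channels} channels, "
                    f"expected {n_ch}"
                )
            if seg.fs != fs0:
                raise ValidationError(
                    f"segment {seg.label.value}: fs {seg.fs} != session fs {fs0}"
                )
            role = segment_role(seg.label)
            if role.kind == "compression" and seg.duration_s < MIN_COMPRESSION_S:
                raise ValidationError(
                    f"segment {seg.label.value}: {seg.duration_s:.2f} s is below "
                    f"the {MIN_COMPRESSION_S:.0f} s minimum for compressions"
                )
            if check_durations:
                nominal = (
                    nominal_control_s if role.kind == "control" else nominal_compression_s
                )
                if abs(seg.duration_s - nominal) > DURATION_TOLERANCE * nominal:
                    warnings.warn(
                        f"segment {seg.label.value}: duration {seg.duration_s:.2f} s "
                        f"deviates >10% from nominal {nominal:.0f} s",
                        stacklevel=2,
                    )
        present = set(self.segments)
        if not require_reference_controls:
            return self
        if any(segment_role(l).paddle == "F" for l in present) and (
            SegmentLabel.C2 not in present
        ):
            raise ValidationError("missing reference control C2 for flat-paddle segments")
        if any(segment_role(l).paddle == "C" for l in present) and (
            SegmentLabel.C3 not in present
        ):
            raise ValidationError("missing reference control C3 for curved-paddle segments")
        return self

    def copy(self) -> "Session":
        return Session(
            self.participant_id,
            {lab: seg.copy() for lab, seg in self.segments.items()},
            self.channel_order,
        )


@dataclass
class Cohort:
    sessions: list[Session]

    def __post_init__(self) -> None:
        ids = [s.participant_id for s in self.sessions]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate participant_ids in cohort")
        orders = {s.channel_order for s in self.sessions}
        if len(orders) > 1:
            raise ValidationError("sessions do not share a channel order")

    def __len__(self) -> int:
        return len(self.sessions)

    def __iter__(self):
        return iter(self.sessions)


# ---------------------------------------------------------------------------
# CSV interchange


def _sort_channels(channels: Iterable[ChannelId]) -> tuple[ChannelId, ...]:
    return tuple(sorted(channels, key=lambda c: _CHANNEL_RANK[c]))


def write_session(session: Session, path, dialect: str = "long") -> None:
    """Write a session to CSV; ``read_session`` round-trips it bit-exactly."""
    if not session.segments:
        raise ValidationError("session has no segments")
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    ch_names = [str(c) for c in session.channel_order]

    def fmt(col: np.ndarray) -> list[str]:
        # repr gives shortest round-trip decimal: read(write(s)) is bit-exact
        return [repr(float(v)) for v in col]

    frames = []
    for seg in session.segments.values():
        if dialect == "long":
            n = seg.n_samples
            for ci, name in enumerate(ch_names):
                frames.append(
                    pd.DataFrame(
                        {
                            "participant_id": session.participant_id,
                            "segment_label": seg.label.value,
                            "channel": name,
                            "sample_index": np.arange(n),
                            "value_mv": fmt(seg.samples[ci]),
                        }
                    )
                )
        else:
            df = pd.DataFrame(
                {
                    "participant_id": session.participant_id,
                    "segment_label": seg.label.value,
                    "sample_index": np.arange(seg.n_samples),
                }
            )
            for ci, name in enumerate(ch_names):
                df[name] = fmt(seg.samples[ci])
            frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# fs_hz={session.fs!r}\n")
        out.to_csv(fh, index=False)


def read_session(path, schema: Mapping | None = None) -> Session:
    """Read a long- or wide-dialect session CSV and validate it.

    ``schema`` may supply ``fs_hz`` (overriding the file header), nominal
    durations, and ``check_durations``.
    """
    schema = dict(schema or {})
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        fs = None
        if first.startswith("# fs_hz="):
            fs = float(first.split("=", 1)[1])
            df = pd.read_csv(fh, float_precision="round_trip")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, float_precision="round_trip")
    fs = float(schema.get("fs_hz", fs) or 0)
    if not fs:
        raise ValidationError(f"{path}: no fs_hz header line and none in schema")

    cols = set(df.columns)
    if {"channel", "value_mv"} <= cols:
        session = _session_from_long(df, fs)
    elif "segment_label" in cols:
        session = _session_from_wide(df, fs)
    else:
        raise ValidationError(f"{path}: unrecognized CSV layout (columns {sorted(cols)})")
    return session.validate(
        nominal_control_s=schema.get("nominal_control_s", NOMINAL_CONTROL_S),
        nominal_compression_s=schema.get("nominal_compression_s", NOMINAL_COMPRESSION_S),
        check_durations=schema.get("check_durations", True),
        require_reference_controls=schema.get("require_reference_controls", True),
    )


def _session_from_long(df: pd.DataFrame, fs: float) -> Session:
    pid = str(df["participant_id"].iloc[0])
    channels = _sort_channels({ChannelId.parse(c) for c in df["channel"].unique()})
    ch_names = [str(c) for c in channels]
    seg_order = list(dict.fromkeys(df["segment_label"]))
    segments: dict[SegmentLabel, Segment] = {}
    for lab_str in seg_order:
        try:
            lab = SegmentLabel(lab_str)
        except ValueError:
            raise ValidationError(f"unknown segment label {lab_str!r}") from None
        sub = df[df["segment_label"] == lab_str]
        lengths = sub.groupby("channel", sort=False)["value_mv"].size()
        if lengths.nunique() > 1:
            bad = lengths.idxmin()
            raise ValidationError(
                f"segment {lab_str}: ragged channel lengths (channel {bad})"
            )
        n = int(lengths.iloc[0])
        mat = np.empty((len(channels), n))
        for ci, name in enumerate(ch_names):
            rows = sub[sub["channel"] == name].sort_values("sample_index")
            if len(rows) != n:
                raise ValidationError(
                    f"segment {lab_str}: ragged channel lengths (channel {name})"
                )
            mat[ci] = rows["value_mv"].to_numpy()
        segments[lab] = Segment(lab, mat, fs)
    return Session(pid, segments, channels)


def _session_from_wide(df: pd.DataFrame, fs: float) -> Session:
    pid = str(df["participant_id"].iloc[0]) if "participant_id" in df else "unknown"
    meta = {"participant_id", "segment_label", "sample_index"}
    ch_cols = [c for c in df.columns if c not in meta]
    channels = _sort_channels({ChannelId.parse(c) for c in ch_cols})
    seg_order = list(dict.fromkeys(df["segment_label"]))
    segments: dict[SegmentLabel, Segment] = {}
    for lab_str in seg_order:
        try:
            lab = SegmentLabel(lab_str)
        except ValueError:
            raise ValidationError(f"unknown segment label {lab_str!r}") from None
        sub = df[df["segment_label"] == lab_str]
        if "sample_index" in sub:
            sub = sub.sort_values("sample_index")
        mat = np.stack([sub[str(c)].to_numpy(dtype=np.float64) for c in channels])
        segments[lab] = Segment(lab, mat, fs)
    return Session(pid, segments, channels)


def write_cohort(cohort: Cohort, directory, dialect: str = "long") -> list[Path]:
    """One CSV per participant under ``directory``; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for session in cohort:
        p = directory / f"{session.participant_id}.csv"
        write_session(session, p, dialect=dialect)
        paths.append(p)
    return paths


def read_cohort(directory, schema: Mapping | None = None) -> Cohort:
    directory = Path(directory)
    paths = sorted(directory.glob("*.csv"))
    if not paths:
        raise ValidationError(f"no session CSVs found in {directory}")
    return Cohort([read_session(p, schema) for p in paths])
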