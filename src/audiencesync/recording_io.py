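"""Data model and tabular IO for audience facial-expression recordings.

An :class:`AudienceRecording` bundles everything one performance produced:
per-participant expression-intensity tracks (8 channels per video frame, each
value in [0, 1]), the seat map of the auditorium, and participant metadata
(age, gender, empathy questionnaire total).  Frames where the automated
expression classifier failed to fit a face model are *missing as a whole* —
if any channel is absent for a frame, the frame is invalid and none of its
channel values are used downstream.

Three plain-CSV formats are defined (one file each per performance):

* expression table: ``participant_id,frame_index,<8 channel columns>``,
  long format, 0-based contiguous ``frame_index`` per participant, empty
  cells marking missing values;
* seat/metadata table: ``participant_id,row,seat,age,gender,empathy_total,
  empathy_scale,questionnaires_complete``;
* engagement script: ``start_s,end_s,score`` with contiguous whole-second
  scenes scored on a 1-3 Likert scale.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Fixed channel order of the expression classifier's output.
CHANNELS: tuple[str, ...] = (
    "neutral", "happy", "sad", "angry",
    "surprise", "fear", "disgust", "contempt",
)

N_CHANNELS = len(CHANNELS)

#: Empathy questionnaire total-score ranges (inclusive).
EMPATHY_SCALES: dict[str, tuple[float, float]] = {
    "EQ-short": (0.0, 44.0),
    "QCAE": (4.0, 124.0),
}

GENDERS = ("female", "male", "other")


class ValidationError(ValueError):
    """Raised when an input table violates the format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTrack:
    """One participant's per-frame 8-channel expression-intensity series.

    ``intensities`` is a ``(n_frames, 8)`` float array with NaN at missing
    entries; ``valid_mask[t]`` is True iff all 8 channels are present at
    frame ``t``.  Missingness is frame-atomic: a frame with any missing
    channel has every channel treated as missing.
    """

    participant_id: str
    frame_rate: float
    intensities: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.shape[1] != N_CHANNELS:
            raise ValidationError(
                f"intensities must be (frames, {N_CHANNELS}); "
                f"got {self.intensities.shape}"
            )
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        mask = ~np.isnan(self.intensities).any(axis=1)
        # frame-atomic missingness: blank out partially missing frames
        self.intensities = self.intensities.copy()
        self.intensities[~mask] = np.nan
        if self.valid_mask is None:
            self.valid_mask = mask
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool) & mask
            self.intensities[~self.valid_mask] = np.nan
        finite = self.intensities[self.valid_mask]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValidationError(
                f"track {self.participant_id!r}: intensity outside [0, 1]"
            )

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's series (NaN at invalid frames)."""
        try:
            j = CHANNELS.index(name)
        except ValueError:
            raise KeyError(f"unknown expression channel {name!r}") from None
        return self.intensities[:, j]


@dataclass
class ParticipantInfo:
    """Questionnaire metadata for one participant."""

    age: float | None = None
    gender: str = "other"
    empathy_total: float | None = None
    empathy_scale: str = "EQ-short"
    questionnaires_complete: bool = False

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValidationError(f"gender must be one of {GENDERS}")
        if self.empathy_scale not in EMPATHY_SCALES:
            raise ValidationError(
                f"empathy_scale must be one of {tuple(EMPATHY_SCALES)}"
            )
        if self.age is not None and not math.isnan(self.age) and self.age < 0:
            raise ValidationError("age must be non-negative")
        if self.empathy_total is not None and not math.isnan(self.empathy_total):
            lo, hi = EMPATHY_SCALES[self.empathy_scale]
            if not lo <= self.empathy_total <= hi:
                raise ValidationError(
                    f"empathy_total {self.empathy_total} outside "
                    f"{self.empathy_scale} range [{lo}, {hi}]"
                )


@dataclass
class AudienceRecording:
    """All tracks of one performance plus seat map and metadata."""

    performance_id: str
    tracks: list[ExpressionTrack]
    seat_map: dict[str, tuple[int, int]]
    info: dict[str, ParticipantInfo] = field(default_factory=dict)

    @property
    def participant_ids(self) -> list[str]:
        return [t.participant_id for t in self.tracks]

    @property
    def n_frames(self) -> int:
        return self.tracks[0].n_frames if self.tracks else 0

    @property
    def frame_rate(self) -> float:
        return self.tracks[0].frame_rate if self.tracks else 50.0

    def track(self, participant_id: str) -> ExpressionTrack:
        for t in self.tracks:
            if t.participant_id == participant_id:
                return t
        raise KeyError(participant_id)

    def subset(self, keep: Sequence[str]) -> "AudienceRecording":
        """New recording restricted to ``keep`` (track order preserved)."""
        keep_set = set(keep)
        return AudienceRecording(
            performance_id=self.performance_id,
            tracks=[t for t in self.tracks if t.participant_id in keep_set],
            seat_map={p: s for p, s in self.seat_map.items() if p in keep_set},
            info={p: i for p, i in self.info.items() if p in keep_set},
        )


@dataclass
class EngagementScript:
    """Ordered contiguous scenes with second-resolution boundaries.

    Each scene is ``(start_s, end_s, score)`` with score in {1, 2, 3};
    the first scene starts at 0 and scenes tile [0, duration) exactly.
    """

    scenes: list[tuple[float, float, int]]

    def __post_init__(self) -> None:
        if not self.scenes:
            raise ValidationError("script needs at least one scene")
        prev_end = 0.0
        for k, (start, end, score) in enumerate(self.scenes):
            if score not in (1, 2, 3):
                raise ValidationError(f"scene {k}: score {score} not in {{1,2,3}}")
            if start != prev_end:
                kind = "gap" if start > prev_end else "overlap"
                raise ValidationError(
                    f"scene {k}: {kind} between {prev_end} s and {start} s"
                )
            if end <= start:
                raise ValidationError(f"scene {k}: end {end} <= start {start}")
            prev_end = end

    @property
    def duration_s(self) -> float:
        return self.scenes[-1][1]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_EXPR_HEADER = ["participant_id", "frame_index", *CHANNELS]
_META_HEADER = [
    "participant_id", "row", "seat", "age", "gender",
    "empathy_total", "empathy_scale", "questionnaires_complete",
]


def read_expression_table(
    stream: IO[str] | str, frame_rate: float = 50.0
) -> list[ExpressionTrack]:
    """Parse a long-format expression CSV into one track per participant.

    Empty channel cells mark missing values; a frame with any missing
    channel is wholly invalid.  Raises :class:`ValidationError` on values
    outside [0, 1], duplicated ``(participant, frame)`` rows, or
    non-contiguous frame indices.
    """
    df = pd.read_csv(stream, dtype={"participant_id": str},
                     float_precision="round_trip")
    missing_cols = [c for c in _EXPR_HEADER if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"expression table missing columns {missing_cols}")

    tracks: list[ExpressionTrack] = []
    for pid, grp in df.groupby("participant_id", sort=False):
        idx = grp["frame_index"].to_numpy()
        if len(np.unique(idx)) != len(idx):
            raise ValidationError(f"participant {pid!r}: duplicated frame_index")
        grp = grp.sort_values("frame_index")
        idx = grp["frame_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise ValidationError(
                f"participant {pid!r}: frame_index not contiguous from 0"
            )
        values = grp[list(CHANNELS)].to_numpy(dtype=float)
        bad = np.nonzero((values < 0) | (values > 1))
        if bad[0].size:
            t, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"participant {pid!r} frame {int(idx[t])} channel "
                f"{CHANNELS[j]!r}: value {values[t, j]} outside [0, 1]"
            )
        tracks.append(ExpressionTrack(str(pid), frame_rate, values))
    return tracks


def write_expression_table(tracks: Iterable[ExpressionTrack], stream: IO[str]) -> None:
    """Write tracks in the long CSV format; inverse of the reader.

    Values round-trip at full precision; missing frames become rows with
    8 empty channel cells.
    """
    frames = []
    for t in tracks:
        df = pd.DataFrame(t.intensities, columns=list(CHANNELS))
        df.insert(0, "frame_index", np.arange(t.n_frames))
        df.insert(0, "participant_id", t.participant_id)
        frames.append(df)
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=_EXPR_HEADER)
    out.to_csv(stream, index=False, float_format="%.17g")


def read_engagement_script(stream: IO[str] | str) -> EngagementScript:
    """Parse a scene-score CSV into a validated :class:`EngagementScript`."""
    df = pd.read_csv(stream)
    for col in ("start_s", "end_s", "score"):
        if col not in df.columns:
            raise ValidationError(f"engagement script missing column {col!r}")
    scenes = [
        (float(r.start_s), float(r.end_s), int(r.score))
        for r in df.itertuples(index=False)
    ]
    scenes.sort(key=lambda s: s[0])
    if scenes and scenes[0][0] != 0:
        raise ValidationError("first scene must start at 0 s")
    return EngagementScript(scenes)


def write_engagement_script(script: EngagementScript, stream: IO[str]) -> None:
    pd.DataFrame(script.scenes, columns=["start_s", "end_s", "score"]).to_csv(
        stream, index=False
    )


def read_metadata_table(
    stream: IO[str] | str,
) -> tuple[dict[str, tuple[int, int]], dict[str, ParticipantInfo]]:
    """Parse the combined seat-map + participant-metadata CSV."""
    df = pd.read_csv(stream, dtype={"participant_id": str})
    missing_cols = [c for c in _META_HEADER if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"metadata table missing columns {missing_cols}")
    seat_map: dict[str, tuple[int, int]] = {}
    info: dict[str, ParticipantInfo] = {}
    for r in df.itertuples(index=False):
        pid = str(r.participant_id)
        if pid in seat_map:
            raise ValidationError(f"duplicate participant_id {pid!r}")
        seat_map[pid] = (int(r.row), int(r.seat))
        age = None if pd.isna(r.age) else float(r.age)
        emp = None if pd.isna(r.empathy_total) else float(r.empathy_total)
        info[pid] = ParticipantInfo(
            age=age,
            gender=str(r.gender),
            empathy_total=emp,
            empathy_scale=str(r.empathy_scale),
            questionnaires_complete=bool(r.questionnaires_complete),
        )
    return seat_map, info


def write_metadata_table(
    seat_map: Mapping[str, tuple[int, int]],
    info: Mapping[str, ParticipantInfo],
    stream: IO[str],
) -> None:
    rows = []
    for pid, (row, seat) in seat_map.items():
        pi = info.get(pid, ParticipantInfo())
        rows.append(
            {
                "participant_id": pid,
                "row": row,
                "seat": seat,
                "age": "" if pi.age is None else pi.age,
                "gender": pi.gender,
                "empathy_total": "" if pi.empathy_total is None else pi.empathy_total,
                "empathy_scale": pi.empathy_scale,
                "questionnaires_complete": pi.questionnaires_complete,
            }
        )
    pd.DataFrame(rows, columns=_META_HEADER).to_csv(stream, index=False)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_recording(recording: AudienceRecording) -> list[str]:
    """Check every recording invariant; return one finding per violation.

    An empty list means the recording is consistent.  Findings, not
    exceptions: callers decide severity.
    """
    findings: list[str] = []
    ids = recording.participant_ids
    if not ids:
        findings.append("recording has no tracks")
        return findings
    seen: set[str] = set()
    for pid in ids:
        if pid in seen:
            findings.append(f"duplicate participant_id {pid!r}")
        seen.add(pid)
    n0 = recording.tracks[0].n_frames
    fr0 = recording.tracks[0].frame_rate
    for t in recording.tracks:
        if t.n_frames != n0:
            findings.append(
                f"unequal track length: {t.participant_id!r} has "
                f"{t.n_frames} frames, expected {n0}"
            )
        if t.frame_rate != fr0:
            findings.append(f"unequal frame rate for {t.participant_id!r}")
    seats_seen: dict[tuple[int, int], str] = {}
    for pid, seat in recording.seat_map.items():
        if pid not in seen:
            findings.append(f"seat map references unknown participant {pid!r}")
        if seat in seats_seen:
            findings.append(
                f"duplicate seat {seat}: {seats_seen[seat]!r} and {pid!r}"
            )
        seats_seen[seat] = pid
    for pid in ids:
        if pid not in recording.seat_map:
            findings.append(f"participant {pid!r} has no seat")
    return findings


def roundtrip_expression_table(tracks: list[ExpressionTrack],
                               frame_rate: float = 50.0) -> list[ExpressionTrack]:
    """Write then re-read tracks (used by tests to assert identity)."""
    buf = io.StringIO()
    write_expression_table(tracks, buf)
    buf.seek(0)
    return read_expression_table(buf, frame_rate)
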