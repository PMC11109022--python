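"""Inclusion filtering and per-individual expression descriptives.

Participants enter the analyses only if their face could be modelled for
more than 90% of the performance *and* they completed all questionnaires;
a performance with fewer than two eligible members is excluded entirely.

Per individual this module computes the mean and standard deviation of each
expression over valid frames, the 8x8 between-expression correlation matrix,
and the directed individual-vs-rest-of-audience ("audience n-1") matrix
whose diagonal captures within-expression synchrony and whose off-diagonal
captures cross-expression coupling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .isc import effectively_constant, fisher_z
from .recording_io import CHANNELS, AudienceRecording, ExpressionTrack

__all__ = [
    "ExpressionSummary",
    "CrossExpressionMatrix",
    "validity_fraction",
    "apply_inclusion",
    "expression_summary",
    "between_expression_matrix",
    "individual_vs_rest_matrix",
    "within_between_contrast",
]

logger = logging.getLogger(__name__)

MIN_JOINT_FRAMES = 3


@dataclass
class ExpressionSummary:
    """Per-channel mean and sample SD over valid frames."""

    participant_id: str
    mean: np.ndarray  # (8,)
    sd: np.ndarray    # (8,)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "expression": CHANNELS,
                "mean": self.mean,
                "sd": self.sd,
            }
        )


@dataclass
class CrossExpressionMatrix:
    """8x8 Pearson-r matrix; NaN marks undefined (zero-variance) entries.

    ``symmetric`` distinguishes the within-individual variant (channel i vs
    channel j of the same person; symmetric, unit diagonal) from the directed
    individual-vs-rest variant (rows: the individual's channels, columns:
    the rest-of-audience average channels).
    """

    values: np.ndarray
    symmetric: bool
    participant_id: str | None = None

    def on_diagonal(self) -> np.ndarray:
        return np.diag(self.values)

    def off_diagonal(self) -> np.ndarray:
        mask = ~np.eye(8, dtype=bool)
        return self.values[mask]


def validity_fraction(track: ExpressionTrack) -> float:
    """Fraction of frames with a complete 8-channel measurement."""
    if track.n_frames == 0:
        raise ValueError("zero-length track")
    return float(track.valid_mask.mean())


def apply_inclusion(
    recording: AudienceRecording,
    min_valid: float = 0.9,
    require_questionnaires: bool = True,
    min_audience: int = 2,
) -> AudienceRecording:
    """Keep participants valid strictly more than ``min_valid`` of the time.

    Also requires completed questionnaires when asked; if fewer than
    ``min_audience`` participants survive, the whole performance is excluded
    (empty recording, logged).  Idempotent.
    """
    keep = []
    for t in recording.tracks:
        if validity_fraction(t) <= min_valid:
            continue
        if require_questionnaires:
            pi = recording.info.get(t.participant_id)
            if pi is None or not pi.questionnaires_complete:
                continue
        keep.append(t.participant_id)
    if len(keep) < min_audience:
        logger.info(
            "performance %s excluded: %d eligible participant(s) < %d",
            recording.performance_id, len(keep), min_audience,
        )
        keep = []
    return recording.subset(keep)


def expression_summary(track: ExpressionTrack) -> ExpressionSummary:
    """Mean and sample SD (n-1 denominator) per channel over valid frames."""
    if int(track.valid_mask.sum()) < 2:
        raise ValueError("need at least 2 valid frames")
    vals = track.intensities[track.valid_mask]
    return ExpressionSummary(
        participant_id=track.participant_id,
        mean=vals.mean(axis=0),
        sd=vals.std(axis=0, ddof=1),
    )


def _corr_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-by-column Pearson r between two (frames, 8) arrays.

    Rows containing NaN in either array are dropped pairwise per column pair.
    """
    out = np.full((8, 8), np.nan)
    for i in range(8):
        for j in range(8):
            ok = ~np.isnan(A[:, i]) & ~np.isnan(B[:, j])
            if ok.sum() < MIN_JOINT_FRAMES:
                continue
            a, b = A[ok, i], B[ok, j]
            if effectively_constant(a) or effectively_constant(b):
                continue
            out[i, j] = float(np.corrcoef(a, b)[0, 1])
    return out


def between_expression_matrix(track: ExpressionTrack) -> CrossExpressionMatrix:
    """Within-individual correlations between the 8 expression channels."""
    if int(track.valid_mask.sum()) < MIN_JOINT_FRAMES:
        raise ValueError("need at least 3 valid frames")
    vals = track.intensities
    M = _corr_columns(vals, vals)
    # constant channels keep NaN on the diagonal; others are exactly 1
    for i in range(8):
        col = vals[track.valid_mask, i]
        if not effectively_constant(col):
            M[i, i] = 1.0
    return CrossExpressionMatrix(M, symmetric=True,
                                 participant_id=track.participant_id)


def rest_of_audience_average(
    recording: AudienceRecording, participant_id: str
) -> np.ndarray:
    """Frame-wise mean over the *other* participants' valid values.

    Frames where no other participant is valid are NaN.
    """
    others = [t for t in recording.tracks if t.participant_id != participant_id]
    if not others:
        raise ValueError("audience of 1 has no rest-of-audience")
    stack = np.stack([t.intensities for t in others])  # (n-1, T, 8)
    with np.errstate(invalid="ignore"):
        return np.nanmean(stack, axis=0)


def individual_vs_rest_matrix(
    recording: AudienceRecording, participant_id: str
) -> CrossExpressionMatrix:
    """Directed matrix: participant channels (rows) vs audience n-1 (columns)."""
    if len(recording.tracks) < 2:
        raise ValueError("need an audience of at least 2")
    track = recording.track(participant_id)
    rest = rest_of_audience_average(recording, participant_id)
    M = _corr_columns(track.intensities, rest)
    return CrossExpressionMatrix(M, symmetric=False, participant_id=participant_id)


def within_between_contrast(
    matrices: list[CrossExpressionMatrix],
) -> pd.DataFrame:
    """Mean on- vs off-diagonal Fisher-z per individual and per expression.

    Returns one row per individual with columns ``on_z`` (mean transformed
    diagonal), ``off_z`` (mean transformed off-diagonal), plus ``on_z_<ch>``
    and ``off_z_<ch>`` per-expression contrasts (that channel's diagonal
    entry vs the mean of its 7 row-wise off-diagonal entries).  Undefined
    entries are excluded from the means; the paired difference vectors
    (on - off) feed the Bayesian t-tests downstream.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    rows = []
    for m in matrices:
        z = fisher_z(m.values)
        diag = np.diag(z)
        off = z[~np.eye(8, dtype=bool)]
        if np.all(np.isnan(diag)) and np.all(np.isnan(off)):
            raise ValueError(
                f"matrix for {m.participant_id!r} has no defined entries"
            )
        row: dict[str, object] = {
            "participant_id": m.participant_id,
            "on_z": np.nanmean(diag),
            "off_z": np.nanmean(off),
        }
        for i, ch in enumerate(CHANNELS):
            row_off = np.concatenate([z[i, :i], z[i, i + 1:]])
            row[f"on_z_{ch}"] = z[i, i]
            row[f"off_z_{ch}"] = (
                np.nanmean(row_off) if not np.all(np.isnan(row_off)) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
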