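"""Sliding-window inter-subject correlation (ISC) of expression time series.

The synchrony measure: each expression channel of each audience member is
Pearson-correlated with the *same* channel of every other member (happy with
happy, sad with sad, ...) inside a sliding window — by default 60 s of video
(3000 frames at 50 frames/s) advanced in 2 s steps (100 frames) until the end
of the recording.  Per window and expression, the r values of all unordered
pairs are averaged, giving a time course of audience synchrony.

Missing frames (face-model failures) are handled pairwise-complete: each
pair's correlation uses only frames valid for both members, and a window is
reported missing when the jointly valid fraction falls below a threshold
(default one half) or either series is constant within the window.

Fisher's r-to-z transform (z = atanh r) is applied wherever correlation
values enter inferential statistics; r = +/-1 is clipped at 1 - 1e-7 first
so z stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .recording_io import CHANNELS, AudienceRecording, ExpressionTrack

__all__ = [
    "WindowSpec",
    "ISCTimeCourse",
    "window_starts",
    "windowed_pair_correlation",
    "sliding_window_isc",
    "pairwise_isc",
    "fisher_z",
    "fisher_z_inv",
]

_CLIP = 1.0 - 1e-7


def effectively_constant(x: np.ndarray) -> bool:
    """True when a series has no variance beyond float rounding noise."""
    x = np.asarray(x, dtype=float)
    return bool(x.std() <= 1e-12 * max(1.0, abs(float(x.mean()))))


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry and coverage requirement.

    window_len: window length in frames (default 3000 = 60 s at 50 fps).
    step: advance in frames (default 100 = 2 s at 50 fps).
    min_valid_fraction: minimum jointly valid fraction of a window for a
        pair's r to be defined there (default 0.5).
    """

    window_len: int = 3000
    step: int = 100
    min_valid_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.window_len:
            raise ValueError("need 0 < step <= window_len")
        if not 0 < self.min_valid_fraction <= 1:
            raise ValueError("min_valid_fraction must be in (0, 1]")


@dataclass
class ISCTimeCourse:
    """Mean pairwise r per sliding window, one column per expression.

    mean_r: (n_windows, 8) array, NaN where no pair was defined.
    n_pairs: (n_windows, 8) int array of contributing pairs.
    starts: window start frames.
    """

    starts: np.ndarray
    mean_r: np.ndarray
    n_pairs: np.ndarray
    frame_rate: float = 50.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w, s in enumerate(self.starts):
            for j, ch in enumerate(CHANNELS):
                rows.append(
                    {
                        "window_start_s": s / self.frame_rate,
                        "expression": ch,
                        "mean_r": self.mean_r[w, j],
                        "n_pairs": int(self.n_pairs[w, j]),
                    }
                )
        return pd.DataFrame(rows)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher r-to-z: atanh of r clipped to +/-(1 - 1e-7)."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr[~np.isnan(arr)]) > 1):
        raise ValueError("|r| > 1")
    out = np.arctanh(np.clip(arr, -_CLIP, _CLIP))
    return float(out) if np.isscalar(r) else out


def fisher_z_inv(z: np.ndarray | float) -> np.ndarray | float:
    """Inverse Fisher transform (tanh)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if np.isscalar(z) else out


def window_starts(n_frames: int, spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Start frames 0, step, 2*step, ... with the trailing partial window dropped.

    Count = floor((n_frames - window_len)/step) + 1.
    """
    if n_frames < spec.window_len:
        raise ValueError(
            f"recording of {n_frames} frames shorter than window "
            f"({spec.window_len} frames)"
        )
    n_win = (n_frames - spec.window_len) // spec.step + 1
    return np.arange(n_win) * spec.step


def _moment_corr(
    cnt: np.ndarray,
    sx: np.ndarray,
    sy: np.ndarray,
    sxx: np.ndarray,
    syy: np.ndarray,
    sxy: np.ndarray,
    min_count: float,
) -> np.ndarray:
    """Pearson r from pairwise-complete summed moments; NaN where undefined."""
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / cnt
        vx = sxx - sx * sx / cnt
        vy = syy - sy * sy / cnt
        r = cov / np.sqrt(vx * vy)
    bad = (cnt < max(min_count, 3)) | ~(vx > 0) | ~(vy > 0)
    r = np.where(bad, np.nan, r)
    return np.clip(r, -1.0, 1.0)


def windowed_pair_correlation(
    track_a: ExpressionTrack,
    track_b: ExpressionTrack,
    expression: str,
    spec: WindowSpec = WindowSpec(),
) -> np.ndarray:
    """Per-window Pearson r of one expression between two tracks.

    Uses jointly valid frames within each window; NaN when the joint-valid
    fraction is below ``spec.min_valid_fraction`` or either series is
    constant in the window.  O(n_frames) via cumulative sums.
    """
    if track_a.n_frames != track_b.n_frames:
        raise ValueError("tracks have unequal length")
    x = track_a.channel(expression)
    y = track_b.channel(expression)
    m = track_a.valid_mask & track_b.valid_mask
    xf = np.where(m, x, 0.0)
    yf = np.where(m, y, 0.0)

    starts = window_starts(track_a.n_frames, spec)
    ends = starts + spec.window_len

    def wsum(arr: np.ndarray) -> np.ndarray:
        c = np.concatenate(([0.0], np.cumsum(arr)))
        return c[ends] - c[starts]

    cnt = wsum(m.astype(float))
    return _moment_corr(
        cnt,
        wsum(xf),
        wsum(yf),
        wsum(xf * xf),
        wsum(yf * yf),
        wsum(xf * yf),
        spec.min_valid_fraction * spec.window_len,
    )


def _stack(recording: AudienceRecording) -> tuple[np.ndarray, np.ndarray]:
    """(n, frames, 8) intensity stack with zeros at invalid frames + mask."""
    X = np.stack([t.intensities for t in recording.tracks])
    M = np.stack([t.valid_mask for t in recording.tracks]).astype(float)
    return np.nan_to_num(X, nan=0.0), M


def _pair_corr_matrix(
    Xc: np.ndarray, M: np.ndarray, min_count: float
) -> np.ndarray:
    """All-pairs pairwise-complete Pearson r for one channel via matmuls.

    Xc: (n, T) channel values with zeros at invalid frames; M: (n, T) mask.
    Returns an (n, n) matrix (diagonal meaningless).
    """
    cnt = M @ M.T
    s = Xc @ M.T          # s[i, j] = sum of x_i over joint-valid frames
    ss = (Xc * Xc) @ M.T
    sxy = Xc @ Xc.T
    return _moment_corr(cnt, s, s.T, ss, ss.T, sxy, min_count)


def sliding_window_isc(
    recording: AudienceRecording, spec: WindowSpec = WindowSpec()
) -> ISCTimeCourse:
    """Audience ISC time course: mean pairwise r per window per expression.

    Raw (untransformed) r values are averaged across all unordered pairs
    with a defined correlation; windows where no pair is defined are NaN.
    """
    n = len(recording.tracks)
    if n < 2:
        raise ValueError("need at least 2 participants")
    X, M = _stack(recording)
    starts = window_starts(recording.n_frames, spec)
    iu = np.triu_indices(n, k=1)
    mean_r = np.full((len(starts), len(CHANNELS)), np.nan)
    n_pairs = np.zeros((len(starts), len(CHANNELS)), dtype=int)
    min_count = spec.min_valid_fraction * spec.window_len
    for w, s in enumerate(starts):
        sl = slice(s, s + spec.window_len)
        Mw = M[:, sl]
        for j in range(len(CHANNELS)):
            R = _pair_corr_matrix(X[:, sl, j], Mw, min_count)
            vals = R[iu]
            ok = ~np.isnan(vals)
            n_pairs[w, j] = int(ok.sum())
            if ok.any():
                mean_r[w, j] = vals[ok].mean()
    return ISCTimeCourse(
        starts=starts, mean_r=mean_r, n_pairs=n_pairs,
        frame_rate=recording.frame_rate,
    )


def pairwise_isc(
    recording: AudienceRecording,
    mode: str = "whole_series",
    spec: WindowSpec = WindowSpec(),
) -> pd.DataFrame:
    """One synchrony value per unordered pair per expression.

    mode="whole_series": Pearson r over all jointly valid frames.
    mode="window_mean": mean of per-window Fisher-z values, back-transformed.
    Columns: participant_a, participant_b (a < b by id), expression, r, z,
    plus seat_distance when the recording has a seat map.  Pairs with fewer
    than 3 joint frames get a missing r.
    """
    if mode not in ("whole_series", "window_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(recording.tracks)
    if n < 2:
        raise ValueError("need at least 2 participants")
    ids = recording.participant_ids
    X, M = _stack(recording)

    if mode == "whole_series":
        R = np.stack(
            [_pair_corr_matrix(X[:, :, j], M, 3) for j in range(len(CHANNELS))],
            axis=-1,
        )  # (n, n, 8)
    else:
        starts = window_starts(recording.n_frames, spec)
        min_count = spec.min_valid_fraction * spec.window_len
        zsum = np.zeros((n, n, len(CHANNELS)))
        zcnt = np.zeros((n, n, len(CHANNELS)))
        for s in starts:
            sl = slice(s, s + spec.window_len)
            Mw = M[:, sl]
            for j in range(len(CHANNELS)):
                Rw = _pair_corr_matrix(X[:, sl, j], Mw, min_count)
                ok = ~np.isnan(Rw)
                zsum[:, :, j][ok] += np.arctanh(
                    np.clip(Rw[ok], -_CLIP, _CLIP)
                )
                zcnt[:, :, j][ok] += 1
        with np.errstate(invalid="ignore"):
            R = np.tanh(zsum / zcnt)

    from .spatial import seat_distance  # local import to avoid a cycle

    rows = []
    order = sorted(range(n), key=lambda i: ids[i])
    for a_pos, b_pos in combinations(order, 2):
        pa, pb = ids[a_pos], ids[b_pos]
        dist = np.nan
        if pa in recording.seat_map and pb in recording.seat_map:
            dist = seat_distance(recording.seat_map[pa], recording.seat_map[pb])
        for j, ch in enumerate(CHANNELS):
            r = R[a_pos, b_pos, j]
            z = np.nan if np.isnan(r) else float(np.arctanh(np.clip(r, -_CLIP, _CLIP)))
            rows.append(
                {
                    "participant_a": pa,
                    "participant_b": pb,
                    "expression": ch,
                    "r": r,
                    "z": z,
                    "seat_distance": dist,
                }
            )
    return pd.DataFrame(rows)
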