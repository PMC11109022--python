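"""Relating expression-ISC time courses to scripted engagement predictions.

The dramaturge scores each scene of the performance 1 (low) to 3 (high
engagement) to the nearest second.  The scores are expanded to the frame
grid (scene intervals half-open, a boundary frame belongs to the later
scene) and resampled with exactly the sliding-window geometry used for the
ISC computation, which smooths the step transitions.  Per expression, the
windowed ISC trace is then correlated with the resampled engagement course
(Pearson r, with a directional Bayes factor), and all 2^8 subsets of the
eight expression-ISC predictors are fitted by least squares and compared
with BIC-approximated posterior odds.

Overlapping windows make consecutive values autocorrelated; no correction
is applied to r or the Bayes factors (flagged in the output metadata).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .bayes import BayesSpec, bf_correlation, bic_model_scores
from .isc import (ISCTimeCourse, WindowSpec, effectively_constant,
                  fisher_z, window_starts)
from .recording_io import CHANNELS, EngagementScript

__all__ = [
    "EngagementCourse",
    "EngagementFit",
    "engagement_frame_series",
    "resample_engagement",
    "isc_engagement_correlation",
    "engagement_regression",
]

logger = logging.getLogger(__name__)


@dataclass
class EngagementCourse:
    """Per-window mean engagement on the same grid as an ISC time course."""

    starts: np.ndarray
    values: np.ndarray  # in [1, 3]

    def __post_init__(self) -> None:
        if len(self.starts) != len(self.values):
            raise ValueError("starts and values must align")


@dataclass
class EngagementFit:
    """Exhaustive-subset regression of engagement on the 8 ISC predictors."""

    models: pd.DataFrame        # columns: model, k, r2, score, rank
    selected: tuple[str, ...]   # predictors of the top-ranked model
    selected_r2: float
    n_windows: int
    autocorrelation_corrected: bool = False  # overlapping windows; no correction


def engagement_frame_series(
    script: EngagementScript, frame_rate: float, n_frames: int
) -> np.ndarray:
    """Scene score per frame; scene intervals are half-open [start, end)."""
    dur = n_frames / frame_rate
    if not np.isclose(script.duration_s, dur):
        raise ValueError(
            f"script covers {script.duration_s} s but recording lasts {dur} s"
        )
    times = np.arange(n_frames) / frame_rate
    out = np.empty(n_frames)
    for start, end, score in script.scenes:
        out[(times >= start) & (times < end)] = score
    return out


def resample_engagement(
    script: EngagementScript,
    spec: WindowSpec,
    frame_rate: float,
    n_frames: int,
) -> EngagementCourse:
    """Window-average the frame series on the ISC sliding-window grid."""
    frames = engagement_frame_series(script, frame_rate, n_frames)
    starts = window_starts(n_frames, spec)
    csum = np.concatenate(([0.0], np.cumsum(frames)))
    vals = (csum[starts + spec.window_len] - csum[starts]) / spec.window_len
    return EngagementCourse(starts=starts, values=vals)


def _check_grids(isc: ISCTimeCourse, course: EngagementCourse) -> None:
    if len(isc.starts) != len(course.starts) or not np.array_equal(
        isc.starts, course.starts
    ):
        raise ValueError("ISC and engagement courses are on different window grids")


def isc_engagement_correlation(
    isc: ISCTimeCourse,
    course: EngagementCourse,
    spec: BayesSpec = BayesSpec(),
) -> pd.DataFrame:
    """Per-expression Pearson r (and BF10) between ISC and engagement.

    Windows where the ISC is missing are dropped per expression; constant
    courses yield a missing r with a warning.  BF10 uses the directional
    positive prior by default.
    """
    _check_grids(isc, course)
    rows = []
    for j, ch in enumerate(CHANNELS):
        y = isc.mean_r[:, j]
        ok = ~np.isnan(y)
        r = np.nan
        bf = np.nan
        n_ok = int(ok.sum())
        if n_ok >= 4:
            x = course.values[ok]
            yy = y[ok]
            if effectively_constant(x) or effectively_constant(yy):
                warnings.warn(
                    f"{ch}: zero variance, engagement correlation undefined",
                    stacklevel=2,
                )
            else:
                r = float(np.corrcoef(x, yy)[0, 1])
                if abs(r) < 1:
                    bf = bf_correlation(r, n_ok, spec).bf10
        rows.append(
            {
                "expression": ch,
                "r": r,
                "z": np.nan if np.isnan(r) else fisher_z(r),
                "bf10": bf,
                "n_windows": n_ok,
            }
        )
    return pd.DataFrame(rows)


def _model_label(subset: tuple[int, ...]) -> str:
    return "+".join(CHANNELS[j] for j in subset) if subset else "null"


def engagement_regression(
    isc: ISCTimeCourse, course: EngagementCourse
) -> EngagementFit:
    """Exhaustive search over the 2^8 expression-ISC predictor subsets.

    Missing windows are dropped listwise across all 8 predictors; each
    subset is fitted by OLS and scored with the BIC posterior-odds proxy
    (uniform model prior).  Degenerate (collinear) subsets are skipped with
    a warning.
    """
    _check_grids(isc, course)
    ok = ~np.isnan(isc.mean_r).any(axis=1)
    n = int(ok.sum())
    if n < 10:
        raise ValueError(f"only {n} complete windows; need >= 10")
    X_all = isc.mean_r[ok]
    y = course.values[ok]
    logger.info("engagement regression on %d windows (listwise complete)", n)

    tss = float(((y - y.mean()) ** 2).sum())
    rss_floor = max(tss, 1.0) * 1e-12  # BIC needs RSS > 0 even for perfect fits
    entries = []
    specs: list[tuple[int, float]] = []
    for size in range(9):
        for subset in combinations(range(8), size):
            Xs = np.column_stack(
                [np.ones(n)] + [X_all[:, j] for j in subset]
            )
            rank = np.linalg.matrix_rank(Xs)
            if rank < Xs.shape[1]:
                warnings.warn(
                    f"model {_model_label(subset)} is collinear; skipped",
                    stacklevel=2,
                )
                continue
            beta, _, _, _ = np.linalg.lstsq(Xs, y, rcond=None)
            resid = y - Xs @ beta
            rss = float(resid @ resid)
            r2 = 1.0 - rss / tss if tss > 0 else np.nan
            entries.append((subset, len(subset) + 1, max(rss, rss_floor), r2))
            specs.append((len(subset) + 1, max(rss, rss_floor)))
    scores, ranking = bic_model_scores(specs, n)
    order = np.empty(len(entries), dtype=int)
    order[ranking] = np.arange(len(entries))
    models = pd.DataFrame(
        {
            "model": [_model_label(e[0]) for e in entries],
            "k": [e[1] for e in entries],
            "r2": [e[3] for e in entries],
            "score": scores,
            "rank": order + 1,
        }
    ).sort_values("rank", ignore_index=True)
    top = entries[int(ranking[0])]
    return EngagementFit(
        models=models,
        selected=tuple(CHANNELS[j] for j in top[0]),
        selected_r2=top[3],
        n_windows=n,
    )
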