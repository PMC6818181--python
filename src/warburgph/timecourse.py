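"""Segment-averaged trajectories over an activation time course.

An activation time course sampled at regular intervals (19 points at
20-minute spacing in the motivating design) is summarized by averaging
consecutive equal-sized blocks of timepoints — six segments of three
points from 18 usable timepoints, with the time-zero point dropped since
it precedes activation — and each gene's segment profile is classified as
rising, falling, peak-then-decline or flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from warburgph.core_io import ValidationError

DEFAULT_SEGMENTS = 6
TREND_RHO = 0.8  # |Spearman rho| needed to call a monotone trend


@dataclass
class TimeCourseMatrix:
    """Gene x timepoint values with a consecutive-block segment map."""

    values: pd.DataFrame  # genes x timepoints, columns ordered by time
    n_segments: int = DEFAULT_SEGMENTS
    dropped_timepoints: list[str] = field(default_factory=list)

    @property
    def segment_map(self) -> np.ndarray:
        n_t = self.values.shape[1]
        block = n_t // self.n_segments
        return np.repeat(np.arange(self.n_segments), block)


def _make_divisible(df: pd.DataFrame, n_segments: int, drop_first: bool) -> tuple[pd.DataFrame, list[str]]:
    n_t = df.shape[1]
    dropped: list[str] = []
    if n_t % n_segments != 0:
        if drop_first and (n_t - 1) % n_segments == 0:
            dropped = [str(df.columns[0])]
            df = df.iloc[:, 1:]
        else:
            raise ValidationError(
                f"{n_t} timepoints not divisible into {n_segments} equal segments"
            )
    return df, dropped


def segment_means(
    tc: TimeCourseMatrix | pd.DataFrame,
    panel: list[str] | None = None,
    n_segments: int = DEFAULT_SEGMENTS,
    drop_first_if_needed: bool = True,
) -> pd.DataFrame:
    """Mean per consecutive timepoint block, genes x segments.

    With 19 timepoints and 6 segments the first (time-zero) point is
    dropped, reported in the matrix's ``dropped_timepoints``; any other
    non-divisible count is an error.  Commutes with gene-wise affine
    transforms of the input.
    """
    if isinstance(tc, pd.DataFrame):
        df = tc
    else:
        df = tc.values
        n_segments = tc.n_segments
    if panel is not None:
        missing = [g for g in panel if g not in df.index]
        if missing:
            raise ValidationError(f"panel genes absent from time course: {missing}")
        df = df.loc[panel]
    df, dropped = _make_divisible(df, n_segments, drop_first_if_needed)
    if isinstance(tc, TimeCourseMatrix):
        tc.dropped_timepoints = dropped
    block = df.shape[1] // n_segments
    vals = df.to_numpy().reshape(df.shape[0], n_segments, block).mean(axis=2)
    return pd.DataFrame(
        vals, index=df.index, columns=[f"T{i}" for i in range(n_segments)]
    )


def trend_classification(seg_means: np.ndarray | pd.Series) -> str:
    """Classify one gene's segment profile.

    rising / falling when Spearman rho with segment index is >= 0.8 /
    <= -0.8; peak_then_decline when the maximum is interior with both
    flanks monotone; otherwise flat.  Reversing a series swaps rising and
    falling.
    """
    y = np.asarray(seg_means, dtype=float)
    if len(y) < 3:
        raise ValidationError("need at least 3 segments to classify a trend")
    if np.ptp(y) == 0.0:
        return "flat"
    rho = stats.spearmanr(np.arange(len(y)), y).statistic
    if rho >= TREND_RHO:
        return "rising"
    if rho <= -TREND_RHO:
        return "falling"
    k = int(np.argmax(y))
    if 0 < k < len(y) - 1:
        left = y[: k + 1]
        right = y[k:]
        if np.all(np.diff(left) >= 0) and np.all(np.diff(right) <= 0):
            return "peak_then_decline"
    return "flat"


def classify_panel_trends(seg: pd.DataFrame) -> pd.Series:
    """Trend call per gene of a segment-mean table."""
    return seg.apply(lambda row: trend_classification(row.to_numpy()), axis=1)
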