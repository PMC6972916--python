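"""Immunoglobulin segment abundances and clonal dominance tracking.

In multiple myeloma the malignant plasma-cell clone expresses one specific
heavy/light-chain segment combination, so in cf-mRNA a single V segment can
take most of the Ig read mass.  This module turns segment x sample read
counts into relative abundances (per Ig class or across all Ig reads),
flags dominant segments, and follows a known clone's summed fraction
through therapy to find the day dominance is lost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CloneCall",
    "CloneTrack",
    "relative_abundance",
    "detect_dominant",
    "track_clone",
]


@dataclass(frozen=True)
class CloneCall:
    """Dominance assessment of one segment in one sample/day."""

    segment: str
    seg_class: str
    day: object
    fraction: float
    dominant: bool
    by_fraction: bool  # fraction > dominance_threshold
    by_fold_over_second: bool  # > min_fold_over_second x runner-up


@dataclass
class CloneTrack:
    """Per-day summed fraction of a clone's segments."""

    fractions: pd.Series  # day -> clone fraction (NaN where undefined)
    dominant: pd.Series  # day -> bool
    loss_of_dominance_day: object | None  # first day after which dominance never recurs


def _split_counts(table: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    if "class" not in table.columns:
        raise ValueError("count table must carry a 'class' column")
    classes = table["class"].astype(str)
    counts = table.drop(columns="class")
    if (counts.to_numpy() < 0).any():
        raise ValueError("read counts must be non-negative")
    return classes, counts


def relative_abundance(table: pd.DataFrame, scope: str = "per-class") -> pd.DataFrame:
    """Fraction of Ig reads per segment, normalized within the chosen scope.

    ``scope="per-class"`` normalizes each segment against the total reads of
    its own Ig class (heavy-variable separate from kappa-variable, etc., as
    repertoire panels are drawn); ``scope="all-Ig"`` normalizes against all
    Ig reads in the sample.  Samples with zero reads in a scope get NaN
    fractions — undefined, never silently zero.

    Parameters
    ----------
    table
        Segment-indexed DataFrame with a ``class`` column followed by one
        count column per sample/day.
    """
    classes, counts = _split_counts(table)
    if scope == "per-class":
        totals = counts.groupby(classes).transform("sum")
    elif scope == "all-Ig":
        totals = pd.DataFrame(
            np.broadcast_to(counts.sum(axis=0).to_numpy(), counts.shape),
            index=counts.index,
            columns=counts.columns,
        )
    else:
        raise ValueError(f"unknown scope {scope!r}")
    fractions = counts / totals.where(totals > 0)
    out = fractions.copy()
    out.insert(0, "class", classes)
    return out


def detect_dominant(
    fractions: pd.DataFrame,
    dominance_threshold: float = 0.5,
    min_fold_over_second: float = 5.0,
    min_total_reads: int = 100,
    counts: pd.DataFrame | None = None,
) -> list[CloneCall]:
    """Flag dominant (clonal) segments per class and sample.

    A segment is dominant when its within-class fraction exceeds
    ``dominance_threshold`` OR exceeds ``min_fold_over_second`` times the
    second-ranked segment of its class — and, when ``counts`` is supplied,
    the class has at least ``min_total_reads`` reads in that sample
    (suppressing dominance calls made from shot noise).

    Returns every (segment, sample) call with both trigger conditions
    recorded, so the evidence behind each flag is reviewable.
    """
    classes, frac = _split_counts(fractions)
    class_counts = None
    if counts is not None:
        _, raw = _split_counts(counts)
        class_counts = raw.groupby(classes).transform("sum")

    calls: list[CloneCall] = []
    for cls in classes.unique():
        block = frac.loc[classes == cls]
        for col in block.columns:
            col_frac = block[col]
            if col_frac.isna().all():
                continue
            order = col_frac.sort_values(ascending=False)
            second = float(order.iloc[1]) if len(order) > 1 else 0.0
            for seg, f in col_frac.items():
                if np.isnan(f):
                    continue
                runner = second if f >= order.iloc[0] else float(order.iloc[0])
                by_frac = f > dominance_threshold
                by_fold = f > min_fold_over_second * runner
                enough = (
                    class_counts is None
                    or class_counts.loc[seg, col] >= min_total_reads
                )
                calls.append(
                    CloneCall(
                        segment=str(seg),
                        seg_class=str(cls),
                        day=col,
                        fraction=float(f),
                        dominant=bool((by_frac or by_fold) and enough),
                        by_fraction=bool(by_frac),
                        by_fold_over_second=bool(by_fold),
                    )
                )
    return calls


def track_clone(
    fractions: pd.DataFrame,
    clone_segments: list[str],
    dominance_threshold: float = 0.5,
) -> CloneTrack:
    """Follow a known clone's summed fraction and find when dominance is lost.

    The clone's per-day fraction is the sum of its segments' fractions.  The
    clone is dominant on a day when that sum exceeds
    ``dominance_threshold``; the loss-of-dominance day is the first day
    after which dominance never recurs within the series (None when the
    clone is dominant through the last day, or never dominant at all).
    """
    _, frac = _split_counts(fractions)
    missing = [s for s in clone_segments if s not in frac.index]
    if missing:
        raise ValueError(f"clone segments absent from table: {missing}")

    clone = frac.loc[list(clone_segments)].sum(axis=0, min_count=1)
    dominant = clone > dominance_threshold

    loss_day = None
    if dominant.any():
        last_dominant_pos = int(np.max(np.flatnonzero(dominant.to_numpy())))
        if last_dominant_pos + 1 < len(dominant):
            loss_day = dominant.index[last_dominant_pos + 1]
    return CloneTrack(
        fractions=clone, dominant=dominant, loss_of_dominance_day=loss_day
    )


def calls_to_frame(calls: list[CloneCall]) -> pd.DataFrame:
    """Tabulate clone calls for writing."""
    return pd.DataFrame(
        [
            (c.segment, c.seg_class, c.day, c.fraction, c.dominant,
             c.by_fraction, c.by_fold_over_second)
            for c in calls
        ],
        columns=[
            "segment", "class", "day", "fraction", "dominant",
            "by_fraction", "by_fold_over_second",
        ],
    )
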