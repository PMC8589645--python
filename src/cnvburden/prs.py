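"""Frequency-matched polygenic-score extreme groups and middle-quantile
controls.

The comparison design: the number of PRS-extreme "cases" in each cohort is
matched to that cohort's high-risk CNV carrier count; controls are the
middle 20-80% of the same PRS distribution (not the opposite extreme, which
would overstate the impact of outlier status). For attainment-type scores
(educational attainment, IQ) the extreme of interest is the low tail; for
liability scores (schizophrenia) the high tail.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "standardize_scores",
    "assign_extremes",
    "middle_controls",
    "prs_grouping",
]

LABELS = ("extreme_case", "middle_control", "neither")


def standardize_scores(scores: pd.Series) -> pd.Series:
    """Z-standardize raw scores within a cohort (sample SD, ddof=1)."""
    sd = scores.std(ddof=1)
    if not sd > 0:
        raise ValueError("score SD must be positive for standardization")
    return (scores - scores.mean()) / sd


def _ordered_index(scores: pd.Series) -> pd.Index:
    """Sample ids in ascending score order, ties broken by sample id."""
    df = pd.DataFrame({"score": scores.to_numpy(), "sid": scores.index})
    df = df.sort_values(["score", "sid"], kind="mergesort")
    return pd.Index(df["sid"])


def assign_extremes(scores: pd.Series, n_cases: int, tail: str = "low") -> pd.Series:
    """Boolean case indicator: the ``n_cases`` most extreme samples in the
    stated tail. Deterministic under ties (score, then sample id)."""
    if n_cases <= 0:
        raise ValueError(f"n_cases must be positive, got {n_cases}")
    if n_cases > len(scores):
        raise ValueError(f"n_cases {n_cases} exceeds cohort size {len(scores)}")
    if tail not in ("low", "high"):
        raise ValueError(f"tail must be 'low' or 'high', got {tail!r}")
    ordered = _ordered_index(scores)
    chosen = ordered[:n_cases] if tail == "low" else ordered[-n_cases:]
    out = pd.Series(False, index=scores.index, name="extreme_case")
    out.loc[chosen] = True
    return out


def middle_controls(scores: pd.Series, low: float = 0.2, high: float = 0.8) -> pd.Series:
    """Boolean control indicator for the middle quantile band of the score
    distribution.

    Rank-based: with ascending ranks r = 1..N (ties broken by sample id),
    controls are the samples with ceil(low*N) < r <= floor(high*N). With
    the default 20-80% band this yields 13,831 controls of N = 23,053 and
    2,937 of N = 4,895.
    """
    if not (0 <= low < high <= 1):
        raise ValueError(f"need 0 <= low < high <= 1, got ({low}, {high})")
    n = len(scores)
    lo_rank = math.ceil(low * n)   # exclusive
    hi_rank = math.floor(high * n)  # inclusive
    if hi_rank <= lo_rank:
        raise ValueError(f"empty control band for N={n}, ({low}, {high})")
    ordered = _ordered_index(scores)
    chosen = ordered[lo_rank:hi_rank]
    out = pd.Series(False, index=scores.index, name="middle_control")
    out.loc[chosen] = True
    return out


def prs_grouping(
    scores: pd.Series,
    n_cases: int,
    tail: str = "low",
    low: float = 0.2,
    high: float = 0.8,
) -> pd.DataFrame:
    """Combined grouping: label each sample extreme_case / middle_control /
    neither (extreme status takes precedence should the bands ever touch),
    plus the standardized score."""
    case = assign_extremes(scores, n_cases, tail)
    ctrl = middle_controls(scores, low, high)
    label = pd.Series("neither", index=scores.index, name="label")
    label[ctrl] = "middle_control"
    label[case] = "extreme_case"
    return pd.DataFrame({
        "score": scores,
        "z": standardize_scores(scores),
        "label": label,
        "tail": tail,
    })
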