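"""Sociability preference indexes from three-chamber trials.

Two indexes, both dimensionless in [-100, 100]:

  chamber index   = (Tc - To) / (Tc + To) * 100
  proximity index = (Tnc - Tno) / (Tnc + Tno) * 100

Positive values mean preference for the conspecific over the object; an
animal that never produced the relevant times (zero denominator) gets a
missing value with a reason code, never a fake 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import BehavioralTrial, ValidationError

#: reason codes for undefined indexes
NO_SIDE_TIME = "no_side_chamber_time"
NO_PROXIMITY_TIME = "no_proximity_time"


def chamber_preference_index(trial: BehavioralTrial) -> tuple[float, str | None]:
    """(Tc - To) / (Tc + To) * 100, or (nan, reason) if Tc + To = 0."""
    denom = trial.Tc + trial.To
    if denom == 0:
        return math.nan, NO_SIDE_TIME
    return (trial.Tc - trial.To) / denom * 100.0, None


def proximity_preference_index(trial: BehavioralTrial) -> tuple[float, str | None]:
    """(Tnc - Tno) / (Tnc + Tno) * 100, or (nan, reason) if Tnc + Tno = 0."""
    denom = trial.Tnc + trial.Tno
    if denom == 0:
        return math.nan, NO_PROXIMITY_TIME
    return (trial.Tnc - trial.Tno) / denom * 100.0, None


def lit_time_percent(trial: BehavioralTrial, session_length: float) -> float:
    """Light-dark test: percent of the session spent in the lit compartment."""
    if session_length <= 0:
        raise ValidationError("session_length must be > 0")
    if trial.lit_time is None:
        return math.nan
    if trial.lit_time > session_length + 1e-9:
        raise ValidationError(
            f"lit_time {trial.lit_time} exceeds session length {session_length} "
            f"for subject {trial.subject_id!r}"
        )
    return trial.lit_time / session_length * 100.0


def time_binned_proximity(
    series: list[tuple[float, bool]], bin_width: float, session_length: float
) -> list[float]:
    """Per-bin in-proximity time from a (timestamp, in-proximity) event series.

    Each entry states the flag that holds from its timestamp until the
    next entry (or session end). Bin sums conserve the whole-session
    proximity total for any bin width.
    """
    if bin_width <= 0:
        raise ValidationError("bin width must be > 0")
    times = [t for t, _ in series]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValidationError("timestamps must be non-decreasing")
    n_bins = int(math.ceil(session_length / bin_width))
    bins = [0.0] * n_bins
    for k, (start, flag) in enumerate(series):
        if not flag:
            continue
        end = series[k + 1][0] if k + 1 < len(series) else session_length
        end = min(end, session_length)
        t = max(start, 0.0)
        while t < end:
            b = min(int(t // bin_width), n_bins - 1)
            edge = min((b + 1) * bin_width, end)
            if edge <= t:  # float rounding at the last bin boundary
                edge = end
            bins[b] += edge - t
            t = edge
    return bins


@dataclass
class PreferenceResult:
    """Per-animal indexes plus group mean/SD over the defined values."""

    table: pd.DataFrame  # subject_id, chamber_index, proximity_index, lit_percent, flags
    chamber_mean: float
    chamber_sd: float
    proximity_mean: float
    proximity_sd: float
    n: int


def score_trials(
    trials: list[BehavioralTrial], session_length: float | None = None
) -> PreferenceResult:
    """Score a cohort of trials; undefined indexes are NaN with a flag."""
    rows = []
    for t in trials:
        ci, ci_flag = chamber_preference_index(t)
        pi, pi_flag = proximity_preference_index(t)
        sess = session_length if session_length is not None else t.session_length
        lit = lit_time_percent(t, sess) if sess else math.nan
        flags = ";".join(f for f in (ci_flag, pi_flag) if f)
        rows.append(
            {
                "subject_id": t.subject_id,
                "chamber_index": ci,
                "proximity_index": pi,
                "lit_percent": lit,
                "flags": flags,
            }
        )
    table = pd.DataFrame(rows)
    ci = table["chamber_index"].dropna()
    pi = table["proximity_index"].dropna()
    return PreferenceResult(
        table=table,
        chamber_mean=float(ci.mean()) if len(ci) else math.nan,
        chamber_sd=float(ci.std(ddof=1)) if len(ci) > 1 else math.nan,
        proximity_mean=float(pi.mean()) if len(pi) else math.nan,
        proximity_sd=float(pi.std(ddof=1)) if len(pi) > 1 else math.nan,
        n=len(table),
    )
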