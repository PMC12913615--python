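"""The RTACC digital biomarker and responder labelling.

RTACC is a per-participant summary of the speed-accuracy relationship over
an entire course of computerized cognitive training:

    RTACC = corr(RT_i, Accuracy_i)

where the index runs over all of a participant's 3-minute tasks, ``RT_i``
is the mean reaction time within task ``i`` (seconds) and ``Accuracy_i``
the proportion of correct trials.  Pairs are pooled across games and
sessions into a single product-moment correlation per participant; a
negative value means the participant tended to be fast *and* accurate on
the same tasks — the speed-accuracy trade-off overcome.

Sensitivity variants restrict the pairs to the first W weeks of training
(time windows) or exclude all tasks of one game (leave-one-game-out).
"""

from __future__ import annotations

import math
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import GameCatalogEntry, default_catalog

DEFAULT_WINDOWS = (1, 2, 3, 6, 12, 24)
MIN_PAIRS = 10

RTACC_COLUMNS = ["participant_id", "window_weeks", "excluded_game",
                 "n_pairs", "value", "defined"]


class RTACCValue(NamedTuple):
    """One participant's RTACC for a stated window / exclusion."""

    participant_id: str
    window_weeks: int
    excluded_game: str | None
    n_pairs: int
    value: float  # NaN when not defined
    defined: bool


def pearson_corr(xs, ys) -> float:
    """Product-moment correlation; NaN when undefined.

    Undefined (rather than raising) for n < 3 or a zero-variance series so
    that batch computation over participants records ``defined = False``
    instead of aborting.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    n = x.size
    if n < 3:
        return math.nan
    # a constant series has no variance; roundoff in the mean would
    # otherwise leave a spurious ~1e-16 numerator
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        return math.nan
    r = float(xc @ yc) / math.sqrt(sxx * syy)
    # guard against roundoff just past the bounds
    return max(-1.0, min(1.0, r))


def _corr(xs, ys, method: str) -> float:
    if method == "pearson":
        return pearson_corr(xs, ys)
    if method == "spearman":
        x = np.asarray(xs, dtype=float)
        if x.size < 3:
            return math.nan
        return pearson_corr(stats.rankdata(xs), stats.rankdata(ys))
    raise ValueError(f"unknown correlation method {method!r}")


def compute_rtacc(records: pd.DataFrame, window_weeks: int = 24,
                  excluded_game: str | None = None,
                  min_pairs: int = MIN_PAIRS,
                  method: str = "pearson") -> RTACCValue:
    """RTACC for one participant's (preprocessed) task records.

    Selects records with ``week <= window_weeks`` and, optionally,
    ``game_id != excluded_game``; pools the remaining (mean RT, accuracy)
    pairs across games and sessions; returns their correlation.
    ``defined`` is False when fewer than ``min_pairs`` pairs remain or a
    series is degenerate.
    """
    if window_weeks < 1:
        raise ValueError("window_weeks must be >= 1")
    pids = records["participant_id"].unique()
    if len(pids) > 1:
        raise ValueError("compute_rtacc expects records of a single participant")
    pid = str(pids[0]) if len(pids) else ""

    sel = records[records["week"] <= window_weeks]
    if excluded_game is not None:
        sel = sel[sel["game_id"] != excluded_game]
    n = len(sel)
    if n < max(min_pairs, 3):
        return RTACCValue(pid, window_weeks, excluded_game, n, math.nan, False)
    r = _corr(sel["mean_rt_s"].to_numpy(), sel["accuracy"].to_numpy(), method)
    return RTACCValue(pid, window_weeks, excluded_game, n, r, not math.isnan(r))


def rtacc_table(records: pd.DataFrame, window_weeks: int = 24,
                excluded_game: str | None = None,
                min_pairs: int = MIN_PAIRS,
                method: str = "pearson") -> pd.DataFrame:
    """One RTACC row per participant in a cohort-level training log."""
    rows = [compute_rtacc(grp, window_weeks, excluded_game, min_pairs, method)
            for _, grp in records.groupby("participant_id", sort=True)]
    return pd.DataFrame(rows, columns=RTACC_COLUMNS)


def rtacc_windows(records: pd.DataFrame,
                  windows: Iterable[int] = DEFAULT_WINDOWS,
                  min_pairs: int = MIN_PAIRS,
                  method: str = "pearson") -> pd.DataFrame:
    """RTACC per participant for each nested time window.

    Windows are inclusive upper week bounds (``week <= W``), so the pair
    sets are nested and ``n_pairs`` is non-decreasing in the window.
    """
    windows = list(windows)
    if windows != sorted(windows):
        raise ValueError("windows must be sorted ascending")
    frames = [rtacc_table(records, w, None, min_pairs, method) for w in windows]
    return pd.concat(frames, ignore_index=True)


def rtacc_leave_one_game_out(records: pd.DataFrame,
                             catalog: list[GameCatalogEntry] | None = None,
                             window_weeks: int = 24,
                             min_pairs: int = MIN_PAIRS,
                             method: str = "pearson") -> pd.DataFrame:
    """RTACC per participant with each catalogue game excluded in turn."""
    entries = catalog if catalog is not None else default_catalog()
    frames = [rtacc_table(records, window_weeks, e.game_id, min_pairs, method)
              for e in entries]
    return pd.concat(frames, ignore_index=True)


def label_responders(profiles: pd.DataFrame) -> pd.DataFrame:
    """Label each participant by the sign of the week-24 RBANS change.

    ``good`` for an increased score, ``poor`` for a decreased score, and
    ``tie`` for exactly zero change (excluded from classification fits
    downstream).
    """
    missing = profiles["rbans_week24"].isna() | profiles["rbans_baseline"].isna()
    if missing.any():
        bad = profiles.loc[missing, "participant_id"].tolist()
        raise ValueError(f"missing RBANS change for participant(s): {bad}")
    change = profiles["rbans_week24"] - profiles["rbans_baseline"]
    label = np.where(change > 0, "good", np.where(change < 0, "poor", "tie"))
    return pd.DataFrame({
        "participant_id": profiles["participant_id"].astype(str),
        "label": label,
    })
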