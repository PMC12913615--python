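"""Ingestion and preprocessing of task-level training logs.

Reads the two CSV schemas, quarantines rows that violate the record
invariants (non-positive RT, accuracy outside [0, 1], ...), counts missing
values, and applies a robust MAD-based outlier rule to each participant's
mean-RT and accuracy series before any correlation is computed.

The MAD rule flags a value ``v`` when ``|v - median| > k * c * MAD`` with
``MAD = median(|v - median|)``, the conventional consistency constant
``c = 1.4826`` (so ``c * MAD`` estimates the SD under normality) and
``k = 3`` by default.  A zero MAD (near-constant series) flags nothing and
emits a warning: under a degenerate scale estimate every deviant would be
flagged, which would discard valid near-constant performers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PreprocessConfig
from .simulate import PARTICIPANT_COLUMNS, TRAINING_LOG_COLUMNS

REQUIRED_LOG_COLUMNS = TRAINING_LOG_COLUMNS
NUMERIC_LOG_COLUMNS = ["week", "session_index", "task_index", "difficulty",
                       "mean_rt_s", "accuracy", "n_trials"]


class SchemaError(ValueError):
    """A required column is missing or the header does not match."""


@dataclass
class PreprocessReport:
    """Counts from missingness checks and outlier filtering."""

    n_records_in: int = 0
    n_missing_rt: int = 0
    n_missing_accuracy: int = 0
    n_flagged_rt: int = 0
    n_flagged_accuracy: int = 0
    n_records_out: int = 0
    n_rejected_rows: int = 0
    n_participants_skipped: int = 0  # too few records to estimate a scale
    per_participant_flags: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_records_in": self.n_records_in,
            "n_missing_rt": self.n_missing_rt,
            "n_missing_accuracy": self.n_missing_accuracy,
            "n_flagged_rt": self.n_flagged_rt,
            "n_flagged_accuracy": self.n_flagged_accuracy,
            "n_records_out": self.n_records_out,
            "n_rejected_rows": self.n_rejected_rows,
            "n_participants_skipped": self.n_participants_skipped,
            "per_participant_flags": dict(sorted(self.per_participant_flags.items())),
            "warnings": list(self.warnings),
        }


def read_training_log(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a training-log CSV into typed records.

    Returns ``(records, rejected)``: rows violating the record invariants
    (mean_rt_s <= 0, accuracy outside [0, 1], week < 1, n_trials < 1, or an
    unparseable numeric) are quarantined into ``rejected`` with their
    1-based source line number and a reason — never silently dropped.
    Cells left empty (missing RT/accuracy) are kept as NaN for the
    missingness check.
    """
    df = pd.read_csv(path, comment="#", dtype={"participant_id": str})
    missing_cols = [c for c in REQUIRED_LOG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"training log is missing required column(s): {missing_cols}")

    # 1-based data line numbers (header is line 1)
    lineno = df.index.to_numpy() + 2
    reasons = np.full(len(df), "", dtype=object)

    for col in NUMERIC_LOG_COLUMNS:
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna()
        for i in np.flatnonzero(bad.to_numpy()):
            reasons[i] = reasons[i] or f"unparseable {col}={raw.iloc[i]!r}"
        df[col] = num

    def _violates(mask: pd.Series, label: str) -> None:
        for i in np.flatnonzero(mask.to_numpy()):
            reasons[i] = reasons[i] or label

    _violates(df["mean_rt_s"].notna() & (df["mean_rt_s"] <= 0), "mean_rt_s <= 0")
    _violates(df["accuracy"].notna() & ((df["accuracy"] < 0) | (df["accuracy"] > 1)),
              "accuracy outside [0, 1]")
    _violates(df["week"].notna() & (df["week"] < 1), "week < 1")
    _violates(df["n_trials"].notna() & (df["n_trials"] < 1), "n_trials < 1")

    bad_mask = reasons != ""
    rejected = df.loc[bad_mask].copy()
    rejected["line"] = lineno[bad_mask]
    rejected["reason"] = reasons[bad_mask]
    records = df.loc[~bad_mask].reset_index(drop=True)
    return records, rejected


def read_participants(path: str | Path) -> pd.DataFrame:
    """Read a participant table; `rho_true` is optional (synthetic only)."""
    df = pd.read_csv(path, comment="#", dtype={"participant_id": str})
    required = [c for c in PARTICIPANT_COLUMNS if c != "rho_true"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"participant table missing column(s): {missing_cols}")
    return df


def check_missing(records: pd.DataFrame) -> PreprocessReport:
    """Count absent mean-RT / accuracy cells (a fragment of the full report)."""
    rep = PreprocessReport(n_records_in=len(records))
    if len(records):
        rep.n_missing_rt = int(records["mean_rt_s"].isna().sum())
        rep.n_missing_accuracy = int(records["accuracy"].isna().sum())
    rep.n_records_out = rep.n_records_in
    return rep


def mad_flags(values, k: float = 3.0, scale: float = 1.4826) -> np.ndarray:
    """Boolean mask of MAD-rule outliers in a 1-D series.

    Flags ``v`` iff ``|v - median| > k * scale * MAD``.  With a zero MAD the
    rule degenerates; nothing is flagged and a warning is emitted.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("mad_flags requires a non-empty series")
    if k <= 0:
        raise ValueError("k must be > 0")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        warnings.warn("MAD is zero (near-constant series); no values flagged",
                      UserWarning, stacklevel=2)
        return np.zeros(v.shape, dtype=bool)
    return np.abs(v - med) > k * scale * mad


def apply_outlier_filter(records: pd.DataFrame,
                         config: PreprocessConfig | None = None
                         ) -> tuple[pd.DataFrame, PreprocessReport]:
    """Apply the MAD rule to each participant's RT and accuracy series.

    A record is removed when flagged on either series.  Rows with missing
    RT or accuracy are counted, excluded from flagging, and dropped from the
    output (report-and-exclude; no imputation).  Participants with fewer
    records than ``config.min_records`` are skipped from flagging and noted.
    With ``config.pooled`` the rule instead runs once on the pooled cohort
    series.
    """
    cfg = config or PreprocessConfig()
    rep = check_missing(records)
    rep.n_records_in = len(records)

    complete = records.dropna(subset=["mean_rt_s", "accuracy"])
    flag_rt = pd.Series(False, index=complete.index)
    flag_acc = pd.Series(False, index=complete.index)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if cfg.pooled:
            if len(complete) >= cfg.min_records:
                flag_rt[:] = mad_flags(complete["mean_rt_s"], cfg.k, cfg.scale)
                flag_acc[:] = mad_flags(complete["accuracy"], cfg.k, cfg.scale)
            else:
                rep.n_participants_skipped = complete["participant_id"].nunique()
        else:
            for pid, grp in complete.groupby("participant_id", sort=False):
                if len(grp) < cfg.min_records:
                    rep.n_participants_skipped += 1
                    continue
                flag_rt.loc[grp.index] = mad_flags(grp["mean_rt_s"], cfg.k, cfg.scale)
                flag_acc.loc[grp.index] = mad_flags(grp["accuracy"], cfg.k, cfg.scale)
    rep.warnings = [str(w.message) for w in caught]

    rep.n_flagged_rt = int(flag_rt.sum())
    rep.n_flagged_accuracy = int(flag_acc.sum())
    removed = flag_rt | flag_acc
    for pid, cnt in complete.loc[removed, "participant_id"].value_counts().items():
        rep.per_participant_flags[str(pid)] = int(cnt)

    filtered = complete.loc[~removed].reset_index(drop=True)
    rep.n_records_out = len(filtered)
    return filtered, rep


def preprocess(records: pd.DataFrame,
               config: PreprocessConfig | None = None
               ) -> tuple[pd.DataFrame, PreprocessReport]:
    """Missingness check followed by the outlier filter; one merged report."""
    return apply_outlier_filter(records, config)
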