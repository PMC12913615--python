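"""Synthetic cohort generator for adaptive cognitive-training trials.

Emulates the data structure of a 24-week multi-domain-intervention trial in
older adults with mild cognitive impairment: a participant table (baseline
covariates, week-24 RBANS outcome, blood-biomarker changes) and a
long-format training log (one row per 3-minute game task with its mean
reaction time and accuracy).

The generative model plants a per-participant latent coupling
``rho_p in (-1, 1)`` between task-level mean RT and accuracy: each task
draws a bivariate standard-normal latent with correlation ``rho_p``; the RT
latent maps through a lognormal transform (positive, small log-scale so the
Pearson correlation of the pair stays within <1% of ``rho_p``) and the
accuracy latent through a linear link clipped to [0, 1].  Task difficulty
follows an up/down staircase on accuracy, clamped to configured bounds; by
default difficulty does not shift the performance distributions, so the
planted coupling is exactly the population RT-accuracy correlation.

Outcomes are generated from planted linear effects: the week-24 RBANS score
is the baseline plus a linear function of covariates and ``rho_p`` plus
Gaussian noise, and each biomarker change is linear in ``rho_p``.  All
randomness flows from ``CohortConfig.seed`` through named substreams, so a
fixed config reproduces the cohort bit-for-bit.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import GameCatalogEntry, default_catalog
from .config import CohortConfig

PARTICIPANT_COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "education_years",
    "apoe_e4",
    "rbans_baseline",
    "rbans_week24",
    "bdnf_change",
    "ptau_change",
    "nfl_change",
    "gfap_change",
    "rho_true",
]

TRAINING_LOG_COLUMNS = [
    "participant_id",
    "week",
    "session_index",
    "task_index",
    "game_id",
    "domain",
    "difficulty",
    "mean_rt_s",
    "accuracy",
    "n_trials",
]

# substream tags so each generation stage has its own independent stream
_STREAM_PARTICIPANTS = 1
_STREAM_TRAINING = 2
_STREAM_OUTCOMES = 3


def _rng(config: CohortConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *tags]))


def _participant_index(participant_id: str) -> int:
    digits = "".join(ch for ch in str(participant_id) if ch.isdigit())
    if not digits:
        raise ValueError(f"cannot derive stream index from id {participant_id!r}")
    return int(digits)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_participants(config: CohortConfig,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw baseline covariates and the latent coupling for a cohort.

    Outcome and biomarker columns are left NaN; fill them with
    :func:`simulate_outcomes`.  Covariates are independent: truncated
    normals for age (eligibility window) and education, a plain normal for
    baseline RBANS, Bernoullis for sex (1 = female) and APOE e4 carriage.
    """
    n = config.n_participants
    cv = config.covariates
    rng = rng if rng is not None else _rng(config, _STREAM_PARTICIPANTS)

    age = _truncnorm(rng, cv.age_mean, cv.age_sd, *cv.age_bounds, size=n)
    education = _truncnorm(rng, cv.education_mean, cv.education_sd,
                           *cv.education_bounds, size=n)
    sex = (rng.random(n) < cv.p_female).astype(int)
    apoe = (rng.random(n) < cv.p_apoe_e4).astype(int)
    rbans0 = rng.normal(cv.rbans_baseline_mean, cv.rbans_baseline_sd, size=n)
    rho = _truncnorm(rng, config.coupling.mean, config.coupling.sd,
                     -1.0, 1.0, size=n)

    df = pd.DataFrame({
        "participant_id": [f"P{i + 1:04d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "education_years": education,
        "apoe_e4": apoe,
        "rbans_baseline": rbans0,
        "rbans_week24": np.nan,
        "bdnf_change": np.nan,
        "ptau_change": np.nan,
        "nfl_change": np.nan,
        "gfap_change": np.nan,
        "rho_true": rho,
    })
    return df


def _staircase(accuracy: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Difficulty level before each task, given the accuracy sequence."""
    d = config.difficulty
    levels = np.empty(accuracy.shape[0], dtype=np.int64)
    level = d.level_start
    up, down, lo, hi = d.up_threshold, d.down_threshold, d.level_min, d.level_max
    acc = accuracy.tolist()
    for t, a in enumerate(acc):
        levels[t] = level
        if a >= up:
            level = min(level + 1, hi)
        elif a < down:
            level = max(level - 1, lo)
    return levels


def _simulate_one_stream(rho: float, config: CohortConfig,
                         rng: np.random.Generator,
                         catalog: Sequence[GameCatalogEntry]) -> dict[str, np.ndarray]:
    """Array-valued training stream for one participant (no id column)."""
    sched = config.schedule
    sessions = rng.integers(sched.sessions_min, sched.sessions_max + 1,
                            size=config.n_weeks)
    tps = sched.tasks_per_session
    tasks_per_week = sessions * tps
    total = int(tasks_per_week.sum())

    week = np.repeat(np.arange(1, config.n_weeks + 1), tasks_per_week)
    session_index = np.concatenate([
        np.repeat(np.arange(1, s + 1), tps) for s in sessions
    ]) if total else np.empty(0, dtype=np.int64)
    task_index = np.tile(np.arange(1, tps + 1), total // tps) if total else np.empty(0, dtype=np.int64)

    trials = rng.integers(sched.trials_min, sched.trials_max + 1, size=total)
    z_acc = rng.standard_normal(total)
    z_rt = rho * z_acc + math.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(total)
    # bounded task-level latents: a 3-minute task score is an average over
    # many trials, so its tails are light and gross outliers do not occur
    b = config.coupling.latent_bound
    z_acc = np.clip(z_acc, -b, b)
    z_rt = np.clip(z_rt, -b, b)

    acc_p, rt_p, dif = config.accuracy, config.rt, config.difficulty
    if acc_p.level_slope == 0.0 and rt_p.level_slope == 0.0:
        accuracy = np.clip(acc_p.mean + acc_p.sd * z_acc, 0.0, 1.0)
        mean_rt = np.maximum(rt_p.floor_s,
                             np.exp(math.log(rt_p.location_s) + rt_p.sigma * z_rt))
        levels = _staircase(accuracy, config)
    else:
        # difficulty feeds back into performance: step sequentially
        accuracy = np.empty(total)
        mean_rt = np.empty(total)
        levels = np.empty(total, dtype=np.int64)
        level = dif.level_start
        for t in range(total):
            levels[t] = level
            a = acc_p.mean + acc_p.level_slope * (level - dif.level_min) + acc_p.sd * z_acc[t]
            a = min(1.0, max(0.0, a))
            accuracy[t] = a
            lr = math.log(rt_p.location_s) + rt_p.level_slope * (level - dif.level_min)
            mean_rt[t] = max(rt_p.floor_s, math.exp(lr + rt_p.sigma * z_rt[t]))
            if a >= dif.up_threshold:
                level = min(level + 1, dif.level_max)
            elif a < dif.down_threshold:
                level = max(level - 1, dif.level_min)

    n_games = len(catalog)
    game_idx = np.arange(total) % n_games
    return {
        "week": week,
        "session_index": session_index,
        "task_index": task_index,
        "game_idx": game_idx,
        "difficulty": levels,
        "mean_rt_s": mean_rt,
        "accuracy": accuracy,
        "n_trials": trials,
    }


def simulate_training_stream(profile: Mapping, config: CohortConfig,
                             rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate the full 24-week task stream for one participant.

    ``profile`` must carry ``participant_id`` and the planted coupling
    ``rho_true``.  When ``rng`` is omitted, a per-participant substream is
    derived from the config seed and the numeric part of the id, so streams
    are reproducible participant-by-participant.
    """
    rho = float(profile["rho_true"])
    if not -1.0 < rho < 1.0 or not np.isfinite(rho):
        raise ValueError("profile needs a planted rho_true in (-1, 1)")
    pid = str(profile["participant_id"])
    if rng is None:
        rng = _rng(config, _STREAM_TRAINING, _participant_index(pid))
    catalog = default_catalog()
    arrays = _simulate_one_stream(rho, config, rng, catalog)
    n = arrays["week"].shape[0]
    game_ids = np.array([e.game_id for e in catalog], dtype=object)
    domains = np.array([e.domain for e in catalog], dtype=object)
    return pd.DataFrame({
        "participant_id": np.repeat(np.array([pid], dtype=object), n),
        "week": arrays["week"],
        "session_index": arrays["session_index"],
        "task_index": arrays["task_index"],
        "game_id": game_ids[arrays["game_idx"]],
        "domain": domains[arrays["game_idx"]],
        "difficulty": arrays["difficulty"],
        "mean_rt_s": arrays["mean_rt_s"],
        "accuracy": arrays["accuracy"],
        "n_trials": arrays["n_trials"],
    })


def simulate_cohort_streams(participants: pd.DataFrame,
                            config: CohortConfig) -> pd.DataFrame:
    """Training log for a whole cohort (concatenated per-participant streams)."""
    catalog = default_catalog()
    game_ids = np.array([e.game_id for e in catalog], dtype=object)
    domains = np.array([e.domain for e in catalog], dtype=object)
    chunks: list[dict[str, np.ndarray]] = []
    ids: list[np.ndarray] = []
    for pid, rho in zip(participants["participant_id"], participants["rho_true"]):
        rng = _rng(config, _STREAM_TRAINING, _participant_index(pid))
        arrays = _simulate_one_stream(float(rho), config, rng, catalog)
        chunks.append(arrays)
        ids.append(np.repeat(np.array([str(pid)], dtype=object),
                             arrays["week"].shape[0]))
    if not chunks:
        return pd.DataFrame(columns=TRAINING_LOG_COLUMNS)
    cat = {k: np.concatenate([c[k] for c in chunks]) for k in chunks[0]}
    return pd.DataFrame({
        "participant_id": np.concatenate(ids),
        "week": cat["week"],
        "session_index": cat["session_index"],
        "task_index": cat["task_index"],
        "game_id": game_ids[cat["game_idx"]],
        "domain": domains[cat["game_idx"]],
        "difficulty": cat["difficulty"],
        "mean_rt_s": cat["mean_rt_s"],
        "accuracy": cat["accuracy"],
        "n_trials": cat["n_trials"],
    })


def simulate_outcomes(participants: pd.DataFrame, config: CohortConfig,
                      rho_true: np.ndarray | None = None,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Fill outcome and biomarker columns from the planted linear effects.

    ``rho_true`` defaults to the cohort's planted couplings.  The outcome
    model on the RBANS change scale is

        change = b0 + b1*age + b2*sex + b3*education + b4*apoe
                 + b5*baseline + b6*rho_p + sum_m c_m * marker_change_m + eps

    and each marker change is ``a_m + b_m * rho_p + eps_m``.  The default
    marker-to-outcome weights ``c_m`` are zero.
    """
    df = participants.copy()
    if rho_true is None:
        rho = df["rho_true"].to_numpy(dtype=float)
    else:
        rho = np.asarray(rho_true, dtype=float)
        if rho.shape[0] != len(df):
            raise ValueError(
                f"rho_true has length {rho.shape[0]} but cohort has {len(df)} participants")
    rng = rng if rng is not None else _rng(config, _STREAM_OUTCOMES)

    marker_effect = np.zeros(len(df))
    for name, path in config.biomarkers.items():
        eps_m = rng.normal(0.0, path.residual_sd, size=len(df))
        change_m = path.intercept + path.coupling_to_marker * rho + eps_m
        df[f"{name}_change"] = change_m
        marker_effect = marker_effect + path.marker_to_outcome * change_m

    oc = config.outcome
    eps = rng.normal(0.0, oc.residual_sd, size=len(df))
    change = (oc.b0
              + oc.b1_age * df["age"].to_numpy(float)
              + oc.b2_sex * df["sex"].to_numpy(float)
              + oc.b3_education * df["education_years"].to_numpy(float)
              + oc.b4_apoe * df["apoe_e4"].to_numpy(float)
              + oc.b5_baseline * df["rbans_baseline"].to_numpy(float)
              + oc.b6_coupling * rho
              + marker_effect
              + eps)
    df["rbans_week24"] = df["rbans_baseline"].to_numpy(float) + change
    return df


def generate_cohort_frames(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Participants (with outcomes) and training log as in-memory frames."""
    participants = generate_participants(config)
    participants = simulate_outcomes(participants, config)
    log = simulate_cohort_streams(participants, config)
    return participants, log


def generate_cohort(config: CohortConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write ``participants.csv``, ``training_log.csv`` and a JSON sidecar.

    Outputs are byte-identical under a fixed config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    participants, log = generate_cohort_frames(config)
    paths = {
        "participants": out / "participants.csv",
        "training_log": out / "training_log.csv",
        "config": out / "cohort_config.json",
    }
    participants.to_csv(paths["participants"], index=False)
    log.to_csv(paths["training_log"], index=False)
    sidecar = {"config": config.to_dict(), "config_hash": config.config_hash(),
               "seed": config.seed}
    paths["config"].write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return paths
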