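"""End-to-end orchestration: simulate/ingest -> preprocess -> RTACC -> models.

Each stage writes its artifacts into the run directory as it completes, so
a failing stage leaves the earlier outputs in place; every artifact carries
the run's config hash (a leading ``#`` comment line in CSVs, a field in
JSON).  Two runs with the same config and seed produce byte-identical
numeric artifacts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, models, preprocess, simulate
from .config import RunConfig

logger = logging.getLogger(__name__)

ARTIFACTS = [
    "preprocess_report.json",
    "rtacc_values.csv",
    "table3_like.csv",
    "table4_like.csv",
    "table5_like.csv",
    "responders_auc.json",
]

_STREAM_BOOTSTRAP = 4


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def summarize_cohort(profiles: pd.DataFrame) -> pd.DataFrame:
    """Baseline demographics table: mean (SD) for continuous fields,
    n (%) for binary ones, plus the mean RBANS change."""
    if profiles.empty:
        raise ValueError("cannot summarize an empty cohort")
    n = len(profiles)
    change = profiles["rbans_week24"] - profiles["rbans_baseline"]

    def cont(series: pd.Series) -> tuple[float, float]:
        return float(series.mean()), float(series.std(ddof=1))

    def binary(series: pd.Series) -> tuple[float, float]:
        cnt = float(series.sum())
        return cnt, 100.0 * cnt / n

    rows = []
    for label, (a, b), kind in [
        ("Years of age", cont(profiles["age"]), "mean_sd"),
        ("Education years", cont(profiles["education_years"]), "mean_sd"),
        ("Female, n", binary(profiles["sex"]), "n_pct"),
        ("APOE e4, n", binary(profiles["apoe_e4"]), "n_pct"),
        ("RBANS baseline", cont(profiles["rbans_baseline"]), "mean_sd"),
        ("RBANS at 24th week", cont(profiles["rbans_week24"]), "mean_sd"),
        ("RBANS change", cont(change), "mean_sd"),
    ]:
        rows.append({"statistic": label, "value": a,
                     "sd_or_pct": b, "kind": kind})
    return pd.DataFrame(rows)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("simulate")
def _stage_simulate(config: RunConfig, out: Path, chash: str):
    if config.participants_csv and config.training_log_csv:
        profiles = preprocess.read_participants(config.participants_csv)
        log, rejected = preprocess.read_training_log(config.training_log_csv)
    else:
        profiles, log = simulate.generate_cohort_frames(config.cohort)
        rejected = log.iloc[0:0]
        _write_csv(profiles, out / "participants.csv", chash)
        _write_csv(log, out / "training_log.csv", chash)
        cfg_dict = config.to_dict()
        cfg_dict.pop("output_dir", None)  # location is not part of the analysis
        sidecar = {"config": cfg_dict, "config_hash": chash,
                   "seed": config.seed}
        (out / "cohort_config.json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True))
    return profiles, log, rejected


@_stage("preprocess")
def _stage_preprocess(config: RunConfig, out: Path, chash: str, log, rejected):
    filtered, report = preprocess.preprocess(log, config.preprocess)
    report.n_rejected_rows = len(rejected)
    payload = report.to_dict()
    payload["config_hash"] = chash
    (out / "preprocess_report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True))
    _write_csv(rejected, out / "rejected_rows.csv", chash)
    return filtered, report


@_stage("rtacc")
def _stage_rtacc(config: RunConfig, out: Path, chash: str, filtered):
    mc = config.metrics
    win = metrics.rtacc_windows(filtered, mc.windows, mc.min_pairs, mc.correlation)
    logo = metrics.rtacc_leave_one_game_out(
        filtered, window_weeks=max(mc.windows),
        min_pairs=mc.min_pairs, method=mc.correlation)
    values = pd.concat([win, logo], ignore_index=True)
    _write_csv(values, out / "rtacc_values.csv", chash)
    return values


@_stage("fit")
def _stage_fit(config: RunConfig, out: Path, chash: str, profiles, values):
    mc, mo = config.metrics, config.models
    full_window = max(mc.windows)

    window_rows = []
    for w in mc.windows:
        table = models.build_analysis_table(profiles, values, window_weeks=w)
        fit = models.fit_linear_rbans(table)
        window_rows.append({
            "window_weeks": w, "model": "ols", "n_obs": fit.n_obs,
            "rtacc_beta": fit.coef("rtacc"), "rtacc_se": fit.se("rtacc"),
            "rtacc_t": fit.t_or_z[fit.terms.index("rtacc")],
            "rtacc_p": fit.pvalue("rtacc"),
        })
    table_full = models.build_analysis_table(profiles, values,
                                             window_weeks=full_window)
    rlm = models.fit_robust_rbans(table_full, tuning=mo.huber_t)
    window_rows.append({
        "window_weeks": full_window, "model": "rlm", "n_obs": rlm.n_obs,
        "rtacc_beta": rlm.coef("rtacc"), "rtacc_se": rlm.se("rtacc"),
        "rtacc_t": rlm.t_or_z[rlm.terms.index("rtacc")],
        "rtacc_p": rlm.pvalue("rtacc"),
    })
    table3 = pd.DataFrame(window_rows)
    _write_csv(table3, out / "table3_like.csv", chash)

    excl_rows = []
    for entry in metrics.default_catalog():
        t = models.build_analysis_table(profiles, values,
                                        window_weeks=full_window,
                                        excluded_game=entry.game_id)
        fit = models.fit_linear_rbans(t)
        excl_rows.append({
            "excluded_game": entry.game_id, "domain": entry.domain,
            "n_obs": fit.n_obs,
            "rtacc_beta": fit.coef("rtacc"), "rtacc_se": fit.se("rtacc"),
            "rtacc_p": fit.pvalue("rtacc"),
        })
    table4 = pd.DataFrame(excl_rows)
    _write_csv(table4, out / "table4_like.csv", chash)

    path_full = models.fit_path_model(table_full,
                                      adjust_covariates=mo.adjust_covariates)
    path_pruned = models.prune_path_model(path_full, alpha=mo.alpha)
    t5 = path_full.to_frame()
    t5["retained_after_pruning"] = [
        p in path_pruned.retained_paths
        for p in path_full.retained_paths
    ]
    _write_csv(t5, out / "table5_like.csv", chash)

    labels = metrics.label_responders(table_full)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed,
                                                        _STREAM_BOOTSTRAP]))
    responders = models.fit_responder_models(table_full, labels,
                                             bootstrap_reps=mo.bootstrap_reps,
                                             rng=rng)
    payload = {
        "config_hash": chash,
        "models": [{
            "model_id": r.model_id,
            "terms": r.fit.terms,
            "auc": r.auc,
            "auc_ci_95": list(r.auc_ci),
            "n_good": r.n_good,
            "n_poor": r.n_poor,
            "separation": r.separation,
        } for r in responders],
    }
    (out / "responders_auc.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True))
    return table_full, table3, table4, path_full, path_pruned, responders


@_stage("report")
def _stage_report(config: RunConfig, out: Path, chash: str, profiles,
                  report, table_full, table3, table4,
                  path_full, path_pruned, responders):
    summary = summarize_cohort(profiles)
    lines = [
        "# RTACC pipeline report",
        f"\nConfig hash: `{chash}`; seed {config.seed}; "
        f"n = {len(profiles)} participants.",
        "\n## Cohort summary\n",
        summary.to_markdown(index=False),
        "\n## Preprocessing\n",
        f"- records in: {report.n_records_in}; out: {report.n_records_out}",
        f"- missing RT: {report.n_missing_rt}; "
        f"missing accuracy: {report.n_missing_accuracy}",
        f"- MAD-flagged RT: {report.n_flagged_rt}; "
        f"accuracy: {report.n_flagged_accuracy}",
    ]
    for w in report.warnings:
        lines.append(f"- warning: {w}")
    lines += [
        "\n## RTACC vs week-24 RBANS (window sensitivity)\n",
        table3.to_markdown(index=False),
        "\n## Leave-one-game-out sensitivity\n",
        table4.to_markdown(index=False),
        "\n## Path model (RTACC -> biomarker changes -> RBANS)\n",
        path_full.to_frame().assign(
            retained=[p in path_pruned.retained_paths
                      for p in path_full.retained_paths]).to_markdown(index=False),
        f"\nDirect effect after pruning: {path_pruned.direct_effect:.3f} "
        f"(SE {path_pruned.direct_se:.3f}, p = {path_pruned.direct_p:.4f}); "
        f"pruned paths: {[p for p, _ in path_pruned.pruning_trace]}",
        "\n## Good-responder classification\n",
    ]
    for r in responders:
        lines.append(f"- Model {r.model_id}: AUC {r.auc:.3f} "
                     f"(95% CI {r.auc_ci[0]:.3f}-{r.auc_ci[1]:.3f}); "
                     f"{r.n_good} good / {r.n_poor} poor")
        if r.separation:
            lines.append("  - warning: possible complete separation")
    (out / "report.md").write_text("\n".join(lines) + "\n")

    _plot_figures(out, table_full, responders)


def _plot_figures(out: Path, table_full: pd.DataFrame, responders) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # plotting is best-effort
        logger.warning("matplotlib unavailable; skipping figures")
        return
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(table_full["rtacc"], table_full["rbans_change"], s=14, alpha=0.7)
    ax.set_xlabel("RTACC")
    ax.set_ylabel("RBANS change (week 24 - baseline)")
    fig.tight_layout()
    fig.savefig(out / "scatter_rtacc_rbans.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for r in responders:
        if r.scores is None or r.labels is None:
            continue
        ax.plot(*_roc_curve(np.asarray(r.scores), r.labels),
                label=f"Model {r.model_id} (AUC {r.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "roc_responders.png", dpi=120)
    plt.close(fig)


def _roc_curve(scores: np.ndarray, labels) -> tuple[np.ndarray, np.ndarray]:
    if labels is None:
        return np.array([0, 1]), np.array([0, 1])
    y = np.asarray(labels).astype(bool)
    order = np.argsort(-np.asarray(scores))
    tp = np.concatenate([[0], np.cumsum(y[order])])
    fp = np.concatenate([[0], np.cumsum(~y[order])])
    return fp / max(1, fp[-1]), tp / max(1, tp[-1])


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run all stages and return the artifact paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    profiles, log, rejected = _stage_simulate(config, out, chash)
    filtered, report = _stage_preprocess(config, out, chash, log, rejected)
    values = _stage_rtacc(config, out, chash, filtered)
    (table_full, table3, table4,
     path_full, path_pruned, responders) = _stage_fit(config, out, chash,
                                                      profiles, values)
    _stage_report(config, out, chash, profiles, report, table_full,
                  table3, table4, path_full, path_pruned, responders)
    return {name: out / name for name in ARTIFACTS} | {"report": out / "report.md"}
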