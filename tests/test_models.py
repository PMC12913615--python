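import numpy as np
import pandas as pd
import pytest

from rtacc import (
    CohortConfig,
    bootstrap_auc_ci,
    build_analysis_table,
    fit_linear_rbans,
    fit_path_model,
    fit_responder_models,
    fit_robust_rbans,
    label_responders,
    prune_path_model,
    roc_auc,
    rtacc_table,
)
from rtacc.config import BiomarkerPath, OutcomeParams
from rtacc.models import LINEAR_TERMS, _design

from conftest import make_planted_table


def random_table(rng, n=80):
    return pd.DataFrame({
        "participant_id": [f"P{i:04d}" for i in range(n)],
        "age": rng.normal(73, 5, n),
        "sex": rng.integers(0, 2, n).astype(float),
        "education_years": rng.normal(11, 4, n),
        "apoe_e4": rng.integers(0, 2, n).astype(float),
        "rbans_baseline": rng.normal(90, 15, n),
        "rtacc": rng.normal(-0.1, 0.2, n),
        "rbans_week24": rng.normal(98, 16, n),
    })


# --------------------------------------------------------- analysis table

def test_analysis_table_conserves_participants(cohort):
    participants, log = cohort
    values = rtacc_table(log)
    table = build_analysis_table(participants, values)
    n_defined = int(values["defined"].sum())
    assert len(table) == n_defined
    assert len(table) + table.attrs["n_dropped"] == len(values)


def test_analysis_table_unknown_window_is_an_error(cohort):
    participants, log = cohort
    values = rtacc_table(log)
    with pytest.raises(ValueError, match="window=3"):
        build_analysis_table(participants, values, window_weeks=3)


# ------------------------------------------------------------------- OLS

def test_noiseless_planted_table_recovered_exactly():
    cfg = CohortConfig(seed=3, outcome=OutcomeParams(residual_sd=0.0))
    table = make_planted_table(cfg)
    fit = fit_linear_rbans(table)
    oc = cfg.outcome
    planted = {
        "intercept": oc.b0, "age": oc.b1_age, "sex": oc.b2_sex,
        "education_years": oc.b3_education, "apoe_e4": oc.b4_apoe,
        "rbans_baseline": 1.0 + oc.b5_baseline, "rtacc": oc.b6_coupling,
    }
    for term, truth in planted.items():
        assert fit.coef(term) == pytest.approx(truth, rel=1e-8)


def test_ols_matches_normal_equations_oracle():
    rng = np.random.default_rng(12)
    for _ in range(20):
        table = random_table(rng)
        fit = fit_linear_rbans(table)
        X = _design(table, LINEAR_TERMS)
        beta = np.linalg.solve(X.T @ X, X.T @ table["rbans_week24"].to_numpy())
        assert np.allclose(fit.coefficients, beta, atol=1e-8)


def test_collinear_term_is_named():
    rng = np.random.default_rng(0)
    table = random_table(rng)
    table["rtacc"] = 0.25  # constant: collinear with the intercept
    with pytest.raises(ValueError, match="collinear"):
        fit_linear_rbans(table)


# ------------------------------------------------------------------- RLM

def test_huber_equals_ols_when_all_weights_are_one():
    """Residuals bounded inside the Huber threshold -> identical fits."""
    rng = np.random.default_rng(5)
    table = random_table(rng, n=120)
    X = _design(table, LINEAR_TERMS)
    beta = np.arange(1.0, 8.0)
    # two-point noise: every |residual| sits near the MAD itself, far below
    # the 1.345 * (1.4826 * MAD) Huber threshold, so every weight is 1
    noise = rng.choice([-4.0, 4.0], len(table))
    table["rbans_week24"] = X @ beta + noise
    ols = fit_linear_rbans(table)
    rlm = fit_robust_rbans(table)
    assert rlm.converged
    assert np.max(np.abs(ols.coefficients - rlm.coefficients)) < 1e-6


def test_huber_limit_recovers_ols():
    rng = np.random.default_rng(6)
    table = random_table(rng)
    ols = fit_linear_rbans(table)
    rlm = fit_robust_rbans(table, tuning=1e9)
    assert np.max(np.abs(ols.coefficients - rlm.coefficients)) < 1e-8


def test_huber_resists_a_gross_outlier():
    cfg = CohortConfig(seed=8, outcome=OutcomeParams(residual_sd=2.0))
    table = make_planted_table(cfg)
    table.loc[table.index[:13], "rbans_week24"] += 50.0
    ols = fit_linear_rbans(table)
    rlm = fit_robust_rbans(table)
    truth = cfg.outcome.b6_coupling
    assert abs(rlm.coef("rtacc") - truth) < abs(ols.coef("rtacc") - truth)


# ------------------------------------------------------------- path model

def test_noiseless_path_system_exact():
    """Planted recursive system with in-sample-orthogonal disturbances.

    Marker disturbances are residualized against RTACC so every equation of
    the system is an exact least-squares solution: all path coefficients
    are recovered to numerical precision.  (Exactly zero marker noise would
    make the markers collinear with RTACC in the outcome equation.)
    """
    rng = np.random.default_rng(4)
    n = 130
    x = rng.normal(-0.1, 0.2, n)
    xc = x - x.mean()
    planted_b = {"bdnf": -3.132, "ptau": 2.832, "nfl": 3.879, "gfap": -31.69}
    planted_c = {"bdnf": -0.118, "ptau": -0.014, "nfl": 0.12, "gfap": -0.015}
    direct = -11.98
    table = pd.DataFrame({"participant_id": [f"P{i:04d}" for i in range(n)],
                          "rtacc": x})
    outcome = direct * x
    for m, b in planted_b.items():
        e = rng.normal(0, 1, n)
        e = e - e.mean() - (e @ xc) / (xc @ xc) * xc  # orthogonal to [1, x]
        table[f"{m}_change"] = b * x + e
        outcome = outcome + planted_c[m] * table[f"{m}_change"]
    table["rbans_change"] = outcome
    pm = fit_path_model(table, adjust_covariates=False)
    for m, b in planted_b.items():
        assert pm.path_coef(("rtacc", m)) == pytest.approx(b, rel=1e-8)
        assert pm.path_coef((m, "rbans")) == pytest.approx(planted_c[m], rel=1e-6)
    assert pm.direct_effect == pytest.approx(direct, rel=1e-6)


def test_indirect_effects_are_exact_products(analysis_table):
    pm = fit_path_model(analysis_table)
    for m, eff in pm.indirect_effects.items():
        assert eff == pm.path_coef(("rtacc", m)) * pm.path_coef((m, "rbans"))


def test_missing_marker_column_is_an_error(analysis_table):
    with pytest.raises(ValueError, match="tau"):
        fit_path_model(analysis_table.drop(columns=["ptau_change"]))


def test_prune_alpha_one_is_identity(analysis_table):
    pm = fit_path_model(analysis_table)
    pruned = prune_path_model(pm, alpha=1.0)
    assert pruned.retained_paths == pm.retained_paths
    assert pruned.pruning_trace == []


def test_prune_trace_conserves_path_count(analysis_table):
    pm = fit_path_model(analysis_table)
    pruned = prune_path_model(pm, alpha=0.05)
    assert len(pruned.pruning_trace) == \
        len(pm.retained_paths) - len(pruned.retained_paths)
    assert ("rtacc", "rbans") in pruned.retained_paths  # direct path kept


# -------------------------------------------------------------------- ROC

def test_auc_by_concordant_pair_counting():
    scores = [0.9, 0.4, 0.8, 0.3, 0.2]
    labels = [1, 1, 0, 0, 0]
    # 0.9 beats all 3 negatives, 0.4 beats 2 of 3 -> 5 of 6 pairs
    assert roc_auc(scores, labels) == pytest.approx(5 / 6)


def test_auc_edge_cases():
    assert roc_auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0
    assert roc_auc([5, 5, 5, 5], [1, 1, 0, 0]) == 0.5
    with pytest.raises(ValueError, match="both classes"):
        roc_auc([1, 2], [1, 1])


def test_bootstrap_ci_is_seeded_and_brackets_the_point_estimate():
    rng = np.random.default_rng(3)
    scores = np.concatenate([rng.normal(1, 1, 60), rng.normal(0, 1, 40)])
    labels = np.concatenate([np.ones(60), np.zeros(40)])
    ci1 = bootstrap_auc_ci(scores, labels, reps=500,
                           rng=np.random.default_rng(11))
    ci2 = bootstrap_auc_ci(scores, labels, reps=500,
                           rng=np.random.default_rng(11))
    assert ci1 == ci2
    auc = roc_auc(scores, labels)
    assert ci1[0] <= auc <= ci1[1]


# -------------------------------------------------------- responder models

def test_responder_models_nested_deviance_and_terms(analysis_table):
    labels = label_responders(analysis_table)
    res = {r.model_id: r for r in
           fit_responder_models(analysis_table, labels, bootstrap_reps=100,
                                rng=np.random.default_rng(2))}
    assert res[3].fit.deviance <= res[1].fit.deviance + 1e-9
    assert res[3].fit.deviance <= res[2].fit.deviance + 1e-9
    assert set(res[3].fit.terms) == set(res[1].fit.terms) | {"rtacc"}
    for r in res.values():
        assert 0.0 <= r.auc <= 1.0
        assert r.auc_ci[0] <= r.auc <= r.auc_ci[1]


def test_single_class_labels_rejected(analysis_table):
    labels = label_responders(analysis_table)
    labels["label"] = "good"
    with pytest.raises(ValueError, match="good and .*poor|poor"):
        fit_responder_models(analysis_table, labels, bootstrap_reps=10)


def test_perfect_separation_is_flagged(analysis_table):
    t = analysis_table.copy()
    t["rtacc"] = np.where(t["rbans_change"] > 0, 1.0, -1.0)
    labels = label_responders(t)
    with pytest.warns(UserWarning, match="separation"):
        res = fit_responder_models(t, labels, bootstrap_reps=10,
                                   rng=np.random.default_rng(0))
    by_id = {r.model_id: r for r in res}
    assert by_id[2].separation and by_id[2].auc == pytest.approx(1.0)
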