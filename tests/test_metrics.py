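import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtacc import (
    compute_rtacc,
    default_catalog,
    label_responders,
    pearson_corr,
    rtacc_leave_one_game_out,
    rtacc_windows,
)

from conftest import python_pearson


def make_records(pid, rts, accs, weeks=None, games=None):
    n = len(rts)
    return pd.DataFrame({
        "participant_id": [pid] * n,
        "week": weeks if weeks is not None else [1] * n,
        "session_index": [1] * n,
        "task_index": list(range(1, n + 1)),
        "game_id": games if games is not None else ["g"] * n,
        "domain": ["attention"] * n,
        "difficulty": [1] * n,
        "mean_rt_s": rts,
        "accuracy": accs,
        "n_trials": [10] * n,
    })


# ------------------------------------------------------------- pearson_corr

def test_pearson_perfect_and_anti_correlation():
    assert pearson_corr([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
    assert pearson_corr([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)


def test_pearson_matches_sum_formula_oracle():
    xs = [1.2, 0.8, 1.5, 0.9]
    ys = [0.6, 0.9, 0.5, 0.8]
    assert pearson_corr(xs, ys) == pytest.approx(python_pearson(xs, ys), abs=1e-12)


def test_pearson_undefined_cases():
    assert math.isnan(pearson_corr([1, 2], [3, 4]))           # n < 3
    assert math.isnan(pearson_corr([1, 1, 1], [1, 2, 3]))     # zero variance
    with pytest.raises(ValueError):
        pearson_corr([1, 2, 3], [1, 2])


@settings(derandomize=True, max_examples=60)
@given(st.integers(3, 40), st.integers(0, 10_000))
def test_pearson_affine_and_symmetry_invariance(n, seed):
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=n), rng.normal(size=n)
    r = pearson_corr(x, y)
    assert -1.0 <= r <= 1.0
    assert pearson_corr(y, x) == pytest.approx(r, abs=1e-12)
    assert pearson_corr(3.7 * x + 2, y) == pytest.approx(r, abs=1e-10)


# ------------------------------------------------------------ compute_rtacc

def test_exact_linear_dependence_gives_minus_one():
    rts = np.linspace(1.0, 3.0, 20)
    rec = make_records("P1", rts, 0.9 - 0.1 * rts)
    v = compute_rtacc(rec)
    assert v.defined and v.value == pytest.approx(-1.0)
    assert v.n_pairs == 20


def test_degenerate_accuracy_undefined():
    rec = make_records("P1", np.linspace(1, 2, 15), [0.8] * 15)
    v = compute_rtacc(rec)
    assert not v.defined and math.isnan(v.value)


def test_empty_selection_undefined_with_zero_pairs():
    rec = make_records("P1", [1.0] * 12, [0.5] * 12, weeks=[5] * 12)
    v = compute_rtacc(rec, window_weeks=2)
    assert not v.defined and v.n_pairs == 0


def test_too_few_pairs_undefined():
    rec = make_records("P1", [1.0, 1.5, 2.0], [0.9, 0.8, 0.7])
    assert not compute_rtacc(rec, min_pairs=10).defined
    assert compute_rtacc(rec, min_pairs=3).defined


def test_multiple_participants_rejected():
    rec = pd.concat([make_records("P1", [1, 2, 3], [0.1, 0.2, 0.3]),
                     make_records("P2", [1, 2, 3], [0.1, 0.2, 0.3])])
    with pytest.raises(ValueError, match="single participant"):
        compute_rtacc(rec)


def test_permutation_invariance(small_cohort):
    _, log = small_cohort
    one = log[log["participant_id"] == log["participant_id"].iloc[0]]
    shuffled = one.sample(frac=1.0, random_state=0)
    assert compute_rtacc(one).value == pytest.approx(
        compute_rtacc(shuffled).value, abs=1e-12)


def test_rt_rescaling_invariance(small_cohort):
    _, log = small_cohort
    one = log[log["participant_id"] == log["participant_id"].iloc[0]].copy()
    base = compute_rtacc(one).value
    one["mean_rt_s"] *= 3.7
    assert compute_rtacc(one).value == pytest.approx(base, abs=1e-10)


# ------------------------------------------------------------------ windows

def test_window_nesting_and_identity(small_cohort):
    _, log = small_cohort
    table = rtacc_windows(log, windows=[1, 2, 4])
    for pid, grp in table.groupby("participant_id"):
        grp = grp.sort_values("window_weeks")
        assert grp["n_pairs"].is_monotonic_increasing
    full = table[table["window_weeks"] == 4].set_index("participant_id")
    for pid in full.index:
        one = log[log["participant_id"] == pid]
        assert compute_rtacc(one, window_weeks=4).value == \
            pytest.approx(full.loc[pid, "value"], abs=1e-12)


def test_windows_must_be_sorted(small_cohort):
    _, log = small_cohort
    with pytest.raises(ValueError, match="sorted"):
        rtacc_windows(log, windows=[6, 2])


# ------------------------------------------------------- leave-one-game-out

def test_leave_one_game_out_has_18_rows_per_participant(small_cohort):
    _, log = small_cohort
    out = rtacc_leave_one_game_out(log, window_weeks=4)
    counts = out.groupby("participant_id").size()
    assert (counts == 18).all()


def test_excluding_unplayed_game_equals_full_value():
    rng = np.random.default_rng(0)
    rts = rng.uniform(1, 3, 30)
    rec = make_records("P1", rts, 0.9 - 0.05 * rts + rng.normal(0, 0.01, 30),
                       games=["grow_tomatoes"] * 30)
    full = compute_rtacc(rec)
    excl = compute_rtacc(rec, excluded_game="honeycomb")
    assert excl.value == full.value  # identical pair set, bitwise equal


def test_excluding_reverse_coupled_game_matches_direct_recomputation():
    rng = np.random.default_rng(1)
    n = 60
    rts = rng.uniform(1, 3, n)
    acc_neg = np.clip(0.9 - 0.1 * rts + rng.normal(0, 0.02, n), 0, 1)
    neg = make_records("P1", rts, acc_neg, games=["grow_tomatoes"] * n)
    rts2 = rng.uniform(1, 3, n)
    acc_pos = np.clip(0.5 + 0.1 * rts2 + rng.normal(0, 0.02, n), 0, 1)
    pos = make_records("P1", rts2, acc_pos, games=["honeycomb"] * n)
    rec = pd.concat([neg, pos], ignore_index=True)

    excl = compute_rtacc(rec, excluded_game="honeycomb")
    manual = compute_rtacc(neg)
    assert excl.value == pytest.approx(manual.value, abs=1e-12)
    assert excl.value < compute_rtacc(rec).value  # shifts toward the negative coupling


# --------------------------------------------------------------- responders

def test_responder_labels_by_sign_of_change():
    profiles = pd.DataFrame({
        "participant_id": ["A", "B", "C"],
        "rbans_baseline": [90.0, 90.0, 90.0],
        "rbans_week24": [98.0, 85.0, 90.0],
    })
    labels = label_responders(profiles).set_index("participant_id")["label"]
    assert labels["A"] == "good" and labels["B"] == "poor" and labels["C"] == "tie"


def test_responder_labels_require_complete_outcomes():
    profiles = pd.DataFrame({
        "participant_id": ["A", "B"],
        "rbans_baseline": [90.0, 91.0],
        "rbans_week24": [np.nan, 95.0],
    })
    with pytest.raises(ValueError, match="A"):
        label_responders(profiles)


def test_all_rtacc_values_bounded(cohort):
    _, log = cohort
    out = rtacc_windows(log, windows=[2, 24])
    defined = out[out["defined"]]
    assert defined["value"].between(-1, 1).all()
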