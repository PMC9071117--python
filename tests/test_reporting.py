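"""Comparison tables, test statistics, rounding, flow accounting."""

import numpy as np
import pandas as pd
import pytest

from d2care import (
    categorical_table,
    continuous_compare,
    flow_accounting,
    pct,
    round_half_up,
)
from d2care.reporting import ConservationError

# last in-care CD4 and VL contingency tables (not-randomized vs randomized)
CD4_TABLE = pd.DataFrame(
    {"not_randomized": [175, 151, 447, 1283], "randomized": [95, 60, 146, 295]},
    index=["<200", "200-299", "300-499", ">=500"],
)
VL_TABLE = pd.DataFrame(
    {"not_randomized": [1741, 554], "randomized": [367, 286]},
    index=["undetectable", "detectable"],
)


def _brute_force_chi2(counts: pd.DataFrame) -> float:
    """Independent chi-square: sum over cells of (O-E)^2/E."""
    obs = counts.to_numpy(dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    return float(((obs - expected) ** 2 / expected).sum())


@pytest.mark.parametrize("table", [CD4_TABLE, VL_TABLE], ids=["cd4", "vl"])
def test_chi_square_matches_brute_force_oracle(table):
    result = categorical_table(counts=table)
    assert result.statistic == pytest.approx(_brute_force_chi2(table), abs=1e-9)
    assert result.p_value < 0.001
    assert result.dof == (table.shape[0] - 1) * (table.shape[1] - 1)


def test_identical_group_distributions_give_null_chi_square():
    counts = pd.DataFrame({"g1": [30, 50, 20], "g2": [30, 50, 20]})
    result = categorical_table(counts=counts)
    assert result.statistic == pytest.approx(0.0)
    assert result.p_value == pytest.approx(1.0)


def test_column_percents_recomputed_from_counts():
    result = categorical_table(counts=VL_TABLE)
    assert result.percents.loc["detectable", "randomized"] == 43.8
    assert result.percents.loc["detectable", "not_randomized"] == 24.1
    assert result.percents.loc["undetectable", "randomized"] == 56.2


def test_zero_count_column_marks_test_not_applicable():
    counts = pd.DataFrame({"g1": [5, 7], "g2": [0, 0]})
    result = categorical_table(counts=counts)
    assert result.p_value is None
    assert "not applicable" in result.test_name
    assert result.counts.loc[0, "g1"] == 5  # table still emitted


def test_raw_factors_build_the_same_table():
    rows = pd.Series(["x"] * 6 + ["y"] * 4 + ["x"] * 3 + ["y"] * 7)
    groups = pd.Series(["a"] * 10 + ["b"] * 10)
    result = categorical_table(rows, groups)
    assert result.counts.loc["x", "a"] == 6
    assert result.counts.loc["y", "b"] == 7


def test_t_statistic_zero_for_identical_samples():
    values = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    groups = pd.Series(["a"] * 3 + ["b"] * 3)
    result = continuous_compare(values, groups)
    assert result.t_statistic == pytest.approx(0.0)


def test_t_sign_matches_shift_direction():
    rng = np.random.default_rng(0)
    a = rng.normal(50, 5, 40)
    values = pd.Series(np.concatenate([a, a + 3.0]))
    groups = pd.Series(["a"] * 40 + ["b"] * 40)
    result = continuous_compare(values, groups)
    assert result.t_statistic < 0  # first group mean is lower


def test_age_difference_recovered_from_simulated_groups():
    """Groups drawn at the study's mean ages (51.6 vs 46.1, sd 12) recover a
    difference whose CI covers 5.5 years."""
    rng = np.random.default_rng(7)
    non_rand = rng.normal(51.6, 12, 2303)
    rand = rng.normal(46.1, 12, 655)
    values = pd.Series(np.concatenate([non_rand, rand]))
    groups = pd.Series(["not_randomized"] * 2303 + ["randomized"] * 655)
    result = continuous_compare(values, groups)
    diff = result.means["not_randomized"] - result.means["randomized"]
    se = 12 * np.sqrt(1 / 2303 + 1 / 655)
    assert abs(diff - 5.5) < 1.96 * se
    assert result.p_value < 0.001


def test_pct_and_round_half_up_conventions():
    assert round_half_up(866.5) == 867
    assert round_half_up(0.25, 1) == 0.3
    assert round_half_up(3116.779) == 3117
    assert pct(2108, 2948) == 71.5
    assert pct(1, 3, 2) == 33.33


def _flow_inputs(n=6):
    boxes = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "in_care": True,
        "box": ["B", "C", "D", "D", "C", "B"][:n],
    })
    conference = pd.DataFrame({
        "patient_id": boxes["patient_id"],
        "box": boxes["box"],
        "disposition": ["WELL_PATIENT", "RECENT_VISIT", "UPCOMING_VISIT",
                        "RANDOMIZABLE", "RANDOMIZABLE", "DECEASED"][:n],
        "watchlist_flag": [False, False, True, False, False, False][:n],
    })
    watchlist_counts = {"watchlist_missed": 1, "watchlist_kept": 0,
                        "watchlist_pending": 0}
    assignments = pd.DataFrame({
        "patient_id": ["P2", "P3", "P4"], "clinic_id": "C1",
        "arm": ["DIS", "SOC", "DIS"], "seed": 0, "block_index": [0, 0, 1],
    })
    return boxes, conference, watchlist_counts, assignments


def test_flow_accounting_counts_and_identities():
    report = flow_accounting(*_flow_inputs())
    assert report["potentially_ooc"] == 6
    assert report["initially_randomizable"] == 2
    assert report["watchlist"] == 1
    assert report["final_randomizable"] == 3
    assert report["randomized"] == 3
    assert report["arm_DIS"] == 2 and report["arm_SOC"] == 1


def test_flow_accounting_names_broken_identity():
    boxes, conference, counts, assignments = _flow_inputs()
    counts = {"watchlist_missed": 5, "watchlist_kept": 0, "watchlist_pending": 0}
    with pytest.raises(ConservationError, match="watchlist"):
        flow_accounting(boxes, conference, counts, assignments)


def test_empty_cohort_gives_all_zero_report():
    empty_boxes = pd.DataFrame(columns=["patient_id", "in_care", "box"])
    empty_conf = pd.DataFrame(
        columns=["patient_id", "box", "disposition", "watchlist_flag"]
    )
    empty_assign = pd.DataFrame(
        columns=["patient_id", "clinic_id", "arm", "seed", "block_index"]
    )
    report = flow_accounting(empty_boxes, empty_conf, {}, empty_assign)
    assert report["cohort"] == 0
    assert report["potentially_ooc"] == 0
    assert report["randomized"] == 0
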