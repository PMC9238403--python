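import math

import numpy as np
import pandas as pd
import pytest

from ecoassembly.partition import (
    ProcessLabel,
    aggregate_profile,
    classify_pair,
    driver_regression,
)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "bnti,rc,expected",
        [
            # selection regions: RC never consulted
            (2.5, None, ProcessLabel.VARIABLE_SELECTION),
            (2.0001, -1.0, ProcessLabel.VARIABLE_SELECTION),
            (10.0, 0.0, ProcessLabel.VARIABLE_SELECTION),
            (-2.5, None, ProcessLabel.HOMOGENIZING_SELECTION),
            (-2.0001, 1.0, ProcessLabel.HOMOGENIZING_SELECTION),
            # stochastic band, RC decides
            (0.5, 0.97, ProcessLabel.DISPERSAL_LIMITATION_DRIFT),
            (1.0, -0.99, ProcessLabel.HOMOGENIZING_DISPERSAL),
            (0.5, 0.2, ProcessLabel.DRIFT),
            (-1.9, -0.2, ProcessLabel.DRIFT),
            # threshold boundaries are strict: exact values fall stochastic
            (2.0, 0.0, ProcessLabel.DRIFT),
            (-2.0, 0.0, ProcessLabel.DRIFT),
            (0.0, 0.95, ProcessLabel.DRIFT),
            (0.0, -0.95, ProcessLabel.DRIFT),
            (2.0, 0.96, ProcessLabel.DISPERSAL_LIMITATION_DRIFT),
            (-2.0, -0.96, ProcessLabel.HOMOGENIZING_DISPERSAL),
        ],
    )
    def test_decision_rule_regions_and_boundaries(self, bnti, rc, expected):
        assert classify_pair(bnti, rc) is expected

    def test_exhaustive_grid_is_total_and_exclusive(self):
        for bnti in np.arange(-4, 4.01, 0.5):
            for rc in np.arange(-1, 1.01, 0.25):
                label = classify_pair(float(bnti), float(rc))
                assert isinstance(label, ProcessLabel)

    def test_missing_bnti_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            classify_pair(float("nan"), 0.0)

    def test_missing_rc_required_in_stochastic_band(self):
        with pytest.raises(ValueError, match="RC"):
            classify_pair(1.0, None)


def results_frame(rows):
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "group", "bnti", "rc", "degenerate"]
    )


class TestAggregateProfile:
    def test_all_drift_group(self):
        res = results_frame(
            [(f"A{i}", f"B{i}", "g", 0.1, 0.0, False) for i in range(4)]
        )
        (profile,) = aggregate_profile(res)
        assert profile.fractions[ProcessLabel.DRIFT] == 1.0
        assert profile.n_pairs == 4

    def test_fractions_sum_to_one(self):
        res = results_frame(
            [
                ("a", "b", "g", 3.0, 0.0, False),
                ("c", "d", "g", -3.0, 0.0, False),
                ("e", "f", "g", 0.0, 0.99, False),
                ("g", "h", "g", 0.0, -0.99, False),
                ("i", "j", "g", 0.0, 0.0, False),
            ]
        )
        (profile,) = aggregate_profile(res)
        assert sum(profile.fractions.values()) == pytest.approx(1.0)
        assert all(v == pytest.approx(0.2) for v in profile.fractions.values())

    def test_six_pair_toy_matches_hand_tally(self):
        res = results_frame(
            [
                ("a", "b", "wk1", 2.5, 0.0, False),
                ("c", "d", "wk1", 2.1, 0.0, False),
                ("e", "f", "wk1", 0.0, 0.0, False),
                ("g", "h", "wk2", -2.5, 0.0, False),
                ("i", "j", "wk2", 0.0, 0.96, False),
                ("k", "l", "wk2", 0.0, 0.2, False),
            ]
        )
        p1, p2 = aggregate_profile(res)
        assert p1.group_label == "wk1"
        assert p1.fractions[ProcessLabel.VARIABLE_SELECTION] == pytest.approx(2 / 3)
        assert p1.fractions[ProcessLabel.DRIFT] == pytest.approx(1 / 3)
        assert p2.fractions[ProcessLabel.HOMOGENIZING_SELECTION] == pytest.approx(1 / 3)
        assert p2.fractions[ProcessLabel.DISPERSAL_LIMITATION_DRIFT] == pytest.approx(1 / 3)

    def test_degenerate_pairs_excluded_but_counted(self):
        res = results_frame(
            [
                ("a", "b", "g", 0.0, 0.0, False),
                ("c", "d", "g", float("nan"), float("nan"), True),
            ]
        )
        (profile,) = aggregate_profile(res)
        assert profile.n_pairs == 1
        assert profile.n_degenerate == 1

    def test_row_order_invariance(self):
        rows = [
            ("a", "b", "g", 3.0, 0.0, False),
            ("c", "d", "g", 0.0, 0.3, False),
            ("e", "f", "h", -3.0, 0.0, False),
        ]
        a = aggregate_profile(results_frame(rows))
        b = aggregate_profile(results_frame(rows[::-1]))
        assert [(p.group_label, p.fractions) for p in a] == [
            (p.group_label, p.fractions) for p in b
        ]

    def test_group_of_only_degenerates_omitted_with_warning(self):
        res = results_frame([("a", "b", "g", float("nan"), float("nan"), True)])
        with pytest.warns(UserWarning, match="no classifiable"):
            assert aggregate_profile(res) == []


def meta_with_cov(cov):
    meta = pd.DataFrame(
        {
            "sample_id": list(cov),
            "patient_id": [f"P{i}" for i in range(len(cov))],
            "ward": ["W"] * len(cov),
            "day_of_life": range(len(cov)),
            "calendar_week": [1] * len(cov),
            "postconception_days": list(cov.values()),
        }
    )
    meta.index = pd.Index(meta["sample_id"], name="sample_id")
    return meta


class TestDriverRegression:
    def test_perfect_linear_relation(self):
        cov = {f"S{i}": 170 + 10 * i for i in range(6)}
        meta = meta_with_cov(cov)
        rows = []
        for i in range(5):
            diff = abs(cov["S0"] - cov[f"S{i + 1}"])
            rows.append(("S0", f"S{i + 1}", "g", 2.0 + 0.1 * diff, 0.0, False))
        res = pd.DataFrame(
            rows, columns=["sample_a", "sample_b", "group", "bnti", "rc", "degenerate"]
        )
        fit = driver_regression(res, meta, "postconception_days")
        assert fit.r == pytest.approx(1.0)
        assert fit.slope == pytest.approx(0.1)
        assert fit.n_pairs == 5

    def test_matches_hand_computed_pearson(self, rng):
        cov = {f"S{i}": float(v) for i, v in enumerate(rng.integers(160, 220, 10))}
        meta = meta_with_cov(cov)
        rows = []
        for i in range(0, 10, 2):
            a, b = f"S{i}", f"S{i + 1}"
            rows.append((a, b, "g", 2.0 + rng.random() * 3, 0.0, False))
        res = pd.DataFrame(
            rows, columns=["sample_a", "sample_b", "group", "bnti", "rc", "degenerate"]
        )
        fit = driver_regression(res, meta, "postconception_days")
        x = np.array([abs(cov[a] - cov[b]) for a, b, *_ in rows])
        y = np.array([r[3] for r in rows])
        r_hand = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert fit.r == pytest.approx(float(r_hand), abs=1e-12)

    def test_only_supra_threshold_pairs_enter(self):
        cov = {f"S{i}": 170 + 5 * i for i in range(8)}
        meta = meta_with_cov(cov)
        rows = [("S0", f"S{i + 1}", "g", 2.5, 0.0, False) for i in range(3)]
        rows += [("S4", "S5", "g", 1.0, 0.0, False)]  # below threshold, ignored
        res = pd.DataFrame(
            rows, columns=["sample_a", "sample_b", "group", "bnti", "rc", "degenerate"]
        )
        fit = driver_regression(res, meta, "postconception_days")
        assert fit.n_pairs == 3

    def test_too_few_pairs_rejected(self):
        meta = meta_with_cov({"S0": 170, "S1": 180})
        res = pd.DataFrame(
            [("S0", "S1", "g", 3.0, 0.0, False)],
            columns=["sample_a", "sample_b", "group", "bnti", "rc", "degenerate"],
        )
        with pytest.raises(ValueError, match=">= 3"):
            driver_regression(res, meta, "postconception_days")

    def test_constant_differences_rejected(self):
        cov = {f"S{i}": 170 + 10 * (i % 2) for i in range(6)}
        meta = meta_with_cov(cov)
        rows = [(f"S{2 * i}", f"S{2 * i + 1}", "g", 2.5 + i, 0.0, False) for i in range(3)]
        res = pd.DataFrame(
            rows, columns=["sample_a", "sample_b", "group", "bnti", "rc", "degenerate"]
        )
        with pytest.raises(ValueError, match="constant"):
            driver_regression(res, meta, "postconception_days")

    def test_unknown_covariate_rejected(self):
        meta = meta_with_cov({"S0": 1, "S1": 2})
        res = pd.DataFrame(
            columns=["sample_a", "sample_b", "group", "bnti", "rc", "degenerate"]
        )
        with pytest.raises(ValueError, match="covariate"):
            driver_regression(res, meta, "nope")
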