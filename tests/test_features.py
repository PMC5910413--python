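"""Feature assembly, group summaries and Welch comparisons."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from craniocurve.clustering import kmeans2
from craniocurve.curvature import CurvatureField
from craniocurve.errors import InputError, StatisticsError
from craniocurve.features import (
    build_features,
    group_summary,
    load_reference_summary,
    reference_group_summary,
    subject_features,
    summary_differences,
    welch_test,
)
from craniocurve.regions import RegionMask
from craniocurve.synthetic import SURGICAL_COHORT, simulate_cohort


def _subject(h_mid, h_left, h_right):
    field = CurvatureField(
        H=np.array([h_mid, h_left, h_right]),
        vertex_area=np.ones(3),
        valid=np.ones(3, bool),
    )
    masks = {
        "midforehead": RegionMask("midforehead", [0], [1.0]),
        "supraorbital_left": RegionMask("supraorbital_left", [1], [1.0]),
        "supraorbital_right": RegionMask("supraorbital_right", [2], [1.0]),
    }
    return {"field": field, "masks": masks}


def _labels(ids, labels):
    return pd.DataFrame({"subject_id": ids, "clinician_label": labels})


class TestBuildFeatures:
    def test_h_orb_is_left_right_average(self):
        table, failed = build_features(
            {"a": _subject(30.0, 4.0, 8.0), "b": _subject(40.0, -2.0, -6.0)}
        )
        assert failed == []
        assert len(table) == 2
        assert table["h_orb"].tolist() == [6.0, -4.0]

    def test_failed_subject_is_flagged_not_fatal(self):
        bad = _subject(30.0, 4.0, 8.0)
        bad["masks"]["supraorbital_left"] = RegionMask("supraorbital_left", [1], [1.0])
        bad["field"].valid[1] = False  # all masked vertices invalid -> fails
        table, failed = build_features({"ok": _subject(30.0, 4.0, 8.0), "bad": bad})
        assert failed == ["bad"]
        assert table["subject_id"].tolist() == ["ok"]

    def test_symmetric_head_features(self, head_features):
        f = head_features
        assert f["h_orb"] == pytest.approx((f["h_orb_left"] + f["h_orb_right"]) / 2)
        assert abs(f["h_orb_left"] - f["h_orb_right"]) < 0.01 * abs(f["h_orb"])

    def test_subject_features_pools_exactly(self):
        row = subject_features("s", **_subject(33.0, 2.0, 10.0))
        assert row["h_orb"] == (row["h_orb_left"] + row["h_orb_right"]) / 2


class TestGroupSummary:
    def test_reference_table_differences(self):
        # published group statistics: mid-forehead 39.0 vs 27.7 -> 11.3;
        # supraorbital -5.9 vs 10.2 -> -16.1
        surgical = reference_group_summary("surgical")
        conservative = reference_group_summary("nonsurgical")
        diffs = summary_differences(surgical, conservative)
        assert diffs["h_mid"] == pytest.approx(11.3)
        assert diffs["h_orb"] == pytest.approx(-16.1)

    def test_reference_table_shape(self):
        df = load_reference_summary()
        assert set(df["group"]) == {
            "surgical", "nonsurgical", "severe_cluster", "mild_cluster"
        }
        assert df.loc[df["group"] == "severe_cluster", "n"].item() == 16

    def test_identical_groups_zero_difference(self):
        features = pd.DataFrame(
            {
                "subject_id": list("abcd"),
                "h_mid": [5.0] * 4,
                "h_orb": [2.0] * 4,
            }
        )
        labels = _labels(list("abcd"), ["operative"] * 2 + ["conservative"] * 2)
        _, _, diffs = group_summary(features, labels)
        assert diffs == {"h_mid": 0.0, "h_orb": 0.0}

    def test_hand_computed_means_and_sds(self):
        features = pd.DataFrame(
            {
                "subject_id": list("abcd"),
                "h_mid": [1.0, 3.0, 5.0, 7.0],
                "h_orb": [0.0, 0.0, 0.0, 0.0],
            }
        )
        labels = _labels(list("abcd"), ["operative", "operative", "conservative", "conservative"])
        surgical, conservative, diffs = group_summary(features, labels)
        assert surgical.h_mid_mean == pytest.approx(2.0)
        assert conservative.h_mid_mean == pytest.approx(6.0)
        assert surgical.h_mid_sd == pytest.approx(np.sqrt(2.0))
        assert conservative.h_mid_sd == pytest.approx(np.sqrt(2.0))
        assert diffs["h_mid"] == pytest.approx(-4.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        features = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(10)],
                "h_mid": rng.normal(30, 5, 10),
                "h_orb": rng.normal(0, 5, 10),
            }
        )
        labels = _labels(features["subject_id"], ["operative"] * 5 + ["conservative"] * 5)
        a = group_summary(features, labels)
        b = group_summary(features.sample(frac=1, random_state=1), labels)
        for sa, sb in zip(a[:2], b[:2]):
            assert sa.group_name == sb.group_name and sa.n == sb.n
            assert sa.h_mid_mean == pytest.approx(sb.h_mid_mean)
            assert sa.h_mid_sd == pytest.approx(sb.h_mid_sd)
            assert sa.h_orb_mean == pytest.approx(sb.h_orb_mean)
            assert sa.h_orb_sd == pytest.approx(sb.h_orb_sd)

    def test_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(1)
        features = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(8)],
                "h_mid": rng.normal(30, 5, 8),
                "h_orb": rng.normal(0, 5, 8),
            }
        )
        lab = ["operative"] * 4 + ["conservative"] * 4
        swapped = ["conservative"] * 4 + ["operative"] * 4
        _, _, d1 = group_summary(features, _labels(features["subject_id"], lab))
        _, _, d2 = group_summary(features, _labels(features["subject_id"], swapped))
        assert d1["h_mid"] == pytest.approx(-d2["h_mid"])
        assert d1["h_orb"] == pytest.approx(-d2["h_orb"])

    def test_tiny_group_rejected(self):
        features = pd.DataFrame(
            {"subject_id": list("abc"), "h_mid": [1.0, 2.0, 3.0], "h_orb": [0.0] * 3}
        )
        labels = _labels(list("abc"), ["operative", "conservative", "conservative"])
        with pytest.raises(StatisticsError):
            group_summary(features, labels)

    def test_unlabeled_subject_rejected(self):
        features = pd.DataFrame(
            {"subject_id": list("abcd"), "h_mid": [1.0] * 4, "h_orb": [0.0] * 4}
        )
        labels = _labels(list("abc"), ["operative", "operative", "conservative"])
        with pytest.raises(InputError):
            group_summary(features, labels)


class TestWelch:
    def test_identical_groups_p_one(self):
        features = pd.DataFrame(
            {"subject_id": list("abcd"), "h_mid": [3.0] * 4, "h_orb": [0.0] * 4}
        )
        labels = _labels(list("abcd"), ["operative"] * 2 + ["conservative"] * 2)
        t, _, p = welch_test(features, labels, "h_mid")
        assert t == 0.0
        assert p == 1.0

    def test_matches_independent_implementation(self):
        # cross-check against statsmodels' unequal-variance t-test
        import statsmodels.stats.weightstats as smw

        rng = np.random.default_rng(5)
        a = rng.normal(39.0, 6.9, 16)
        b = rng.normal(27.7, 4.6, 27)
        features = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(43)],
                "h_mid": np.concatenate([a, b]),
                "h_orb": np.zeros(43),
            }
        )
        labels = _labels(
            features["subject_id"], ["operative"] * 16 + ["conservative"] * 27
        )
        t, df, p = welch_test(features, labels, "h_mid")
        t_sm, p_sm, df_sm = smw.ttest_ind(b, a, usevar="unequal")
        assert abs(abs(t) - abs(t_sm)) < 1e-10
        assert abs(p - p_sm) < 1e-10
        assert abs(df - df_sm) < 1e-10

    def test_simulated_cohort_is_significant(self):
        tab = simulate_cohort(dataclasses.replace(SURGICAL_COHORT, seed=42))
        labels = pd.DataFrame(
            {
                "subject_id": tab["subject_id"],
                "clinician_label": tab["group"].map(
                    {"surgical": "operative", "nonsurgical": "conservative"}
                ),
            }
        )
        _, _, p_orb = welch_test(tab, labels, "h_orb")
        assert p_orb < 1e-4

    def test_student_variant_available(self):
        rng = np.random.default_rng(9)
        features = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(12)],
                "h_mid": rng.normal(0, 1, 12),
                "h_orb": np.zeros(12),
            }
        )
        labels = _labels(features["subject_id"], ["operative"] * 6 + ["conservative"] * 6)
        t_w, df_w, _ = welch_test(features, labels, "h_mid")
        t_s, df_s, _ = welch_test(features, labels, "h_mid", equal_var=True)
        assert df_s == pytest.approx(10.0)
        assert df_w <= df_s + 1e-9


def test_pipeline_features_separate_phenotype_dials(head_features):
    """A moderately ridged/retruded head lands between the two phenotypes."""
    f = head_features
    assert 20.0 < f["h_mid"] < 45.0
    assert np.isfinite(f["h_orb"])
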