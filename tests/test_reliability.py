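import itertools

import numpy as np
import pandas as pd
import pytest

from romexam.reliability import (
    RatingTable,
    agreement_panel,
    bland_altman,
    build_rating_table,
    icc_3k,
    rep_mean_sd,
    repeatability_table,
    validity_flags,
)


def brute_force_icc3k(x):
    """Independent oracle: explicit two-way ANOVA sums of squares by double
    loops (written separately from the vectorized main path)."""
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    ss_rows = sum(k * (sum(x[i]) / k - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (sum(x[i][j] for i in range(n)) / n - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    return (bms - ems) / bms


def _table(values, angle="a", source="measurement"):
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    return RatingTable(angle, source, values, list(range(n)), list(range(k)))


class TestRepMeanSd:
    def test_identical_repetitions(self):
        assert rep_mean_sd([140, 140, 140, 140, 140]) == (140.0, 0.0)

    def test_sample_sd_uses_n_minus_1(self):
        mean, sd = rep_mean_sd([138, 139, 140, 141, 142])
        assert mean == 140.0
        assert sd == pytest.approx(1.5811, abs=1e-4)

    def test_single_repetition_rejected(self):
        with pytest.raises(ValueError):
            rep_mean_sd([140])


class TestRepeatabilityTable:
    def _sheet(self, values_by_subject):
        rows = []
        for s, reps in values_by_subject.items():
            for k, v in enumerate(reps):
                rows.append((s, 0, "elbow_flexion_R", k, v))
        return pd.DataFrame(rows, columns=["subject", "rater", "angle_id", "rep", "v"])

    def test_identical_repetitions_everywhere_give_zero(self):
        sheet = self._sheet({0: [5, 5, 5], 1: [9, 9, 9]})
        out = repeatability_table({"measurement": (sheet, "v")})
        assert out["mean_sd_deg"].tolist() == [0.0]

    def test_mean_of_per_subject_sds(self):
        # per-subject SDs of 2 and 4 average to 3
        sheet = self._sheet({0: [0, 2 * np.sqrt(2)], 1: [0, 4 * np.sqrt(2)]})
        out = repeatability_table({"measurement": (sheet, "v")})
        assert out["mean_sd_deg"].iloc[0] == pytest.approx(3.0)

    def test_family_grouping_collapses_sides(self, catalog):
        rows = []
        for aid, sd_scale in (("knee_flexion_L", 1.0), ("knee_flexion_R", 3.0)):
            for s in range(2):
                rows += [(s, 0, aid, 0, 0.0), (s, 0, aid, 1, sd_scale * np.sqrt(2))]
        sheet = pd.DataFrame(rows, columns=["subject", "rater", "angle_id", "rep", "v"])
        out = repeatability_table({"measurement": (sheet, "v")}, catalog)
        assert out["family"].tolist() == ["knee:Flexion"]
        assert out["mean_sd_deg"].iloc[0] == pytest.approx(2.0)


class TestICC:
    def test_identical_rater_columns_give_one(self):
        x = np.tile(np.array([[1.0], [5.0], [9.0], [2.0]]), (1, 3))
        r = icc_3k(_table(x))
        assert r.icc_3k == pytest.approx(1.0)
        assert r.acceptable

    def test_matches_brute_force_oracle(self, rng):
        worst = 0.0
        for _ in range(100):
            x = rng.normal(size=(20, 3)) * 3 + rng.normal(size=(20, 1)) * 8
            worst = max(worst, abs(icc_3k(_table(x)).icc_3k - brute_force_icc3k(x)))
        assert worst < 1e-10

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(size=(15, 3)) * 4 + rng.normal(size=(15, 1)) * 9
        df = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(15), 3),
                "rater": np.tile(np.arange(3), 15),
                "y": x.ravel(),
            }
        )
        ref = (
            pg.intraclass_corr(df, targets="subj", raters="rater", ratings="y")
            .set_index("Type")
            .loc["ICC(C,k)", "ICC"]
        )
        assert icc_3k(_table(x)).icc_3k == pytest.approx(ref, abs=1e-12)

    def test_rater_bias_does_not_change_icc(self, rng):
        """Adding a constant to one rater's column only moves the rater main
        effect, which the two-way consistency model removes."""
        x = rng.normal(size=(20, 3)) * 3 + rng.normal(size=(20, 1)) * 8
        shifted = x.copy()
        shifted[:, 1] += 25.0
        assert icc_3k(_table(shifted)).icc_3k == pytest.approx(icc_3k(_table(x)).icc_3k, abs=1e-12)

    def test_subject_permutation_invariance(self, rng):
        x = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)) * 5
        perm = rng.permutation(12)
        assert icc_3k(_table(x[perm])).icc_3k == pytest.approx(icc_3k(_table(x)).icc_3k, abs=1e-12)

    def test_zero_subject_variance_is_undefined(self):
        x = np.ones((6, 3)) * 42.0
        r = icc_3k(_table(x))
        assert r.undefined
        assert np.isnan(r.icc_3k)
        assert not r.acceptable

    def test_negative_estimate_reported_raw(self):
        # almost no subject variance but large disagreement → EMS > BMS
        x = np.array([[0.0, 1.0], [1.0, 0.0], [0.1, 1.0], [1.0, 0.1]])
        r = icc_3k(_table(x))
        assert r.icc_3k < 0.0  # raw value, not clipped for computation
        assert not r.acceptable
        assert not r.undefined

    def test_acceptability_threshold_inclusive(self):
        # construct a matrix with ICC exactly at threshold is fragile;
        # check the rule on the dataclass contract instead
        x = np.tile(np.array([[1.0], [5.0], [9.0], [2.0]]), (1, 3))
        r = icc_3k(_table(x))
        assert r.acceptable == (r.icc_3k >= 0.8)


class TestBlandAltman:
    def test_equal_raters_zero_mdiff_zero_loa(self):
        x = np.column_stack([np.arange(5.0), np.arange(5.0)])
        b = bland_altman(_table(x), (0, 1))
        assert (b.mdiff, b.loa_low, b.loa_high) == (0.0, 0.0, 0.0)
        assert b.mdiff_acceptable

    def test_constant_offset_is_boundary_unacceptable(self):
        """b ≡ a + 5 gives MDiff = −5 with zero-width limits; the rule is
        strictly below 5°, so the flag is False."""
        a = np.arange(6.0)
        x = np.column_stack([a, a + 5.0])
        b = bland_altman(_table(x), (0, 1))
        assert b.mdiff == -5.0
        assert b.sd_diff == 0.0
        assert not b.mdiff_acceptable

    def test_loa_from_direct_formula(self):
        a = np.array([0.0, 0.0, 0.0])
        x = np.column_stack([a + [-2.0, 0.0, 2.0], a])
        b = bland_altman(_table(x), (0, 1))
        assert b.mdiff == 0.0
        assert b.sd_diff == pytest.approx(2.0)
        assert b.loa_low == pytest.approx(-3.92)
        assert b.loa_high == pytest.approx(3.92)

    def test_antisymmetry(self, rng):
        x = rng.normal(size=(10, 2)) * 5 + 60
        fwd = bland_altman(_table(x), (0, 1))
        rev = bland_altman(_table(x), (1, 0))
        assert fwd.mdiff == pytest.approx(-rev.mdiff)
        assert fwd.loa_low == pytest.approx(-rev.loa_high)
        assert fwd.loa_high == pytest.approx(-rev.loa_low)

    def test_unknown_pair_rejected(self):
        x = np.zeros((3, 2))
        x[:, 0] = [1, 2, 3]
        with pytest.raises(KeyError):
            bland_altman(_table(x), (0, 7))


class TestAgreementPanel:
    def test_three_raters_give_nine_comparisons_in_order(self, rng):
        m = _table(rng.normal(size=(8, 3)) + 50, source="measurement")
        e = _table(rng.normal(size=(8, 3)) + 50, source="examiner")
        panel = agreement_panel(m, e)
        pairs = [b.rater_pair for b in panel]
        assert pairs == [
            ("Ex1", "Meas1"), ("Ex2", "Meas2"), ("Ex3", "Meas3"),
            ("Meas1", "Meas2"), ("Meas1", "Meas3"), ("Meas2", "Meas3"),
            ("Ex1", "Ex2"), ("Ex1", "Ex3"), ("Ex2", "Ex3"),
        ]

    def test_two_raters_give_four_comparisons(self, rng):
        m = _table(rng.normal(size=(5, 2)), source="measurement")
        e = _table(rng.normal(size=(5, 2)), source="examiner")
        assert len(agreement_panel(m, e)) == 4

    def test_identical_columns_give_zero_mdiff_everywhere(self, rng):
        col = rng.normal(size=(6, 1)) + 70
        vals = np.tile(col, (1, 3))
        panel = agreement_panel(_table(vals, source="measurement"), _table(vals, source="examiner"))
        assert all(b.mdiff == 0.0 for b in panel)


class TestValidityFlags:
    def test_between_the_two_references(self, catalog):
        out = validity_flags({"cervical_rotation_L": 75.0}, catalog)
        assert out.iloc[0]["flag_ref1"] == "below"  # vs 80
        assert out.iloc[0]["flag_ref2"] == "above"  # vs 70

    def test_boundary_is_within(self, catalog):
        out = validity_flags({"cervical_rotation_L": 70.0}, catalog)
        assert out.iloc[0]["flag_ref2"] == "within"

    def test_below_both_references(self, catalog):
        out = validity_flags({"elbow_supination_L": 47.0}, catalog)
        assert out.iloc[0]["flag_ref1"] == "below"
        assert out.iloc[0]["flag_ref2"] == "below"

    def test_inside_a_range_reference(self, catalog):
        out = validity_flags({"hip_lateral_rotation_L": 38.0}, catalog)
        assert out.iloc[0]["flag_ref1"] == "within"  # 35–40


class TestBuildRatingTable:
    def test_incomplete_subjects_dropped_and_counted(self):
        rows = []
        for s in range(4):
            for r in range(3):
                if s == 2 and r == 1:
                    continue  # subject 2 misses rater 1
                for k in range(2):
                    rows.append((s, r, "a", k, 50.0 + s))
        sheet = pd.DataFrame(rows, columns=["subject", "rater", "angle_id", "rep", "v"])
        t = build_rating_table(sheet, "a", "measurement", "v")
        assert t.n == 3
        assert t.n_dropped == 1
        assert 2 not in t.subject_ids

    def test_values_are_repetition_means(self):
        rows = [(0, 0, "a", 0, 10.0), (0, 0, "a", 1, 20.0),
                (1, 0, "a", 0, 30.0), (1, 0, "a", 1, 50.0),
                (0, 1, "a", 0, 0.0), (0, 1, "a", 1, 0.0),
                (1, 1, "a", 0, 0.0), (1, 1, "a", 1, 0.0)]
        sheet = pd.DataFrame(rows, columns=["subject", "rater", "angle_id", "rep", "v"])
        t = build_rating_table(sheet, "a", "measurement", "v")
        assert t.values[:, 0].tolist() == [15.0, 40.0]
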