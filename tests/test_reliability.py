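"""Agreement statistics: ICC(A,1), Gwet's AC1, Bland-Altman, banding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import parafat as pf


def brute_force_icc_a1(values):
    """Independent two-way ANOVA oracle, computed from raw sums of squares."""
    y = np.asarray(values, float)
    n, k = y.shape
    grand = sum(y[i, j] for i in range(n) for j in range(k)) / (n * k)
    ss_rows = sum(k * (sum(y[i]) / k - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (sum(y[:, j]) / n - grand) ** 2 for j in range(k))
    ss_tot = sum((y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestAssembleCompleteCases:
    def test_fully_complete_input_retained(self, small_records):
        m = pf.assemble_complete_cases(small_records, "mfi", "interobserver")
        assert m.n_subjects == 3
        assert m.k_raters == 2
        assert m.n_dropped == 0

    def test_subject_missing_an_observer_is_dropped(self, small_records):
        records = small_records[
            ~((small_records.patient_id == 2) & (small_records.observer == 2))
        ]
        m = pf.assemble_complete_cases(records, "mfi", "interobserver")
        assert m.n_subjects == 2
        assert m.n_dropped == 1
        assert all(s[0] != 2 for s in m.subjects)

    def test_intraobserver_pairs_sessions(self, small_records):
        m = pf.assemble_complete_cases(small_records, "mfi", "intraobserver", observer=1)
        assert m.columns == [1, 2]
        assert m.n_subjects == 3

    def test_empty_input_errors(self, small_records):
        with pytest.raises(ValueError):
            pf.assemble_complete_cases(small_records.iloc[0:0], "mfi", "interobserver")

    def test_interobserver_uses_session_one_only(self, small_records):
        tampered = small_records.copy()
        tampered.loc[tampered.session == 2, "mfi"] = 99.0
        m = pf.assemble_complete_cases(tampered, "mfi", "interobserver")
        assert m.values.max() < 1.0


class TestIcc:
    def test_identical_columns_give_one(self):
        vals = np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0], [5.0, 5.0, 5.0]])
        r = pf.icc_absolute_agreement(vals)
        assert r.estimate == pytest.approx(1.0)
        assert r.band == "excellent"

    def test_matches_brute_force_oracle_on_small_integers(self):
        vals = np.array(
            [[9, 2, 5], [6, 1, 3], [8, 4, 6], [7, 1, 2], [10, 5, 6]], dtype=float
        )
        r = pf.icc_absolute_agreement(vals)
        assert r.estimate == pytest.approx(brute_force_icc_a1(vals), abs=1e-8)

    def test_matches_pingouin_estimate_and_ci(self, rng):
        """Independent cross-check against pingouin's ICC2 (A,1) row."""
        pg = pytest.importorskip("pingouin")
        vals = rng.normal(5, 2, size=(10, 3)) + rng.normal(0, 1.5, size=(10, 1))
        r = pf.icc_absolute_agreement(vals)
        long = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(10), 3),
                "rater": list(range(3)) * 10,
                "y": vals.ravel(),
            }
        )
        table = pg.intraclass_corr(long, "subj", "rater", "y").set_index("Type")
        key = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
        assert r.estimate == pytest.approx(table.loc[key, "ICC"], abs=1e-10)
        lo, hi = table.loc[key, "CI95"]
        # pingouin rounds its CI to two decimals
        assert r.ci_low == pytest.approx(lo, abs=6e-3)
        assert r.ci_high == pytest.approx(hi, abs=6e-3)

    @given(
        shift=st.floats(-100, 100),
        scale=st.floats(0.01, 100),
    )
    @settings(max_examples=40, deadline=None)
    def test_affine_invariance(self, shift, scale):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 1, (6, 3)) + rng.normal(0, 2, (6, 1))
        base = pf.icc_absolute_agreement(vals).estimate
        moved = pf.icc_absolute_agreement(vals * scale + shift).estimate
        assert moved == pytest.approx(base, abs=1e-9)

    def test_zero_total_variance_is_perfect_by_convention(self):
        with pytest.warns(UserWarning, match="degenerate"):
            r = pf.icc_absolute_agreement(np.full((4, 3), 2.5))
        assert (r.estimate, r.ci_low, r.ci_high) == (1.0, 1.0, 1.0)

    def test_incomplete_matrix_rejected(self):
        vals = np.array([[1.0, np.nan], [2.0, 2.0]])
        with pytest.raises(ValueError, match="complete"):
            pf.icc_absolute_agreement(vals)


class TestGwetAc1:
    def test_perfect_agreement_is_exactly_one(self):
        vals = np.array([[0, 0], [3, 3], [1, 1], [4, 4]])
        assert pf.gwet_ac1(vals, q=5).estimate == 1.0

    def test_hand_evaluated_closed_form(self):
        # 2 raters, 10 subjects, q = 2; agreement on 8 of 10:
        # p_a = 0.8; pi = (0.7, 0.3); p_e = 0.7*0.3 + 0.3*0.7 = 0.42
        # AC1 = (0.8 - 0.42) / 0.58
        vals = np.array([[0, 0]] * 6 + [[1, 1]] * 2 + [[0, 1], [1, 0]])
        r = pf.gwet_ac1(vals, q=2)
        assert r.estimate == pytest.approx((0.8 - 0.42) / (1 - 0.42), abs=1e-12)

    def test_invariant_under_category_relabelling(self, rng):
        vals = rng.integers(0, 5, size=(15, 3))
        perm = rng.permutation(5)
        relabelled = perm[vals]
        a = pf.gwet_ac1(vals, q=5).estimate
        b = pf.gwet_ac1(relabelled, q=5).estimate
        assert b == pytest.approx(a, abs=1e-12)

    def test_out_of_range_category_rejected(self):
        with pytest.raises(ValueError, match="0..4"):
            pf.gwet_ac1(np.array([[0, 5], [1, 1]]), q=5)

    def test_ci_contains_estimate(self, rng):
        vals = rng.integers(0, 3, size=(20, 3))
        r = pf.gwet_ac1(vals, q=3)
        assert r.ci_low <= r.estimate <= r.ci_high


class TestBlandAltman:
    def test_identical_pairs(self):
        r = pf.bland_altman([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert r.bias == 0.0
        assert r.loa_low == 0.0 and r.loa_high == 0.0

    def test_constant_difference_gives_zero_width(self):
        r = pf.bland_altman([0.4, 0.5], [0.5, 0.6])
        assert r.bias == pytest.approx(-0.1)
        assert r.loa_low == pytest.approx(-0.1)
        assert r.loa_high == pytest.approx(-0.1)

    def test_two_point_formula(self):
        # differences {-0.2, 0.0}: bias -0.1, sd = 0.1414..., LoA = bias -/+ 1.96 sd
        r = pf.bland_altman([0.3, 0.5], [0.5, 0.5])
        sd = np.std([-0.2, 0.0], ddof=1)
        assert r.bias == pytest.approx(-0.1)
        assert r.loa_low == pytest.approx(-0.1 - 1.96 * sd)
        assert r.loa_high == pytest.approx(-0.1 + 1.96 * sd)

    @given(shift=st.floats(-5, 5))
    @settings(max_examples=40, deadline=None)
    def test_shift_equivariance(self, shift):
        a = np.array([0.4, 0.5, 0.7, 0.9])
        b = np.array([0.5, 0.4, 0.8, 0.7])
        base = pf.bland_altman(a, b)
        moved = pf.bland_altman(a + shift, b)
        assert moved.bias == pytest.approx(base.bias + shift, abs=1e-12)
        width = base.loa_high - base.loa_low
        assert moved.loa_high - moved.loa_low == pytest.approx(width, abs=1e-12)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pf.bland_altman([0.5], [0.4])

    def test_coordinates_for_plotting(self):
        r = pf.bland_altman([0.4, 0.6], [0.2, 0.8])
        assert list(r.coordinates["mean"]) == pytest.approx([0.3, 0.7])
        assert list(r.coordinates["difference"]) == pytest.approx([0.2, -0.2])


class TestInterpretBand:
    @pytest.mark.parametrize(
        "est,label",
        [(0.0, "poor"), (0.49, "poor"), (0.505, "moderate"), (0.76, "good"),
         (0.79, "good"), (0.905, "excellent"), (0.91, "excellent"), (1.0, "excellent")],
    )
    def test_icc_bands(self, est, label):
        assert pf.interpret_band(est, "ICC") == label

    @pytest.mark.parametrize(
        "est,label",
        [(0.0, "poor"), (0.1, "slight"), (0.33, "fair"), (0.55, "moderate"),
         (0.64, "substantial"), (0.92, "almost perfect"), (1.0, "almost perfect")],
    )
    def test_ac1_bands(self, est, label):
        assert pf.interpret_band(est, "AC1") == label

    def test_every_estimate_gets_exactly_one_label(self):
        for est in np.linspace(-1, 1, 401):
            assert pf.interpret_band(float(est), "ICC")
            assert pf.interpret_band(float(est), "AC1")

    def test_unknown_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            pf.interpret_band(0.5, "kappa")
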