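"""Robust z / zeta scoring and the well-filtering pass."""

import numpy as np
import pytest

from schurdle.core_data import ValidationError, subset_wells
from schurdle.qc import (
    MAD_SCALE,
    filter_wells,
    housekeeper_r2,
    robust_z_positive,
    zeta_scores,
)

from conftest import make_et


def brute_robust_z(values):
    """Direct evaluation of (x - median) / (c * MAD) as an oracle."""
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    return (values - med) / (MAD_SCALE * mad)


class TestRobustZ:
    def test_hand_computed_example(self):
        col = np.array([10.0, 12.0, 14.0, 16.0, 100.0])
        z = robust_z_positive(col)
        # median 14, MAD 2, c*MAD = 2.9652
        assert z[4] == pytest.approx((100 - 14) / 2.9652, rel=1e-6)
        assert z[4] == pytest.approx(29.0, abs=0.01)
        np.testing.assert_allclose(z, brute_robust_z(col), rtol=1e-12)

    def test_median_scores_zero(self):
        z = robust_z_positive(np.array([3.0, 5.0, 9.0]))
        assert z[1] == 0.0

    def test_too_few_positive_wells_gives_no_scores(self):
        z = robust_z_positive(np.array([0.0, 0.0, 4.0, 6.0]))
        assert np.isnan(z).all()

    def test_zeros_never_scored(self):
        z = robust_z_positive(np.array([0.0, 3.0, 5.0, 9.0]))
        assert np.isnan(z[0]) and np.isfinite(z[1:]).all()

    def test_mad_zero_degeneracy(self):
        z = robust_z_positive(np.array([5.0, 5.0, 5.0, 8.0]))
        assert z[0] == 0.0 and z[3] == np.inf


class TestZeta:
    def test_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        et = make_et(np.where(rng.random((12, 30)) < 0.4, 10.0, 0.0))
        p = et.detected.mean(axis=1)
        f = np.arcsin(np.sqrt(p))
        med = np.median(f)
        mad = np.median(np.abs(f - med))
        np.testing.assert_allclose(zeta_scores(et), (f - med) / (MAD_SCALE * mad), rtol=1e-12)

    def test_quarter_expressed_transform_value(self):
        # 24 of 96 genes detected -> p = 1/4, f = arcsin(1/2) = pi/6
        p = 24 / 96
        assert np.arcsin(np.sqrt(p)) == pytest.approx(np.pi / 6)

    def test_median_well_scores_zero(self):
        vals = np.zeros((5, 10))
        for i, k in enumerate([2, 3, 5, 7, 8]):
            vals[i, :k] = 10.0
        z = zeta_scores(make_et(vals))
        assert z[2] == 0.0  # f equal to the across-well median

    def test_single_fully_expressed_outlier(self):
        vals = np.zeros((21, 20))
        rng = np.random.default_rng(0)
        for i in range(20):
            on = rng.choice(20, size=6, replace=False)
            vals[i, on] = 10.0
        vals[20, :] = 10.0  # every gene on
        z = zeta_scores(make_et(vals))
        assert abs(z[20]) > 3
        assert np.all(np.abs(z[:20]) < abs(z[20]))


class TestFilterWells:
    def test_null_wells_removed_with_reason(self):
        vals = np.ones((4, 3)) * 12.0
        vals[1] = 0.0
        et = make_et(vals)
        kept, report = filter_wells(et)
        assert report.null_wells == ["w1"]
        assert report.flagged["w1"] == ["null"]
        assert kept.n_wells == 3

    def test_single_outlier_well_removed(self):
        rng = np.random.default_rng(1)
        vals = 12.0 + rng.normal(0, 1, (21, 4))
        vals[7, 2] = 60.0  # one wild measurement
        et = make_et(vals)
        kept, report = filter_wells(et, k_z=9, k_zeta=np.inf)
        assert set(report.flagged) == {"w7"}
        assert report.flagged["w7"] == ["z-outlier"]
        assert kept.n_wells == 20

    def test_infinite_thresholds_keep_everything_but_null(self):
        rng = np.random.default_rng(2)
        vals = np.where(rng.random((30, 8)) < 0.5, 10 + rng.normal(0, 1, (30, 8)), 0.0)
        vals[[3, 11]] = 0.0
        et = make_et(vals)
        kept, report = filter_wells(et, k_z=np.inf, k_zeta=np.inf)
        assert kept.n_wells == 28
        assert all(r == ["null"] for r in report.flagged.values())

    def test_all_null_plate_errors(self):
        with pytest.raises(ValidationError, match="all wells null"):
            filter_wells(make_et(np.zeros((5, 3))))

    def test_filtering_is_pure_row_selection(self, contaminated_bundle):
        sc = subset_wells(contaminated_bundle, contaminated_bundle.cells_per_well == 1)
        kept, _ = filter_wells(sc)
        idx = {w: i for i, w in enumerate(sc.well_ids)}
        rows = [idx[w] for w in kept.well_ids]
        np.testing.assert_array_equal(kept.et, sc.et[rows])

    def test_lowering_thresholds_only_grows_flag_set(self, contaminated_bundle):
        sc = subset_wells(contaminated_bundle, contaminated_bundle.cells_per_well == 1)
        previous = None
        for k in (15.0, 9.0, 5.0, 3.0):
            _, report = filter_wells(sc, k_z=k, k_zeta=k)
            flags = set(report.flagged)
            if previous is not None:
                assert previous <= flags
            previous = flags

    def test_null_removal_must_precede_zeta(self):
        """With many empty wells, computing zeta before dropping nulls blows
        up the MAD of the detected-fraction transform and masks genuine
        proportion outliers; removing nulls first restores the flags."""
        rng = np.random.default_rng(8)
        m = 96
        vals = np.zeros((30, m))
        for i in range(12, 26):  # 14 well-behaved wells, ~45% detection
            on = rng.choice(m, size=40 + (i % 8), replace=False)
            vals[i, on] = 12.0
        for i in range(26, 30):  # 4 near-fully-detecting outlier wells
            on = rng.choice(m, size=93, replace=False)
            vals[i, on] = 12.0
        et = make_et(vals)  # wells 0-11 are null (40% of the plate)
        _, report = filter_wells(et, k_z=np.inf, k_zeta=4.0)
        correct_flags = {w for w, r in report.flagged.items() if "zeta-outlier" in r}
        assert correct_flags == {f"w{i}" for i in range(26, 30)}
        wrong_order = zeta_scores(et)  # nulls still present: broken estimate
        null_ids = {f"w{i}" for i in range(12)}
        wrong_flags = {
            w for w, z in zip(et.well_ids, wrong_order) if abs(z) > 4.0 and w not in null_ids
        }
        assert wrong_flags != correct_flags


class TestHousekeeperR2:
    def test_gene_against_itself(self):
        rng = np.random.default_rng(3)
        vals = np.tile(10 + rng.normal(0, 2, (50, 1)), (1, 2))
        assert housekeeper_r2(make_et(vals), "g0", "g1") == pytest.approx(1.0)

    def test_affine_shift_is_perfect(self):
        rng = np.random.default_rng(3)
        a = 10 + rng.normal(0, 2, 50)
        vals = np.column_stack([a, a + 5.0])
        assert housekeeper_r2(make_et(vals), "g0", "g1") == pytest.approx(1.0)

    def test_independent_genes_near_zero(self):
        rng = np.random.default_rng(5)
        vals = 15 + rng.normal(0, 2, (1000, 2))
        assert housekeeper_r2(make_et(vals), "g0", "g1") < 0.05

    def test_too_few_coexpressed_wells_undefined(self):
        vals = np.array([[5.0, 6.0], [7.0, 0.0], [0.0, 8.0], [0.0, 0.0]])
        assert np.isnan(housekeeper_r2(make_et(vals), "g0", "g1"))
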