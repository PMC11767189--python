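import numpy as np
import pytest

from discopad.meff import (
    adjusted_pwer,
    disco_pad,
    effective_tests_from_pwer,
    grouped_from_matrix,
    meff_baseline,
    meff_from_matrix,
    meff_galwey,
    meff_gao,
    meff_grouped,
    meff_liji,
    meff_nyholt,
    meff_peluso,
)
from discopad.psd import eigenvalues
from discopad.synthetic import iid_normal, random_partition
from discopad.types import AssociationMatrix, DataError, EigenSpectrum, GroupPartition

from conftest import make_features, orthonormal_features


def spec(*values):
    return EigenSpectrum(np.array(values, dtype=float))


def equicorr_spectrum(M, rho):
    vals = [1.0 + (M - 1) * rho] + [1.0 - rho] * (M - 1)
    return spec(*vals)


class TestNyholt:
    def test_identity(self):
        assert meff_nyholt(spec(*([1.0] * 7))) == pytest.approx(7.0)

    def test_hand_sample_variance(self):
        # var((2,2,0,0)) with M-1 denominator = 4/3; 1 + 3*(1 - (4/3)/4) = 3
        assert meff_nyholt(spec(2, 2, 0, 0)) == pytest.approx(3.0)

    def test_single_spike(self):
        # var((4,0,0,0)) = 4 = M, so Meff = 1
        assert meff_nyholt(spec(4, 0, 0, 0)) == pytest.approx(1.0)

    def test_needs_two(self):
        with pytest.raises(DataError):
            meff_nyholt(spec(3.0))


class TestLiJi:
    def test_identity(self):
        assert meff_liji(spec(*([1.0] * 9))) == pytest.approx(9.0)

    def test_integer_eigenvalues(self):
        assert meff_liji(spec(2, 2, 0, 0)) == pytest.approx(2.0)

    def test_fractional(self):
        assert meff_liji(spec(1.5, 1, 1, 0.5)) == pytest.approx(4.0)


class TestGao:
    def test_single_spike(self):
        assert meff_gao(spec(4, 0, 0, 0)) == 1

    def test_identity_200(self):
        assert meff_gao(spec(*([1.0] * 200))) == 199

    def test_two_components(self):
        assert meff_gao(spec(2, 2, 0, 0)) == 2

    def test_all_zero_error(self):
        with pytest.raises(DataError):
            meff_gao(spec(0, 0, 0))


class TestGalwey:
    def test_identity(self):
        assert meff_galwey(spec(*([1.0] * 6))) == pytest.approx(6.0)

    def test_two_twos(self):
        assert meff_galwey(spec(2, 2, 0, 0)) == pytest.approx(2.0)

    def test_single_spike(self):
        assert meff_galwey(spec(4, 0, 0, 0)) == pytest.approx(1.0)


class TestPeluso:
    def test_single_spike(self):
        # (sum sqrt = 2 / ln 4)^2 / (1 + 4)
        expected = (2.0 / np.log(4.0)) ** 2 / 5.0
        assert meff_peluso(spec(4, 0, 0, 0)) == pytest.approx(expected, rel=1e-12)
        assert meff_peluso(spec(4, 0, 0, 0)) == pytest.approx(0.4163, abs=5e-4)

    def test_two_twos(self):
        expected = (2.0 * np.sqrt(2.0) / np.log(2.0)) ** 2 / 4.0
        assert meff_peluso(spec(2, 2, 0, 0)) == pytest.approx(expected, rel=1e-12)
        assert meff_peluso(spec(2, 2, 0, 0)) == pytest.approx(4.1636, abs=5e-3)

    def test_identity_undefined(self):
        with pytest.raises(DataError, match="undefined"):
            meff_peluso(spec(*([1.0] * 4)))

    def test_can_exceed_M(self):
        # near-identity spectrum: tiny log(lambda_max) inflates the estimate
        s = spec(1.05, *([0.999] * 20), 0.93)
        assert meff_peluso(s) > s.M


class TestBaselinesAndThresholds:
    def test_bonferroni_reports_M(self):
        assert meff_baseline(761, "bonferroni").value == 761.0

    def test_minimal(self):
        assert meff_baseline(1, "bonferroni").value == 1.0
        assert meff_baseline(10, "sidak").value == 10.0

    def test_bonferroni_type_pwer(self):
        assert adjusted_pwer(0.05, 10, "bonferroni-type").pwer == pytest.approx(0.005)

    def test_sidak_identity_case(self):
        assert adjusted_pwer(0.05, 1, "sidak-type").pwer == pytest.approx(0.05)

    def test_sidak_761_rescaling(self):
        thr = adjusted_pwer(0.05, 761, "sidak-type")
        assert thr.pwer == pytest.approx(6.740e-5, rel=1e-3)
        assert round(0.05 / thr.pwer) == 742

    def test_sidak_first_order_is_bonferroni(self):
        # the ratio tends to 1 + alpha/2, so relative agreement is O(alpha)
        for M in (10, 100, 1000):
            s = adjusted_pwer(0.05, M, "sidak-type").pwer
            b = adjusted_pwer(0.05, M, "bonferroni-type").pwer
            assert s == pytest.approx(b, rel=0.03)

    def test_effective_tests_from_pwer(self):
        assert effective_tests_from_pwer(0.05, 0.05) == pytest.approx(1.0)
        assert effective_tests_from_pwer(0.05, 0.005) == pytest.approx(10.0)
        meff0 = effective_tests_from_pwer(0.05, 1 - 0.95 ** (1 / 761))
        assert meff0 == pytest.approx(741.84, abs=0.01)
        assert round(meff0) == 742

    def test_pwer_errors(self):
        with pytest.raises(DataError):
            adjusted_pwer(0.0, 10, "bonferroni-type")
        with pytest.raises(DataError):
            adjusted_pwer(0.05, 0.5, "sidak-type")
        with pytest.raises(DataError):
            effective_tests_from_pwer(0.05, 0.1)


class TestSpectrumProperties:
    def test_identity_estimators_equal_M(self):
        s = spec(*([1.0] * 30))
        assert meff_nyholt(s) == pytest.approx(30.0)
        assert meff_liji(s) == pytest.approx(30.0)
        assert meff_galwey(s) == pytest.approx(30.0)

    @pytest.mark.parametrize("estimator", [meff_nyholt, meff_liji, meff_galwey, meff_gao])
    def test_nonincreasing_in_rho(self, estimator):
        values = [estimator(equicorr_spectrum(20, rho)) for rho in np.linspace(0, 0.99, 12)]
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    def test_bounded_by_M_on_unit_trace_spectra(self, rng):
        for _ in range(20):
            x = rng.standard_normal((40, 8))
            s = eigenvalues(
                AssociationMatrix(np.corrcoef(x, rowvar=False), "pearson",
                                  [f"f{i}" for i in range(8)])
            )
            for f in (meff_nyholt, meff_liji, meff_galwey):
                assert 1.0 - 1e-9 <= f(s) <= 8.0 + 1e-9
            assert 1 <= meff_gao(s) <= 8


class TestGrouped:
    def test_single_group_equals_ungrouped(self, rng):
        X = make_features(rng.standard_normal((60, 6)))
        partition = GroupPartition({f: "all" for f in X.feature_ids})
        g = meff_grouped(X, partition, "pearson", "galwey")
        u = disco_pad(X, "galwey", corr_method="pearson")[0]
        assert g.value == pytest.approx(u.value, abs=1e-10)
        assert g.per_group["all"] == pytest.approx(u.value, abs=1e-10)

    def test_independent_identity_blocks_sum(self):
        # exactly orthogonal columns: identity correlation, galwey = group size
        X = orthonormal_features(32, 5)
        partition = GroupPartition(
            {f: ("a" if i < 3 else "b") for i, f in enumerate(X.feature_ids)}
        )
        g = meff_grouped(X, partition, "pearson", "galwey")
        assert g.per_group["a"] == pytest.approx(3.0, abs=1e-8)
        assert g.per_group["b"] == pytest.approx(2.0, abs=1e-8)
        assert g.value == pytest.approx(5.0, abs=1e-8)

    def test_singleton_group_contributes_one(self, rng):
        X = make_features(rng.standard_normal((30, 4)))
        partition = GroupPartition(
            {X.feature_ids[0]: "solo", **{f: "rest" for f in X.feature_ids[1:]}}
        )
        with pytest.warns(UserWarning, match="singleton"):
            g = meff_grouped(X, partition, "pearson", "nyholt")
        assert g.per_group["solo"] == 1.0
        g2 = meff_grouped(X, partition, "pearson", "liji")
        assert g2.per_group["solo"] == 1.0

    def test_reference_cardinalities_partition(self):
        cards = (365, 99, 181, 24, 25, 32, 10, 25)
        assert sum(cards) == 761
        ids = [f"m{i}" for i in range(761)]
        p = random_partition(ids, cards, seed=3)
        assert sorted(p.cardinalities().values()) == sorted(cards)
        p.validate_against(ids)

    def test_per_group_sums_to_value(self, rng):
        X = make_features(rng.standard_normal((50, 9)))
        partition = random_partition(X.feature_ids, [3, 3, 3], seed=5)
        g = meff_grouped(X, partition, "pearson", "liji")
        assert g.value == pytest.approx(sum(g.per_group.values()))


class TestDiscoPad:
    def test_large_n_consistency(self):
        X = iid_normal(20, 2000, seed=42)
        est, thr = disco_pad(X, "liji", alpha=0.05, style="bonferroni-type")
        assert est.value == pytest.approx(20.0, abs=2.0)
        assert thr.pwer == pytest.approx(0.05 / est.value)

    def test_duplicated_features_galwey(self, rng):
        base = orthonormal_features(64, 5)
        dup = np.hstack([base.values, base.values])
        X = make_features(dup)
        est, _ = disco_pad(X, "galwey", corr_method="pearson")
        assert est.value == pytest.approx(5.0, abs=1e-6)

    def test_pearson_branch_shares_code_path(self, rng):
        X = make_features(rng.standard_normal((40, 5)))
        from discopad.assoc import pearson_matrix

        est, _ = disco_pad(X, "liji", corr_method="pearson")
        direct = meff_from_matrix(pearson_matrix(X), "liji")
        assert est.value == direct.value

    def test_deterministic(self, rng):
        X = make_features(rng.standard_normal((30, 6)))
        a = disco_pad(X, "galwey")[0].value
        b = disco_pad(X, "galwey")[0].value
        assert a == b

    def test_grouped_matrix_route_matches(self, rng):
        X = make_features(rng.standard_normal((40, 6)))
        from discopad.assoc import distance_matrix

        partition = random_partition(X.feature_ids, [3, 3], seed=1)
        via_x = meff_grouped(X, partition, "distance", "galwey")
        via_a = grouped_from_matrix(distance_matrix(X), partition, "galwey")
        assert via_x.value == pytest.approx(via_a.value, abs=1e-12)
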