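import math

import mpmath as mp
import pytest
from hypothesis import given

from fermadm import (
    FFN,
    complement,
    dominance_leq,
    ff_add,
    ff_mul,
    ff_power,
    ff_scale,
    ffdywa,
    ffdywg,
)

from conftest import ffn_series, ffns


def mp_dywa(series, weights, dps=50):
    """High-precision direct-product oracle for the averaging operator."""
    with mp.workdps(dps):
        surv = mp.mpf(1)
        nu = mp.mpf(1)
        for f, w in zip(series, weights):
            surv *= (1 - mp.mpf(f.mu) ** 3) ** mp.mpf(w)
            nu *= mp.mpf(f.nu) ** mp.mpf(w)
        return float(mp.cbrt(1 - surv)), float(nu)


def mp_dywg(series, weights, dps=50):
    with mp.workdps(dps):
        mu = mp.mpf(1)
        surv = mp.mpf(1)
        for f, w in zip(series, weights):
            mu *= mp.mpf(f.mu) ** mp.mpf(w)
            surv *= (1 - mp.mpf(f.nu) ** 3) ** mp.mpf(w)
        return float(mu), float(mp.cbrt(1 - surv))


class TestOperationalLaws:
    def test_dynamic_sum_direct_evaluation(self):
        out = ff_add(FFN(0.7, 0.6), FFN(0.8, 0.7))
        assert out.mu == pytest.approx(math.cbrt(0.343 + 0.512 - 0.343 * 0.512), abs=1e-12)
        assert out.nu == pytest.approx(0.42, abs=1e-12)

    def test_dynamic_product_direct_evaluation(self):
        out = ff_mul(FFN(0.9, 0.3), FFN(0.8, 0.6))
        assert out.mu == pytest.approx(0.72, abs=1e-12)
        assert out.nu == pytest.approx(math.cbrt(0.027 + 0.216 - 0.027 * 0.216), abs=1e-12)

    @given(ffns())
    def test_sum_identity_and_absorbing_elements(self, f):
        out = ff_add(f, FFN(0.0, 1.0))
        assert (out.mu, out.nu) == pytest.approx((f.mu, f.nu), abs=1e-12)
        absorbed = ff_add(FFN(1.0, 0.0), f)
        assert (absorbed.mu, absorbed.nu) == (1.0, 0.0)

    @given(ffns())
    def test_product_identity_and_absorbing_elements(self, f):
        out = ff_mul(f, FFN(1.0, 0.0))
        assert (out.mu, out.nu) == pytest.approx((f.mu, f.nu), abs=1e-12)
        absorbed = ff_mul(FFN(0.0, 1.0), f)
        assert (absorbed.mu, absorbed.nu) == (0.0, 1.0)

    @given(ffns(), ffns())
    def test_de_morgan_duality_of_sum_and_product(self, f1, f2):
        lhs = complement(ff_add(f1, f2))
        rhs = ff_mul(complement(f1), complement(f2))
        assert (lhs.mu, lhs.nu) == pytest.approx((rhs.mu, rhs.nu), abs=1e-12)

    def test_scalar_multiple_direct_evaluation(self):
        out = ff_scale(0.25, FFN(0.7, 0.6))
        assert out.mu == pytest.approx(math.cbrt(1 - 0.657**0.25), abs=1e-12)
        assert out.nu == pytest.approx(0.6**0.25, abs=1e-12)

    def test_power_direct_evaluation(self):
        out = ff_power(FFN(0.9, 0.3), 0.25)
        assert out.mu == pytest.approx(0.9**0.25, abs=1e-12)
        assert out.nu == pytest.approx(math.cbrt(1 - 0.973**0.25), abs=1e-12)

    @given(ffns())
    def test_unit_exponent_is_identity(self, f):
        for out in (ff_scale(1.0, f), ff_power(f, 1.0)):
            assert (out.mu, out.nu) == pytest.approx((f.mu, f.nu), abs=1e-12)

    def test_scale_and_power_fixed_points(self):
        for eps in (0.1, 1.0, 4.0):
            assert ff_scale(eps, FFN(0.0, 1.0)) == FFN(0.0, 1.0)
            assert ff_power(FFN(1.0, 0.0), eps) == FFN(1.0, 0.0)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_exponent_rejected(self, bad):
        with pytest.raises(ValueError):
            ff_scale(bad, FFN(0.5, 0.5))
        with pytest.raises(ValueError):
            ff_power(FFN(0.5, 0.5), bad)


class TestPublishedAggregates:
    """Regression against printed worked-example values (3-decimal source,
    hence the ±0.002 band)."""

    def test_averaging_three_period_series(self):
        out = ffdywa([FFN(0.7, 0.6), FFN(0.8, 0.7), FFN(0.9, 0.5)], [0.25, 0.3, 0.45])
        assert out.mu == pytest.approx(0.841, abs=0.002)
        assert out.nu == pytest.approx(0.578, abs=0.002)

    def test_averaging_four_period_series(self):
        out = ffdywa(
            [FFN(0.8, 0.7), FFN(0.6, 0.7), FFN(0.6, 0.8), FFN(0.9, 0.4)],
            [0.2, 0.4, 0.3, 0.1],
        )
        assert out.mu == pytest.approx(0.710, abs=0.002)
        assert out.nu == pytest.approx(0.688, abs=0.002)

    def test_geometric_four_period_series(self):
        out = ffdywg(
            [FFN(0.9, 0.4), FFN(0.8, 0.5), FFN(0.7, 0.3), FFN(0.6, 0.5)],
            [0.25, 0.47, 0.13, 0.15],
        )
        assert out.mu == pytest.approx(0.775, abs=0.002)
        assert out.nu == pytest.approx(0.461, abs=0.002)

    def test_geometric_three_period_series_membership_and_closure(self):
        # The published non-membership for this input (0.881) breaks the
        # operator's own closure guarantee (0.781^3 + 0.881^3 > 1); the
        # closed form gives 0.681, confirmed here against the oracle.
        series = [FFN(0.9, 0.3), FFN(0.8, 0.6), FFN(0.7, 0.8)]
        eps = [0.25, 0.35, 0.4]
        out = ffdywg(series, eps)
        assert out.mu == pytest.approx(0.781, abs=0.002)
        mu_ref, nu_ref = mp_dywg(series, eps)
        assert out.nu == pytest.approx(nu_ref, abs=1e-12)
        assert out.nu == pytest.approx(0.681, abs=0.002)
        assert out.mu**3 + out.nu**3 <= 1 + 1e-12


class TestOperatorProperties:
    @given(ffn_series(min_size=1, max_size=6))
    def test_closure(self, sw):
        series, ws = sw
        for op in (ffdywa, ffdywg):
            out = op(series, ws)
            assert out.mu**3 + out.nu**3 <= 1 + 1e-12

    @given(ffns(), ffn_series(min_size=3, max_size=3))
    def test_idempotency(self, f, sw):
        _, ws = sw
        for op in (ffdywa, ffdywg):
            out = op([f, f, f], ws)
            assert (out.mu, out.nu) == pytest.approx((f.mu, f.nu), abs=1e-12)

    @given(ffn_series(min_size=2, max_size=6))
    def test_boundedness_by_componentwise_extremes(self, sw):
        series, ws = sw
        mus = [f.mu for f in series]
        nus = [f.nu for f in series]
        for op in (ffdywa, ffdywg):
            out = op(series, ws)
            assert min(mus) - 1e-12 <= out.mu <= max(mus) + 1e-12
            assert min(nus) - 1e-12 <= out.nu <= max(nus) + 1e-12

    @given(ffn_series(min_size=2, max_size=5), ffns())
    def test_monotonicity_in_dominance_order(self, sw, g):
        series, ws = sw
        # raise one entry to a dominating value
        idx = len(series) // 2
        f = series[idx]
        better = FFN(max(f.mu, g.mu), min(f.nu, g.nu))
        if better.mu**3 + better.nu**3 > 1:
            return
        improved = list(series)
        improved[idx] = better
        for op in (ffdywa, ffdywg):
            assert dominance_leq(op(series, ws), op(improved, ws))

    @given(ffn_series(min_size=1, max_size=6))
    def test_duality_through_complement(self, sw):
        series, ws = sw
        lhs = ffdywg(series, ws)
        rhs = complement(ffdywa([complement(f) for f in series], ws))
        assert (lhs.mu, lhs.nu) == pytest.approx((rhs.mu, rhs.nu), abs=1e-12)

    @given(ffn_series(min_size=1, max_size=6))
    def test_averaging_dominates_geometric(self, sw):
        series, ws = sw
        avg, geo = ffdywa(series, ws), ffdywg(series, ws)
        assert avg.mu >= geo.mu - 1e-12
        assert avg.nu <= geo.nu + 1e-12

    @given(ffn_series(min_size=1, max_size=6))
    def test_log_space_kernel_matches_high_precision_oracle(self, sw):
        series, ws = sw
        for op, oracle in ((ffdywa, mp_dywa), (ffdywg, mp_dywg)):
            out = op(series, ws)
            mu_ref, nu_ref = oracle(series, ws)
            assert out.mu == pytest.approx(mu_ref, abs=1e-12)
            assert out.nu == pytest.approx(nu_ref, abs=1e-12)

    @given(ffns())
    def test_single_period_with_unit_weight_reduces_to_input(self, f):
        for op in (ffdywa, ffdywg):
            out = op([f], [1.0])
            assert (out.mu, out.nu) == pytest.approx((f.mu, f.nu), abs=1e-12)

    def test_length_mismatch_and_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            ffdywa([FFN(0.5, 0.5)], [0.5, 0.5])
        with pytest.raises(ValueError):
            ffdywa([FFN(0.5, 0.5), FFN(0.4, 0.4)], [0.9, 0.3])
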