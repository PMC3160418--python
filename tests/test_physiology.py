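"""Transfer functions of the vascular loop: anchors, monotonicity, mixing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from setpointnet import (
    PhysiologyParams,
    chemoreceptor_discharge,
    flow_from_efferent,
    mix_venous,
    pulmonary_exchange,
    sample_mixing_weights,
    tissue_gas_exchange,
)


class TestFlowFromEfferent:
    def test_calibration_anchor(self, phys):
        # mid-range discharge E = kappa gives nominal flow F = 1
        assert flow_from_efferent(0.5, phys) == pytest.approx(1.0)

    def test_hand_value(self, phys):
        assert flow_from_efferent(0.05, phys) == pytest.approx(10.0)

    @given(e1=st.floats(0.05, 1.0), e2=st.floats(0.05, 1.0))
    def test_strictly_decreasing(self, e1, e2):
        phys = PhysiologyParams()
        if e1 < e2:
            f1, f2 = flow_from_efferent(e1, phys), flow_from_efferent(e2, phys)
            assert f1 >= f2
            if e2 - e1 > 1e-9:
                assert f1 > f2

    def test_clips_out_of_range_discharge(self, phys):
        assert flow_from_efferent(0.01, phys) == flow_from_efferent(0.05, phys)
        assert flow_from_efferent(3.0, phys) == flow_from_efferent(1.0, phys)

    def test_rejects_non_finite(self, phys):
        with pytest.raises(ValueError):
            flow_from_efferent(np.nan, phys)


class TestTissueGasExchange:
    def test_nominal_flow_gives_normal_venous_tensions(self, phys):
        po2v, pco2v = tissue_gas_exchange(1.0, phys)
        assert po2v == pytest.approx(40.0)
        assert pco2v == pytest.approx(45.0)

    def test_zero_flow_carbon_dioxide_extreme(self, phys):
        # stagnant blood equilibrates toward the 90 mmHg venous extreme
        _, pco2v = tissue_gas_exchange(1e-9, phys)
        assert pco2v == pytest.approx(90.0, abs=1e-5)

    def test_high_flow_asymptotes(self, phys):
        po2v, pco2v = tissue_gas_exchange(1e3, phys)
        assert po2v == pytest.approx(phys.po2v_max)
        assert pco2v == pytest.approx(phys.pco2v_asymptote, abs=0.1)

    def test_monotone_in_flow(self, phys):
        F = np.linspace(0.05, 10, 200)
        po2v, pco2v = tissue_gas_exchange(F, phys)
        assert np.all(np.diff(po2v) > 0)
        assert np.all(np.diff(pco2v) < 0)

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.inf])
    def test_rejects_non_positive_flow(self, phys, bad):
        with pytest.raises(ValueError):
            tissue_gas_exchange(bad, phys)


class TestMixingWeights:
    def test_range(self, phys, rng):
        w = sample_mixing_weights(rng, 10_000, phys)
        assert np.all((w >= 0) & (w <= 1))

    def test_degenerate_sd(self, rng):
        phys = PhysiologyParams(noise_sd=0.0)
        assert np.all(sample_mixing_weights(rng, 100, phys) == 1.0)

    def test_mean_matches_truncated_normal(self, phys, rng):
        """Empirical mean agrees with the closed-form truncated-normal mean."""
        w = sample_mixing_weights(rng, 400_000, phys)
        a = (0.0 - phys.noise_mean) / phys.noise_sd
        b = (1.0 - phys.noise_mean) / phys.noise_sd
        expected = stats.truncnorm.mean(a, b, loc=phys.noise_mean,
                                        scale=phys.noise_sd)
        assert w.mean() == pytest.approx(expected, abs=3e-3)


class TestMixVenous:
    def test_constant_field_is_preserved(self, rng):
        w = rng.uniform(0.01, 1, 20)
        mo, mc = mix_venous(np.full(20, 40.0), np.full(20, 45.0), w)
        assert mo == pytest.approx(40.0)
        assert mc == pytest.approx(45.0)

    def test_single_tissue_passthrough(self):
        mo, mc = mix_venous([33.0], [52.0], [0.4])
        assert (mo, mc) == (33.0, 52.0)

    def test_hand_average(self):
        mo, _ = mix_venous([30.0, 50.0], [45.0, 45.0], [1.0, 1.0])
        assert mo == pytest.approx(40.0)

    @given(st.integers(1, 12), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_convex_combination_bounds(self, n, seed):
        r = np.random.default_rng(seed)
        po2v = r.uniform(3, 60, n)
        pco2v = r.uniform(40, 90, n)
        w = r.uniform(0.01, 1, n)
        mo, mc = mix_venous(po2v, pco2v, w)
        assert po2v.min() - 1e-9 <= mo <= po2v.max() + 1e-9
        assert pco2v.min() - 1e-9 <= mc <= pco2v.max() + 1e-9

    def test_all_zero_weights_signal_resample(self):
        with pytest.raises(ValueError, match="resample"):
            mix_venous([40.0, 40.0], [45.0, 45.0], [0.0, 0.0])


class TestPulmonaryExchange:
    def test_normal_venous_gives_normal_arterial(self, phys):
        assert pulmonary_exchange(40.0, 45.0, phys) == (95.0, 40.0)

    def test_threshold_boundary_is_continuous(self, phys):
        assert pulmonary_exchange(39.55, 45.2, phys) == (95.0, 40.0)
        eps = 1e-9
        po2a, pco2a = pulmonary_exchange(39.55 - eps, 45.2 + eps, phys)
        assert po2a == pytest.approx(95.0, abs=1e-6)
        assert pco2a == pytest.approx(40.0, abs=1e-6)

    def test_linear_degradation(self, phys):
        # impaired diffusion: 95 - 2*(39.55-35), 40 + 2*(50-45.2)
        assert pulmonary_exchange(35.0, 50.0, phys) == \
            (pytest.approx(85.9), pytest.approx(49.6))

    def test_per_gas_independence(self, phys):
        # one abnormal gas does not drag the other off normal
        po2a, pco2a = pulmonary_exchange(30.0, 45.0, phys)
        assert po2a < 95.0 and pco2a == 40.0
        po2a, pco2a = pulmonary_exchange(40.0, 50.0, phys)
        assert po2a == 95.0 and pco2a > 40.0

    def test_oxygen_floor(self, phys):
        po2a, _ = pulmonary_exchange(0.0, 45.0, phys)
        assert po2a >= 0.0

    def test_rejects_negative_input(self, phys):
        with pytest.raises(ValueError):
            pulmonary_exchange(-1.0, 45.0, phys)


class TestChemoreceptorDischarge:
    def test_silent_at_normal_arterial(self, phys):
        assert chemoreceptor_discharge(95.0, 40.0, phys) == 0.0

    def test_silent_above_normal_oxygen_below_normal_co2(self, phys):
        assert chemoreceptor_discharge(100.0, 35.0, phys) == 0.0

    def test_hand_value(self, phys):
        # deficits of 10 mmHg each: 0.5*(e^0.5-1)*2
        expected = np.expm1(0.5)
        assert chemoreceptor_discharge(85.0, 50.0, phys) == \
            pytest.approx(expected)

    def test_clipped_at_one(self, phys):
        assert chemoreceptor_discharge(0.0, 120.0, phys) == 1.0

    @given(st.floats(0, 95), st.floats(40, 100))
    def test_increasing_in_each_deficit(self, po2a, pco2a):
        phys = PhysiologyParams()
        c = chemoreceptor_discharge(po2a, pco2a, phys)
        c_worse = chemoreceptor_discharge(max(0.0, po2a - 1), pco2a + 1, phys)
        assert 0.0 <= c <= 1.0
        assert c_worse >= c


class TestParams:
    def test_calibration_identity_is_exact(self, phys):
        po2v, pco2v = tissue_gas_exchange(1.0, phys)
        assert po2v == pytest.approx(phys.venous_po2_normal, abs=1e-12)
        assert pco2v == pytest.approx(phys.venous_pco2_normal, abs=1e-12)

    def test_round_trip_fixed_point(self, phys):
        """The zero-error operating point exists by construction."""
        F = flow_from_efferent(phys.flow_scale, phys)
        po2v, pco2v = tissue_gas_exchange(F, phys)
        po2a, pco2a = pulmonary_exchange(po2v, pco2v, phys)
        assert chemoreceptor_discharge(po2a, pco2a, phys) == 0.0

    @pytest.mark.parametrize("kwargs", [
        {"flow_scale": -0.5},
        {"o2_threshold": 41.0},
        {"co2_threshold": 44.0},
        {"o2_slope": 0.0},
        {"pco2v_zero_flow": 30.0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhysiologyParams(**kwargs)


def test_monotone_chain_efferent_to_chemoreceptor(phys, rng):
    """Raising every efferent rate starves tissues and raises C."""
    n = 30
    E = rng.uniform(0.1, 0.8, n)
    w = rng.uniform(0.1, 1.0, n)

    def chain(E):
        F = flow_from_efferent(E, phys)
        po2v, pco2v = tissue_gas_exchange(F, phys)
        mo, mc = mix_venous(po2v, pco2v, w)
        return mo, mc, chemoreceptor_discharge(*pulmonary_exchange(mo, mc, phys),
                                               phys)

    mo_lo, mc_lo, c_lo = chain(E)
    mo_hi, mc_hi, c_hi = chain(np.clip(E + 0.15, 0.05, 1.0))
    assert mo_hi <= mo_lo
    assert mc_hi >= mc_lo
    assert c_hi >= c_lo
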