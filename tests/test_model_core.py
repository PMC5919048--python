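"""Peleg-Fermi sigmoid, double-exponential parameter functions, inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irepf import (
    DoubleExponential,
    PelegFermiParams,
    eval_double_exponential,
    field_at_survival,
    pulse_count_family,
    pulse_length_family,
    survival_percent,
    survival_surface,
)
from irepf.errors import (
    DegenerateSteepnessError,
    DomainError,
    ExtrapolationWarning,
    InvalidParameterError,
)

TABLE_100US_EC = DoubleExponential(8.428, -0.2237, 1.038, -0.003552)
TABLE_100US_A = DoubleExponential(1.0790, -0.33910, 0.1678, -0.01329)


class TestSurvivalPercent:
    def test_half_kill_at_ec(self):
        p = PelegFermiParams(ec=1.3, a_steep=0.2)
        assert survival_percent(1.3, p) == pytest.approx(50.0)

    def test_one_percent_survival_at_calibrated_parameters(self):
        # E_c and A from the 100-us family evaluated at n = 90; the field at
        # 1 % survival is the closed-form E_c + A ln 99 = 0.98713 kV/cm.
        p = PelegFermiParams(ec=0.75397, a_steep=0.050739)
        assert survival_percent(0.98713, p) == pytest.approx(1.000, abs=5e-4)

    def test_deep_tail_limit(self):
        p = PelegFermiParams(ec=1.0, a_steep=0.05)
        s = survival_percent(1.0 + 20 * 0.05, p)
        assert s == pytest.approx(100.0 / (1.0 + np.e**20), rel=1e-12)

    def test_strictly_decreasing_in_field(self):
        p = PelegFermiParams(ec=0.9, a_steep=0.07)
        sweep = survival_percent(np.linspace(0.0, 5.0, 200), p)
        assert np.all(np.diff(sweep) < 0)

    @pytest.mark.parametrize("bad_a", [0.0, -0.1])
    def test_rejects_nonpositive_steepness(self, bad_a):
        with pytest.raises(InvalidParameterError):
            PelegFermiParams(ec=1.0, a_steep=bad_a)

    def test_rejects_nonfinite_field(self):
        p = PelegFermiParams(ec=1.0, a_steep=0.1)
        with pytest.raises(InvalidParameterError):
            survival_percent(np.nan, p)


class TestDoubleExponential:
    def test_calibrated_ec_at_n90(self):
        # frozen from direct double-precision arithmetic on the 100-us row:
        # 8.428 e^(-20.133) + 1.038 e^(-0.31968) = 0.753984
        assert eval_double_exponential(90, TABLE_100US_EC) == pytest.approx(
            0.753984, abs=2e-6
        )

    def test_rate_zero_is_constant(self):
        de = DoubleExponential(3.7, 0.0, 0.0, 0.0)
        assert eval_double_exponential(123.0, de) == pytest.approx(3.7)

    def test_single_exponential_row(self):
        # one-pulse E_c(t) family row: 44.3 * exp(-0.0162 * 100) = 8.767
        de = DoubleExponential(44.300, -0.01620, 0.0, 0.0)
        assert eval_double_exponential(100, de) == pytest.approx(8.767, abs=5e-4)

    def test_negative_x_rejected(self):
        with pytest.raises(DomainError):
            eval_double_exponential(-1.0, TABLE_100US_EC)


class TestSurvivalSurface:
    def test_composition_at_n90(self, family_100us):
        assert survival_surface(0.98713, 90, family_100us) == pytest.approx(
            1.00, abs=5e-3
        )

    def test_half_kill_on_the_ec_curve(self, family_100us):
        ec = eval_double_exponential(45, family_100us.ec_fn)
        assert survival_surface(ec, 45, family_100us) == pytest.approx(50.0)

    def test_one_percent_at_n60(self, family_100us):
        # E_c(60) + A(60) ln 99 = 1.18616 kV/cm
        assert survival_surface(1.18616, 60, family_100us) == pytest.approx(
            1.00, abs=5e-3
        )

    def test_degenerate_steepness_identifies_x(self):
        fam = pulse_count_family(100.0).__class__(
            ec_fn=TABLE_100US_EC,
            a_fn=DoubleExponential(-1.0, 0.0, 0.0, 0.0),
            mode="vs_pulse_number",
            fixed_other=100.0,
        )
        with pytest.raises(DegenerateSteepnessError, match="x = 5"):
            survival_surface(1.0, 5, fam)

    def test_extrapolation_warns(self, family_100us):
        with pytest.warns(ExtrapolationWarning):
            survival_surface(1.0, 90, family_100us)


class TestFieldAtSurvival:
    def test_fifty_percent_returns_ec(self):
        p = PelegFermiParams(ec=2.2, a_steep=0.3)
        assert field_at_survival(50.0, p) == pytest.approx(2.2, rel=1e-14)

    @pytest.mark.parametrize(
        "pulse_length, eft_v_cm",
        [(100.0, 987), (25.0, 1397)],
    )
    def test_one_percent_thresholds_at_n90(self, pulse_length, eft_v_cm):
        fam = pulse_count_family(pulse_length)
        e_kv = field_at_survival(1.0, fam.params_at(90))
        assert round(e_kv * 1000.0) == eft_v_cm

    @pytest.mark.parametrize("bad", [0.0, 100.0, -3.0, 104.0])
    def test_domain_errors(self, bad):
        p = PelegFermiParams(ec=1.0, a_steep=0.1)
        with pytest.raises(DomainError):
            field_at_survival(bad, p)

    @given(
        e=st.floats(0.1, 10.0),
        ec=st.floats(0.2, 5.0),
        a=st.floats(0.01, 1.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_round_trip_inversion(self, e, ec, a):
        p = PelegFermiParams(ec=ec, a_steep=a)
        s = survival_percent(e, p)
        # inversion is exact only where s is representably inside (0, 100):
        # beyond that, 100 - s loses the information the inverse needs
        if 1e-3 < s < 100.0 - 1e-3:
            assert field_at_survival(s, p) == pytest.approx(e, rel=1e-10, abs=1e-10)


class TestPackagedFamilies:
    def test_threshold_decreases_with_pulse_count(self, family_100us):
        efts = [
            field_at_survival(1.0, family_100us.params_at(n)) for n in (30, 60, 90)
        ]
        assert efts[0] > efts[1] > efts[2]
        assert [round(e * 1000) for e in efts] == [1461, 1186, 987]

    def test_threshold_nonincreasing_with_pulse_length(self):
        fam = pulse_length_family(60)
        ts = np.arange(10.0, 101.0, 5.0)
        efts = [field_at_survival(1.0, fam.params_at(t)) for t in ts]
        assert np.all(np.diff(efts) <= 1e-12)

    def test_unknown_row_rejected(self):
        with pytest.raises(DomainError):
            pulse_count_family(33.0)
        with pytest.raises(DomainError):
            pulse_length_family(7)
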