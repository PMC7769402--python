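"""mMK survival model: gamma conversion, interrupted-schedule survival,
LQ inversion and RBE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mkrbe import (
    CellLineParams,
    DeliverySchedule,
    DomainGeometry,
    delivery_time,
    gamma,
    lq_invert,
    neg_log_sf,
    rbe,
    repair_rate_from_halftime,
)

TABLE_CELL = CellLineParams(alpha0=0.21, beta0=0.07, repair_rate=0.46)
GAMMA_6MV = gamma(2.34)  # unit-density 0.5-um domain


def naive_neg_log_sf(doses, gaps_min, cell, gamma_gy):
    """Explicit double-loop oracle, units converted by hand."""
    alpha = cell.alpha0 + gamma_gy * cell.beta0
    starts_h = [0.0]
    for g in gaps_min:
        starts_h.append(starts_h[-1] + g / 60.0)
    total = sum(alpha * d + cell.beta0 * d * d for d in doses)
    for n in range(len(doses)):
        for m in range(n + 1, len(doses)):
            decay = math.exp(-cell.repair_rate * (starts_h[m] - starts_h[n]))
            total += 2.0 * cell.beta0 * decay * doses[n] * doses[m]
    return total


class TestGamma:
    def test_zero_energy(self):
        assert gamma(0.0) == 0.0

    def test_hand_unit_conversion(self):
        # 2.34 keV/um in a unit-density 0.5-um sphere:
        # 2.34 * 0.1602176634 / (pi * 0.25) Gy
        expected = 2.34 * 0.1602176634 / (math.pi * 0.25)
        assert gamma(2.34, DomainGeometry(0.5, 1.0)) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(0.47735, abs=5e-6)

    def test_radius_squared_scaling(self):
        g1 = gamma(2.34, DomainGeometry(0.5, 1.0))
        g2 = gamma(2.34, DomainGeometry(1.0, 1.0))
        assert g2 == pytest.approx(g1 / 4.0, rel=1e-12)

    @pytest.mark.parametrize("r_d,rho", [(0.0, 1.0), (0.5, 0.0), (-1.0, 1.0)])
    def test_nonpositive_geometry_rejected(self, r_d, rho):
        with pytest.raises(ValueError):
            DomainGeometry(r_d, rho)


class TestRepairRate:
    def test_ln2_halftime_gives_unit_rate(self):
        assert repair_rate_from_halftime(math.log(2.0)) == pytest.approx(1.0)

    def test_inverse_of_tabulated_rate(self):
        # (a+c) = 0.46 h^-1 corresponds to T_1/2 = ln2/0.46 = 1.5069 h
        assert repair_rate_from_halftime(1.5069) == pytest.approx(0.460, abs=5e-4)

    def test_no_repair_limit(self):
        assert repair_rate_from_halftime(1e12) == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_halftime_rejected(self):
        with pytest.raises(ValueError):
            repair_rate_from_halftime(0.0)


class TestSchedule:
    def test_gap_count_must_match_fields(self):
        with pytest.raises(ValueError, match="interruptions"):
            DeliverySchedule([2.0, 2.0], [10.0, 10.0])

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            DeliverySchedule([-1.0])

    def test_equal_split(self):
        s = DeliverySchedule.equal_split(8.0, 4, 30.0)
        assert s.field_doses == (2.0, 2.0, 2.0, 2.0)
        assert s.interruptions_min == (30.0, 30.0, 30.0)

    def test_delivery_time_additivity(self):
        s = DeliverySchedule.equal_split(8.0, 4, 30.0, dose_rate_gy_min=3.0)
        assert delivery_time(s) == pytest.approx(8.0 / 3.0 + 90.0)
        single = DeliverySchedule([8.0], dose_rate_gy_min=3.0)
        assert delivery_time(single) == pytest.approx(8.0 / 3.0)
        assert delivery_time(DeliverySchedule([0.0])) == 0.0

    def test_zero_dose_rate_rejected(self):
        with pytest.raises(ValueError, match="dose rate"):
            delivery_time(DeliverySchedule([2.0], dose_rate_gy_min=0.0))


class TestNegLogSf:
    def test_single_field_reduces_to_lq(self):
        s = DeliverySchedule([2.0])
        alpha = 0.21 + GAMMA_6MV * 0.07
        expected = alpha * 2.0 + 0.07 * 4.0
        assert neg_log_sf(s, TABLE_CELL, GAMMA_6MV) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(0.76683, abs=5e-6)

    def test_two_fields_one_hour_gap(self):
        s = DeliverySchedule([4.0, 4.0], [60.0])
        val = neg_log_sf(s, TABLE_CELL, GAMMA_6MV)
        assert val == pytest.approx(
            naive_neg_log_sf([4.0, 4.0], [60.0], TABLE_CELL, GAMMA_6MV), abs=1e-12
        )
        assert val == pytest.approx(5.6014, abs=5e-5)

    def test_zero_gaps_collapse_to_total_dose_lq(self):
        s = DeliverySchedule([4.0, 4.0], [0.0])
        single = DeliverySchedule([8.0])
        assert neg_log_sf(s, TABLE_CELL, GAMMA_6MV) == pytest.approx(
            neg_log_sf(single, TABLE_CELL, GAMMA_6MV), rel=1e-12
        )
        alpha = 0.21 + GAMMA_6MV * 0.07
        assert neg_log_sf(s, TABLE_CELL, GAMMA_6MV) == pytest.approx(
            alpha * 8.0 + 0.07 * 64.0, rel=1e-12
        )

    @given(
        doses=st.lists(st.floats(0.0, 10.0), min_size=1, max_size=8),
        data=st.data(),
        rate=st.floats(0.0, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_vectorized_matches_double_loop_oracle(self, doses, data, rate):
        gaps = data.draw(
            st.lists(
                st.floats(0.0, 240.0),
                min_size=len(doses) - 1,
                max_size=len(doses) - 1,
            )
        )
        cell = CellLineParams(0.21, 0.07, rate)
        s = DeliverySchedule(doses, gaps)
        assert neg_log_sf(s, cell, GAMMA_6MV) == pytest.approx(
            naive_neg_log_sf(doses, gaps, cell, GAMMA_6MV), abs=1e-12, rel=1e-12
        )

    def test_reversal_symmetry_equal_doses_and_gaps(self):
        gaps = [10.0, 25.0, 40.0]
        s = DeliverySchedule([2.0] * 4, gaps)
        s_rev = DeliverySchedule([2.0] * 4, gaps[::-1])
        assert neg_log_sf(s, TABLE_CELL, GAMMA_6MV) == pytest.approx(
            neg_log_sf(s_rev, TABLE_CELL, GAMMA_6MV), rel=1e-12
        )


class TestLqInvert:
    def test_zero_effect(self):
        assert lq_invert(0.0, 0.24, 0.07) == 0.0

    @given(
        dose=st.floats(0.0, 30.0),
        alpha=st.floats(0.0, 2.0),
        beta=st.floats(1e-4, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trips_forward_lq(self, dose, alpha, beta):
        nls = alpha * dose + beta * dose**2
        assert lq_invert(nls, alpha, beta) == pytest.approx(dose, abs=1e-9)

    def test_hand_quadratic_oracle(self):
        # (-a + sqrt(a^2 + 4*b*x)) / (2*b) at x=5.6014, a=0.24341, b=0.07
        a, b, x = 0.24341, 0.07, 5.6014
        expected = (-a + math.sqrt(a * a + 4 * b * x)) / (2 * b)
        assert lq_invert(x, a, b) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(7.3741, abs=5e-4)

    def test_zero_beta_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            lq_invert(1.0, 0.2, 0.0)


class TestRbe:
    def test_uninterrupted_schedule_has_unit_rbe(self):
        s = DeliverySchedule([2.0, 2.0, 2.0, 2.0], [0.0, 0.0, 0.0])
        res = rbe(s, TABLE_CELL, GAMMA_6MV)
        assert res.rbe == pytest.approx(1.0, abs=1e-12)
        assert res.reference_dose_gy == pytest.approx(8.0, abs=1e-9)

    def test_result_consistency(self):
        s = DeliverySchedule.equal_split(8.0, 2, 60.0)
        res = rbe(s, TABLE_CELL, GAMMA_6MV)
        assert res.surviving_fraction == pytest.approx(
            math.exp(-res.neg_log_sf), rel=1e-12
        )
        assert res.rbe == pytest.approx(res.reference_dose_gy / 8.0, rel=1e-12)
        assert 0 < res.surviving_fraction <= 1

    @pytest.mark.parametrize(
        "total,n_fields,tau,expected",
        [
            (8.0, 2, 60.0, 0.921),
            (8.0, 4, 30.0, 0.900),
            (2.0, 2, 10.0, 0.990),
        ],
    )
    def test_reported_rbe_values(self, total, n_fields, tau, expected):
        s = DeliverySchedule.equal_split(total, n_fields, tau)
        assert rbe(s, TABLE_CELL, GAMMA_6MV).rbe == pytest.approx(
            expected, abs=0.002
        )

    def test_strictly_decreasing_in_tau(self):
        taus = [0.0, 1.0, 5.0, 15.0, 60.0, 240.0]
        vals = [
            rbe(DeliverySchedule.equal_split(8.0, 2, t), TABLE_CELL, GAMMA_6MV).rbe
            for t in taus
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_non_increasing_in_repair_rate(self):
        s = DeliverySchedule.equal_split(8.0, 4, 30.0)
        vals = [
            rbe(s, CellLineParams(0.21, 0.07, r), GAMMA_6MV).rbe
            for r in [0.0, 0.46, 1.0, 2.0, 5.0]
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_complete_repair_limit(self):
        """As every gap -> inf the cross terms vanish and survival is the sum
        of independent single-field LQ curves; for two 4-Gy fields the
        limiting RBE is ~0.7736."""
        s = DeliverySchedule([4.0, 4.0], [1e9])
        res = rbe(s, TABLE_CELL, GAMMA_6MV)
        alpha = 0.21 + GAMMA_6MV * 0.07
        limit_nls = 2 * (alpha * 4.0 + 0.07 * 16.0)
        assert res.neg_log_sf == pytest.approx(limit_nls, rel=1e-9)
        assert res.rbe == pytest.approx(0.7736, abs=5e-5)

    def test_zero_total_dose_rejected(self):
        with pytest.raises(ValueError):
            rbe(DeliverySchedule([0.0]), TABLE_CELL, GAMMA_6MV)
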