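"""Unit and property tests for the S-state forward models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flashox import (
    FiveSParams,
    FlashPattern,
    FlashProtocol,
    KokParams,
    SStateVector,
    detected_amplitude,
    flash_transition,
    flash_transition_kok,
    interflash_relaxation,
    normalize_to_y3,
    simulate_pattern,
    total_miss,
)
from flashox.errors import (
    ModelMismatchError,
    NormalizationError,
    ParameterError,
    ProtocolError,
)
from flashox.presets import FIVE_S_ROWS


def make_params(alpha=(0, 0, 0, 0), d=1.0, C=1.0, init=(0, 0, 0, 1), **kw):
    return FiveSParams(alpha=alpha, d=d, C=C, init=init, **kw)


class TestFlashTransition:
    def test_lossless_single_step_advance(self):
        state = SStateVector(0, 0, 0, 1, 0)
        new, fast, slow = flash_transition(state, make_params())
        assert new == SStateVector(1, 0, 0, 0, 0)
        assert fast == 1.0 and slow == 0.0

    def test_bifurcation_splits_advancing_flux(self):
        state = SStateVector(0, 0, 0, 1, 0)
        p = make_params(alpha=(0, 0, 0, 0.12), d=0.30)
        new, fast, slow = flash_transition(state, p)
        assert new.s3 == pytest.approx(0.12)
        assert fast == pytest.approx(0.88 * 0.30)   # 0.264
        assert slow == pytest.approx(0.88 * 0.70)   # 0.616
        assert new.s0 == pytest.approx(0.264) and new.s4p == pytest.approx(0.616)

    def test_miss_retains_occupancy(self):
        state = SStateVector(0, 0, 1, 0, 0)
        p = make_params(alpha=(0, 0, 0.785, 0))
        new, fast, _ = flash_transition(state, p)
        assert new.s2 == pytest.approx(0.785)
        assert new.s3 == pytest.approx(0.215)
        assert fast == 0.0

    def test_existing_slow_pool_is_flash_inert(self):
        state = SStateVector(0.2, 0.2, 0.2, 0.1, 0.3)
        new, _, slow = flash_transition(state, make_params(alpha=(0.1,) * 4, d=0.5))
        assert new.s4p == pytest.approx(0.3 + slow)

    @given(
        occ=st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5),
        alpha=st.lists(st.floats(0, 1), min_size=4, max_size=4),
        d=st.floats(0, 1),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_conservation_property(self, occ, alpha, d):
        occ = np.array(occ) / np.sum(occ)
        state = SStateVector(*occ)
        p = make_params(alpha=tuple(alpha), d=d)
        new, fast, slow = flash_transition(state, p)
        assert abs(sum(new.as_array()) - 1.0) < 1e-12
        # O2-producing flux plus pool addition equals what left S3
        assert fast + slow == pytest.approx((1 - alpha[3]) * state.s3, abs=1e-12)


class TestInterflashRelaxation:
    def test_one_time_constant_decay(self):
        state = SStateVector(0, 0, 0, 0, 1)
        p = make_params(tau_s4p=150.0)
        new, released = interflash_relaxation(state, 150.0, p)
        assert released == pytest.approx(1 - math.exp(-1))
        assert new.s0 == pytest.approx(released)

    def test_zero_time_is_identity(self):
        state = SStateVector(0.5, 0, 0, 0, 0.5)
        new, released = interflash_relaxation(state, 0.0, make_params())
        assert released == 0.0 and new == state

    def test_closed_form_partial_pool(self):
        state = SStateVector(0.384, 0, 0, 0, 0.616)
        p = make_params(tau_s4p=150.0)
        _, released = interflash_relaxation(state, 300.0, p)
        assert released == pytest.approx(0.616 * (1 - math.exp(-2)), abs=1e-9)

    def test_negative_interval_rejected(self):
        with pytest.raises(ParameterError):
            interflash_relaxation(SStateVector(1, 0, 0, 0, 0), -1.0, make_params())


class TestDetectedAmplitude:
    def test_prompt_release_undamped(self):
        assert detected_amplitude(1.0, 0.0, 7, make_params()) == 1.0

    def test_geometric_damping_at_flash_16(self):
        p = make_params(C=0.995)
        assert detected_amplitude(1.0, 0.0, 16, p) == pytest.approx(0.995**15)

    def test_window_capture_of_slow_release(self):
        p = make_params(window_ms=30.0, tau_s4p=150.0)
        assert detected_amplitude(0.0, 1.0, 1, p) == pytest.approx(1 - math.exp(-0.2))

    def test_flash_index_is_one_based(self):
        with pytest.raises(ParameterError):
            detected_amplitude(1.0, 0.0, 0, make_params())


class TestKokTransition:
    def test_plain_advance(self):
        state = SStateVector(0, 1, 0, 0, 0)
        new, y = flash_transition_kok(state, KokParams(0.0, 0.0, 1.0, (0, 1, 0, 0)))
        assert new.s2 == 1.0 and y == 0.0

    def test_double_hit_from_s1(self):
        state = SStateVector(0, 1, 0, 0, 0)
        new, y = flash_transition_kok(state, KokParams(0.0, 0.05, 1.0, (0, 1, 0, 0)))
        assert new.s2 == pytest.approx(0.95) and new.s3 == pytest.approx(0.05)
        assert y == 0.0

    def test_release_from_s3(self):
        state = SStateVector(0, 0, 0, 1, 0)
        new, y = flash_transition_kok(state, KokParams(0.1, 0.0, 1.0, (0, 0, 0, 1)))
        assert y == pytest.approx(0.9)
        assert new.s0 == pytest.approx(0.9) and new.s3 == pytest.approx(0.1)

    def test_slow_pool_incompatible_with_kok(self):
        with pytest.raises(ModelMismatchError):
            flash_transition_kok(
                SStateVector(0, 0, 0, 0.5, 0.5), KokParams(0.1, 0.0, 1.0, (0, 0, 0, 1))
            )

    def test_alpha_gamma_budget_enforced(self):
        with pytest.raises(ParameterError):
            KokParams(alpha=0.7, gamma=0.5, C=1.0, init=(1, 0, 0, 0))


class TestSimulatePattern:
    def test_period_four_limit(self, standard_protocol):
        p = make_params(init=(0, 1, 0, 0))
        amps = simulate_pattern(p, standard_protocol).amplitudes
        nonzero = np.nonzero(amps > 1e-12)[0]
        assert list(nonzero) == [2, 6, 10, 14]
        assert np.allclose(amps[nonzero], amps[2])

    def test_control_first_maximum_at_third_flash(self, standard_protocol):
        amps = simulate_pattern(FIVE_S_ROWS["control"], standard_protocol).amplitudes
        assert int(np.argmax(amps[:5])) == 2  # flash 3, 1-based

    def test_second_flash_yield_from_initial_s2(self, standard_protocol):
        amps = simulate_pattern(FIVE_S_ROWS["control"], standard_protocol).amplitudes
        assert amps[1] > 0

    def test_conservation_through_full_train(self, standard_protocol):
        p = FIVE_S_ROWS["pq"]
        state = p.initial_state()
        for i, t in enumerate(standard_protocol.flash_times):
            if i:
                state, _ = interflash_relaxation(
                    state, t - standard_protocol.flash_times[i - 1], p
                )
            state, _, _ = flash_transition(state, p)
        assert abs(sum(state.as_array()) - 1.0) < 1e-9

    def test_kok_equivalence_of_five_s_with_d_one(self, standard_protocol):
        alpha, C, init = 0.08, 0.99, (0.1, 0.7, 0.15, 0.05)
        five_s = make_params(alpha=(alpha,) * 4, d=1.0, C=C, init=init)
        kok = KokParams(alpha=alpha, gamma=0.0, C=C, init=init)
        a1 = simulate_pattern(five_s, standard_protocol).amplitudes
        a2 = simulate_pattern(kok, standard_protocol).amplitudes
        np.testing.assert_allclose(a1, a2, atol=1e-14)

    def test_increasing_alpha2_decreases_third_flash(self, standard_protocol):
        base = FIVE_S_ROWS["control"]
        lo = simulate_pattern(base, standard_protocol).amplitudes[2]
        bumped = FiveSParams(
            alpha=(0.001, 0.001, 0.85, 0.001), d=base.d, C=base.C, init=base.init
        )
        hi = simulate_pattern(bumped, standard_protocol).amplitudes[2]
        assert hi < lo

    def test_decreasing_C_damps_late_flashes(self, standard_protocol):
        base = FIVE_S_ROWS["control"]
        dimmed = FiveSParams(alpha=base.alpha, d=base.d, C=0.95, init=base.init)
        r_base = simulate_pattern(base, standard_protocol).amplitudes
        r_dim = simulate_pattern(dimmed, standard_protocol).amplitudes
        assert r_dim[14] / r_dim[2] < r_base[14] / r_base[2]


class TestNormalization:
    def test_divides_by_third_flash(self):
        pat = FlashPattern(np.array([0, 0.2, 2.0, 1.0]))
        out = normalize_to_y3(pat)
        np.testing.assert_allclose(out.amplitudes, [0, 0.1, 1.0, 0.5])
        assert out.normalization == "y3"

    def test_idempotent(self):
        pat = normalize_to_y3(FlashPattern(np.array([0, 0.2, 2.0, 1.0])))
        again = normalize_to_y3(pat)
        np.testing.assert_array_equal(pat.amplitudes, again.amplitudes)

    def test_zero_third_flash_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_to_y3(FlashPattern(np.array([0.0, 0.0, 0.0, 1.0])))

    def test_errors_scaled_identically(self):
        pat = FlashPattern(np.array([1.0, 1.0, 2.0, 1.0]), errors=np.array([0.2] * 4))
        out = normalize_to_y3(pat)
        np.testing.assert_allclose(out.errors, 0.1)


class TestTotalMiss:
    @pytest.mark.parametrize(
        "row, expected", [("control", 0.788), ("pq", 1.73)]
    )
    def test_preparation_rows(self, row, expected):
        assert total_miss(FIVE_S_ROWS[row]) == pytest.approx(expected)

    def test_zero_misses(self):
        assert total_miss(make_params()) == 0.0


class TestProtocol:
    def test_standard_shape(self):
        p = FlashProtocol.standard()
        assert p.count == 16
        assert p.flash_times[1] - p.flash_times[0] == 300.0

    @pytest.mark.parametrize("pair, idx", [("1-2", 1), ("2-3", 2)])
    def test_varied_interval_placement(self, pair, idx):
        p = FlashProtocol.with_varied_interval(pair, 50.0)
        gaps = np.diff(p.flash_times)
        assert gaps[idx - 1] == 50.0
        assert np.all(np.delete(gaps, idx - 1) == 300.0)

    def test_varied_interval_range_enforced(self):
        with pytest.raises(ProtocolError):
            FlashProtocol.with_varied_interval("2-3", 2.0)
        with pytest.raises(ProtocolError):
            FlashProtocol.with_varied_interval("3-4", 100.0)

    def test_times_strictly_increasing(self):
        with pytest.raises(ProtocolError):
            FlashProtocol((0.0, 300.0, 300.0))


class TestValidation:
    def test_state_must_sum_to_one(self):
        with pytest.raises(ParameterError):
            SStateVector(0.5, 0.5, 0.5, 0, 0)

    def test_probabilities_bounded(self):
        with pytest.raises(ParameterError):
            make_params(alpha=(1.2, 0, 0, 0))

    def test_init_distribution_checked(self):
        with pytest.raises(ParameterError):
            make_params(init=(0.5, 0.2, 0.1, 0.1))
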