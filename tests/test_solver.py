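"""Contrast solving, maximization, feasibility and waveforms."""

import numpy as np
import pytest

from substim import (
    ContrastRequest,
    Device,
    Primary,
    UncontrolledPhotoreceptorError,
    build_a_matrix,
    check_feasibility,
    maximize,
    solve_contrasts,
    waveform,
)
from substim.device import AMatrix
from substim.observer import PHOTORECEPTORS
from substim.synth import (
    default_device,
    gaussian_led,
    oracle_solve,
    random_device,
    random_silent_request,
    synthetic_observer,
)


def identity_amatrix(n):
    labels = PHOTORECEPTORS[:n]
    eye = np.eye(5, n)
    return AMatrix(
        raw=eye,
        normalized=eye,
        controlled=labels,
        all_photoreceptors=PHOTORECEPTORS,
        primaries=tuple(f"P{i}" for i in range(n)),
    )


class TestContrastRequest:
    def test_magnitude_above_one_rejected(self):
        with pytest.raises(ValueError):
            ContrastRequest({"L": 1.5, "M": 0.0, "S": 0.0})

    def test_uncontrolled_photoreceptor_explains_rule(self, device, observer):
        am = build_a_matrix(device, observer)
        req = ContrastRequest({"L": 0, "M": 0, "S": 0, "rod": 0, "mel": 0.2})
        with pytest.raises(UncontrolledPhotoreceptorError, match="4-primary"):
            solve_contrasts(am, req)

    def test_incomplete_request_rejected(self, device, observer):
        am = build_a_matrix(device, observer)
        with pytest.raises(ValueError, match="missing"):
            solve_contrasts(am, ContrastRequest({"L": 0.1}))


class TestSolveContrasts:
    def test_identity_matrix_returns_request(self):
        am = identity_amatrix(3)
        c = solve_contrasts(am, ContrastRequest({"L": 0.2, "M": 0.0, "S": 0.0}))
        np.testing.assert_allclose(c, [0.2, 0.0, 0.0], atol=1e-15)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dev = random_device(rng, n_primaries=int(rng.integers(3, 6)))
        obs = synthetic_observer()
        req = random_silent_request(rng, build_a_matrix(dev, obs).controlled)
        c = solve_contrasts(build_a_matrix(dev, obs), req)
        np.testing.assert_allclose(c, oracle_solve(dev, obs, req), atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_silenced_classes_stay_silent_forward(self, seed):
        rng = np.random.default_rng(1000 + seed)
        dev = default_device()
        obs = synthetic_observer()
        am = build_a_matrix(dev, obs)
        req = random_silent_request(rng, am.controlled)
        c = solve_contrasts(am, req)
        forward = am.controlled_block @ c
        for i, name in enumerate(am.controlled):
            if req.desired[name] == 0.0:
                assert abs(forward[i]) < 1e-10

    def test_linearity_in_the_request(self, device, observer):
        am = build_a_matrix(device, observer)
        base = {"L": 0.0, "M": 0.1, "S": -0.05, "rod": 0.2}
        c1 = solve_contrasts(am, ContrastRequest(base))
        c3 = solve_contrasts(am, ContrastRequest({k: 3 * v for k, v in base.items()}))
        np.testing.assert_allclose(c3, 3 * c1, rtol=1e-10)

    def test_luminance_scale_invariance(self, device, observer):
        scaled = Device(
            tuple(
                Primary(p.name, p.emission, 5 * p.mean_luminance,
                        (5 * p.lum_range[0], 5 * p.lum_range[1]))
                for p in device.primaries
            ),
            device.vlambda,
        )
        req = ContrastRequest({"L": 0, "M": 0, "S": 0.3, "rod": 0})
        c1 = solve_contrasts(build_a_matrix(device, observer), req)
        c2 = solve_contrasts(build_a_matrix(scaled, observer), req)
        np.testing.assert_allclose(c1, c2, rtol=1e-9)


class TestMaximize:
    def test_arithmetic_example(self):
        c, factor = maximize(np.array([0.5, -0.25, 0.1, 0.05]))
        np.testing.assert_allclose(c, [1.0, -0.5, 0.2, 0.1], rtol=1e-14)
        assert factor == pytest.approx(2.0)

    def test_peak_is_exactly_one(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            c, _ = maximize(rng.normal(size=4))
            assert np.max(np.abs(c)) == 1.0

    def test_already_maximal_is_unchanged(self):
        v = np.array([1.0, -0.5, 0.2])
        c, factor = maximize(v)
        np.testing.assert_array_equal(c, v)
        assert factor == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            maximize(np.zeros(4))

    def test_photoreceptor_contrasts_scale_proportionally(self, device, observer):
        am = build_a_matrix(device, observer)
        req = ContrastRequest({"L": 0, "M": 0, "S": 0, "rod": 0.1})
        c = solve_contrasts(am, req)
        scaled, factor = maximize(c)
        np.testing.assert_allclose(
            am.normalized @ scaled, factor * (am.normalized @ c), rtol=1e-12, atol=1e-14
        )


class TestCheckFeasibility:
    def make_device(self, lum, hi, vlambda):
        prims = tuple(
            Primary(f"P{i}", gaussian_led(p, 20), lum, (0.0, hi))
            for i, p in enumerate((460, 520, 590, 640))
        )
        return Device(prims, vlambda)

    def test_envelope_arithmetic(self, vlambda):
        dev = self.make_device(100.0, 200.0, vlambda)
        sol = check_feasibility(np.full(4, 0.5), dev)
        np.testing.assert_allclose(sol.min_luminance, 50.0)
        np.testing.assert_allclose(sol.max_luminance, 150.0)
        assert sol.feasible

    def test_contrast_above_100_percent_flagged(self, vlambda):
        dev = self.make_device(100.0, 500.0, vlambda)
        sol = check_feasibility(np.array([1.2, 0.1, 0.1, 0.1]), dev)
        assert not sol.feasible_primary[0]
        assert not sol.feasible
        assert any("exceeds 100%" in w for w in sol.warnings)

    def test_luminance_range_violation_flagged(self, vlambda):
        dev = self.make_device(100.0, 120.0, vlambda)
        sol = check_feasibility(np.array([0.5, 0.1, 0.1, 0.1]), dev)
        assert sol.max_luminance[0] == pytest.approx(150.0)
        assert not sol.feasible_primary[0]
        assert sol.feasible_primary[1]

    def test_tiny_contrast_warns_but_stays_feasible(self, vlambda):
        dev = self.make_device(100.0, 200.0, vlambda)
        sol = check_feasibility(np.array([0.001, 0.1, 0.1, 0.1]), dev)
        assert sol.feasible
        assert any("resolution" in w for w in sol.warnings)

    def test_negative_contrast_envelope_uses_magnitude(self, vlambda):
        dev = self.make_device(100.0, 200.0, vlambda)
        pos = check_feasibility(np.full(4, 0.5), dev)
        neg = check_feasibility(np.full(4, -0.5), dev)
        np.testing.assert_array_equal(pos.min_luminance, neg.min_luminance)
        np.testing.assert_array_equal(pos.max_luminance, neg.max_luminance)

    def test_maximized_vector_never_violates_contrast_magnitude(self, observer):
        rng = np.random.default_rng(11)
        for seed in range(10):
            dev = random_device(rng)
            am = build_a_matrix(dev, observer)
            req = random_silent_request(rng, am.controlled)
            c, _ = maximize(solve_contrasts(am, req))
            sol = check_feasibility(c, dev)
            assert not any("exceeds 100%" in w for w in sol.warnings)


class TestWaveform:
    def test_mean_luminance_at_t0_and_peak_at_quarter_period(self, device):
        c = np.array([0.5, -0.25, 0.1, 0.05])
        t, lum = waveform(device, c, frequency=1.0, n_samples=5, duration=1.0)
        means = device.mean_luminances
        np.testing.assert_allclose(lum[:, 0], means, rtol=1e-12)
        # t = 0.25 s is the quarter period of a 1 Hz sine
        np.testing.assert_allclose(lum[:, 1], means * (1 + c), rtol=1e-9)

    def test_counterphase_series_sum_to_twice_mean(self, device):
        c = np.array([0.5, -0.25, 0.1, 0.05])
        _, pos = waveform(device, c, 4.0, 100, 1.0)
        _, neg = waveform(device, -c, 4.0, 100, 1.0)
        expected = np.broadcast_to(2 * device.mean_luminances[:, None], pos.shape)
        np.testing.assert_allclose(pos + neg, expected, rtol=1e-12)

    @pytest.mark.parametrize("freq,n", [(0.0, 10), (-1.0, 10), (2.0, 1)])
    def test_invalid_parameters_rejected(self, device, freq, n):
        with pytest.raises(ValueError):
            waveform(device, np.zeros(4), freq, n, 1.0)
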