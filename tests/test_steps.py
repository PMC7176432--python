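"""Step fitting: exact segmentation, BIC selection, counting, dwell gaps."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from smtrace import simkit, steps
from smtrace.errors import InvalidArgumentError
from smtrace.traces import FluorescenceTrace


def trace_from(y, dt=0.1, **meta):
    y = np.asarray(y, dtype=float)
    return FluorescenceTrace("t", np.arange(y.size) * dt, y, meta=meta)


def brute_force_loglik(y, m, min_len=2):
    """Exhaustive enumeration over all change-point placements."""
    n = y.size
    best = -np.inf
    positions = range(min_len, n - min_len + 1)
    for cps in itertools.combinations(positions, m - 1):
        bounds = list(zip((0, *cps), (*[c - 1 for c in cps], n - 1)))
        if any(b - a + 1 < min_len for a, b in bounds):
            continue
        sse = sum(((y[a:b + 1] - y[a:b + 1].mean()) ** 2).sum()
                  for a, b in bounds)
        sigma2 = max(sse / n, 1e-12)
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
        best = max(best, loglik)
    return best


class TestNormalize:
    def test_scaling(self):
        t = steps.normalize_trace(trace_from(np.full(10, 800.0)))
        assert np.allclose(t.intensity, 1.0)
        assert t.meta["scale"] == 800.0
        one_probe = steps.normalize_trace(trace_from(np.full(10, 80.0)))
        assert np.allclose(one_probe.intensity, 0.1)
        ident = steps.normalize_trace(trace_from(np.full(10, 3.0)), scale=1.0)
        assert np.allclose(ident.intensity, 3.0)


class TestFitLevels:
    def test_flat_trace_single_level(self):
        fit = steps.fit_levels(trace_from(np.full(30, 42.0)), 1)
        assert fit.levels == pytest.approx([42.0])
        assert fit.change_points.size == 0

    def test_noiseless_jump_located_exactly(self):
        y = np.concatenate([np.full(12, 10.0), np.full(18, 90.0)])
        fit = steps.fit_levels(trace_from(y), 2)
        assert list(fit.change_points) == [12]
        assert fit.levels == pytest.approx([10.0, 90.0])

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_matches_brute_force_enumeration(self, m, rng):
        for _ in range(8):
            n = int(rng.integers(10, 41))
            y = rng.normal(0, 1, n) + rng.choice([0.0, 3.0], n)
            fit = steps.fit_levels(trace_from(y), m)
            oracle = brute_force_loglik(y, min(m, n // 2))
            assert fit.log_likelihood == pytest.approx(oracle, abs=1e-9)

    def test_k_validation(self):
        with pytest.raises(InvalidArgumentError):
            steps.fit_levels(trace_from(np.zeros(5)), 0)
        with pytest.raises(InvalidArgumentError):
            steps.fit_levels(trace_from(np.zeros(5)), 6)

    def test_bic_identity(self):
        y = np.concatenate([np.full(20, 0.0), np.full(20, 5.0)])
        fit = steps.fit_levels(trace_from(y + 0.01 * np.sin(np.arange(40))), 2)
        n_params = fit.levels.size + 1 + fit.change_points.size
        expected = -2 * fit.log_likelihood + n_params * np.log(40)
        assert fit.bic == pytest.approx(expected)

    def test_loglik_nondecreasing_in_k(self, rng):
        y = rng.normal(0, 1, 60) + np.repeat([0, 4, 0], 20)
        logliks = [steps.fit_levels(trace_from(y), k).log_likelihood
                   for k in range(1, 7)]
        assert np.all(np.diff(logliks) >= -1e-9)

    def test_scaling_invariance_of_path(self, rng):
        y = rng.normal(0, 20, 80) + np.repeat([0, 80], 40)
        t1 = steps.normalize_trace(trace_from(y), scale=800.0)
        t2 = steps.normalize_trace(trace_from(2 * y), scale=1600.0)
        f1 = steps.fit_levels(t1, 2)
        f2 = steps.fit_levels(t2, 2)
        assert np.array_equal(f1.path, f2.path)

    def test_determinism(self, rng):
        y = rng.normal(0, 10, 100) + np.repeat([0, 80], 50)
        t = trace_from(y)
        f1, f2 = steps.fit_levels(t, 3), steps.fit_levels(t, 3)
        assert np.array_equal(f1.path, f2.path)
        assert f1.bic == f2.bic


class TestBicSelection:
    def test_noiseless_flat_selects_one(self):
        curve = steps.bic_model_selection(trace_from(np.full(60, 5.0)))
        assert curve.selected == 1

    def test_four_state_staircase_selected(self, rng):
        hits = 0
        for _ in range(100):
            y = np.concatenate([np.full(100, v)
                                for v in (0.0, 80.0, 160.0, 240.0)])
            y = y + rng.normal(0, 20, 400)  # SNR 4
            if steps.bic_model_selection(trace_from(y)).selected == 4:
                hits += 1
        assert hits >= 90

    def test_constructed_knee_found(self):
        # BIC strictly decreasing then flat: knee at the flattening point
        y = np.concatenate([np.full(50, v) for v in (0.0, 1.0, 2.0)])
        y = y + np.random.default_rng(0).normal(0, 0.1, 150)
        curve = steps.bic_model_selection(trace_from(y))
        assert curve.selected == 3

    def test_k_max_validated(self):
        with pytest.raises(InvalidArgumentError):
            steps.bic_model_selection(trace_from(np.zeros(10)), k_max=1)


class TestCountBleachSteps:
    def test_baseline_only(self):
        assert steps.count_bleach_steps(trace_from(np.full(50, 3.0))) == 0

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    def test_noiseless_label_consistency(self, n):
        y = np.concatenate([np.full(40, 80.0 * (n - i)) for i in range(n + 1)])
        assert steps.count_bleach_steps(trace_from(y)) == n

    def test_single_egfp_classification_rate(self):
        single = 0
        for i in range(120):
            cfg = simkit.SimConfig(n_frames=600, seed=40000 + i)
            tr, _ = simkit.simulate_photobleaching_trace(1, cfg,
                                                         bleach_rate=0.1)
            single += steps.count_bleach_steps(tr) == 1
        assert single / 120 >= 0.90


class TestFixedLevels:
    def test_flat_baseline_counts_zero(self):
        t = trace_from(np.full(60, 1.0))
        probes, intensity = steps.count_max_bound(t, np.arange(8) * 80.0)
        assert probes == 0
        assert intensity == pytest.approx(1.0)

    def test_simulated_occupancy_recovered(self):
        scheme = simkit.BindingScheme(n_sites=7, k_on_per_site=0.05,
                                      k_off_per_site=0.15)
        cfg = simkit.SimConfig(n_frames=600, seed=5)
        tr, truth = simkit.simulate_binding_trace(scheme, "always-on", cfg)
        probes, intensity = steps.count_max_bound(tr, np.arange(8) * 80.0)
        assert probes == _max_sustained(truth.path)
        assert intensity == pytest.approx(80.0 * probes, rel=0.1)

    def test_occupancy_histogram_multinomial(self):
        est, true = [], []
        levels = np.arange(8) * 80.0
        scheme = simkit.BindingScheme(n_sites=7, k_on_per_site=0.03,
                                      k_off_per_site=0.12)
        for i in range(150):
            cfg = simkit.SimConfig(n_frames=400, seed=50000 + i)
            tr, truth = simkit.simulate_binding_trace(scheme, "always-on", cfg)
            est.append(steps.count_max_bound(tr, levels)[0])
            true.append(_max_sustained(truth.path))
        est_hist = np.bincount(est, minlength=8) / len(est)
        true_hist = np.bincount(true, minlength=8) / len(true)
        se = np.sqrt(true_hist * (1 - true_hist) / len(est))
        assert np.all(np.abs(est_hist - true_hist) <= 3.5 * se + 0.02)

    def test_empty_levels_rejected(self):
        with pytest.raises(InvalidArgumentError):
            steps.count_max_bound(trace_from(np.zeros(10)), [])


def _max_sustained(path, min_run=3):
    best = 0
    run, prev = 0, None
    for s in path:
        run = run + 1 if s == prev else 1
        prev = s
        if run >= min_run:
            best = max(best, s)
    return int(best)


class TestCalibrateLevels:
    def test_recovers_quantized_levels(self):
        traces = []
        for i in range(12):
            cfg = simkit.SimConfig(n_frames=600, seed=100 + i)
            tr, _ = simkit.simulate_binding_trace(
                simkit.BindingScheme(n_sites=3, k_on_per_site=0.03,
                                     k_off_per_site=0.05),
                "always-on", cfg,
            )
            traces.append(steps.normalize_trace(tr, 800.0))
        levels = steps.calibrate_levels(traces)
        assert levels.size == 4
        assert np.allclose(levels, [0.0, 0.1, 0.2, 0.3], atol=0.02)
        spacing = np.diff(levels)
        assert np.allclose(spacing, 0.1, atol=0.02)  # one probe = 0.1 scaled

    def test_identical_flat_traces_single_level(self, rng):
        traces = [trace_from(np.full(200, 0.1) + rng.normal(0, 0.02, 200))
                  for _ in range(5)]
        assert steps.calibrate_levels(traces).size == 1

    def test_needs_two_traces(self):
        with pytest.raises(InvalidArgumentError):
            steps.calibrate_levels([trace_from(np.zeros(10))])


class TestDwellGaps:
    def test_single_binding_event_empty(self):
        path = np.concatenate([np.zeros(10), np.ones(30)]).astype(int)
        assert len(steps.extract_dwell_gaps(path, 0.1)) == 0

    def test_gap_arithmetic(self):
        path = np.zeros(80, dtype=int)
        path[10:] = 1
        path[30:] = 2
        path[50:] = 3
        gaps = steps.extract_dwell_gaps(path, 0.1)
        assert sorted(gaps.gaps) == pytest.approx([2.0, 4.0])

    def test_no_upward_transition_is_empty_not_error(self):
        assert len(steps.extract_dwell_gaps(np.zeros(20, dtype=int), 0.1)) == 0

    def test_collection_stops_at_permanent_zero(self):
        path = np.array([0, 0, 1, 1, 0, 0, 0, 1, 1, 0], dtype=int)
        # second binding group occurs before the final return to zero
        gaps = steps.extract_dwell_gaps(path, 1.0)
        assert list(gaps.gaps) == [5.0]

    def test_gated_binding_has_heavy_tail(self):
        all_gaps = []
        scheme = simkit.BindingScheme(n_sites=7, k_on_per_site=0.3,
                                      k_off_per_site=0.25, phospho_gated=True,
                                      probe_bleach_rate=0.01)
        driver = simkit.TelegraphParams(k_gen=0.8, k_rem=0.58)
        for i in range(60):
            cfg = simkit.SimConfig(n_frames=1800, seed=60000 + i)
            _, truth = simkit.simulate_binding_trace(scheme, driver, cfg)
            all_gaps.extend(steps.extract_dwell_gaps(truth.path, 0.1).gaps)
        all_gaps = np.asarray(all_gaps)
        assert all_gaps.size > 100
        assert np.mean(all_gaps > 10.0) > 0.05  # tail beyond tens of seconds


@given(st.integers(min_value=0, max_value=10_000))
def test_fit_is_deterministic_across_calls(seed):
    rng = np.random.default_rng(seed % 7)
    y = rng.normal(0, 15, 60) + np.repeat([0.0, 80.0, 0.0], 20)
    t = trace_from(y)
    a = steps.bic_model_selection(t, k_max=5)
    b = steps.bic_model_selection(t, k_max=5)
    assert a.selected == b.selected
    assert np.array_equal(a.bic, b.bic)
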