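"""Generator correctness: trivial constructions, closed forms, determinism."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from smtrace import simkit
from smtrace.errors import InvalidArgumentError


def cfg(n_frames=100, noise_sd=0.0, seed=0, **kw):
    return simkit.SimConfig(n_frames=n_frames, noise_sd=noise_sd, seed=seed, **kw)


class TestPhotobleaching:
    def test_zero_fluorophores_flat_at_background(self):
        trace, truth = simkit.simulate_photobleaching_trace(
            0, cfg(background_level=30.0)
        )
        assert np.all(trace.intensity == 30.0)
        assert truth.events == []

    def test_single_fluorophore_one_step_of_unit_intensity(self):
        trace, truth = simkit.simulate_photobleaching_trace(
            1, cfg(n_frames=200, noise_sd=0.0, seed=5), bleach_rate=1.0
        )
        assert len(truth.events) == 1
        values = np.unique(trace.intensity)
        assert set(values) <= {0.0, 80.0}
        drops = np.diff(trace.intensity)
        assert np.sum(drops < 0) == 1
        assert drops[drops < 0][0] == -80.0

    def test_noiseless_trace_is_nonincreasing_step_function(self):
        trace, truth = simkit.simulate_photobleaching_trace(
            4, cfg(n_frames=5000, noise_sd=0.0, seed=9), bleach_rate=0.05
        )
        steps_down = np.diff(trace.intensity)
        assert np.all(steps_down <= 0)
        assert np.sum(steps_down < 0) == len(truth.events) <= 4

    def test_mean_bleach_time_matches_exponential(self):
        times = []
        for i in range(1000):
            _, truth = simkit.simulate_photobleaching_trace(
                1, cfg(n_frames=2000, seed=i), bleach_rate=0.1
            )
            if truth.events:
                times.append(truth.events[0][0])
        # the 200 s window censors a vanishing e^-20 tail
        mean = np.mean(times)
        se = 10.0 / np.sqrt(len(times))
        assert abs(mean - 10.0) < 3 * se

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            simkit.simulate_photobleaching_trace(-1, cfg())
        with pytest.raises(InvalidArgumentError):
            simkit.SimConfig(n_frames=0)


class TestTelegraph:
    def test_absorbing_cases(self):
        on = simkit.simulate_telegraph(
            simkit.TelegraphParams(k_gen=1.0, k_rem=0.0), 50.0, cfg(n_frames=500)
        )
        switched = np.flatnonzero(on.path == 1)
        assert np.all(on.path[switched[0]:] == 1)
        off = simkit.simulate_telegraph(
            simkit.TelegraphParams(k_gen=0.0, k_rem=1.0), 50.0, cfg(n_frames=500)
        )
        assert np.all(off.path == 0)

    def test_stationary_fraction(self):
        p = simkit.TelegraphParams(k_gen=0.8, k_rem=0.58)
        truth = simkit.simulate_telegraph(p, 1e4, cfg(n_frames=100000, seed=3))
        n_trans = len(truth.events)
        tol = 3.0 / np.sqrt(n_trans)
        assert abs(truth.path.mean() - 0.580) < tol

    def test_rejects_degenerate_rates(self):
        with pytest.raises(InvalidArgumentError):
            simkit.TelegraphParams(k_gen=0.0, k_rem=0.0)


class TestBinding:
    def test_no_on_rate_flat_baseline(self):
        scheme = simkit.BindingScheme(k_on_per_site=0.0, k_off_per_site=0.1)
        trace, truth = simkit.simulate_binding_trace(scheme, "always-on", cfg())
        assert np.all(truth.path == 0)
        assert np.all(trace.intensity == 0.0)

    def test_absorbing_saturates_at_n_sites(self):
        scheme = simkit.BindingScheme(
            n_sites=3, k_on_per_site=1.0, k_off_per_site=0.0
        )
        trace, truth = simkit.simulate_binding_trace(
            scheme, "always-on", cfg(n_frames=1000)
        )
        assert truth.path.max() == 3
        assert truth.path[-1] == 3

    def test_stationary_occupancy(self):
        k_on, k_off = 0.3, 0.6
        scheme = simkit.BindingScheme(
            n_sites=1, k_on_per_site=k_on, k_off_per_site=k_off
        )
        occ = []
        for i in range(40):
            _, truth = simkit.simulate_binding_trace(
                scheme, "always-on", cfg(n_frames=20000, seed=i)
            )
            occ.append(truth.path.mean())
        expected = k_on / (k_on + k_off)
        assert abs(np.mean(occ) - expected) < 0.02

    def test_occupancy_never_exceeds_sites(self):
        scheme = simkit.BindingScheme(
            n_sites=4, k_on_per_site=2.0, k_off_per_site=0.5
        )
        _, truth = simkit.simulate_binding_trace(
            scheme, simkit.TelegraphParams(), cfg(n_frames=2000, seed=7)
        )
        assert truth.path.max() <= 4


class TestFretSimulation:
    def test_static_half_efficiency_channels_equal(self):
        scheme = simkit.FretScheme(e_levels=(0.5,), switch_rates=((0.0,),),
                                   beta=0.0)
        trace, _ = simkit.simulate_fret_trace(scheme, cfg())
        sl = trace.analysis_slice
        assert np.allclose(trace.donor[sl], trace.acceptor[sl])

    def test_leakage_only_apparent_efficiency(self):
        # E_true = 0 with beta = 0.12 reads beta/(1+beta) apparent
        scheme = simkit.FretScheme(e_levels=(0.0,), switch_rates=((0.0,),),
                                   beta=0.12)
        trace, _ = simkit.simulate_fret_trace(scheme, cfg())
        sl = trace.analysis_slice
        apparent = trace.acceptor[sl] / (trace.donor[sl] + trace.acceptor[sl])
        assert np.allclose(apparent, 0.12 / 1.12)

    def test_donor_bleach_zeroes_both_channels(self):
        scheme = simkit.FretScheme(e_levels=(0.6,), switch_rates=((0.0,),),
                                   donor_bleach_rate=2.0)
        trace, truth = simkit.simulate_fret_trace(scheme, cfg(n_frames=400))
        t_bleach = truth.params["donor_bleach_time"]
        dark = trace.time >= max(t_bleach, trace.check_frames * 0.1)
        assert np.all(trace.donor[dark] == 0.0)
        assert np.all(trace.acceptor[dark] == 0.0)

    def test_stationary_occupancy_of_levels(self):
        scheme = simkit.FretScheme()
        pi = scheme.stationary()
        assert pi == pytest.approx([0.35, 0.65])


class TestProgressCurves:
    def test_zero_time_gives_zero_count(self):
        curves = simkit.simulate_progress_curves(
            simkit.MMParams(), [10.0, 100.0], [0.0, 5.0, 10.0, 20.0],
            500, 0.8, cfg(n_frames=1)
        )
        for curve in curves:
            assert curve.counts[0] == 0

    def test_saturation_and_half_rate_identities(self):
        mm = simkit.MMParams(K_M=29.2, k_cat_max=0.22)
        expected = simkit.expected_progress(mm, 29.2, [1e9], 500, 1.0)
        assert expected[0] == pytest.approx(500.0)
        assert mm.rate(29.2) == pytest.approx(0.11)

    def test_labeling_eff_validated(self):
        with pytest.raises(InvalidArgumentError):
            simkit.simulate_progress_curves(
                simkit.MMParams(), [10.0], [1.0, 2.0], 10, 1.5, cfg()
            )


class TestInhibitionSeries:
    def test_zero_concentration_is_full_activity(self):
        comp = simkit.CompetitionParams()
        table = simkit.simulate_inhibition_series(
            comp, [0.0, 1.0, 10.0], 1.0, 1, 0.0, cfg(n_frames=1)
        )
        assert table["activity_pct"][0] == pytest.approx(100.0)

    def test_no_phosphatase_steady_state_is_flat(self):
        comp = simkit.CompetitionParams()
        # steady-state telegraph occupancy saturates without phosphatase:
        # approaching scale -> 0+ the normalised signal flattens out
        f = comp.steady_state_signal(np.array([0.0, 1.0, 10.0]), 1e-9)
        assert np.all(f / f[0] > 0.999)

    def test_half_activity_shifts_down_with_phosphatase(self):
        comp = simkit.CompetitionParams()
        concs = np.logspace(-2, 3, 200)
        crossings = []
        for scale in (0.3, 1.0, 3.0, 10.0):
            table = simkit.simulate_inhibition_series(
                comp, concs, scale, 1, 0.0, cfg(n_frames=1)
            )
            act = table["activity_pct"]
            crossings.append(concs[np.argmin(np.abs(act - 50.0))])
        assert np.all(np.diff(crossings) < 0)


class TestSpotsAndMovies:
    def test_zero_spots_empty_and_spacing_formula(self):
        assert simkit.sample_spot_positions(0, (40.0, 80.0), cfg()).shape == (0, 2)
        # 1000 spots in 40x80 um^2: characteristic spacing sqrt(3200/1000)
        assert np.sqrt(3200.0 / 1000.0) == pytest.approx(1.789, abs=1e-3)

    def test_nearest_neighbour_distance_poisson(self):
        n = 4000
        pos = simkit.sample_spot_positions(n, (100.0, 100.0), cfg(seed=4))
        from scipy.spatial import cKDTree
        d, _ = cKDTree(pos).query(pos, k=2)
        expected = 0.5 / np.sqrt(n / 1e4)
        assert np.mean(d[:, 1]) == pytest.approx(expected, rel=0.05)

    def test_render_conserves_flux(self):
        from smtrace.traces import FluorescenceTrace
        trace = FluorescenceTrace("s", np.arange(5) * 0.1, np.full(5, 800.0))
        stack = simkit.render_movie([(15.0, 15.0)], [trace], 1.0,
                                    (31, 31, 5), cfg(n_frames=5))
        assert stack[0].sum() == pytest.approx(800.0, rel=0.01)

    def test_mismatched_positions_rejected(self):
        with pytest.raises(InvalidArgumentError):
            simkit.render_movie([(5.0, 5.0)], [], 1.0, (11, 11, 2), cfg())


@given(seed=st.integers(min_value=0, max_value=2**31 - 1))
def test_identical_seed_bit_identical_output(seed):
    c = simkit.SimConfig(n_frames=50, noise_sd=15.0, seed=seed)
    t1, g1 = simkit.simulate_photobleaching_trace(2, c)
    t2, g2 = simkit.simulate_photobleaching_trace(2, c)
    assert np.array_equal(t1.intensity, t2.intensity)
    assert g1.events == g2.events
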