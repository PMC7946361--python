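"""Waveforms, parameter sampling, patch placement, noise, source activity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taaspread.geometry import grow_patch, SurfacePatch
from taaspread.sources import (TRIANGLE_AMP, PARAM_RANGES, Q_DEFAULTS,
                               triangle_wave, pulse_wave, pulse_amplitude,
                               sample_params, place_patches, pink_noise,
                               background_noise, correlated_seizure_noise,
                               seizure_activity, source_activity,
                               recruitment_times, SourceParams,
                               SourceConfiguration)
from taaspread.synthetic import make_flat_sheet, make_electrodes, ShaftSpec


class TestWaveforms:
    def test_triangle_extremes(self):
        assert triangle_wave(0.0, 5.0) == pytest.approx(np.sqrt(3.0))
        assert triangle_wave(0.1, 5.0) == pytest.approx(-np.sqrt(3.0))  # half period

    def test_triangle_periodic_zero_mean_unit_variance(self):
        f = 7.0
        t = np.arange(0, 1000 / f, 1e-4)  # 1000 whole periods
        y = triangle_wave(t, f)
        assert np.abs(y).max() <= TRIANGLE_AMP + 1e-12
        assert abs(y.mean()) < 1e-3
        assert abs(y.var() - 1.0) < 1e-3
        np.testing.assert_allclose(triangle_wave(t + 5.0 / f, f), y, atol=1e-9)

    def test_triangle_is_continuous(self):
        t = np.linspace(0, 2, 20001)
        y = triangle_wave(t, 3.0)
        assert np.abs(np.diff(y)).max() < 4 * TRIANGLE_AMP * 3.0 * (t[1] - t[0]) * 1.01

    def test_pulse_levels(self):
        f = 4.0
        assert pulse_wave(0.1 / f, f) == pytest.approx(np.sqrt(16.0 / 3.0))
        assert pulse_wave(0.9 / f, f) == 0.0
        assert pulse_amplitude(0.25) ** 2 == pytest.approx(16.0 / 3.0)

    def test_pulse_duty_fraction_and_variance(self):
        f = 6.0
        t = np.arange(0, 500 / f, 1e-4)
        y = pulse_wave(t, f)
        high = y > 0
        assert abs(high.mean() - 0.25) < 0.01
        assert abs(y.var() - 1.0) < 1e-2

    @given(duty=st.floats(0.05, 0.95))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_pulse_unit_variance_any_duty(self, duty):
        t = np.arange(0, 100.0, 1e-4)
        y = pulse_wave(t, 5.0, duty)
        assert abs(y.var() - 1.0) < 2e-2

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            triangle_wave(0.0, 0.0)


class TestSampling:
    def test_frequency_range_and_mean(self):
        rng = np.random.default_rng(0)
        f = np.array([sample_params("spreading", rng).f for _ in range(10000)])
        assert f.min() >= 4.0 and f.max() <= 13.0
        assert abs(f.mean() - 8.5) < 0.1

    def test_degenerate_range(self):
        rng = np.random.default_rng(0)
        p = sample_params("one_source", rng, ranges={"f": (7.0, 7.0)})
        assert p.f == 7.0

    def test_determinism(self):
        p1 = sample_params("two_sources", np.random.default_rng(5), noisy=True)
        p2 = sample_params("two_sources", np.random.default_rng(5), noisy=True)
        assert p1 == p2

    def test_default_q_table(self):
        rng = np.random.default_rng(0)
        for kind in ("one_source", "two_sources", "spreading"):
            for noisy in (False, True):
                p = sample_params(kind, rng, noisy=noisy)
                assert p.q == Q_DEFAULTS[(kind, noisy)]
                for name, (lo, hi) in PARAM_RANGES.items():
                    val = getattr(p, {"patch_size": "patch_size", "f": "f",
                                      "delta": "delta", "Delta": "Delta",
                                      "u_spread": "u_spread", "u_wave": "u_wave"}[name])
                    if val is not None:
                        assert lo <= val <= hi

    def test_empty_range_errors(self):
        with pytest.raises(ValueError, match="empty"):
            sample_params("one_source", np.random.default_rng(0),
                          ranges={"f": (10.0, 4.0)})


@pytest.fixture(scope="module")
def sheet():
    return make_flat_sheet((40.0, 40.0), 1.0)


@pytest.fixture(scope="module")
def contacts(sheet):
    arr = make_electrodes([ShaftSpec("A", (13.0, 20.0, 2.0), (1, 0, 0))])
    return arr.positions


class TestPlacement:
    def test_no_nearby_vertex_errors(self, sheet):
        rng = np.random.default_rng(0)
        params = SourceParams("one_source", 400.0, 8.0, 8.16, False, delta=5.0)
        far = np.array([[500.0, 500.0, 500.0]])
        with pytest.raises(ValueError, match="15"):
            place_patches(sheet, far, params, rng)

    def test_center_near_contacts(self, sheet, contacts):
        rng = np.random.default_rng(1)
        params = SourceParams("one_source", 400.0, 8.0, 8.16, False, delta=5.0)
        for _ in range(25):
            config = place_patches(sheet, contacts, params, rng)
            center = sheet.vertices[config.patches[0].center]
            dmin = np.linalg.norm(contacts - center, axis=1).min()
            assert dmin < 15.0

    def test_two_source_constraints(self, sheet, contacts):
        rng = np.random.default_rng(2)
        params = SourceParams("two_sources", 800.0, 8.0, 9.96, False,
                              delta=5.0, delta2=5.0, Delta=2.0)
        for _ in range(10):
            config = place_patches(sheet, contacts, params, rng)
            p1, p2 = config.patches
            assert not set(p1.members.tolist()) & set(p2.members.tolist())
            for p in (p1, p2):
                maxa = sheet.vertex_area.max()
                assert 400.0 <= p.area <= 400.0 + maxa + 1e-9
            c1, c2 = sheet.vertices[p1.center], sheet.vertices[p2.center]
            assert np.linalg.norm(c1 - c2) < 10.0

    def test_spreading_origin_in_patch(self, sheet, contacts):
        rng = np.random.default_rng(3)
        params = SourceParams("spreading", 600.0, 8.0, 16.28, False,
                              u_spread=2.0, u_wave=200.0)
        config = place_patches(sheet, contacts, params, rng)
        assert config.origin in config.patches[0].members
        assert config.origin_distance.min() == 0.0
        assert len(config.origin_distance) == len(config.patches[0].members)


class TestPinkNoise:
    def test_unit_variance(self):
        y = pink_noise(2 ** 16, 256.0, np.random.default_rng(0))
        assert 0.95 <= y.var() <= 1.05

    def test_spectral_slope(self):
        fs = 256.0
        n = 2 ** 14
        psds = []
        for seed in range(50):
            y = pink_noise(n, fs, np.random.default_rng(seed))
            spec = np.abs(np.fft.rfft(y)) ** 2 / n
            psds.append(spec)
        freqs = np.fft.rfftfreq(n, 1 / fs)
        mean_psd = np.mean(psds, axis=0)
        sel = (freqs >= 1.0) & (freqs <= fs / 4)
        slope = np.polyfit(np.log10(freqs[sel]), np.log10(mean_psd[sel]), 1)[0]
        assert -1.2 <= slope <= -0.8

    def test_determinism(self):
        a = pink_noise(4096, 256.0, np.random.default_rng(7))
        b = pink_noise(4096, 256.0, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


@pytest.fixture(scope="module")
def patch():
    sheet = make_flat_sheet((40.0, 40.0), 1.5)
    return sheet, grow_patch(sheet, sheet.n_vertices // 2, 350.0)


class TestCorrelatedNoise:
    def _empirical_corr(self, sheet, patch, i, j, n_real=20, dense=True):
        vals = []
        kw = {"dense_threshold": 10 ** 6} if dense else {"dense_threshold": 1,
                                                         "n_anchors": 64}
        for seed in range(n_real):
            nu = correlated_seizure_noise(sheet, patch, 4096, 256.0,
                                          np.random.default_rng(seed), **kw)
            x = nu.full()
            vals.append(np.corrcoef(x[i], x[j])[0, 1])
        return float(np.mean(vals))

    def test_same_vertex_correlation_one(self, patch):
        sheet, p = patch
        nu = correlated_seizure_noise(sheet, p, 2048, 256.0, np.random.default_rng(0))
        x = nu.full()
        assert np.corrcoef(x[0], x[0])[0, 1] == pytest.approx(1.0)
        # unit variance per vertex (expectation-normalized, sampling tolerance)
        assert np.abs(x.var(axis=1).mean() - 1.0) < 0.1

    @pytest.mark.parametrize("dense", [True, False])
    def test_kernel_decay_at_correlation_length(self, patch, dense):
        sheet, p = patch
        from taaspread.geometry import geodesic_distances
        d = geodesic_distances(sheet, int(p.members[0]))[p.members]
        j = int(np.argmin(np.abs(d - 10.0)))
        corr = self._empirical_corr(sheet, p, 0, j, dense=dense)
        assert abs(corr - np.exp(-d[j] / 10.0)) < 0.1

    def test_far_pair_nearly_uncorrelated(self):
        sheet = make_flat_sheet((70.0, 12.0), 1.5)
        patch = grow_patch(sheet, 0, sheet.total_area)
        from taaspread.geometry import geodesic_distances
        d = geodesic_distances(sheet, int(patch.members[0]))[patch.members]
        j = int(np.argmin(np.abs(d - 55.0)))
        vals = []
        for seed in range(10):
            nu = correlated_seizure_noise(sheet, patch, 4096, 256.0,
                                          np.random.default_rng(seed))
            x0, xj = nu.chunk(slice(None))[[0, j]]
            vals.append(np.corrcoef(x0, xj)[0, 1])
        assert abs(np.mean(vals)) < 0.1

    def test_series_are_pink(self, patch):
        sheet, p = patch
        nu = correlated_seizure_noise(sheet, p, 2 ** 14, 256.0,
                                      np.random.default_rng(0))
        x = nu.full()[::40]
        spec = np.abs(np.fft.rfft(x, axis=1)) ** 2
        freqs = np.fft.rfftfreq(2 ** 14, 1 / 256.0)
        sel = (freqs >= 1.0) & (freqs <= 64.0)
        slope = np.polyfit(np.log10(freqs[sel]),
                           np.log10(spec.mean(axis=0)[sel]), 1)[0]
        assert -1.3 <= slope <= -0.7


@pytest.fixture(scope="module")
def spreading_setup():
    sheet = make_flat_sheet((40.0, 40.0), 1.0)
    patch_ = grow_patch(sheet, sheet.n_vertices // 2, 800.0)
    from taaspread.geometry import geodesic_distances
    origin = int(patch_.members[0])
    dist = geodesic_distances(sheet, origin)[patch_.members]
    config = SourceConfiguration([patch_], origin=origin, origin_distance=dist)
    params = SourceParams("spreading", 800.0, 8.0, 16.28, False, t0=10.0,
                          u_spread=2.0, u_wave=200.0)
    return sheet, config, params


class TestSourceActivity:
    def test_recruitment_time_matches_distance(self, spreading_setup):
        sheet, config, params = spreading_setup
        d = config.origin_distance
        v = int(np.argmin(np.abs(d - 10.0)))
        t_recruit = params.t0 + d[v] / params.u_spread
        t = np.array([t_recruit - 0.01, t_recruit + 0.01])
        _, recruited = seizure_activity(config, params, t)
        assert not recruited[v, 0] and recruited[v, 1]

    def test_recruitment_monotone_and_complete(self, spreading_setup):
        sheet, config, params = spreading_setup
        t = np.linspace(0.0, 60.0, 61)
        _, recruited = seizure_activity(config, params, t)
        assert np.all(recruited[:, :-1] <= recruited[:, 1:])  # never un-recruited
        assert recruited[:, -1].all()                          # whole patch in the end
        times = recruitment_times(config, params)
        order = np.argsort(config.origin_distance)
        assert np.all(np.diff(times[order]) >= 0)

    def test_one_source_envelope_half(self):
        sheet = make_flat_sheet((20.0, 20.0), 1.0)
        patch = grow_patch(sheet, 0, 100.0)
        config = SourceConfiguration([patch])
        params = SourceParams("one_source", 100.0, 8.0, 1.0, False, t0=5.0, delta=4.0)
        t = np.array([params.t0 + params.delta / 2.0])
        act, rec = seizure_activity(config, params, t)
        expected = 0.5 * triangle_wave(params.delta / 2.0, params.f)
        np.testing.assert_allclose(act[:, 0], expected)
        assert rec.all()

    def test_two_source_with_zero_delay_reduces_to_one_source(self):
        sheet = make_flat_sheet((20.0, 20.0), 1.0)
        patch = grow_patch(sheet, 0, 150.0)
        half = len(patch.members) // 2
        p1 = SurfacePatch(sheet, patch.members[:half], int(patch.members[0]), 0.0)
        p2 = SurfacePatch(sheet, patch.members[half:], int(patch.members[half]), 0.0)
        t = np.linspace(0.0, 20.0, 512)
        one = SourceParams("one_source", 150.0, 6.0, 2.0, False, t0=5.0, delta=3.0)
        two = SourceParams("two_sources", 150.0, 6.0, 2.0, False, t0=5.0,
                           delta=3.0, delta2=3.0, Delta=0.0)
        act1, _ = seizure_activity(SourceConfiguration([patch]), one, t)
        act2, _ = seizure_activity(SourceConfiguration([p1, p2]), two, t)
        np.testing.assert_allclose(act2, act1)

    def test_chunked_evaluation_bitwise_identical(self, spreading_setup):
        sheet, config, params = spreading_setup
        fs = 256.0
        n = int(20 * fs)
        t = np.arange(n) / fs
        rng = np.random.default_rng(0)
        bg = background_noise(sheet, n, fs, rng)
        full = source_activity(sheet, config, params, bg, t, slice(0, n))
        first = source_activity(sheet, config, params, bg, t[:n // 2], slice(0, n // 2))
        second = source_activity(sheet, config, params, bg, t[n // 2:], slice(n // 2, n))
        np.testing.assert_array_equal(np.concatenate([first, second], axis=1), full)

    def test_unrecruited_vertices_carry_background(self, spreading_setup):
        sheet, config, params = spreading_setup
        fs = 64.0
        n = int(5 * fs)  # all before t0=10: nothing recruited
        t = np.arange(n) / fs
        bg = background_noise(sheet, n, fs, np.random.default_rng(1))
        act = source_activity(sheet, config, params, bg, t, slice(0, n))
        np.testing.assert_array_equal(
            act, bg.vertex_series(np.arange(sheet.n_vertices), slice(0, n)))

    def test_non_uniform_time_errors(self, spreading_setup):
        sheet, config, params = spreading_setup
        bg = background_noise(sheet, 16, 4.0, np.random.default_rng(0))
        with pytest.raises(ValueError, match="uniform"):
            source_activity(sheet, config, params, bg,
                            np.array([0.0, 0.1, 0.3]), slice(0, 3))
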