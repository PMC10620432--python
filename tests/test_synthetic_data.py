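"""List-mode coincidence simulator: geometry, decay statistics, IO."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from petrange.synthetic_data import (
    ActivityComponent,
    ImplantationSpec,
    ListModeParseError,
    PhantomSpec,
    RunConfig,
    ScannerSpec,
    build_decay_schedule,
    detect_pair,
    detect_pairs,
    read_listmode,
    sample_stopping_points,
    simulate_run,
    write_listmode,
)
from petrange.yield_model import BeamCycle, cumulative_decays

O15_COMPONENT = ActivityComponent(
    species="15O", half_life=122.24, yield_per_ion=1.0, positron_rms_range=1.0
)


class TestStoppingPoints:
    def test_empty(self, rng):
        pts = sample_stopping_points(ImplantationSpec(105.0), 0, rng)
        assert pts.shape == (0, 3)

    def test_degenerate_distribution(self, rng):
        impl = ImplantationSpec(105.0, range_straggling_sigma=0.0, lateral_sigma=0.0)
        pts = sample_stopping_points(impl, 100, rng)
        assert np.all(pts == [105.0, 0.0, 0.0])

    def test_median_depth_near_mean_range(self, rng):
        impl = ImplantationSpec(105.0, range_straggling_sigma=2.0)
        pts = sample_stopping_points(impl, 100_000, rng)
        # median of a Normal sample: SE = 1.2533 sigma / sqrt(n) ~ 8 um
        assert abs(np.median(pts[:, 0]) - 105.0) < 0.05

    def test_points_inside_phantom(self, rng, phantom):
        impl = ImplantationSpec(340.0, range_straggling_sigma=20.0)
        pts = sample_stopping_points(impl, 10_000, rng, phantom)
        assert pts[:, 0].max() <= phantom.depth_interval[1]

    def test_mean_range_outside_phantom_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_stopping_points(ImplantationSpec(400.0), 10, rng)


class TestDecaySchedule:
    def test_stable_component_never_decays_in_run(self, rng):
        run = RunConfig(BeamCycle(1.0, 1.5), ions_per_pulse=100, n_cycles=3, rng_seed=1)
        comp = ActivityComponent(
            species="x",
            half_life=1e12,
            yield_per_ion=1.0,
            deterministic=True,
            positron_rms_range=0.0,
        )
        pts = sample_stopping_points(ImplantationSpec(105.0), 300, rng)
        sched = build_decay_schedule([comp], pts, run, rng)
        assert len(sched) == 300
        assert (sched["decay_time"] > run.duration).all()

    def test_beam_off_decays_match_analytic_model(self, rng):
        """Cumulative beam-OFF decay counts track the pulsed activation
        closed form within Poisson fluctuations."""
        cycle = BeamCycle(1.0, 1.5)
        run = RunConfig(cycle, ions_per_pulse=10_000, n_cycles=5, rng_seed=7)
        pts = sample_stopping_points(ImplantationSpec(105.0), 50_000, rng)
        sched = build_decay_schedule([O15_COMPONENT], pts, run, rng)
        t = sched["decay_time"].to_numpy()
        in_run = t[t < run.duration]
        off = in_run[(in_run % cycle.T) >= cycle.t_p]
        for n in range(1, 6):
            expected = cumulative_decays(run.ions_per_pulse, 122.24, cycle, n)
            observed = np.sum(off < n * cycle.T)
            assert abs(observed - expected) < 3 * np.sqrt(expected)

    def test_plateau_component_uniform_depth(self, rng):
        run = RunConfig(BeamCycle(1.0, 1.5), ions_per_pulse=10_000, n_cycles=1, rng_seed=3)
        impl = ImplantationSpec(105.0, range_straggling_sigma=0.0, lateral_sigma=0.0)
        pts = sample_stopping_points(impl, 10_000, rng)
        comp = ActivityComponent(
            species="tf",
            half_life=1220.84,
            yield_per_ion=1.0,
            spatial_kind="plateau",
            positron_rms_range=0.0,
        )
        sched = build_decay_schedule([comp], pts, run, rng)
        ks = stats.kstest(sched["depth"], stats.uniform(0, 105.0).cdf)
        assert ks.pvalue > 0.01

    def test_shifted_peak_moves_upstream(self, rng):
        run = RunConfig(BeamCycle(1.0, 1.5), ions_per_pulse=1000, n_cycles=1, rng_seed=3)
        impl = ImplantationSpec(105.0, range_straggling_sigma=0.0, lateral_sigma=0.0)
        pts = sample_stopping_points(impl, 1000, rng)
        comp = ActivityComponent(
            species="pf",
            half_life=19.31,
            yield_per_ion=1.0,
            spatial_kind="shifted_peak",
            shift=7.0,
            positron_rms_range=0.0,
        )
        sched = build_decay_schedule([comp], pts, run, rng)
        assert np.allclose(sched["depth"], 98.0)

    def test_positron_range_adds_in_quadrature(self, rng):
        """Blurring by the positron range widens the depth spread from
        sigma_straggle to sqrt(sigma_straggle^2 + sigma_blur^2)."""
        run = RunConfig(BeamCycle(1.0, 1.5), ions_per_pulse=200_000, n_cycles=1, rng_seed=5)
        impl = ImplantationSpec(105.0, range_straggling_sigma=2.0, lateral_sigma=0.0)
        pts = sample_stopping_points(impl, 200_000, rng)
        comp = ActivityComponent(
            species="x",
            half_life=122.24,
            yield_per_ion=1.0,
            deterministic=True,
            positron_rms_range=1.0,
        )
        sched = build_decay_schedule([comp], pts, run, rng)
        expected = np.hypot(2.0, 1.0)
        assert sched["depth"].std() == pytest.approx(expected, rel=0.01)

    def test_unknown_spatial_kind_rejected(self):
        with pytest.raises(ValueError):
            ActivityComponent(species="x", half_life=1.0, yield_per_ion=1.0, spatial_kind="blob")

    def test_empty_component_list_rejected(self, rng):
        run = RunConfig(BeamCycle(1.0, 1.5), ions_per_pulse=10, n_cycles=1)
        with pytest.raises(ValueError):
            build_decay_schedule([], np.zeros((10, 3)), run, rng)


class TestDetection:
    def test_perpendicular_lor_always_accepted(self, scanner, phantom):
        """A vertical annihilation axis from under the panel centre hits
        both panels; with unit efficiency and no attenuation the pair is
        always detected."""
        rng = np.random.default_rng(0)
        detected = 0
        for _ in range(200):
            res = detect_pair(
                [112.5, 0.0, 0.0],
                ScannerSpec(per_photon_efficiency=1.0),
                rng,
                phantom,
                attenuation=False,
            )
            if res is not None:
                detected += 1
                (td, tw), (bd, bw) = res
                assert abs(td - 112.5) < 200 and abs(tw) < 200
        # isotropic directions: roughly the geometric acceptance
        assert 0 < detected < 200

    def test_centered_point_source_acceptance(self, phantom, rng):
        """Detected-pair fraction for a centred source equals the
        rectangle solid-angle closed form 2*Omega/4pi = 0.186."""
        sc = ScannerSpec(per_photon_efficiency=1.0)
        n = 400_000
        pos = np.tile([sc.center_depth, 0.0, 0.0], (n, 1))
        ok, _, _ = detect_pairs(pos, sc, rng, phantom, attenuation=False)
        p = 0.18594
        assert abs(ok.mean() - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_vertical_attenuation_survival(self, phantom, scanner):
        """A vertical LOR from the beam plane crosses the full 120 mm
        phantom height; the pair survival is exp(-mu*120) ~ 0.254."""
        from petrange.synthetic_data import _chord_length

        src = np.array([[105.0, 0.0, 0.0]])
        top = np.array([[105.0, 175.0, 0.0]])
        bottom = np.array([[105.0, -175.0, 0.0]])
        path_up = _chord_length(src, top, phantom)[0]
        path_down = _chord_length(src, bottom, phantom)[0]
        assert path_up + path_down == pytest.approx(120.0)
        survival = np.exp(-phantom.mu_511 * (path_up + path_down))
        assert survival == pytest.approx(0.254, abs=0.001)

    def test_hits_quantized_to_crystal_pitch(self, scanner, phantom, rng):
        pos = np.tile([112.5, 0.0, 0.0], (5000, 1))
        ok, top, bot = detect_pairs(pos, scanner, rng, phantom, attenuation=False)
        u0, _ = scanner.panel_depth_interval
        w0, _ = scanner.panel_width_interval
        frac_d = (top[ok, 0] - u0 - 2.0) % 4.0
        frac_w = (bot[ok, 1] - w0 - 2.0) % 4.0
        assert np.allclose(frac_d, 0.0)
        assert np.allclose(frac_w, 0.0)


class TestSimulateRun:
    def make_run(self, seed=11, **kw):
        defaults = dict(
            cycle=BeamCycle(1.0, 1.5),
            ions_per_pulse=5000,
            n_cycles=3,
            rng_seed=seed,
            beam_on_background_rate=1e-3,
        )
        defaults.update(kw)
        return RunConfig(**defaults)

    def test_zero_intensity_yields_no_events(self, phantom, scanner):
        run = self.make_run(ions_per_pulse=0)
        events, truth = simulate_run(
            run, ImplantationSpec(105.0), [O15_COMPONENT], phantom, scanner
        )
        assert len(events) == 0
        assert truth["n_decays_in_run"] == 0

    def test_beam_on_flag_matches_cycle_phase(self, phantom, scanner):
        run = self.make_run()
        events, _ = simulate_run(
            run, ImplantationSpec(105.0), [O15_COMPONENT], phantom, scanner
        )
        T, t_p = run.cycle.T, run.cycle.t_p
        phase = (events["t_ms"].to_numpy() / 1000.0) % T
        assert np.array_equal(events["beam_on"].to_numpy(), phase < t_p)
        assert events["t_ms"].max() < run.duration * 1000

    def test_same_seed_reproduces_event_list(self, phantom, scanner, tmp_path):
        run = self.make_run()
        impl = ImplantationSpec(105.0)
        ev1, _ = simulate_run(run, impl, [O15_COMPONENT], phantom, scanner)
        ev2, _ = simulate_run(run, impl, [O15_COMPONENT], phantom, scanner)
        p1 = write_listmode(ev1, tmp_path / "a.tsv")
        p2 = write_listmode(ev2, tmp_path / "b.tsv")
        assert p1.read_bytes() == p2.read_bytes()

    def test_detected_beam_off_counts_scale_with_model(self, phantom):
        """Beam-OFF event counts ~ pair acceptance x analytic decay yield."""
        sc = ScannerSpec(per_photon_efficiency=1.0)
        run = self.make_run(
            ions_per_pulse=40_000, n_cycles=4, beam_on_background_rate=0.0
        )
        impl = ImplantationSpec(105.0, lateral_sigma=2.0)
        events, truth = simulate_run(run, impl, [O15_COMPONENT], phantom, sc)
        n_off = int((~events["beam_on"]).sum())
        model_decays = cumulative_decays(run.ions_per_pulse, 122.24, run.cycle, 4)
        # acceptance for a source near the FoV centre, attenuated; bounded
        # above by the geometric acceptance and below by full-chord loss
        upper = 0.186 * model_decays
        lower = 0.186 * np.exp(-0.01141 * 120) * model_decays * 0.5
        assert lower < n_off < upper
        assert sum(truth["beam_off_decays_per_cycle"]) >= n_off


class TestListModeIO:
    def test_roundtrip_empty(self, tmp_path):
        empty = pd.DataFrame(
            columns=[
                "t_ms",
                "top_depth_mm",
                "top_width_mm",
                "bottom_depth_mm",
                "bottom_width_mm",
                "beam_on",
            ]
        )
        path = write_listmode(empty, tmp_path / "e.tsv")
        df, _ = read_listmode(path)
        assert len(df) == 0

    def test_roundtrip_preserves_fields(self, phantom, scanner, tmp_path):
        run = RunConfig(BeamCycle(1.0, 1.5), ions_per_pulse=20_000, n_cycles=2, rng_seed=4)
        events, _ = simulate_run(
            run, ImplantationSpec(105.0), [O15_COMPONENT], phantom, scanner
        )
        path = write_listmode(events, tmp_path / "r.tsv", scanner, phantom, seed=4)
        df, sidecar = read_listmode(path, expected_scanner=scanner)
        pd.testing.assert_frame_equal(df, events)
        assert sidecar["seed"] == 4

    def test_geometry_mismatch_warns(self, phantom, scanner, tmp_path):
        run = RunConfig(BeamCycle(1.0, 1.5), ions_per_pulse=1000, n_cycles=1, rng_seed=4)
        events, _ = simulate_run(
            run, ImplantationSpec(105.0), [O15_COMPONENT], phantom, scanner
        )
        path = write_listmode(events, tmp_path / "g.tsv", scanner, phantom)
        other = ScannerSpec(panel_separation=400.0)
        with pytest.warns(UserWarning, match="geometry"):
            read_listmode(path, expected_scanner=other)

    def test_malformed_file_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "t_ms\ttop_depth_mm\ttop_width_mm\tbottom_depth_mm\tbottom_width_mm\tbeam_on\n"
            "10\t1.0\t2.0\t3.0\t4.0\t0\n"
            "11\t1.0\toops\t3.0\t4.0\t0\n"
        )
        with pytest.raises(ListModeParseError, match="line 3"):
            read_listmode(path)
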