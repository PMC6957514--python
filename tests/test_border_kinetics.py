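"""Border-kinetics chain: segmentation, polar projection, steps, rates, energy."""

import numpy as np
import pytest

import memkin as mk
from memkin.border_kinetics import (
    LATTICE,
    MEMBRANE,
    MICA,
    Kymograph,
    OccurrenceHistogram,
    StepTrace,
)


def make_kymo(radii, dt=0.3, theta_bin=0):
    radii = np.asarray(radii, dtype=float)
    return Kymograph(
        theta_deg=0.0,
        theta_bin=theta_bin,
        times=np.arange(radii.size) * dt,
        radii=radii,
        frame_interval=dt,
    )


class TestSegmentLevels:
    def test_noise_free_segmentation_is_exact(self):
        p = mk.LatticeSimParams(n_frames=2, n_theta=16, grid_size_px=(96, 96),
                                pixel_size=3.0, patch_radius=120.0,
                                init_lattice_radius=60.0, noise_sd=0.0, seed=0)
        movie, log = mk.generate_afm_lattice_movie(p)
        labels = mk.segment_levels(movie.heights[0], (0.0, 3.15, 6.1))
        assert np.array_equal(labels, log["labels"][0])

    def test_noisy_segmentation_agreement(self, lattice_movie):
        _, movie, log = lattice_movie
        labels = mk.segment_levels(movie.heights[0], (0.0, 3.15, 6.1), tolerance=0.5)
        agree = np.mean(labels == log["labels"][0])
        assert agree >= 0.99

    def test_all_zero_frame_is_all_mica(self):
        labels = mk.segment_levels(np.zeros((32, 32)), (0.0, 3.15, 6.1))
        assert np.all(labels == MICA)

    def test_small_lattice_fragments_are_relabeled(self):
        frame = np.zeros((40, 40))
        frame[10:20, 10:20] = 6.1  # main lattice
        frame[30, 30] = 6.1  # stray pixel
        labels = mk.segment_levels(frame, (0.0, 3.15, 6.1))
        assert labels[30, 30] == MEMBRANE
        assert labels[15, 15] == LATTICE

    def test_rejects_unsorted_centers(self):
        with pytest.raises(ValueError):
            mk.segment_levels(np.zeros((4, 4)), (3.15, 0.0, 6.1))


class TestExtractBorderPolar:
    def test_perfect_disk(self):
        n_theta = 32
        radii = np.full((2, n_theta), 100.0)
        p = mk.LatticeSimParams(n_frames=2, n_theta=n_theta, grid_size_px=(160, 160),
                                pixel_size=2.0, patch_radius=150.0,
                                init_lattice_radius=100.0, noise_sd=0.0, seed=0)
        movie = mk.render_lattice_movie(p, radii, noise=False)
        trace = mk.extract_border_polar(movie, n_theta=n_theta)
        assert np.all(np.abs(trace.radii - 100.0) <= movie.pixel_size)

    def test_matches_ground_truth_radii(self, lattice_movie):
        p, movie, log = lattice_movie
        trace = mk.extract_border_polar(movie, n_theta=p.n_theta)
        err_px = np.abs(trace.radii - log["radii_nm"]) / p.pixel_size
        assert np.mean(err_px <= 1.0) >= 0.95

    def test_expansion_confined_to_scripted_bins(self):
        # lattice grows only in the 60-120 degree sector
        n_theta = 24
        n_frames = 10
        radii = np.full((n_frames, n_theta), 80.0)
        bins = np.arange(n_theta) * (360.0 / n_theta)
        grow = (bins >= 60.0) & (bins < 120.0)
        for f in range(n_frames):
            radii[f, grow] = 80.0 + 8.85 * (f // 3)
        p = mk.LatticeSimParams(n_frames=n_frames, n_theta=n_theta,
                                grid_size_px=(200, 200), pixel_size=2.0,
                                patch_radius=180.0, init_lattice_radius=80.0,
                                noise_sd=0.0, seed=0)
        movie = mk.render_lattice_movie(p, radii, noise=False)
        trace = mk.extract_border_polar(movie, n_theta=n_theta)
        change = trace.radii[-1] - trace.radii[0]
        grown = change > 8.85 / 2
        expected = (trace.theta_bins >= 60.0) & (trace.theta_bins <= 120.0)
        assert np.array_equal(grown, expected)

    def test_raises_without_lattice(self):
        movie = mk.AFMMovie(np.zeros((2, 32, 32)), 2.0, 0.3)
        with pytest.raises(ValueError, match="no lattice"):
            mk.extract_border_polar(movie, n_theta=8)


class TestKymograph:
    def test_flat_trace_gives_flat_kymograph(self):
        trace = mk.BorderTrace(
            theta_bins=np.array([45.0, 135.0, 225.0, 315.0]),
            radii=np.full((5, 4), 50.0), center=(10, 10), frame_interval=0.3,
        )
        kymo = mk.build_kymograph(trace, 90.0)
        assert np.all(kymo.radii == 50.0)
        assert kymo.theta_bin == 1

    def test_single_event_steps_at_right_frame(self):
        radii = np.full((10, 4), 50.0)
        radii[6:, 2] += 8.85
        trace = mk.BorderTrace(
            theta_bins=np.array([45.0, 135.0, 225.0, 315.0]),
            radii=radii, center=(0, 0), frame_interval=0.3,
        )
        kymo = mk.build_kymograph(trace, 225.0)
        assert np.argmax(np.diff(kymo.radii) > 0) == 5

    def test_angle_modulo_normalization(self):
        trace = mk.BorderTrace(
            theta_bins=np.array([45.0, 135.0, 225.0, 315.0]),
            radii=np.ones((3, 4)), center=(0, 0), frame_interval=0.3,
        )
        assert mk.build_kymograph(trace, 370.0).theta_bin == 0
        assert mk.build_kymograph(trace, -10.0).theta_bin == 3


class TestIdealizeTrace:
    def test_noise_free_two_level_recovery(self):
        r = np.array([0.0] * 5 + [8.85] * 5) + 100.0
        st = mk.idealize_trace(make_kymo(r), step_length=8.85)
        assert [(s[0], s[1]) for s in st.segments] == [(0, 4), (5, 9)]
        assert st.levels[1] - st.levels[0] == pytest.approx(8.85)
        assert not st.low_confidence

    def test_noisy_steps_recovered(self, rng):
        # 1 nm noise on 8.85 nm steps: every switch frame within +/- 1
        true_levels = np.repeat([0, 1, 0, -1, 0, 1, 2], [8, 6, 9, 7, 8, 6, 6])
        r = 100.0 + 8.85 * true_levels + rng.normal(0, 1.0, true_levels.size)
        st = mk.idealize_trace(make_kymo(r), step_length=8.85)
        switch_true = np.nonzero(np.diff(true_levels))[0] + 1
        switch_fit = np.array([s[0] for s in st.segments[1:]])
        assert switch_fit.size == switch_true.size
        assert np.all(np.abs(switch_fit - switch_true) <= 1)

    def test_ramp_is_flagged_low_confidence(self):
        r = 100.0 + np.linspace(0, 40, 80)  # drift, no steps
        st = mk.idealize_trace(make_kymo(r), step_length=8.85)
        assert len(st.segments) > 1
        k = np.diff(st.levels) / 8.85
        assert np.allclose(k, np.round(k))  # successive multiples of the step
        assert st.low_confidence

    def test_sub_threshold_wander_collapses_with_warning(self):
        # excursions larger than one step but never crossing the detection
        # threshold reduce to a single segment and are flagged
        t = np.linspace(0, 4 * np.pi, 60)
        r = 100.0 + 5.0 * np.sin(t)
        with pytest.warns(UserWarning, match="single segment"):
            st = mk.idealize_trace(make_kymo(r), step_length=8.85,
                                   threshold_fraction=1.0)
        assert len(st.segments) == 1
        assert st.low_confidence


class TestDwellTimes:
    def test_hand_counted_dwell(self):
        # [level0 x5, level+1 x3, level0 x2]: the internal +1 segment lasts
        # 0.9 s and ends in a -step, so it lands in the dissociation list
        st = StepTrace(theta_bin=0, step_length=8.85,
                       segments=[(0, 4, 0.0), (5, 7, 8.85), (8, 9, 0.0)])
        assoc, dissoc = mk.extract_dwell_times([st], 0.3)
        assert assoc == []
        assert dissoc == pytest.approx([0.9])

    def test_censored_only_trace_contributes_nothing(self):
        st = StepTrace(theta_bin=0, step_length=8.85, segments=[(0, 9, 0.0)])
        assoc, dissoc = mk.extract_dwell_times([st], 0.3)
        assert assoc == [] and dissoc == []

    def test_dwells_match_simulator_waiting_times(self, lattice_movie):
        # noise-free replay: idealized traces on the true radii reproduce
        # the frame-quantized dwell statistics of the logged events
        p, _, log = lattice_movie
        trace = mk.BorderTrace(
            theta_bins=(np.arange(p.n_theta) + 0.5) * 360.0 / p.n_theta,
            radii=log["radii_nm"], center=(0, 0), frame_interval=p.frame_interval,
        )
        steps = [mk.idealize_trace(mk.build_kymograph(trace, th),
                                   step_length=p.step_length)
                 for th in trace.theta_bins]
        assoc, dissoc = mk.extract_dwell_times(steps, p.frame_interval)
        pooled = assoc + dissoc
        # mean dwell ~ 1/(k_a+k_d) after the whole-frame geometric correction
        mean_frames = np.mean(pooled) / p.frame_interval
        k_tot = -np.log(1 - 1 / mean_frames) / p.frame_interval
        assert k_tot == pytest.approx(p.k_assoc + p.k_dissoc, rel=0.15)


class TestRateFitting:
    def test_mle_on_equal_dwells(self):
        k, ci, n = mk.fit_exponential_rate([0.5] * 20)
        assert k == pytest.approx(2.0)
        assert n == 20

    def test_mle_consistency_on_seeded_draws(self, rng):
        d = rng.exponential(1 / 2.3, size=5000)
        k, ci, _ = mk.fit_exponential_rate(d)
        assert 2.2 <= k <= 2.4
        assert ci[0] < 2.3 < ci[1]

    def test_histogram_agrees_with_mle(self, rng):
        d = rng.exponential(1 / 2.3, size=5000)
        k_mle, _, _ = mk.fit_exponential_rate(d, method="mle")
        k_hist, _, _ = mk.fit_exponential_rate(d, method="histogram")
        assert k_hist == pytest.approx(k_mle, rel=0.10)

    def test_floor_and_validity_checks(self):
        with pytest.raises(ValueError, match="at least"):
            mk.fit_exponential_rate([1.0] * 5)
        with pytest.raises(ValueError, match="positive"):
            mk.fit_exponential_rate([1.0] * 10 + [-1.0] * 1, min_dwells=5)

    def test_equilibrium_constant(self):
        assert mk.equilibrium_constant(2.3, 2.0) == pytest.approx(1.15)
        assert mk.equilibrium_constant(0.7, 0.7) == 1.0
        assert mk.equilibrium_constant(0.0, 2.0) == 0.0
        with pytest.raises(ValueError):
            mk.equilibrium_constant(1.0, 0.0)


class TestDeltaRHistogram:
    def test_static_trace_all_mass_at_zero(self):
        trace = mk.BorderTrace(theta_bins=np.array([0.5]),
                               radii=np.full((10, 1), 50.0),
                               center=(0, 0), frame_interval=0.3)
        hist = mk.delta_r_histogram(trace, 1, 8.85)
        assert hist.counts[hist.delta_r_steps == 0] == 9
        assert hist.total == 9

    def test_total_is_conserved(self, lattice_movie):
        p, movie, _ = lattice_movie
        trace = mk.extract_border_polar(movie, n_theta=p.n_theta)
        for lag in (1, 3):
            hist = mk.delta_r_histogram(trace, lag, p.step_length)
            assert hist.total == p.n_theta * (p.n_frames - lag)

    def test_side_lobes_match_logged_events(self, lattice_movie):
        # frames with exactly one event in a bin land at +/- 1 step
        p, _, log = lattice_movie
        trace = mk.BorderTrace(
            theta_bins=(np.arange(p.n_theta) + 0.5) * 360.0 / p.n_theta,
            radii=log["radii_nm"], center=(0, 0), frame_interval=p.frame_interval,
        )
        hist = mk.delta_r_histogram(trace, 1, p.step_length)
        d_steps = np.round(np.diff(log["radii_nm"], axis=0) / p.step_length)
        for s in (-1, 1):
            logged = int(np.sum(d_steps == s))
            measured = int(hist.counts[hist.delta_r_steps == s][0])
            assert measured == logged

    def test_short_movie_rejected(self):
        trace = mk.BorderTrace(theta_bins=np.array([0.5]),
                               radii=np.full((2, 1), 1.0),
                               center=(0, 0), frame_interval=0.3)
        with pytest.raises(ValueError, match="shorter"):
            mk.delta_r_histogram(trace, 5, 8.85)


class TestEnergyLandscape:
    def make_hist(self, mapping):
        steps = np.array(sorted(mapping))
        counts = np.array([mapping[s] for s in steps])
        return OccurrenceHistogram(delta_r_steps=steps, counts=counts,
                                   step_length=8.85, lag_frames=1,
                                   total=int(counts.sum()))

    def test_hand_computed_values(self):
        prof = mk.energy_landscape(self.make_hist({0: 100, 1: 10}))
        g0 = prof.delta_G[prof.delta_r_steps == 0][0]
        g1 = prof.delta_G[prof.delta_r_steps == 1][0]
        assert g0 == pytest.approx(-np.log(100), abs=1e-3)  # -4.605
        assert g1 == pytest.approx(-np.log(10), abs=1e-3)  # -2.303
        assert g1 - g0 == pytest.approx(2.303, abs=1e-3)

    def test_single_count_is_zero_reference(self):
        prof = mk.energy_landscape(self.make_hist({0: 1}))
        assert prof.delta_G[prof.delta_r_steps == 0][0] == 0.0

    def test_argmin_at_max_count_and_nan_at_zero(self):
        prof = mk.energy_landscape(self.make_hist({-1: 5, 0: 500, 1: 7, 2: 0}))
        finite = np.isfinite(prof.delta_G)
        amin = prof.delta_r_steps[finite][np.argmin(prof.delta_G[finite])]
        assert amin == 0
        assert np.isnan(prof.delta_G[prof.delta_r_steps == 2][0])
        assert 0 in prof.local_minima

    def test_empty_or_zero_center_rejected(self):
        with pytest.raises(ValueError):
            mk.energy_landscape(self.make_hist({0: 0, 1: 3}))
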