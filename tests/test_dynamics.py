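"""Time-lapse analytics: drift, linking, speeds, protrusions,
induction kinetics, fate and origin mapping."""

import numpy as np
import pandas as pd
import pytest

from cscmap import dynamics, gating, synthgen
from cscmap.containers import ChannelStack, Track
from cscmap.synthgen import ReporterKinetics, SceneConfig


def truth_tracks(mt, observed=True):
    xcol, ycol = ("x_obs", "y_obs") if observed else ("x_um", "y_um")
    out = []
    for cid, g in mt.tracks.groupby("cell_id"):
        out.append(Track(int(cid), g.frame.to_numpy(),
                         g[xcol].to_numpy(float), g[ycol].to_numpy(float),
                         mt.frame_interval,
                         sensor=g.sensor_intensity.to_numpy(float)))
    return out


@pytest.fixture(scope="module")
def drift_movie():
    cfg = SceneConfig(field_size=(300, 300), n_cells=15,
                      csc_fraction_baseline=0.0, seed=3)
    return synthgen.generate_timelapse(
        cfg, ReporterKinetics(), {"nonCSC": 0.0}, 0.3, 58, 2, seed=3,
        render=True)


class TestDrift:
    def test_injected_drift_recovered(self, drift_movie):
        movie, mt = drift_movie
        corr, drift = dynamics.correct_drift(movie)
        assert np.abs(drift - mt.drift_um).max() < 0.05

    def test_zero_drift_identity(self):
        cfg = SceneConfig(field_size=(200, 200), n_cells=8,
                          csc_fraction_baseline=0.0, seed=5, noise_sd=0.0)
        movie, _ = synthgen.generate_timelapse(
            cfg, ReporterKinetics(), {"nonCSC": 0.0}, 0.0, 10, 2, seed=5,
            render=True)
        _, drift = dynamics.correct_drift(movie)
        assert np.abs(drift).max() < 0.05

    def test_featureless_reference_errors(self):
        movie = ChannelStack(
            {"volume": np.zeros((5, 64, 64), np.float32)}, 0.5, 2.0)
        with pytest.raises(ValueError, match="featureless"):
            dynamics.correct_drift(movie)

    def test_residual_drift_small_after_correction(self, drift_movie):
        movie, mt = drift_movie
        corr, _ = dynamics.correct_drift(movie)
        fid = mt.tracks[mt.tracks.frame == 0][["x_um", "y_um"]]
        assert dynamics.residual_drift(corr, fid) <= 0.02

    def test_uncorrected_residual_near_injected_rate(self, drift_movie):
        movie, mt = drift_movie
        # track fiducials in the *uncorrected* movie from their drifted
        # positions: apparent speed ≈ the injected 0.3 µm/min
        fid = mt.tracks[mt.tracks.frame == 0].rename(
            columns={"x_obs": "x", "y_obs": "y"})
        # center windows mid-movie so the object stays inside
        mid = mt.tracks[mt.tracks.frame == 15][["x_obs", "y_obs"]].rename(
            columns={"x_obs": "x_um", "y_obs": "y_um"})
        res = dynamics.residual_drift(movie, mid, window_um=15.0)
        assert res == pytest.approx(0.3, abs=0.1)


class TestLinking:
    def test_single_cell_single_full_track(self):
        det = pd.DataFrame({
            "frame": np.arange(20),
            "x_um": np.linspace(0, 10, 20),
            "y_um": np.zeros(20),
        })
        tracks = dynamics.link_tracks(det, max_step_um=2.0, frame_interval=2.0)
        assert len(tracks) == 1 and len(tracks[0]) == 20

    def test_distant_cells_no_identity_swaps(self):
        frames = np.arange(15)
        a = pd.DataFrame({"frame": frames, "x_um": 10 + 0.5 * frames,
                          "y_um": np.zeros(15)})
        b = pd.DataFrame({"frame": frames, "x_um": 100 - 0.5 * frames,
                          "y_um": np.full(15, 50.0)})
        det = pd.concat([a, b], ignore_index=True)
        tracks = dynamics.link_tracks(det, max_step_um=3.0, frame_interval=2.0)
        assert len(tracks) == 2
        for tr in tracks:
            dy = np.diff(tr.y_um)
            assert np.all(dy == 0)  # pure tracks, no swaps

    def test_gated_step_starts_new_track(self):
        det = pd.DataFrame({
            "frame": [0, 1], "x_um": [0.0, 50.0], "y_um": [0.0, 0.0]})
        tracks = dynamics.link_tracks(det, max_step_um=5.0, frame_interval=2.0)
        assert len(tracks) == 2

    def test_crossing_cells_greedy_matches_exhaustive_on_pairs(self):
        # two detections per frame; greedy assignment must equal the
        # exhaustive minimal-total-distance assignment
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = rng.uniform(0, 20, (2, 2))
            q = rng.uniform(0, 20, (2, 2))
            det = pd.DataFrame({
                "frame": [0, 0, 1, 1],
                "x_um": [p[0, 0], p[1, 0], q[0, 0], q[1, 0]],
                "y_um": [p[0, 1], p[1, 1], q[0, 1], q[1, 1]],
            })
            tracks = dynamics.link_tracks(det, max_step_um=30.0,
                                          frame_interval=1.0)
            n_links = sum(1 for t in tracks if len(t) == 2)
            d = np.hypot(*(p[:, None, :] - q[None, :, :]).transpose(2, 0, 1))
            best_links = 2 if min(d[0, 0] + d[1, 1], d[0, 1] + d[1, 0]) <= 60 else 0
            assert n_links == min(2, best_links) or n_links == 2


class TestSpeed:
    def test_straight_line_exact(self):
        tr = Track(0, np.arange(31), np.linspace(0, 12, 31), np.zeros(31), 2.0)
        assert dynamics.track_speed(tr)["speed_um_per_min"] == pytest.approx(0.2)

    def test_stationary_zero(self):
        tr = Track(0, np.arange(10), np.zeros(10), np.zeros(10), 2.0)
        assert dynamics.track_speed(tr)["speed_um_per_min"] == 0.0

    def test_single_frame_undefined(self):
        tr = Track(0, np.array([0]), np.array([0.0]), np.array([0.0]), 2.0)
        with pytest.raises(ValueError):
            dynamics.track_speed(tr)

    def test_random_walk_truth_speed_recovered_within_ten_percent(self):
        cfg = SceneConfig(field_size=(500, 500), n_cells=40,
                          csc_fraction_baseline=0.5, seed=1)
        _, mt = synthgen.generate_timelapse(
            cfg, ReporterKinetics(), {"CSC": 0.2, "nonCSC": 1.0}, 0.0, 60, 2,
            seed=1, localization_jitter_um=0.3, render=False)
        cls = dynamics.classify_speeds(truth_tracks(mt))
        merged = cls.merge(mt.cells, on="cell_id")
        for truth_speed, grp in merged.groupby("speed_truth"):
            med = grp.speed_um_per_min.median()
            assert med == pytest.approx(truth_speed, rel=0.10)

    def test_speed_invariant_under_corrected_drift_and_inflated_without(self):
        cfg = SceneConfig(field_size=(500, 500), n_cells=20,
                          csc_fraction_baseline=0.0, seed=6)
        _, mt = synthgen.generate_timelapse(
            cfg, ReporterKinetics(), {"nonCSC": 0.0}, 0.3, 60, 2, seed=6,
            render=False)
        drift_free = dynamics.classify_speeds(truth_tracks(mt, observed=False))
        with_drift = dynamics.classify_speeds(truth_tracks(mt, observed=True))
        assert drift_free.speed_um_per_min.max() < 1e-9
        assert with_drift.speed_um_per_min.median() == pytest.approx(0.3,
                                                                     rel=0.05)


class TestProtrusions:
    def test_clean_sinusoid_six_per_hour_period_ten(self):
        tr = synthgen.generate_kymograph(10, 2, 60, 1, 0, seed=0)
        res = dynamics.protrusion_analysis(tr)
        assert res["events_per_hour"] == 6.0
        assert res["period_min"] == 10.0

    def test_flat_trace_zero_events(self):
        res = dynamics.protrusion_analysis(np.zeros(60), sampling_min=1.0)
        assert res["events_per_hour"] == 0.0

    def test_rate_times_period_near_sixty(self):
        tr = synthgen.generate_kymograph(12, 2, 240, 1, 0.1, seed=4)
        res = dynamics.protrusion_analysis(tr)
        assert res["events_per_hour"] * res["period_min"] == pytest.approx(
            60.0, rel=0.1)

    def test_noisy_period_within_one_sample_of_spectrum_oracle(self):
        tr = synthgen.generate_kymograph(10, 2, 180, 1, 0.2, seed=1)
        res = dynamics.protrusion_analysis(tr)
        x = tr.position_um - tr.position_um.mean()
        freqs = np.fft.rfftfreq(len(x), d=1.0)
        mag = np.abs(np.fft.rfft(x))
        oracle = 1.0 / freqs[1:][np.argmax(mag[1:])]
        assert abs(res["period_min"] - oracle) <= tr.sampling_min

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            dynamics.protrusion_analysis(np.zeros(5), sampling_min=1.0)


class TestInduction:
    def make_track(self, kin, contact_frame=10, n_frames=120, dt=2.0,
                   noise_seed=0):
        rng = np.random.default_rng(noise_seed)
        frames = np.arange(n_frames)
        t_h = (frames - contact_frame) * dt / 60.0
        raw = kin.baseline_mean + rng.normal(0, kin.baseline_sd, n_frames)
        raw = raw + np.where(t_h >= 0, kin.signal(t_h + 1e-12), 0.0)
        return Track(0, frames, np.zeros(n_frames), np.zeros(n_frames), dt,
                     sensor=raw)

    def test_flat_trace_no_induction(self):
        # exactly flat trace: normalization degenerates to zeros, no call
        frames = np.arange(60)
        tr = Track(0, frames, np.zeros(60), np.zeros(60), 2.0,
                   sensor=np.full(60, 30.0))
        trace = dynamics.induction_trace(tr, 10)
        assert dynamics.induction_time(trace) is None

    def test_baseline_noise_rarely_called_induced(self):
        # no production: the 2-SD sustained rule keeps the false-call
        # rate low over many noisy baseline traces
        kin = ReporterKinetics(production_rate=0.0)
        calls = 0
        for seed in range(40):
            trace = dynamics.induction_trace(self.make_track(
                kin, noise_seed=seed), 10)
            if dynamics.induction_time(trace) is not None:
                calls += 1
        assert calls <= 5  # measured false-call rate ~5%

    def test_step_to_max_at_half_hour(self):
        frames = np.arange(60)
        raw = np.where(frames < 25, 10.0, 100.0)  # step 0.5 h after contact
        tr = Track(0, frames, np.zeros(60), np.zeros(60), 2.0, sensor=raw)
        trace = dynamics.induction_trace(tr, 10)
        assert dynamics.induction_time(trace) == pytest.approx(0.5)

    def test_first_order_kinetics_crossing_matches_closed_form(self):
        kin = ReporterKinetics(half_life_h=1.5, production_rate=150.0,
                               baseline_sd=4.0)
        times = []
        for seed in range(10):
            tr = self.make_track(kin, noise_seed=seed)
            trace = dynamics.induction_trace(tr, 10)
            t = dynamics.induction_time(trace, k_sd=2.0)
            assert t is not None
            times.append(t)
        # closed-form crossing of baseline + 2 SD
        expected = kin.crossing_time_h(2 * kin.baseline_sd)
        assert np.median(times) == pytest.approx(expected, abs=2 * 2 / 60)

    def test_normalization_scale_invariant_and_idempotent(self):
        kin = ReporterKinetics()
        tr = self.make_track(kin, noise_seed=3)
        trace1 = dynamics.induction_trace(tr, 10)
        tr_scaled = Track(0, tr.frames, tr.x_um, tr.y_um, tr.frame_interval,
                          sensor=tr.sensor * 7.3)
        trace2 = dynamics.induction_trace(tr_scaled, 10)
        np.testing.assert_allclose(trace1.normalized, trace2.normalized,
                                   rtol=1e-9)
        assert trace1.normalized[trace1.t_h >= 0].max() == pytest.approx(1.0)
        pre = trace1.normalized[trace1.t_h < 0]
        assert pre.mean() == pytest.approx(0.0, abs=1e-9)

    def test_requires_three_precontact_frames(self):
        kin = ReporterKinetics()
        tr = self.make_track(kin, contact_frame=1)
        with pytest.raises(ValueError):
            dynamics.induction_trace(tr, 1)


@pytest.fixture(scope="module")
def conversion_movie():
    cfg = SceneConfig(field_size=(1500, 1500), n_cells=520,
                      csc_fraction_baseline=0.0,
                      contact_fraction_by_class={"nonCSC": 113 / 520},
                      seed=6)
    _, mt = synthgen.generate_timelapse(
        cfg, ReporterKinetics(), {"nonCSC": 0.2}, 0.0, 16 * 60, 10, seed=6,
        conversion_prob_contacted=0.23, conversion_prob_uncontacted=0.05,
        render=False)
    thr = gating.fit_control_threshold(
        np.random.default_rng(1).normal(20, 5, 5000))
    return mt, thr


class TestFateOrigin:
    def test_worked_arithmetic(self):
        s = dynamics.ConversionSummary(
            "fate", {"contacted": 20, "uncontacted": 20},
            {"contacted": 5, "uncontacted": 0})
        assert s.frequencies["contacted"] == 0.25
        assert s.frequencies["uncontacted"] == 0.0
        assert np.isnan(s.ratio)  # zero denominator flagged

    def test_counts_equal_brute_force_event_scan(self, conversion_movie):
        mt, thr = conversion_movie
        contacted = dict(zip(mt.cells.cell_id, mt.cells.contacted))
        s = dynamics.fate_map(mt.tracks, contacted, thr.value)
        # brute force over the sensor series
        mat = mt.tracks.pivot(index="frame", columns="cell_id",
                              values="sensor_intensity").to_numpy()
        conv = {"contacted": 0, "uncontacted": 0}
        n = {"contacted": 0, "uncontacted": 0}
        for j, cid in enumerate(sorted(mt.cells.cell_id)):
            if mat[:3, j].mean() > thr.value:
                continue
            g = "contacted" if contacted[cid] else "uncontacted"
            n[g] += 1
            above = mat[3:, j] > thr.value
            if any(above[i] and above[i + 1] for i in range(len(above) - 1)):
                conv[g] += 1
        assert s.n == n and s.conversions == conv

    def test_recovers_planted_conversion_rates(self, conversion_movie):
        mt, thr = conversion_movie
        contacted = dict(zip(mt.cells.cell_id, mt.cells.contacted))
        s = dynamics.fate_map(mt.tracks, contacted, thr.value)
        planted = mt.cells.groupby("contacted").converted.mean()
        assert s.frequencies["contacted"] == pytest.approx(
            planted[True], abs=0.02)
        assert s.frequencies["uncontacted"] == pytest.approx(
            planted[False], abs=0.02)

    def test_origin_all_end_positive_started_positive(self):
        frames = np.repeat(np.arange(10), 2)
        tracks = pd.DataFrame({
            "frame": frames,
            "cell_id": np.tile([0, 1], 10),
            "sensor_intensity": np.tile([100.0, 5.0], 10),
        })
        s = dynamics.origin_map(tracks, 0, 18, threshold=50, frame_interval=2)
        assert s.n["end_positive"] == 1
        assert s.conversions["end_positive"] == 0

    def test_fate_and_origin_agree_on_fully_observed_movie(
            self, conversion_movie):
        mt, thr = conversion_movie
        contacted = dict(zip(mt.cells.cell_id, mt.cells.contacted))
        fate = dynamics.fate_map(mt.tracks, contacted, thr.value)
        t_end = mt.tracks.t_min.max()
        origin = dynamics.origin_map(mt.tracks, 0, t_end, thr.value,
                                     mt.frame_interval)
        assert origin.conversions["end_positive"] == sum(
            fate.conversions.values())
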