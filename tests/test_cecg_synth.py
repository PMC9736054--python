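"""Signal synthesis: dipole loop, acquisition chain, determinism."""

from types import SimpleNamespace

import numpy as np
import pytest

from cecglead import (CardiacCycleModel, MotionEventModel, SignalTrace,
                      add_motion_artifact, add_noise, calibrated_noise_sigma,
                      dipole_trajectory, downsample_averaging,
                      simulate_lead_signal)
from cecglead.cecg_synth import (R_MOMENT, WaveComponent, lead_transfer,
                                 read_trace_csv, write_trace_csv)
from cecglead.qrs_pipeline import estimate_snr


@pytest.fixture(scope="module")
def model():
    return CardiacCycleModel.default()


class TestDipoleTrajectory:
    def test_r_instant_magnitude_within_one_percent(self, model):
        m = dipole_trajectory(model, np.array([model.r_phase]))[0]
        assert np.linalg.norm(m) == pytest.approx(R_MOMENT, rel=0.01)

    def test_zero_amplitudes_give_zero_moment(self):
        waves = tuple(WaveComponent(w.name, w.center, w.width, 0.0, w.direction)
                      for w in CardiacCycleModel.default().waves)
        silent = CardiacCycleModel(60.0, waves)
        t = np.linspace(0, 3, 200)
        assert not dipole_trajectory(silent, t).any()

    def test_periodicity_to_rounding(self, model):
        t = np.linspace(0, 0.99, 57)
        a = dipole_trajectory(model, t)
        b = dipole_trajectory(model, t + model.cycle_length)
        assert np.allclose(a, b, rtol=0, atol=1e-12 * R_MOMENT)

    def test_unordered_waves_rejected(self):
        w = CardiacCycleModel.default().waves
        with pytest.raises(ValueError, match="ordered"):
            CardiacCycleModel(60.0, (w[2], w[0], w[1], w[3], w[4]))


class TestSimulateLeadSignal:
    def test_peak_matches_static_r_instant_voltage(self, thorax_study):
        tr = simulate_lead_signal(thorax_study["basis"],
                                  thorax_study["coupling_a"],
                                  thorax_study["coupling_b"],
                                  thorax_study["model"], 10.0, 2300.0)
        ell = lead_transfer(thorax_study["basis"], thorax_study["coupling_a"],
                            thorax_study["coupling_b"])
        static = abs(thorax_study["model"].r_moment() @ ell)
        assert np.abs(tr.samples).max() == pytest.approx(static, rel=0.02)

    def test_linearity_in_moment_amplitudes(self, thorax_study):
        model = thorax_study["model"]
        doubled = CardiacCycleModel(model.heart_rate, tuple(
            WaveComponent(w.name, w.center, w.width, 2 * w.amplitude,
                          w.direction) for w in model.waves))
        kw = (thorax_study["basis"], thorax_study["coupling_a"],
              thorax_study["coupling_b"])
        t1 = simulate_lead_signal(*kw, model, 5.0, 2300.0)
        t2 = simulate_lead_signal(*kw, doubled, 5.0, 2300.0)
        assert np.allclose(t2.samples, 2.0 * t1.samples, rtol=1e-12)

    def test_fifteen_minutes_at_60_bpm_has_900_beats(self, thorax_study):
        tr = simulate_lead_signal(thorax_study["basis"],
                                  thorax_study["coupling_a"],
                                  thorax_study["coupling_b"],
                                  thorax_study["model"], 900.0, 2300.0)
        assert len(tr.annotations) == 900
        assert len(tr.samples) == 900 * 2300

    def test_nonpositive_duration_rejected(self, thorax_study):
        with pytest.raises(ValueError):
            simulate_lead_signal(thorax_study["basis"],
                                 thorax_study["coupling_a"],
                                 thorax_study["coupling_b"],
                                 thorax_study["model"], 0.0)


class TestMotionArtifact:
    def test_zero_excursion_is_identity(self, thorax_study):
        tr = simulate_lead_signal(thorax_study["basis"],
                                  thorax_study["coupling_a"],
                                  thorax_study["coupling_b"],
                                  thorax_study["model"], 30.0, 500.0)
        ev = MotionEventModel(rate_per_min=4, excursion=0.0, seed=1)
        out = add_motion_artifact(tr, thorax_study["basis"],
                                  thorax_study["model"],
                                  thorax_study["coupling_a"], ev)
        assert np.array_equal(out.samples, tr.samples)

    def test_uniform_surface_potential_gives_no_artifact(self, thorax_study):
        """Gap modulation only rescales Ce; on an equipotential surface
        the Ve ratio is invariant, so events leave the trace untouched."""
        coup = thorax_study["coupling_a"]
        n_patch = len(coup.patch.vertex_idx)
        flat_basis = SimpleNamespace(
            boundary_potential_series=lambda mom, idx: np.full(
                (len(mom), n_patch), 3.3))
        tr = SignalTrace(500.0, np.zeros(15000), np.arange(1, 29))
        ev = MotionEventModel(rate_per_min=6, excursion=5e-4, seed=2)
        out = add_motion_artifact(tr, flat_basis, thorax_study["model"],
                                  coup, ev)
        assert np.allclose(out.samples, tr.samples, atol=1e-12)

    def test_distortion_confined_to_event_windows(self, thorax_study):
        tr = simulate_lead_signal(thorax_study["basis"],
                                  thorax_study["coupling_a"],
                                  thorax_study["coupling_b"],
                                  thorax_study["model"], 60.0, 500.0)
        ev = MotionEventModel(rate_per_min=6, excursion=5e-4, seed=5)
        out = add_motion_artifact(tr, thorax_study["basis"],
                                  thorax_study["model"],
                                  thorax_study["coupling_a"], ev)
        starts = out.meta["motion_events"]
        assert starts.size > 0
        diff = np.abs(out.samples - tr.samples)
        t = tr.times()
        inside = np.zeros(len(t), bool)
        for s in starts:
            inside |= (t >= s) & (t < s + ev.duration)
        assert diff[~inside].max() <= 1e-12
        assert diff[inside].max() > 0

    def test_reproducible_for_fixed_seed(self, thorax_study):
        tr = simulate_lead_signal(thorax_study["basis"],
                                  thorax_study["coupling_a"],
                                  thorax_study["coupling_b"],
                                  thorax_study["model"], 30.0, 500.0)
        ev = MotionEventModel(rate_per_min=6, excursion=5e-4, seed=9)
        args = (thorax_study["basis"], thorax_study["model"],
                thorax_study["coupling_a"], ev)
        a = add_motion_artifact(tr, *args)
        b = add_motion_artifact(tr, *args)
        assert np.array_equal(a.samples, b.samples)

    def test_contact_violation_rejected(self, thorax_study):
        tr = SignalTrace(500.0, np.zeros(5000), np.arange(1, 9))
        ev = MotionEventModel(rate_per_min=30, excursion=-2e-3, seed=0)
        with pytest.raises(ValueError, match="through the body"):
            add_motion_artifact(tr, thorax_study["basis"],
                                thorax_study["model"],
                                thorax_study["coupling_a"], ev)


class TestNoiseAndDownsampling:
    def test_zero_sigma_is_identity(self):
        tr = SignalTrace(100.0, np.sin(np.arange(1000)), np.array([1.0, 2.0]))
        assert np.array_equal(add_noise(tr, 0.0).samples, tr.samples)

    def test_noise_sd_matches_sigma(self):
        tr = SignalTrace(1000.0, np.zeros(200_000), np.array([1.0, 2.0]))
        out = add_noise(tr, 0.5, seed=4)
        assert np.std(out.samples - tr.samples) == pytest.approx(0.5, rel=0.05)

    def test_same_seed_reproduces_noise(self):
        tr = SignalTrace(100.0, np.zeros(5000), np.array([1.0, 2.0]))
        assert np.array_equal(add_noise(tr, 1.0, seed=7).samples,
                              add_noise(tr, 1.0, seed=7).samples)

    def test_2300_to_72_hz_sample_count(self):
        tr = SignalTrace(2300.0, np.zeros(2300), np.array([0.33]))
        out = downsample_averaging(tr, 72.0)
        assert len(out.samples) == 72
        assert out.fs == 72.0
        assert np.array_equal(out.annotations, tr.annotations)

    def test_constant_signal_survives_averaging(self):
        tr = SignalTrace(2300.0, np.full(4600, 1.7), np.array([0.33]))
        out = downsample_averaging(tr, 72.0)
        assert np.allclose(out.samples, 1.7, rtol=1e-14)

    def test_integer_ratio_averaging_preserves_the_mean(self):
        rng = np.random.default_rng(0)
        tr = SignalTrace(2300.0, rng.normal(size=2300), np.array([0.33]))
        out = downsample_averaging(tr, 46.0)  # exact factor 50
        assert out.samples.mean() == pytest.approx(tr.samples.mean(),
                                                   abs=1e-12)

    def test_upsampling_rejected(self):
        tr = SignalTrace(72.0, np.zeros(720), np.array([1.0]))
        with pytest.raises(ValueError):
            downsample_averaging(tr, 500.0)


class TestSnrCalibration:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_hits_target_within_one_db(self, thorax_study, seed):
        tr = simulate_lead_signal(thorax_study["basis"],
                                  thorax_study["coupling_a"],
                                  thorax_study["coupling_b"],
                                  thorax_study["model"], 120.0, 2300.0)
        tr = downsample_averaging(tr, 72.0)
        sigma = calibrated_noise_sigma(tr, 20.0)
        noisy = add_noise(tr, sigma, seed=seed)
        est = estimate_snr(noisy)
        assert est.snr_db == pytest.approx(20.0, abs=1.0)


def test_trace_csv_round_trip(tmp_path):
    tr = SignalTrace(72.0, np.sin(np.arange(720) / 7.0),
                     np.array([0.5, 1.5, 2.5]), meta={"noise_sigma": 0.1})
    path = tmp_path / "trace.csv"
    write_trace_csv(tr, str(path))
    back = read_trace_csv(str(path))
    assert back.fs == tr.fs
    assert np.allclose(back.samples, tr.samples, rtol=1e-6)
    assert np.allclose(back.annotations, tr.annotations)
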