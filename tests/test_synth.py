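"""Generator contracts: trajectories, Poisson structure, WAV round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy.io import wavfile
from scipy.signal import hilbert

from usvkit.synth import (
    CallSpec,
    SessionDesign,
    contour_from_spec,
    sample_call_spec,
    simulate_events,
    synthesize_call,
    synthesize_session,
    write_session,
)

FS = 250_000.0


class TestCallSpec:
    def test_lf_band_enforced(self):
        with pytest.raises(ValueError, match=r"\[20, 30\)"):
            CallSpec("LF", 0.0, 50.0, 35.0)

    def test_high_band_enforced(self):
        with pytest.raises(ValueError, match=r"\[30, 100\]"):
            CallSpec("Flat", 0.0, 50.0, 25.0)

    def test_trill_needs_two_cycles(self):
        with pytest.raises(ValueError, match="cycles"):
            CallSpec("Trill", 0.0, 20.0, 60.0, trill_rate_hz=60.0, trill_depth_khz=5.0)

    def test_trajectory_must_stay_in_band(self):
        with pytest.raises(ValueError, match="outside"):
            CallSpec("FM", 0.0, 50.0, 95.0, sweep_khz=20.0)


class TestSynthesizeCall:
    def test_flat_trajectory_is_constant(self):
        spec = CallSpec("Flat", 0.0, 30.0, 55.0)
        t = np.linspace(0, 0.03, 100)
        f = spec.trajectory_khz(t)
        assert f.max() - f.min() < 0.1

    def test_trill_completes_expected_cycles(self):
        # 75 Hz for 40 ms -> exactly 3 oscillation cycles
        spec = CallSpec("Trill", 0.0, 40.0, 60.0, trill_rate_hz=75.0, trill_depth_khz=5.0)
        t = (np.arange(4000) + 0.5) * 0.04 / 4000  # avoid exact zeros of the sine
        f = spec.trajectory_khz(t) - 60.0
        crossings = np.sum(np.diff(np.sign(f)) != 0)
        assert crossings in (5, 6)  # 3 full cycles up to the endpoint sample

    def test_fm_instantaneous_frequency_matches_ramp(self):
        # Hilbert-transform oracle on the rendered waveform
        spec = CallSpec("FM", 0.0, 50.0, 50.0, sweep_khz=20.0)
        w = synthesize_call(spec, FS)
        inst = np.diff(np.unwrap(np.angle(hilbert(w)))) * FS / (2 * np.pi) / 1000.0
        t = (np.arange(w.size - 1) + 0.5) / FS
        prog = spec.trajectory_khz(t)
        n = w.size
        mid = slice(n // 10, -n // 10)  # exclude envelope ramps
        rms = np.sqrt(np.mean((inst[mid] - prog[mid]) ** 2))
        assert rms < 0.5

    def test_duration_matches_within_one_sample(self):
        w = synthesize_call(CallSpec("Flat", 0.0, 33.3, 44.0), FS)
        assert abs(w.size - 0.0333 * FS) <= 1

    def test_nyquist_violation_names_frequency(self):
        with pytest.raises(ValueError, match="90"):
            synthesize_call(CallSpec("Flat", 0.0, 30.0, 90.0), 100_000.0)

    @pytest.mark.parametrize("ct", ["LF", "Flat", "FM", "Trill"])
    def test_sampled_specs_render_in_band(self, ct, rng):
        for _ in range(20):
            spec = sample_call_spec(ct, rng)
            lo, hi = spec.freq_range_khz()
            assert 20.0 <= lo and hi <= 100.0


class TestSimulateEvents:
    def test_zero_rate_gives_empty_stream(self):
        zero = {k: 0.0 for k in ("LF", "Flat", "FM", "Trill")}
        d = SessionDesign(base_rates=zero, baseline_minutes=5, post_minutes=5)
        ev = simulate_events(d, np.random.default_rng(0))
        assert len(ev) == 0

    def test_poisson_count_conservation(self):
        # constant 3/min per type for 30 min -> E[count] = 90 per type
        flat = {k: 3.0 for k in ("LF", "Flat", "FM", "Trill")}
        d = SessionDesign(
            base_rates=flat, baseline_decay=1.0, baseline_minutes=30, post_minutes=0,
            cno_multiplier={}, sex_trill_multiplier=1.0,
        )
        totals = {k: [] for k in flat}
        for seed in range(200):
            ev = simulate_events(d, np.random.default_rng(seed))
            vc = ev["call_type"].value_counts()
            for k in flat:
                totals[k].append(vc.get(k, 0))
        for k, v in totals.items():
            mean = np.mean(v)
            se = np.std(v, ddof=1) / np.sqrt(len(v))
            assert abs(mean - 90.0) <= 3 * se, f"{k}: {mean} vs 90 (se {se:.2f})"

    def test_cno_multiplier_halves_fm_rate(self):
        ratios_num, ratios_den = [], []
        for seed in range(200):
            for drug, acc in (("VEH", ratios_den), ("CNO", ratios_num)):
                d = SessionDesign(
                    drug=drug, baseline_minutes=10, post_minutes=0, baseline_decay=1.0,
                    cno_multiplier={"FM": 0.5, "Trill": 0.5},
                )
                ev = simulate_events(d, np.random.default_rng(1000 + seed))
                acc.append((ev["call_type"] == "FM").sum())
        ratio = np.mean(ratios_num) / np.mean(ratios_den)
        assert 0.45 <= ratio <= 0.55

    def test_refractory_gap_enforced(self):
        d = SessionDesign(baseline_minutes=5, post_minutes=5)
        ev = simulate_events(d, np.random.default_rng(3))
        for epoch, sub in ev.groupby("epoch"):
            ends = (sub["time_s"] + sub["duration_ms"] / 1000.0).to_numpy()
            starts = sub["time_s"].to_numpy()
            assert np.all(starts[1:] - ends[:-1] >= d.refractory_ms / 1000.0 - 1e-9)

    def test_overload_raises(self):
        heavy = {k: 2000.0 for k in ("LF", "Flat", "FM", "Trill")}
        d = SessionDesign(base_rates=heavy, baseline_minutes=1, post_minutes=0)
        with pytest.raises(ValueError, match="refractory"):
            simulate_events(d, np.random.default_rng(0))

    def test_post_profile_peaks_in_first_two_bins(self):
        d = SessionDesign()
        for ct in ("Flat", "FM", "Trill"):
            r = d.bin_rates(ct, "post_amph")
            assert r[0] == r.max() and np.all(np.diff(r) <= 1e-12)


class TestSynthesizeSession:
    def test_zero_rate_session_is_noise_only(self):
        zero = {k: 0.0 for k in ("LF", "Flat", "FM", "Trill")}
        d = SessionDesign(base_rates=zero, baseline_minutes=0.1, post_minutes=0.0)
        wave, rec = synthesize_session(d, 0)
        assert len(rec) == 0
        assert wave.size == int(0.1 * 60 * FS)
        assert 0 < wave.std() < 0.05  # noise present, far below call amplitude

    def test_ground_truth_windows_contain_call_energy(self):
        d = SessionDesign(baseline_minutes=0.5, post_minutes=0.0, snr_db=40.0)
        wave, rec = synthesize_session(d, 2)
        assert len(rec) > 0
        for _, r in rec.iterrows():
            i0 = int(r.onset_s * FS)
            i1 = int((r.onset_s + r.duration_ms / 1000.0) * FS)
            inside = np.sum(wave[i0:i1] ** 2)
            pad = int(0.02 * FS)
            around = np.sum(wave[max(0, i0 - pad) : i1 + pad] ** 2)
            assert inside >= 0.9 * around

    def test_determinism_byte_identical(self, tmp_path):
        d = SessionDesign(baseline_minutes=0.2, post_minutes=0.0)
        out = []
        for run in range(2):
            wave, rec = synthesize_session(d, 42)
            wav = tmp_path / f"run{run}.wav"
            csv = tmp_path / f"run{run}.csv"
            write_session(wave, rec, wav, csv, FS)
            out.append((wav.read_bytes(), csv.read_bytes()))
        assert out[0] == out[1]


class TestWriteSession:
    def test_empty_records_give_header_only_csv(self, tmp_path):
        write_session(np.zeros(1000), pd.DataFrame(), tmp_path / "e.wav",
                      tmp_path / "e.csv", FS)
        df = pd.read_csv(tmp_path / "e.csv")
        assert len(df) == 0 and "call_type" in df.columns

    def test_wav_roundtrip_preserves_sample_count(self, tmp_path):
        x = np.random.default_rng(0).normal(0, 0.1, 12345)
        write_session(x, pd.DataFrame(), tmp_path / "r.wav", tmp_path / "r.csv", FS)
        fs, back = wavfile.read(tmp_path / "r.wav")
        assert fs == FS and back.size == x.size and back.dtype == np.int16

    def test_full_scale_sine_hits_int16_limit(self, tmp_path):
        # 62.5 kHz at 250 kHz sampling: 4 samples/cycle, peaks hit exactly 1
        t = np.arange(5000) / FS
        x = np.sin(2 * np.pi * 62_500 * t)
        write_session(x, pd.DataFrame(), tmp_path / "f.wav", tmp_path / "f.csv", FS)
        _, back = wavfile.read(tmp_path / "f.wav")
        assert np.abs(back).max() == 32767


class TestContourFromSpec:
    def test_matches_programmed_trajectory(self):
        spec = CallSpec("FM", 1.0, 50.0, 40.0, sweep_khz=15.0)
        c = contour_from_spec(spec)
        assert abs(c.times[0] - 1.0) < 1e-9
        assert abs(c.freqs_khz[0] - 40.0) < 0.2
        assert abs(c.freqs_khz[-1] - 55.0) < 0.5
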