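"""Trace processing and evoked-response extraction."""

import numpy as np
import pandas as pd
import pytest

from neurorecon import (
    EvokedResponseTensor,
    SimulationConfig,
    StimulusTiming,
    TraceMatrix,
    TrialTable,
    extract_evoked_responses,
    process_traces,
    simulate_traces,
)


def make_table(n_stim, n_trials, step, pad):
    rows = []
    frame = pad
    for t in range(n_trials):
        for i in range(n_stim):
            rows.append((i, t, frame, "unknown"))
            frame += step
    return TrialTable(
        pd.DataFrame(rows, columns=["stimulus_id", "trial_index", "onset_frame", "locomotion"])
    )


class TestProcessTraces:
    def test_constant_trace_gives_zero_dff(self):
        tm = TraceMatrix(np.full((3, 600), 50.0))
        dff = process_traces(tm)
        assert np.allclose(dff.signal, 0.0, atol=1e-8)
        assert dff.valid.all()

    def test_neuropil_subtraction_at_awake_ratio(self):
        """With ratio 0.7 the ring signal is scaled and removed before dF/F."""
        rng = np.random.default_rng(0)
        ring = 10.0 * np.sin(np.linspace(0, 40, 900))[None, :]
        clean = np.full((1, 900), 100.0)
        tm = TraceMatrix(clean + 0.7 * ring, neuropil=ring)
        dff = process_traces(tm, contamination_ratio=0.7, preset="awake")
        assert np.max(np.abs(dff.signal)) < 1.0  # contamination removed

    def test_nonpositive_baseline_flags_cell_invalid(self):
        tm = TraceMatrix(np.vstack([np.full(600, -5.0), np.full(600, 50.0)]))
        dff = process_traces(tm)
        assert not dff.valid[0]
        assert dff.valid[1]

    def test_bad_contamination_ratio_rejected(self):
        tm = TraceMatrix(np.ones((1, 100)))
        with pytest.raises(ValueError):
            process_traces(tm, contamination_ratio=1.0)

    def test_planted_transient_survives_filtering(self):
        """A calcium-like transient keeps its windowed amplitude within 10%."""
        timing = StimulusTiming()
        n = 3000
        base = np.full(n, 100.0)
        onset = 1500
        t = np.arange(n, dtype=float)
        kern = np.zeros(n)
        for fl in range(3):
            on = onset + fl * timing.cycle_frames
            kern[t >= on] += np.exp(-(t[t >= on] - on) / 15.0)
        from scipy.signal import savgol_filter

        smooth_gain = np.mean(
            [savgol_filter(kern, 15, 4)[w].mean() for w in timing.stimulus_windows(onset)]
        )
        amp = 40.0  # %dF/F
        trace = base * (1.0 + amp / 100.0 * kern / smooth_gain)
        dff = process_traces(TraceMatrix(trace[None, :]))
        table = TrialTable(
            pd.DataFrame(
                [(0, 0, onset), (0, 1, onset)],
                columns=["stimulus_id", "trial_index", "onset_frame"],
            )
        )
        tensor = extract_evoked_responses(dff, table)
        assert tensor.evoked[0, 0, 0] == pytest.approx(amp, rel=0.10)


class TestExtractEvoked:
    def test_flat_trace_gives_zero_evoked(self):
        timing = StimulusTiming()
        dff = TraceMatrix(np.zeros((2, 2000)), is_dff=True)
        table = make_table(3, 2, timing.train_frames + 60, 60)
        tensor = extract_evoked_responses(dff, table)
        assert np.allclose(tensor.evoked, 0.0)
        assert tensor.evoked.shape == (2, 3, 2)

    def test_baseline_window_is_six_frames_at_30hz(self):
        """200 ms of baseline at 30 Hz = the 6 frames before onset."""
        timing = StimulusTiming(frame_rate=30.0)
        assert timing.baseline_frames == 6
        np.testing.assert_array_equal(
            timing.baseline_window(100), np.arange(94, 100)
        )

    def test_windows_outside_trace_raise(self):
        dff = TraceMatrix(np.zeros((1, 50)), is_dff=True)
        table = make_table(1, 1, 40, 2)  # baseline window would start at -4
        with pytest.raises(ValueError):
            extract_evoked_responses(dff, table)

    def test_low_trial_stimuli_flagged(self):
        timing = StimulusTiming()
        step = timing.train_frames + 60
        rows = [(0, t, 60 + t * step) for t in range(6)] + [(1, 0, 60 + 6 * step)]
        table = TrialTable(
            pd.DataFrame(rows, columns=["stimulus_id", "trial_index", "onset_frame"])
        )
        dff = TraceMatrix(np.zeros((1, 5000)), is_dff=True)
        tensor = extract_evoked_responses(dff, table, min_trials=6)
        assert 1 in tensor.flagged_stimuli
        assert 0 not in tensor.flagged_stimuli

    def test_extraction_commutes_with_cell_permutation(self, rng):
        timing = StimulusTiming()
        sig = rng.normal(10, 1, size=(4, 2500))
        table = make_table(3, 3, timing.train_frames + 40, 50)
        perm = rng.permutation(4)
        t1 = extract_evoked_responses(TraceMatrix(sig, is_dff=True), table)
        t2 = extract_evoked_responses(TraceMatrix(sig[perm], is_dff=True), table)
        np.testing.assert_allclose(t1.evoked[perm], t2.evoked)


class TestTensor:
    def test_zscore_normalizes_each_cell(self, rng):
        ev = rng.normal(5, 3, size=(4, 10, 6))
        tensor = EvokedResponseTensor(evoked=ev)
        z = tensor.zscored.reshape(4, -1)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-12)

    def test_zscoring_is_idempotent(self, rng):
        ev = rng.normal(size=(3, 8, 5))
        once = EvokedResponseTensor(evoked=ev).zscored
        twice = EvokedResponseTensor(evoked=once).zscored
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_missing_trials_stay_missing(self, rng):
        ev = rng.normal(size=(2, 4, 6))
        ev[:, 1, 4:] = np.nan
        tensor = EvokedResponseTensor(evoked=ev)
        assert np.isnan(tensor.zscored[:, 1, 4:]).all()
        np.testing.assert_array_equal(tensor.n_trials_per_stim, [6, 4, 6, 6])

    def test_hdf5_roundtrip(self, rng, tmp_path):
        ev = rng.normal(size=(3, 5, 4))
        tensor = EvokedResponseTensor(evoked=ev)
        tensor.save(tmp_path / "t.h5")
        back = EvokedResponseTensor.load(tmp_path / "t.h5")
        np.testing.assert_array_equal(back.evoked, tensor.evoked)


class TestSimulatedTraceRoundTrip:
    def test_zero_evoked_extracts_near_zero(self):
        cfg = SimulationConfig(seed=3, n_cells=4, n_images=4, n_trials=3,
                               trace_noise_sd=0.0, drift_amplitude=0.0)
        tensor = EvokedResponseTensor(evoked=np.zeros((4, 4, 3)))
        traces, table = simulate_traces(tensor, cfg)
        dff = process_traces(traces)
        out = extract_evoked_responses(dff, table)
        assert np.nanmax(np.abs(out.evoked)) < 0.5  # %dF/F

    def test_high_snr_roundtrip_bias_below_ten_percent(self):
        cfg = SimulationConfig(seed=5, n_cells=10, n_images=8, n_trials=4)
        rng = np.random.default_rng(8)
        ev = rng.normal(0, 5, size=(10, 8, 4))
        ev[rng.random(ev.shape) < 0.1] += 50.0  # planted large responses
        tensor = EvokedResponseTensor(
            evoked=ev, baseline=rng.normal(0, 2, size=ev.shape)
        )
        traces, table = simulate_traces(tensor, cfg)
        dff = process_traces(traces)
        out = extract_evoked_responses(dff, table)
        big = np.abs(ev) > 20
        rel = (out.evoked[big] - ev[big]) / ev[big]
        assert abs(np.mean(rel)) < 0.10

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=9, n_cells=3, n_images=3, n_trials=2)
        tensor = EvokedResponseTensor(evoked=np.ones((3, 3, 2)) * 10)
        t1, tab1 = simulate_traces(tensor, cfg)
        t2, tab2 = simulate_traces(tensor, cfg)
        np.testing.assert_array_equal(t1.signal, t2.signal)
        pd.testing.assert_frame_equal(tab1.table, tab2.table)
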