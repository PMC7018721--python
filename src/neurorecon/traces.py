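"""Fluorescence-trace post-processing and evoked-response extraction.

Raw per-cell calcium traces (30 Hz) are converted to %dF/F by neuropil
subtraction, slow-drift (low-cut) removal, Savitzky-Golay smoothing and a
20th-percentile baseline.  Evoked responses are then read out around each
stimulus presentation: the stimulus is a train of three 200 ms flashes
interleaved with 200 ms gaps; the response is the mean stimulus-window
activity minus the mean of the six frames (200 ms) immediately before
onset, one value per (stimulus, trial).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, median_filter
from scipy.signal import savgol_filter

__all__ = [
    "TraceMatrix",
    "TrialTable",
    "StimulusTiming",
    "EvokedResponseTensor",
    "process_traces",
    "extract_evoked_responses",
]

LOCOMOTION_LABELS = ("unknown", "rest", "run")


@dataclass
class TraceMatrix:
    """cells x frames fluorescence (arbitrary units or %dF/F)."""

    signal: np.ndarray
    frame_rate: float = 30.0
    neuropil: np.ndarray | None = None
    is_dff: bool = False
    valid: np.ndarray | None = None  # per-cell flag set by process_traces

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, float))
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("trace signal must be finite")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.valid is None:
            self.valid = np.ones(self.signal.shape[0], dtype=bool)

    @property
    def n_cells(self) -> int:
        return self.signal.shape[0]

    @property
    def n_frames(self) -> int:
        return self.signal.shape[1]


@dataclass
class TrialTable:
    """Stimulus presentation schedule: one row per (stimulus, trial)."""

    table: pd.DataFrame  # columns: stimulus_id, trial_index, onset_frame, locomotion

    def __post_init__(self):
        required = {"stimulus_id", "trial_index", "onset_frame"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"trial table missing columns {sorted(missing)}")
        if "locomotion" not in self.table.columns:
            self.table = self.table.assign(locomotion="unknown")
        bad = ~self.table["locomotion"].isin(LOCOMOTION_LABELS)
        if bad.any():
            raise ValueError("locomotion labels must be run/rest/unknown")
        if self.table.duplicated(["stimulus_id", "trial_index"]).any():
            raise ValueError("(stimulus_id, trial_index) pairs must be unique")

    @property
    def stimulus_ids(self) -> np.ndarray:
        return np.unique(self.table["stimulus_id"].to_numpy())

    @property
    def n_trials(self) -> int:
        return int(self.table["trial_index"].max()) + 1

    @classmethod
    def from_csv(cls, path) -> "TrialTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class StimulusTiming:
    """Flash-train geometry in frames at the acquisition rate."""

    frame_rate: float = 30.0
    n_flashes: int = 3
    flash_frames: int = 6  # 200 ms at 30 Hz
    gap_frames: int = 6
    baseline_frames: int = 6

    @property
    def cycle_frames(self) -> int:
        return self.flash_frames + self.gap_frames

    @property
    def train_frames(self) -> int:
        return self.n_flashes * self.cycle_frames

    def stimulus_windows(self, onset: int) -> list[np.ndarray]:
        """Frame indices of each per-flash readout window (the flash itself)."""
        return [
            onset + k * self.cycle_frames + np.arange(self.flash_frames)
            for k in range(self.n_flashes)
        ]

    def baseline_window(self, onset: int) -> np.ndarray:
        return onset - self.baseline_frames + np.arange(self.baseline_frames)


@dataclass
class EvokedResponseTensor:
    """cells x stimuli x trials evoked amplitudes in %dF/F.

    Missing trials are NaN and are never imputed.  ``zscored`` standardizes
    each cell over its non-missing entries across stimuli and trials.
    """

    evoked: np.ndarray
    baseline: np.ndarray | None = None
    stimulus_ids: np.ndarray | None = None
    locomotion: np.ndarray | None = None  # stimuli x trials label codes (str)
    cell_valid: np.ndarray | None = None
    flagged_stimuli: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self):
        self.evoked = np.asarray(self.evoked, float)
        if self.evoked.ndim != 3:
            raise ValueError("evoked must be cells x stimuli x trials")
        if self.baseline is None:
            self.baseline = np.zeros_like(self.evoked)
        if self.stimulus_ids is None:
            self.stimulus_ids = np.arange(self.evoked.shape[1])
        if self.cell_valid is None:
            self.cell_valid = np.ones(self.evoked.shape[0], dtype=bool)

    @property
    def n_cells(self) -> int:
        return self.evoked.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.evoked.shape[1]

    @property
    def n_trials(self) -> int:
        return self.evoked.shape[2]

    @property
    def n_trials_per_stim(self) -> np.ndarray:
        return np.sum(~np.isnan(self.evoked[0]), axis=1)

    @property
    def zscored(self) -> np.ndarray:
        flat = self.evoked.reshape(self.n_cells, -1)
        mean = np.nanmean(flat, axis=1)
        sd = np.nanstd(flat, axis=1)
        sd = np.where(sd > 0, sd, 1.0)
        return (self.evoked - mean[:, None, None]) / sd[:, None, None]

    def trial_mean(self, zscored: bool = False) -> np.ndarray:
        """cells x stimuli trial-averaged responses (NaN-aware)."""
        data = self.zscored if zscored else self.evoked
        return np.nanmean(data, axis=2)

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.attrs["schema"] = "neurorecon.evoked_tensor/1"
            h5.create_dataset("evoked", data=self.evoked)
            h5.create_dataset("baseline", data=self.baseline)
            h5.create_dataset("stimulus_ids", data=np.asarray(self.stimulus_ids))
            h5.create_dataset("cell_valid", data=self.cell_valid)
            if self.locomotion is not None:
                h5.create_dataset(
                    "locomotion", data=np.char.encode(self.locomotion.astype(str))
                )

    @classmethod
    def load(cls, path) -> "EvokedResponseTensor":
        import h5py

        with h5py.File(path, "r") as h5:
            loco = None
            if "locomotion" in h5:
                loco = np.char.decode(h5["locomotion"][()])
            return cls(
                evoked=h5["evoked"][()],
                baseline=h5["baseline"][()],
                stimulus_ids=h5["stimulus_ids"][()],
                cell_valid=h5["cell_valid"][()],
                locomotion=loco,
            )


def _low_cut(signal: np.ndarray, frame_rate: float, preset: str, period_s: float) -> np.ndarray:
    """Remove components slower than ``period_s`` seconds/cycle, keep the mean."""
    mean = signal.mean(axis=1, keepdims=True)
    if preset == "anesthetized":
        # Gaussian low-pass in time approximates a frequency-domain Gaussian
        # with cutoff 1/period_s Hz; subtracting it is the low-cut.
        sigma = period_s * frame_rate / (2.0 * np.pi)
        slow = gaussian_filter1d(signal, sigma=sigma, axis=1, mode="nearest")
    elif preset == "awake":
        win = int(round(period_s * frame_rate))
        win = min(win | 1, signal.shape[1] | 1)  # odd, not longer than trace
        slow = median_filter(signal, size=(1, win), mode="nearest")
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return signal - slow + mean


def process_traces(
    traces: TraceMatrix,
    contamination_ratio: float = 0.0,
    preset: str = "anesthetized",
    low_cut_period_s: float = 60.0,
    savgol_window: int = 15,
    savgol_order: int = 4,
) -> TraceMatrix:
    """Raw fluorescence -> %dF/F.

    Steps: (1) subtract ``contamination_ratio`` times the neuropil ring
    signal (skipped when absent; the awake preset of the source protocol
    uses 0.7 for all cells); (2) low-cut everything slower than one cycle
    per ``low_cut_period_s`` (Gaussian low-cut for the anesthetized preset,
    running-median for awake); (3) Savitzky-Golay smoothing (order 4,
    15 frames); (4) dF/F against the per-cell 20th percentile F20 of the
    filtered trace, reported in percent.  Cells with F20 <= 0 are flagged
    invalid and excluded downstream.
    """
    if not 0.0 <= contamination_ratio < 1.0:
        raise ValueError("contamination_ratio must be in [0, 1)")
    sig = traces.signal.copy()
    if traces.neuropil is not None and contamination_ratio > 0:
        sig = sig - contamination_ratio * np.asarray(traces.neuropil, float)
    sig = _low_cut(sig, traces.frame_rate, preset, low_cut_period_s)
    win = min(savgol_window, sig.shape[1] - (sig.shape[1] + 1) % 2)
    if win > savgol_order:
        sig = savgol_filter(sig, window_length=win, polyorder=savgol_order, axis=1)
    f20 = np.percentile(sig, 20, axis=1)
    valid = f20 > 0
    denom = np.where(valid, f20, 1.0)
    dff = 100.0 * (sig - f20[:, None]) / denom[:, None]
    dff[~valid] = np.nan
    dff = np.nan_to_num(dff)  # invalid cells carry zeros + valid=False flag
    return TraceMatrix(dff, traces.frame_rate, is_dff=True, valid=valid)


def extract_evoked_responses(
    dff: TraceMatrix,
    trials: TrialTable,
    timing: StimulusTiming | None = None,
    min_trials: int | None = None,
) -> EvokedResponseTensor:
    """Evoked %dF/F per (cell, stimulus, trial).

    Baseline is the mean of the 6 frames before onset; the stimulus value
    is the mean over each flash window of the three-flash train, averaged
    across flashes.  Stimuli with fewer than ``min_trials`` available
    trials are flagged (awake protocol: at least six).
    """
    timing = timing or StimulusTiming(frame_rate=dff.frame_rate)
    tab = trials.table
    stim_ids = np.unique(tab["stimulus_id"].to_numpy())
    n_trials = int(tab["trial_index"].max()) + 1
    n_cells = dff.n_cells
    evoked = np.full((n_cells, len(stim_ids), n_trials), np.nan)
    baseline = np.full_like(evoked, np.nan)
    loco = np.full((len(stim_ids), n_trials), "unknown", dtype=object)
    stim_pos = {s: i for i, s in enumerate(stim_ids)}
    for row in tab.itertuples(index=False):
        onset = int(row.onset_frame)
        bwin = timing.baseline_window(onset)
        swins = timing.stimulus_windows(onset)
        if bwin[0] < 0 or swins[-1][-1] >= dff.n_frames:
            raise ValueError(f"trial window outside trace (onset {onset})")
        i = stim_pos[row.stimulus_id]
        t = int(row.trial_index)
        base = dff.signal[:, bwin].mean(axis=1)
        stim = np.mean([dff.signal[:, w].mean(axis=1) for w in swins], axis=0)
        baseline[:, i, t] = base
        evoked[:, i, t] = stim - base
        loco[i, t] = getattr(row, "locomotion", "unknown")
    counts = np.sum(~np.isnan(evoked[0]), axis=1)
    flagged = np.where(counts < (min_trials or 0))[0]
    return EvokedResponseTensor(
        evoked=evoked,
        baseline=baseline,
        stimulus_ids=stim_ids,
        locomotion=loco.astype(str),
        cell_valid=dff.valid.copy(),
        flagged_stimuli=flagged,
    )
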