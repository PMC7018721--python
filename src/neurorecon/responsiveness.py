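"""Responsive-cell detection, shuffle false-positive control, sparseness.

A cell is visually responsive when a one-way ANOVA over N stimulus
activities plus one baseline activity (the per-trial mean of the baseline
windows across stimuli) rejects at ``alpha``.  A responsive cell responds
to a particular image when a per-image t-test (stimulus vs baseline,
paired across trials) rejects at ``alpha`` AND the trial-averaged evoked
response exceeds ``amp_threshold`` %dF/F.  The amplitude gate keeps the
per-image false-positive rate well below the responsive fraction; the
label-shuffle control estimates all three rates empirically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .traces import EvokedResponseTensor

__all__ = [
    "ResponsivenessResult",
    "detect_responsive",
    "shuffled_false_positive_rate",
    "population_sparseness",
]


@dataclass
class ResponsivenessResult:
    cell_responsive: np.ndarray  # (cells,) bool, ANOVA gate
    image_responsive: np.ndarray  # (cells, stimuli) bool, all gates
    anova_p: np.ndarray  # (cells,)
    ttest_p: np.ndarray  # (cells, stimuli)
    amplitude_pass: np.ndarray  # (cells, stimuli) bool
    cell_tested: np.ndarray  # (cells,) bool; zero-variance cells are not
    alpha: float = 0.01
    amp_threshold: float = 10.0

    @property
    def responsive_fraction(self) -> float:
        return float(np.mean(self.cell_responsive))

    def responsive_cells(self, image: int) -> np.ndarray:
        return np.where(self.image_responsive[:, image])[0]

    def to_frame(self) -> pd.DataFrame:
        cells, stims = np.nonzero(np.ones_like(self.ttest_p, dtype=bool))
        return pd.DataFrame(
            {
                "cell": cells,
                "stimulus": stims,
                "anova_p": self.anova_p[cells],
                "ttest_p": self.ttest_p[cells, stims],
                "cell_responsive": self.cell_responsive[cells],
                "amplitude_pass": self.amplitude_pass[cells, stims],
                "image_responsive": self.image_responsive[cells, stims],
            }
        )


def _anova_dataset(tensor: EvokedResponseTensor) -> np.ndarray:
    """cells x (N+1 groups) x trials activity array (NaN for missing).

    Stimulus groups hold the stimulus-window activity (evoked + baseline);
    the extra group holds the per-trial baseline averaged across stimuli.
    """
    stim_act = tensor.evoked + tensor.baseline
    base_group = np.nanmean(tensor.baseline, axis=1, keepdims=True)
    return np.concatenate([stim_act, base_group], axis=1)


def _anova_pvalues(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA across the leading axis.

    ``data`` is cells x groups x samples with NaN for missing samples.
    Returns (p-values, tested flag); cells with zero within-group variance
    are not tested.
    """
    counts = np.sum(~np.isnan(data), axis=2)  # (cells, groups)
    gmean = np.nanmean(data, axis=2)
    n_tot = counts.sum(axis=1)
    grand = np.nansum(np.where(np.isnan(data), 0.0, data), axis=(1, 2)) / n_tot
    ss_between = np.sum(counts * (gmean - grand[:, None]) ** 2, axis=1)
    ss_within = np.nansum((data - gmean[:, :, None]) ** 2, axis=(1, 2))
    k = data.shape[1]
    df_b = k - 1
    df_w = n_tot - k
    tested = (ss_within > 0) & (df_w > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / np.maximum(df_w, 1))
    p = np.full(data.shape[0], np.nan)
    p[tested] = stats.f.sf(F[tested], df_b, df_w[tested])
    return p, tested


def detect_responsive(
    tensor: EvokedResponseTensor,
    alpha: float = 0.01,
    amp_threshold: float = 10.0,
) -> ResponsivenessResult:
    """Apply the ANOVA / t-test / amplitude criteria to an evoked tensor."""
    if np.min(tensor.n_trials_per_stim) < 2:
        raise ValueError("need at least two trials per stimulus")
    data = _anova_dataset(tensor)
    anova_p, tested = _anova_pvalues(data)
    cell_resp = tested & (anova_p < alpha) & tensor.cell_valid

    stim_act = tensor.evoked + tensor.baseline
    with np.errstate(invalid="ignore"):
        t_stat, ttest_p = stats.ttest_rel(stim_act, tensor.baseline, axis=2, nan_policy="omit")
    ttest_p = np.asarray(ttest_p)
    amp = np.nanmean(tensor.evoked, axis=2)
    amp_pass = amp > amp_threshold
    image_resp = cell_resp[:, None] & (ttest_p < alpha) & amp_pass
    return ResponsivenessResult(
        cell_responsive=cell_resp,
        image_responsive=image_resp,
        anova_p=anova_p,
        ttest_p=ttest_p,
        amplitude_pass=amp_pass,
        cell_tested=tested,
        alpha=alpha,
        amp_threshold=amp_threshold,
    )


def shuffled_false_positive_rate(
    tensor: EvokedResponseTensor,
    alpha: float = 0.01,
    amp_threshold: float = 10.0,
    n_shuffles: int = 20,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """False-positive rates of the criteria on label-shuffled data.

    Within every (cell, trial) the N+1 group labels (stimulus activities
    plus the baseline-group value) are independently permuted, the
    criteria re-applied, and flagged fractions averaged over shuffles.
    Returns rates (fractions in [0, 1]) for the ANOVA-only (per cell),
    t-test-only and combined (per cell-image) criteria.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    data = _anova_dataset(tensor)  # cells x (N+1) x trials
    n_cells, n_groups, n_trials = data.shape
    rates = {"anova": [], "ttest": [], "combined": []}
    for _ in range(n_shuffles):
        perm = np.argsort(rng.random((n_cells, n_trials, n_groups)), axis=2)
        shuf = np.take_along_axis(
            np.swapaxes(data, 1, 2), perm, axis=2
        )  # cells x trials x groups
        shuf = np.swapaxes(shuf, 1, 2)
        anova_p, tested = _anova_pvalues(shuf)
        cell_flag = tested & (anova_p < alpha)
        stim_act = shuf[:, :-1, :]
        base = shuf[:, -1:, :]
        with np.errstate(invalid="ignore"):
            _, ttest_p = stats.ttest_rel(
                stim_act, np.broadcast_to(base, stim_act.shape), axis=2, nan_policy="omit"
            )
        ttest_p = np.asarray(ttest_p)
        amp = np.nanmean(stim_act - base, axis=2)
        t_flag = ttest_p < alpha
        comb = cell_flag[:, None] & t_flag & (amp > amp_threshold)
        rates["anova"].append(np.mean(cell_flag))
        rates["ttest"].append(np.mean(t_flag))
        rates["combined"].append(np.mean(comb))
    return {k: float(np.mean(v)) for k, v in rates.items()}


def population_sparseness(responses: np.ndarray) -> float:
    """Treves-Rolls population sparseness of one response vector.

    ``s = [1 - (sum R_i)^2 / (N * sum R_i^2)] / (1 - 1/N)`` over cells.
    0 for a uniform population response, 1 for a one-hot response.
    """
    r = np.asarray(responses, float).ravel()
    n = r.size
    if n < 2:
        raise ValueError("need at least two cells")
    ss = np.sum(r**2)
    if ss == 0:
        raise ValueError("sparseness undefined for an all-zero vector")
    return float((1.0 - np.sum(r) ** 2 / (n * ss)) / (1.0 - 1.0 / n))
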