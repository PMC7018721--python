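"""End-to-end pipeline driver: simulate -> extract -> respond -> encode ->
reconstruct -> analyze -> report.

The resolved configuration (defaults merged with overrides) is written next
to the outputs, and a structured log records every threshold applied and
every filter's survivor counts, so a run is reproducible from its output
directory alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    EvokedResponseTensor,
    build_gabor_bank,
    detect_responsive,
    encode_images,
    extract_evoked_responses,
    fit_encoding_cv,
    fit_reconstruction,
    fit_reverse_scale,
    generate_images,
    generate_population,
    make_cv_split,
    noise_correlation,
    population_sparseness,
    process_traces,
    reconstruct_and_score,
    simulate_responses,
    simulate_traces,
    trial_reliability,
)
from .gabor import decode_features
from .simulate import SimulationConfig

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

SCHEMA = "neurorecon.pipeline/1"


@dataclass
class PipelineConfig:
    """Stage toggles and every analysis threshold, at protocol defaults."""

    seed: int = 0
    out_dir: str = "neurorecon_out"
    preset: str = "anesthetized"  # anesthetized | awake
    # synthetic experiment conditions
    n_cells: int = 60
    n_images: int = 80
    n_trials: int = 12
    noise_sd: float = 8.0
    shared_noise_corr: float = 0.0
    simulate_traces: bool = False  # full trace round trip vs direct tensor
    # analysis thresholds (protocol defaults)
    alpha: float = 0.01
    amp_threshold: float = 10.0  # %dF/F
    n_folds: int = 10
    contamination_ratio: float = 0.0  # awake protocol uses 0.7
    recon_mode: str = "cell_selection"  # all_cell | cell_selection | nested_cv
    stages: tuple[str, ...] = (
        "simulate",
        "extract",
        "respond",
        "encode",
        "reconstruct",
        "analyze",
        "report",
    )

    def resolved(self) -> dict:
        d = asdict(self)
        d["schema"] = SCHEMA
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    out_dir: Path
    log: list = field(default_factory=list)
    bank: object = None
    images: object = None
    tensor: EvokedResponseTensor | None = None
    responsiveness: object = None
    encoding_models: list = field(default_factory=list)
    reconstruction: object = None
    score: object = None
    tables: dict = field(default_factory=dict)


def _log(result: PipelineResult, stage: str, **info):
    entry = {"stage": stage, **info}
    result.log.append(entry)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured stages in order with shared seeds and splits."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.resolved(), fh)
    result = PipelineResult(config=config, out_dir=out)
    stages = set(config.stages)

    sim_cfg = SimulationConfig(
        seed=config.seed,
        n_cells=config.n_cells,
        n_images=config.n_images,
        n_trials=config.n_trials,
        noise_sd=config.noise_sd,
        shared_noise_corr=config.shared_noise_corr,
    )
    bank = build_gabor_bank()
    images = generate_images(sim_cfg)
    bank = fit_reverse_scale(bank, images)
    result.bank, result.images = bank, images
    feats = encode_images(bank, images)
    targets = decode_features(bank, feats)  # I': evaluation targets

    if "simulate" in stages:
        pop = generate_population(sim_cfg, bank, images)
        tensor, clean = simulate_responses(pop, images, sim_cfg, bank)
        if config.simulate_traces:
            traces, table = simulate_traces(tensor, sim_cfg)
            _log(result, "simulate", n_frames=traces.n_frames)
            if "extract" in stages:
                dff = process_traces(
                    traces,
                    contamination_ratio=config.contamination_ratio,
                    preset=config.preset,
                )
                tensor = extract_evoked_responses(dff, table)
                _log(result, "extract", n_valid_cells=int(dff.valid.sum()))
        result.tensor = tensor
        _log(
            result,
            "simulate",
            n_cells=tensor.n_cells,
            n_stimuli=tensor.n_stimuli,
            n_trials=tensor.n_trials,
            seed=config.seed,
        )
    if result.tensor is None:
        raise RuntimeError("no tensor available; enable the simulate stage")
    tensor = result.tensor

    if "respond" in stages:
        resp = detect_responsive(tensor, alpha=config.alpha, amp_threshold=config.amp_threshold)
        result.responsiveness = resp
        _log(
            result,
            "respond",
            alpha=config.alpha,
            amp_threshold=config.amp_threshold,
            n_responsive_cells=int(resp.cell_responsive.sum()),
            n_image_responses=int(resp.image_responsive.sum()),
        )

    splits = make_cv_split(config.n_images, config.n_folds, seed=config.seed)
    if "encode" in stages:
        z = tensor.zscored
        models = [
            fit_encoding_cv(z[k], feats, splits, cell_id=k) for k in range(tensor.n_cells)
        ]
        result.encoding_models = models
        perfs = [m.cv_performance for m in models]
        _log(
            result,
            "encode",
            n_folds=config.n_folds,
            median_cv_performance=float(np.median(perfs)),
            median_n_features=float(np.median([m.n_features for m in models])),
        )

    if "reconstruct" in stages:
        recon = fit_reconstruction(
            tensor,
            feats,
            splits,
            mode=config.recon_mode,
            encoding_models=result.encoding_models or None,
        )
        stack, score = reconstruct_and_score(recon, tensor, bank, targets)
        result.reconstruction, result.score = recon, score
        _log(
            result,
            "reconstruct",
            mode=config.recon_mode,
            median_R=score.median_R,
            median_CD=score.median_CD,
        )
        score.per_image.to_csv(out / "reconstruction_scores.csv", index=False)
        stack.to_tiff(out / "reconstructed.tiff")

    if "analyze" in stages:
        tables = {}
        if result.responsiveness is not None:
            tables["responsiveness"] = result.responsiveness.to_frame()
            evoked_avg = tensor.trial_mean()
            spars = [
                population_sparseness(np.maximum(evoked_avg[:, i], 0.0))
                for i in range(tensor.n_stimuli)
                if np.any(evoked_avg[:, i] > 0)
            ]
            tables["sparseness"] = pd.DataFrame(
                {"stimulus": np.arange(len(spars)), "sparseness": spars}
            )
            _log(result, "analyze", median_sparseness=float(np.median(spars)))
        nc = noise_correlation(tensor)
        iu = np.triu_indices_from(nc, k=1)
        tables["noise_correlation"] = pd.DataFrame({"r": nc[iu]})
        _log(result, "analyze", median_noise_correlation=float(np.nanmedian(nc[iu])))
        if result.score is not None:
            rel_rows = []
            for i in range(tensor.n_stimuli):
                zi = tensor.zscored[:, i, :]
                if np.all(np.isfinite(zi)):
                    rep = trial_reliability(zi.T)
                    rel_rows.append(
                        (i, rep.across_trial_similarity, rep.across_trial_variability)
                    )
            tables["response_reliability"] = pd.DataFrame(
                rel_rows, columns=["stimulus", "similarity", "variability"]
            )
        result.tables = tables

    if "report" in stages:
        for name, df in result.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        with open(out / "pipeline_log.json", "w") as fh:
            json.dump(result.log, fh, indent=2)
    return result
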