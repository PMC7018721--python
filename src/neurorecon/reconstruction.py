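"""Linear image reconstruction (decoding) from population activity.

Every Gabor feature value is regressed on the single-trial z-scored
responses of the population, ``F_j = H_j R + c_j`` (ridge with
evidence-maximized regularizer, per feature, per CV fold).  Reconstructed
feature vectors are decoded to images with the reverse Gabor transform and
scored against the Gabor round-tripped stimuli ``I'`` with the pixel
Pearson correlation R and the coefficient of determination
``CD = 1 - sum(I' - Ihat)^2 / sum(I' - mean(I'))^2``.

Three decoder variants: the all-cell model (every cell predicts every
feature), the cell-selection model (a cell participates only in features
it encodes, taken from the per-cell encoding models; features no cell
encodes are fixed at zero), and a nested-CV cell-selection model in which
the selection itself is made without touching the test fold
(10% test / 9% validation / 81% training).

Reconstruction from a cell subset rescales the frozen decoder by a single
free factor ``a'`` (``F' = a' H R' + c``) fitted on the training folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cv import CVSplit
from .encoding import EncodingModel, feature_correlations
from .gabor import FeatureMatrix, GaborBank, ImageStack, decode_features
from .ridge import ridge_em, ridge_em_multi

__all__ = [
    "ReconstructionModel",
    "ReconstructionScore",
    "selection_mask",
    "fit_reconstruction",
    "reconstruct_and_score",
    "subset_reconstruct",
    "feature_count_sweep",
]


@dataclass
class ReconstructionModel:
    mode: str  # all_cell | cell_selection | nested_cv
    mask: np.ndarray  # (f, n_cells) bool
    fold_H: list  # per fold: (f, n_cells), masked-out entries exactly 0
    fold_c: list  # per fold: (f,)
    splits: CVSplit
    subset_scale: float = 1.0
    fold_masks: list | None = None  # nested CV: per-fold selection masks

    @property
    def f(self) -> int:
        return self.mask.shape[0]

    @property
    def n_cells(self) -> int:
        return self.mask.shape[1]

    def mask_for_fold(self, fold: int) -> np.ndarray:
        if self.fold_masks is not None:
            return self.fold_masks[fold]
        return self.mask

    def mean_H(self) -> np.ndarray:
        return np.mean(self.fold_H, axis=0)

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.attrs["schema"] = "neurorecon.reconstruction/1"
            h5.attrs["mode"] = self.mode
            h5.attrs["subset_scale"] = self.subset_scale
            h5.attrs["n_folds"] = self.splits.n_folds
            h5.attrs["cv_seed"] = self.splits.seed
            h5.create_dataset("mask", data=self.mask)
            h5.create_dataset("fold_of_image", data=self.splits.fold_of_image)
            h5.create_dataset("fold_H", data=np.array(self.fold_H))
            h5.create_dataset("fold_c", data=np.array(self.fold_c))

    @classmethod
    def load(cls, path) -> "ReconstructionModel":
        import h5py

        with h5py.File(path, "r") as h5:
            splits = CVSplit(
                fold_of_image=h5["fold_of_image"][()],
                n_folds=int(h5.attrs["n_folds"]),
                seed=int(h5.attrs["cv_seed"]),
            )
            return cls(
                mode=str(h5.attrs["mode"]),
                mask=h5["mask"][()],
                fold_H=list(h5["fold_H"][()]),
                fold_c=list(h5["fold_c"][()]),
                splits=splits,
                subset_scale=float(h5.attrs["subset_scale"]),
            )


@dataclass
class ReconstructionScore:
    per_trial: pd.DataFrame  # stimulus, trial, R, CD
    per_image: pd.DataFrame  # stimulus, R, CD (from the trial-averaged image)

    @property
    def median_R(self) -> float:
        return float(self.per_image["R"].median())

    @property
    def median_CD(self) -> float:
        return float(self.per_image["CD"].median())


def selection_mask(models: list[EncodingModel], f: int) -> np.ndarray:
    """(f, n_cells) mask: cell participates in features it encodes."""
    mask = np.zeros((f, len(models)), dtype=bool)
    for k, m in enumerate(models):
        mask[m.selected_features, k] = True
    return mask


def _flat_samples(z: np.ndarray, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flatten (cells, stimuli, trials) over given images; drop missing trials."""
    n_trials = z.shape[2]
    R = z[:, images, :].reshape(z.shape[0], -1)
    img_of = np.repeat(images, n_trials)
    ok = np.all(np.isfinite(R), axis=0)
    return R[:, ok], img_of[ok]


def _fit_fold(R_tr, F_tr, mask) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature ridge-EM regressions for one fold; exact zeros off-mask."""
    f, n_cells = mask.shape
    H = np.zeros((f, n_cells))
    c = np.zeros(f)
    if mask.all():
        W, b, _ = ridge_em_multi(R_tr, F_tr)
        return W, b
    # group features by identical cell sets to share the design SVD
    patterns: dict[bytes, list[int]] = {}
    for j in range(f):
        patterns.setdefault(mask[j].tobytes(), []).append(j)
    for key, feats_j in patterns.items():
        cells = np.frombuffer(key, dtype=bool)
        if not cells.any():
            continue  # feature reconstructs to 0 (bias fixed at 0)
        W, b, _ = ridge_em_multi(R_tr[cells], F_tr[feats_j])
        H[np.ix_(feats_j, np.where(cells)[0])] = W
        c[feats_j] = b
    return H, c


def _nested_selection_models(z, feats, splits, fold, thresholds):
    """Encoding-style feature selection without the test fold.

    The selection correlation is computed on the 81% training images, the
    per-cell threshold chosen on the 9% validation fold, mirroring the
    encoding model but leaving the outer test fold untouched.
    """
    tr_img, va_img = splits.nested_split(fold)
    F = feats.values
    n_cells = z.shape[0]
    mask = np.zeros((F.shape[0], n_cells), dtype=bool)
    for k in range(n_cells):
        zk = z[k]
        y_tr = zk[tr_img].ravel()
        img_tr = np.repeat(tr_img, zk.shape[1])
        ok = np.isfinite(y_tr)
        y_tr, img_tr = y_tr[ok], img_tr[ok]
        corr = feature_correlations(y_tr, F[:, img_tr])
        best_perf, best_sel = -np.inf, np.zeros(0, dtype=int)
        va_avg = np.nanmean(zk[va_img], axis=1)
        for th in thresholds:
            sel = np.where(corr > th)[0]
            fit = ridge_em(F[np.ix_(sel, img_tr)], y_tr)
            pred = (
                fit.weights @ F[np.ix_(sel, va_img)] + fit.bias
                if sel.size
                else np.full(va_img.size, fit.bias)
            )
            perf = _safe_corr(va_avg, pred)
            if perf >= best_perf:  # ties -> higher threshold (sparser)
                best_perf, best_sel = perf, sel
        mask[best_sel, k] = True
    return mask


def _safe_corr(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
        return 0.0
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def fit_reconstruction(
    tensor,
    feats: FeatureMatrix,
    splits: CVSplit,
    mask: np.ndarray | None = None,
    mode: str = "all_cell",
    encoding_models: list[EncodingModel] | None = None,
    thresholds: np.ndarray | None = None,
) -> ReconstructionModel:
    """Fit the per-feature decoder on each CV fold.

    ``mode='all_cell'`` uses every cell for every feature;
    ``'cell_selection'`` takes the mask from ``encoding_models`` (or an
    explicit ``mask``); ``'nested_cv'`` redoes the selection inside each
    fold on the 81/9 split.  Regression samples are single trials across
    stimuli; masked-out weight entries are exactly zero and features with
    no participating cell reconstruct to zero.
    """
    z = tensor.zscored
    F = feats.values
    f, n_cells = F.shape[0], z.shape[0]
    if mode == "all_cell":
        mask = np.ones((f, n_cells), dtype=bool)
    elif mode == "cell_selection":
        if mask is None:
            if encoding_models is None:
                raise ValueError("cell selection needs encoding_models or a mask")
            mask = selection_mask(encoding_models, f)
    elif mode == "nested_cv":
        mask = np.zeros((f, n_cells), dtype=bool)  # filled as the fold-mask union
    else:
        raise ValueError(f"unknown mode {mode!r}")

    from .encoding import THRESHOLD_GRID

    thresholds = THRESHOLD_GRID if thresholds is None else thresholds
    fold_H, fold_c, fold_masks = [], [], []
    for fold in range(splits.n_folds):
        tr_img = splits.train_images(fold)
        R_tr, img_tr = _flat_samples(z, tr_img)
        if R_tr.shape[1] < 2:
            raise ValueError("fewer than two training samples")
        F_tr = F[:, img_tr]
        fold_mask = (
            _nested_selection_models(z, feats, splits, fold, thresholds)
            if mode == "nested_cv"
            else mask
        )
        H, c = _fit_fold(R_tr, F_tr, fold_mask)
        fold_H.append(H)
        fold_c.append(c)
        fold_masks.append(fold_mask)
        if mode == "nested_cv":
            mask |= fold_mask
    return ReconstructionModel(
        mode=mode,
        mask=mask,
        fold_H=fold_H,
        fold_c=fold_c,
        splits=splits,
        fold_masks=fold_masks if mode == "nested_cv" else None,
    )


def _score_images(ihat: np.ndarray, target: np.ndarray) -> tuple[float, float]:
    """Pixel R and CD of one reconstructed image against its target."""
    tmean = target.mean()
    denom = np.sum((target - tmean) ** 2)
    if denom == 0:
        return np.nan, np.nan
    cd = 1.0 - np.sum((target - ihat) ** 2) / denom
    # ptp is exact for constant arrays where np.std can leave rounding dust
    r = np.nan if np.ptp(ihat) == 0 else float(np.corrcoef(ihat, target)[0, 1])
    return r, float(cd)


def reconstruct_and_score(
    model: ReconstructionModel,
    tensor,
    bank: GaborBank,
    targets: ImageStack,
    cell_subset: np.ndarray | None = None,
) -> tuple[ImageStack, ReconstructionScore]:
    """Predict held-out features per single trial, decode, and score.

    ``targets`` are the Gabor round-tripped stimuli I'.  Returns the
    trial-averaged reconstructed stack and per-trial / per-image R and CD
    tables.  With ``cell_subset`` the responses of excluded cells are
    zeroed and the model's ``subset_scale`` applied.
    """
    z = tensor.zscored
    if cell_subset is not None:
        keep = np.zeros(z.shape[0], dtype=bool)
        keep[np.asarray(cell_subset, int)] = True
        z = np.where(keep[:, None, None], z, 0.0)
    n_images = targets.n_images
    recon_avg = np.zeros((bank.p, n_images))
    rows = []
    a = model.subset_scale
    for fold in range(model.splits.n_folds):
        te_img = model.splits.test_images(fold)
        H, c = model.fold_H[fold], model.fold_c[fold]
        for i in te_img:
            zi = z[:, i, :]
            ok = np.all(np.isfinite(zi), axis=0)
            Fhat = a * (H @ zi[:, ok]) + c[:, None]
            imgs = decode_features(bank, Fhat).pixels  # p x trials
            tgt = targets.pixels[:, i]
            for t_idx, t in enumerate(np.where(ok)[0]):
                r, cd = _score_images(imgs[:, t_idx], tgt)
                rows.append((i, t, r, cd))
            avg = imgs.mean(axis=1)
            recon_avg[:, i] = avg
    per_trial = pd.DataFrame(rows, columns=["stimulus", "trial", "R", "CD"])
    per_image_rows = []
    for i in range(n_images):
        r, cd = _score_images(recon_avg[:, i], targets.pixels[:, i])
        per_image_rows.append((i, r, cd))
    per_image = pd.DataFrame(per_image_rows, columns=["stimulus", "R", "CD"])
    stack = ImageStack(recon_avg, bank.spec.image_side, bank.spec.degrees_per_pixel)
    return stack, ReconstructionScore(per_trial=per_trial, per_image=per_image)


def fit_subset_scale(
    model: ReconstructionModel, tensor, feats: FeatureMatrix, cell_subset: np.ndarray
) -> float:
    """Closed-form ``a'`` minimizing sum (a' H R' + c - F)^2 on training folds."""
    z = tensor.zscored
    keep = np.zeros(z.shape[0], dtype=bool)
    keep[np.asarray(cell_subset, int)] = True
    zs = np.where(keep[:, None, None], z, 0.0)
    F = feats.values
    num = den = 0.0
    for fold in range(model.splits.n_folds):
        tr_img = model.splits.train_images(fold)
        R_tr, img_tr = _flat_samples(zs, tr_img)
        P = model.fold_H[fold] @ R_tr  # f x n
        resid = F[:, img_tr] - model.fold_c[fold][:, None]
        num += float(np.sum(P * resid))
        den += float(np.sum(P * P))
    return num / den if den > 0 else 0.0


def subset_reconstruct(
    model: ReconstructionModel,
    tensor,
    feats: FeatureMatrix,
    bank: GaborBank,
    targets: ImageStack,
    cell_subset: np.ndarray,
) -> tuple[float, ImageStack, ReconstructionScore]:
    """Reconstruct from a cell subset with the rescaled frozen decoder."""
    cell_subset = np.asarray(cell_subset, int)
    a = fit_subset_scale(model, tensor, feats, cell_subset) if cell_subset.size else 0.0
    scaled = replace(model, subset_scale=a)
    stack, score = reconstruct_and_score(scaled, tensor, bank, targets, cell_subset)
    return a, stack, score


def feature_count_sweep(
    tensor,
    feats: FeatureMatrix,
    bank: GaborBank,
    targets: ImageStack,
    splits: CVSplit,
    encoding_models: list[EncodingModel],
    factors: np.ndarray = np.array([0.1, 0.3, 1.0, 3.0, 10.0, 20.0]),
) -> pd.DataFrame:
    """Reconstruction performance vs features-per-cell scaling factor.

    For each factor the per-cell selected-feature count of the original
    encoding model is multiplied by the factor and the cell's threshold
    adjusted accordingly (top-k features by |correlation| with the cell's
    responses); the cell-selection decoder is refit and scored per CV.
    """
    factors = np.asarray(factors, float)
    if np.any(factors <= 0):
        raise ValueError("factors must be positive")
    z = tensor.zscored
    F = feats.values
    f = F.shape[0]
    n_cells = z.shape[0]
    # |r| on all samples, matching the final encoding-model selection
    corr = np.zeros((n_cells, f))
    for k in range(n_cells):
        y, img_of = _flatten_cell(z[k])
        corr[k] = feature_correlations(y, F[:, img_of])
    base_counts = np.array([m.n_features for m in encoding_models])
    rows = []
    for factor in factors:
        mask = np.zeros((f, n_cells), dtype=bool)
        for k in range(n_cells):
            kk = int(np.clip(round(base_counts[k] * factor), 0, f))
            if kk > 0:
                top = np.argpartition(corr[k], -kk)[-kk:]
                mask[top, k] = True
        model = fit_reconstruction(tensor, feats, splits, mask=mask, mode="cell_selection")
        _, score = reconstruct_and_score(model, tensor, bank, targets)
        rows.append((factor, score.median_R, score.median_CD))
    return pd.DataFrame(rows, columns=["factor", "median_R", "median_CD"])


def _flatten_cell(zk: np.ndarray):
    n_images, n_trials = zk.shape
    vals = zk.ravel()
    img_of = np.repeat(np.arange(n_images), n_trials)
    ok = np.isfinite(vals)
    return vals[ok], img_of[ok]
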