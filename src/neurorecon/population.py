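"""Population-level analyses of the reconstruction.

Covers: addition/drop performance curves over amplitude-ordered cells,
representation areas of reverse filters and their pairwise overlap,
robustness to sequential dropping of overlapping cells, across-trial
similarity/variability (the variability ratio equals the inverse of the
one-way ANOVA F-value), noise correlations and their removal by
within-stimulus trial shuffling, responsive-cell accumulation across
images, the basis-capacity fit of the decoder weights, and the running
modulation index (RMI) for locomotion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk

from .gabor import FeatureMatrix, GaborBank, ImageStack
from .reconstruction import (
    ReconstructionModel,
    _flat_samples,
    _score_images,
)
from .responsiveness import ResponsivenessResult
from .traces import EvokedResponseTensor

__all__ = [
    "RepresentationArea",
    "OverlapSet",
    "ReliabilityReport",
    "CapacityFit",
    "reverse_filters",
    "representation_areas",
    "overlap_index",
    "overlap_sets",
    "cell_curves",
    "sequential_drop",
    "trial_reliability",
    "noise_correlation",
    "shuffle_trials",
    "image_accumulation",
    "capacity_fit",
    "running_modulation_index",
]


@dataclass
class RepresentationArea:
    cell_id: int
    mask: np.ndarray  # (p,) bool, single connected component (or empty)
    reverse_filter: np.ndarray  # (p,)

    @property
    def empty(self) -> bool:
        return not self.mask.any()


@dataclass
class OverlapSet:
    reference: int
    members: np.ndarray  # includes the reference
    overlap_with_reference: dict

    @property
    def size(self) -> int:
        return self.members.size


@dataclass
class ReliabilityReport:
    across_trial_similarity: float
    across_trial_variability: float


@dataclass
class CapacityFit:
    coeffs: np.ndarray  # B, cells x images
    offsets: np.ndarray  # d, (f,)
    error_percent: np.ndarray  # per image, Eq.-style image-space error x 100
    rank_deficient: bool = False


# ---------------------------------------------------------------------------
# representation areas and overlap


def reverse_filters(model: ReconstructionModel, bank: GaborBank) -> np.ndarray:
    """p x n_cells image-space maps: reverse transform of each cell's weights.

    Uses the fold-averaged decoder weights; the z-scoring applied downstream
    removes the global alpha scale.
    """
    return bank.reverse @ model.mean_H()


def representation_areas(
    model: ReconstructionModel,
    bank: GaborBank,
    z_threshold: float = 1.5,
    smooth_radius: int = 3,
) -> list[RepresentationArea]:
    """Threshold |z| of each reverse filter, keep the largest 8-connected
    cluster, smooth the contour by morphological closing (3-px disc)."""
    side = bank.spec.image_side
    rev = reverse_filters(model, bank)
    out = []
    struct = np.ones((3, 3), dtype=bool)  # 8-connectivity
    footprint = disk(smooth_radius)
    for k in range(rev.shape[1]):
        v = rev[:, k]
        sd = v.std()
        if sd == 0:
            out.append(RepresentationArea(k, np.zeros(bank.p, dtype=bool), v))
            continue
        z = (v - v.mean()) / sd
        mask2d = (np.abs(z) > z_threshold).reshape(side, side)
        labels, n = ndimage.label(mask2d, structure=struct)
        if n == 0:
            out.append(RepresentationArea(k, np.zeros(bank.p, dtype=bool), v))
            continue
        sizes = ndimage.sum_labels(mask2d, labels, index=np.arange(1, n + 1))
        largest = labels == (1 + int(np.argmax(sizes)))
        smoothed = ndimage.binary_closing(largest, structure=footprint)
        # closing can merge in stray pixels only by bridging; re-keep largest
        labels2, n2 = ndimage.label(smoothed, structure=struct)
        if n2 > 1:
            sizes2 = ndimage.sum_labels(smoothed, labels2, index=np.arange(1, n2 + 1))
            smoothed = labels2 == (1 + int(np.argmax(sizes2)))
        out.append(RepresentationArea(k, smoothed.ravel(), v))
    return out


def overlap_index(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index |A∩B| / |A∪B| of two pixel masks."""
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def overlap_sets(
    areas: list[RepresentationArea],
    responsive_cells: np.ndarray,
    threshold: float = 0.2,
) -> list[OverlapSet]:
    """Per reference responsive cell, the responsive cells overlapping it.

    Cells with empty representation areas are excluded.
    """
    cells = [c for c in np.asarray(responsive_cells, int) if not areas[c].empty]
    sets = []
    for ref in cells:
        overlaps = {}
        for other in cells:
            if other == ref:
                continue
            oi = overlap_index(areas[ref].mask, areas[other].mask)
            if oi > threshold:
                overlaps[other] = oi
        members = np.array([ref] + sorted(overlaps), dtype=int)
        sets.append(OverlapSet(reference=ref, members=members, overlap_with_reference=overlaps))
    return sets


# ---------------------------------------------------------------------------
# subset-reconstruction machinery shared by the curve analyses


class _SubsetReconstructor:
    """Incremental single-image reconstruction from growing/shrinking subsets.

    Precomputes, for the fold containing the target image, each cell's
    contribution to the training-side feature prediction (for the closed
    form a') and to the test-side decoded image, so that adding or
    dropping a cell is an O(f) update instead of a refit.
    """

    def __init__(self, model: ReconstructionModel, tensor, feats, bank, image: int):
        self.model = model
        self.bank = bank
        self.image = image
        fold = int(model.splits.fold_of_image[image])
        self.fold = fold
        z = tensor.zscored
        tr_img = model.splits.train_images(fold)
        R_tr, img_tr = _flat_samples(z, tr_img)
        H, c = model.fold_H[fold], model.fold_c[fold]
        self.H, self.c = H, c
        self.resid = feats.values[:, img_tr] - c[:, None]  # f x n_train
        self.R_tr = R_tr
        zi = z[:, image, :]
        ok = np.all(np.isfinite(zi), axis=0)
        self.R_te = zi[:, ok]  # cells x trials
        self.n_trials = self.R_te.shape[1]
        # per-cell decoded-image contribution per trial: (p, cells-on-demand)
        self.rev = bank.reverse  # p x f

    def reconstruct(self, subset: np.ndarray) -> tuple[float, np.ndarray]:
        """Trial-resolved images (p x trials) from the cell subset."""
        subset = np.asarray(subset, int)
        if subset.size == 0:
            a = 0.0
            Fhat = np.broadcast_to(self.c[:, None], (self.c.size, self.n_trials))
        else:
            P = self.H[:, subset] @ self.R_tr[subset]  # f x n_train
            den = float(np.sum(P * P))
            a = float(np.sum(P * self.resid)) / den if den > 0 else 0.0
            Fhat = a * (self.H[:, subset] @ self.R_te[subset]) + self.c[:, None]
        imgs = self.rev @ Fhat
        return a, imgs


def cell_curves(
    image: int,
    tensor,
    responsiveness: ResponsivenessResult,
    model: ReconstructionModel,
    feats: FeatureMatrix,
    bank: GaborBank,
    targets: ImageStack,
    direction: str = "addition",
    min_responsive: int | None = None,
    counts: np.ndarray | None = None,
) -> pd.DataFrame:
    """R/CD vs number of cells for one image (addition or drop order).

    Cells are ordered by descending trial-averaged evoked amplitude,
    responsive cells first, then the remaining cells.  ``addition`` adds
    cells from the top; ``drop`` removes them from the full set starting
    at the top.  Images with fewer responsive cells than the filter
    (10 for addition, 5 for drop) are rejected.
    """
    if min_responsive is None:
        min_responsive = 10 if direction == "addition" else 5
    resp = responsiveness.responsive_cells(image)
    if resp.size < min_responsive:
        raise ValueError(
            f"image {image} has {resp.size} responsive cells (< {min_responsive})"
        )
    amp = np.nanmean(tensor.evoked[:, image, :], axis=1)
    order_resp = resp[np.argsort(-amp[resp])]
    rest = np.setdiff1d(np.arange(tensor.n_cells), resp)
    order_rest = rest[np.argsort(-amp[rest])]
    order = np.concatenate([order_resp, order_rest])
    n = order.size
    if counts is None:
        counts = np.arange(1, n + 1)
    rec = _SubsetReconstructor(model, tensor, feats, bank, image)
    tgt = targets.pixels[:, image]
    rows = []
    for cnt in counts:
        subset = order[:cnt] if direction == "addition" else order[cnt:]
        a, imgs = rec.reconstruct(subset)
        r, cd = _score_images(imgs.mean(axis=1), tgt)
        rows.append((int(cnt), subset.size, a, r, cd))
    df = pd.DataFrame(rows, columns=["rank", "n_cells", "a_prime", "R", "CD"])
    df.attrs["n_responsive"] = int(resp.size)
    df.attrs["order"] = order
    return df


def sequential_drop(
    overlap_set: OverlapSet,
    areas: list[RepresentationArea],
    image: int,
    tensor,
    model: ReconstructionModel,
    feats: FeatureMatrix,
    bank: GaborBank,
    targets: ImageStack,
    n_orders: int = 120,
    seed: int | np.random.Generator = 0,
    min_members: int = 5,
) -> pd.DataFrame:
    """Local-R degradation as overlapping cells are dropped in random order.

    The reference cell is dropped first, the remaining members in random
    order; after each drop the image is reconstructed from the surviving
    members and the pixel correlation computed on the local overlap region
    (the reference cell's area covered by at least one other member's
    area).  Median/percentiles are taken over ``n_orders`` random orders.
    """
    if overlap_set.size < min_members:
        raise ValueError(f"overlap set has {overlap_set.size} members (< {min_members})")
    rng = np.random.default_rng(seed)
    ref = overlap_set.reference
    others = overlap_set.members[overlap_set.members != ref]
    local = areas[ref].mask & np.any([areas[o].mask for o in others], axis=0)
    if not local.any():
        raise ValueError("empty local overlap area")
    rec = _SubsetReconstructor(model, tensor, feats, bank, image)
    tgt = targets.pixels[:, image][local]
    n_members = overlap_set.size
    local_r = np.full((n_orders, n_members + 1), np.nan)
    for o in range(n_orders):
        seq = np.concatenate([[ref], rng.permutation(others)])
        for dropped in range(n_members + 1):
            subset = np.setdiff1d(overlap_set.members, seq[:dropped])
            _, imgs = rec.reconstruct(subset)
            r, _ = _score_images(imgs.mean(axis=1)[local], tgt)
            local_r[o, dropped] = r
    rows = []
    for dropped in range(n_members + 1):
        vals = local_r[:, dropped]
        rows.append(
            (dropped, np.nanmedian(vals), np.nanpercentile(vals, 25), np.nanpercentile(vals, 75))
        )
    return pd.DataFrame(rows, columns=["n_dropped", "median_R", "q25_R", "q75_R"])


# ---------------------------------------------------------------------------
# reliability and noise correlations


def trial_reliability(stack: np.ndarray) -> ReliabilityReport:
    """Across-trial similarity and variability of a trials x units array.

    Similarity: mean over trials of the Pearson correlation between the
    single-trial pattern and the trial average.  Variability: the
    DoF-corrected ratio of within-trial squared error to across-unit
    spread of the trial average — identically the inverse of the one-way
    ANOVA F-value with units as groups and trials as samples.
    """
    A = np.asarray(stack, float)
    if A.ndim != 2 or A.shape[0] < 2 or A.shape[1] < 2:
        raise ValueError("need >= 2 trials and >= 2 units")
    n_trial, n_u = A.shape
    avg = A.mean(axis=0)
    grand = avg.mean()
    denom = n_trial * np.sum((avg - grand) ** 2) / (n_u - 1)
    if denom == 0:
        raise ValueError("variability undefined: trial average has no spread")
    num = np.sum((A - avg) ** 2) / (n_u * (n_trial - 1))
    sims = [
        float(np.corrcoef(A[t], avg)[0, 1]) if np.std(A[t]) > 0 else np.nan
        for t in range(n_trial)
    ]
    return ReliabilityReport(
        across_trial_similarity=float(np.nanmean(sims)),
        across_trial_variability=float(num / denom),
    )


def noise_correlation(tensor: EvokedResponseTensor) -> np.ndarray:
    """Pairwise noise correlations of per-stimulus z-scored responses.

    Evoked responses are z-scored across trials within each (cell,
    stimulus), collected across stimuli, and correlated per cell pair.
    Constant cells give NaN rows/columns.
    """
    ev = tensor.evoked
    mean = np.nanmean(ev, axis=2, keepdims=True)
    sd = np.nanstd(ev, axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (ev - mean) / sd
    flat = z.reshape(tensor.n_cells, -1)
    df = pd.DataFrame(flat.T)
    return df.corr(min_periods=2).to_numpy()


def shuffle_trials(
    tensor: EvokedResponseTensor, seed: int | np.random.Generator = 0
) -> EvokedResponseTensor:
    """Remove noise correlations: permute trials within stimulus per cell."""
    rng = np.random.default_rng(seed)
    ev = tensor.evoked.copy()
    base = tensor.baseline.copy()
    for k in range(tensor.n_cells):
        for i in range(tensor.n_stimuli):
            avail = np.where(np.isfinite(ev[k, i]))[0]
            perm = rng.permutation(avail)
            ev[k, i, avail] = tensor.evoked[k, i, perm]
            base[k, i, avail] = tensor.baseline[k, i, perm]
    return EvokedResponseTensor(
        evoked=ev,
        baseline=base,
        stimulus_ids=tensor.stimulus_ids,
        locomotion=tensor.locomotion,
        cell_valid=tensor.cell_valid,
    )


# ---------------------------------------------------------------------------
# accumulation, capacity, locomotion


def image_accumulation(
    responsiveness: ResponsivenessResult, image_order: np.ndarray
) -> pd.DataFrame:
    """Cumulative distinct responsive cells as images accrue in given order."""
    seen: set[int] = set()
    rows = []
    for i in np.asarray(image_order, int):
        cells = set(responsiveness.responsive_cells(i).tolist())
        new = cells - seen
        seen |= cells
        rows.append((i, len(new), len(seen)))
    return pd.DataFrame(rows, columns=["stimulus", "newly_added", "cumulative"])


def capacity_fit(
    H: np.ndarray,
    target_feats: np.ndarray,
    bank: GaborBank,
) -> CapacityFit:
    """Fit target features as a linear combination of decoder weight columns.

    Solves ``F = H B + d + e`` by least squares (``d`` shared across
    images) and reports the image-space percent error
    ``sum(I' - Ihat)^2 / sum(I' - mean I')^2 * 100`` per image, where
    ``I'`` decodes ``F`` and ``Ihat`` decodes ``H B + d``.
    """
    F = np.asarray(target_feats, float)
    if F.ndim == 1:
        F = F[:, None]
    if F.shape[0] != H.shape[0]:
        raise ValueError("feature-count mismatch between F and H")
    # with d shared across images, the optimum is d = column mean of F and
    # per-image B_i the least-squares fit of the centered column on H
    d = F.mean(axis=1)
    B, _, rank, _ = np.linalg.lstsq(H, F - d[:, None], rcond=None)
    Fhat = H @ B + d[:, None]
    rev = bank.reverse
    I_t = rev @ F
    I_h = rev @ Fhat
    errs = []
    for i in range(F.shape[1]):
        tgt = I_t[:, i]
        denom = np.sum((tgt - tgt.mean()) ** 2)
        errs.append(100.0 * np.sum((tgt - I_h[:, i]) ** 2) / denom if denom > 0 else np.nan)
    return CapacityFit(
        coeffs=B,
        offsets=d,
        error_percent=np.array(errs),
        rank_deficient=rank < min(H.shape),
    )


def running_modulation_index(
    tensor: EvokedResponseTensor,
    responsiveness: ResponsivenessResult,
    min_responsive: int = 5,
    min_trials_per_state: int = 4,
) -> pd.DataFrame:
    """RMI = (R_run - R_rest) / (R_run + R_rest) per cell.

    Computed per responded image from the mean evoked response in running
    vs resting trials, then averaged across that cell's responded images.
    Images need at least ``min_responsive`` responsive cells and
    ``min_trials_per_state`` trials in each locomotion state; pairs with
    R_run + R_rest == 0 are flagged undefined (NaN).
    """
    if tensor.locomotion is None:
        raise ValueError("tensor carries no locomotion labels")
    loco = tensor.locomotion
    rows = []
    per_cell: dict[int, list[float]] = {}
    for i in range(tensor.n_stimuli):
        run_t = loco[i] == "run"
        rest_t = loco[i] == "rest"
        resp = responsiveness.responsive_cells(i)
        if (
            resp.size < min_responsive
            or run_t.sum() < min_trials_per_state
            or rest_t.sum() < min_trials_per_state
        ):
            continue
        for k in resp:
            r_run = np.nanmean(tensor.evoked[k, i, run_t])
            r_rest = np.nanmean(tensor.evoked[k, i, rest_t])
            total = r_run + r_rest
            rmi = np.nan if total == 0 else (r_run - r_rest) / total
            per_cell.setdefault(int(k), []).append(rmi)
    for k, vals in sorted(per_cell.items()):
        rows.append((k, float(np.nanmean(vals)), len(vals)))
    return pd.DataFrame(rows, columns=["cell", "rmi", "n_images"])
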