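"""Cross-validation folds shared by the encoding and reconstruction models.

Folds are assigned per stimulus image (all trials of an image travel
together) so that the encoding models, receptive-field estimates and the
reconstruction decoder are trained and tested on identical data splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

__all__ = ["CVSplit", "make_cv_split"]


@dataclass(frozen=True)
class CVSplit:
    fold_of_image: np.ndarray  # (n_images,) fold id per stimulus
    n_folds: int
    seed: int

    @property
    def n_images(self) -> int:
        return self.fold_of_image.size

    def test_images(self, fold: int) -> np.ndarray:
        return np.where(self.fold_of_image == fold)[0]

    def train_images(self, fold: int, exclude: tuple[int, ...] = ()) -> np.ndarray:
        drop = {fold, *exclude}
        return np.where(~np.isin(self.fold_of_image, list(drop)))[0]

    def nested_split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train, validation) images for nested 10/9/81 CV.

        The outer ``fold`` is the 10% test set; a tenth of the remaining
        images (9% of the total) becomes the validation set used for model
        selection, the rest (81%) the training set.  The split is a
        deterministic function of the CV seed and the fold.
        """
        remaining = self.train_images(fold)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, fold]))
        perm = rng.permutation(remaining)
        n_val = max(1, round(0.1 * remaining.size))
        return np.sort(perm[n_val:]), np.sort(perm[:n_val])

    def sample_mask(self, images: np.ndarray, n_trials: int) -> np.ndarray:
        """Boolean mask over stimulus-major flattened (image, trial) samples."""
        mask = np.zeros((self.n_images, n_trials), dtype=bool)
        mask[images] = True
        return mask.ravel()


def make_cv_split(n_images: int, n_folds: int = 10, seed: int = 0) -> CVSplit:
    """Seeded image-level fold assignment (every image in exactly one fold)."""
    if n_folds < 2 or n_folds > n_images:
        raise ValueError("need 2 <= n_folds <= n_images")
    fold = np.empty(n_images, dtype=int)
    splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for k, (_, test) in enumerate(splitter.split(np.arange(n_images))):
        fold[test] = k
    return CVSplit(fold_of_image=fold, n_folds=n_folds, seed=seed)
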