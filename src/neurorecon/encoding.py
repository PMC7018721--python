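"""Per-neuron encoding models on Gabor features.

A cell's single-trial (z-scored) responses are predicted as
``R = NL(W . F_select + b)``: Gabor features whose |Pearson correlation|
with the response exceeds a threshold are selected on the training folds,
a ridge regression with evidence-maximized regularizer fits ``W, b``, and
a four-parameter sigmoid ``NL(x) = A / (1 + exp(Bx + C)) + D`` rescales
the linear prediction without touching the weights.  The selection
threshold is chosen from a 13-point grid (0.05-0.35) by ten-fold CV;
performance is the Pearson correlation between trial-averaged observed
and predicted responses over held-out images.

The module also provides the forward filter (weight-summed Gabor map),
the pairwise feature-overlap metric, and receptive-field estimation by a
regularized pseudoinverse of the pixel design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .cv import CVSplit
from .gabor import FeatureMatrix, GaborBank, ImageStack
from .ridge import RidgeFit, ridge_em

__all__ = [
    "THRESHOLD_GRID",
    "RF_REG_GRID",
    "EncodingModel",
    "ReceptiveField",
    "select_features",
    "feature_correlations",
    "fit_nonlinear_scaling",
    "sigmoid",
    "fit_encoding_cv",
    "forward_filter",
    "feature_overlap",
    "estimate_rf",
]

# 13-point correlation-threshold grid for feature selection
THRESHOLD_GRID = np.linspace(0.05, 0.35, 13)
# 13 log-spaced regularizers for the receptive-field pseudoinverse
RF_REG_GRID = np.logspace(-3, 3, 13)


@dataclass
class EncodingModel:
    cell_id: int
    selected_features: np.ndarray  # indices into the bank
    weights: np.ndarray
    bias: float
    nl_params: tuple[float, float, float, float]
    nl_ok: bool
    threshold: float
    lam: float
    cv_performance: float
    perf_by_threshold: np.ndarray = field(default=None, repr=False)
    threshold_grid: np.ndarray = field(default=None, repr=False)

    @property
    def n_features(self) -> int:
        return self.selected_features.size

    def predict(self, feats: FeatureMatrix | np.ndarray) -> np.ndarray:
        values = feats.values if isinstance(feats, FeatureMatrix) else np.asarray(feats)
        lin = (
            self.weights @ values[self.selected_features] + self.bias
            if self.n_features
            else np.full(values.shape[1], self.bias)
        )
        return sigmoid(lin, *self.nl_params) if self.nl_ok else lin


@dataclass
class ReceptiveField:
    cell_id: int
    rf: np.ndarray  # (p,)
    bias: float
    reg_param: float
    cv_performance: float

    def predict(self, images: ImageStack) -> np.ndarray:
        return self.rf @ images.pixels + self.bias


def sigmoid(x, A, B, C, D):
    # clip the exponent: keeps the sigmoid finite for extreme linear inputs
    z = np.clip(B * np.asarray(x, float) + C, -500, 500)
    return A / (1.0 + np.exp(z)) + D


def feature_correlations(responses: np.ndarray, feat_samples: np.ndarray) -> np.ndarray:
    """|Pearson r| of every feature with a single-trial response vector.

    ``feat_samples`` is features x samples (feature values repeated over
    trials); ``responses`` the matching samples.  Features or responses
    with zero variance yield 0.
    """
    y = np.asarray(responses, float)
    X = np.asarray(feat_samples, float)
    yc = y - y.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    sy = np.sqrt(np.sum(yc**2))
    sx = np.sqrt(np.sum(Xc**2, axis=1))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / denom
    r[~np.isfinite(r)] = 0.0
    return np.abs(r)


def select_features(
    responses: np.ndarray, feat_samples: np.ndarray, threshold: float
) -> np.ndarray:
    """Indices of features with |r| above the threshold (may be empty)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return np.where(feature_correlations(responses, feat_samples) > threshold)[0]


def _identity_params(x: np.ndarray) -> tuple[float, float, float, float]:
    """Sigmoid parameters approximating NL(x) = x over the observed range."""
    lo, hi = float(np.min(x)), float(np.max(x))
    span = max(hi - lo, 1.0)
    A = 8.0 * span
    B = -4.0 / A
    m = 0.5 * (lo + hi)
    return (A, B, -B * m, m - A / 2.0)


def fit_nonlinear_scaling(
    pred_linear: np.ndarray, observed: np.ndarray, n_starts: int = 3
) -> tuple[tuple[float, float, float, float], bool]:
    """Least-squares sigmoid rescaling of the linear prediction.

    Multi-start (varying slope) nonlinear least squares; on failure the
    identity scaling over the data range is returned with ``ok=False``.
    """
    x = np.asarray(pred_linear, float)
    y = np.asarray(observed, float)
    if x.size < 4:
        return _identity_params(x), False
    sx = np.std(x)
    if sx == 0:
        return _identity_params(x), False
    yr = float(np.max(y) - np.min(y))
    A0 = yr if yr > 0 else 1.0
    D0 = float(np.min(y))

    def resid(p):
        return sigmoid(x, *p) - y

    def jac(p):
        A, B, C, _ = p
        z = np.clip(B * x + C, -500, 500)
        s = 1.0 / (1.0 + np.exp(z))
        ds = -s * (1.0 - s)  # dS/dz
        return np.column_stack([s, A * ds * x, A * ds, np.ones_like(x)])

    best, best_cost = None, np.inf
    for slope in (1.0, 4.0, 8.0):
        B0 = -slope / sx
        C0 = -B0 * float(np.mean(x))
        try:
            res = least_squares(
                resid, x0=[A0, B0, C0, D0], jac=jac, method="lm", max_nfev=200
            )
        except Exception:
            continue
        if res.cost < best_cost and np.all(np.isfinite(res.x)):
            best, best_cost = res.x, res.cost
    if best is None:
        return _identity_params(x), False
    return tuple(float(v) for v in best), True


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _flatten_samples(z: np.ndarray, images: np.ndarray):
    """(images,) selection -> flattened (sample values, image-of-sample)."""
    n_trials = z.shape[1]
    vals = z[images].ravel()
    img_of = np.repeat(images, n_trials)
    ok = np.isfinite(vals)
    return vals[ok], img_of[ok]


def fit_encoding_cv(
    responses: np.ndarray,
    feats: FeatureMatrix,
    splits: CVSplit,
    cell_id: int = 0,
    thresholds: np.ndarray = THRESHOLD_GRID,
) -> EncodingModel:
    """Cross-validated encoding model for one cell.

    ``responses`` is stimuli x trials (z-scored evoked responses, NaN for
    missing trials).  For every threshold on the selection grid a model is
    fit per fold (selection, ridge-EM, sigmoid on the training samples)
    and scored on held-out images; the best threshold wins (ties go to the
    higher threshold, i.e. the sparser model) and the returned model is
    refit on all data at that threshold.  If every selection is empty the
    model degenerates to bias-only with performance 0.
    """
    z = np.asarray(responses, float)
    F = feats.values
    n_images, n_trials = z.shape
    trial_avg = np.nanmean(z, axis=1)

    preds = np.full((thresholds.size, n_images), np.nan)
    for fold in range(splits.n_folds):
        tr_img = splits.train_images(fold)
        te_img = splits.test_images(fold)
        y_tr, img_tr = _flatten_samples(z, tr_img)
        X_tr_full = F[:, img_tr]
        corr = feature_correlations(y_tr, X_tr_full)
        cache: dict[bytes, np.ndarray] = {}  # identical selections share a fit
        for ti, th in enumerate(thresholds):
            sel = np.where(corr > th)[0]
            key = sel.tobytes()
            if key not in cache:
                fit = ridge_em(X_tr_full[sel], y_tr)
                lin_tr = fit.predict(X_tr_full[sel])
                nl, ok = fit_nonlinear_scaling(lin_tr, y_tr)
                lin_te = (
                    fit.weights @ F[np.ix_(sel, te_img)] + fit.bias
                    if sel.size
                    else np.full(te_img.size, fit.bias)
                )
                cache[key] = sigmoid(lin_te, *nl) if ok else lin_te
            preds[ti, te_img] = cache[key]

    perf = np.array([_pearson(trial_avg, preds[ti]) for ti in range(thresholds.size)])
    best = int(np.flatnonzero(perf == perf.max())[-1])  # tie -> highest threshold

    # final model: refit on all data at the winning threshold
    y_all, img_all = _flatten_samples(z, np.arange(n_images))
    X_all = F[:, img_all]
    corr_all = feature_correlations(y_all, X_all)
    sel = np.where(corr_all > thresholds[best])[0]
    fit = ridge_em(X_all[sel], y_all)
    lin_all = fit.predict(X_all[sel]) if sel.size else np.full(y_all.size, fit.bias)
    nl, ok = fit_nonlinear_scaling(lin_all, y_all)
    return EncodingModel(
        cell_id=cell_id,
        selected_features=sel,
        weights=fit.weights,
        bias=fit.bias,
        nl_params=nl,
        nl_ok=ok,
        threshold=float(thresholds[best]),
        lam=fit.lam,
        cv_performance=float(perf[best]),  # 0.0 when every prediction is constant
        perf_by_threshold=perf,
        threshold_grid=np.asarray(thresholds),
    )


def forward_filter(model: EncodingModel, bank: GaborBank) -> np.ndarray:
    """Image-space map ``sum_j W_j * GaborFilter_j`` (zero for bias-only)."""
    out = np.zeros(bank.p)
    if model.n_features:
        out = model.weights @ bank.forward[model.selected_features]
    return out


def feature_overlap(model_a: EncodingModel, model_b: EncodingModel) -> float:
    """Percent feature overlap, averaged over the two cells' set sizes."""
    a = set(model_a.selected_features.tolist())
    b = set(model_b.selected_features.tolist())
    if not a or not b:
        return 0.0
    inter = len(a & b)
    return 50.0 * (inter / len(a) + inter / len(b))


def estimate_rf(
    responses: np.ndarray,
    images: ImageStack,
    splits: CVSplit,
    cell_id: int = 0,
    reg_grid: np.ndarray = RF_REG_GRID,
) -> ReceptiveField:
    """Receptive field by a regularized inverse of the pixel design.

    ``rf = (S S^T + lam I)^-1 S y`` on training folds for each of the 13
    log-spaced regularizers; the regularizer with the best held-out
    response prediction (Pearson r) is kept and the RF refit on all data.
    """
    z = np.asarray(responses, float)
    S = images.pixels  # p x images
    n_images, n_trials = z.shape
    trial_avg = np.nanmean(z, axis=1)
    preds = np.full((reg_grid.size, n_images), np.nan)
    for fold in range(splits.n_folds):
        tr_img = splits.train_images(fold)
        te_img = splits.test_images(fold)
        y_tr, img_tr = _flatten_samples(z, tr_img)
        X = S[:, img_tr]
        xm = X.mean(axis=1)
        ym = y_tr.mean()
        Xc = X - xm[:, None]
        # eigendecomposition shared across the regularizer grid
        U, sv, _ = np.linalg.svd(Xc, full_matrices=False)
        proj = U.T @ (Xc @ (y_tr - ym))
        for li, lam in enumerate(reg_grid):
            rf = U @ (proj / (sv**2 + lam))
            b = ym - rf @ xm
            preds[li, te_img] = rf @ S[:, te_img] + b
    perf = np.array([_pearson(trial_avg, preds[li]) for li in range(reg_grid.size)])
    best = int(np.argmax(perf))
    y_all, img_all = _flatten_samples(z, np.arange(n_images))
    X = S[:, img_all]
    xm = X.mean(axis=1)
    ym = y_all.mean()
    Xc = X - xm[:, None]
    U, sv, _ = np.linalg.svd(Xc, full_matrices=False)
    rf = U @ ((U.T @ (Xc @ (y_all - ym))) / (sv**2 + reg_grid[best]))
    return ReceptiveField(
        cell_id=cell_id,
        rf=rf,
        bias=float(ym - rf @ xm),
        reg_param=float(reg_grid[best]),
        cv_performance=float(perf[best]),
    )
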