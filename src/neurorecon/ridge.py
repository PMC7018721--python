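"""Evidence-maximizing ridge regression (Bayesian linear model, EM updates).

Solves ``min ||y - (w.x + b)||^2 + lam * ||w||^2`` with the regularizer
``lam = prior_precision / noise_precision`` set by maximizing the marginal
likelihood via the classic fixed-point (EM) updates of the Gaussian linear
model.  The bias is unpenalized (handled by centering).  With ``lam``
forced to 0 the fit reduces to ordinary least squares.

Design matrices are laid out predictors x samples, matching the feature
matrix (f x trials) convention used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RidgeFit", "ridge_em", "ridge_em_multi", "ridge_fixed"]

_EPS = 1e-12


@dataclass
class RidgeFit:
    weights: np.ndarray  # (d,) in the original predictor space
    bias: float
    lam: float  # alpha / beta; 0 for the OLS limit
    n_iter: int = 0
    converged: bool = True

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.weights @ X + self.bias


def _center(X, y):
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    if X.shape[1] != y.size:
        raise ValueError(f"X has {X.shape[1]} samples, y has {y.size}")
    xm = X.mean(axis=1)
    ym = y.mean()
    return X - xm[:, None], y - ym, xm, ym


def ridge_fixed(X: np.ndarray, y: np.ndarray, lam: float) -> RidgeFit:
    """Ridge solution at a fixed regularizer (bias unpenalized)."""
    Xc, yc, xm, ym = _center(X, y)
    d, n = Xc.shape
    if d == 0:
        return RidgeFit(np.zeros(0), ym, lam)
    if lam == 0.0:
        w, *_ = np.linalg.lstsq(Xc.T, yc, rcond=None)
    else:
        A = Xc @ Xc.T + lam * np.eye(d)
        w = np.linalg.solve(A, Xc @ yc)
    return RidgeFit(w, ym - w @ xm, lam)


def ridge_em(
    X: np.ndarray,
    y: np.ndarray,
    lam: float | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> RidgeFit:
    """Fit with ``lam`` chosen by evidence maximization (``lam=None``).

    Pass ``lam`` explicitly (including 0) to bypass the evidence loop.
    Non-convergence within ``max_iter`` returns the last iterate with
    ``converged=False``.
    """
    if lam is not None:
        fit = ridge_fixed(X, y, lam)
        return fit
    W, b, lams, n_iter, conv = _em_core(*_prep(X, y))
    return RidgeFit(W[0], float(b[0]), float(lams[0]), n_iter, bool(conv[0]))


def ridge_em_multi(
    X: np.ndarray,
    Y: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evidence-maximizing fits of many targets sharing one design.

    ``Y`` is targets x samples.  The SVD of the centered design is computed
    once and the EM recursions run vectorized across targets.  Returns
    ``(W, b, lam)`` with ``W`` of shape (targets, predictors).
    """
    prep = _prep(X, Y, multi=True)
    W, b, lams, _, _ = _em_core(*prep, max_iter=max_iter, tol=tol)
    return W, b, lams


def _prep(X, Y, multi=False):
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[None, :]
    d, n = X.shape
    if Y.shape[1] != n:
        raise ValueError("sample-count mismatch between X and Y")
    xm = X.mean(axis=1)
    Xc = X - xm[:, None]
    ym = Y.mean(axis=1)
    Yc = Y - ym[:, None]
    # thin SVD of the centered design, shared across targets
    if d == 0:
        U = np.zeros((n, 0))
        s = np.zeros(0)
        Vt = np.zeros((0, 0))
    else:
        U, s, Vt = np.linalg.svd(Xc.T, full_matrices=False)  # Xc.T = U s Vt
    return Xc, Yc, xm, ym, U, s, Vt


def _em_core(Xc, Yc, xm, ym, U, s, Vt, max_iter=200, tol=1e-6):
    d, n = Xc.shape
    t = Yc.shape[0]
    e = s**2  # eigenvalues of Xc Xc^T (row space)
    Z = U.T @ Yc.T  # (k, t) projections of the targets
    yss = np.sum(Yc**2, axis=1)  # total (centered) sum of squares per target
    resid_base = yss - np.sum(Z**2, axis=0)  # out-of-rowspace residual

    alpha = np.ones(t)
    beta = np.where(yss > _EPS, n / np.maximum(yss, _EPS), 1.0)
    ev_old = np.full(t, -np.inf)
    active = yss > _EPS
    n_done = 0
    for it in range(max_iter):
        n_done = it + 1
        lam = alpha / np.maximum(beta, _EPS)
        # mean weights in the eigenbasis: m_i = s_i z_i / (e_i + lam)
        denom = e[:, None] + lam[None, :]
        coef = s[:, None] * Z / denom  # (k, t)
        m_sq = np.sum(coef**2, axis=0)
        # residual ||yc - Xc^T m||^2
        fit_res = resid_base + np.sum((Z - s[:, None] * coef) ** 2, axis=0)
        gamma = np.sum(e[:, None] / (e[:, None] + lam[None, :]), axis=0)
        new_alpha = gamma / np.maximum(m_sq, _EPS)
        new_beta = np.maximum(n - gamma, _EPS) / np.maximum(fit_res, _EPS)
        # evidence (up to constants); d-k zero eigenvalues contribute log(alpha)
        with np.errstate(divide="ignore"):
            log_det = np.sum(np.log(e[:, None] * new_beta[None, :] + new_alpha[None, :]), axis=0)
            log_det += (d - len(e)) * np.log(np.maximum(new_alpha, _EPS))
            ev = 0.5 * (
                d * np.log(np.maximum(new_alpha, _EPS))
                + n * np.log(np.maximum(new_beta, _EPS))
                - new_beta * fit_res
                - new_alpha * m_sq
                - log_det
            )
        rel = np.abs(ev - ev_old) / np.maximum(np.abs(ev), 1.0)
        alpha = np.where(active, new_alpha, alpha)
        beta = np.where(active, new_beta, beta)
        ev_old = np.where(active, ev, ev_old)
        active = active & (rel > tol)
        if not active.any():
            break
    converged = ~active
    lam = alpha / np.maximum(beta, _EPS)
    denom = e[:, None] + lam[None, :]
    coef = s[:, None] * Z / denom
    W = (Vt.T @ coef).T  # (t, d)
    W[yss <= _EPS] = 0.0
    b = ym - W @ xm
    return W, b, lam, n_done, converged
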