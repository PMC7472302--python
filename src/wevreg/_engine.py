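"""Vectorized forward/gradient engine shared by the two weighted estimators.

All training-time computation (leave-one-out predictions, loss gradients,
batch prediction) runs through the routines here. They are algebraically
identical to the scalar reference path in :mod:`wevreg.core` — the
evidential forward uses the odds form r_i = phi_i / (1 - phi_i), under which

    m_i = r_i / (1 + sum_j r_j),      m* = 1 / (1 + sum_j r_j),

well-defined because phi is clamped below 1 — and agreement between the two
routes is covered by the test suite.

Gradient chain (per query row i with neighbours j):

    dL/dw = (2/n) sum_i (yhat_i - y_i) sum_j (dyhat_i/dd_ij) (dd_ij/dw)

with, for the evidential model,

    dyhat/dphi_j = (y_j - yhat) / ((1 + R) (1 - phi_j)^2)
    dphi/dd      = -(2 d / gamma) phi             (phi = exp(-d^2/gamma))

and for the kernel k-NN baseline (s_j = exp(-d_j/beta), pi_j = s_j / Z):

    dyhat/dd_j = -(1/beta) pi_j (y_j - yhat)

while for the weighted Minkowski distance (w >= 0)

    dd/dw_m = d^(1-p) w_m^(p-1) |x_m - x'_m|^p,

which vanishes at coincident points. The |delta|^p tensor is independent of
w, so for moderate problem sizes it is precomputed once per fit; larger
problems fall back to a chunked path that never materializes it.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import NDArray
from scipy.spatial.distance import cdist

from .core import PHI_CAP

# precompute the (n, n, q) |delta|^p tensor only below this element count
DENSE_LIMIT = 3e8
_CHUNK_ROWS = 64


def delta_pow(Xq: NDArray, Xt: NDArray, p: float) -> NDArray:
    """|x_q - x_t|^p tensor of shape (n_q, n_t, q)."""
    return np.abs(Xq[:, None, :] - Xt[None, :, :]) ** p


def pairwise_distances(Xq: NDArray, Xt: NDArray, w: NDArray, p: float,
                       A: NDArray | None = None) -> NDArray:
    """Weighted Minkowski distance matrix, via the w-transform trick."""
    if A is not None:
        return (A @ (w ** p)) ** (1.0 / p)
    return cdist(Xq * w, Xt * w, metric="minkowski", p=p)


def k_nearest(d: NDArray, k: int, exclude_diag_offset: int | None = None
              ) -> tuple[NDArray, NDArray]:
    """Indices/distances of the k smallest entries per row, stable ties.

    ``exclude_diag_offset`` masks entry (i, i + offset) per row, used for
    leave-one-out chunks where query i is training row i + offset.
    """
    if exclude_diag_offset is not None:
        rows = np.arange(d.shape[0])
        d = d.copy()
        d[rows, rows + exclude_diag_offset] = np.inf
    k = min(k, d.shape[1] - (1 if exclude_diag_offset is not None else 0))
    idx = np.argsort(d, axis=1, kind="stable")[:, :k]
    return idx, np.take_along_axis(d, idx, axis=1)


def loo_bounds(y: NDArray) -> tuple[NDArray, NDArray]:
    """Per-row (min, max) of y with that row excluded (n >= 2)."""
    order = np.argsort(y, kind="stable")
    n = y.size
    y_inf = np.full(n, y[order[0]])
    y_inf[order[0]] = y[order[1]]
    y_sup = np.full(n, y[order[-1]])
    y_sup[order[-1]] = y[order[-2]]
    return y_inf, y_sup


def _phi(d: NDArray, gamma: float, phi_form: str) -> NDArray:
    if phi_form == "squared":
        val = np.exp(-(d * d) / gamma)
    elif phi_form == "linear":
        val = np.exp(-d / (gamma * gamma))
    else:
        raise ValueError(f"unknown phi_form {phi_form!r}")
    return np.minimum(val, PHI_CAP)


def _dphi_dd(d: NDArray, gamma: float, phi_form: str, phi: NDArray) -> NDArray:
    grad = -(2.0 * d / gamma) * phi if phi_form == "squared" else -phi / (gamma * gamma)
    # the clamp region is flat
    return np.where(phi < PHI_CAP, grad, 0.0)


def evreg_forward(d_nb: NDArray, y_nb: NDArray, c_mid: NDArray, gamma: float,
                  phi_form: str, want_grad: bool
                  ) -> tuple[NDArray, NDArray, NDArray | None]:
    """Evidential prediction per row; optionally dyhat/dd per neighbour.

    Returns (yhat, domain_mass, dyhat_dd or None). ``c_mid`` is the
    per-row domain midpoint (y_inf + y_sup)/2 of the usable evidence.
    """
    phi = _phi(d_nb, gamma, phi_form)
    F = 1.0 - phi
    r = phi / F
    denom = 1.0 + r.sum(axis=1)
    yhat = ((r * y_nb).sum(axis=1) + c_mid) / denom
    mstar = 1.0 / denom
    if not want_grad:
        return yhat, mstar, None
    dy_dphi = (y_nb - yhat[:, None]) / (denom[:, None] * F * F)
    dy_dd = dy_dphi * _dphi_dd(d_nb, gamma, phi_form, phi)
    return yhat, mstar, dy_dd


def wknn_forward(d_nb: NDArray, y_nb: NDArray, beta: float, want_grad: bool
                 ) -> tuple[NDArray, NDArray | None]:
    """Kernel-weighted k-NN mean per row; optionally dyhat/dd per neighbour.

    Kernel weights exp(-d/beta) are computed relative to the row minimum
    distance (a shift that cancels in the normalized mean) so the
    normalizer never underflows.
    """
    s = np.exp(-(d_nb - d_nb.min(axis=1, keepdims=True)) / beta)
    Z = s.sum(axis=1)
    pi = s / Z[:, None]
    yhat = (pi * y_nb).sum(axis=1)
    if not want_grad:
        return yhat, None
    dy_dd = -pi * (y_nb - yhat[:, None]) / beta
    return yhat, dy_dd


def _dd_dw_scale(d_nb: NDArray, p: float) -> NDArray:
    """The d^(1-p) factor of dd/dw, zeroed at coincident points."""
    with np.errstate(divide="ignore"):
        return np.where(d_nb > 0, d_nb ** (1.0 - p), 0.0)


def accumulate_weight_gradient(coeff: NDArray, idx: NDArray, Xq: NDArray,
                               Xt: NDArray, w: NDArray, p: float,
                               A: NDArray | None = None) -> NDArray:
    """Sum_ij coeff_ij * dd_ij/dw, with coeff already including d^(1-p).

    ``coeff`` has shape (n_q, k); ``idx`` are neighbour column indices.
    """
    nq, k = coeff.shape
    q = Xt.shape[1]
    if A is not None:
        flat = A.reshape(-1, q)
        rows = (np.arange(nq)[:, None] * Xt.shape[0] + idx).ravel()
        g = coeff.ravel() @ flat[rows]
    else:
        g = np.zeros(q)
        for lo in range(0, nq, _CHUNK_ROWS):
            hi = min(lo + _CHUNK_ROWS, nq)
            dp = np.abs(Xq[lo:hi, None, :] - Xt[idx[lo:hi]]) ** p
            g += np.einsum("ij,ijq->q", coeff[lo:hi], dp)
    return (w ** (p - 1.0)) * g


class EpochWorkspace:
    """Per-fit cache: normalized training matrix and (optionally) |delta|^p."""

    def __init__(self, X: NDArray, p: float):
        self.X = X
        self.p = p
        n, q = X.shape
        self.A = delta_pow(X, X, p) if n * n * q <= DENSE_LIMIT else None

    def distances(self, w: NDArray) -> NDArray:
        return pairwise_distances(self.X, self.X, w, self.p, self.A)


def loo_pass(ws: EpochWorkspace, y: NDArray, w: NDArray, k: int, gamma: float,
             p: float, phi_form: str, kind: str, want_grad: bool
             ) -> tuple[NDArray, NDArray | None]:
    """One leave-one-out sweep: predictions for every row, optional gradient.

    ``kind`` selects the evidential model ("evreg") or the kernel k-NN
    baseline ("wknn"). The gradient is the full-batch gradient of the MSE
    over all leave-one-out predictions with respect to w.
    """
    n = y.size
    if n < 2:
        raise ValueError("leave-one-out requires at least two rows")
    d = ws.distances(w)
    idx, d_nb = k_nearest(d, k, exclude_diag_offset=0)
    y_nb = y[idx]
    if kind == "evreg":
        y_inf, y_sup = loo_bounds(y)
        yhat, _, dy_dd = evreg_forward(d_nb, y_nb, 0.5 * (y_inf + y_sup),
                                       gamma, phi_form, want_grad)
    elif kind == "wknn":
        yhat, dy_dd = wknn_forward(d_nb, y_nb, gamma, want_grad)
    else:
        raise ValueError(f"unknown estimator kind {kind!r}")
    if not want_grad:
        return yhat, None
    resid = (2.0 / n) * (yhat - y)
    coeff = resid[:, None] * dy_dd * _dd_dw_scale(d_nb, p)
    grad = accumulate_weight_gradient(coeff, idx, ws.X, ws.X, w, p, ws.A)
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError("non-finite weight gradient encountered")
    return yhat, grad


def batch_predict(Xq: NDArray, Xt: NDArray, y: NDArray, w: NDArray, k: int,
                  gamma: float, p: float, phi_form: str, kind: str,
                  y_inf: float, y_sup: float
                  ) -> tuple[NDArray, NDArray]:
    """Predictions for normalized queries; returns (yhat, domain_mass).

    For the kernel baseline the returned domain mass is zero (it carries
    no ignorance term).
    """
    k = min(k, Xt.shape[0])
    yhat = np.empty(Xq.shape[0])
    mstar = np.zeros(Xq.shape[0])
    for lo in range(0, Xq.shape[0], 512):
        hi = min(lo + 512, Xq.shape[0])
        d = pairwise_distances(Xq[lo:hi], Xt, w, p)
        idx, d_nb = k_nearest(d, k)
        y_nb = y[idx]
        if kind == "evreg":
            c = np.full(hi - lo, 0.5 * (y_inf + y_sup))
            yh, ms, _ = evreg_forward(d_nb, y_nb, c, gamma, phi_form, False)
            yhat[lo:hi], mstar[lo:hi] = yh, ms
        else:
            yh, _ = wknn_forward(d_nb, y_nb, gamma, False)
            yhat[lo:hi] = yh
    return yhat, mstar
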