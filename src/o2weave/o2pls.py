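"""Two-block O2PLS decomposition.

O2PLS is a symmetric two-block latent-variable model.  Each preprocessed
matrix is decomposed into three parts::

    X = T Wt + T_yo P_yot + E        (n x p)
    Y = U Ct + U_xo P_xot + F        (n x q)

where ``T, U`` are joint scores capturing variation correlated across the two
blocks, ``T_yo, U_xo`` are block-specific (orthogonal) scores uncorrelated
with the joint part, and ``E, F`` are residuals.  Joint loadings come from the
singular value decomposition of the cross-product ``X'Y``; orthogonal
components are extracted from each block's residual and deflated before the
joint part is re-estimated; the inner relation ``B`` regresses the Y joint
scores on the X joint scores.

Fitting is fully deterministic: there is no random initialisation, component
order follows decreasing singular value, and every loading column is
sign-fixed so that its largest-magnitude entry is positive (ties broken by
earliest feature index).
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .io import OmicsBlock

__all__ = [
    "O2PLSError",
    "O2PLSConfig",
    "O2PLSModel",
    "VarianceStats",
    "joint_svd",
    "fit_o2pls",
    "variance_stats",
    "save_model",
]


class O2PLSError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class O2PLSConfig:
    """Component counts: ``n_joint`` joint components plus ``n_orth_x`` /
    ``n_orth_y`` block-specific components."""

    n_joint: int
    n_orth_x: int = 1
    n_orth_y: int = 1

    def __post_init__(self) -> None:
        if self.n_joint < 1:
            raise O2PLSError("n_joint must be >= 1")
        if self.n_orth_x < 0 or self.n_orth_y < 0:
            raise O2PLSError("orthogonal component counts must be >= 0")

    def validate_for(self, n_samples: int, p: int, q: int) -> None:
        if self.n_joint + self.n_orth_x > min(n_samples - 1, p):
            raise O2PLSError(
                f"n_joint + n_orth_x = {self.n_joint + self.n_orth_x} exceeds "
                f"min(n_samples - 1, p) = {min(n_samples - 1, p)}"
            )
        if self.n_joint + self.n_orth_y > min(n_samples - 1, q):
            raise O2PLSError(
                f"n_joint + n_orth_y = {self.n_joint + self.n_orth_y} exceeds "
                f"min(n_samples - 1, q) = {min(n_samples - 1, q)}"
            )


@dataclasses.dataclass
class O2PLSModel:
    """Fitted O2PLS decomposition.

    Attributes follow the usual two-block notation: ``W`` (p x a) and ``C``
    (q x a) are the joint loadings, ``T``/``U`` the joint scores, ``P_yo`` /
    ``T_yo`` the X-block orthogonal loadings/scores, ``P_xo`` / ``U_xo`` the
    Y-block ones, ``B`` the inner-relation coefficients regressing U on T,
    and ``E``/``F`` the residual matrices.
    """

    config: O2PLSConfig
    W: np.ndarray
    C: np.ndarray
    T: np.ndarray
    U: np.ndarray
    P_yo: np.ndarray
    T_yo: np.ndarray
    P_xo: np.ndarray
    U_xo: np.ndarray
    B: np.ndarray
    E: np.ndarray
    F: np.ndarray
    singular_values: np.ndarray
    x_name: str = "x"
    y_name: str = "y"
    x_feature_ids: list[str] | None = None
    y_feature_ids: list[str] | None = None

    @property
    def n_joint(self) -> int:
        return self.W.shape[1]

    def reconstruct_x(self) -> np.ndarray:
        return self.T @ self.W.T + self.T_yo @ self.P_yo.T + self.E

    def reconstruct_y(self) -> np.ndarray:
        return self.U @ self.C.T + self.U_xo @ self.P_xo.T + self.F


@dataclasses.dataclass
class VarianceStats:
    """Variance-explained summary of a fit.

    ``r2x_model`` (Rt2) / ``r2y_model`` (Rm2): fraction of each block's total
    sum of squares captured by joint + orthogonal parts.  ``r2x_joint``
    (RtCORR) / ``r2y_joint`` (RmCORR): fraction captured by the joint part
    alone.  The ratios measure how much of the modeled variation is shared
    across blocks.
    """

    r2x_model: float
    r2y_model: float
    r2x_joint: float
    r2y_joint: float
    joint_ratio_x: float
    joint_ratio_y: float


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (ties: earliest row)."""
    V = V.copy()
    for k in range(V.shape[1]):
        col = V[:, k]
        idx = int(np.argmax(np.abs(col)))
        if col[idx] < 0:
            V[:, k] = -col
    return V


def _rank_tol(s: np.ndarray, p: int, q: int) -> float:
    return np.finfo(float).eps * max(p, q) * (s[0] if s.size else 0.0)


def joint_svd(X: np.ndarray, Y: np.ndarray, n_joint: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top ``n_joint`` singular triplets of the cross-product ``X'Y``.

    Returns sign-fixed ``W`` (p x a, left vectors), ``C`` (q x a, right
    vectors) and the singular values in decreasing order.  When the sample
    count is smaller than both feature counts the SVD is computed through QR
    factorizations of the two blocks, avoiding the dense p x q cross-product;
    the result is identical to the dense route up to round-off.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise O2PLSError("X and Y must share the sample axis")
    n, p = X.shape
    q = Y.shape[1]
    if n_joint < 1:
        raise O2PLSError("n_joint must be >= 1")

    if n < min(p, q):
        # X'Y = (Qx Rx)(Ry' Qy') with X' = Qx Rx, Y' = Qy Ry
        Qx, Rx = np.linalg.qr(X.T)
        Qy, Ry = np.linalg.qr(Y.T)
        u, s, vt = np.linalg.svd(Rx @ Ry.T)
        W_full = Qx @ u
        C_full = Qy @ vt.T
    else:
        u, s, vt = np.linalg.svd(X.T @ Y, full_matrices=False)
        W_full = u
        C_full = vt.T

    rank = int(np.sum(s > _rank_tol(s, p, q)))
    if n_joint > rank:
        raise O2PLSError(
            f"requested {n_joint} joint components but the cross-product X'Y "
            f"has numerical rank {rank}"
        )
    W = _fix_signs(W_full[:, :n_joint])
    C = _fix_signs(C_full[:, :n_joint])
    return W, C, s[:n_joint].copy()


def _extract_orthogonal(
    M: np.ndarray,
    scores: np.ndarray,
    loadings: np.ndarray,
    n_orth: int,
    block_label: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sequentially extract ``n_orth`` block-specific components from ``M``.

    Each step takes the leading direction of the residual ``M - scores @
    loadings'`` as seen through the current joint scores, deflates it and
    refreshes the joint scores.  Returns the deflated matrix, refreshed
    scores, and the stacked orthogonal scores/loadings.
    """
    n, p = M.shape
    t_list: list[np.ndarray] = []
    p_list: list[np.ndarray] = []
    Md = M
    Tt = scores
    for i in range(n_orth):
        resid = Md - Tt @ loadings.T
        u, s, _ = np.linalg.svd(resid.T @ Tt, full_matrices=False)
        w_o = u[:, 0]
        # sign convention as for joint loadings
        idx = int(np.argmax(np.abs(w_o)))
        if w_o[idx] < 0:
            w_o = -w_o
        t_o = Md @ w_o
        ss = float(t_o @ t_o)
        scale = np.linalg.norm(resid) * np.linalg.norm(Tt)
        if s[0] <= np.finfo(float).eps * max(p, Tt.shape[1]) * scale or ss <= 1e-300:
            raise O2PLSError(
                f"{block_label}: orthogonal component {i + 1} is undefined "
                f"(zero residual); reduce n_orth"
            )
        p_o = Md.T @ t_o / ss
        Md = Md - np.outer(t_o, p_o)
        Tt = Md @ loadings
        t_list.append(t_o)
        p_list.append(p_o)
    if t_list:
        T_o = np.column_stack(t_list)
        P_o = np.column_stack(p_list)
    else:
        T_o = np.zeros((n, 0))
        P_o = np.zeros((p, 0))
    return Md, Tt, T_o, P_o


def _fit_arrays(X: np.ndarray, Y: np.ndarray, config: O2PLSConfig) -> O2PLSModel:
    n, p = X.shape
    q = Y.shape[1]
    if n < 2:
        raise O2PLSError("at least 2 samples are required")
    if Y.shape[0] != n:
        raise O2PLSError("X and Y must share the sample axis")
    config.validate_for(n, p, q)
    a = config.n_joint

    W, C, _ = joint_svd(X, Y, a)
    T = X @ W
    U = Y @ C

    Xd, T, T_yo, P_yo = _extract_orthogonal(X, T, W, config.n_orth_x, "X block")
    Yd, U, U_xo, P_xo = _extract_orthogonal(Y, U, C, config.n_orth_y, "Y block")

    # re-estimate the joint part on the deflated blocks
    W, C, svals = joint_svd(Xd, Yd, a)
    T = Xd @ W
    U = Yd @ C

    B, *_ = np.linalg.lstsq(T, U, rcond=None)
    E = Xd - T @ W.T
    F = Yd - U @ C.T

    return O2PLSModel(
        config=config,
        W=W,
        C=C,
        T=T,
        U=U,
        P_yo=P_yo,
        T_yo=T_yo,
        P_xo=P_xo,
        U_xo=U_xo,
        B=B,
        E=E,
        F=F,
        singular_values=svals,
    )


def fit_o2pls(
    X: OmicsBlock | np.ndarray,
    Y: OmicsBlock | np.ndarray,
    config: O2PLSConfig,
) -> O2PLSModel:
    """Fit the O2PLS decomposition on two preprocessed blocks.

    Blocks must be at least mean-centered and share the same sample order.
    Accepts :class:`OmicsBlock` (feature identifiers are carried onto the
    model) or plain arrays.
    """
    x_arr = X.values if isinstance(X, OmicsBlock) else np.asarray(X, dtype=float)
    y_arr = Y.values if isinstance(Y, OmicsBlock) else np.asarray(Y, dtype=float)
    if isinstance(X, OmicsBlock) and isinstance(Y, OmicsBlock):
        if X.sample_ids != Y.sample_ids:
            raise O2PLSError("blocks must share identical sample ids in the same order")
    model = _fit_arrays(x_arr, y_arr, config)
    if isinstance(X, OmicsBlock):
        model.x_name = X.block_name
        model.x_feature_ids = list(X.feature_ids)
    else:
        model.x_feature_ids = [f"x{j}" for j in range(x_arr.shape[1])]
    if isinstance(Y, OmicsBlock):
        model.y_name = Y.block_name
        model.y_feature_ids = list(Y.feature_ids)
    else:
        model.y_feature_ids = [f"y{j}" for j in range(y_arr.shape[1])]
    return model


def variance_stats(
    model: O2PLSModel,
    X: OmicsBlock | np.ndarray,
    Y: OmicsBlock | np.ndarray,
) -> VarianceStats:
    """Variance-explained fractions of a fit on the matrices it was fitted to.

    ``r2*_model = 1 - ||residual||^2 / ||block||^2`` and ``r2*_joint =
    ||joint part||^2 / ||block||^2`` with Frobenius sums of squares.
    """
    x_arr = X.values if isinstance(X, OmicsBlock) else np.asarray(X, dtype=float)
    y_arr = Y.values if isinstance(Y, OmicsBlock) else np.asarray(Y, dtype=float)
    ssx = float(np.sum(x_arr**2))
    ssy = float(np.sum(y_arr**2))
    if ssx <= 0 or ssy <= 0:
        raise O2PLSError("variance stats undefined for a zero-norm block")
    r2x_model = 1.0 - float(np.sum(model.E**2)) / ssx
    r2y_model = 1.0 - float(np.sum(model.F**2)) / ssy
    r2x_joint = float(np.sum((model.T @ model.W.T) ** 2)) / ssx
    r2y_joint = float(np.sum((model.U @ model.C.T) ** 2)) / ssy
    return VarianceStats(
        r2x_model=r2x_model,
        r2y_model=r2y_model,
        r2x_joint=r2x_joint,
        r2y_joint=r2y_joint,
        joint_ratio_x=r2x_joint / r2x_model if r2x_model > 0 else 0.0,
        joint_ratio_y=r2y_joint / r2y_model if r2y_model > 0 else 0.0,
    )


def save_model(model: O2PLSModel, out_dir: str | Path) -> Path:
    """Serialize a fitted model to a directory of TSV matrices + JSON metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrices = {
        "W": (model.W, model.x_feature_ids),
        "C": (model.C, model.y_feature_ids),
        "T": (model.T, None),
        "U": (model.U, None),
        "P_yo": (model.P_yo, model.x_feature_ids),
        "T_yo": (model.T_yo, None),
        "P_xo": (model.P_xo, model.y_feature_ids),
        "U_xo": (model.U_xo, None),
        "B": (model.B, None),
        "E": (model.E, model.x_feature_ids),
        "F": (model.F, model.y_feature_ids),
    }
    for name, (mat, ids) in matrices.items():
        frame = pd.DataFrame(mat)
        if ids is not None and mat.shape[0] == len(ids):
            frame.index = ids
        frame.to_csv(out_dir / f"{name}.tsv", sep="\t")
    meta = {
        "n_joint": model.config.n_joint,
        "n_orth_x": model.config.n_orth_x,
        "n_orth_y": model.config.n_orth_y,
        "x_name": model.x_name,
        "y_name": model.y_name,
        "singular_values": model.singular_values.tolist(),
        "sign_convention": "largest-magnitude loading entry positive",
        "component_order": "decreasing singular value",
    }
    with open(out_dir / "model.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out_dir
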