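"""Two-way orthogonal PLS (O2PLS) as a scikit-learn style estimator.

O2PLS decomposes two row-matched matrices X (N x p) and Y (N x q) into a
joint part shared by the blocks, block-specific "orthogonal" parts, and
residuals::

    X = T W' + T_yosc P_yosc' + E
    Y = U C' + U_xosc P_xosc' + F

Joint loadings W, C come from the SVD of X'Y; block-specific loadings are
extracted sequentially from the residual structure that the joint part does
not explain, and the joint loadings are then re-estimated on the deflated
matrices.  The inner relations U ~ T (coefficients B_t) and T ~ U (B_u)
carry the cross-block prediction.  The "systematic part" of a block is its
joint + orthogonal reconstruction, i.e. the input minus the residual.

The construction keeps every orthogonal loading orthonormal and orthogonal
to the joint loadings of its own block, which makes the Frobenius energy
partition ||X||^2 = ||joint||^2 + ||orthogonal||^2 + ||E||^2 an exact
identity of the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = ["O2PLS", "ComponentSelection", "cross_validate", "preprocess", "inverse_preprocess"]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def preprocess(
    X: np.ndarray,
    center: bool = True,
    scale: str = "none",
    feature_names=None,
):
    """Center (and optionally unit-variance scale) columns of X.

    Returns ``(X_processed, record)`` where ``record`` holds the centering
    and scaling vectors needed to invert the transform.  A constant column
    with ``scale="unit_variance"`` is an error (its variance is zero).
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("preprocess requires complete data; drop missing features upstream")
    mean = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mean
    if scale == "unit_variance":
        sd = Xc.std(axis=0, ddof=1)
        bad = np.where(sd == 0)[0]
        if bad.size:
            name = feature_names[bad[0]] if feature_names is not None else f"column {bad[0]}"
            raise ValueError(f"constant feature {name!r} cannot be unit-variance scaled")
    elif scale == "none":
        sd = np.ones(X.shape[1])
    else:
        raise ValueError(f"unknown scale mode {scale!r}")
    record = {"center": mean, "scale": sd}
    return Xc / sd, record


def inverse_preprocess(X: np.ndarray, record: dict) -> np.ndarray:
    return X * record["scale"] + record["center"]


# ---------------------------------------------------------------------------
# linear-algebra helpers
# ---------------------------------------------------------------------------


def _cross_svd(X: np.ndarray, Y: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Rank-n SVD factors of X'Y without forming the p x q product.

    Uses thin QR of each block: X' Y = Qx (Rx Ry') Qy', so the singular
    triplets come from an SVD of a small (<=N x <=N) core.
    """
    Qx, Rx = np.linalg.qr(X.T)
    Qy, Ry = np.linalg.qr(Y.T)
    core = Rx @ Ry.T
    U, s, Vt = np.linalg.svd(core, full_matrices=False)
    tol = max(core.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    attainable = int((s > tol).sum())
    if attainable < n:
        raise ValueError(
            f"requested {n} joint components but the cross-product supports "
            f"at most {attainable}"
        )
    return Qx @ U[:, :n], Qy @ Vt[:n].T


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Flip each loading column so its largest-|.| entry is positive (in place)."""
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
            scores[:, j] = -scores[:, j]


def _remove_orthogonal(Xc: np.ndarray, W_init: np.ndarray, n_orth: int):
    """Sequentially extract block-specific components not shared with the other block.

    Each step takes the leading left singular vector of E'T, where T = Xd W
    are current joint-direction scores and E = Xd - T W' the unexplained
    part; the loading is orthogonal to W and to previously extracted
    loadings, and Xd is deflated by the rank-1 piece it carries.
    """
    N, p = Xc.shape
    Xd = Xc.copy()
    P = np.zeros((p, 0))
    T_o = np.zeros((N, 0))
    scale = np.linalg.norm(Xc)
    for j in range(n_orth):
        T = Xd @ W_init
        E = Xd - T @ W_init.T
        M = E.T @ T
        U, s, _ = np.linalg.svd(M, full_matrices=False)
        if not s.size or s[0] <= 1e-12 * max(1.0, scale**2):
            raise ValueError(
                f"requested {n_orth} orthogonal components but only {j} attainable"
            )
        p_j = U[:, :1]
        t_j = Xd @ p_j
        Xd -= t_j @ p_j.T
        P = np.hstack([P, p_j])
        T_o = np.hstack([T_o, t_j])
    return Xd, P, T_o


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class O2PLS(BaseEstimator):
    """Two-way orthogonal PLS decomposition of paired matrices.

    Parameters
    ----------
    n_joint : int, default 1
        Number of joint components shared by the two blocks.
    n_orth_x, n_orth_y : int, default 0
        Number of block-specific (orthogonal) components removed from X
        and Y respectively.
    center : bool, default True
        Column-center each block before fitting.
    scale : {"none", "unit_variance"}, default "none"
        Optional unit-variance scaling per feature.  Off by default:
        per-feature variance differences carry differential-expression
        signal.

    Attributes
    ----------
    W_, C_ : ndarray
        Joint loadings for X (p x n) and Y (q x n), orthonormal columns.
    T_, U_ : ndarray
        Joint scores (N x n) for X and Y.
    P_yosc_, T_yosc_ : ndarray
        X-specific orthogonal loadings (p x nx) and scores (N x nx).
    P_xosc_, U_xosc_ : ndarray
        Y-specific orthogonal loadings (q x ny) and scores (N x ny).
    B_t_, B_u_ : ndarray
        Inner-relation coefficients: U ~ T B_t, T ~ U B_u.
    E_, F_ : ndarray
        Residual matrices on the preprocessed scale.
    x_record_, y_record_ : dict
        Centering/scaling vectors for each block.
    """

    def __init__(self, n_joint=1, n_orth_x=0, n_orth_y=0, center=True, scale="none"):
        self.n_joint = n_joint
        self.n_orth_x = n_orth_x
        self.n_orth_y = n_orth_y
        self.center = center
        self.scale = scale

    # -- fitting ------------------------------------------------------------

    def fit(self, X, Y):
        X = check_array(X, dtype=float)
        Y = check_array(Y, dtype=float)
        n, nx, ny = int(self.n_joint), int(self.n_orth_x), int(self.n_orth_y)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must share sample rows in identical order")
        N, p = X.shape
        q = Y.shape[1]
        if n < 1:
            raise ValueError("n_joint must be >= 1")
        if nx < 0 or ny < 0:
            raise ValueError("orthogonal component counts must be >= 0")
        if n > min(p, q, N - 1):
            raise ValueError(f"n_joint={n} exceeds min(p, q, N-1)={min(p, q, N - 1)}")
        if N <= n + max(nx, ny):
            raise ValueError("need N > n_joint + max(n_orth_x, n_orth_y) samples")

        Xc, self.x_record_ = preprocess(X, center=self.center, scale=self.scale)
        Yc, self.y_record_ = preprocess(Y, center=self.center, scale=self.scale)

        W1, C1 = _cross_svd(Xc, Yc, n)
        Xd, P_yosc, T_yosc = _remove_orthogonal(Xc, W1, nx)
        Yd, P_xosc, U_xosc = _remove_orthogonal(Yc, C1, ny)
        W, C = _cross_svd(Xd, Yd, n)

        T = Xd @ W
        U = Yd @ C
        _fix_signs(W, T)
        _fix_signs(C, U)
        _fix_signs(P_yosc, T_yosc)
        _fix_signs(P_xosc, U_xosc)

        self.W_, self.C_ = W, C
        self.T_, self.U_ = T, U
        self.P_yosc_, self.T_yosc_ = P_yosc, T_yosc
        self.P_xosc_, self.U_xosc_ = P_xosc, U_xosc
        self.B_t_ = np.linalg.lstsq(T, U, rcond=None)[0]
        self.B_u_ = np.linalg.lstsq(U, T, rcond=None)[0]
        self.E_ = Xd - T @ W.T
        self.F_ = Yd - U @ C.T
        self.n_samples_ = N
        self.n_features_x_ = p
        self.n_features_y_ = q
        return self

    # -- derived quantities ---------------------------------------------------

    def _check_block(self, block: str) -> str:
        if block not in ("X", "Y"):
            raise ValueError("block must be 'X' or 'Y'")
        return block

    def joint_part(self, block: str = "X") -> np.ndarray:
        check_is_fitted(self, "W_")
        if self._check_block(block) == "X":
            return self.T_ @ self.W_.T
        return self.U_ @ self.C_.T

    def orthogonal_part(self, block: str = "X") -> np.ndarray:
        check_is_fitted(self, "W_")
        if self._check_block(block) == "X":
            return self.T_yosc_ @ self.P_yosc_.T
        return self.U_xosc_ @ self.P_xosc_.T

    def systematic_part(self, block: str = "X", original_scale: bool = False) -> np.ndarray:
        """Joint + orthogonal reconstruction of a block (input minus residual)."""
        sys = self.joint_part(block) + self.orthogonal_part(block)
        if original_scale:
            rec = self.x_record_ if block == "X" else self.y_record_
            return inverse_preprocess(sys, rec)
        return sys

    def residual(self, block: str = "X") -> np.ndarray:
        check_is_fitted(self, "W_")
        return self.E_ if self._check_block(block) == "X" else self.F_

    # -- prediction -----------------------------------------------------------

    def transform(self, X=None, Y=None):
        """Joint scores of new data for whichever blocks are provided."""
        check_is_fitted(self, "W_")
        out = []
        if X is not None:
            Xc = (np.asarray(X, float) - self.x_record_["center"]) / self.x_record_["scale"]
            Xc = Xc - (Xc @ self.P_yosc_) @ self.P_yosc_.T
            out.append(Xc @ self.W_)
        if Y is not None:
            Yc = (np.asarray(Y, float) - self.y_record_["center"]) / self.y_record_["scale"]
            Yc = Yc - (Yc @ self.P_xosc_) @ self.P_xosc_.T
            out.append(Yc @ self.C_)
        if not out:
            raise ValueError("provide X and/or Y")
        return out[0] if len(out) == 1 else tuple(out)

    def predict(self, data, block: str = "Y") -> np.ndarray:
        """Predict one block from the other via joint scores and inner relations.

        ``block`` names the block being *predicted*: ``predict(X, block="Y")``
        maps X-scores through B_t onto Y-loadings and returns Y on the
        original scale.
        """
        check_is_fitted(self, "W_")
        if self._check_block(block) == "Y":
            T = self.transform(X=data)
            Yc = T @ self.B_t_ @ self.C_.T
            return inverse_preprocess(Yc, self.y_record_)
        U = self.transform(Y=data)
        Xc = U @ self.B_u_ @ self.W_.T
        return inverse_preprocess(Xc, self.x_record_)

    def variance_explained(self, block: str = "X") -> dict:
        """Fraction of preprocessed block variance in joint/orthogonal/residual parts."""
        check_is_fitted(self, "W_")
        joint = np.linalg.norm(self.joint_part(block)) ** 2
        orth = np.linalg.norm(self.orthogonal_part(block)) ** 2
        resid = np.linalg.norm(self.residual(block)) ** 2
        total = joint + orth + resid
        return {
            "joint": joint / total,
            "orthogonal": orth / total,
            "residual": resid / total,
        }

    # -- serialization ---------------------------------------------------------

    def save(self, path) -> None:
        """Serialize the fitted model as a single archive of named arrays.

        Written with fixed zip metadata so identical models produce
        byte-identical files (np.load-compatible .npz).
        """
        check_is_fitted(self, "W_")
        import io
        import json
        import zipfile

        header = json.dumps(
            {"n_joint": self.n_joint, "n_orth_x": self.n_orth_x, "n_orth_y": self.n_orth_y,
             "center": self.center, "scale": self.scale}
        )
        arrays = {
            "header": np.frombuffer(header.encode(), dtype=np.uint8),
            "W": self.W_, "C": self.C_, "T": self.T_, "U": self.U_,
            "P_yosc": self.P_yosc_, "T_yosc": self.T_yosc_,
            "P_xosc": self.P_xosc_, "U_xosc": self.U_xosc_,
            "B_t": self.B_t_, "B_u": self.B_u_, "E": self.E_, "F": self.F_,
            "x_center": self.x_record_["center"], "x_scale": self.x_record_["scale"],
            "y_center": self.y_record_["center"], "y_scale": self.y_record_["scale"],
        }
        with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
            for name, arr in arrays.items():
                buf = io.BytesIO()
                np.lib.format.write_array(buf, np.asarray(arr))
                info = zipfile.ZipInfo(name + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
                zf.writestr(info, buf.getvalue())

    @classmethod
    def load(cls, path) -> "O2PLS":
        import json

        with np.load(path) as z:
            header = json.loads(bytes(z["header"]).decode())
            model = cls(**header)
            model.W_, model.C_ = z["W"], z["C"]
            model.T_, model.U_ = z["T"], z["U"]
            model.P_yosc_, model.T_yosc_ = z["P_yosc"], z["T_yosc"]
            model.P_xosc_, model.U_xosc_ = z["P_xosc"], z["U_xosc"]
            model.B_t_, model.B_u_ = z["B_t"], z["B_u"]
            model.E_, model.F_ = z["E"], z["F"]
            model.x_record_ = {"center": z["x_center"], "scale": z["x_scale"]}
            model.y_record_ = {"center": z["y_center"], "scale": z["y_scale"]}
            model.n_samples_ = model.T_.shape[0]
            model.n_features_x_ = model.W_.shape[0]
            model.n_features_y_ = model.C_.shape[0]
        return model


# ---------------------------------------------------------------------------
# cross-validated component selection
# ---------------------------------------------------------------------------


@dataclass
class ComponentSelection:
    """Result of grid cross-validation over (n_joint, n_orth_x, n_orth_y)."""

    n_joint: int
    n_orth_x: int
    n_orth_y: int
    cv_error: pd.DataFrame  # columns n_joint, n_orth_x, n_orth_y, error
    folds: int
    seed: int


def default_grid(max_joint: int = 3, max_orth: int = 2):
    """Small-sample default grid: n in 1..3, nx, ny in 0..2."""
    return [
        (n, nx, ny)
        for n in range(1, max_joint + 1)
        for nx in range(0, max_orth + 1)
        for ny in range(0, max_orth + 1)
    ]


def cross_validate(
    X,
    Y,
    grid=None,
    k_folds: int = 5,
    seed: int = 0,
    center: bool = True,
    scale: str = "none",
) -> ComponentSelection:
    """Row-wise k-fold CV of symmetric cross-block prediction error.

    For each grid triple the error is
    ``sum_folds ||Y_test - Yhat(X_test)||_F^2 + ||X_test - Xhat(Y_test)||_F^2``.
    The triple with minimal total error wins; exact ties break toward the
    lexicographically smallest (n, nx, ny).  Deterministic given ``seed``.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    N = X.shape[0]
    if grid is None:
        grid = default_grid()
    grid = sorted({(int(n), int(nx), int(ny)) for n, nx, ny in grid})
    if not grid:
        raise ValueError("empty component grid")
    # sequential orthogonal extraction supports at most n components per block
    grid = [(n, nx, ny) for n, nx, ny in grid if nx <= n and ny <= n]
    if not grid:
        raise ValueError("no grid point satisfies n_orth <= n_joint")
    if k_folds > N:
        raise ValueError("more folds than samples")
    if N // k_folds < 2:
        raise ValueError("each CV fold needs at least 2 samples")

    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    min_train = min(len(tr) for tr, _ in splits)
    # near-ties (below 1e-12 of the total data energy) resolve to parsimony
    tie_tol = 1e-12 * float(np.sum(X**2) + np.sum(Y**2))
    rows = []
    for n, nx, ny in grid:
        if min_train <= n + max(nx, ny) or n > min(X.shape[1], Y.shape[1], min_train - 1):
            raise ValueError(
                f"grid point (n={n}, nx={nx}, ny={ny}) infeasible for fold size {min_train}"
            )
        err = 0.0
        for train, test in splits:
            model = O2PLS(n_joint=n, n_orth_x=nx, n_orth_y=ny, center=center, scale=scale)
            model.fit(X[train], Y[train])
            err += float(np.sum((Y[test] - model.predict(X[test], block="Y")) ** 2))
            err += float(np.sum((X[test] - model.predict(Y[test], block="X")) ** 2))
        rows.append({"n_joint": n, "n_orth_x": nx, "n_orth_y": ny, "error": err})

    table = pd.DataFrame(rows)
    best = None
    for row in rows:  # grid is lexicographically sorted: first material min wins ties
        if best is None or row["error"] < best["error"] - tie_tol:
            best = row
    return ComponentSelection(
        n_joint=best["n_joint"],
        n_orth_x=best["n_orth_x"],
        n_orth_y=best["n_orth_y"],
        cv_error=table,
        folds=k_folds,
        seed=seed,
    )
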