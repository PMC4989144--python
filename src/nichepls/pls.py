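"""Single-response partial least squares regression via NIPALS, from scratch.

The PLS1 algorithm extracts latent components one at a time from the
centered/scaled design: for component a,

    w_a = X'y / ||X'y||        (weight; direction of maximal covariance with y)
    t_a = X w_a                (score)
    p_a = X't_a / (t_a't_a)    (X loading)
    q_a = y't_a / (t_a't_a)    (response loading)
    X <- X - t_a p_a'          (deflation; y is not deflated)

For a single response the inner iteration converges in one pass, so each
component is computed in closed form. Regression coefficients in the scaled
space are B = W (P'W)^{-1} q; raw-scale coefficients and an intercept are
recovered by inverting the centering/scaling.

Variable importance in the projection (VIP) summarizes each predictor's
contribution to the explained response variance across components:

    VIP_j = sqrt( p * sum_a SSY_a w_{ja}^2 / sum_a SSY_a ),  SSY_a = q_a^2 t_a't_a

so that mean(VIP^2) = 1; predictors with VIP below ~0.8 are conventionally
considered uninformative.

Sign convention: the first nonzero entry of every weight vector is made
non-negative, which fixes the otherwise arbitrary sign of (w, t, p, q)
without changing fitted values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import DesignMatrix

__all__ = ["PLSModel", "fit_nipals", "predict", "vip_scores", "explained_variance"]


@dataclass
class PLSModel:
    """Fitted PLS1 model in the centered/scaled space plus raw-scale mapping."""

    n_components: int
    column_names: list[str]
    W: np.ndarray             # (p, A) weights, unit norm columns
    P: np.ndarray             # (p, A) X loadings
    T: np.ndarray             # (s, A) scores
    q: np.ndarray             # (A,) response loadings
    t_norms: np.ndarray       # (A,) t_a't_a
    coeff_scaled: np.ndarray  # (p,)
    coeff_raw: np.ndarray     # (p,) cells per raw predictor unit
    intercept_raw: float      # cells
    vip: np.ndarray           # (p,)
    explained_x: np.ndarray   # (A,) cumulative fraction of X sum of squares
    explained_y: np.ndarray   # (A,) cumulative fraction of y sum of squares
    column_means: np.ndarray
    column_sds: np.ndarray
    y_mean: float
    y_sd: float

    def to_dict(self) -> dict:
        """Plain-type representation for text serialization."""
        return {
            "n_components": int(self.n_components),
            "column_names": list(self.column_names),
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "q": self.q.tolist(),
            "t_norms": self.t_norms.tolist(),
            "coeff_scaled": self.coeff_scaled.tolist(),
            "coeff_raw": self.coeff_raw.tolist(),
            "intercept_raw": float(self.intercept_raw),
            "vip": self.vip.tolist(),
            "explained_x": self.explained_x.tolist(),
            "explained_y": self.explained_y.tolist(),
            "column_means": self.column_means.tolist(),
            "column_sds": self.column_sds.tolist(),
            "y_mean": float(self.y_mean),
            "y_sd": float(self.y_sd),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        arr = lambda k: np.asarray(d[k], dtype=float)
        return cls(
            n_components=int(d["n_components"]),
            column_names=list(d["column_names"]),
            W=arr("W"), P=arr("P"), T=np.zeros((0, int(d["n_components"]))),
            q=arr("q"), t_norms=arr("t_norms"),
            coeff_scaled=arr("coeff_scaled"), coeff_raw=arr("coeff_raw"),
            intercept_raw=float(d["intercept_raw"]), vip=arr("vip"),
            explained_x=arr("explained_x"), explained_y=arr("explained_y"),
            column_means=arr("column_means"), column_sds=arr("column_sds"),
            y_mean=float(d["y_mean"]), y_sd=float(d["y_sd"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PLSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _matrix_rank(X: np.ndarray) -> int:
    s = np.linalg.svd(X, compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    return int((s > 1e-10 * s[0]).sum())


def fit_nipals(dm: DesignMatrix, n_components: int) -> PLSModel:
    """Fit a PLS1 model with ``n_components`` latent components.

    ``dm`` must be centered/scaled. Extraction stops early (with a warning)
    when no covariance with the response remains.
    """
    if not dm.scaled:
        raise ValueError("fit_nipals requires a centered/scaled design matrix")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    rank = _matrix_rank(dm.X)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank} of X")

    X = dm.X.copy()
    y = dm.y.copy()
    s, p = X.shape
    ssx_total = float((dm.X**2).sum())
    ssy_total = float((y**2).sum())

    W, P, T, q, t_norms = [], [], [], [], []
    explained_x, explained_y = [], []
    cov0 = float(np.linalg.norm(X.T @ y))
    ssy_cum = 0.0

    for _ in range(n_components):
        c = X.T @ y
        nc = float(np.linalg.norm(c))
        if nc < 1e-12 * max(cov0, 1e-300):
            warnings.warn(
                f"no covariance with the response left after {len(q)} component(s); "
                f"stopping early (requested {n_components})",
                stacklevel=2,
            )
            break
        w = c / nc
        nz = np.flatnonzero(np.abs(w) > 1e-14)
        if nz.size and w[nz[0]] < 0:
            w = -w
        t = X @ w
        tt = float(t @ t)
        p_a = X.T @ t / tt
        q_a = float(y @ t) / tt
        X = X - np.outer(t, p_a)

        W.append(w)
        P.append(p_a)
        T.append(t)
        q.append(q_a)
        t_norms.append(tt)
        ssy_cum += q_a**2 * tt
        explained_x.append(1.0 - float((X**2).sum()) / ssx_total)
        explained_y.append(ssy_cum / ssy_total)

    A = len(q)
    W = np.column_stack(W)
    P = np.column_stack(P)
    T = np.column_stack(T)
    q = np.asarray(q)
    t_norms = np.asarray(t_norms)

    coeff_scaled = W @ np.linalg.solve(P.T @ W, q)
    coeff_raw = dm.y_sd * coeff_scaled / dm.column_sds
    intercept_raw = dm.y_mean - float(coeff_raw @ dm.column_means)

    ssy = q**2 * t_norms
    vip = np.sqrt(p * (W**2 @ ssy) / ssy.sum())

    return PLSModel(
        n_components=A,
        column_names=list(dm.column_names),
        W=W, P=P, T=T, q=q, t_norms=t_norms,
        coeff_scaled=coeff_scaled,
        coeff_raw=coeff_raw,
        intercept_raw=intercept_raw,
        vip=vip,
        explained_x=np.asarray(explained_x),
        explained_y=np.asarray(explained_y),
        column_means=dm.column_means.copy(),
        column_sds=dm.column_sds.copy(),
        y_mean=dm.y_mean,
        y_sd=dm.y_sd,
    )


def _as_matrix(model: PLSModel, rows, column_names: Sequence[str] | None) -> np.ndarray:
    """Align new rows (DataFrame or array + names) to the model's columns."""
    if isinstance(rows, pd.DataFrame):
        missing = [c for c in model.column_names if c not in rows.columns]
        if missing:
            raise KeyError(f"prediction rows lack required column(s) {missing}")
        return rows[model.column_names].to_numpy(dtype=float)
    X = np.asarray(rows, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if column_names is None:
        if X.shape[1] != len(model.column_names):
            raise KeyError(
                f"got {X.shape[1]} columns for a {len(model.column_names)}-column model; "
                "pass column_names to align by name"
            )
        return X
    names = list(column_names)
    missing = [c for c in model.column_names if c not in names]
    if missing:
        raise KeyError(f"prediction rows lack required column(s) {missing}")
    idx = [names.index(c) for c in model.column_names]
    return X[:, idx]


def predict(model: PLSModel, rows, column_names: Sequence[str] | None = None) -> np.ndarray:
    """Predict day-7 cell counts for rows given in raw predictor units.

    ``rows`` may be a DataFrame (aligned by column name; extra columns — e.g.
    ones pruned from a reduced model — are ignored) or an array with
    ``column_names``.
    """
    X = _as_matrix(model, rows, column_names)
    Xs = (X - model.column_means) / model.column_sds
    return model.y_mean + model.y_sd * (Xs @ model.coeff_scaled)


def vip_scores(model: PLSModel) -> np.ndarray:
    """Variable importance in the projection, one value per predictor."""
    return model.vip.copy()


def explained_variance(model: PLSModel) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative explained fractions of X and y sum of squares per component."""
    return model.explained_x.copy(), model.explained_y.copy()
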