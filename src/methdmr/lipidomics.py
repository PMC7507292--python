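"""OPLS-DA with VIP scoring and the differential-lipid filter.

Orthogonal projections to latent structures discriminant analysis splits
X-variation into a single class-predictive component and k components
orthogonal to the class response (O-PLS deflation with a single response).
Variable importance in projection (VIP) scores summarise each feature's
contribution to the predictive component; mean(VIP^2) = 1 by construction,
so VIP > 1 marks above-average influence.

Differential lipids are features with VIP > 1 whose univariate two-group
test (Welch t on log2 intensities) survives at alpha = 0.05, with or
without Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import adjust_fdr

__all__ = ["OplsdaModel", "preprocess", "fit_oplsda", "vip_scores", "filter_lipids"]

logger = logging.getLogger(__name__)

META_COLUMNS = ["feature_id", "mz", "rt", "mode"]


@dataclass
class OplsdaModel:
    """Fitted OPLS-DA decomposition (one predictive component).

    Scores/loadings follow the usual latent-variable notation: t/p/w for
    the predictive component, T/P/W (columns) for orthogonal components,
    q the y-loading.  ``r2x``/``r2y`` are fractions of X/y variation
    explained; ``q2`` is the cross-validated prediction statistic.
    """

    t_pred: np.ndarray
    p_pred: np.ndarray
    w_pred: np.ndarray
    q: float
    t_orth: np.ndarray  # (n, k)
    p_orth: np.ndarray  # (p, k)
    w_orth: np.ndarray  # (p, k)
    y: np.ndarray
    r2x: float = np.nan
    r2y: float = np.nan
    q2: float = np.nan
    vip: np.ndarray = field(default=None)

    @property
    def n_orthogonal(self) -> int:
        return self.t_orth.shape[1]


def preprocess(matrix: pd.DataFrame, scaling: str = "pareto", log_transform: bool = False) -> pd.DataFrame:
    """Center (and scale) a features x samples intensity matrix.

    Returns a samples x features matrix ready for :func:`fit_oplsda`.
    ``scaling``: "pareto" divides centered columns by sqrt(SD) (the
    metabolomics convention — damps dominant high-intensity features
    without amplifying noise as much as unit variance), "unit-variance"
    divides by SD (zero-variance features dropped, logged), or "none".
    ``log_transform`` applies log2(x+1) before centering.
    """
    if scaling not in ("pareto", "unit-variance", "none"):
        raise ValueError(f"unknown scaling {scaling!r}")
    X = matrix.T.astype(float)  # samples x features
    if log_transform:
        X = np.log2(X + 1.0)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if scaling == "unit-variance":
        zero = sd == 0
        if zero.any():
            logger.info("preprocess: dropped %d zero-variance features", int(zero.sum()))
            X = X.loc[:, ~zero]
            sd = sd[~zero]
        X = X / sd
    elif scaling == "pareto":
        nz = sd > 0
        X.loc[:, nz] = X.loc[:, nz] / np.sqrt(sd[nz])
    return X


def _opls_fit(X: np.ndarray, y: np.ndarray, n_orthogonal: int):
    """Single-response O-PLS: returns (t, p, w, q, T_o, P_o, W_o, X_resid)."""
    Xc = X.copy()
    T_o, P_o, W_o = [], [], []
    for _ in range(n_orthogonal):
        w = Xc.T @ y / (y @ y)
        w /= np.linalg.norm(w)
        t = Xc @ w
        p = Xc.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:
            break  # no orthogonal variation left
        w_o /= nrm
        t_o = Xc @ w_o
        p_o = Xc.T @ t_o / (t_o @ t_o)
        Xc = Xc - np.outer(t_o, p_o)
        T_o.append(t_o)
        P_o.append(p_o)
        W_o.append(w_o)
    w = Xc.T @ y / (y @ y)
    w /= np.linalg.norm(w)
    t = Xc @ w
    p = Xc.T @ t / (t @ t)
    q = float(y @ t / (t @ t))
    T = np.column_stack(T_o) if T_o else np.zeros((X.shape[0], 0))
    P = np.column_stack(P_o) if P_o else np.zeros((X.shape[1], 0))
    W = np.column_stack(W_o) if W_o else np.zeros((X.shape[1], 0))
    Xres = Xc - np.outer(t, p)
    return t, p, w, q, T, P, W, Xres


def _predict(Xnew: np.ndarray, w_pred, W_o, P_o, q) -> np.ndarray:
    Xc = Xnew.copy()
    for j in range(W_o.shape[1]):
        t_o = Xc @ W_o[:, j]
        Xc = Xc - np.outer(t_o, P_o[:, j])
    return (Xc @ w_pred) * q


def fit_oplsda(X, y, n_orthogonal: int = 1, cv_folds: int = 7, random_state: int = 0) -> OplsdaModel:
    """Fit OPLS-DA on a preprocessed samples x features matrix.

    ``y`` is the class indicator (+1/-1, both classes present).  With
    ``n_orthogonal = 0`` the model reduces to the first PLS1 component.
    Q2 is estimated by ``cv_folds``-fold cross-validation on the supplied
    (already scaled) matrix.
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    classes = np.unique(ya)
    if len(classes) != 2:
        raise ValueError("y must contain exactly two classes")
    n, p = Xa.shape
    if n <= n_orthogonal + 1:
        raise ValueError(f"{n} samples cannot support {n_orthogonal} orthogonal components")
    yc = ya - ya.mean()

    t, pl, w, q, T, P, W, Xres = _opls_fit(Xa, yc, n_orthogonal)
    ssx = (Xa**2).sum()
    r2x = 1.0 - (Xres**2).sum() / ssx if ssx > 0 else np.nan
    r2y = 1.0 - ((yc - t * q) ** 2).sum() / (yc**2).sum()

    # cross-validated Q2
    rng = np.random.default_rng(random_state)
    order = rng.permutation(n)
    folds = np.array_split(order, min(cv_folds, n))
    press, ss = 0.0, (yc**2).sum()
    for hold in folds:
        mask = np.ones(n, dtype=bool)
        mask[hold] = False
        if len(np.unique(ya[mask])) < 2:
            continue
        yc_tr = ya[mask] - ya[mask].mean()
        t_, p_, w_, q_, T_, P_, W_, _ = _opls_fit(Xa[mask], yc_tr, n_orthogonal)
        yhat = _predict(Xa[hold], w_, W_, P_, q_)
        press += ((ya[hold] - ya[mask].mean() - yhat) ** 2).sum()
    q2 = 1.0 - press / ss if ss > 0 else np.nan

    model = OplsdaModel(t_pred=t, p_pred=pl, w_pred=w, q=q, t_orth=T, p_orth=P, w_orth=W, y=ya, r2x=r2x, r2y=r2y, q2=q2)
    model.vip = vip_scores(model)
    return model


def vip_scores(model: OplsdaModel) -> np.ndarray:
    """Variable importance in projection for the predictive component.

    With a single predictive component VIP_j = sqrt(p) * |w_j| / ||w||, so
    the mean squared VIP is exactly 1.
    """
    w = model.w_pred
    p = len(w)
    return np.sqrt(p) * np.abs(w) / np.linalg.norm(w)


def filter_lipids(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    vip: np.ndarray | pd.Series,
    alpha: float = 0.05,
    vip_thresh: float = 1.0,
    adjust: str = "fdr",
    group_order: list[str] | None = None,
) -> pd.DataFrame:
    """Differential lipids: VIP > threshold and (adjusted) p < alpha.

    ``matrix`` is features x samples raw intensities (index = feature
    ids); the univariate test is a two-sided Welch t on log2 intensities.
    ``adjust="fdr"`` applies BH (the headline filter); ``"none"``
    reproduces the raw-p variant.  Returns all features with VIP, p, q,
    log2 fold change and direction, plus a boolean ``significant`` column.
    """
    if adjust not in ("fdr", "none"):
        raise ValueError(f"unknown adjust {adjust!r}")
    labels = sorted(set(groups.values())) if group_order is None else list(group_order)
    a_cols = [s for s, g in groups.items() if g == labels[0]]
    b_cols = [s for s, g in groups.items() if g == labels[1]]
    A = np.log2(matrix[a_cols].to_numpy(dtype=float) + 1.0)
    B = np.log2(matrix[b_cols].to_numpy(dtype=float) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.asarray(stats.ttest_ind(A, B, axis=1, equal_var=False).pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    q = adjust_fdr(p)
    p_eff = q if adjust == "fdr" else p
    vip = np.asarray(vip, dtype=float)
    if len(vip) != len(matrix):
        raise ValueError("VIP vector length does not match feature count")
    lfc = np.log2((matrix[b_cols].mean(axis=1).to_numpy() + 1e-9) / (matrix[a_cols].mean(axis=1).to_numpy() + 1e-9))
    out = pd.DataFrame(
        {
            "feature_id": matrix.index,
            "vip": vip,
            "p_value": p,
            "q_value": q,
            "log2_fc": lfc,
            "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none")),
            "significant": (vip > vip_thresh) & (p_eff < alpha),
        }
    ).reset_index(drop=True)
    return out
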