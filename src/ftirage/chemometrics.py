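"""PCA, Q-residual outlier screening, kernel PLS1 regression and
score-plot discrimination statistics.

Both PCA and PLS are implemented directly on mean-centered matrices
(SVD for PCA; the improved kernel algorithm of Dayal & MacGregor for
single-response PLS).  A NIPALS PLS1 is kept as an internal oracle for
cross-checking — the two must agree on predictions to numerical
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CVError,
    DegenerateDataError,
    GroupError,
    RankError,
    ShapeError,
    ValidationError,
)
from .io_spectra import SpectraSet


@dataclass
class DataMatrix:
    """Samples-by-wavenumbers matrix with per-row metadata."""

    X: np.ndarray
    row_meta: pd.DataFrame
    columns: np.ndarray  # wavenumber of each column

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ShapeError("X must be 2-D")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("X contains non-finite values")
        if self.X.shape[0] < 3 or self.X.shape[1] < 2:
            raise ShapeError("need at least 3 rows and 2 columns")
        if len(self.row_meta) != self.X.shape[0]:
            raise ShapeError("row_meta length mismatch")
        if len(self.columns) != self.X.shape[1]:
            raise ShapeError("columns length mismatch")

    @classmethod
    def from_spectra(cls, spectra_set: SpectraSet) -> "DataMatrix":
        X, meta = spectra_set.to_matrix()
        return cls(X, meta, spectra_set.grid.copy())

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    column_means: np.ndarray
    loadings: np.ndarray  # (p, k), orthonormal columns
    scores: np.ndarray  # (n, k)
    explained_variance: np.ndarray  # sigma_i^2 / (n - 1), non-increasing
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def project(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.column_means) @ self.loadings


def pca_fit(data: DataMatrix, n_components: int = 7) -> PCAModel:
    """Mean-centered SVD principal component analysis.

    ``n_components`` is capped at 7 by convention for these spectra;
    requesting more components than the data rank raises.
    """
    X = data.X
    n, p = X.shape
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    if n_components > min(n - 1, p):
        raise RankError(
            f"{n_components} components > min(rows-1, cols) = {min(n - 1, p)}"
        )
    mu = X.mean(axis=0)
    Xc = X - mu
    U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(sv > sv[0] * 1e-12)) if sv.size and sv[0] > 0 else 0
    if n_components > rank:
        raise RankError(f"{n_components} components > numerical rank {rank}")
    loadings = Vt[:n_components].T
    scores = Xc @ loadings
    var = sv**2 / (n - 1)
    total = var.sum()
    return PCAModel(
        column_means=mu,
        loadings=loadings,
        scores=scores,
        explained_variance=var[:n_components],
        explained_variance_ratio=var[:n_components] / total if total > 0 else var[:n_components],
    )


def q_residuals(model: PCAModel, data: DataMatrix) -> np.ndarray:
    """Squared distance of each row from the model subspace (SPE).

    Q_i = || x_c - L L^T x_c ||^2 with x_c the mean-centered row.
    """
    if data.X.shape[1] != model.loadings.shape[0]:
        raise ShapeError("column count does not match the fitted model")
    Xc = data.X - model.column_means
    resid = Xc - (Xc @ model.loadings) @ model.loadings.T
    return np.einsum("ij,ij->i", resid, resid)


def flag_outliers(q: np.ndarray, rule: str = "mad", k: float = 3.5) -> np.ndarray:
    """Flag large Q-residuals.

    ``mad``: q > median + k * 1.4826 * MAD (robust z-score; if MAD is 0
    nothing exceeds the threshold unless strictly above the median by 0,
    so identical values are never flagged).  ``quantile``: q above the
    k-quantile.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValidationError("Q-residuals must be nonnegative")
    if rule == "mad":
        med = np.median(q)
        mad = np.median(np.abs(q - med))
        return q > med + k * 1.4826 * mad
    if rule == "quantile":
        if not 0 < k < 1:
            raise ValidationError("quantile rule needs 0 < k < 1")
        return q > np.quantile(q, k)
    raise ValidationError(f"unknown outlier rule {rule!r}")


# ---------------------------------------------------------------------------
# PLS1
# ---------------------------------------------------------------------------

@dataclass
class CVSpec:
    """Random K-fold cross-validation settings."""

    n_folds: int = 10
    seed: int = 0


@dataclass
class PLSModel:
    """Fitted single-response PLS with per-factor CV error.

    ``predict``/``scores`` evaluate at any factor count up to
    ``max_factors``; ``n_factors`` is the parsimony-selected count.
    """

    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray  # (p, A) weights
    P: np.ndarray  # (p, A) X-loadings
    q: np.ndarray  # (A,) y-loadings
    R: np.ndarray  # (p, A) W (P'W)^-1, direct score projection
    T: np.ndarray  # (n, A) training scores
    cv_rmse: np.ndarray | None = None
    y_cv: np.ndarray | None = None  # (n, A) out-of-fold predictions
    n_factors: int = 0
    y_fitted: np.ndarray | None = None
    pearson_r: float = float("nan")

    @property
    def max_factors(self) -> int:
        return self.W.shape[1]

    def coefficients(self, n_factors: int | None = None) -> np.ndarray:
        a = self.n_factors if n_factors is None else n_factors
        return self.R[:, :a] @ self.q[:a]

    def predict(self, X: np.ndarray, n_factors: int | None = None) -> np.ndarray:
        b = self.coefficients(n_factors)
        return self.y_mean + (np.asarray(X, float) - self.x_mean) @ b

    def transform(self, X: np.ndarray, n_factors: int | None = None) -> np.ndarray:
        a = self.n_factors if n_factors is None else n_factors
        return (np.asarray(X, float) - self.x_mean) @ self.R[:, :a]


def _kernel_pls1(
    X: np.ndarray, y: np.ndarray, max_factors: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """Improved-kernel PLS1 on mean-centered data.

    Works on the cross-product kernels X'X and X'y only; the X matrix is
    never deflated, which keeps the fit O(p^2) per factor.
    """
    n, p = X.shape
    mu = X.mean(axis=0)
    ybar = float(y.mean())
    Xc = X - mu
    yc = y - ybar
    XtX = Xc.T @ Xc
    s = Xc.T @ yc
    if not np.any(np.abs(s) > 0):
        raise DegenerateDataError("X carries no covariance with y")
    W = np.zeros((p, max_factors))
    P = np.zeros((p, max_factors))
    R = np.zeros((p, max_factors))
    q = np.zeros(max_factors)
    a_used = 0
    for a in range(max_factors):
        norm_s = np.linalg.norm(s)
        if norm_s <= 1e-14:
            break
        w = s / norm_s
        r = w.copy()
        for j in range(a):
            r -= (P[:, j] @ w) * R[:, j]
        tt = float(r @ XtX @ r)
        if tt <= 1e-14:
            break
        P[:, a] = (XtX @ r) / tt
        q[a] = float(s @ r) / tt
        W[:, a] = w
        R[:, a] = r
        s = s - P[:, a] * (q[a] * tt)
        a_used = a + 1
    if a_used == 0:
        raise DegenerateDataError("no usable PLS factor (zero-variance X)")
    W, P, R, q = W[:, :a_used], P[:, :a_used], R[:, :a_used], q[:a_used]
    T = Xc @ R
    return W, P, R, q, T, mu, ybar


def nipals_pls1(
    X: np.ndarray, y: np.ndarray, max_factors: int
) -> tuple[np.ndarray, np.ndarray]:
    """Classic NIPALS PLS1 with explicit X deflation.

    Internal oracle: returns (fitted y, regression coefficients) for the
    same centered problem; must agree with the kernel route.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    mu = X.mean(axis=0)
    ybar = y.mean()
    E = X - mu
    f = y - ybar
    Ws, Ps, qs = [], [], []
    for _ in range(max_factors):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw <= 1e-14:
            break
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt <= 1e-14:
            break
        p_load = E.T @ t / tt
        q_load = float(f @ t) / tt
        E = E - np.outer(t, p_load)
        f = f - q_load * t
        Ws.append(w)
        Ps.append(p_load)
        qs.append(q_load)
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    q = np.array(qs)
    R = W @ np.linalg.inv(P.T @ W)
    b = R @ q
    return ybar + (X - mu) @ b, b


def pls_fit(
    data: DataMatrix,
    y: Sequence[float],
    max_factors: int = 7,
    cv: CVSpec | None = CVSpec(),
    groups: Sequence[object] | None = None,
) -> PLSModel:
    """Fit kernel PLS1 of a response (age in months) on spectra.

    Per-factor root-mean-square error of prediction is estimated by
    seeded random K-fold cross-validation; the factor count is then
    chosen by :func:`select_n_factors` and ``pearson_r`` reports the
    training correlation between y and fitted y at that count.

    ``groups`` (e.g. the animal each technical replicate came from)
    makes the folds respect group boundaries: all rows of a group are
    held out together, so replicate correlation cannot leak into the
    CV error.
    """
    X = data.X
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if len(y) != n:
        raise ShapeError("y length does not match X rows")
    if n < 6:
        raise ShapeError("PLS needs at least 6 samples")
    if np.ptp(y) == 0:
        raise DegenerateDataError("constant response y")
    max_factors = min(max_factors, n - 1, X.shape[1])

    W, P, R, q, T, mu, ybar = _kernel_pls1(X, y, max_factors)
    model = PLSModel(x_mean=mu, y_mean=ybar, W=W, P=P, q=q, R=R, T=T)

    if cv is not None:
        rng = np.random.default_rng(cv.seed)
        if groups is not None:
            if len(groups) != n:
                raise ShapeError("groups length does not match X rows")
            codes = pd.factorize(np.asarray(groups, dtype=object))[0]
            uniq = np.arange(codes.max() + 1)
            if cv.n_folds < 2 or cv.n_folds > len(uniq):
                raise CVError(
                    f"cannot make {cv.n_folds} folds from {len(uniq)} groups"
                )
            fold_groups = np.array_split(rng.permutation(uniq), cv.n_folds)
            folds = [
                np.flatnonzero(np.isin(codes, fg)) for fg in fold_groups
            ]
            order = np.arange(n)
        else:
            if cv.n_folds < 2 or cv.n_folds > n:
                raise CVError(f"cannot make {cv.n_folds} folds from {n} rows")
            order = rng.permutation(n)
            folds = np.array_split(order, cv.n_folds)
        sse = np.zeros(model.max_factors)
        counts = np.zeros(model.max_factors)
        y_cv = np.full((n, model.max_factors), np.nan)
        for hold in folds:
            train = np.setdiff1d(order, hold)
            try:
                Wf, Pf, Rf, qf, _, muf, ybarf = _kernel_pls1(
                    X[train], y[train], model.max_factors
                )
            except DegenerateDataError:
                continue
            for a in range(1, Rf.shape[1] + 1):
                b = Rf[:, :a] @ qf[:a]
                pred = ybarf + (X[hold] - muf) @ b
                y_cv[hold, a - 1] = pred
                sse[a - 1] += float(np.sum((y[hold] - pred) ** 2))
                counts[a - 1] += len(hold)
        valid = counts > 0
        cv_rmse = np.full(model.max_factors, np.inf)
        cv_rmse[valid] = np.sqrt(sse[valid] / counts[valid])
        model.cv_rmse = cv_rmse
        model.y_cv = y_cv
        model.n_factors = select_n_factors(model)
    else:
        model.n_factors = model.max_factors

    model.y_fitted = model.predict(X)
    model.pearson_r = pearson_r(y, model.y_fitted)
    return model


def select_n_factors(model: PLSModel, tolerance: float = 0.02) -> int:
    """Smallest factor count within (1 + tolerance) of the CV minimum.

    A one-sided parsimony band: more factors are only accepted when they
    buy a real (>2% by default) drop in cross-validated error.
    """
    if model.cv_rmse is None:
        raise ValidationError("cv_rmse not populated")
    best = float(np.min(model.cv_rmse))
    for a, rmse in enumerate(model.cv_rmse, start=1):
        if rmse <= (1.0 + tolerance) * best:
            return a
    return model.max_factors


# ---------------------------------------------------------------------------
# Score discrimination
# ---------------------------------------------------------------------------

@dataclass
class DiscriminationResult:
    """Confusion counts of a score-sign classification of two groups."""

    factor_index: int
    positive_group: object
    threshold: float
    tp: int
    fn: int
    tn: int
    fp: int
    flipped: bool  # True when scores were negated to orient the positive group

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)


def score_discrimination(
    scores: np.ndarray,
    labels: Sequence[object],
    positive_group: object,
    factor_index: int = 1,
    threshold: float = 0.0,
    orient: str = "auto",
) -> DiscriminationResult:
    """Classify samples by the sign of one latent-variable score.

    Mirrors reading a score plot: samples of the positive group (the
    older age, or the tissue of interest) should fall on the positive
    side of the origin.  With ``orient="auto"`` (latent-variable scores,
    whose sign is arbitrary) the axis is flipped if needed so the
    positive group has the larger mean; ``orient="fixed"`` keeps the
    axis as given — right for scores with an intrinsic direction, such
    as cross-validated predicted age, where auto-flipping would bias a
    null comparison upward.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    pos = labels == positive_group
    neg = ~pos
    if not pos.any() or not neg.any():
        raise GroupError("both groups must be nonempty")
    if orient not in ("auto", "fixed"):
        raise ValidationError(f"unknown orientation rule {orient!r}")
    flipped = False
    if orient == "auto" and scores[pos].mean() < scores[neg].mean():
        scores = -scores
        flipped = True
    called_pos = scores > threshold
    tp = int(np.sum(pos & called_pos))
    fn = int(np.sum(pos & ~called_pos))
    tn = int(np.sum(neg & ~called_pos))
    fp = int(np.sum(neg & called_pos))
    return DiscriminationResult(
        factor_index=factor_index,
        positive_group=positive_group,
        threshold=threshold,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        flipped=flipped,
    )


def pearson_r(a: Sequence[float], b: Sequence[float]) -> float:
    """Product-moment correlation; errors on constant input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ShapeError("pearson_r needs two equal-length vectors, n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateDataError("correlation undefined for constant input")
    return float(stats.pearsonr(a, b).statistic)
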