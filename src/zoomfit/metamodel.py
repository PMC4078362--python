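"""Standardization, polynomial expansion, NIPALS PLSR, PCA and sensitivity.

The classical metamodel predicts standardized output metrics from
standardized (and polynomially expanded) input parameters with partial least
squares regression; its regression coefficients are the sensitivity
measures, and the Pearson matrix over [parameters, metrics] gives the
bird's-eye view of the system.

PLSR is the sequential NIPALS algorithm: components are extracted one at a
time to maximize X-Y covariance, X is deflated after each, and with as many
components as the rank of X the fit coincides with ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from .batch import SimulationBatch


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scaler:
    """Column-wise centre/scale with sample SD (n-1 denominator).

    Zero-variance columns cannot be standardized; they are dropped from the
    transformed matrix (with a warning at fit time) and restored to their
    mean by :meth:`inverse_transform`, so a round trip is the identity.
    """

    means: np.ndarray
    sds: np.ndarray
    kept: np.ndarray  # boolean mask of modelled columns
    names: Optional[tuple[str, ...]] = None

    @classmethod
    def fit(cls, X, names: Optional[Sequence[str]] = None) -> "Scaler":
        if isinstance(X, pd.DataFrame):
            names = tuple(map(str, X.columns))
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ModelError("need a 2-D matrix with >= 2 rows")
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        # relative floor: a column whose spread is at rounding level of its
        # magnitude is constant for all modelling purposes
        kept = sds > 1e-12 * np.maximum(1.0, np.abs(means))
        if not np.all(kept):
            bad = (
                [n for n, k in zip(names, kept) if not k]
                if names is not None
                else np.flatnonzero(~kept).tolist()
            )
            warnings.warn(f"dropping zero-variance column(s) from modelling: {bad}")
        return cls(means, sds, kept, tuple(names) if names is not None else None)

    @property
    def kept_names(self) -> Optional[tuple[str, ...]]:
        if self.names is None:
            return None
        return tuple(n for n, k in zip(self.names, self.kept) if k)

    def transform(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X[:, self.kept] - self.means[self.kept]) / self.sds[self.kept]

    def inverse_transform(self, Z) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        out = np.tile(self.means, (Z.shape[0], 1))
        out[:, self.kept] = Z * self.sds[self.kept] + self.means[self.kept]
        return out


# ---------------------------------------------------------------------------
# polynomial expansion
# ---------------------------------------------------------------------------


def expand_polynomial(X, names: Optional[Sequence[str]] = None):
    """Append squares and pairwise products: [x_j] + [x_j^2] + [x_j*x_k, j<k].

    Returns ``(expanded, expanded_names, base_map)`` where ``base_map`` maps
    each expanded column name to the base columns it involves.  Expanded
    dimension is ``p + p + p(p-1)/2``.
    """
    if isinstance(X, pd.DataFrame):
        names = list(map(str, X.columns))
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    cols = [X]
    out_names = list(names)
    base_map = {n: (n,) for n in names}
    cols.append(X**2)
    for n in names:
        out_names.append(f"{n}^2")
        base_map[f"{n}^2"] = (n,)
    cross = []
    for j in range(p):
        for k in range(j + 1, p):
            cross.append(X[:, j] * X[:, k])
            nm = f"{names[j]}*{names[k]}"
            out_names.append(nm)
            base_map[nm] = (names[j], names[k])
    if cross:
        cols.append(np.column_stack(cross))
    return np.hstack(cols), out_names, base_map


# ---------------------------------------------------------------------------
# PLSR (NIPALS)
# ---------------------------------------------------------------------------


@dataclass
class PLSRModel:
    ncomp: int
    x_weights: np.ndarray  # W  (p x A)
    x_loadings: np.ndarray  # P  (p x A)
    y_loadings: np.ndarray  # Q  (m x A)
    x_rotation: np.ndarray  # R = W (P'W)^-1, maps standardized X to scores
    coefficients: np.ndarray  # B (p x m) in standardized space
    scaler_x: Scaler
    scaler_y: Scaler
    x_scores: np.ndarray  # training scores T (n x A)

    def transform(self, X) -> np.ndarray:
        """Project new rows onto the latent X-score space."""
        return self.scaler_x.transform(X) @ self.x_rotation

    def predict(self, X) -> np.ndarray:
        Ys = self.scaler_x.transform(X) @ self.coefficients
        return self.scaler_y.inverse_transform(Ys)

    def raw_coefficients(self):
        """(intercept, B) on the original scales of X and Y."""
        sx = self.scaler_x
        sy = self.scaler_y
        B = np.zeros((len(sx.means), len(sy.means)))
        Bk = (self.coefficients / sx.sds[sx.kept][:, None]) * sy.sds[sy.kept][None, :]
        B[np.ix_(sx.kept, sy.kept)] = Bk
        intercept = sy.means - sx.means @ B
        return intercept, B


def _nipals(Xs: np.ndarray, Ys: np.ndarray, ncomp: int, tol: float = 1e-12, max_iter: int = 500):
    X = Xs.copy()
    Y = Ys.copy()
    n, p = X.shape
    m = Y.shape[1]
    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    Q = np.zeros((m, ncomp))
    T = np.zeros((n, ncomp))
    stored = 0
    for a in range(ncomp):
        if np.linalg.norm(X) < 1e-12 or np.linalg.norm(Y) < 1e-12:
            break
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        w = None
        w_old = None
        degenerate = False
        for _ in range(max_iter):
            w = X.T @ u
            nw = np.linalg.norm(w)
            if nw < 1e-15:
                degenerate = True
                break
            w /= nw
            t = X @ w
            tt = t @ t
            if tt < 1e-30:
                degenerate = True
                break
            q = Y.T @ t / tt
            qq = q @ q
            u = Y @ q / qq if qq > 0 else t
            if w_old is not None and np.linalg.norm(w - w_old) < tol:
                break
            w_old = w
        if degenerate or w is None:
            break
        t = X @ w
        tt = t @ t
        pvec = X.T @ t / tt
        q = Y.T @ t / tt
        X = X - np.outer(t, pvec)
        Y = Y - np.outer(t, q)
        W[:, a] = w
        P[:, a] = pvec
        Q[:, a] = q
        T[:, a] = t
        stored = a + 1
    return W[:, :stored], P[:, :stored], Q[:, :stored], T[:, :stored]


def _coef_from(W, P, Q):
    if W.shape[1] == 0:
        R = np.zeros((W.shape[0], 0))
        return np.zeros((W.shape[0], Q.shape[0])), R
    R = W @ np.linalg.pinv(P.T @ W)
    return R @ Q.T, R


def plsr_fit(
    X,
    Y,
    ncomp=None,
    cv_folds: int = 10,
    max_ncomp: Optional[int] = None,
    seed: int = 0,
) -> PLSRModel:
    """Fit a PLSR model; both blocks are standardized internally.

    ``ncomp`` may be an integer, ``"max"`` (maximal supportable complexity,
    ``min(p, n - 2)`` -- the right choice for noise-free deterministic
    responses, where PLSR approaches a minimum-norm least-squares fit), or
    ``None`` for k-fold cross-validation (minimum predictive residual with a
    one-standard-error parsimony rule, capped at ``min(n // 3, p, n - 2)``).
    A requested ``ncomp`` beyond what the data supports is capped with a
    warning.
    """
    x_names = list(map(str, X.columns)) if isinstance(X, pd.DataFrame) else None
    y_names = list(map(str, Y.columns)) if isinstance(Y, pd.DataFrame) else None
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.atleast_2d(np.asarray(X, dtype=float))
    Ya = Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, dtype=float)
    if Ya.ndim == 1:
        Ya = Ya[:, None]
    if np.isnan(Xa).any() or np.isnan(Ya).any():
        raise ModelError("NaN rows must be removed before fitting")
    n = Xa.shape[0]
    sx = Scaler.fit(Xa, x_names)
    sy = Scaler.fit(Ya, y_names)
    Xs = sx.transform(Xa)
    Ys = sy.transform(Ya)
    if Ys.shape[1] == 0:
        # every response is constant: the model is the mean
        p = Xs.shape[1]
        zeroQ = np.zeros((0, 0))
        model = PLSRModel(0, np.zeros((p, 0)), np.zeros((p, 0)), zeroQ,
                          np.zeros((p, 0)), np.zeros((p, 0)), sx, sy, np.zeros((n, 0)))
        return model

    hard_cap = min(Xs.shape[1], n - 1)
    if ncomp == "max":
        ncomp = max(1, min(Xs.shape[1], n - 2))
    elif ncomp is None:
        cap = max(1, min(n // 3, Xs.shape[1], n - 2))
        if max_ncomp is not None:
            cap = max(1, min(cap, max_ncomp))
        ncomp = _select_ncomp_cv(Xs, Ys, cap, cv_folds, seed)
    elif ncomp > hard_cap:
        warnings.warn(f"ncomp={ncomp} exceeds rank bound {hard_cap}; capping")
        ncomp = hard_cap
    if ncomp < 1:
        raise ModelError("ncomp must be >= 1")

    W, P, Q, T = _nipals(Xs, Ys, int(ncomp))
    B, R = _coef_from(W, P, Q)
    return PLSRModel(W.shape[1], W, P, Q, R, B, sx, sy, T)


def _select_ncomp_cv(Xs: np.ndarray, Ys: np.ndarray, max_a: int, folds: int, seed: int) -> int:
    n = Xs.shape[0]
    folds = max(2, min(folds, n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_sse = np.zeros((folds, max_a))
    fold_cnt = np.zeros(folds)
    for f in range(folds):
        val = perm[f::folds]
        cal = np.setdiff1d(perm, val)
        a_max = min(max_a, len(cal) - 1, Xs.shape[1])
        W, P, Q, _ = _nipals(Xs[cal], Ys[cal], a_max)
        a_fit = W.shape[1]
        for a in range(1, max_a + 1):
            aa = min(a, a_fit)
            B, _ = _coef_from(W[:, :aa], P[:, :aa], Q[:, :aa])
            resid = Ys[val] - Xs[val] @ B
            fold_sse[f, a - 1] = np.sum(resid**2)
        fold_cnt[f] = len(val) * Ys.shape[1]
    press = fold_sse.sum(axis=0) / fold_cnt.sum()
    best = int(np.argmin(press))
    per_fold = fold_sse / fold_cnt[:, None]
    se = per_fold[:, best].std(ddof=1) / np.sqrt(folds)
    threshold = press[best] + se
    for a in range(best + 1):
        if press[a] <= threshold:
            return a + 1
    return best + 1


def plsr_predict(model: PLSRModel, Xnew) -> np.ndarray:
    return model.predict(Xnew)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """PCA of standardized data (correlation structure), with the 99% cut.

    ``k99`` is the minimal number of components whose cumulative explained
    variance fraction reaches 0.99.
    """

    loadings: np.ndarray  # (k, p_kept) orthonormal rows
    explained_variance_fractions: np.ndarray
    k99: int
    scaler: Scaler


def pca_fit(X, n_components: Optional[int] = None, variance_cut: float = 0.99) -> PCAModel:
    scaler = Scaler.fit(X)
    Z = scaler.transform(X)
    k = min(Z.shape[0] - 1, Z.shape[1]) if n_components is None else min(
        n_components, Z.shape[0] - 1, Z.shape[1]
    )
    k = max(k, 1)
    pca = _SkPCA(n_components=k, svd_solver="full")
    pca.fit(Z)
    evr = pca.explained_variance_ratio_
    k99 = int(np.searchsorted(np.cumsum(evr), variance_cut) + 1)
    k99 = min(k99, len(evr))
    return PCAModel(pca.components_, evr, k99, scaler)


def pca_project(model: PCAModel, rows) -> np.ndarray:
    Z = model.scaler.transform(rows)
    return Z @ model.loadings.T


# ---------------------------------------------------------------------------
# sensitivity outputs
# ---------------------------------------------------------------------------


@dataclass
class SensitivityResult:
    coefficients: pd.DataFrame  # expanded inputs x outputs, standardized space
    ranking: pd.DataFrame  # per output: expanded inputs sorted by |coefficient|
    ncomp: int


def sensitivity_coefficients(
    batch: SimulationBatch, ncomp: Optional[int] = None, seed: int = 0
) -> SensitivityResult:
    """Classical-metamodel sensitivities: standardized PLSR coefficients.

    Parameters are standardized, expanded with squares and cross-terms, and
    regressed against standardized metrics; the coefficient magnitudes rank
    the impact of each (expanded) input on each output.
    """
    cb = batch.complete()
    X = cb.params
    Y = cb.metrics
    if len(X) < X.shape[1] + 2:
        raise ModelError(f"under-determined batch: {len(X)} rows for {X.shape[1]} parameters")
    sx = Scaler.fit(X)
    Xs = sx.transform(X)
    Xe, names_e, _ = expand_polynomial(Xs, list(sx.kept_names or X.columns))
    model = plsr_fit(pd.DataFrame(Xe, columns=names_e, index=X.index), Y, ncomp=ncomp, seed=seed)
    coef = np.zeros((len(names_e), Y.shape[1]))
    coef[np.ix_(model.scaler_x.kept, model.scaler_y.kept)] = model.coefficients
    table = pd.DataFrame(coef, index=names_e, columns=Y.columns)
    ranking = pd.DataFrame(
        {out: table[out].abs().sort_values(ascending=False).index for out in table.columns}
    )
    return SensitivityResult(table, ranking, model.ncomp)


def pearson_matrix(batch: SimulationBatch) -> pd.DataFrame:
    """Pearson's R over all [parameters, metrics] columns.

    Symmetric with unit diagonal; correlations involving a constant column
    are reported as NaN (undefined).
    """
    cb = batch.complete()
    joint = pd.concat([cb.params, cb.metrics], axis=1)
    if len(joint) < 3:
        raise ModelError("need >= 3 complete rows for a correlation matrix")
    vals = joint.to_numpy(dtype=float)
    sds = vals.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(vals, rowvar=False)
    R[np.ix_(sds == 0, np.ones(len(sds), dtype=bool))] = np.nan
    R[np.ix_(np.ones(len(sds), dtype=bool), sds == 0)] = np.nan
    np.fill_diagonal(R, np.where(sds > 0, 1.0, np.nan))
    return pd.DataFrame(R, index=joint.columns, columns=joint.columns)
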