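"""Hierarchical cluster-based PLSR for nonlinear (inverse) metamodelling.

A global PLSR model is fitted first; fuzzy C-means (FCM) clustering on its
latent X-scores partitions the observations into locally-linear regimes; a
local PLSR model is fitted per cluster (on the rows whose dominant
membership falls there).  Predictions route a new point through the global
score space: by default the local predictions are combined weighted by the
point's fuzzy memberships, optionally by its hard-max cluster alone.

Used inversely (metrics as regressors, parameters as responses) this gives
a parameter-identifiability readout: the per-parameter r-squared between
simulated and predicted values on a held-out test set, with poorly
predicted ("sloppy") parameters screened out by an r^2 > 0.7 rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metamodel import ModelError, PLSRModel, plsr_fit

R2_SCREEN_DEFAULT = 0.70


def _as_df(A) -> pd.DataFrame:
    if isinstance(A, pd.DataFrame):
        return A
    arr = np.asarray(A, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame(arr)



# ---------------------------------------------------------------------------
# fuzzy C-means
# ---------------------------------------------------------------------------


@dataclass
class FCMModel:
    centers: np.ndarray  # (c, d)
    fuzzifier: float
    memberships: np.ndarray  # (n, c), rows sum to 1
    objective_history: np.ndarray
    n_iter: int
    tol: float
    max_iter: int

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]

    def membership(self, Z) -> np.ndarray:
        """Closed-form memberships of new points given the fitted centers."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return _memberships(Z, self.centers, self.fuzzifier)


def _memberships(Z: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    d2 = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    n, c = d2.shape
    U = np.zeros((n, c))
    zero = d2 <= 1e-300
    any_zero = zero.any(axis=1)
    if any_zero.any():
        U[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
    rest = ~any_zero
    if rest.any():
        power = 1.0 / (m - 1.0)
        inv = d2[rest] ** (-power)
        U[rest] = inv / inv.sum(axis=1, keepdims=True)
    return U


def fcm_cluster(
    Z,
    c: int,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    allow_empty: bool = False,
) -> FCMModel:
    """Alternating optimization of centers and memberships (Euclidean FCM).

    Deterministic given ``seed``.  The objective sum(u^m d^2) is
    non-increasing across iterations; convergence is declared when the
    largest membership change falls below ``tol``.  A cluster that ends up
    with no dominant members is re-seeded once before erroring.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n = Z.shape[0]
    if c < 1:
        raise ModelError("cluster count must be >= 1")
    if c > n:
        raise ModelError(f"cannot form {c} clusters from {n} points")
    if m <= 1:
        raise ModelError("fuzzifier must be > 1")
    if c == 1:
        center = Z.mean(axis=0, keepdims=True)
        U = np.ones((n, 1))
        d2 = ((Z - center) ** 2).sum(axis=1)
        return FCMModel(center, m, U, np.array([float(d2.sum())]), 1, tol, max_iter)

    for attempt in range(2):
        rng = np.random.default_rng(seed + 7919 * attempt)
        U = rng.uniform(size=(n, c))
        U /= U.sum(axis=1, keepdims=True)
        history = []
        n_it = 0
        for n_it in range(1, max_iter + 1):
            Um = U**m
            centers = (Um.T @ Z) / Um.sum(axis=0)[:, None]
            d2 = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            history.append(float((Um * d2).sum()))
            U_new = _memberships(Z, centers, m)
            delta = np.abs(U_new - U).max()
            U = U_new
            if delta < tol:
                break
        hard = np.bincount(np.argmax(U, axis=1), minlength=c)
        if allow_empty or np.all(hard > 0):
            return FCMModel(centers, m, U, np.asarray(history), n_it, tol, max_iter)
        if attempt == 0:
            warnings.warn("FCM produced an empty effective cluster; re-seeding once")
    raise ModelError("FCM produced an empty effective cluster after re-seeding")


# ---------------------------------------------------------------------------
# HC-PLSR
# ---------------------------------------------------------------------------


@dataclass
class HCPLSRModel:
    global_model: PLSRModel
    fcm: FCMModel
    locals: list[PLSRModel]
    routing: str  # "weighted" | "hard"
    score_min: np.ndarray  # training score hull (per-component bounds)
    score_max: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.locals)

    def predict(self, Xnew, return_extrapolation: bool = False):
        T = self.global_model.transform(Xnew)
        U = self.fcm.membership(T)
        preds = np.stack([loc.predict(Xnew) for loc in self.locals], axis=0)  # (c, n, m)
        if self.routing == "hard":
            idx = np.argmax(U, axis=1)
            out = preds[idx, np.arange(T.shape[0]), :]
        else:
            out = np.einsum("nc,cnm->nm", U, preds)
        if return_extrapolation:
            flags = ((T < self.score_min) | (T > self.score_max)).any(axis=1)
            return out, flags
        return out


@dataclass
class IdentifiabilityReport:
    """Per-target test-set prediction accuracy and the inclusion screen."""

    r2: pd.Series
    threshold: float = R2_SCREEN_DEFAULT

    @property
    def included(self) -> pd.Series:
        return self.r2 > self.threshold  # strict: exactly 0.70 is excluded

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r2": self.r2, "included": self.included})


def hcplsr_fit(
    X,
    Y,
    c: int,
    seed: int = 0,
    ncomp=None,
    fuzzifier: float = 2.0,
    min_cluster_size: int = 10,
    routing: str = "weighted",
) -> HCPLSRModel:
    """Global PLSR -> FCM on its X-scores -> local PLSR per cluster.

    Local models are fitted on hard-assigned rows (dominant membership);
    fuzzy weighting enters only at prediction time.  Clusters smaller than
    ``min_cluster_size`` are merged into the nearest surviving cluster
    (with a warning).  With ``c == 1`` the global model itself is the single
    local model, so prediction coincides exactly with plain PLSR.
    """
    if routing not in ("weighted", "hard"):
        raise ModelError(f"unknown routing rule '{routing}'")
    Xdf = _as_df(X)
    Ydf = _as_df(Y)
    global_model = plsr_fit(Xdf, Ydf, ncomp=ncomp, seed=seed)
    T = global_model.x_scores
    smin, smax = T.min(axis=0), T.max(axis=0)

    if c == 1:
        center = T.mean(axis=0, keepdims=True)
        fcm = FCMModel(center, fuzzifier, np.ones((T.shape[0], 1)), np.zeros(1), 0, 0.0, 0)
        return HCPLSRModel(global_model, fcm, [global_model], routing, smin, smax)

    # empty effective clusters are tolerated here: the merge step below
    # folds them into their nearest neighbours
    fcm = fcm_cluster(T, c, m=fuzzifier, seed=seed, allow_empty=True)
    labels = np.argmax(fcm.memberships, axis=1)
    counts = np.bincount(labels, minlength=fcm.n_clusters)
    keep = counts >= min_cluster_size
    if not keep.any():
        # fall back to the largest cluster alone rather than failing outright
        keep = counts == counts.max()
    if not keep.all():
        small = np.flatnonzero(~keep).tolist()
        warnings.warn(f"merging undersized cluster(s) {small} into nearest neighbours")
        surv_centers = fcm.centers[keep]
        fcm = FCMModel(
            surv_centers, fcm.fuzzifier,
            _memberships(T, surv_centers, fcm.fuzzifier),
            fcm.objective_history, fcm.n_iter, fcm.tol, fcm.max_iter,
        )
        # hard labels against the surviving centers (0..c_surv-1)
        d2 = ((T[:, None, :] - surv_centers[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)

    locals_: list[PLSRModel] = []
    for k in range(fcm.n_clusters):
        rows = np.flatnonzero(labels == k)
        nk = len(rows)
        local_ncomp = max(1, min(global_model.ncomp, nk - 2))
        locals_.append(
            plsr_fit(Xdf.iloc[rows], Ydf.iloc[rows], ncomp=local_ncomp, seed=seed + k)
        )
    return HCPLSRModel(global_model, fcm, locals_, routing, smin, smax)


def hcplsr_predict(model: HCPLSRModel, Xnew, return_extrapolation: bool = False):
    return model.predict(Xnew, return_extrapolation=return_extrapolation)


def r2_score_pearson(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Squared Pearson correlation between simulated and predicted values.

    Returns 0.0 when either side is (numerically) constant, i.e. the
    predictor is degenerate for that target.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if np.std(y_true) < 1e-14 or np.std(y_pred) < 1e-14:
        return 0.0
    return float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)


def validate_testset(
    X,
    Y,
    c: int,
    test_fraction: float = 1.0 / 3.0,
    seed: int = 0,
    threshold: float = R2_SCREEN_DEFAULT,
    **fit_kwargs,
) -> IdentifiabilityReport:
    """Random calibration/test split; per-target r^2 on the held-out part.

    The model sees only the calibration rows; the r^2 of each response on
    the test rows estimates how well that target could be predicted from
    genuinely new data.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ModelError("test_fraction must be in (0, 1)")
    Xdf = _as_df(X)
    Ydf = _as_df(Y)
    n = len(Xdf)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(n * test_fraction)))
    test, cal = perm[:n_test], perm[n_test:]
    model = hcplsr_fit(Xdf.iloc[cal], Ydf.iloc[cal], c=c, seed=seed, **fit_kwargs)
    pred = model.predict(Xdf.iloc[test])
    r2 = pd.Series(
        [r2_score_pearson(Ydf.iloc[test, j].to_numpy(), pred[:, j]) for j in range(Ydf.shape[1])],
        index=Ydf.columns,
    )
    return IdentifiabilityReport(r2, threshold)


def _smallest_within_tolerance(scores: Mapping[int, float], tol: float) -> int:
    """Smallest cluster count whose score is within ``tol`` (relative) of the best."""
    best = max(scores.values())
    cutoff = best * (1.0 - tol)
    for c in sorted(scores):
        if scores[c] >= cutoff:
            return c
    return max(scores)  # unreachable for tol >= 0


def select_n_clusters(
    X,
    Y,
    candidates: Sequence[int],
    seed: int = 0,
    tol: float = 0.01,
    **kwargs,
):
    """Pick the smallest cluster count giving (near-)maximal predictive ability.

    Each candidate is scored by the mean test-set r^2 over all targets; the
    chosen ``c`` is the smallest whose score is within ``tol`` (relative) of
    the maximum -- parsimony over marginal gains.
    Returns ``(chosen_c, scores_by_c)``.
    """
    scores: dict[int, float] = {}
    for c in candidates:
        try:
            rep = validate_testset(X, Y, c=c, seed=seed, **kwargs)
            scores[c] = float(rep.r2.mean())
        except ModelError as exc:
            warnings.warn(f"skipping c={c}: {exc}")
    if not scores:
        raise ModelError("no candidate cluster count could be evaluated")
    return _smallest_within_tolerance(scores, tol), scores
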