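"""The iterative fitting loop: design -> simulate -> metrics -> look-up -> zoom.

Each iteration samples a Latin hypercube over the current parameter ranges,
runs the simulator at three cell lengths, reduces every run to the metric
vector, ranks all runs by PCA-score distance to the target, assembles the
guideline set (20 nearest parameter vectors, joined in the first iteration
by the screened inverse-metamodel prediction), and zooms the ranges onto
the guideline hull.  The loop stops as soon as any simulation satisfies all
success criteria, or after a maximum number of iterations.

Model reduction reuses the same loop: variants of the simulator with
components disabled (parameters pinned to fixed values) are fitted against
the same target, and a variant that still converges is declared reducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .batch import SimulationBatch
from .design import (
    IterationState,
    ParameterSpace,
    STEPSIZE_INITIAL,
    adapt_stepsize,
    clamp_to_constraints,
    lhd_sample,
    update_ranges,
)
from .hcplsr import (
    IdentifiabilityReport,
    hcplsr_fit,
    select_n_clusters,
    validate_testset,
)
from .lookup import (
    DistanceReport,
    GuidelineSet,
    SuccessCriteria,
    TargetMetrics,
    assemble_guideline_set,
    evaluate_success_batch,
    score_distance,
)
from .metamodel import Scaler, expand_polynomial
from .metrics import (
    ForceScaler,
    FpcaCurve,
    FpcaMetrics,
    InsufficientDataError,
    TensionTransient,
    UndefinedMetricsError,
    assemble_metric_vector,
    fpca_metrics,
    metric_key,
    transient_metrics,
)


class PipelineError(RuntimeError):
    pass


class IterationAbort(PipelineError):
    """Too many failed simulations (or no usable rows) in one iteration."""


@dataclass
class SimulatorSpec:
    """Contract a simulator must satisfy to enter the pipeline.

    ``run(params, lam)`` maps a parameter mapping and a length factor to a
    ``(TensionTransient, FpcaCurve)`` pair and must be deterministic; a
    failure for one parameter set raises, and the pipeline records it
    per-row instead of aborting.  ``pinned`` fixes parameters to constants
    (model-reduction switches); pinned parameters are removed from the
    sampled space.  ``run_batch(params_df, lam)``, when provided, returns
    ``(time, tension_matrix, pca_grid, force_matrix)`` for a whole design at
    once and is used purely as a fast path.
    """

    name: str
    param_names: tuple[str, ...]
    run: Callable
    pinned: dict = field(default_factory=dict)
    run_batch: Optional[Callable] = None


@dataclass
class FitConfig:
    """Everything that parameterises one fitting run."""

    space: ParameterSpace
    criteria: SuccessCriteria
    design_size: int = 500
    max_iterations: int = 25
    seed: int = 0
    n_nearest: int = 20
    r2_screen: float = 0.70
    n_clusters: Optional[int] = None  # None: auto-select over cluster_candidates
    cluster_candidates: tuple[int, ...] = (1, 2, 4, 8)
    test_fraction: float = 1.0 / 3.0
    lambdas: tuple[float, ...] = (0.9, 1.0, 1.1)
    use_inverse_metamodel: bool = True
    min_cluster_size: int = 10
    ncomp: "int | str | None" = "max"  # maximal complexity: noise-free simulators
    max_failed_fraction: float = 0.5
    stepsize_initial: int = STEPSIZE_INITIAL
    include_target_in_pca: bool = True
    routing: str = "weighted"

    def __post_init__(self):
        if self.design_size < 1 or self.max_iterations < 1 or self.n_nearest < 1:
            raise ValueError("counts must be positive")
        if not (0.0 < self.r2_screen < 1.0):
            raise ValueError("r2_screen must be in (0, 1)")


@dataclass
class IterationLogRecord:
    iteration: int
    stepsize: int
    min_rmsd: float
    n_pass: int
    n_failed: int
    n_incomplete: int
    k99: int
    lower: np.ndarray
    upper: np.ndarray


@dataclass
class IterationOutput:
    state: IterationState
    batch: SimulationBatch
    distances: DistanceReport
    guideline: GuidelineSet
    passers: pd.DataFrame
    passer_metrics: pd.DataFrame
    record: IterationLogRecord
    prediction: Optional[pd.Series]
    identifiability: Optional[IdentifiabilityReport]
    force_scalers: dict


@dataclass
class FitResult:
    status: str  # "converged" | "not converged"
    feasible: pd.DataFrame
    feasible_metrics: pd.DataFrame
    log: list
    summary: Optional[pd.DataFrame]
    identifiability: Optional[IdentifiabilityReport]
    force_scalers: dict
    n_iterations: int

    @property
    def converged(self) -> bool:
        return self.status == "converged"


def _derive_seed(seed: int, iteration: int, salt: int) -> int:
    return (int(seed) * 1000003 + iteration * 101 + salt * 7) % (2**31)


# ---------------------------------------------------------------------------
# simulation + metric extraction for one design
# ---------------------------------------------------------------------------


def simulate_design_metrics(
    params: pd.DataFrame,
    simulator: SimulatorSpec,
    target: TargetMetrics,
    lambdas: Sequence[float],
    force_scalers: Optional[dict] = None,
):
    """Metrics table for every design row; returns (metrics, errors, scalers).

    Failed rows get all-NaN metric vectors and an entry in ``errors``;
    individually undefined descriptors (e.g. RT90 not reached) stay NaN in
    an otherwise valid row.  ``force_scalers`` (per length factor) hold the
    point-wise force statistics used to standardize RMSDforce; when absent
    they are fitted on this batch and returned for reuse in later
    iterations (frozen first-design statistics).
    """
    full = params.copy()
    for k, v in simulator.pinned.items():
        full[k] = v
    n = len(full)
    errors: dict = {}
    freeze = force_scalers is None
    scalers = {} if freeze else dict(force_scalers)
    per_lam_twitch: dict[float, list] = {}
    per_lam_fpca: dict[float, list] = {}

    for lam in lambdas:
        tw_rows: list = [None] * n
        fp_rows: list = [None] * n
        if simulator.run_batch is not None:
            time, F, pca_grid, forces = simulator.run_batch(full, lam)
        else:
            time = pca_grid = None
            F = [None] * n
            forces = [None] * n
            for i in range(n):
                try:
                    tr, curve = simulator.run(full.iloc[i].to_dict(), lam)
                except Exception as exc:  # per-row failure contract
                    errors[full.index[i]] = f"lambda={lam:g}: {exc}"
                    continue
                if time is None:
                    time, pca_grid = tr.time, curve.pca
                elif curve.pca.shape != pca_grid.shape or not np.allclose(curve.pca, pca_grid):
                    raise PipelineError("simulator returned inconsistent pCa grids")
                F[i] = tr.tension
                forces[i] = curve.force
            if time is None:  # every row failed at this length
                per_lam_twitch[lam] = [None] * n
                per_lam_fpca[lam] = [None] * n
                continue
            F = np.array([f if f is not None else np.full_like(time, np.nan) for f in F])
            forces = np.array(
                [f if f is not None else np.full_like(pca_grid, np.nan) for f in forces]
            )

        ok = ~np.isnan(F).any(axis=1)
        # twitch + Hill-line metrics row by row
        for i in range(n):
            idx = full.index[i]
            if not ok[i]:
                continue
            try:
                tw_rows[i] = transient_metrics(TensionTransient(time, F[i], lam))
                fp_rows[i] = fpca_metrics(FpcaCurve(pca_grid, forces[i], lam))
            except (UndefinedMetricsError, InsufficientDataError) as exc:
                errors[idx] = f"lambda={lam:g}: {exc}"
                tw_rows[i] = fp_rows[i] = None
                ok[i] = False

        # standardized RMSD of the normalized force curves against the target
        rmsdf = np.full(n, np.nan)
        if target.force_curves is not None and lam in target.force_curves:
            tc = target.force_curves[lam]
            if tc.pca.shape != pca_grid.shape or not np.allclose(tc.pca, pca_grid):
                raise PipelineError("target force curve is on a different pCa grid")
            ft = tc.force / tc.force.max()
            with np.errstate(invalid="ignore", divide="ignore"):
                fnorm = forces / np.nanmax(forces, axis=1, keepdims=True)
            if freeze:
                if ok.sum() >= 2:
                    scalers[lam] = ForceScaler.fit(pca_grid, fnorm[ok])
                else:
                    scalers[lam] = ForceScaler(pca_grid, ft, np.ones_like(ft))
            sc = scalers[lam]
            diff = (fnorm - ft[None, :]) / sc.sds[None, :]
            rmsdf[ok] = np.sqrt(np.nanmean(diff[ok] ** 2, axis=1))

        per_lam_twitch[lam] = tw_rows
        per_lam_fpca[lam] = [
            (None if fp is None else FpcaMetrics(fp.slope, fp.intercept, fp.rmsep, fp.r2force, fp.max, rmsdf[i]))
            for i, fp in enumerate(fp_rows)
        ]

    # assemble row vectors; a row that failed at any length is all-NaN
    from .metrics import metric_names

    cols = metric_names(lambdas)
    data = np.full((n, len(cols)), np.nan)
    for i in range(n):
        idx = full.index[i]
        if any(per_lam_twitch[lam][i] is None for lam in lambdas):
            errors.setdefault(idx, "simulation or metric extraction failed")
            continue
        vec = assemble_metric_vector(
            {lam: per_lam_twitch[lam][i] for lam in lambdas},
            {lam: per_lam_fpca[lam][i] for lam in lambdas},
        )
        data[i] = vec.to_numpy()
    metrics = pd.DataFrame(data, index=full.index, columns=cols)
    return metrics, errors, scalers


# ---------------------------------------------------------------------------
# one iteration
# ---------------------------------------------------------------------------


def _inverse_prediction(
    batch: SimulationBatch,
    target: TargetMetrics,
    config: FitConfig,
    seed_validate: int,
    seed_fit: int,
):
    """Inverse HC-PLSR: screen identifiability, then predict the target's
    parameters.  Unscreened parameters come back NaN."""
    cb = batch.complete()
    mscaler = Scaler.fit(cb.metrics)
    Xs = mscaler.transform(cb.metrics)
    Xe, names_e, _ = expand_polynomial(Xs, list(mscaler.kept_names))
    Xe_df = pd.DataFrame(Xe, columns=names_e, index=cb.metrics.index)
    common = dict(
        fuzzifier=2.0,
        min_cluster_size=config.min_cluster_size,
        routing=config.routing,
        ncomp=config.ncomp,
    )
    if config.n_clusters is None:
        # the cluster-count scan: smallest c with (near-)maximal predictive
        # ability on the held-out split
        c, _scores = select_n_clusters(
            Xe_df, cb.params, config.cluster_candidates, seed=seed_validate,
            test_fraction=config.test_fraction, threshold=config.r2_screen,
            **common,
        )
    else:
        c = config.n_clusters
    report = validate_testset(
        Xe_df, cb.params, c=c,
        test_fraction=config.test_fraction, seed=seed_validate,
        threshold=config.r2_screen, **common,
    )
    model = hcplsr_fit(Xe_df, cb.params, c=c, seed=seed_fit, **common)
    tgt = target.values.reindex(cb.metrics.columns).to_numpy(dtype=float)[None, :]
    tXs = mscaler.transform(tgt)
    tXe, _, _ = expand_polynomial(tXs, list(mscaler.kept_names))
    pred = pd.Series(model.predict(tXe)[0], index=cb.params.columns)
    pred[~report.included] = np.nan
    return pred, report


def run_iteration(
    state: IterationState,
    simulator: SimulatorSpec,
    target: TargetMetrics,
    config: FitConfig,
    force_scalers: Optional[dict] = None,
    allow_prediction: Optional[bool] = None,
) -> IterationOutput:
    """One pass of steps design -> simulate -> metrics -> look-up -> zoom."""
    it = state.iteration
    if allow_prediction is None:
        allow_prediction = it == 1 and config.use_inverse_metamodel

    design = lhd_sample(state.space, config.design_size, _derive_seed(config.seed, it, 1))
    params = design.to_frame()
    metrics, errors, scalers = simulate_design_metrics(
        params, simulator, target, config.lambdas, force_scalers
    )
    batch = SimulationBatch(params, metrics, errors)
    n_failed = int(metrics.isna().all(axis=1).sum())
    if n_failed > config.max_failed_fraction * len(params):
        raise IterationAbort(
            f"iteration {it}: {n_failed}/{len(params)} simulations failed; "
            f"first errors: {dict(list(errors.items())[:5])}"
        )
    cb = batch.complete()
    n_incomplete = batch.n - n_failed - cb.n
    if cb.n < 2:
        raise IterationAbort(f"iteration {it}: only {cb.n} complete rows")

    prediction = identifiability = None
    if allow_prediction:
        prediction, identifiability = _inverse_prediction(
            batch, target, config, _derive_seed(config.seed, it, 2), _derive_seed(config.seed, it, 3)
        )

    distances = score_distance(cb.metrics, target, config.include_target_in_pca)
    pass_mask = evaluate_success_batch(cb.metrics, config.criteria)
    passers = cb.params.loc[pass_mask]
    passer_metrics = cb.metrics.loc[pass_mask]

    guideline = assemble_guideline_set(
        distances, cb.params, prediction if it == 1 else None,
        k=config.n_nearest, space=state.space,
    )

    min_rmsd = float(distances.rmsd.min())
    if it == 1:
        stepsize = state.stepsize
    else:
        stepsize = adapt_stepsize(state.stepsize, min_rmsd < state.prev_min_rmsd)
    new_space = update_ranges(guideline, stepsize, state.space)
    new_state = IterationState(
        iteration=it + 1,
        stepsize=stepsize,
        space=new_space,
        best_rmsd=min(state.best_rmsd, min_rmsd),
        prev_min_rmsd=min_rmsd,
    )
    record = IterationLogRecord(
        it, stepsize, min_rmsd, int(pass_mask.sum()), n_failed, n_incomplete,
        distances.k99, state.space.lower.copy(), state.space.upper.copy(),
    )
    return IterationOutput(
        new_state, batch, distances, guideline, passers, passer_metrics,
        record, prediction, identifiability, scalers,
    )


# ---------------------------------------------------------------------------
# the full loop, summaries, model-variant comparison
# ---------------------------------------------------------------------------


def run_pipeline(simulator: SimulatorSpec, target: TargetMetrics, config: FitConfig) -> FitResult:
    """Iterate until at least one simulation passes every success clause.

    All passing parameter sets encountered along the way are collected; the
    run converges as soon as any iteration produces at least one.  Reaching
    the iteration cap without a passer returns status "not converged" with
    the full audit trail.
    """
    space = config.space
    pinned = [p for p in simulator.pinned if p in space.names]
    if pinned:
        space = space.drop(pinned)
    state = IterationState(1, int(config.stepsize_initial), clamp_to_constraints(space))

    feasible = []
    feasible_metrics = []
    log: list[IterationLogRecord] = []
    identifiability = None
    force_scalers: Optional[dict] = None
    it = 0
    for it in range(1, config.max_iterations + 1):
        out = run_iteration(state, simulator, target, config, force_scalers)
        state = out.state
        if force_scalers is None:
            force_scalers = out.force_scalers
        if out.identifiability is not None:
            identifiability = out.identifiability
        log.append(out.record)
        if len(out.passers):
            tagged = out.passers.copy()
            tagged.insert(0, "iteration", out.record.iteration)
            feasible.append(tagged)
            feasible_metrics.append(out.passer_metrics)
            break

    if feasible:
        status = "converged"
        fdf = pd.concat(feasible)
        fmet = pd.concat(feasible_metrics)
        summary = summarize_parameter_sets(fdf.drop(columns="iteration"))
    else:
        status = "not converged"
        fdf = pd.DataFrame(columns=["iteration", *space.names])
        fmet = pd.DataFrame()
        summary = None
    return FitResult(
        status, fdf, fmet, log, summary, identifiability, force_scalers or {}, it
    )


def summarize_parameter_sets(sets: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter mean, sample SD and SD as % of |mean| over feasible sets.

    The across-parameter average CV%% is stored in ``.attrs['mean_cv_pct']``
    (parameters with zero mean are excluded from the average, their CV being
    undefined).
    """
    if len(sets) == 0:
        raise ValueError("need at least one parameter set")
    mean = sets.mean(axis=0)
    sd = sets.std(axis=0, ddof=1) if len(sets) > 1 else pd.Series(0.0, index=sets.columns)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = 100.0 * sd / mean.abs()
    cv[mean == 0] = np.nan
    out = pd.DataFrame({"mean": mean, "sd": sd, "cv_pct": cv})
    out.attrs["mean_cv_pct"] = float(cv.dropna().mean()) if cv.notna().any() else np.nan
    return out


@dataclass
class VariantResult:
    result: FitResult
    verdict: str  # "reducible" | "not reducible"
    mean_cv_pct: float


def compare_model_variants(
    variants: Mapping[str, SimulatorSpec],
    target: TargetMetrics,
    config: FitConfig,
) -> dict[str, VariantResult]:
    """Fit every simulator variant against the same target and criteria.

    A variant (typically the model with a component disabled via pinned
    parameters) is "reducible" when its fit still converges -- the reduced
    model can replicate the target within the same bands.  The feasible-set
    CV%% comparison quantifies how tightly each variant constrains its
    parameters.
    """
    if not variants:
        raise ValueError("no variants given")
    out = {}
    for name, sim in variants.items():
        res = run_pipeline(sim, target, config)
        cv = res.summary.attrs["mean_cv_pct"] if res.summary is not None else np.nan
        out[name] = VariantResult(res, "reducible" if res.converged else "not reducible", cv)
    return out
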