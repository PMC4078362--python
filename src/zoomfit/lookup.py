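"""Look-up of simulations near the target, guideline sets, success criteria.

The proximity of every simulation to the target metric vector is measured
in PCA score space: simulations and target are stacked, standardized and
decomposed, the minimal number of components explaining 99% of the variance
is retained, and the root-mean-square distance over those score coordinates
ranks the simulations.  The parameters of the 20 nearest simulations --
optionally joined by a screened inverse-metamodel prediction in the first
iteration -- form the guideline set (at most 21 rows) that steers the next
iteration's parameter ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .design import ParameterSpace
from .metamodel import pca_fit, pca_project
from .metrics import metric_key


@dataclass
class TargetMetrics:
    """The metric vector the fit aims for, with optional extras.

    ``force_curves`` (per length factor) are kept so RMSDforce against this
    target can be recomputed; ``ground_truth`` carries the generating
    parameters when the target is synthetic (for recovery scoring only).
    """

    values: pd.Series
    provenance: Optional[Mapping[str, str]] = None
    force_curves: Optional[Mapping[float, object]] = None
    ground_truth: Optional[Mapping[str, float]] = None


@dataclass
class DistanceReport:
    rmsd: pd.Series  # per-simulation RMSD to the target in PCA scores
    ranking: np.ndarray  # row labels sorted by ascending RMSD (stable ties)
    k99: int


@dataclass
class GuidelineSet:
    """At most 21 parameter vectors steering the next iteration's ranges."""

    params: pd.DataFrame
    sources: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.params)


def score_distance(
    metrics: pd.DataFrame,
    target,
    include_target_in_fit: bool = True,
) -> DistanceReport:
    """RMSD of each simulation to the target in the retained PCA scores.

    The PCA (and the standardization behind it) is fitted on the stacked
    [simulations; target] matrix by default -- the target participates in
    the statistics -- or on the simulations alone when
    ``include_target_in_fit`` is false.  RMSD divides by the number of
    retained components; ties in the ranking break by ascending row label.
    """
    tgt = target.values if isinstance(target, TargetMetrics) else target
    tgt = tgt.reindex(metrics.columns)
    if tgt.isna().any():
        missing = list(tgt.index[tgt.isna()])
        raise ValueError(f"target lacks metric(s) {missing}")
    all_missing = metrics.columns[metrics.isna().all(axis=0)]
    if len(all_missing):
        warnings.warn(f"dropping all-missing metric column(s): {list(all_missing)}")
        metrics = metrics.drop(columns=all_missing)
        tgt = tgt.drop(index=all_missing)
    if metrics.isna().any().any():
        raise ValueError("incomplete metric vectors; filter rows before ranking")
    if len(metrics) < 2:
        raise ValueError("need >= 2 simulations")

    stack = np.vstack([metrics.to_numpy(dtype=float), tgt.to_numpy(dtype=float)[None, :]])
    fit_on = stack if include_target_in_fit else stack[:-1]
    model = pca_fit(fit_on)
    scores = pca_project(model, stack)[:, : model.k99]
    diff = scores[:-1] - scores[-1]
    rmsd = np.sqrt((diff**2).mean(axis=1))
    rmsd_s = pd.Series(rmsd, index=metrics.index, name="rmsd")
    order = np.lexsort((np.arange(len(rmsd)), rmsd))
    return DistanceReport(rmsd_s, metrics.index.to_numpy()[order], model.k99)


def assemble_guideline_set(
    report: DistanceReport,
    params: pd.DataFrame,
    prediction: Optional[pd.Series] = None,
    k: int = 20,
    space: Optional[ParameterSpace] = None,
) -> GuidelineSet:
    """Parameters of the ``k`` nearest simulations, plus a screened prediction.

    ``prediction`` (the inverse metamodel's estimate at the target, only
    supplied in the first iteration) may have NaN entries for parameters
    that failed the identifiability screen; those are filled with the mean
    of the ``k`` nearest parameter vectors.  When a ``space`` is given the
    appended row is clamped to its hard constraints.
    """
    if len(params) == 0:
        raise ValueError("empty batch")
    take = list(report.ranking[: min(k, len(report.ranking))])
    if len(take) < k:
        warnings.warn(f"only {len(take)} simulations available; guideline set is short of {k}")
    rows = params.loc[take].copy()
    sources = ["simulation"] * len(rows)
    if prediction is not None:
        pred = prediction.reindex(params.columns).astype(float)
        fill = rows.mean(axis=0)
        pred = pred.fillna(fill)
        if space is not None:
            vals = np.clip(
                pred[list(space.names)].to_numpy(dtype=float),
                space.hard_lower,
                space.hard_upper,
            )
            pred = pd.Series(vals, index=list(space.names)).reindex(params.columns)
        pred_df = pred.to_frame().T
        pred_df.index = ["metamodel"]
        rows = pd.concat([rows, pred_df])
        sources.append("metamodel")
    return GuidelineSet(rows, tuple(sources))


# ---------------------------------------------------------------------------
# success criteria
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Clause:
    """One interval condition on a named metric at a length factor.

    Closed bounds are inclusive ("between a and b"); a strict upper bound
    encodes "less than".  Either bound may be absent (one-sided clause).
    """

    metric: str
    lam: float
    lower: Optional[float] = None
    upper: Optional[float] = None
    upper_strict: bool = False
    lower_strict: bool = False

    @property
    def key(self) -> str:
        return metric_key(self.metric, self.lam)

    def holds(self, value: float) -> bool:
        if np.isnan(value):
            return False
        if self.lower is not None:
            if self.lower_strict:
                if not value > self.lower:
                    return False
            elif not value >= self.lower:
                return False
        if self.upper is not None:
            if self.upper_strict:
                if not value < self.upper:
                    return False
            elif not value <= self.upper:
                return False
        return True


@dataclass
class SuccessCriteria:
    clauses: tuple[Clause, ...]

    def __post_init__(self):
        for cl in self.clauses:
            if cl.lower is not None and cl.upper is not None and cl.lower > cl.upper:
                raise ValueError(f"empty interval in clause for {cl.key}")

    @classmethod
    def from_config(cls, source) -> "SuccessCriteria":
        """YAML list of ``{metric, lambda, min?, max?, max_strict?, min_strict?}``."""
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        elif isinstance(source, (list, tuple)):
            doc = list(source)
        else:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        entries = doc["criteria"] if isinstance(doc, dict) else doc
        clauses = []
        for e in entries:
            clauses.append(
                Clause(
                    metric=e["metric"],
                    lam=float(e["lambda"]),
                    lower=float(e["min"]) if e.get("min") is not None else None,
                    upper=float(e["max"]) if e.get("max") is not None else None,
                    upper_strict=bool(e.get("max_strict", False)),
                    lower_strict=bool(e.get("min_strict", False)),
                )
            )
        return cls(tuple(clauses))

    def to_config(self, path=None):
        entries = []
        for cl in self.clauses:
            e: dict = {"metric": cl.metric, "lambda": cl.lam}
            if cl.lower is not None:
                e["min"] = cl.lower
                if cl.lower_strict:
                    e["min_strict"] = True
            if cl.upper is not None:
                e["max"] = cl.upper
                if cl.upper_strict:
                    e["max_strict"] = True
            entries.append(e)
        doc = {"criteria": entries}
        if path is not None:
            with open(path, "w") as fh:
                yaml.safe_dump(doc, fh, sort_keys=False)
        return doc


def evaluate_success(metrics: pd.Series, criteria: SuccessCriteria):
    """Check one metric vector against every clause.

    Returns ``(passed, report)``: pass only if every clause holds; a clause
    whose metric is missing (absent or NaN) fails and is flagged.
    """
    rows = []
    ok = True
    for cl in criteria.clauses:
        present = cl.key in metrics.index
        value = float(metrics[cl.key]) if present else np.nan
        missing = (not present) or np.isnan(value)
        holds = (not missing) and cl.holds(value)
        ok = ok and holds
        rows.append(
            {
                "clause": cl.key,
                "value": value,
                "min": cl.lower,
                "max": cl.upper,
                "passed": holds,
                "missing": missing,
            }
        )
    return ok, pd.DataFrame(rows).set_index("clause")


def evaluate_success_batch(metrics: pd.DataFrame, criteria: SuccessCriteria) -> pd.Series:
    """Vectorized pass/fail over the rows of a metrics table."""
    ok = pd.Series(True, index=metrics.index)
    for cl in criteria.clauses:
        if cl.key not in metrics.columns:
            ok[:] = False
            break
        v = metrics[cl.key]
        good = v.notna()
        if cl.lower is not None:
            good &= (v > cl.lower) if cl.lower_strict else (v >= cl.lower)
        if cl.upper is not None:
            good &= (v < cl.upper) if cl.upper_strict else (v <= cl.upper)
        ok &= good
    return ok
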