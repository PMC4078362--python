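"""Latin hypercube designs and adaptive zooming of parameter ranges.

The parameter space is the coordinate system for the whole fitting loop: a
named, ordered set of parameters, each with a current sampling range and
optional hard physiological constraints.  Successive iterations shrink
(or cautiously extend) the ranges around a *guideline set* of promising
parameter vectors, controlled by an integer zoom stepsize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

STEPSIZE_INITIAL = 4
STEPSIZE_MAX = 20
STEPSIZE_INCREMENT = 2

#: relative width used to re-open a range that collapsed to a single point
DEGENERATE_EPS = 1e-9


class DesignError(ValueError):
    """Invalid design request (bad sample count, inconsistent space...)."""


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered parameter identifiers with ranges and optional hard bounds.

    ``lower``/``upper`` are the *current sampling ranges* (model units) and
    move between iterations; ``hard_lower``/``hard_upper`` are fixed a-priori
    constraints (``-inf``/``+inf`` where one-sided or absent) that every
    proposed range is clamped to.
    """

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    hard_lower: np.ndarray = field(default=None)  # type: ignore[assignment]
    hard_upper: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        p = len(names)
        if lower.shape != (p,) or upper.shape != (p,):
            raise DesignError("lower/upper must have one entry per parameter")
        hl = self.hard_lower
        hu = self.hard_upper
        hl = np.full(p, -np.inf) if hl is None else np.asarray(hl, dtype=float)
        hu = np.full(p, np.inf) if hu is None else np.asarray(hu, dtype=float)
        if np.any(hl > hu):
            raise DesignError("hard_lower must not exceed hard_upper")
        if np.any(lower > upper):
            raise DesignError("lower must not exceed upper")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        object.__setattr__(self, "hard_lower", hl)
        object.__setattr__(self, "hard_upper", hu)

    # -- convenience ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lower": self.lower,
                "upper": self.upper,
                "hard_lower": self.hard_lower,
                "hard_upper": self.hard_upper,
            },
            index=list(self.names),
        )

    def with_ranges(self, lower: np.ndarray, upper: np.ndarray) -> "ParameterSpace":
        return ParameterSpace(self.names, lower, upper, self.hard_lower, self.hard_upper)

    def drop(self, names: Iterable[str]) -> "ParameterSpace":
        """Return a space without the given parameters (e.g. pinned ones)."""
        drop = set(names)
        keep = [i for i, n in enumerate(self.names) if n not in drop]
        if not keep:
            raise DesignError("cannot drop every parameter")
        idx = np.asarray(keep)
        return ParameterSpace(
            tuple(self.names[i] for i in keep),
            self.lower[idx],
            self.upper[idx],
            self.hard_lower[idx],
            self.hard_upper[idx],
        )

    # -- config round-trip ------------------------------------------------

    @classmethod
    def from_config(cls, source) -> "ParameterSpace":
        """Build from a YAML path/stream or an already-parsed list of dicts.

        Each entry: ``{name, min, max, hard_min?, hard_max?}`` (one-sided hard
        bounds allowed; missing sides are unbounded).
        """
        if isinstance(source, (list, tuple)):
            entries = source
        else:
            if hasattr(source, "read"):
                doc = yaml.safe_load(source)
            else:
                with open(source) as fh:
                    doc = yaml.safe_load(fh)
            entries = doc["parameters"] if isinstance(doc, dict) else doc
        names, lo, hi, hlo, hhi = [], [], [], [], []
        for e in entries:
            names.append(e["name"])
            lo.append(float(e["min"]))
            hi.append(float(e["max"]))
            hlo.append(float(e.get("hard_min", -np.inf)) if e.get("hard_min") is not None else -np.inf)
            hhi.append(float(e.get("hard_max", np.inf)) if e.get("hard_max") is not None else np.inf)
        return cls(tuple(names), np.array(lo), np.array(hi), np.array(hlo), np.array(hhi))

    def to_config(self, path=None):
        entries = []
        for i, n in enumerate(self.names):
            e = {"name": n, "min": float(self.lower[i]), "max": float(self.upper[i])}
            if np.isfinite(self.hard_lower[i]):
                e["hard_min"] = float(self.hard_lower[i])
            if np.isfinite(self.hard_upper[i]):
                e["hard_max"] = float(self.hard_upper[i])
            entries.append(e)
        doc = {"parameters": entries}
        if path is not None:
            with open(path, "w") as fh:
                yaml.safe_dump(doc, fh, sort_keys=False)
        return doc


@dataclass(frozen=True)
class DesignMatrix:
    """An ``n x p`` Latin hypercube sample tied to the space it came from."""

    rows: np.ndarray
    space: ParameterSpace
    seed: int

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        if rows.ndim != 2 or rows.shape[1] != len(self.space):
            raise DesignError("rows must be an n x p matrix matching the space")
        object.__setattr__(self, "rows", rows)

    @property
    def n(self) -> int:
        return self.rows.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=list(self.space.names))

    def to_csv(self, path, sidecar=None) -> None:
        """Write the design as CSV; optionally a YAML sidecar with the seed
        and the ranges it was drawn from (provenance for re-runs)."""
        self.to_frame().to_csv(path, index=False)
        if sidecar is not None:
            doc = {"seed": int(self.seed), "space": self.space.to_config()}
            with open(sidecar, "w") as fh:
                yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class IterationState:
    """Mutable state carried across fitting iterations."""

    iteration: int
    stepsize: int
    space: ParameterSpace
    best_rmsd: float = np.inf
    prev_min_rmsd: float = np.inf


def lhd_sample(space: ParameterSpace, n: int, seed: int) -> DesignMatrix:
    """Draw a plain Latin hypercube design over the current ranges.

    Each column is stratified into ``n`` equal-width bins of its range with
    exactly one uniform draw per bin, independently permuted per column.  No
    space-filling optimisation (maximin etc.) is applied.
    """
    if n < 1:
        raise DesignError(f"sample count must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    p = len(space)
    rows = np.empty((n, p))
    for j in range(p):
        lo, hi = space.lower[j], space.upper[j]
        if hi == lo:
            warnings.warn(
                f"parameter '{space.names[j]}' has a degenerate range; column is constant",
                stacklevel=2,
            )
            rows[:, j] = lo
            # keep the RNG stream aligned across degenerate/non-degenerate cases
            rng.uniform(size=n)
            rng.permutation(n)
            continue
        width = (hi - lo) / n
        strata = lo + width * (np.arange(n) + rng.uniform(size=n))
        rows[:, j] = strata[rng.permutation(n)]
    return DesignMatrix(rows, space, int(seed))


def clamp_to_constraints(space: ParameterSpace) -> ParameterSpace:
    """Move range bounds to the nearest constraint boundary when outside.

    A proposed range disjoint from its constraint interval collapses to the
    constraint interval (with a warning): the a-priori bounds win.
    """
    lo = space.lower.copy()
    hi = space.upper.copy()
    for j, name in enumerate(space.names):
        hlo, hhi = space.hard_lower[j], space.hard_upper[j]
        if hi[j] < hlo or lo[j] > hhi:
            warnings.warn(
                f"proposed range for '{name}' [{lo[j]:g}, {hi[j]:g}] is disjoint from "
                f"its constraints [{hlo:g}, {hhi:g}]; collapsing to the constraints",
                stacklevel=2,
            )
            lo[j] = hlo if np.isfinite(hlo) else hhi
            hi[j] = hhi if np.isfinite(hhi) else hlo
            continue
        lo[j] = min(max(lo[j], hlo), hhi)
        hi[j] = min(max(hi[j], hlo), hhi)
    return space.with_ranges(lo, hi)


def update_ranges(
    guideline,
    stepsize: float,
    space: ParameterSpace,
    degenerate_eps: float = DEGENERATE_EPS,
) -> ParameterSpace:
    """New sampling ranges: guideline hull extended by ``|mean| / stepsize``.

    Per parameter ``i`` with guideline column ``X1_i``::

        new_upper_i = max(X1_i) + |mean(X1_i)| / stepsize
        new_lower_i = min(X1_i) - |mean(X1_i)| / stepsize

    so a *larger* stepsize gives a *narrower* extension beyond the hull
    (a stronger zoom).  The result is clamped to the hard constraints; a
    range that collapses to a point is re-opened symmetrically by a tiny
    relative epsilon (with a warning).

    ``guideline`` may be a plain ``(m, p)`` array, a DataFrame with parameter
    columns, or any object exposing ``.params`` as such a DataFrame.
    """
    if stepsize <= 0:
        raise DesignError("stepsize must be positive")
    X1 = getattr(guideline, "params", guideline)
    if isinstance(X1, pd.DataFrame):
        X1 = X1[list(space.names)].to_numpy(dtype=float)
    else:
        X1 = np.asarray(X1, dtype=float)
        if X1.ndim == 1:
            X1 = X1[None, :]
    if X1.shape[0] == 0:
        raise DesignError("guideline set is empty")
    if X1.shape[1] != len(space):
        raise DesignError("guideline columns do not match the parameter space")

    ext = np.abs(X1.mean(axis=0)) / float(stepsize)
    lo = X1.min(axis=0) - ext
    hi = X1.max(axis=0) + ext
    out = clamp_to_constraints(space.with_ranges(np.minimum(lo, hi), np.maximum(lo, hi)))

    lo, hi = out.lower.copy(), out.upper.copy()
    degenerate = hi <= lo
    if np.any(degenerate):
        for j in np.flatnonzero(degenerate):
            eps = degenerate_eps * max(1.0, abs(lo[j]))
            warnings.warn(
                f"range for '{space.names[j]}' is degenerate; widening by {eps:g}",
                stacklevel=2,
            )
            lo[j] -= eps
            hi[j] += eps
            # stay inside the constraints if they pinched the range
            lo[j] = max(lo[j], space.hard_lower[j])
            hi[j] = min(hi[j], space.hard_upper[j])
            if hi[j] <= lo[j]:  # constraints themselves are a point
                hi[j] = lo[j] + eps
    return out.with_ranges(lo, hi)


def adapt_stepsize(stepsize: int, improved: bool) -> int:
    """One move of the zoom schedule.

    Starts at 4; +2 whenever the best PCA-score RMSD decreased, capped at 20;
    at the cap, a non-improving iteration backs off by 2; below the cap a
    non-improving iteration leaves the stepsize unchanged.
    """
    s = int(stepsize)
    if not (2 <= s <= STEPSIZE_MAX):
        raise DesignError(f"stepsize {s} outside [2, {STEPSIZE_MAX}]")
    if improved:
        return min(s + STEPSIZE_INCREMENT, STEPSIZE_MAX)
    if s == STEPSIZE_MAX:
        return s - STEPSIZE_INCREMENT
    return s
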