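"""Descriptor vectors for twitch tension transients and force-pCa curves.

Simulated curves are reduced to the small set of metrics muscle
physiologists routinely report: for a twitch, time to peak (TTP), times from
peak to 50% and 90% relaxation (RT50/RT90), peak and minimum tension; for
the steady-state force-pCa relationship, the slope/intercept/goodness of a
straight-line fit in Hill-linearized coordinates, the maximal tension, and
an RMS distance to a target force curve in standardized variables.

Conventions (the literature leaves some latitude):

* TTP is measured from the first sample of the record (stimulus at t=0).
* RTx is the first time after the peak at which tension falls to
  ``Peak - x/100 * (Peak - Min)``, located by linear interpolation, minus
  the peak time.
* pCa is -log10 of [Ca] in mol/L; the Hill linearization uses
  ``y = log10(F / (1 - F))`` with F normalized by the maximal simulated
  tension, so |slope| is an apparent Hill coefficient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: rows with (1 - F) below this are dropped before the Hill fit to avoid
#: log blow-up at saturation
HILL_SATURATION_FILTER = 1e-3

TWITCH_METRIC_NAMES = ("RT50", "RT90", "TTP", "Peak", "Min")
FPCA_METRIC_NAMES = ("Slope", "Intercept", "RMSEP", "R2force", "Max", "RMSDforce")


class UndefinedMetricsError(ValueError):
    """The record is degenerate (e.g. flat) and the metrics are undefined."""


class InsufficientDataError(ValueError):
    """Too few points survive filtering to fit anything."""


def metric_key(metric: str, lam: float) -> str:
    """Canonical column name for a metric at a length factor, e.g. 'RT50@1'."""
    return f"{metric}@{lam:g}"


@dataclass(frozen=True)
class TensionTransient:
    """Active tension vs time (ms, kPa) at one relative cell length."""

    time: np.ndarray
    tension: np.ndarray
    length_factor: float = 1.0

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.tension, dtype=float)
        if t.size < 3 or t.shape != f.shape:
            raise ValueError("need >= 3 matching (time, tension) samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(f))):
            raise ValueError("non-finite values in transient")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "tension", f)


@dataclass(frozen=True)
class TwitchMetrics:
    rt50: float
    rt90: float
    ttp: float
    peak: float
    min: float

    def as_series(self) -> pd.Series:
        return pd.Series(
            [self.rt50, self.rt90, self.ttp, self.peak, self.min],
            index=list(TWITCH_METRIC_NAMES),
        )


@dataclass(frozen=True)
class FpcaCurve:
    """Steady-state tension (kPa) per pCa sample at one length factor."""

    pca: np.ndarray
    force: np.ndarray
    length_factor: float = 1.0

    def __post_init__(self):
        x = np.asarray(self.pca, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if x.shape != f.shape or x.ndim != 1:
            raise ValueError("pca and force must be matching 1-D arrays")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(f))):
            raise ValueError("non-finite values in force-pCa curve")
        object.__setattr__(self, "pca", x)
        object.__setattr__(self, "force", f)


@dataclass(frozen=True)
class FpcaMetrics:
    slope: float
    intercept: float
    rmsep: float
    r2force: float
    max: float
    rmsd_force: float = math.nan  # NaN when no target curve was supplied

    def as_series(self) -> pd.Series:
        return pd.Series(
            [self.slope, self.intercept, self.rmsep, self.r2force, self.max, self.rmsd_force],
            index=list(FPCA_METRIC_NAMES),
        )


@dataclass(frozen=True)
class ForceScaler:
    """Per-pCa-point mean/SD used to standardize force curves for RMSDforce."""

    pca: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    @classmethod
    def fit(cls, pca: np.ndarray, forces: np.ndarray) -> "ForceScaler":
        forces = np.asarray(forces, dtype=float)
        means = forces.mean(axis=0)
        sds = forces.std(axis=0, ddof=1)
        # points with (numerically) no batch spread contribute raw differences
        sds = np.where(sds > 1e-9 * np.maximum(1.0, np.abs(means)), sds, 1.0)
        return cls(np.asarray(pca, dtype=float), means, sds)


def transient_metrics(tr: TensionTransient, amplitude_floor: float = 1e-9) -> TwitchMetrics:
    """Reduce a twitch to (RT50, RT90, TTP, Peak, Min).

    Raises :class:`UndefinedMetricsError` on a flat record.  An RTx level that
    is never reached within the record is reported as NaN (caller flags the
    row as incomplete).
    """
    t, f = tr.time, tr.tension
    peak_idx = int(np.argmax(f))
    peak = float(f[peak_idx])
    fmin = float(f.min())
    amplitude = peak - fmin
    if amplitude <= amplitude_floor:
        raise UndefinedMetricsError("flat transient: twitch metrics are undefined")
    ttp = float(t[peak_idx] - t[0])

    def relax_time(frac: float) -> float:
        level = peak - frac * amplitude
        seg_t, seg_f = t[peak_idx:], f[peak_idx:]
        below = np.flatnonzero(seg_f <= level)
        # the peak sample itself is above the level by construction
        below = below[below > 0]
        if below.size == 0:
            return math.nan
        i = int(below[0])
        f0, f1 = seg_f[i - 1], seg_f[i]
        t0, t1 = seg_t[i - 1], seg_t[i]
        if f1 == f0:
            tc = t1
        else:
            tc = t0 + (level - f0) * (t1 - t0) / (f1 - f0)
        return float(tc - t[peak_idx])

    return TwitchMetrics(relax_time(0.5), relax_time(0.9), ttp, peak, fmin)


def hill_linearize(curve: FpcaCurve):
    """Normalize, filter and log-transform a force-pCa curve.

    Force is normalized to [0, 1] by its maximum; saturated rows with
    ``(1 - F) < 1e-3`` and non-positive rows are removed; the surviving
    ``(pCa, log10(F / (1 - F)))`` pairs are returned in ascending pCa order.
    """
    fmax = curve.force.max()
    if fmax <= 0:
        raise InsufficientDataError("curve has no positive force")
    F = curve.force / fmax
    keep = (F > 0) & ((1.0 - F) >= HILL_SATURATION_FILTER)
    if keep.sum() < 4:
        raise InsufficientDataError(
            f"only {int(keep.sum())} points survive the saturation filter (need >= 4)"
        )
    x = curve.pca[keep]
    Fk = F[keep]
    y = np.log10(Fk / (1.0 - Fk))
    order = np.argsort(x, kind="stable")
    return x[order], y[order]


def fpca_metrics(
    curve: FpcaCurve,
    target: Optional[FpcaCurve] = None,
    scaler: Optional[ForceScaler] = None,
) -> FpcaMetrics:
    """Straight-line Hill fit by ordinary least squares, plus target distance.

    ``RMSDforce`` compares max-normalized forces on the curve's pCa grid,
    standardized point-wise by ``scaler`` when one is supplied (the batch
    statistics of the surrounding experiment); it is NaN without a target.
    Mismatched target grids are linearly re-gridded with a warning.
    """
    x, y = hill_linearize(curve)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    resid = y - yhat
    rmsep = float(np.sqrt(np.mean(resid**2)))
    if np.allclose(y, y[0]):
        r2 = 0.0
    elif rmsep < 1e-14:
        r2 = 1.0
    else:
        r2 = float(np.corrcoef(yhat, y)[0, 1] ** 2)

    rmsd_force = math.nan
    if target is not None:
        f_sim = curve.force / curve.force.max()
        tgt_pca, tgt_force = target.pca, target.force
        if tgt_pca.shape != curve.pca.shape or not np.allclose(tgt_pca, curve.pca):
            warnings.warn("target pCa grid differs; re-gridding by linear interpolation")
            lo = max(curve.pca.min(), tgt_pca.min())
            hi = min(curve.pca.max(), tgt_pca.max())
            grid = curve.pca[(curve.pca >= lo) & (curve.pca <= hi)]
            order = np.argsort(tgt_pca)
            tgt_force = np.interp(grid, tgt_pca[order], tgt_force[order])
            f_sim = f_sim[(curve.pca >= lo) & (curve.pca <= hi)]
            sc_grid = grid
        else:
            sc_grid = curve.pca
        f_tgt = tgt_force / tgt_force.max()
        if scaler is not None:
            if scaler.pca.shape == sc_grid.shape and np.allclose(scaler.pca, sc_grid):
                sds = scaler.sds
            else:
                order = np.argsort(scaler.pca)
                sds = np.interp(sc_grid, scaler.pca[order], scaler.sds[order])
            diff = (f_sim - f_tgt) / sds
        else:
            diff = f_sim - f_tgt
        rmsd_force = float(np.sqrt(np.mean(diff**2)))

    return FpcaMetrics(
        float(slope), float(intercept), rmsep, r2, float(curve.force.max()), rmsd_force
    )


def metric_names(lams: Sequence[float]) -> list[str]:
    """Deterministic column order of the full metric vector."""
    names = []
    for lam in sorted(lams):
        for m in TWITCH_METRIC_NAMES:
            names.append(metric_key(m, lam))
        for m in FPCA_METRIC_NAMES:
            names.append(metric_key(m, lam))
    return names


def assemble_metric_vector(
    twitch: Mapping[float, TwitchMetrics],
    fpca: Mapping[float, FpcaMetrics],
) -> pd.Series:
    """Concatenate per-length metrics into one named vector.

    Twitch and force-pCa blocks must cover the same length factors; missing
    individual metrics propagate as NaN entries.
    """
    if not twitch or not fpca:
        raise ValueError("empty metric input")
    if set(twitch) != set(fpca):
        raise ValueError(
            f"inconsistent length factors: twitch {sorted(twitch)} vs fpca {sorted(fpca)}"
        )
    values: dict[str, float] = {}
    for lam in sorted(twitch):
        tw = twitch[lam].as_series()
        fp = fpca[lam].as_series()
        for m in TWITCH_METRIC_NAMES:
            values[metric_key(m, lam)] = float(tw[m])
        for m in FPCA_METRIC_NAMES:
            values[metric_key(m, lam)] = float(fp[m])
    return pd.Series(values, index=metric_names(sorted(twitch)))
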