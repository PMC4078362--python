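"""Bundled synthetic test system: calcium transient + minimal twitch model.

The fitting framework is simulator-agnostic; to exercise every stage
without external model code it ships a deliberately minimal two-state model
of cardiac twitch tension with known ground truth:

* a mouse-like intracellular calcium transient (fast two-exponential pulse,
  diastolic ~0.1 uM, peak ~1 uM, decay time constant ~20 ms at 37 C),
* troponin-like activation ``b`` relaxing toward a Hill function of calcium
  with rate ``k_off``, and tension ``F`` relaxing toward ``Fmax(lambda)*b``
  with rate ``alpha_r``,
* length-dependence through ``Fmax(lambda) = Tref*(1 + beta0*(lambda-1))``
  (filament overlap) and ``Ca50(lambda) = Ca50ref*(1 + beta1*(lambda-1))``
  (length-dependent calcium sensitivity, ``beta1 < 0``: longer = more
  sensitive),
* an exactly-Hill steady-state force-pCa curve (closed form), and
* a *vestigial* parameter the equations never read -- a built-in
  non-identifiability control for the sloppiness machinery.

This is a test harness, not a biophysical model: no crossbridge states, no
velocity dependence, no ATP kinetics.  Any real contraction model can be
plugged into the pipeline through the same simulator contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .design import ParameterSpace
from .metrics import (
    FpcaCurve,
    FpcaMetrics,
    TensionTransient,
    assemble_metric_vector,
    fpca_metrics,
    metric_key,
    transient_metrics,
)
from .lookup import Clause, SuccessCriteria, TargetMetrics

DEFAULT_LAMBDAS = (0.9, 1.0, 1.1)


@dataclass(frozen=True)
class CaTransient:
    """Two-exponential intracellular calcium pulse (uM vs ms)."""

    time: np.ndarray
    concentration: np.ndarray
    diastolic: float
    peak: float
    tau_rise: float
    tau_decay: float

    @property
    def peak_time(self) -> float:
        """Analytic peak time of the continuous pulse."""
        tr, td = self.tau_rise, self.tau_decay
        return math.log(td / tr) * tr * td / (td - tr)


def gen_ca_transient(
    diastolic: float = 0.1,
    peak: float = 1.0,
    tau_rise: float = 5.0,
    tau_decay: float = 20.0,
    duration: float = 160.0,
    dt: float = 0.5,
) -> CaTransient:
    """C(t) = diastolic + A*(exp(-t/tau_decay) - exp(-t/tau_rise)).

    The amplitude A is normalized so the maximum over the sampled grid
    equals ``peak`` exactly.  Units: ms and uM.
    """
    if tau_rise >= tau_decay:
        raise ValueError("tau_rise must be smaller than tau_decay")
    if duration <= 5 * tau_decay:
        raise ValueError("duration must exceed 5 * tau_decay")
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    shape = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    A = (peak - diastolic) / shape.max()
    conc = diastolic + A * shape
    return CaTransient(t, conc, diastolic, peak, tau_rise, tau_decay)


@dataclass(frozen=True)
class ToyModelParams:
    """Ground-truth-style parameters of the minimal twitch model.

    Units: ca50ref in uM, rates in 1/ms, t_ref in kPa; n_h, beta0, beta1 and
    the inert ``vestigial`` are dimensionless.
    """

    ca50ref: float = 0.5
    n_h: float = 5.0
    k_off: float = 0.15
    alpha_r: float = 0.08
    t_ref: float = 120.0
    beta0: float = 1.65
    beta1: float = -1.5
    vestigial: float = 0.5

    def __post_init__(self):
        if min(self.ca50ref, self.k_off, self.alpha_r, self.t_ref) <= 0:
            raise ValueError("rates, tensions and concentrations must be positive")
        if self.n_h < 1:
            raise ValueError("Hill coefficient must be >= 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "Ca50ref": self.ca50ref,
            "nH": self.n_h,
            "k_off": self.k_off,
            "alpha_r": self.alpha_r,
            "Tref": self.t_ref,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "vestigial": self.vestigial,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ToyModelParams":
        return cls(
            ca50ref=float(d["Ca50ref"]),
            n_h=float(d["nH"]),
            k_off=float(d["k_off"]),
            alpha_r=float(d["alpha_r"]),
            t_ref=float(d["Tref"]),
            beta0=float(d["beta0"]),
            beta1=float(d["beta1"]),
            vestigial=float(d.get("vestigial", 0.0)),
        )


PARAM_NAMES = tuple(ToyModelParams().as_dict().keys())


def toy_parameter_space() -> ParameterSpace:
    """Initial sampling ranges and hard constraints for the toy-model fit.

    Ranges bracket the ground truth generously (the fit has to find it);
    hard bounds encode a-priori physiology: Hill coefficients stay in
    [1, 15], reference tension in [90, 140] kPa, overlap effect capped at 6.
    """
    entries = [
        {"name": "Ca50ref", "min": 0.3, "max": 0.8, "hard_min": 0.1, "hard_max": 1.5},
        {"name": "nH", "min": 2.0, "max": 9.0, "hard_min": 1.0, "hard_max": 15.0},
        {"name": "k_off", "min": 0.05, "max": 0.4, "hard_min": 0.01, "hard_max": 1.0},
        {"name": "alpha_r", "min": 0.02, "max": 0.2, "hard_min": 0.005, "hard_max": 0.5},
        {"name": "Tref", "min": 100.0, "max": 140.0, "hard_min": 90.0, "hard_max": 140.0},
        {"name": "beta0", "min": 1.0, "max": 5.0, "hard_min": 0.0, "hard_max": 6.0},
        {"name": "beta1", "min": -2.0, "max": -1.0, "hard_min": -8.0, "hard_max": 0.0},
        {"name": "vestigial", "min": 0.0, "max": 1.0},
    ]
    return ParameterSpace.from_config(entries)


def default_fpca_grid() -> np.ndarray:
    """82 log-spaced calcium concentrations in [0.15, 1] uM plus 10 uM."""
    return np.concatenate([np.geomspace(0.15, 1.0, 82), [10.0]])


def _hill(ca, k, n):
    x = (np.asarray(ca, dtype=float) / k) ** n
    return x / (1.0 + x)


def _ca50(p: Mapping[str, float], lam: float) -> float:
    return p["Ca50ref"] * (1.0 + p["beta1"] * (lam - 1.0))


def _fmax(p: Mapping[str, float], lam: float) -> float:
    return p["Tref"] * (1.0 + p["beta0"] * (lam - 1.0))


def simulate_twitch_batch(
    params: pd.DataFrame, lam: float, ca: CaTransient
) -> np.ndarray:
    """Tension transients (rows x times, kPa) for many parameter sets at once.

    The two linear relaxation ODEs are integrated with an exact exponential
    step assuming the forcing is linear within each sampling interval of the
    calcium record -- machine-precision for the activation stage driven by
    the sampled transient, and cheap enough to run whole designs.
    """
    t = ca.time
    dt = float(t[1] - t[0])
    names = list(PARAM_NAMES)
    P = {n: params[n].to_numpy(dtype=float) for n in names if n in params.columns}
    for n in ("Ca50ref", "nH", "k_off", "alpha_r", "Tref", "beta0", "beta1"):
        if n not in P:
            raise KeyError(f"missing parameter column '{n}'")
    K = P["Ca50ref"] * (1.0 + P["beta1"] * (lam - 1.0))
    Fmax = P["Tref"] * (1.0 + P["beta0"] * (lam - 1.0))
    # rows whose length-adjusted parameters leave the model's valid domain
    # fail individually (NaN transients), not the whole batch
    bad = (K <= 0) | (Fmax <= 0)
    K = np.where(bad, 1.0, K)
    ratio = ca.concentration[None, :] / K[:, None]
    H = ratio ** P["nH"][:, None]
    H = H / (1.0 + H)

    # activation stage: b' = k_off * (H(Ca(t)) - b), b(0) = H(Ca(0))
    b = _integrate_linear_relax(H, P["k_off"], dt)
    # tension stage: F' = alpha_r * (Fmax*b - F), F(0) = Fmax*b(0)
    F = _integrate_linear_relax(Fmax[:, None] * b, P["alpha_r"], dt)
    F[bad] = np.nan
    return F


def _integrate_linear_relax(forcing: np.ndarray, rate: np.ndarray, dt: float) -> np.ndarray:
    """Exact stepping of x' = rate*(u(t) - x) for piecewise-linear u.

    For u(s) = u0 + (du/dt)*s on a step, the exact update is
    ``x1 = u1 - du/(rate*dt) + (x0 - u0 + du/(rate*dt)) * exp(-rate*dt)``.
    """
    rate = np.asarray(rate, dtype=float)
    E = np.exp(-rate * dt)
    c = 1.0 / (rate * dt)
    out = np.empty_like(forcing)
    x = forcing[:, 0].copy()
    out[:, 0] = x
    for i in range(forcing.shape[1] - 1):
        u0 = forcing[:, i]
        u1 = forcing[:, i + 1]
        du = u1 - u0
        x = (u1 - du * c) + (x - u0 + du * c) * E
        out[:, i + 1] = x
    return out


def simulate_twitch(p: ToyModelParams, lam: float, ca: CaTransient) -> TensionTransient:
    """Single-parameter-set twitch; the vestigial parameter is never read."""
    if not (0.8 <= lam <= 1.2):
        raise ValueError("length factor must be within [0.8, 1.2]")
    df = pd.DataFrame([p.as_dict()])
    F = simulate_twitch_batch(df, lam, ca)
    if np.isnan(F[0]).any():
        raise ValueError("parameters leave the model's valid domain at this length")
    return TensionTransient(ca.time, F[0], lam)


def simulate_fpca(
    p: ToyModelParams, lam: float, ca_grid: Optional[np.ndarray] = None
) -> FpcaCurve:
    """Closed-form steady-state force-pCa curve: F(Ca) = Fmax(lambda)*H(Ca)."""
    grid = default_fpca_grid() if ca_grid is None else np.asarray(ca_grid, dtype=float)
    d = p.as_dict()
    K = _ca50(d, lam)
    force = _fmax(d, lam) * _hill(grid, K, d["nH"])
    pca = -np.log10(grid * 1e-6)  # grid is in uM; pCa is on mol/L
    return FpcaCurve(pca, force, lam)


def simulate_fpca_batch(params: pd.DataFrame, lam: float, ca_grid=None) -> np.ndarray:
    grid = default_fpca_grid() if ca_grid is None else np.asarray(ca_grid, dtype=float)
    K = params["Ca50ref"].to_numpy(float) * (1.0 + params["beta1"].to_numpy(float) * (lam - 1.0))
    Fmax = params["Tref"].to_numpy(float) * (1.0 + params["beta0"].to_numpy(float) * (lam - 1.0))
    x = (grid[None, :] / K[:, None]) ** params["nH"].to_numpy(float)[:, None]
    return Fmax[:, None] * x / (1.0 + x)


def make_reference_target(
    p: Optional[ToyModelParams] = None,
    lams: Sequence[float] = DEFAULT_LAMBDAS,
    ca: Optional[CaTransient] = None,
    ca_grid: Optional[np.ndarray] = None,
) -> TargetMetrics:
    """Full target metric vector from known ground truth.

    RMSDforce entries are zero by definition (the target matches itself);
    the raw force-pCa curves and the generating parameters ride along for
    later distance computations and recovery scoring.
    """
    p = p or ToyModelParams()
    ca = ca or gen_ca_transient()
    twitch = {}
    fpca = {}
    curves = {}
    for lam in lams:
        tr = simulate_twitch(p, lam, ca)
        twitch[lam] = transient_metrics(tr)
        curve = simulate_fpca(p, lam, ca_grid)
        curves[lam] = curve
        fm = fpca_metrics(curve)
        fpca[lam] = FpcaMetrics(fm.slope, fm.intercept, fm.rmsep, fm.r2force, fm.max, 0.0)
    values = assemble_metric_vector(twitch, fpca)
    return TargetMetrics(
        values,
        provenance={"source": "synthetic reference model"},
        force_curves=curves,
        ground_truth=p.as_dict(),
    )


def reference_success_criteria(
    target: TargetMetrics,
    twitch_tolerance: float = 0.25,
    peak_long_tolerance: float = 0.10,
    peak_short_tolerance: float = 0.20,
    min_tension_cap: float = 1.0,
    rmsd_force_cap: float = 0.15,
    lams: Sequence[float] = DEFAULT_LAMBDAS,
) -> SuccessCriteria:
    """Success bands around a synthetic target, mirroring experimental practice.

    Twitch metrics at resting length get symmetric relative bands (default
    +-25%, the typical width of published mouse twitch error bars); peak
    tension at 110% length a tighter +-10% band and at 90% length +-20%;
    minimum tension at 110% length must stay below an absolute 1 kPa; and
    the standardized force-curve RMSD must be below 0.15 at every length.
    """
    v = target.values
    lams = sorted(lams)
    lam_mid = lams[len(lams) // 2]
    lam_hi = lams[-1]
    lam_lo = lams[0]
    clauses = []
    for mname in ("RT50", "RT90", "TTP", "Peak"):
        val = float(v[metric_key(mname, lam_mid)])
        clauses.append(
            Clause(mname, lam_mid, val * (1 - twitch_tolerance), val * (1 + twitch_tolerance))
        )
    peak_hi = float(v[metric_key("Peak", lam_hi)])
    clauses.append(
        Clause("Peak", lam_hi, peak_hi * (1 - peak_long_tolerance), peak_hi * (1 + peak_long_tolerance))
    )
    clauses.append(Clause("Min", lam_hi, None, min_tension_cap, upper_strict=True))
    peak_lo = float(v[metric_key("Peak", lam_lo)])
    clauses.append(
        Clause("Peak", lam_lo, peak_lo * (1 - peak_short_tolerance), peak_lo * (1 + peak_short_tolerance))
    )
    for lam in lams:
        clauses.append(Clause("RMSDforce", lam, None, rmsd_force_cap, upper_strict=True))
    return SuccessCriteria(tuple(clauses))


def toy_simulator(
    pinned: Optional[Mapping[str, float]] = None,
    ca: Optional[CaTransient] = None,
    ca_grid: Optional[np.ndarray] = None,
):
    """Wrap the toy model in the pipeline's simulator contract.

    ``pinned`` fixes parameters (model-reduction switches), e.g.
    ``{"vestigial": 0.0}`` or ``{"nH": 1.0}``; pinned parameters are no
    longer sampled.  Supplies the vectorized batch fast path.
    """
    from .pipeline import SimulatorSpec  # deferred to keep imports acyclic

    ca = ca or gen_ca_transient()
    grid = default_fpca_grid() if ca_grid is None else np.asarray(ca_grid, dtype=float)
    pinned = dict(pinned or {})

    def run(params: Mapping[str, float], lam: float):
        p = ToyModelParams.from_dict({**params, **pinned})
        return simulate_twitch(p, lam, ca), simulate_fpca(p, lam, grid)

    def run_batch(df: pd.DataFrame, lam: float):
        full = df.copy()
        for k, v in pinned.items():
            full[k] = v
        F = simulate_twitch_batch(full, lam, ca)
        forces = simulate_fpca_batch(full, lam, grid)
        return ca.time, F, -np.log10(grid * 1e-6), forces

    return SimulatorSpec("toy-twitch", PARAM_NAMES, run, pinned, run_batch)
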