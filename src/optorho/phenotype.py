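"""Phenotype score gamma, weight calibration and (rho x period) maps.

The morphodynamic outcome of an activation is summarized by a single signed
number comparing the integrated activities of RhoA and Cdc42 over the first
two minutes after activation (the time at which the phenotype is visible):

    gamma = [ w I(r-1) - I(c-1) ] / [ w I|r-1| + I|c-1| ],   I = integral
            over [0, T]

gamma is dimensionless and bounded in [-1, 1]; positive gamma means RhoA
dominates and the cell retracts, negative means Cdc42 dominates and it
protrudes, with a gray zone of half-width epsilon around zero labeled
``mixed``.  The relative weight w of RhoA versus Cdc42 is not measurable
from relocation biosensors, so it is calibrated once: w is the value that
places gamma = 0 at rho = Geq/Kb = 0.5 under a reference sustained step —
the expression level at which mixed phenotypes are observed.  Pulsed-train
phenotype maps are then genuine model output rather than true by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import CalibrationError, ParameterError, WindowError
from .gtpase import KineticParams, simulate_cdc42, simulate_rhoa
from .stimulus import (
    PulseProtocol,
    RecruitmentParams,
    Trace,
    analytic_to_trace,
    constant_input,
    simulate_recruitment,
    step_input,
)

__all__ = [
    "PhenotypeScore",
    "PhenotypeMap",
    "compute_gamma",
    "calibrate_weight",
    "build_phenotype_map",
    "intensity_sweep",
    "label_from_gamma",
]

DEFAULT_WINDOW = 120.0  # s, "first two minutes"
DEFAULT_EPSILON = 0.05  # gray-zone half-width on gamma


@dataclass(frozen=True)
class PhenotypeScore:
    gamma: float
    weight: float
    window: float
    epsilon: float
    label: str  # retraction | protrusion | mixed

    def __post_init__(self):
        if self.window <= 0:
            raise ParameterError("window T must be positive")


@dataclass
class PhenotypeMap:
    """Phenotype label/score surface over expression (rho) and pulse period."""

    rho_grid: np.ndarray
    period_grid: np.ndarray
    gamma: np.ndarray  # shape (n_rho, n_period)
    labels: np.ndarray  # same shape, dtype=object strings
    protocol: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rho_grid = np.asarray(self.rho_grid, dtype=float)
        self.period_grid = np.asarray(self.period_grid, dtype=float)
        want = (self.rho_grid.size, self.period_grid.size)
        if self.gamma.shape != want or self.labels.shape != want:
            raise ParameterError("map matrices must match the grids")

    def switchable_band(self, require_both: bool = True, period_range=None):
        """rho-interval where the label depends on the pulse period.

        With ``require_both`` the band only counts rows showing both a
        protrusion and a retraction across periods (the frequency-switchable
        band proper); otherwise any period-dependence of the label counts.
        ``period_range=(lo, hi)`` restricts the periods considered.
        Returns (rho_lo, rho_hi, rho_center) or None.
        """
        cols = np.ones(self.period_grid.size, dtype=bool)
        if period_range is not None:
            cols = (self.period_grid >= period_range[0] - 1e-9) & (
                self.period_grid <= period_range[1] + 1e-9
            )
        rows = []
        for i in range(self.rho_grid.size):
            row = set(self.labels[i, cols])
            if require_both:
                if {"protrusion", "retraction"} <= row:
                    rows.append(i)
            elif len(row) > 1:
                rows.append(i)
        if not rows:
            return None
        lo, hi = self.rho_grid[rows[0]], self.rho_grid[rows[-1]]
        return float(lo), float(hi), float(0.5 * (lo + hi))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.gamma, index=pd.Index(self.rho_grid, name="rho"),
                            columns=pd.Index(self.period_grid, name="period_s"))

    def save_heatmap(self, path):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.pcolormesh(self.period_grid, self.rho_grid, self.gamma,
                           cmap="RdBu_r", vmin=-1, vmax=1, shading="nearest")
        fig.colorbar(im, ax=ax, label=r"phenotype score $\gamma$")
        ax.set_xlabel("inter-pulse period (s)")
        ax.set_ylabel(r"expression $G_{eq}/K_b$")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def label_from_gamma(gamma: float, epsilon: float = DEFAULT_EPSILON) -> str:
    if gamma > epsilon:
        return "retraction"
    if gamma < -epsilon:
        return "protrusion"
    return "mixed"


def _window_integrals(tr: Trace, T: float):
    """(integral of (x-1), integral of |x-1|) over [0, T], trapezoidal."""
    t, v = tr.times, tr.values
    if t[-1] < T - 1e-9 or t[0] > 1e-9:
        raise WindowError(f"trace [{t[0]:g}, {t[-1]:g}] does not cover [0, {T:g}]")
    m = (t >= -1e-12) & (t <= T + 1e-12)
    tt, vv = t[m], v[m]
    if tt[-1] < T - 1e-12:  # close the window by interpolation
        tt = np.append(tt, T)
        vv = np.append(vv, tr.value_at(T))
    dev = vv - 1.0
    return float(np.trapezoid(dev, tt)), float(np.trapezoid(np.abs(dev), tt))


def compute_gamma(
    r: Trace,
    c: Trace,
    weight: float,
    window: float = DEFAULT_WINDOW,
    epsilon: float = DEFAULT_EPSILON,
    normalized: bool = True,
) -> PhenotypeScore:
    """Phenotype score from free-RhoA and Cdc42 traces.

    ``normalized=False`` returns the raw weighted difference of integrated
    activities (unbounded), kept for sensitivity analysis.
    """
    if weight <= 0:
        raise ParameterError("weight must be positive")
    ir, jr = _window_integrals(r, window)
    ic, jc = _window_integrals(c, window)
    num = weight * ir - ic
    den = weight * jr + jc
    if normalized:
        gamma = 0.0 if den < 1e-12 else num / den
    else:
        gamma = num
    return PhenotypeScore(gamma=float(gamma), weight=weight, window=window,
                          epsilon=epsilon, label=label_from_gamma(gamma, epsilon))


def _step_responses(rho, params: KineticParams, fold, T, dt):
    grid = np.arange(0.0, T + dt / 2, dt)
    ana = step_input(fold, T)
    g = analytic_to_trace(ana, grid)
    kin = KineticParams(k2=params.k2, rho=rho, koff_sensor=params.koff_sensor)
    r = simulate_rhoa(g, kin)
    c = simulate_cdc42(g, kin)
    return r, c


def calibrate_weight(
    params: KineticParams,
    target_rho: float = 0.5,
    fold: float = 2.0,
    window: float = DEFAULT_WINDOW,
    dt: float = 0.5,
    bracket=(1e-3, 1e3),
    xtol: float = 1e-6,
) -> float:
    """RhoA-vs-Cdc42 weight placing gamma = 0 at ``target_rho``.

    Reference stimulus: sustained step of g to ``fold`` held over the scoring
    window.  The root is bracketed and solved to ``xtol``; w > 1 is required
    (RhoA must dominate at low expression, where the cell retracts).
    """
    r, c = _step_responses(target_rho, params, fold, window, dt)

    def f(w):
        return compute_gamma(r, c, w, window=window).gamma

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        w = lo
    elif fhi == 0.0:
        w = hi
    elif flo * fhi > 0:
        raise CalibrationError(
            f"gamma does not change sign on w in [{lo:g}, {hi:g}] "
            f"(gamma({lo:g})={flo:.3g}, gamma({hi:g})={fhi:.3g})"
        )
    else:
        w = brentq(f, lo, hi, xtol=xtol)
    if w <= 1.0:
        raise CalibrationError(f"calibrated weight {w:.4g} <= 1; RhoA must dominate at low rho")
    return float(w)


def build_phenotype_map(
    rho_grid,
    period_grid,
    params: KineticParams,
    weight: float,
    fold: float = 1.5,
    window: float = DEFAULT_WINDOW,
    epsilon: float = DEFAULT_EPSILON,
    recruitment: RecruitmentParams = RecruitmentParams(),
    dt: float = 0.5,
) -> PhenotypeMap:
    """Score a regular pulse train at every (rho, period) grid point.

    The per-pulse amplitude is fixed (``fold``) for every period, so period
    changes frequency at constant pulse strength.  Labels use the calibrated
    weight and the gray-zone rule.
    """
    rho_grid = np.asarray(rho_grid, dtype=float)
    period_grid = np.asarray(period_grid, dtype=float)
    if rho_grid.size == 0 or period_grid.size == 0:
        raise ParameterError("rho and period grids must be non-empty")
    gamma = np.empty((rho_grid.size, period_grid.size))
    labels = np.empty_like(gamma, dtype=object)
    for j, period in enumerate(period_grid):
        # pulses strictly inside the scoring window: a pulse at t = T would
        # jump r at the boundary with zero integrated contribution
        n_pulses = int(np.ceil(window / period - 1e-9))
        protocol = PulseProtocol.regular(float(period), fold, window, n_pulses=n_pulses)
        g = simulate_recruitment(protocol, recruitment, dt=dt)
        c = simulate_cdc42(g, params)  # independent of rho
        for i, rho in enumerate(rho_grid):
            kin = KineticParams(k2=params.k2, rho=float(rho), koff_sensor=params.koff_sensor)
            r = simulate_rhoa(g, kin)
            score = compute_gamma(r, c, weight, window=window, epsilon=epsilon)
            gamma[i, j] = score.gamma
            labels[i, j] = score.label
    return PhenotypeMap(rho_grid, period_grid, gamma, labels,
                        protocol={"amplitude_fold": fold, "window_s": window, "dt_s": dt})


def intensity_sweep(
    rho: float,
    period: float,
    params: KineticParams,
    weight: float,
    fold_range=(1.1, 3.0),
    n_folds: int = 20,
    window: float = DEFAULT_WINDOW,
    epsilon: float = DEFAULT_EPSILON,
    recruitment: RecruitmentParams = RecruitmentParams(),
    dt: float = 0.5,
):
    """Labels across per-pulse fold at fixed rho and period.

    The model is linear in the input amplitude, so no label switch between
    protrusion and retraction is expected within the measurable fold range;
    ``switched`` flags the unexpected case.  fold = 1 is the null stimulus
    (gamma = 0, mixed).
    """
    kin = KineticParams(k2=params.k2, rho=float(rho), koff_sensor=params.koff_sensor)
    folds = np.linspace(fold_range[0], fold_range[1], n_folds)
    results = []
    grid = np.arange(0.0, window + dt / 2, dt)
    for fold in folds:
        if fold <= 1.0 + 1e-12:
            g = analytic_to_trace(constant_input(window), grid)
        else:
            protocol = PulseProtocol.regular(float(period), float(fold), window)
            g = simulate_recruitment(protocol, recruitment, dt=dt)
        r = simulate_rhoa(g, kin)
        c = simulate_cdc42(g, kin)
        score = compute_gamma(r, c, weight, window=window, epsilon=epsilon)
        results.append((float(fold), score.gamma, score.label))
    present = {lab for _, _, lab in results}
    switched = {"protrusion", "retraction"} <= present
    return {"labels": results, "switched": switched}
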