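"""Quasi-steady-state model of free active RhoA under GEF sequestration.

The GEF (optoPRG) activates RhoA by mass action; its PH domain also binds
RhoA-GTP into a signaling-dead complex GR with dissociation constant Kb,
while the complexed GEF stays catalytically active.  With the normalizations
r = R/Req and g = Gtot/Geq, a fast binding equilibrium gives the main
equation integrated here:

    dr/dt = [ k2 (g - r) - rho * r * dg/dt ] / (1 + rho * g),    rho = Geq/Kb

Across an instantaneous pulse of g (jump by delta at t0) the k2 term is
negligible and r jumps analytically:

    r+ = r- * (1 + rho * g-) / (1 + rho * g+)

Cdc42 is activated by the same GEF with the shared deactivation rate k2 and
no sequestration (dc/dt = k2 (g - c)), and the relocation biosensor tracks
free active RhoA as a first-order follower (db/dt = koff (r - b)).

``simulate_full`` integrates the un-approximated mass-action system and
serves as the independent oracle for the QSSA in the fast-binding limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp
from scipy.signal import savgol_filter

from .errors import InvariantError, NumericalError, ParameterError
from .stimulus import AnalyticInput, Trace

__all__ = [
    "KineticParams",
    "FullModelParams",
    "SimResult",
    "simulate_rhoa",
    "simulate_cdc42",
    "simulate_biosensor",
    "simulate_full",
    "simulate_cell",
    "relax_piecewise_linear",
    "pulse_jump_factor",
]

_RTOL = 1e-8
_ATOL = 1e-10


@dataclass(frozen=True)
class KineticParams:
    """Effective-model rates.

    k2: endogenous GAP-mediated deactivation rate (1/s), shared by RhoA and
        Cdc42; point estimate 0.014 1/s.
    rho: Geq/Kb, basal GEF level relative to the GR dissociation constant;
        the single per-cell free parameter.
    koff_sensor: RBD biosensor unbinding rate (1/s), point estimate 0.08 1/s.
    """

    k2: float = 0.014
    rho: float = 0.0
    koff_sensor: float = 0.08

    def __post_init__(self):
        if self.k2 <= 0:
            raise ParameterError("k2 must be positive")
        if self.rho < 0:
            raise ParameterError("rho (Geq/Kb) must be non-negative")
        if self.koff_sensor <= 0:
            raise ParameterError("koff_sensor must be positive")


@dataclass(frozen=True)
class FullModelParams:
    """Mass-action parameters for the un-approximated sequestration model."""

    kon_bind: float  # 1/(conc s)
    koff_bind: float  # 1/s
    Geq: float  # basal free GEF concentration
    Req: float  # basal free active RhoA concentration

    def __post_init__(self):
        for name in ("kon_bind", "koff_bind", "Geq", "Req"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")

    @property
    def Kb(self) -> float:
        return self.koff_bind / self.kon_bind

    @property
    def rho(self) -> float:
        """Matched QSSA sequestration parameter Geq/Kb."""
        return self.Geq / self.Kb


@dataclass
class SimResult:
    """Aligned simulated channels plus the parameters that produced them."""

    g: Trace
    r: Trace | None = None
    c: Trace | None = None
    b: Trace | None = None
    params: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        for tr in (self.r, self.c, self.b):
            if tr is not None:
                if tr.times.shape != self.g.times.shape or not np.allclose(
                    tr.times, self.g.times
                ):
                    raise InvariantError("all SimResult traces must share one grid")
                if np.any(tr.values <= 0):
                    raise InvariantError("activities must stay positive")

    def to_csv(self, path, sidecar: str | None = None) -> None:
        cols = {"time_s": self.g.times, "g": self.g.values}
        for name, tr in (("r", self.r), ("c", self.c), ("b", self.b)):
            if tr is not None:
                cols[name] = tr.values
        pd.DataFrame(cols).to_csv(path, index=False)
        if sidecar:
            with open(sidecar, "w") as fh:
                yaml.safe_dump({"params": self.params, "diagnostics": self.diagnostics}, fh)


def pulse_jump_factor(rho: float, g_minus: float, g_plus: float) -> float:
    """Multiplicative jump of r across an instantaneous pulse of g."""
    return (1.0 + rho * g_minus) / (1.0 + rho * g_plus)


def _require_analytic(g: Trace) -> AnalyticInput | None:
    ana = g.meta.get("analytic")
    return ana if isinstance(ana, AnalyticInput) else None


def _integrate_analytic(times, ana, rhs_for_segment, jump_map=None, rtol=_RTOL, atol=_ATOL):
    """Integrate a scalar ODE driven by a piecewise-analytic input.

    ``rhs_for_segment(seg)`` returns f(t, y) valid inside that segment.
    ``jump_map(state, g_minus, g_plus)`` is applied at input jump times (the
    state is continuous when jump_map is None).  Returns (values, jumps)
    where jumps lists (time, pre_value, post_value) of applied state jumps.
    """
    t0, tN = times[0], times[-1]
    jump_lookup = {}
    if jump_map is not None:
        for tj, gm, gp in ana.jumps:
            if t0 <= tj <= tN:
                jump_lookup[tj] = (gm, gp)
    bps = {t0, tN}
    bps.update(jump_lookup)
    for seg in ana.segments:
        if t0 < seg.t0 < tN:
            bps.add(seg.t0)
    bps = sorted(bps)

    out = np.empty_like(times)
    state = 1.0
    applied_jumps = []
    for k, a in enumerate(bps):
        if a in jump_lookup:
            gm, gp = jump_lookup[a]
            pre = state
            state = jump_map(state, gm, gp)
            applied_jumps.append((a, pre, state))
        out[np.isclose(times, a, rtol=0, atol=1e-9)] = state
        if k == len(bps) - 1:
            break
        b = bps[k + 1]
        seg_idx = int(ana._idx(0.5 * (a + b)))
        rhs = rhs_for_segment(ana.segments[seg_idx])
        interior = times[(times > a + 1e-9) & (times < b - 1e-9)]
        t_eval = np.concatenate([interior, [b]])
        sol = solve_ivp(rhs, (a, b), [state], t_eval=t_eval, rtol=rtol, atol=atol, method="RK45")
        if not sol.success:
            raise NumericalError(
                f"integration failed on [{a:g}, {b:g}]: {sol.message}",
                {"interval": (a, b), "message": sol.message},
            )
        y = sol.y[0]
        if interior.size:
            out[(times > a + 1e-9) & (times < b - 1e-9)] = y[:-1]
        state = y[-1]
    return out, applied_jumps


def simulate_rhoa(
    g: Trace,
    params: KineticParams,
    smooth_window: int = 5,
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> Trace:
    """Free active RhoA r(t) from a GEF trace via the main QSSA equation.

    Synthetic inputs carrying their piecewise-analytic form are integrated
    segment-by-segment with the analytic derivative, applying the exact jump
    map at pulses.  Measured (sampled) inputs go through local quadratic
    smoothing (Savitzky-Golay, ``smooth_window`` points) for dg/dt followed
    by an exponential midpoint integrator.
    """
    k2, rho = params.k2, params.rho
    ana = _require_analytic(g)
    if ana is not None:

        def rhs_for_segment(seg):
            t0 = seg.t0

            def rhs(t, y):
                gv = seg.g(t - t0)
                return [(k2 * (gv - y[0]) - rho * y[0] * seg.dgdt(t - t0)) / (1.0 + rho * gv)]

            return rhs

        def jump_map(state, gm, gp):
            return state * pulse_jump_factor(rho, gm, gp)

        values, jumps3 = _integrate_analytic(g.times, ana, rhs_for_segment, jump_map, rtol, atol)
        jumps = [(t, pre) for t, pre, _ in jumps3]
    else:
        pulse_idx = _pulse_indices(g.times, g.meta.get("pulse_times", ()))
        values, jumps = _integrate_qssa_sampled(
            g.times, g.values, k2, rho, smooth_window, pulse_idx
        )
    if np.any(values <= 0):
        raise InvariantError("simulated r became non-positive")
    meta = {"params": params, "jumps": jumps}
    return Trace(g.times, values, channel="r", meta=meta)


def _pulse_indices(times, pulse_times):
    """Map known pulse times to sample indices (ignoring off-grid pulses)."""
    idx = []
    for tp in pulse_times:
        hits = np.flatnonzero(np.isclose(times, tp, rtol=0, atol=1e-6))
        if hits.size and hits[0] > 0:
            idx.append(int(hits[0]))
    return sorted(set(idx))


def _segment_smooth_derivative(times, gvals, window, pulse_idx):
    """Smoothed g and dg/dt, computed per inter-pulse segment.

    Smoothing windows never straddle a pulse discontinuity, which would
    otherwise contaminate the derivative near jumps.
    """
    n = times.size
    gs = np.array(gvals, dtype=float)
    dg = np.empty(n)
    bounds = [0] + list(pulse_idx) + [n]
    dt = np.diff(times)
    uniform = np.allclose(dt, dt[0]) if dt.size else True
    w = window if window % 2 == 1 else window + 1
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a >= 2:
            seg = gvals[a:b]
            if uniform and w >= 5 and b - a > w:
                seg = savgol_filter(seg, w, 2)
            gs[a:b] = seg
            dg[a:b] = np.gradient(gs[a:b], times[a:b])
        elif b - a == 1:
            dg[a] = 0.0
    return gs, dg


def _integrate_qssa_sampled(times, gvals, k2, rho, window, pulse_idx=()):
    """Integrate the main equation on sampled g via the total-activity form.

    The substitution T = r (1 + rho g) (total active RhoA, free + complexed)
    turns the main equation into dT/dt = k2 (g - T / (1 + rho g)): T is
    continuous across pulses and no dg/dt appears, so measured (noisy,
    jumpy) inputs integrate without numerical differentiation.  g is lightly
    smoothed per inter-pulse segment (Savitzky-Golay, quadratic) before use;
    the step update freezes coefficients at interval midpoints and solves
    each linear step exactly.  Returns (r, jumps) with the pre-pulse r value
    recorded at each known pulse sample.
    """
    n = times.size
    dt = np.diff(times)
    pulse_set = set(pulse_idx)
    gs, _ = _segment_smooth_derivative(times, gvals, window, sorted(pulse_set))
    denom = 1.0 + rho * gs
    alpha = k2 * gs
    beta = k2 / denom
    T = np.empty(n)
    T[0] = denom[0]  # equilibrium r = 1
    jumps = []
    for i in range(1, n):
        h = dt[i - 1]
        if i in pulse_set:
            # the jump happens at times[i]: the whole step is pre-pulse
            am, bm = alpha[i - 1], beta[i - 1]
        else:
            am = 0.5 * (alpha[i - 1] + alpha[i])
            bm = 0.5 * (beta[i - 1] + beta[i])
        target = am / bm
        T[i] = target + (T[i - 1] - target) * math.exp(-bm * h)
        if i in pulse_set:
            jumps.append((times[i], T[i] / (1.0 + rho * gs[i - 1])))
    return T / denom, jumps


def simulate_cdc42(g: Trace, params: KineticParams, rtol: float = _RTOL, atol: float = _ATOL) -> Trace:
    """Active Cdc42 c(t): mass-action activation by the GEF, no sequestration.

    dc/dt = k2 (g - c); c is continuous even across pulses of g.
    """
    k2 = params.k2
    ana = _require_analytic(g)
    if ana is not None:

        def rhs_for_segment(seg):
            t0 = seg.t0

            def rhs(t, y):
                return [k2 * (seg.g(t - t0) - y[0])]

            return rhs

        # jumps in g do not touch c, but breaking at them helps the solver
        bps_ana = AnalyticInput(ana.segments, ana.jumps, ana.t_end, ana.baseline)

        def jump_map(state, gm, gp):
            return state

        values, _ = _integrate_analytic(g.times, bps_ana, rhs_for_segment, jump_map, rtol, atol)
    else:
        values = relax_piecewise_linear(g.times, g.values, k2)
    if np.any(values <= 0):
        raise InvariantError("simulated c became non-positive")
    return Trace(g.times, values, channel="c", meta={"params": params})


def relax_piecewise_linear(times, forcing, rate, jumps=None, x0=1.0):
    """Exact solution of dx/dt = rate (f - x) for piecewise-linear f.

    ``forcing`` may be 1-D (n,) or stacked (m, n).  ``jumps`` maps a sample
    index i to the forcing value *just before* times[i] (forcing[i] holding
    the post-jump value), so instantaneous drops are not smeared across the
    sample interval.
    """
    times = np.asarray(times, dtype=float)
    f = np.asarray(forcing, dtype=float)
    one_d = f.ndim == 1
    f = np.atleast_2d(f)
    jumps = jumps or {}
    n = times.size
    out = np.empty_like(f)
    out[:, 0] = x0
    for i in range(1, n):
        h = times[i] - times[i - 1]
        f0 = f[:, i - 1]
        f1 = jumps[i] if i in jumps else f[:, i]
        f1 = np.broadcast_to(np.asarray(f1, dtype=float), f0.shape)
        slope = (f1 - f0) / h
        e = math.exp(-rate * h)
        out[:, i] = f1 - slope / rate + (out[:, i - 1] - f0 + slope / rate) * e
    return out[0] if one_d else out


def simulate_biosensor(r: Trace, params: KineticParams) -> Trace:
    """RBD biosensor signal b(t): first-order follower of free active RhoA.

    db/dt = koff_sensor (r - b), b = 1 at equilibrium.  Pulse-time jumps of
    r recorded by ``simulate_rhoa`` are honored exactly.
    """
    jump_idx = {}
    for tj, pre in r.meta.get("jumps", []):
        hits = np.flatnonzero(np.isclose(r.times, tj, rtol=0, atol=1e-9))
        if hits.size and hits[0] > 0:
            jump_idx[int(hits[0])] = pre
    values = relax_piecewise_linear(r.times, r.values, params.koff_sensor, jumps=jump_idx)
    if np.any(values <= 0):
        raise InvariantError("simulated b became non-positive")
    return Trace(r.times, values, channel="b", meta={"params": params})


def simulate_full(g: Trace, params: FullModelParams, k2: float) -> SimResult:
    """Integrate the un-approximated mass-action sequestration system.

    Species: free active RhoA R and complex GR, with total GEF Gtot(t)
    following the recruitment input (Gtot jumps at pulses, R and GR are
    continuous).  Production is k1*Gtot (the complexed GEF keeps its
    exchange activity), deactivation k2 acts on free R, and binding is
    kon*(Gtot - GR)*R <-> koff_bind*GR.  k1 is calibrated so the dark-state
    equilibrium is (Req, Geq*Req/Kb).  Returns the normalized free-RhoA
    trace for comparison with the QSSA solution.
    """
    ana = _require_analytic(g)
    if ana is None:
        raise ParameterError("simulate_full requires a synthetic g trace with analytic form")
    if k2 <= 0:
        raise ParameterError("k2 must be positive")
    Geq, Req, Kb = params.Geq, params.Req, params.Kb
    kon, koffb = params.kon_bind, params.koff_bind
    GR0 = Geq * Req / Kb  # from kon*Geq*Req = koff_bind*GR at equilibrium
    Gtot_eq = Geq + GR0
    k1 = k2 * Req / Gtot_eq

    times = g.times
    t0, tN = times[0], times[-1]
    bps = {t0, tN}
    bps.update(tj for tj, _, _ in ana.jumps if t0 < tj <= tN)
    bps.update(seg.t0 for seg in ana.segments if t0 < seg.t0 < tN)
    bps = sorted(bps)

    out = np.empty_like(times)
    state = np.array([Req, GR0])

    def rhs(t, y):
        R, GR = y
        Gtot = Gtot_eq * ana.g(t)
        Gfree = Gtot - GR
        bind = kon * Gfree * R - koffb * GR
        return [k1 * Gtot - k2 * R - bind, bind]

    atol = 1e-10 * max(Req, GR0, Geq)
    for k, a in enumerate(bps):
        out[np.isclose(times, a, rtol=0, atol=1e-9)] = state[0] / Req
        if k == len(bps) - 1:
            break
        b = bps[k + 1]
        interior = times[(times > a + 1e-9) & (times < b - 1e-9)]
        t_eval = np.concatenate([interior, [b]])
        sol = solve_ivp(rhs, (a, b), state, t_eval=t_eval, rtol=1e-9, atol=atol, method="Radau")
        if not sol.success:
            raise NumericalError(
                f"stiff integration failed on [{a:g}, {b:g}]: {sol.message}",
                {"interval": (a, b), "message": sol.message},
            )
        if interior.size:
            out[(times > a + 1e-9) & (times < b - 1e-9)] = sol.y[0, :-1] / Req
        state = sol.y[:, -1]

    r_tr = Trace(times, out, channel="r", meta={"model": "full-mass-action"})
    diag = {"binding_speed_ratio": koffb / k2, "rho_matched": params.rho}
    return SimResult(g=g, r=r_tr, params={"k2": k2, "Kb": Kb, "Geq": Geq, "Req": Req}, diagnostics=diag)


def qssa_full_discrepancy(g: Trace, params: FullModelParams, k2: float, settle: float = 2.0):
    """Sup-norm distance between the QSSA and mass-action free-RhoA traces.

    The mass-action solution is continuous across pulses and equilibrates the
    GR complex over ~1/(koff_bind (1 + rho g)) seconds, while the QSSA jumps
    instantaneously; samples within ``settle`` seconds after a pulse are in
    that boundary layer and are excluded from the sup (the full sup is also
    returned for regime documentation).
    """
    rq = simulate_rhoa(g, KineticParams(k2=k2, rho=params.rho))
    full = simulate_full(g, params, k2)
    d = np.abs(full.r.values - rq.values)
    ana = _require_analytic(g)
    mask = np.ones(g.times.size, dtype=bool)
    for tj, _, _ in ana.jumps:
        mask &= ~((g.times >= tj - 1e-9) & (g.times < tj + settle))
    return {
        "sup_settled": float(d[mask].max()) if mask.any() else float("nan"),
        "sup_all": float(d.max()),
        "binding_speed_ratio": params.koff_bind / k2,
    }


def simulate_cell(g: Trace, params: KineticParams) -> SimResult:
    """Full QSSA pipeline g -> (r, c, b) on a shared grid."""
    r = simulate_rhoa(g, params)
    c = simulate_cdc42(g, params)
    b = simulate_biosensor(r, params)
    return SimResult(g=g, r=r, c=c, b=b, params={"k2": params.k2, "rho": params.rho, "koff_sensor": params.koff_sensor})
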