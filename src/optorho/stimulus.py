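"""Illumination protocols and the membrane-recruited GEF input curve g(t).

The optogenetic dimer (iLID/SspB class) recruits the GEF to the membrane on
each blue-light pulse and dissociates in the dark with a time constant of
about 20 s.  Recruitment is treated as input data: each pulse increments the
normalized GEF abundance g = Gtot/Geq instantaneously by an amplitude
``delta = fold - 1`` and g relaxes exponentially back toward its
pre-activation baseline (1 under the normalization) between pulses.

A finite-rise variant (linear ramp over a configurable rise time) is kept
behind the ``rise_time`` flag for oracle comparisons of the jump handling in
the GTPase model.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ParameterError, ProtocolError

__all__ = [
    "Trace",
    "PulseProtocol",
    "RecruitmentParams",
    "AnalyticInput",
    "simulate_recruitment",
    "step_input",
    "constant_input",
    "read_trace",
    "write_trace",
    "load_protocol",
    "dump_protocol",
    "resample_trace",
]

_SNAP_TOL = 1e-6  # seconds; pulse times further than this from the grid warn


@dataclass
class Trace:
    """A single-channel per-cell time series.

    times are in seconds (strictly increasing), values dimensionless
    (normalized to pre-activation mean 1 for measured channels).  ``channel``
    tags the quantity: ``g`` (GEF recruitment), ``b`` (biosensor), ``r``
    (free active RhoA), ``c`` (active Cdc42) or ``area``.
    """

    times: np.ndarray
    values: np.ndarray
    channel: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise FormatError("trace times and values must be 1-D")
        if self.times.size != self.values.size:
            raise FormatError("trace times and values must have equal length")
        if self.times.size == 0:
            raise FormatError("empty trace")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.values)):
            raise FormatError("trace contains non-finite entries")
        if np.any(np.diff(self.times) <= 0):
            raise FormatError("trace times must be strictly increasing and unique")

    def __len__(self):
        return self.times.size

    def value_at(self, t):
        """Linear interpolation of the trace at time(s) t."""
        return np.interp(t, self.times, self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "value": self.values})


@dataclass(frozen=True)
class PulseProtocol:
    """Blue-light pulse schedule driving GEF recruitment.

    ``amplitude_fold`` is the fold-increase of g after one pulse, so the
    per-pulse increment of g is ``delta = amplitude_fold - 1``; measurable
    folds range from about 1.1 to 3.
    """

    pulse_times: tuple
    amplitude_fold: float
    t_end: float
    period: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "pulse_times", tuple(float(t) for t in self.pulse_times))
        pt = np.asarray(self.pulse_times, dtype=float)
        if pt.size and np.any(np.diff(pt) <= 0):
            raise ProtocolError("pulse times must be strictly increasing")
        if pt.size and (pt[0] < 0 or pt[-1] > self.t_end):
            raise ProtocolError("pulse times must lie within [0, t_end]")
        if self.amplitude_fold <= 1.0:
            raise ProtocolError("amplitude_fold must exceed 1 (delta > 0)")
        if self.t_end <= 0:
            raise ProtocolError("t_end must be positive")
        if self.period is not None and self.period <= 0:
            raise ProtocolError("period must be positive")

    @property
    def delta(self) -> float:
        """Per-pulse increment of g (fold - 1)."""
        return self.amplitude_fold - 1.0

    @classmethod
    def regular(cls, period, amplitude_fold, t_end, n_pulses=None, t_start=0.0):
        """Regular train starting at ``t_start`` with the given period."""
        if period <= 0:
            raise ProtocolError("period must be positive")
        times = []
        t = float(t_start)
        while t <= t_end + 1e-12 and (n_pulses is None or len(times) < n_pulses):
            times.append(t)
            t += period
        return cls(tuple(times), amplitude_fold, t_end, period=period)


@dataclass(frozen=True)
class RecruitmentParams:
    """Kinetics of the optogenetic dimer itself.

    tau_off: dark-state dissociation time constant (s), ~20 s for iLID/SspB.
    baseline: g before activation; 1 under the g = Gtot/Geq normalization.
    """

    tau_off: float = 20.0
    baseline: float = 1.0

    def __post_init__(self):
        if self.tau_off <= 0:
            raise ParameterError("tau_off must be positive")
        if self.baseline <= 0:
            raise ParameterError("baseline must be positive")


@dataclass(frozen=True)
class _Segment:
    t0: float
    kind: str  # 'const' | 'exp' | 'ramp'
    g0: float  # value just after t0
    coef: float  # exp: tau; ramp: slope; const: unused
    baseline: float = 1.0

    def g(self, s):
        if self.kind == "const":
            return self.g0 * np.ones_like(np.asarray(s, dtype=float))
        if self.kind == "exp":
            return self.baseline + (self.g0 - self.baseline) * np.exp(-np.asarray(s, dtype=float) / self.coef)
        return self.g0 + self.coef * np.asarray(s, dtype=float)

    def dgdt(self, s):
        if self.kind == "const":
            return np.zeros_like(np.asarray(s, dtype=float))
        if self.kind == "exp":
            return -(self.g0 - self.baseline) / self.coef * np.exp(-np.asarray(s, dtype=float) / self.coef)
        return self.coef * np.ones_like(np.asarray(s, dtype=float))


class AnalyticInput:
    """Piecewise-analytic g(t) with known derivative and jump set.

    Segments are right-closed at their start: at a jump time the post-jump
    segment applies (g is right-continuous).
    """

    def __init__(self, segments, jumps, t_end, baseline=1.0):
        self.segments = list(segments)
        #: list of (time, g_minus, g_plus) instantaneous discontinuities
        self.jumps = list(jumps)
        self.t_end = float(t_end)
        self.baseline = float(baseline)
        self._starts = np.array([s.t0 for s in self.segments])
        if np.any(np.diff(self._starts) <= 0):
            raise ProtocolError("segment starts must be increasing")

    def _idx(self, t):
        return np.clip(np.searchsorted(self._starts, t, side="right") - 1, 0, len(self.segments) - 1)

    def g(self, t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        out = np.empty_like(t)
        idx = self._idx(t)
        for k in np.unique(idx):
            m = idx == k
            out[m] = self.segments[k].g(t[m] - self.segments[k].t0)
        return out[0] if scalar else out

    def dgdt(self, t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        out = np.empty_like(t)
        idx = self._idx(t)
        for k in np.unique(idx):
            m = idx == k
            out[m] = self.segments[k].dgdt(t[m] - self.segments[k].t0)
        return out[0] if scalar else out


def _train_input(protocol: PulseProtocol, params: RecruitmentParams, rise_time: float = 0.0) -> AnalyticInput:
    base = params.baseline
    tau = params.tau_off
    delta = protocol.delta
    segments = [_Segment(-math.inf, "const", base, 0.0, base)]
    jumps = []
    g_post = base  # value just after the most recent event
    t_last = None  # time of the most recent event (end of ramp if any)
    for tp in protocol.pulse_times:
        if t_last is not None and tp < t_last:
            raise ProtocolError("pulses closer together than the rise time")
        g_minus = base if t_last is None else base + (g_post - base) * math.exp(-(tp - t_last) / tau)
        if rise_time <= 0:
            jumps.append((tp, g_minus, g_minus + delta))
            segments.append(_Segment(tp, "exp", g_minus + delta, tau, base))
            g_post, t_last = g_minus + delta, tp
        else:
            segments.append(_Segment(tp, "ramp", g_minus, delta / rise_time, base))
            segments.append(_Segment(tp + rise_time, "exp", g_minus + delta, tau, base))
            g_post, t_last = g_minus + delta, tp + rise_time
    return AnalyticInput(segments, jumps, protocol.t_end, base)


def step_input(fold: float, t_end: float, t_on: float = 0.0, baseline: float = 1.0) -> AnalyticInput:
    """Sustained step of g from baseline to ``fold * baseline`` at ``t_on``."""
    if fold <= 0:
        raise ProtocolError("fold must be positive")
    top = fold * baseline
    segments = [
        _Segment(-math.inf, "const", baseline, 0.0, baseline),
        _Segment(t_on, "const", top, 0.0, baseline),
    ]
    jumps = [] if fold == 1.0 else [(t_on, baseline, top)]
    return AnalyticInput(segments, jumps, t_end, baseline)


def constant_input(t_end: float, level: float = 1.0) -> AnalyticInput:
    """g held constant at ``level`` (null stimulus when level = 1)."""
    return AnalyticInput([_Segment(-math.inf, "const", level, 0.0, level)], [], t_end, level)


def analytic_to_trace(ana: AnalyticInput, grid: np.ndarray, channel: str = "g", meta=None) -> Trace:
    m = {"analytic": ana}
    if meta:
        m.update(meta)
    return Trace(grid, ana.g(grid), channel=channel, meta=m)


def simulate_recruitment(
    protocol: PulseProtocol,
    params: RecruitmentParams = RecruitmentParams(),
    grid: np.ndarray | None = None,
    dt: float = 1.0,
    rise_time: float = 0.0,
) -> Trace:
    """Membrane-recruited GEF abundance g(t) for a pulse protocol.

    g starts at the baseline (1), jumps by ``protocol.delta`` at each pulse
    (or ramps over ``rise_time`` if positive) and relaxes exponentially back
    toward baseline with ``params.tau_off`` between pulses.  Pulse times off
    the output grid by more than 1e-6 s are snapped with a warning.
    """
    if grid is None:
        grid = np.arange(0.0, protocol.t_end + dt / 2, dt)
    grid = np.asarray(grid, dtype=float)
    if grid[0] > 0.0 or grid[-1] < protocol.t_end - 1e-9:
        raise ProtocolError("grid must cover [0, t_end]")

    snapped = []
    for tp in protocol.pulse_times:
        i = int(np.argmin(np.abs(grid - tp)))
        if abs(grid[i] - tp) > _SNAP_TOL:
            warnings.warn(
                f"pulse at t={tp:g}s is off-grid by {abs(grid[i]-tp):.3g}s; snapped to {grid[i]:g}s",
                stacklevel=2,
            )
        snapped.append(grid[i])
    if snapped != list(protocol.pulse_times):
        protocol = PulseProtocol(tuple(snapped), protocol.amplitude_fold, protocol.t_end, protocol.period)

    ana = _train_input(protocol, params, rise_time=rise_time)
    return analytic_to_trace(ana, grid, "g", {"protocol": protocol, "recruitment": params})


# ---------------------------------------------------------------------------
# trace and protocol I/O


def write_trace(trace: Trace, path, normalized: bool = True) -> None:
    """Write a trace as CSV: '#' comment header then time_s,value columns."""
    with open(path, "w") as fh:
        fh.write(f"# channel: {trace.channel or 'unknown'}\n")
        fh.write(f"# normalized: {'true' if normalized else 'false'}\n")
        trace.to_frame().to_csv(fh, index=False)


def read_trace(path) -> Trace:
    """Read a delimited-text trace (columns time_s, value; '#' comments)."""
    channel = ""
    try:
        with open(path) as fh:
            text = fh.read()
    except OSError as exc:
        raise FormatError(f"cannot read trace file {path}: {exc}") from exc
    for line in text.splitlines():
        if line.startswith("#") and "channel:" in line:
            channel = line.split("channel:", 1)[1].strip()
    try:
        df = pd.read_csv(io.StringIO(text), comment="#")
    except Exception as exc:
        raise FormatError(f"unparseable trace file {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"empty trace file {path}")
    missing = {"time_s", "value"} - set(df.columns)
    if missing:
        raise FormatError(f"trace file {path} missing columns {sorted(missing)}")
    return Trace(df["time_s"].to_numpy(), df["value"].to_numpy(), channel=channel)


def dump_protocol(protocol: PulseProtocol, path) -> None:
    doc = {
        "pulse_times": list(protocol.pulse_times),
        "amplitude_fold": protocol.amplitude_fold,
        "t_end": protocol.t_end,
    }
    if protocol.period is not None:
        doc["period"] = protocol.period
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_protocol(path) -> PulseProtocol:
    """Load a protocol YAML: either explicit pulse_times or period/n_pulses."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise FormatError("protocol YAML must be a mapping")
    try:
        fold = float(doc["amplitude_fold"])
        t_end = float(doc["t_end"])
    except KeyError as exc:
        raise FormatError(f"protocol YAML missing key {exc}") from exc
    if "pulse_times" in doc:
        return PulseProtocol(tuple(doc["pulse_times"]), fold, t_end)
    if "period" in doc:
        return PulseProtocol.regular(
            float(doc["period"]), fold, t_end, n_pulses=doc.get("n_pulses")
        )
    raise FormatError("protocol YAML needs pulse_times or period")


def resample_trace(trace: Trace, grid: np.ndarray) -> Trace:
    """Linear resampling of a trace onto a new grid (within its span)."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] < trace.times[0] - 1e-9 or grid[-1] > trace.times[-1] + 1e-9:
        raise FormatError("resampling grid extends beyond the trace span")
    return Trace(grid, trace.value_at(grid), channel=trace.channel, meta=dict(trace.meta))
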