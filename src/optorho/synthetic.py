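"""Synthetic per-cell traces and cohorts emulating the optogenetic experiments.

Stands in for the microscopy data: noisy recruitment (g) and biosensor (b)
traces generated by the model itself, plus transfection-style cohorts whose
expression distribution straddles the empirical ~40 a.u. phenotype
threshold.  Expression maps to the model's free parameter linearly with a
single anchor rho(40 a.u.) = 0.5, tying the measured threshold to the
model's transition; the membrane-area readout is a deliberate affine
stand-in for the morphodynamic response, not a mechanical model.

Measurement noise is i.i.d. multiplicative Gaussian per frame (default 5% of
signal), with no temporal autocorrelation — the simplest model sufficient to
exercise the fitters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError
from .gtpase import KineticParams, simulate_biosensor, simulate_cdc42, simulate_rhoa
from .phenotype import DEFAULT_EPSILON, DEFAULT_WINDOW, compute_gamma, label_from_gamma
from .quant import classify_from_area
from .stimulus import PulseProtocol, RecruitmentParams, Trace, simulate_recruitment, write_trace

__all__ = [
    "NoiseModel",
    "CellRecord",
    "DEFAULT_PROTOCOL",
    "default_protocol",
    "expression_to_rho",
    "gen_cell_traces",
    "gen_cohort",
    "cohort_to_csv",
]

I_THRESH_DEFAULT = 40.0  # a.u.; arbitrary-unit convention of the intensity scale
AREA_GAIN_DEFAULT = 0.6  # affine gain from gamma to normalized 5-min area
AREA_EVAL_S = 300.0


def default_protocol(t_end: float = 320.0, period: float = 30.0, fold: float = 1.5) -> PulseProtocol:
    """Standard activation train: one pulse every 30 s, fold increase 1.5."""
    return PulseProtocol.regular(period, fold, t_end)


DEFAULT_PROTOCOL = default_protocol()

#: cohort stimulus: high-frequency train whose phenotype transition sits at
#: the anchored expression threshold (gamma = 0 near rho = 0.5), making the
#: expression -> rho mapping self-consistent with the area classifier
COHORT_PROTOCOL = default_protocol(period=15.0)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian measurement noise (sigma as signal fraction)."""

    sigma: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if self.sigma < 0:
            raise ParameterError("noise sigma must be non-negative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0:
            return values.copy()
        return values * (1.0 + self.sigma * rng.standard_normal(values.shape))


@dataclass
class CellRecord:
    """One synthetic cell: expression, mapped rho, traces and labels."""

    cell_id: str
    expression: float  # a.u. mean fluorescence
    rho: float
    g: Trace
    b: Trace
    area_trace: Trace
    gamma: float
    true_label: str
    observed_label: str
    area_5min: float
    seed: int | None = None


def expression_to_rho(intensity, i_thresh: float = I_THRESH_DEFAULT, rho_at_thresh: float = 0.5):
    """Linear expression -> Geq/Kb map anchored at rho(i_thresh) = rho_at_thresh."""
    return np.asarray(intensity, dtype=float) * (rho_at_thresh / i_thresh)


def gen_cell_traces(
    rho: float,
    protocol: PulseProtocol = DEFAULT_PROTOCOL,
    params: KineticParams = KineticParams(),
    recruitment: RecruitmentParams = RecruitmentParams(),
    noise: NoiseModel = NoiseModel(),
    seed: int | None = None,
    dt: float = 1.0,
    t_pre: float = 30.0,
):
    """Simulate one cell's clean (g, b) and apply per-frame multiplicative noise.

    Deterministic given ``seed``; with sigma = 0 the clean model output is
    returned exactly.  The grid covers [-t_pre, t_end] so that traces carry
    pre-activation frames (normalized mean 1).
    """
    grid = np.arange(-t_pre, protocol.t_end + dt / 2, dt)
    kin = KineticParams(k2=params.k2, rho=float(rho), koff_sensor=params.koff_sensor)
    g = simulate_recruitment(protocol, recruitment, grid=grid)
    r = simulate_rhoa(g, kin)
    b = simulate_biosensor(r, kin)
    rng = np.random.default_rng(seed if seed is not None else noise.seed)
    # pulse times are known to the experimenter (illumination protocol), so
    # measured traces legitimately carry them for jump-aware model fitting
    meta = {
        "rho_true": float(rho),
        "sigma": noise.sigma,
        "seed": seed,
        "pulse_times": tuple(protocol.pulse_times),
    }
    g_noisy = Trace(grid, noise.apply(g.values, rng), channel="g", meta=dict(meta))
    b_noisy = Trace(grid, noise.apply(b.values, rng), channel="b", meta=dict(meta))
    return g_noisy, b_noisy


def gen_cohort(
    n: int,
    weight: float,
    expression_mu: float = math.log(I_THRESH_DEFAULT),
    expression_sigma: float = 0.7,
    i_thresh: float = I_THRESH_DEFAULT,
    protocol: PulseProtocol | None = None,
    params: KineticParams = KineticParams(),
    recruitment: RecruitmentParams = RecruitmentParams(),
    area_gain: float = AREA_GAIN_DEFAULT,
    noise: NoiseModel = NoiseModel(),
    seed: int | None = None,
    window: float = DEFAULT_WINDOW,
    epsilon: float = DEFAULT_EPSILON,
    area_delta: float = 0.05,
    dt: float = 1.0,
    t_pre: float = 30.0,
) -> list[CellRecord]:
    """Sample a transfection-style cohort of ``n`` cells.

    Expression I is log-normal (median 40 a.u. by default, straddling the
    phenotype threshold); rho = I / (2 * i_thresh); the phenotype score gamma
    is computed from the clean model response and the normalized 5-min area
    is the affine readout 1 - area_gain * gamma plus additive noise of the
    same sigma.  ``true_label`` comes from gamma, ``observed_label`` from the
    area classifier — their disagreement emulates measurement-limited calls.
    """
    if n < 0:
        raise ParameterError("n must be non-negative")
    if expression_sigma <= 0 or not math.isfinite(expression_mu):
        raise ParameterError("invalid expression distribution parameters")
    if protocol is None:
        protocol = COHORT_PROTOCOL
    if protocol.t_end < AREA_EVAL_S:
        raise ParameterError("cohort protocol must cover the 5-min area readout")
    master = np.random.SeedSequence(seed)
    cell_seeds = master.spawn(max(n, 1))
    records: list[CellRecord] = []
    grid = np.arange(-t_pre, protocol.t_end + dt / 2, dt)
    g = simulate_recruitment(protocol, recruitment, grid=grid)
    c = simulate_cdc42(g, params)  # Cdc42 response is expression-independent
    for i in range(n):
        crng = np.random.default_rng(cell_seeds[i])
        intensity = float(np.exp(expression_mu + expression_sigma * crng.standard_normal()))
        rho = float(expression_to_rho(intensity, i_thresh))
        kin = KineticParams(k2=params.k2, rho=rho, koff_sensor=params.koff_sensor)
        r = simulate_rhoa(g, kin)
        b = simulate_biosensor(r, kin)
        gamma = compute_gamma(r, c, weight, window=window, epsilon=epsilon).gamma
        true_label = label_from_gamma(gamma, epsilon)
        area5 = float(1.0 - area_gain * gamma + noise.sigma * crng.standard_normal())
        area_vals = 1.0 + (area5 - 1.0) * np.clip(grid / AREA_EVAL_S, 0.0, None)
        area_tr = Trace(grid, area_vals, channel="area", meta={"area_gain": area_gain})
        observed = classify_from_area(area_tr, t_eval=AREA_EVAL_S, delta=area_delta)
        meta = {"rho_true": rho, "sigma": noise.sigma, "pulse_times": tuple(protocol.pulse_times)}
        g_noisy = Trace(grid, NoiseModel(noise.sigma).apply(g.values, crng), channel="g", meta=dict(meta))
        b_noisy = Trace(grid, NoiseModel(noise.sigma).apply(b.values, crng), channel="b", meta=dict(meta))
        records.append(
            CellRecord(
                cell_id=f"cell{i:04d}",
                expression=intensity,
                rho=rho,
                g=g_noisy,
                b=b_noisy,
                area_trace=area_tr,
                gamma=float(gamma),
                true_label=true_label,
                observed_label=observed,
                area_5min=area5,
                seed=i,
            )
        )
    return records


def cohort_to_csv(records: list[CellRecord], out_dir, config: dict | None = None) -> Path:
    """Write a cohort manifest CSV plus per-cell trace CSVs and a config YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        cell_dir = out / rec.cell_id
        cell_dir.mkdir(exist_ok=True)
        write_trace(rec.g, cell_dir / "g.csv")
        write_trace(rec.b, cell_dir / "b.csv")
        write_trace(rec.area_trace, cell_dir / "area.csv")
        rows.append(
            {
                "cell_id": rec.cell_id,
                "I_au": rec.expression,
                "rho": rec.rho,
                "gamma": rec.gamma,
                "true_label": rec.true_label,
                "observed_label": rec.observed_label,
                "area_5min": rec.area_5min,
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config or {}, fh)
    return out
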