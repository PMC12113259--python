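# Methods

## Model

The package models the response of a well-mixed membrane region to pulsed
optogenetic recruitment of a RhoA GEF (the DH–PH module of PDZ-RhoGEF) whose
PH domain also binds RhoA-GTP into a signaling-dead complex.

**Recruitment input.** Light pulses are instantaneous increments of the
normalized total GEF abundance `g = Gtot/Geq` (baseline 1), each of size
`delta = fold − 1` with measurable folds 1.1–3; between pulses `g` relaxes
exponentially to baseline with the dimer dark-state time constant
`tau_off = 20 s` (mono-exponential dissociation assumed). Recruitment is
treated as input data, not mechanism: there is no saturation (`delta` is the
same for every pulse), no photobleaching, and no illumination geometry. A
finite-rise variant (linear ramp over a configurable rise time) exists solely
to cross-check the jump handling of the dynamics; superposition of
single-pulse responses holds exactly for the instantaneous form.

**RhoA with sequestration (QSSA).** Binding of free GEF to RhoA-GTP
(dissociation constant `Kb`) is fast relative to activation/deactivation, the
complexed GEF keeps its exchange activity, and GAP-mediated deactivation
(lumped rate `k2`) acts on free RhoA-GTP only. With `r = R/Req` and
`rho = Geq/Kb` this yields

    dr/dt = [ k2 (g − r) − rho · r · dg/dt ] / (1 + rho g).

Across an instantaneous pulse the deactivation term is negligible and `r`
jumps multiplicatively by `(1 + rho g₋)/(1 + rho g₊)`. The absolute catalytic
rate is absorbed by the normalization and never appears. For constant input
`g = ĝ` the fixed point is `r = ĝ` with relaxation rate `k2/(1 + rho ĝ)` —
sequestration shapes transients only.

**Cdc42.** The same GEF activates Cdc42 with the same mass-action law and the
same deactivation rate `k2`, without sequestration: `dc/dt = k2 (g − c)`.
This minimal symmetric choice makes the `rho = 0` limit of RhoA and Cdc42
exactly degenerate. No Gαs dependence, Rac1 feedback or downstream mechanics
are modeled.

**Biosensor.** The relocation sensor (RBD) is an unsaturated first-order
tracker of free active RhoA, `db/dt = koff (r − b)`, used in excess (no
depletion of RhoA-GTP by the sensor). The printed uncertainty on the sensor
rate in the source estimates exceeds the estimate itself (almost certainly a
typo); 0.08 s⁻¹ is used as a point value and the error bar is not
interpreted.

**Mass-action oracle.** `simulate_full` integrates the un-approximated system
(free RhoA-GTP `R`, complex `GR`, total GEF following the input; production
`k1·Gtot`, deactivation `k2·R`, binding `kon·(Gtot−GR)·R ⇌ koff_bind·GR`,
with `k1` calibrated to the dark-state equilibrium). Its fast-binding limit
reproduces the QSSA equation provided the bound GEF fraction is negligible
(`Req ≪ Kb`), which is the regime used for oracle tests. Because the QSSA
solution jumps at pulses while the mass-action solution is continuous with a
boundary layer of width `~1/(koff_bind (1 + rho g))`, the agreement metric
(`qssa_full_discrepancy`) excludes samples within 2 s after each pulse; at a
binding-speed ratio `koff_bind/k2 = 100` the settled sup-norm discrepancy is
~0.003, and it decreases monotonically with that ratio.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| `k2` | GAP-mediated deactivation (RhoA and Cdc42) | 0.014 | 1/s |
| `koff_sensor` | biosensor unbinding rate | 0.08 | 1/s |
| `rho = Geq/Kb` | basal GEF vs complex dissociation constant | per cell | – |
| `tau_off` | dimer dark-state dissociation time constant | 20 | s |
| `amplitude_fold` | per-pulse fold increase of g | 1.5 | – |
| `T` | phenotype integration window | 120 | s |
| `epsilon` | gray-zone half-width on γ | 0.05 | – |
| `w` | RhoA-vs-Cdc42 weight | calibrated (≈3.34) | – |

## Phenotype score and map

γ compares baseline-subtracted integrated activities over the first two
minutes of activation (when the phenotype becomes visible):
`γ = [w∫(r−1) − ∫(c−1)] / [w∫|r−1| + ∫|c−1|]` with trapezoidal quadrature and
`0/0 → 0`. This exact form is a package choice: among the family of
"relative difference" statistics it is the one that is dimensionless, bounded
in [−1, 1], and zero for null stimuli; a raw-difference variant
(`normalized=False`) is kept for sensitivity analysis and agrees in sign.
γ > ε labels retraction, γ < −ε protrusion, otherwise mixed; ε = 0.05 is an
arbitrary but fixed rendering of the qualitative gray zone.

The weight `w` is unmeasurable from relocation sensors and is calibrated
once: the unique `w` with γ = 0 at `rho = 0.5` under a *sustained* step of g
to 2 held for the window (bracketed root solved to 1e-6; `w > 1` is required
since low-expression cells retract). Calibrating on a step rather than on a
pulse train keeps the pulsed phenotype map a genuine model prediction rather
than true by construction; the cost is that the map's transition under any
particular train need not sit exactly at 0.5.

`build_phenotype_map` scores regular trains with fixed per-pulse fold over a
(rho × period) grid, placing pulses strictly inside the scoring window (a
pulse at exactly t = T would jump `r` with zero integrated contribution).
γ is monotone non-increasing in rho at every period. Along the period axis γ
is slightly jagged because the number of pulses inside the 120 s window is a
step function of the period; the protrusion→retraction ordering with
increasing period is nonetheless strict once gray-zone labels are collapsed.
The frequency-switchable band is reported as the rho rows whose label flips
between protrusion and retraction across a period range; for the
experimentally probed 15–60 s range its center falls at rho = 0.60 on the
default grid (0.05 resolution), consistent with the intermediate-expression
transition near 0.5. Intensity sweeps at fixed rho (folds 1.1–3) never flip
the label — the model is close to linear in input amplitude — which is
asserted as a property.

## Fitting

All fits are plain (unweighted) least squares minimized with Powell's
direction-set method, three fixed starts, best-RSS selection; an optional
pre-activation-variance weighting exists but is off by default. Search bounds
bracket the expected values by at least an order of magnitude: rho ∈ [0, 10],
k2 ∈ [1e-4, 1] s⁻¹, koff ∈ [1e-3, 1] s⁻¹.

**Rates (k2, koff).** Estimated jointly from a pooled cohort of
low-expression cells (rho fixed to 0), where the model is a cascade of two
first-order relaxations driven by the measured g. That cascade is exactly
symmetric under exchange of the two rates, so the labeling carries a physical
prior: the sensor is the fast stage (~12.5 s) and deactivation the slow one
(~71 s); estimates are canonicalized accordingly, and a warning fires if the
two time constants come within 1.5× of each other. Standard errors are
residual-based (forward-difference Jacobian). A lack-of-fit flag compares
signal-scaled residuals (the noise model is multiplicative) against their
chi-square expectation at the 0.999 quantile, using the relative noise
variance estimated from pre-activation frames; it ignores propagation of
input (g) noise and is therefore slightly anticonservative for very large
cohorts.

**Per-cell expression (rho).** With rates fixed, rho is fitted to the
biosensor trace given the measured recruitment as input. A flat biosensor
bounds rho only from below; an optimum at the upper search bound is flagged
non-identifiable.

**Numerics on measured traces.** Rather than differentiating noisy g for the
`rho·r·dg/dt` term, sampled inputs are integrated through the substitution
`T = r (1 + rho g)` (total active RhoA), whose equation
`dT/dt = k2 (g − T/(1 + rho g))` contains no derivative of g and is
continuous across pulses; g itself is lightly smoothed (Savitzky–Golay,
window 5, quadratic, per inter-pulse segment so windows never straddle a
jump). Steps freeze coefficients at interval midpoints and solve each linear
step exactly; intervals ending at a known pulse use pre-pulse coefficients.
Pulse times are taken from trace metadata — they are known to the
experimenter from the illumination protocol — and treated as forcing
discontinuities; without this the sensor-rate estimate biases upward by tens
of percent. Synthetic (noise-free, analytic) inputs instead use adaptive
Runge–Kutta (rtol 1e-8, atol 1e-10) segment-by-segment with the exact jump
map; the two paths agree to ~3e-4 on noise-free data.

## Synthetic data

The generator emulates: pulsed recruitment with 20 s off-kinetics; biosensor
traces obeying the model across expression levels, including the
dip-then-rise shape at high expression; i.i.d. multiplicative Gaussian frame
noise (σ = 0.05 by default, no temporal autocorrelation — the simplest model
sufficient to exercise the fitters); and transfection-style cohorts.
Expression is log-normal (median 40 a.u., log-sd 0.7, straddling the
phenotype threshold) and maps linearly to the model parameter with the single
anchor `rho(40 a.u.) = 0.5`, tying the empirical threshold to the model
transition; the intensity scale is an arbitrary-unit convention. The default
cohort stimulus is the 15 s-period fold-1.5 train because under the model the
γ = 0 crossing for that stimulus lies at rho ≈ 0.49, i.e. at the anchor —
the property that makes the threshold/transition identification coherent
(slower trains put the crossing at higher rho).

The normalized 5-minute membrane area is an affine readout of the score,
`area = 1 − 0.6·γ + noise`, with a linear-in-time area trace passing through
it — a deliberate stand-in for morphodynamics, not a mechanical model. The
observed label comes from the area classifier (gray zone ±0.05 around 1), the
true label from γ. Because γ is continuous, noiseless cells just below the
expression threshold fall inside the gray zone and classify as mixed; the
below-threshold population is therefore "no protrusions, retraction away from
the boundary layer" rather than literally 100% retraction. What passing
cohort tests show is internal consistency of the generator + classifier
chain, not agreement with real imaging data: real traces have autocorrelated
noise, photobleaching, segmentation error and cell-to-cell kinetic
variability that the generator deliberately omits.

## Stack quantification

Masks are binary grids with unit-square pixels; area is a pixel count (the
convention of thresholded segmentation — no subpixel geometry). Biosensor
normalization follows the four-step recipe (background subtraction; mean in
the cell∩region intersection; division by the mean over the non-activated
part of the cell; division by the pre-activation mean), making pre-activation
frames 1 by construction; the pre-activation baseline is the mean over all
frames before activation start. Background estimation is out of scope —
background is a required input. Persistence is net displacement over total
path length, in [0, 1], undefined (NaN) for zero total displacement.
Optical-flow segmentation and membrane-ruffle metrics are not implemented.

## Problem sizes and determinism

Simulations use 1 s output grids (0.5 s inside phenotype maps); the default
map grid is 31 rho × 23 period points. The pooled rate fit uses 20 cells ×
20 minutes at 1 Hz; recovery studies in the tests use ~10 seeds per
condition. All randomness flows through seeded numpy Generators
(per-cell seeds spawned from a master SeedSequence), so cohorts and traces
are bit-reproducible given a seed. Fixed solver settings make simulation
output stable across runs.

## Known limitations

- The activated region is a well-mixed compartment: no diffusion, no spatial
  gradients, no flow of the phenotype back onto signaling (no Rac1/actin
  feedback), hence no mixed-phenotype mechanism beyond the gray zone.
- The linearity that forbids intensity-driven switching is a model property;
  an auto-amplification process would break it.
- k2 is shared between RhoA and Cdc42 by assumption; only their ratio of
  weights `w` is calibrated, not absolute activities.
- The exchange symmetry of the low-expression cascade means the rate labels
  rest on the fast-sensor prior, not on the data alone.
- The area readout and expression→rho mapping in the cohort generator are
  conventions, so cohort-level percentages probe the pipeline, not biology.
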