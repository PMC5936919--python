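# Methods

This note records the models implemented in `pertraction`, their
assumptions, the defaults and where they come from, the numerical choices,
and the limits of what the synthetic-data tests demonstrate.

## Physical-property estimation

**Diffusivities** use the Wilke–Chang correlation,
D = 7.4·10⁻⁸ (φM)^0.5 T/(μ V^0.6) cm²/s, with the solvent association
factor φ = 2.6 for water and 1.0 for non-associated organic solvents, μ in
cP and the solute molar volume V in cm³/mol. The correlation's own accuracy
is ~10% for small organic solutes; everything downstream of a diffusivity
inherits at least that uncertainty.

**Molar volumes** default to Le Bas additive increments (C 14.8, H 3.7,
O 7.4 cm³/mol for carbonyl oxygen, etc.). No ring correction is applied,
although carvone is cyclic; for carvone this over-counts V by ~7%
(207.2 vs ~192 cm³/mol with the six-membered-ring correction), which
propagates as ~4% on D via V^0.6. A measured or otherwise preferred V can
be supplied directly on `SoluteSpec`.

**Partition estimates** from replicate two-phase equilibria report the mean
and sample SD of per-replicate log₁₀P. Replicates with zero aqueous
concentration are excluded with a warning. When the initial (all-aqueous)
concentration is known, a mass-balance closure fraction
(c_w + (V_org/V_aq)·c_s)/c_total is reported and flagged outside a
configurable 0.85–1.15 band, a range consistent with the ≥90% recoveries
typical of well-behaved two-phase systems with some surface adsorption.

## Contactor geometry and mass-transfer coefficients

The module object carries the fibre bundle geometry and derives the inner
and outer interfacial areas, log-mean diameter, packing fraction
θ = n d_o²/D_shell² and hydraulic diameter d_h = (D_shell² − n d_o²)/(n d_o)
(wetted-perimeter form counting only the fibre surfaces).

The reference scenario fixes what is part of the printed record for the
three-fibre PTFE module: n = 3, d_i = 3 mm, L = 20 cm, 1 µm pores, inner
area ≈ 56 cm². The remaining geometry is **assumed, not measured**, chosen
once as typical of porous-PTFE tubing and kept fixed:

| parameter | value | status |
|---|---|---|
| fibre outer diameter d_o | 4.0 mm (0.5 mm wall) | assumed |
| shell inner diameter | 10 mm | assumed |
| porosity ε | 0.45 | assumed |
| tortuosity τ | 2.0 | assumed |
| shell correlation β | 5.8 | literature (hydrophobic membranes) |

All operations accept explicit overrides, and the key-value config format
exposes every one of these.

**Lumen side**: Lévêque solution k = 1.62 (D/d_i)(d_i² v/(L D))^⅓,
equivalently Sh = 1.62 Gz^⅓, with the volumetric lumen flow split evenly
over the parallel fibres and v the mean velocity in one fibre. The solution
is accurate for Gz > 4; below that a `LowGraetzWarning` is emitted (never a
hard error), since at low Gz the Lévêque form overestimates the
coefficient.

**Shell side**: the parallel-flow correlation
k = β(D/d_h)(1−θ)(d_h/L) Re^0.6 Sc^0.33 with Re built on d_h and the
superficial velocity over the free shell cross-section (whether the
original correlation intended superficial or interstitial velocity is
ambiguous in the literature; superficial is used and documented here).

**Membrane**: k_m = 2εD/(τ(d_o−d_i)) with D the diffusivity in the
pore-wetting phase. For hydrophobic PTFE the wetting phase is the organic
solvent, which is also why the organic-film and membrane resistances carry
the partition coefficient in the series sum.

**Overall coefficient**: 1/(K_w d_basis) = 1/(P k_o d_other) +
1/(P k_m d_lm) + 1/(k_w d_basis), with d_basis = d_i when the aqueous phase
is in the lumen ("in-out") and d_o when in the shell ("out-in"). The
breakdown object reports the three resistance fractions (they sum to 1);
for P ≳ 100 the aqueous film carries >95% of the resistance and K_w is
effectively the aqueous-side film coefficient.

### A known discrepancy in the out-in calculated coefficient

For the reference conditions the shell correlation bounds the out-in
calculated coefficient sharply: K_w(out-in) ≈ k_shell(water), and with
Re = 4ρQ/(π n d_o μ) (independent of the shell bore) and d_o > d_i = 3 mm,
k_shell < 3.5·10⁻⁶ (1−θ) m/s for *any* physical geometry at 40 ml/min —
with the assumed geometry it evaluates to ≈1.5·10⁻⁶ m/s. Reported
out-in calculated values near 4.5·10⁻⁶ m/s therefore cannot be reproduced
from this correlation chain regardless of the unknown geometry; shell-side
mass transfer at low Re and low packing fraction is at the lower validity
limit of the correlation and is generally acknowledged to be poorly
predictable. The package reports what the stated equations give.

### Interfacial-area basis for the experimental coefficient

When inverting a measured efficiency Φ to K_w, the area defaults to the
mode-consistent basis (inner area for in-out, outer for out-in) but is
always overridable: which basis produced a published experimental K_w is
often ambiguous, and for the reference scenario the printed ≈56 cm² inner
area is the only area in the record — using it reproduces the reported
experimental out-in coefficient.

## Recirculating extraction model

Assumptions: two perfectly mixed reservoirs, constant volumes and flows,
constant P, a module at quasi-steady state relative to the reservoir time
scale, no solute losses (adsorption, evaporation, degradation). Under
these, dc_w/dt = −(Q_w Φ/V_w)[c_w(1+1/R) − c_w0/R] with closed form

c_w(t) = c_w0 [1/R + e^(−(Q_wΦ/V_w)(1+1/R)t)]/(1+1/R),

and c_s(t) by conservation. The equilibrium aqueous level is c_w0/(1+R) and
the phase ratio there satisfies c_s/c_w = P exactly. With the 2:1
aqueous:organic volume ratio the long-time concentration factor
(V_w/V_s)·R/(R+1) → 2, matching the intent of a volume-reducing capture
step. Tests verify the closed form against `scipy.integrate.solve_ivp` on
the raw balance to 10⁻⁸ relative and mass conservation to 10⁻¹² relative.

The efficiency expression Φ(x, E), x = K_w A/Q_w, has a removable
singularity at E = 1 handled by the analytic limit x/(1+x) (switch at
|E−1| < 10⁻⁹); its supremum in x is min(1, E), and the numeric inversion
(`brentq`, relative tolerance 10⁻¹⁴, bracket doubling) refuses efficiencies
at or above that bound with an explanatory error. The E → ∞ closed form
K_w = −Q_w ln(1−Φ)/A is used as an oracle in tests, not in the
implementation.

**Reservoir volumes**: the reference scenario's 100 ml aqueous / 50 ml
organic implement the 2:1 phase ratio; the absolute values are assumed
(only the ratio is part of the record), and every quantity that depends on
absolute time — the slope, hence any Φ or K_w fitted from a time axis —
scales with them. Dimensionless results (Φ from a given K_w, factors E and
R) do not.

## Inference

The linearization y = ln[(1+1/R)c_w/c_w0 − 1/R] is exact for the model;
points whose log argument is ≤ 0 (at/below the equilibrium floor, where
measurement noise pushes c_w past c_w0/(1+R)) or censored are excluded with
a stated reason. The slope is fitted through the origin by default because
the model forces y(0) = 0; a free intercept is available as a diagnostic
(a non-zero fitted intercept flags an inconsistent c_w0 or early-time
transient). Φ̂ = −slope·V_w/(Q_w(1+1/R)); K_w follows by the monotone
inversion above. P is an input from equilibrium data, never co-estimated.

**Uncertainty**: nonparametric pairs bootstrap over time points (seeded,
1000 resamples by default). The reported 95% interval is the normal
approximation Φ̂ ± t₀.₉₇₅,ₙ₋₁·SE_boot rather than a percentile interval:
8–9-point schedules that concentrate leverage in the last sample make
percentile intervals undercover badly (~80% observed at nominal 95%),
while the Student-calibrated normal interval reaches ≈92% coverage in
seeded simulations at 2% noise. The K_w interval is the Φ interval mapped
through the strictly monotone inversion, which is exact for any
quantile-based interval and avoids per-resample root finding.

## Synthetic data

The generators emulate: triplicate two-phase equilibria (all solute
initially aqueous at 0.4 mg/ml, 1:1 phase ratio) and 8-hour recirculation
runs sampled at 0, 15, 30, 60, 120, 240, 360 and 480 min, with
multiplicative Gaussian noise of SD 2% by default (typical HPLC
repeatability) and optional lower-limit-of-quantification censoring to NaN.
Module-outlet stream concentrations follow the single-pass balance
c_w,out = c_w(1−Φ) + (Φ/P)c_s and its flow-weighted organic counterpart.
Ground truth always travels with the noisy output.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: solute adsorption to tubing and module
materials (real recoveries are 91–93%, not 100%), drift in flows or
temperature, membrane fouling or partial pore wetting by water, inlet/outlet
transients, and correlated analytical errors. Parameter-recovery results
here certify the estimator, not the field accuracy of the model.

The scenario's partition table (predicted vs experimental log P per
solvent) is synthetic: plausible values with the qualitative structure of
solvation-model screening — non-polar solvents predicted within 0.2 log
units, water-miscible alcohols flagged unreliable — not measured data.
The solvent property table (molar masses, viscosities, densities, vapour
pressures, ICH Q3C classes) contains published values.

## Screening

The selection narrative "prefer the least-toxic solvent class, then the
highest log P, then the lowest vapour pressure" is formalized as the default
lexicographic policy; a weighted-score alternative (min-max-normalized
fields, user weights) is provided since no single ordering is canonical.
Water-miscibility flags are input metadata — computing mutual miscibility
is out of scope — and propagate into the ranking rationale.

## Problem sizes

Tests and simulations run at the scale of the scenario itself: 8–9 time
points per course, 100-replicate noise sweeps, 200-replicate coverage
checks with 500 bootstrap resamples, 20-seed partition round trips. The
entire suite completes in a few seconds.

## Known limitations

- Parallel-flow shell correlation only; cross-flow modules and multi-module
  cascades are out of scope.
- No distributed-parameter (axial) contactor model; the module is a
  quasi-steady efficiency Φ.
- No transmembrane-pressure/breakthrough model; operating below the
  breakthrough pressure is assumed.
- Le Bas volumes without ring corrections (see above).
- P constant over the run; strong solute–matrix interactions (salts,
  glycerol) must be captured in the measured P supplied.
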