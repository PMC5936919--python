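# pertraction

Mass-transfer modelling and parameter estimation for **membrane-assisted
solvent extraction** (pertraction) of hydrophobic solutes — such as
biotechnologically produced monoterpenes — in hollow-fibre membrane
contactors.

In a hydrophobic (PTFE) hollow-fibre contactor the aqueous donor stream and
the organic acceptor stream flow on opposite sides of a microporous wall;
the organic phase wets the pores and the liquid–liquid interface is pinned
at the pore mouth, so extraction proceeds without dispersion or settling.
This package implements the computational chain used to design and evaluate
such a process:

- **Solvent screening** — validate predicted partition coefficients
  (log *P*) against experimental two-phase data and rank candidate solvents
  by an explicit policy (ICH Q3C residual-solvent class, log *P*, vapour
  pressure).
- **Film and overall coefficients** — Wilke–Chang diffusivities
  (D = 7.4·10⁻⁸ (φM)^½ T / (μ V^0.6), with Le Bas molar volumes),
  the Lévêque solution Sh = 1.62 Gz^⅓ for laminar lumen flow, a
  parallel-flow shell correlation Sh = β d_h(1−θ)/L · Re^0.6 Sc^0.33
  (β = 5.8 for hydrophobic membranes), the porous-wall membrane coefficient
  k_m = 2εD/(τ(d_o−d_i)), combined by the resistance-in-series model

      1/(K_w d_i/o) = 1/(P k_o d_o/i) + 1/(P k_m d_lm) + 1/(k_w d_i/o)

- **Recirculating extraction dynamics** — both phases circulate between
  reservoirs and the module, so the driving force decays; the closed-form
  solution of the two-reservoir balance gives c_w(t) in terms of the module
  efficiency Φ = [1 − e^(−x(1−1/E))]/[1 − e^(−x(1−1/E))/E] (x = K_w A/Q_w),
  the module extraction factor E = P Q_s/Q_w and the reservoir factor
  R = P V_s/V_w.
- **Inference** — the trace linearizes as
  ln[(1+1/R) c_w/c_w0 − 1/R] = −(Q_w Φ/V_w)(1+1/R) t, so a through-origin
  least-squares slope yields Φ̂, and K_w follows by monotone inversion of
  the efficiency expression, with seeded bootstrap confidence intervals.
- **Synthetic data** — seeded generators for equilibrium partition
  replicates and noisy/censored time courses with known ground truth, plus
  a complete reference scenario (carvone / water / n-heptane, three-fibre
  module).

## Worked example

Fit Φ and K_w to a noisy synthetic 8-hour run of the reference scenario
(three PTFE fibres, 3 mm ID, 20 cm, ≈56 cm² inner area; aqueous lumen flow
3 ml/min, organic shell flow 40 ml/min, 100:50 ml reservoirs, 0.15 mg/ml
carvone, log P = 2.8):

```python
from pertraction import (ExtractionModel, SyntheticConfig,
                         carvone_heptane_scenario, synth_timecourse)

s = carvone_heptane_scenario()
op = s.operating_in_out
cfg = SyntheticConfig(logP=s.logP, phi=0.222, sd=0.02, seed=7)
noisy, truth = synth_timecourse(cfg, op)

model = ExtractionModel.from_timecourse(noisy, operating=op,
                                        module=s.module, partition=s.P)
res = model.fit(bootstrap=1000, seed=7)
print(res.summary())
```

```
Recirculating extraction fit
==============================================
observations used                            8
excluded points                              0
R-squared                             0.999918
partition coefficient P                    631
extraction factor E                       8413
reservoir factor R                       315.5
interfacial area A, m^2               0.005655
----------------------------------------------
slope, 1/s                       -1.110856e-04
efficiency Phi                        0.221469
K_w, m/s                          2.213581e-06
Phi 95% CI                  [0.217991, 0.224947]
K_w 95% CI, m/s             [2.1742e-06, 2.2532e-06]
```

The fitted single-pass efficiency (22.1%) and overall coefficient
(2.21·10⁻⁶ m/s) recover the generating ground truth (Φ = 0.222) from 2%
multiplicative measurement noise; R² is that of the linearized trace.

The same operations are available from the shell:

```bash
pertraction synth --seed 7 --out demo/          # scenario tables + noisy run
pertraction kw  --module-config demo/module.cfg --p 631        # predicted K_w
pertraction fit --timeseries demo/timecourse.csv \
                --module-config demo/module.cfg --p 631 --bootstrap 1000 --seed 7
pertraction screen --partition-table demo/partition.csv \
                   --properties-table demo/solvents.csv
```

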