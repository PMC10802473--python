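# hsrkit

Modeling and analysis toolkit for the *Saccharomyces cerevisiae* heat shock
response (HSR): the transcriptional program driven by heat shock factor 1
(Hsf1) and repressed by the chaperone Hsp70. The package is aimed at
quantitative biologists studying chaperone-mediated feedback — it bundles a
mechanistic ODE model of the Hsf1–Hsp70 circuit, single-parameter fits of
that model to mutant reporter time courses, regulon-wide induction-kinetics
analysis (logistic fits + PCA), ethanol dose–response (EC50/IC50) fitting,
flow-cytometry and growth-curve quantification, and seeded synthetic-data
generators that emulate the statistical structure of a 42-gene Hsf1-target
reporter library.

## The model

Free Hsf1 (`Ff`) activates transcription of Hsp70; free Hsp70 (`Hf`) binds
and represses Hsf1 — a negative feedback loop closed at the level of
chaperone *availability*. Stress injects unfolded client proteins `U` that
titrate Hsp70 into complexes `HU`, freeing Hsf1. Two further ingredients:

* an **affinity switch**: accumulated clients titrate the J-domain protein
  Sis1 away from Hsf1, lowering the Hsp70–Hsf1 association rate,
  `k_bF(U) = k_bF0 / (1 + (U/K_sis)^h)`;
* **productive release** `k_rel`: Hsp70 is released from a client *coupled
  to client folding/clearance*. This single rate is the knob through which
  auxiliary feedback factors (Fes1-, Ubi4-, Gre3-, Pin3-like) act, and it is
  the one parameter tuned when fitting their ΔHSE mutants.

With an HSE-driven YFP reporter (immature `Y`, mature `Ym`) the system is

```
dU/dt  = k_U0·s − k_bU·Hf·U + k_offU·HU − γ·U
dHU/dt = k_bU·Hf·U − (k_rel + k_offU + γ)·HU
dHf/dt = β0 + β1·Hill(Ff; K_hsf, n_hsf) + (k_rel + k_offU)·HU
         − k_bU·Hf·U − k_bF(U)·Hf·Ff + k_uF·HF − γ·Hf
dHF/dt = k_bF(U)·Hf·Ff − (k_uF + γ)·HF ,   dFf/dt = −dHF/dt
dY/dt  = α_y·Hill(Ff; K_y, n_y) − (m + γ)·Y ,   dYm/dt = m·Y − γ·Ym
```

where `s` is the stress multiplier on client influx (heat or ethanol,
onset-inclusive step) and total Hsf1 `Ff + HF = F_tot` is conserved.
Reporter output is always the fold change `Ym(t)/Ym(0)`, which cancels the
arbitrary units. Genotypes map onto parameters: wild type is the identity;
`Hsp70ΔFBL` (core loop broken) sets `β1 = 0` with `β0` raised to preserve
the basal chaperone pool; auxiliary ΔHSE mutants scale `k_rel` down.

Fits minimize the unweighted residual sum of squares between observed and
simulated fold change. Regulon kinetics use a 4-parameter logistic
`f(t) = B + (M−B)/(1+exp(−k(t−t50)))`, whose time-to-half-max (`t50`) and
maximal induction rate (`k(M−B)/4`) are closed-form; dose–response uses the
Hill form `r(c) = floor + (ceiling−floor)·cⁿ/(C50ⁿ+cⁿ)` (mirrored for
growth inhibition).

## Worked example

```python
import numpy as np
from hsrkit import default_parameters, default_heat_protocol, simulate
from hsrkit.fitting import fit_release_scale
from hsrkit.model_core import StrainGenotype
from hsrkit.synthetic_data import NoiseSpec, gen_mutant_panel, gen_ethanol_panel
from hsrkit.dose_response import fit_hill

base = default_parameters()
protocol = default_heat_protocol()       # 39 °C from t=0, 10 samples / 240 min

wt = simulate(base, protocol)
print("WT HSE-YFP fold change:", np.round(wt.yfp_fold_change, 2))

panel = gen_mutant_panel(
    [StrainGenotype("fes1_dHSE", "AUX_DHSE", release_scale=0.3)],
    protocol, NoiseSpec(replicate_cv=0.05), base, seed=1,
)
fit = fit_release_scale(panel[0], base, protocol)
print(f"fitted release scale: {fit.release_scale:.3f}  (RSS = {fit.rss:.3f})")

ethanol = gen_ethanol_panel(seed=1)
hill = fit_hill(ethanol.endpoint_curve)
print(f"EC50 = {hill.C50:.2f}% ethanol (Hill n = {hill.n:.1f})")
```

prints

```
WT HSE-YFP fold change: [1.   1.19 2.27 2.93 3.23 3.38 3.33 3.24 3.15 2.98]
fitted release scale: 0.302  (RSS = 0.251)
EC50 = 7.00% ethanol (Hill n = 6.0)
```

The wild-type reporter rises ~3.4-fold and plateaus as the core feedback
restores free Hsp70; a mutant simulated with 30% of the wild-type productive
release rate is recovered from its noisy 3-replicate fold-change course to
`0.302`; and a Hill fit of the synthetic 4-hour ethanol panel returns the
half-maximal activation dose within noise of the calibrated 6.9%.

A CLI mirrors the library (`hsrkit simulate|fit|dynamics|doseresponse|flow|
growth|synth`); run `hsrkit --help`.

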