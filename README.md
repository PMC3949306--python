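# tightbind

Tight-binding enzyme kinetics of phosphatase–inhibitor sequestration.

## The problem

At mitotic exit, the phosphatase PP2A-B55 must dephosphorylate the CDK
substrates that drove M phase. During M phase it is held silent by
Greatwall-phosphorylated Endosulfine (pEndos), which binds it with
sub-nanomolar affinity. The twist is that pEndos is not a conventional
inhibitor: it is simultaneously a **tight-binding inhibitor and a slow
substrate** of the very enzyme it inhibits ("inhibition by unfair
competition"). Because its K_m (~1 nM) is orders of magnitude below that of
ordinary substrates (~85 µM for a CDK-site reporter) it monopolises the
active site; because its k_cat is small (~0.05 s⁻¹) it is consumed slowly —
but it *is* consumed, so once the upstream kinase shuts off, the phosphatase
eats its own inhibitor and frees itself within about a minute.

`tightbind` implements the quantitative machinery this argument rests on,
for enzymologists and modellers working with comparable enzyme–inhibitor
systems:

* **Morrison (tight-binding) velocity fitting** — when enzyme concentration
  is comparable to K_m, the free-ligand approximation fails and the complex
  concentration is the physical root of

  `[NP]² − ([N]_T + [P]_T + K_m)[NP] + [N]_T[P]_T = 0`,

  giving `v = (k_cat/2){([P]_T+[N]_T+K_m) − √(([P]_T+[N]_T+K_m)² − 4[P]_T[N]_T)}`.
  Fitting the classic hyperbola to such data overestimates K_m.
* **Competitive-displacement K_m determination** — sub-nanomolar K_m values
  are measured by competing substrate turnover against graded doses of an
  active-site inhibitor of known K_d (okadaic acid, K_dO = 30 nM),
  integrating `d[N]_T/dt = −k_cat[N]_T[P]/K_m` with free `[P]` from the
  coupled tight-binding algebra.
* **The auto-reset model** — reporter dephosphorylation with and without a
  consumable inhibitor, including first-order enzyme decay; two-stage
  nonlinear regression, lag-time extraction, tight-binding dose–response
  (IC50) fitting and the IC50 → K_d conversion
  `K_d = (IC50 − [P]_T/2)/(1 + [S]/K_m^S)`.
* **M-phase-exit simulations** — total quasi-steady-state (tQSSA)
  integration of desequestration under three scenarios (phosphatase alone, a
  second conventional phosphatase assisting, and a dead-end-inhibitor
  counterfactual), cross-checked against explicit mass-action ODEs, with
  validity diagnostics (ε, transient time t_c) and fractional-velocity
  decomposition between two enzymes.
* **Synthetic assay generators** — seeded, truth-annotated datasets for the
  three assay designs, so every fitting stage is testable end to end.

All concentrations are handled internally in nM and times in seconds;
weighted regression assumes identically distributed fractional errors.

## Worked example

```python
import tightbind as tb

# How fast does 250 nM phosphatase escape 1 uM of consumable inhibitor
# (Km = 1 nM, kcat = 0.05/s)?
traj = tb.simulate_tqssa(tb.single_phosphatase_scenario())
print(tb.half_desequestration_time(traj))   # 74.31 s

# Recover kinetic constants from a noisy synthetic titration
# (truth Km = 1 nM, kcat = 0.03/s; enzyme 0.5 nM; 10% fractional noise)
data = tb.gen_velocity_dataset(tb.KineticParams(Km=1.0, kcat=0.03),
                               noise=tb.NoiseModel(cv=0.10, replicates=3, seed=1))
fit = tb.fit_velocity_curve(data)
print(fit.estimates)  # {'Km': 0.9381, 'kcat': 0.0301}
print(fit.stderrs)    # {'Km': 0.0734, 'kcat': 0.0005}
```

Half of the enzyme is free after ~74 s even though each catalytic cycle
takes ~20 s — sequestered enzyme works through a 4-fold excess of inhibitor
in roughly `N_T0/(k_cat · P_T)` seconds. The regression recovers the
simulating truth within one standard error.

The same stages are scriptable from a shell:

```sh
tightbind simulate-exit --scenario single --out-prefix exit_A --plot
tightbind synth velocity --seed 1 --cv 0.10 --out-prefix vel
tightbind fit-vs vel.csv --p-t 0.5 --out fit.json
```

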