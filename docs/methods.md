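# Methods

## Models

### Tight-binding (Morrison) velocity

For an enzyme P acting on a ligand N at comparable concentrations, mass
conservation plus the quasi-steady-state condition for the complex NP give
the quadratic `[NP]² − ([N]_T+[P]_T+K_m)[NP] + [N]_T[P]_T = 0`; the smaller
root is physical and `v = k_cat[NP]`. The root is evaluated in the
conjugate form `2ab/(s + √(s² − 4ab))`, which is immune to the catastrophic
cancellation the textbook "minus" form suffers when `4ab ≪ s²`. Zero
concentrations short-circuit to exact zeros. In `tqssa_free_pair` the
nearly-consumed species is recovered from `N·P = K_m·NP` rather than by
subtraction, for the same reason.

### Competitive displacement

With a dead-end competitor O sharing the active site, the coupled relations
`[N] = [N]_T/(1+[P]/K_m)`, `[O] = [O]_T/(1+[P]/K_dO)`,
`[P] = [P]_T/(1+[O]/K_dO+[N]/K_m)` are closed under the ligand-excess
approximation `[N] ≈ [N]_T`, leaving a quadratic in [P]
(`aP² + (aK_dO + O_T − P_T)P − P_T·K_dO = 0`, `a = 1+N_T/K_m`) solved in a
sign-stable form. The approximation's relative error is bounded by
`P_T/N_T`; the public solver enforces `N_T ≥ 100·P_T` (≤1% error; 0.1%
needs roughly thousand-fold excess). `predict_release` validates this on
the initial totals and then integrates
`d[N]_T/dt = −k_cat[N]_T[P]/K_m` with the unguarded algebra, since the
<20%-conversion design keeps the trajectory inside the regime. The
competitor is strictly dead-end: no catalytic term. Its dissociation
constant K_dO (default 30 nM) is treated as known and never co-fitted;
propagating its stated ±2 nM uncertainty moves the recovered K_m by <10%.

### Auto-reset

A consumable tight-binding inhibitor silences the enzyme only until the
enzyme has dephosphorylated the inhibitor pool. The reporter substrate
(0.47 µM, far below its ~85 µM K_m) binds a negligible enzyme fraction, so
reporter release is `d[³²P]/dt = (k_cat/K_m)^C · [pC]_T · [P]` with [P] the
free enzyme from the tQSSA pair, while the inhibitor depletes as
`d[N]_T/dt = −k_cat[P][N]/K_m`. Enzyme activity additionally decays at
k_deg (first order on total enzyme); in the no-inhibitor control the
release integrates in closed form to
`(k_cat/K_m)^C [pC]_T [P]_T(0)(1−e^{−k_deg t})/k_deg`, with the k_deg → 0
limit handled via expm1. The decay onset is 0 for the control but deferred
(default 25 min, configurable) for inhibitor-containing samples —
inhibitor binding appears to stabilise the enzyme, and the asymmetry does
not materially affect the fitted constants. In `dead_end` mode the
inhibitor is not consumed (k_cat → 0, K_m → K_d).

The lag a consumable inhibitor imposes is defined as the first time the
inhibited sample's instantaneous reporter rate reaches 50% of the matched
control's rate at the same time; it is computed from the fitted/ simulated
model rates (root-finding on dense ODE output), not from finite differences
of noisy data, and returns an explicit beyond-horizon sentinel when the
threshold is never reached.

Fitting is two-stage: (eff_C, k_deg) by regression of the closed form on
the control course, then (K_m, k_cat) by forward simulation of the
inhibited course with the control estimates fixed. Both stages recover a
noiseless truth exactly.

### Dose–response and IC50 → K_d

For tight-binding inhibitors the dose–response shape is the free-enzyme
fraction from the binding quadratic with the apparent dissociation constant
`K_d^app = K_d(1+[S]/K_m^S)`; the fitted IC50 is then
`K_d^app + [P]_T/2`. Weak inhibitors use a logistic (Hill) form. The
`auto` mode fits the logistic first and switches to the tight-binding shape
when the midpoint lands within 20× the enzyme concentration. The inverse
conversion `K_d = (IC50 − [P]_T/2)/(1+[S]/K_m^S)` fails loudly at the
stoichiometric-titration limit `IC50 ≤ [P]_T/2`, where the dose–response
measures enzyme concentration rather than affinity. Applied to the
measured IC50s (197 pM for the thiophosphorylated inhibitor at 0.125 nM
enzyme and 5 µM reporter), the conversion gives K_d ≈ 0.127 nM; the
rounded 0.12 nM is used as the dead-end scenario default.

### M-phase-exit scenarios

The tQSSA closes the two-enzyme system with
`[N] = [N]_T/(1+[P]/K_m^P+[X]/K_m^X)`, `[P] = [P]_T/(1+[N]/K_m^P)`,
`[X] = [X]_T/(1+[N]/K_m^X)` and
`d[N]_T/dt = −(k_cat^P[P]/K_m^P + k_cat^X[X]/K_m^X)[N]`. The one-enzyme
case uses the closed-form quadratic; the two-enzyme free-ligand equation is
monotone in [N] and solved by Brent bracketing on [0, N_T]. Scenario
defaults are the study conditions: total phosphatase 250 nM, initial ligand
1 µM, K_m 1 nM, k_cat 0.05 s⁻¹; the assisting phosphatase PPX at 250 nM
with K_m 85 µM, k_cat 22.5 s⁻¹; the dead-end counterfactual with
K_d 0.12 nM. Default horizons: 600 s (substrate scenarios), 20 000 s
(dead-end).

The mass-action cross-check integrates (N, P, NP, X, NX) explicitly,
starting unbound. Dissociation rates follow the Briggs–Haldane relation
`k_off = k_on·K_m − k_cat` (with the measured k_on = 0.057 nM⁻¹s⁻¹ this
gives 0.007 s⁻¹, matching the measured 0.0068 s⁻¹ within its precision);
dead-end complexes use `k_off = k_on·K_d`. Agreement with the tQSSA is
assessed as the sup-norm deviation of the phospho-ligand *fraction* (a
magnitude-1 quantity) beyond t = 1 s, which is below 1% in all scenarios.
A relative criterion is deliberately not used on the late exponential tail:
both solutions decay with slightly different rates (an O(ε) eigenvalue
difference inherent to the approximation), so the relative gap grows
without bound while the fractions themselves are below 10⁻¹⁰ — a regime
with no physical or graphical meaning.

Validity diagnostics: `ε = k_cat[P]_T/{k_on([N]_T(0)+[P]_T+K_m)²}`
(1.4×10⁻⁴ at the single-phosphatase conditions; the variant reading
without the [P]_T factor, 5.6×10⁻⁷ nM⁻¹, is reported alongside) and the
binding transient `t_c = 1/{k_on([N]_T(0)+K_m)} ≈ 0.02 s`, inside which
tQSSA and mass action legitimately differ.

## Regression and error model

All fitters assume identically distributed fractional errors, implemented
as iteratively reweighted least squares: weights `1/max(y_model, ε)²` with
`ε = 10⁻¹² nM/s`, frozen per outer iteration, refit until all parameters
move by <10⁻⁸ relative (cap 500 iterations); a fixed observed-value
weighting is available (`weighting="observed"`). Parameters are fitted on
the log scale — positivity without bound constraints — with standard errors
mapped back by the delta method from the weighted-residual covariance.
Initial guesses are data-driven (plateau for k_cat, half-max interpolation
for K_m). Cross-experiment pooling is the inverse-variance weighted mean
with pooled SE `(Σ 1/SE_i²)^{-1/2}`.

ODE integration uses LSODA with rtol 10⁻⁸, atol 10⁻¹² nM and dense output;
threshold crossings (half-desequestration, lag) are located by bracketing
on the dense solution and Brent refinement rather than grid interpolation.

## Synthetic data

Generators apply multiplicative Gaussian noise `y(1 + cv·z)` truncated at
zero (default cv 0.10, 3 replicates; a moment-matched lognormal variant is
available) and are pure functions of (truth, design, seed). Designs mirror
the assay conditions: velocity titrations at 0.5 nM enzyme over a
1–1100 nM ligand grid; competition assays at 50 nM ligand, 0.25 nM enzyme,
10-min incubations, with a half-decade competitor grid from 3 nM to 30 µM —
the upper end chosen so the doses bracket the competition midpoint
`K_dO(1+N_T/K_m)`, without which the dose curve's transition is unsampled
and K_m is poorly identified; reset time courses in triplicate at 10-min
spacing over 2 h. Simulated truths embed their parameters in the dataset
metadata so recovery tests are self-describing.

What the generators do *not* emulate: scintillation-counting statistics,
background subtraction, pipetting covariance between replicates, or any
systematic error (enzyme-prep activity differences, concentration
mis-calibration). Passing recovery tests therefore demonstrate estimator
correctness and precision under the stated noise model, not robustness to
the systematic effects that dominate the spread between real experimental
preparations.

## Problem sizes

The default test and acceptance runs use 1001-point trajectory sampling on
600 s / 20 000 s horizons, a 400-point 2-h grid for the reset model, and
50-seed Monte-Carlo batches for estimator-precision comparisons — sizes at
which every reported quantity is converged to well inside its comparison
tolerance (doubling any of them changes no reported digit).

## Known limitations

* The ligand-excess closure of the competition model limits
  `predict_release` to designs with `N_T0 ≥ 100·P_T`; the exact
  three-species tight-binding system without that approximation is not
  implemented.
* Okadaic-acid binding is modelled as instantaneous single-step
  equilibrium; slow-onset (two-step) inhibition is out of scope.
* The exit scenarios hold total phosphatase constant (no synthesis or
  degradation) and omit the upstream kinase, cyclin dynamics and any
  feedback — they describe the release step only, from a fully
  phosphorylated, fully sequestered initial state.
* Allosteric and uncompetitive inhibition modes are deliberately absent:
  the model commits to active-site competition.
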