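# Methods

`sixmp` implements a model-based workflow for individualizing oral
6-mercaptopurine (6-MP) therapy in childhood acute lymphoblastic leukemia
maintenance treatment: simulate the drug's metabolism and its hematological
effects, reduce the parameter space by global sensitivity analysis, fit the
few sensitive parameters per patient from sparse clinical measurements, and
optimize the dose by receding-horizon control.

## Models

### 6-MP metabolism

A four-state mass-action/Michaelis–Menten system: gut amount `x_g` (pmol),
plasma amount `x_p` (pmol), and the RBC metabolite concentrations `x_t`
(6-TGN) and `x_m` (MeMP), both in pmol per 8×10⁸ RBCs.

    dx_g/dt = u(t) − k_a·x_g
    dx_p/dt = k_a·x_g − k_e·x_p
    dx_t/dt = (1 − e/e_max)·k_pt·x_p/(K_t + x_p) − k_te·x_t
    dx_m/dt = (e/e_max)·k_pm·x_p/(K_m + x_p) − k_me·x_m

Oral doses are instantaneous boluses into `x_g` (mg → pmol via the molar
mass 152.177 g/mol). The TPMT activity `e` (relative to the population
maximum `e_max`) partitions the converted drug: high TPMT shunts flux into
inactive/hepatotoxic methylated metabolites and starves the active 6-TGN
pathway. The conversion fluxes do not deplete plasma drug: the amounts and
RBC concentrations are in incommensurable units, the formation constants
absorb the volume/partition factors, and first-pass elimination (half-life
1.2 h) dominates the plasma balance.

Two structural consequences matter downstream:

* **Exposure ceiling.** Steady-state 6-TGN can never exceed
  `f_tgn·k_pt/k_te` regardless of dose — the Michaelis–Menten factor is
  bounded by 1. For the average patient (`f_tgn = 0.5`, `k_pt = 25.1`,
  `k_te = 0.0661`) the ceiling is ≈ 190 pmol/8×10⁸ RBC.
* **Deep conversion saturation.** The Michaelis constants default to
  1×10⁴ pmol, far below clinical plasma amounts (daily 75 mg ≈ 4.9×10⁸
  pmol), so the conversion runs near capacity across the dosing interval.
  This is the regime required by the reported sensitivity ranking, in
  which the absorption and plasma-elimination rates and the Michaelis
  constants contribute essentially nothing to 6-TGN variance. Its flip
  side: above a few mg/day, steady 6-TGN responds only weakly to dose, so
  exposure titration works mostly through low or zero-dose intervals.

### Hematopoiesis (leukocytes, RBCs, MCV)

Both lineages are transit-compartment models: a proliferating progenitor
pool `S`, three identical maturation compartments `C1..C3`, and a
circulating pool. Proliferation is amplified by a decreasing Hill feedback
of the circulating count (G-CSF for leukocytes, EPO for RBCs), and 6-TGN
kills proliferating cells only (nucleated, DNA-incorporating), via a Hill
term `E_max·x_t^h/(EC50^h + x_t^h)`:

    dS/dt  = [k_max·θ^s/(θ^s + C^s) − E(x_t) − k_t − k_s]·S
    dCi/dt = k_t·(prev − Ci)
    dL/dt  = κ·k_tl·C_L3 − k_dl·L          (leukocytes, cells/L; κ = 15.5 kg/L)
    dR/dt  = k_tr·C_R3 − k_dr·R            (RBCs, cells/kg)
    dM/dt  = (k_tr·C_R3/R)·(M_in − M) + k_m6·x_t

`k_s` is a background progenitor attrition rate. It is required for the
two leukopoiesis anchors to coexist: the steady-state proliferation demand
is 0.157 d⁻¹ while the transit rate is 0.1207 d⁻¹; without an explicit
attrition term no steady state exists with that gap (the difference is the
random progenitor death the transit chain does not otherwise represent).

MCV (mean corpuscular volume, `M`) relaxes toward the release volume
`M_in` through cell turnover and is pushed up linearly by 6-TGN exposure.
The ~15% volume loss RBCs experience over their lifespan is lumped into an
effective `M_in`: at the drug-free steady state inflow and death terms
cancel exactly, which is what that lumping encodes. A useful closed form
follows from `dR/dt = 0` holding at any drugged steady state: the MCV-shift
plateau is exactly `ΔM = k_m6·x_t/k_dr`, independent of the degree of RBC
suppression.

### Average-patient calibration

The defaults in `sixmp.params` are reproduced deterministically by
`sixmp.calibrate` (CLI: `sixmp calibrate`) from reported clinical anchors:

| anchor | gives |
|---|---|
| plasma half-life 1.2 h | `k_e = ln 2/(1.2/24) ≈ 13.86 d⁻¹` |
| transit rate 0.1207 d⁻¹, steady-state proliferation 0.157 d⁻¹ | `k_tl`, `k_sl = 0.0363 d⁻¹` |
| baseline leukocytes 6×10⁹/L, feedback half-effect there | `θ_L = 6×10⁹`, `k_pl = 0.314 d⁻¹` |
| ECL₅₀ = 84 pmol/8×10⁸ RBC; 75 mg/day titrates leukocytes to 3×10⁹/L | `EL_max = 0.0755 d⁻¹` |
| 120-day RBC lifespan | `k_dr = 1/120 d⁻¹` |
| ~8 fL MCV-shift plateau at sustained 6-TGN of 158 | `k_m6 = 8·k_dr/158` |
| TPMT median 13 of maximum 26 | `e`, `e_max` |
| reported patient-table mean row | `k_pt = 25.1`, `k_te = 0.0661` |

Parameters with no reported anchor are physiological choices: `k_a = 4.8
d⁻¹` (few-hour absorption), `k_dl = 2.4 d⁻¹` (≈7 h circulating leukocyte
half-life), `k_pm/k_me` sized for MeMP plateaus in the low thousands,
`θ_R = 3.5×10¹¹ cells/kg` (normal RBC mass), `M_in = 85 fL`, Hill
coefficients 1.

**Feedback steepness and loop stability.** The feedback/transit loop
contains two slow modes (the self-renewing progenitor pool is a neutral
integrator at equilibrium; the circulating pool turns over at `k_d`).
Linearized eigenanalysis at the drugged equilibrium fixed the steepness
values: `s_l = 1` gives the leukocyte loop a 107-day oscillation decaying
with a 142-day time constant (a damped decline-and-rebound, as seen
clinically); steeper feedback (e.g. `s_l = 2`) is nearly undamped and rings
for years. The erythroid loop, with its 120-day lifespan integrator, is
unstable at comparable gains, so `s_r = 0.2` — also encoding that the EPO
feedback is much weaker than the leukocyte feedback — with a small drug
effect on RBC count (`ER_max = 0.01 d⁻¹`, ≈18% RBC suppression at standard
exposure; MCV macrocytosis, not anemia, is the dominant erythroid response).

## Simulation engines

* `engine="lsoda"` (default): adaptive stiff-capable integration restarted
  at each dose event, rtol 1e-8, state-scaled atol.
* `engine="fast"`: gut/plasma kinetics propagated in closed form between
  boluses; metabolite equations integrated by exponential-trapezoidal
  quadrature on a 0.02-day grid (an IIR recursion); hematopoiesis by
  classical RK4 at 0.1 day, batched over parameter candidates. Agreement
  with the adaptive engine is ≤1e-3 (relative, trajectory-wide); fitting,
  sensitivity analysis and control loops use this path, which makes a
  full-course simulation ~milliseconds per candidate in batch.

## Parameter estimation

Weighted least squares `Σ_k w_k Σ_i (model(t_i) − y_i)²`. Per-variable
weights default to `1/mean(|y|)²`, making multi-variable costs
dimensionless; per-record weights can override (the recovery studies use
`1/y_i²`, i.e. relative residuals, matching the multiplicative assay
noise). The optimizer is a hybrid: a seeded differential-evolution global
stage (vectorized through the batch engine; population 50, 100 generations
by default) followed by bounded local refinement (L-BFGS-B), keeping the
better of the two — the cost never increases across the handoff, and the
whole fit is deterministic given its seed. Simulation failures map to +inf
cost. Bounds collapsed to a point pin the parameter.

Individualization refits **only** the sensitive set from the sensitivity
analysis; redundant parameters stay bit-identical to the average patient.

## Model reduction (Sobol)

Uniform sampling over `[0.5, 2.0] ×` nominal per parameter with a scrambled
Sobol' sequence arranged as Saltelli paired matrices (N base samples →
N·(d+2) model evaluations); total-effect indices by Jansen's formula,
estimated for the clinically measurable output (6-TGN, leukocytes, or MCV)
at six equally spaced time points over the treatment period. Each index is
converted to a freezing error `sqrt(S_T·Var(Y)/p)` — a Chebyshev-type bound
that holds with probability ≥ 1−p (p = 0.05) — and aggregated over the six
time points by root-sum-of-squares (the aggregation operator only affects a
common scale, not the classification, which uses error ratios). Parameters
below 5% of the largest error are redundant. For the 6-MP model this
yields {k_pt, k_te} sensitive with the remainder redundant, stable across
seeds at N = 1000.

## Dose optimization (NMPC)

Piecewise-constant daily dosing, one decision per 15-day sampling interval
over a 75-day window (5 moves), shrinking prediction horizon (the full
remaining window). Quadratic tracking cost at interval endpoints; targets:
6-TGN 300 pmol/8×10⁸ RBC (therapeutic-window midpoint), leukocytes 3×10⁹
cells/L, or both leukocytes and an 8 fL MCV shift (weights default to
inverse squared references). Constraints: dose range [0, 150] mg/day and a
50 mg/day slew bound per interval, enforced exactly by projection. The
solver is multi-start SLSQP (deterministic start set: hold, max, min,
mid-range, plus seeded restarts); only the first move is applied, then the
problem is re-solved from the measured state (perfect-model feedback; no
observer).

An optional leukocyte **hard floor** (`wbc_floor`) adds a stiff penalty on
predicted-count shortfall below the floor, checked every 5 days across the
horizon. The endpoint-only cost does not see inter-sample dips, so pure
tracking solutions can graze ~5% below the target between visits; in floor
mode the operator sets the floor slightly above the clinical limit (the
tests use 2.9×10⁹/L to guarantee 2.85×10⁹/L), standard practice for
penalty-enforced constraints.

The TPMT-guided initial dose bisects the constant daily dose whose steady
6-TGN hits the therapeutic-window midpoint (317.5) under the average model
with the patient's measured activity; an unreachable window (e.g. the
average patient's ceiling of ≈190 at `f_tgn = 0.5`) returns the clipped
dose bound with a warning.

## Synthetic data: what it emulates, what it does not

The package ships the seven reported patient-specific (k_pt, k_te) pairs
verbatim. The 8 leukopoiesis and 10 MCV patient sets are **synthetic
stand-ins** (lognormal spread, CV 30%, fixed seed, so labelled in their
`source` field) sized to reproduce the 56 = 7×8 and 70 = 7×10
virtual-patient cross-combinations; they vary drug-response/turnover
parameters (`EL_max`, `ECL_50`, `k_dl`; `ER_max`, `ECR_50`, `k_m6`) so all
patients share the same drug-free baseline.

Observation noise: multiplicative lognormal (parameterized for an unbiased
mean) with the reported inter-assay CVs of 18% (6-TGN) and 22% (MeMP),
10% CV for leukocyte counts and 1 fL additive noise on the MCV shift
(typical CBC analytics). Sampling schedules are study conditions:

* metabolite recovery: 22 front-loaded samples over 16 weeks (twice-weekly
  draws during the first month of dose-finding, then tapering; chosen by
  Fisher-information design — sparse 6-point schedules carry only ~20–25%
  median error at 18% CV, and the design also keeps the 20-seed median
  stable across replications of the whole study);
* holdout prediction: weekly panels of both metabolites over 24 weeks,
  twice-weekly CBC over 16 weeks, twice-weekly MCV (from the same CBC
  draws) over 24 weeks — the slow marker needs the long window — split
  chronologically at 2/3;
* cohort variability summaries: 336 days for leukocytes (the first
  treatment transient peaks near day 107 and subsides as feedback
  re-equilibrates the cohort), 112 days — the 4-month evaluation window —
  for the MCV shift (whose spread is still growing there).

Passing these studies shows the workflow is internally consistent under
realistic noise and inter-patient spread; it does not validate the models
against real patients, adherence gaps, dose interruptions, co-therapy
(methotrexate), or assay drift, none of which the generator emulates.

## Numerical choices and degenerate inputs

Integrator tolerances as above; RK4 states are clipped at zero (population
non-negativity); zero circulating RBCs is a singular state (error); no
positive equilibrium (proliferation below transit + attrition) raises an
infeasible-baseline error; zero output variance at a sensitivity time point
flags the point and excludes it from cumulative errors; an all-infeasible
optimizer budget raises a no-feasible-candidate error; ties in the NMPC
solver keep the hold-previous-dose plan (so an indifferent cost changes
nothing). Holdout gaps floor their denominator at 1e-5 of the weighted
data scale — below that, an SSE is a noise-free fit converged to optimizer
tolerance — so such fits report a vanishing gap rather than a 0/0 artifact.

## Known limitations

* The exposure ceiling means the 300 pmol/8×10⁸ RBC 6-TGN target is
  structurally unreachable for reported patients whose `f_tgn·k_pt/k_te`
  is below it (5 of 7 at the median TPMT split; 2 of 7 even at TPMT-null) —
  the controller saturates at the ceiling. See the validation study output.
* Deep conversion saturation makes steady 6-TGN nearly dose-flat above a
  few mg/day; dose-responsiveness of exposure and the reported
  insensitivity to absorption/elimination parameters are in structural
  tension, and this package resolves it in favor of the sensitivity
  ranking.
* Leukocyte dynamics are total-WBC, one lineage; no platelets/neutrophil
  subsets, no inter-occasion variability, no state estimation, and
  measurements at visits are assumed exact.
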