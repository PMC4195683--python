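# sixmp

Model-based individualized dosing of 6-mercaptopurine (6-MP) for childhood
acute lymphoblastic leukemia (ALL) maintenance therapy.

During the 2–3 year maintenance phase, children take daily oral 6-MP. The
drug is a pro-drug: intracellular metabolism splits it between active
6-thioguanine nucleotides (6-TGN, the cytotoxic species measured in red
cells) and inactive methylated metabolites (MeMP), with the split governed
by the polymorphic enzyme TPMT. Underdosing risks relapse; overdosing
causes life-threatening leukopenia. Clinicians currently titrate doses by
trial and error against the complete blood count. This package implements
a quantitative alternative for pharmacometricians and control engineers:

* **Simulate** — three coupled semi-mechanistic ODE systems: 6-MP
  metabolism (gut → plasma → RBC metabolites, TPMT-partitioned
  Michaelis–Menten conversion), transit-compartment leukopoiesis with
  count feedback and a Hill-type 6-TGN kill term, and erythropoiesis with
  mean-corpuscular-volume (MCV) dynamics — the MCV rise under therapy is a
  surrogate efficacy marker.
* **Reduce** — variance-based (Sobol) global sensitivity analysis over
  [0.5, 2]× parameter boxes; total-effect indices become probabilistic
  parameter-freezing errors and a 5% rule splits parameters into a
  sensitive set (individualized per patient) and a redundant set (frozen
  at average-patient values). For the 6-MP model the sensitive set is
  {k_pt, k_te}: the 6-TGN formation capacity and elimination rate.
* **Individualize** — weighted least-squares fitting of only the sensitive
  parameters to sparse, noisy clinical measurements (18%/22% metabolite
  assay CVs), with a seeded hybrid global+local optimizer, plus
  forward-in-time holdout validation.
* **Optimize** — nonlinear model predictive control of the daily dose:
  15-day clinical visits over a 75-day window, quadratic tracking of a
  6-TGN target (300 pmol/8×10⁸ RBC), a leukocyte target (3×10⁹ cells/L,
  optionally with a hard safety floor), or leukocytes + an 8 fL MCV shift,
  under dose-range and slew-rate constraints; only the first move of each
  plan is prescribed.

The models, their average-patient calibration, the synthetic-data
generator and all numerical choices are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

Simulating the standard 75 mg/day regimen for 16 weeks
(`python examples/01_simulate_treatment_course.py`):

```
6-TGN plateau (day 112):     189.6 pmol/8e8 RBC (100-250 is the range reported across human studies)
MeMP plateau (day 112):       2997 pmol/8e8 RBC
leukocyte nadir:              1.89 e9 cells/L at day 74 (baseline 6.00; marrow transit delays the dip)
MCV shift at day 112:         5.68 fL (rises toward ~8 fL under sustained exposure)
```

The 6-TGN exposure settles inside the reported human range; the
leukocyte count dips with a multi-week delay (marrow maturation) before
feedback pulls it back; the MCV shift climbs slowly toward its ~8 fL
plateau — efficacy shows up months after exposure.

Model reduction on the metabolism model
(`python examples/03_model_reduction_gsa.py`):

```
parameter error pct_of_max classification
      k_a  23.6       2.76      redundant
      k_e    15       1.75      redundant
     k_pt   817      95.42      sensitive
      K_t  8.98       1.05      redundant
     k_pm     0       0.00      redundant
      K_m     0       0.00      redundant
     k_te   856     100.00      sensitive
     k_me     0       0.00      redundant
```

Only the two 6-TGN turnover parameters matter for the measurable exposure,
so those two are what sparse clinical data must identify — fitting them
from 22 noisy 6-TGN samples recovers both to ~10% median error
(`examples/02_fit_individual_patient.py`), and the dose optimizer then
runs on the individualized model (`examples/04_nmpc_dose_optimization.py`,
`examples/05_virtual_cohort.py` for cohort-level variability).

## Command line

A thin CLI wraps the library for shell use:

```bash
sixmp simulate --regimen daily:75mg:112d --out traj.csv
sixmp fit --obs obs.csv --free k_pt,k_te --seed 7
sixmp gsa --model 6mp --n 1000 --seed 11 --out report.json
sixmp optimize --mode tgn --out trace.csv
sixmp cohort --mode leuko --dose daily:75mg:112d --out summary.csv
sixmp calibrate
```

Exit codes: 0 success, 2 configuration error, 3 numerical failure.

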