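"""Simulate a standard 16-week maintenance course for the average patient.

Prints the steady RBC 6-TGN and MeMP exposure reached under 75 mg/day oral
6-MP, the leukocyte nadir caused by marrow suppression, and the MCV shift
used as the efficacy surrogate.
"""

import numpy as np

from sixmp import DoseRegimen, simulate_course

regimen = DoseRegimen.daily(75, 112)          # 75 mg/day for 16 weeks
traj = simulate_course(regimen, horizon_days=112.0)

x_t = traj.values["x_t"]
L = traj.values["L"]
dmcv = traj.values["dmcv"]

print(f"6-TGN plateau (day 112):   {x_t[-1]:7.1f} pmol/8e8 RBC "
      "(100-250 is the range reported across human studies)")
print(f"MeMP plateau (day 112):    {traj.values['x_m'][-1]:7.0f} pmol/8e8 RBC")
nadir = np.argmin(L)
print(f"leukocyte nadir:           {L[nadir] / 1e9:7.2f} e9 cells/L at day "
      f"{traj.times[nadir]:.0f} (baseline 6.00; marrow transit delays the dip)")
print(f"MCV shift at day 112:      {dmcv[-1]:7.2f} fL "
      "(rises toward ~8 fL under sustained exposure)")
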