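"""Sobol model reduction of the 6-MP metabolism model.

Samples the 8-parameter space over [0.5, 2.0] x nominal, estimates total
sensitivity indices of the RBC 6-TGN output at six representative time
points, converts them to parameter-freezing errors, and applies the 5%
redundancy rule.  Only the sensitive parameters are estimated per patient;
the rest stay at average values.
"""

from sixmp import GsaSpec, run_gsa

report = run_gsa(GsaSpec(output="x_t", n=1000, seed=11))

print(report.table.to_string(index=False,
                             formatters={"error": "{:.3g}".format,
                                         "pct_of_max": "{:.2f}".format}))
print()
print("sensitive (individualized per patient):", ", ".join(report.sensitive))
print("redundant (frozen at average values):  ", ", ".join(report.redundant))
print("\nThe 6-TGN formation capacity (k_pt) and elimination rate (k_te) drive")
print("essentially all output variance; absorption/elimination of the parent")
print("drug and the Michaelis constants are redundant at clinical exposures.")
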