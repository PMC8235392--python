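"""Generate the default 10+10 synthetic cohort, fit every spectrum, and
build the per-temperature fast-vs-slow Py comparison table.

The cohort emulates the study design: ten water-bath (fast) and ten air
(slow) thawed samples, measured at each 0.5 degC from 0 to 4 degC and once
more the next day after >16 h of chilled storage.  The Mann-Whitney U test
compares the groups at each temperature.
"""

import thawspec as ts
from thawspec.simulate import MEASUREMENT_TEMPS
from thawspec.stats import comparison_rows_to_frame, py_mapping_from_fits

cohort = ts.generate_cohort(ts.SimulatorConfig(seed=0))
fits = ts.fit_cohort(cohort)
rows = ts.comparison_table(py_mapping_from_fits(fits, MEASUREMENT_TEMPS), MEASUREMENT_TEMPS)

print(f"{'T (degC)':>9} {'fast mean':>10} {'slow mean':>10} {'MWU p':>8}")
for r in rows:
    print(f"{r.temperature_label:>9} {r.fast.mean:10.2f} {r.slow.mean:10.2f} {r.p_value:8.4f}")

frame = comparison_rows_to_frame(rows)
print("\nLong-format table columns:", ", ".join(frame.columns))
print("During thawing the fast group keeps a higher Py (more intact membranes);")
print("after a night of chilled storage both groups collapse toward low Py and the")
print("gap shrinks sharply (whether it stays significant varies from draw to draw).")
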