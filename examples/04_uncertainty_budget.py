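"""Build and render the absolute-dose uncertainty budget.

Components are relative standard uncertainties (%, 1 SD) accumulated in
quadrature; the combined value is expanded with a coverage factor k=2.
"""

from ebt3dose import UncertaintyBudget, absolute_dose_budget

budget = absolute_dose_budget()
print(budget.render(k=2.0))
print()

# Truncating the chain after calibration gives the film-response part only:
truncated = UncertaintyBudget(coverage_factor=2.0)
for comp in budget.components[:2]:
    truncated.add(comp.label, comp.value_pct)
print(f"film calibration chain only: {truncated.combined():.2f} % (1 SD), "
      f"{truncated.expanded():.2f} % (k=2)")
# The final row of the table is the expanded uncertainty of an absolute
# film dose measurement; each cumulative entry is the root sum of squares
# of the steps above it.
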