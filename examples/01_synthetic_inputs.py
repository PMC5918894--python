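"""Generate every synthetic input the pipeline consumes.

Builds Gompertz-Makeham life tables, a 2008-like demography pyramid
(2.23 million people, 51 % women), and the cost/utility tables, then prints
a few headline numbers.  The life-table q values are annual other-cause
death probabilities; the pyramid counts sum exactly to the requested total.
"""
from crcsim import (default_cost_utility_tables, default_life_tables,
                    generate_demography)

life_tables = default_life_tables()
pyramid = generate_demography()
costs, utilities = default_cost_utility_tables()

print("male q(50) =", round(life_tables["male"].q[50], 5),
      "| q(80) =", round(life_tables["male"].q[80], 4))
print("population:", pyramid.total, "| female share:",
      round(pyramid.female_share, 4))
print("invitation cost:", costs.invitation, "EUR |",
      "colonoscopy disutility:", utilities.disutility_colonoscopy, "QALY")
# q rises steeply with age (Gompertz), the female share is the published
# 51 %, and the unit costs/disutilities are the published 2012-euro values.
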