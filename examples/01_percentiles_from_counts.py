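"""From raw prescribing counts to peer percentiles.

Builds a tiny three-practice measure table by hand, converts the monthly
numerator/denominator counts to ratios, and ranks each practice among its
peers month by month. Note how practice C's zero-denominator month becomes a
missing percentile rather than a zero.
"""

import pandas as pd

from peercusum import compute_percentiles, compute_ratios

table = pd.DataFrame(
    [
        # entity, month, numerator, denominator
        ("A", "2020-01", 10, 100),
        ("B", "2020-01", 25, 100),
        ("C", "2020-01", 60, 100),
        ("A", "2020-02", 12, 100),
        ("B", "2020-02", 30, 100),
        ("C", "2020-02", 0, 0),  # no qualifying prescribing this month
    ],
    columns=["entity_id", "month", "numerator", "denominator"],
)

ratios = compute_ratios(table)
percentiles = compute_percentiles(ratios)

print("ratios (numerator / denominator):")
print(ratios.round(2), "\n")
print("peer percentiles (0 = lowest ratio that month, 100 = highest):")
print(percentiles)
print(
    "\nIn 2020-01 the three practices span 0/50/100; in 2020-02 practice C "
    "reports nothing, so A and B split the scale and C is missing."
)
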