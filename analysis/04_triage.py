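#!/usr/bin/env python
"""Three-step risk triage of the cohort.

Applies the screening rule — densitometry (T-score, TBS, bone strain), serum
CTX, Romberg balance test — to every record and tabulates the risk levels
and the criteria that triggered them.
"""

from collections import Counter

import pandas as pd

from osteomap.clinical import TriageThresholds, triage_risk
from osteomap.cohort import read_cohort_csv

cohort = read_cohort_csv("results/cohort.csv")
th = TriageThresholds()
cats = [triage_risk(row, th) for _, row in cohort.data.iterrows()]

df = pd.DataFrame(
    {
        "patient_id": cohort.ids,
        "risk_level": [c.level for c in cats],
        "reasons": ["; ".join(c.reasons) for c in cats],
    }
)
df.to_csv("results/triage.csv", index=False)

print("risk levels:")
for level in ("high", "intermediate", "low"):
    print(f"  {level:12s} {sum(c.level == level for c in cats):4d}")

reason_counts = Counter(r for c in cats for r in c.reasons)
print("\ncriteria triggered:")
for reason, n in reason_counts.most_common():
    print(f"  {reason:24s} {n:4d}")
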