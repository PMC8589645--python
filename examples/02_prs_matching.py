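"""Frequency-matched PRS-extreme cases and middle-quantile controls.

The number of PRS-extreme "cases" is matched to the cohort's high-risk CNV
carrier count, and controls are the middle 20-80% of the same score
distribution — comparing an extreme against the bulk, not against the
opposite extreme. With N = 23,053 the rank rule yields exactly 13,831
controls (and 2,937 for N = 4,895).
"""

import numpy as np
import pandas as pd

from cnvburden import prs_grouping

rng = np.random.default_rng(7)
for n, n_carriers in ((23_053, 573), (4_895, 171)):
    scores = pd.Series(rng.standard_normal(n),
                       index=[f"s{i:05d}" for i in range(n)])
    g = prs_grouping(scores, n_cases=n_carriers, tail="low")
    counts = g["label"].value_counts()
    print(f"N={n}: {counts['extreme_case']} extreme cases "
          f"(matched to {n_carriers} carriers), "
          f"{counts['middle_control']} middle-band controls, "
          f"{counts['neither']} outside both groups")
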