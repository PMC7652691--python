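"""Published bicluster tallies used for verification.

Inner/outer patient counts across the seven biclusters of high-risk
comorbidities reported for a 2010 Medicare hip-fracture readmission
cohort (6150 readmitted patients carrying at least one of the eight
significant, replicated comorbidities).  "Outer" patients carry exactly
one of the network's comorbidities; "inner" patients more than one.
These printed counts are plain inputs: the heterogeneity chi-square and
the per-bicluster shares are recomputed from them at run time.
"""

from __future__ import annotations

import numpy as np

BICLUSTER_LABELS = [
    "CHF",
    "Arrhythmia",
    "Stroke",
    "MCMCT",
    "COPD",
    "Vascular disease",
    "Renal failure and diabetes",
]

# rows: exactly one comorbidity, more than one comorbidity
INNER_OUTER_COUNTS = np.array(
    [
        [536, 545, 37, 337, 510, 114, 1062],
        [536, 236, 233, 518, 726, 412, 348],
    ]
)
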