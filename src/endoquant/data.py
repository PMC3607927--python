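"""Published summary time courses for IGF-II and insulin internalization through IR-B.

Mean per-cell internalization ratios (QD_interior / QD_total), s.e.m. and
cell counts from the microscopy experiment, at 0, 10, 20 and 150 minutes at
37 degC.  These summaries are the worked-example inputs for the kinetic fits.
"""

from __future__ import annotations

import pandas as pd

TIMES_MIN = (0.0, 10.0, 20.0, 150.0)

#: ligand -> (mean ratios, s.e.m., n cells) at TIMES_MIN
REFERENCE_TIMECOURSES: dict[str, dict[str, tuple]] = {
    "IGF-II": {
        "mean": (0.17, 0.60, 0.72, 0.96),
        "sem": (0.03, 0.03, 0.03, 0.01),
        "n": (29, 20, 20, 19),
    },
    "insulin": {
        "mean": (0.06, 0.38, 0.41, 0.95),
        "sem": (0.01, 0.03, 0.03, 0.01),
        "n": (28, 10, 20, 23),
    },
}


def reference_summary() -> pd.DataFrame:
    """The published summaries as a tidy frame (ligand, time_min, mean, sem, n)."""
    rows = []
    for ligand, d in REFERENCE_TIMECOURSES.items():
        for t, m, s, n in zip(TIMES_MIN, d["mean"], d["sem"], d["n"]):
            rows.append({"ligand": ligand, "time_min": t, "mean": m, "sem": s, "n": n})
    return pd.DataFrame(rows)
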