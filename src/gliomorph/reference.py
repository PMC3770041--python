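"""Published reference-cohort summary statistics.

Group-level (mean, SD, n) cells of the reference glioma nuclear
morphometry study: 10 non-neoplastic controls (CG), 14 low-grade gliomas
(LGG: 10 diffuse astrocytoma, 4 oligoastrocytoma; WHO grade II) and 16
high-grade gliomas (HGG: 3 anaplastic astrocytoma grade III, 13
glioblastoma grade IV).  Each case's value is the mean over its 100
selected nuclei (shape parameters) or its five high-power fields (ND,
%TNA), so the SDs are between-case SDs of per-case means.

These cells are the calibration targets of the synthetic-cohort
generator and the inputs to the summary-statistics t-test path.
"""

from __future__ import annotations

import pandas as pd

GROUP_SIZES = {"CG": 10, "LGG": 14, "HGG": 16}

#: parameter -> group -> (mean, sd, n).  Units: MAJX/MINX/NP µm, NA µm²,
#: NR %, ND mm^-2, TNA %, Age years.
REFERENCE_GROUP_STATS: dict[str, dict[str, tuple[float, float, int]]] = {
    "MAJX": {"CG": (6.96, 0.59, 10), "LGG": (9.41, 0.81, 14),
             "HGG": (10.73, 1.33, 16)},
    "MINX": {"CG": (4.62, 0.35, 10), "LGG": (6.34, 0.70, 14),
             "HGG": (7.11, 0.94, 16)},
    "NA": {"CG": (23.44, 4.01, 10), "LGG": (42.62, 7.26, 14),
           "HGG": (55.22, 13.48, 16)},
    "NP": {"CG": (21.54, 2.11, 10), "LGG": (29.79, 2.80, 14),
           "HGG": (34.24, 4.49, 16)},
    "NR": {"CG": (65.55, 4.34, 10), "LGG": (61.53, 5.42, 14),
           "HGG": (59.78, 5.80, 16)},
    "ND": {"CG": (1107.0, 138.0, 10), "LGG": (3232.0, 1596.0, 14),
           "HGG": (4350.0, 1089.0, 16)},
    "TNA": {"CG": (2.32, 0.54, 10), "LGG": (9.98, 4.34, 14),
            "HGG": (15.88, 7.48, 16)},
    "Age": {"CG": (46.3, 3.5, 10), "LGG": (39.1, 14.1, 14),
            "HGG": (54.6, 16.8, 16)},
}

#: parameter -> group -> (min, max) of the per-case means.
REFERENCE_GROUP_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "MAJX": {"CG": (6.23, 8.07), "LGG": (7.51, 10.30), "HGG": (8.90, 12.87)},
    "MINX": {"CG": (4.18, 5.30), "LGG": (4.98, 7.56), "HGG": (4.66, 8.70)},
    "NA": {"CG": (19.42, 30.33), "LGG": (27.15, 55.23), "HGG": (30.26, 76.90)},
    "NP": {"CG": (18.84, 25.33), "LGG": (23.34, 32.74), "HGG": (28.92, 41.91)},
    "NR": {"CG": (59.85, 73.48), "LGG": (48.99, 70.43), "HGG": (48.94, 70.40)},
    "ND": {"CG": (849.0, 1282.0), "LGG": (1456.0, 5633.0),
           "HGG": (1941.0, 6360.0)},
    "TNA": {"CG": (1.65, 3.33), "LGG": (3.63, 17.35), "HGG": (6.64, 35.33)},
    "Age": {"CG": (40.0, 53.0), "LGG": (9.0, 62.0), "HGG": (27.0, 79.0)},
}


def reference_summary_frame() -> pd.DataFrame:
    """The reference cells as a tidy frame (parameter, group, n, mean, sd).

    This is the format accepted by the ``analyze --from-summary`` path,
    so the published pairwise P values can be recomputed with no images.
    """
    rows = []
    for param, per_group in REFERENCE_GROUP_STATS.items():
        for group, (mean, sd, n) in per_group.items():
            rows.append({"parameter": param, "group": group, "n": n,
                         "mean": mean, "sd": sd})
    return pd.DataFrame(rows)
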