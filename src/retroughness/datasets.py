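"""Published reference values for desk-scale cross-checks.

Group mean (and SD) fractal dimensions of the 10 retinal-layer thickness
maps, as printed (4 decimals) in a clinical study of 19 mild Alzheimer's
disease patients and 24 healthy controls.  These printed group means are
the inputs to the paired-layer comparisons (paired t, variance ratio,
Shapiro-Wilk) that can be reproduced without the clinical per-subject
data; subject-level FD values were not published.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .surfaces_io import LAYER_NAMES

#: per-layer FD mean and SD, disease group, layers 1..10 (NFL..RPE)
FD_MEAN_AD = np.array(
    [2.1074, 2.1033, 2.1136, 2.1105, 2.1180, 2.0939, 2.1281, 2.1217, 2.1230, 2.1269]
)
FD_SD_AD = np.array(
    [0.0057, 0.0083, 0.0069, 0.0080, 0.0076, 0.0088, 0.0081, 0.0103, 0.0106, 0.0071]
)

#: per-layer FD mean and SD, control group
FD_MEAN_CTL = np.array(
    [2.1018, 2.1012, 2.1110, 2.1078, 2.1169, 2.0885, 2.1278, 2.1219, 2.1219, 2.1232]
)
FD_SD_CTL = np.array(
    [0.0040, 0.0061, 0.0060, 0.0067, 0.0084, 0.0087, 0.0067, 0.0075, 0.0053, 0.0043]
)

#: total-retina FD (surface 11 minus surface 1)
FD_TOTAL_AD = (2.0782, 0.0105)
FD_TOTAL_CTL = (2.0800, 0.0085)

#: published cohort-level mean FD over the 10 layers (mean, SD) per group
MEAN_FD_10_AD = (2.1146, 0.0054)
MEAN_FD_10_CTL = (2.1122, 0.0043)
MEAN_FD_9_AD = (2.1133, 0.0056)
MEAN_FD_9_CTL = (2.1110, 0.0044)

N_AD = 19
N_CTL = 24


def layer_fd_table() -> pd.DataFrame:
    """The published per-layer FD group means and SDs as a tidy table."""
    return pd.DataFrame(
        {
            "layer": LAYER_NAMES,
            "fd_mean_ad": FD_MEAN_AD,
            "fd_sd_ad": FD_SD_AD,
            "fd_mean_ctl": FD_MEAN_CTL,
            "fd_sd_ctl": FD_SD_CTL,
        },
        index=pd.RangeIndex(1, 11, name="layer_index"),
    )
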