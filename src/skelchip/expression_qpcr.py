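"""Reference-normalized relative expression between WT and KO groups.

Per-sample target abundance is normalized to a reference gene (Gapdh)
measured in the same sample, and all ratios are rescaled so the wild-type
group mean equals 1; a knockout group mean above or below 1 then reads
directly as up- or down-regulation relative to wild type.  Group differences
are tested with the classical two-tailed unpaired (pooled-variance) Student
t-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def relative_expression(samples: pd.DataFrame, ct_scale: bool = False) -> pd.DataFrame:
    """Per-sample target/reference ratios scaled so the WT mean is 1.

    ``samples`` requires columns genotype (WT|KO), target, reference.  With
    ``ct_scale`` the inputs are interpreted as qPCR cycle thresholds and the
    ratio is ``2**-(Ct_target - Ct_reference)``; otherwise inputs are
    linear-scale abundances and the ratio is ``target / reference``.
    """
    df = samples.copy()
    if (df["reference"] <= 0).any() and not ct_scale:
        raise ValueError("reference measures must be positive on the linear scale")
    if ct_scale:
        df["ratio"] = 2.0 ** -(df["target"] - df["reference"])
    else:
        df["ratio"] = df["target"] / df["reference"]
    wt = df.loc[df["genotype"] == "WT", "ratio"]
    if len(wt) == 0:
        raise ValueError("need at least one WT sample to define the scale")
    df["relative"] = df["ratio"] / wt.mean()
    return df


def group_ttest(wt, ko) -> tuple[float, float]:
    """Equal-variance two-tailed unpaired t-test; returns (t, p)."""
    wt = np.asarray(wt, dtype=float)
    ko = np.asarray(ko, dtype=float)
    if len(wt) < 2 or len(ko) < 2:
        raise ValueError("each group needs at least 2 values for a t-test")
    if wt.var(ddof=1) == 0.0 and ko.var(ddof=1) == 0.0:
        # degenerate pooled variance: equal means are indistinguishable,
        # unequal means are separated with certainty
        if wt.mean() == ko.mean():
            return 0.0, 1.0
        return float(np.sign(wt.mean() - ko.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(wt, ko, equal_var=True)
    return float(t), float(p)
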