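"""The statistical battery applied to quantification outputs.

Paired t tests for within-embryo (stripe vs interstripe) comparisons,
unpaired t tests between genotypes, one-way ANOVA with Dunnett's multiple
comparisons against a control, and the two normality checks
(D'Agostino-Pearson omnibus and Shapiro-Wilk).  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedMeasurements",
    "paired_t",
    "unpaired_t",
    "anova_dunnett",
    "normality_check",
    "stars",
]


@dataclass
class GroupedMeasurements:
    """Label -> values, with an optional within-subject pairing key."""

    groups: dict[str, np.ndarray]
    pairing: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if self.pairing is not None:
            lens = {k: len(v) for k, v in self.groups.items()}
            if len(set(lens.values())) != 1:
                raise ValueError("paired groups must have equal lengths")
            keys = [tuple(self.pairing[k]) for k in self.groups]
            if len(set(keys)) != 1:
                raise ValueError("pairing keys misaligned across groups")


def paired_t(group_a, group_b) -> tuple[float, float]:
    """Paired two-sided t test (intragroup comparisons, e.g. stripe vs
    interstripe within the same embryos)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must be aligned and equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if d.std(ddof=1) == 0:
        if np.allclose(d, 0):
            return 0.0, 1.0
        raise ValueError("constant nonzero difference; paired t undefined")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def unpaired_t(group_a, group_b, welch: bool = False) -> tuple[float, float]:
    """Two-sample two-sided t test (intergroup comparisons); classic
    equal-variance by default, Welch via flag."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def anova_dunnett(groups: dict[str, np.ndarray], control_label: str) -> pd.DataFrame:
    """Ordinary one-way ANOVA followed by Dunnett's multiple comparisons
    against the control group.

    Returns a tidy frame: one row per non-control group with the ANOVA F/p
    (repeated) and the Dunnett-adjusted p value for that comparison.
    """
    if control_label not in groups:
        raise ValueError(f"control group '{control_label}' missing")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = [k for k in groups if k != control_label]
    control = np.asarray(groups[control_label], dtype=float)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    f_stat, f_p = sps.f_oneway(control, *samples)
    dunnett = sps.dunnett(*samples, control=control)
    return pd.DataFrame(
        {
            "comparison": [f"{k} vs {control_label}" for k in labels],
            "anova_F": float(f_stat),
            "anova_p": float(f_p),
            "statistic": dunnett.statistic,
            "p_adjusted": dunnett.pvalue,
            "stars": [stars(p) for p in dunnett.pvalue],
        }
    )


def normality_check(values) -> pd.DataFrame:
    """D'Agostino-Pearson omnibus and Shapiro-Wilk normality tests.

    Tests whose sample-size minimum is not met are reported with a note
    instead of a statistic; a constant sample is flagged degenerate.
    """
    arr = np.asarray(values, dtype=float)
    rows = []
    degenerate = arr.size > 0 and np.ptp(arr) == 0
    # D'Agostino-Pearson needs n >= 8 for the kurtosis component
    if degenerate:
        rows.append({"test": "dagostino_pearson", "statistic": np.nan, "p": np.nan,
                     "note": "degenerate: constant sample"})
    elif arr.size >= 8:
        s, p = sps.normaltest(arr)
        rows.append({"test": "dagostino_pearson", "statistic": float(s), "p": float(p), "note": ""})
    else:
        rows.append({"test": "dagostino_pearson", "statistic": np.nan, "p": np.nan,
                     "note": f"skipped: n={arr.size} < 8"})
    if degenerate:
        rows.append({"test": "shapiro_wilk", "statistic": np.nan, "p": np.nan,
                     "note": "degenerate: constant sample"})
    elif arr.size >= 3:
        s, p = sps.shapiro(arr)
        rows.append({"test": "shapiro_wilk", "statistic": float(s), "p": float(p), "note": ""})
    else:
        rows.append({"test": "shapiro_wilk", "statistic": np.nan, "p": np.nan,
                     "note": f"skipped: n={arr.size} < 3"})
    return pd.DataFrame(rows)


def stars(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
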