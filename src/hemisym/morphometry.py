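"""Corpus-callosum volume statistics.

Five anteroposterior callosal segments are regrouped into a posterior section
(posterior + mid-posterior + central) and an anterior section (mid-anterior +
anterior).  Because a cross-sectional area scales as the 2/3 power of an
object's volume, relative section sizes are the section volume divided by the
total brain volume to the 2/3 power.  Group contrasts are directional
two-sample t-tests on the relative sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "POSTERIOR_SEGMENTS",
    "ANTERIOR_SEGMENTS",
    "regroup_segments",
    "relative_callosal_size",
    "summarize_callosal_table",
    "cc_group_test",
    "cc_brain_correlation",
    "CCTestResult",
]

POSTERIOR_SEGMENTS = ["cc_posterior", "cc_midposterior", "cc_central"]
ANTERIOR_SEGMENTS = ["cc_midanterior", "cc_anterior"]


def regroup_segments(segments) -> tuple[float, float]:
    """Sum five segment volumes into (posterior, anterior) section volumes.

    Segment order: posterior, mid-posterior, central, mid-anterior, anterior.
    """
    seg = np.asarray(segments, dtype=float)
    if seg.shape != (5,):
        raise ValueError("exactly five segment volumes are required")
    if np.any(seg <= 0):
        raise ValueError("segment volumes must be strictly positive")
    return float(seg[:3].sum()), float(seg[3:].sum())


def relative_callosal_size(section_volume: float, brain_volume: float) -> float:
    """Section volume normalised by brain volume to the two-thirds power."""
    if brain_volume <= 0:
        raise ValueError("brain volume must be positive")
    return float(section_volume) / float(brain_volume) ** (2.0 / 3.0)


def summarize_callosal_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject section sums, totals, and relative sizes.

    Expects the callosal CSV dialect (columns ``subject_id, group,
    cc_posterior, cc_midposterior, cc_central, cc_midanterior, cc_anterior,
    brain_volume``).  Regrouping conserves total CC volume exactly.
    """
    required = POSTERIOR_SEGMENTS + ANTERIOR_SEGMENTS + ["brain_volume"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    seg = table[POSTERIOR_SEGMENTS + ANTERIOR_SEGMENTS].to_numpy(dtype=float)
    if np.any(seg <= 0) or np.any(table["brain_volume"].to_numpy(dtype=float) <= 0):
        raise ValueError("all volumes must be strictly positive")
    out = pd.DataFrame(
        {
            "subject_id": table["subject_id"],
            "group": table["group"],
            "posterior": table[POSTERIOR_SEGMENTS].sum(axis=1),
            "anterior": table[ANTERIOR_SEGMENTS].sum(axis=1),
            "brain_volume": table["brain_volume"],
        }
    )
    out["total_cc"] = out["posterior"] + out["anterior"]
    brain23 = out["brain_volume"] ** (2.0 / 3.0)
    out["rel_posterior"] = out["posterior"] / brain23
    out["rel_anterior"] = out["anterior"] / brain23
    return out


@dataclass
class CCTestResult:
    t: float
    p: float
    percent_difference: float
    section: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int


def cc_group_test(
    summaries: pd.DataFrame,
    group_a: str,
    group_b: str,
    section: str = "posterior",
    tail: str = "greater",
    equal_var: bool = True,
) -> CCTestResult:
    """Directional two-sample t-test on relative section sizes (A vs B).

    Pooled variance by default (Welch via ``equal_var=False``).  The percent
    difference of group means is reported as ``(mean_A - mean_B)/mean_B*100``.
    """
    col = {"posterior": "rel_posterior", "anterior": "rel_anterior"}.get(section)
    if col is None:
        raise ValueError("section must be 'posterior' or 'anterior'")
    a = summaries.loc[summaries["group"] == group_a, col].to_numpy(dtype=float)
    b = summaries.loc[summaries["group"] == group_b, col].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("at least 2 subjects per group are required")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("degenerate variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=tail)
    pct = (a.mean() - b.mean()) / b.mean() * 100.0
    return CCTestResult(
        t=float(res.statistic),
        p=float(res.pvalue),
        percent_difference=float(pct),
        section=section,
        group_a=group_a,
        group_b=group_b,
        n_a=int(a.size),
        n_b=int(b.size),
    )


def cc_brain_correlation(summaries: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation between total CC volume and total brain volume."""
    if len(summaries) < 4:
        raise ValueError("at least 4 subjects are required")
    cc = summaries["total_cc"].to_numpy(dtype=float)
    brain = summaries["brain_volume"].to_numpy(dtype=float)
    if np.ptp(cc) == 0 or np.ptp(brain) == 0:
        raise ValueError("zero variance in one of the columns")
    res = stats.pearsonr(cc, brain)
    return float(res.statistic), float(res.pvalue)
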