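"""Clinical summary statistics for patient tables.

Small helpers for the descriptive layer of the study: mean +/- sample SD
of QTc intervals, Welch's unequal-variance t-test for group comparisons,
and keyword tabulation of free-text cardiac-event strings into
syncope / ventricular fibrillation / cardiac arrest categories.
"""

from __future__ import annotations

import re

import numpy as np
from scipy import stats

__all__ = ["mean_sd", "welch_t", "event_tabulate"]


def mean_sd(values) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values for a sample SD")
    return float(x.mean()), float(x.std(ddof=1))


def welch_t(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch two-sample t-test (two-sided); returns (t, df, p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# category patterns, in priority order: one record counts in at most one
# category; syncope outranks VF outranks cardiac arrest.  Sudden-death
# strings do not form a category of their own.
_EVENT_PATTERNS = [
    ("syncope", re.compile(r"\bsyncope\b", re.IGNORECASE)),
    ("VF", re.compile(r"\bVF\b", re.IGNORECASE)),
    ("CA", re.compile(r"\bCA\b|cardiac arrest", re.IGNORECASE)),
]


def event_tabulate(records) -> dict[str, int]:
    """Count cardiac-event categories over free-text event strings.

    Asymptomatic and unmatched records contribute to no category, so the
    counts sum to at most the number of records.
    """
    counts = {"syncope": 0, "VF": 0, "CA": 0}
    for rec in records:
        text = str(rec)
        for name, pat in _EVENT_PATTERNS:
            if pat.search(text):
                counts[name] += 1
                break
    return counts
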