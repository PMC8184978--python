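"""Published reference results from the motivating eight-patient study.

The study that motivates this package followed bipolar-I patients with
continuous wrist actigraphy for ~180 days; eight experienced a mood episode
(three manic, five depressive).  Its raw recordings were never deposited,
but the per-patient outcome tables were published and serve here as inputs
for group-level computations (Fisher combination, significance counts) and
as fixed points for the mean-activity comparison labels.

``reported_trend_tests`` holds the per-patient Mann-Kendall outcomes for
each early-warning indicator (z, tau, n, two-sided p, reported direction).
Entries printed as "< 0.001" are stored as 0.001 with ``p_is_upper_bound``
set.  Note the published direction column disagrees with the sign of z/tau
for three kurtosis rows (patients 3, 4, 15); this package derives direction
from sign(S) and keeps the printed column verbatim here.

``reported_mean_activity`` holds the euthymic-reference vs comparison-week
mean counts, for the week before onset (``period="pre_onset"``) and, from
the post-hoc analysis, the first week of the episode (``period="during"``).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reported_trend_tests", "reported_mean_activity"]

# id, episode_type, indicator, z, tau, n, p, p_is_upper_bound, printed direction
_TREND_ROWS = [
    (1, "D", "variance", 3.319, 0.444, 28, 0.001, False, "increase"),
    (1, "D", "kurtosis", 1.857, 0.249, 28, 0.066, False, "increase"),
    (1, "D", "acf720", 1.663, 0.233, 28, 0.096, False, "increase"),
    (2, "M", "variance", 0.988, 0.132, 28, 0.336, False, "increase"),
    (2, "M", "kurtosis", 0.553, 0.074, 28, 0.597, False, "increase"),
    (2, "M", "acf720", -2.736, -0.380, 28, 0.006, False, "decrease"),
    (3, "D", "variance", 0.909, 0.122, 28, 0.377, False, "increase"),
    (3, "D", "kurtosis", -1.976, -0.265, 28, 0.050, False, "increase"),
    (3, "D", "acf720", -5.719, -0.783, 28, 0.001, True, "decrease"),
    (4, "M", "variance", 2.015, 0.270, 28, 0.045, False, "increase"),
    (4, "M", "kurtosis", -3.714, -0.497, 28, 0.001, False, "increase"),
    (4, "M", "acf720", 2.894, 0.419, 28, 0.004, False, "increase"),
    (8, "M", "variance", -3.161, -0.423, 28, 0.001, False, "increase"),
    (8, "M", "kurtosis", 2.134, 0.286, 28, 0.034, False, "increase"),
    (8, "M", "acf720", -2.341, -0.328, 28, 0.019, False, "decrease"),
    (9, "D", "variance", 0.198, 0.026, 28, 0.860, False, "increase"),
    (9, "D", "kurtosis", 1.936, 0.259, 28, 0.055, False, "increase"),
    (9, "D", "acf720", -3.935, -0.553, 28, 0.001, True, "decrease"),
    (11, "D", "variance", 0.121, 0.019, 21, 0.929, False, "increase"),
    (11, "D", "kurtosis", 0.846, 0.133, 21, 0.420, False, "increase"),
    (11, "D", "acf720", -0.799, -0.132, 21, 0.424, False, "decrease"),
    (15, "D", "variance", 3.161, 0.423, 28, 0.001, False, "increase"),
    (15, "D", "kurtosis", -3.082, -0.413, 28, 0.002, False, "increase"),
    (15, "D", "acf720", -1.013, -0.139, 28, 0.311, False, "decrease"),
]

# id, episode_type, euthymic mean, comparison mean, printed label, period
_MEAN_ACTIVITY_ROWS = [
    (1, "D", 96.1, 139.1, "more", "pre_onset"),
    (2, "M", 153.8, 124.6, "less", "pre_onset"),
    (3, "D", 100.4, 109.1, "more", "pre_onset"),
    (4, "M", 51.2, 61.7, "more", "pre_onset"),
    (8, "M", 91.9, 92.9, "more", "pre_onset"),
    (9, "D", 171.3, 211.0, "more", "pre_onset"),
    (11, "D", 186.2, 192.0, "more", "pre_onset"),
    (15, "D", 110.7, 166.2, "more", "pre_onset"),
    (1, "D", 108.403, 87.236, "less", "during"),
    (2, "M", 145.258, 144.386, "less", "during"),
    (3, "D", 94.089, 96.359, "more", "during"),
    (4, "M", 49.156, 54.576, "more", "during"),
    (8, "M", 94.559, 112.914, "more", "during"),
    (9, "D", 196.669, 196.399, "less", "during"),
    (11, "D", 186.464, 168.594, "less", "during"),
    (15, "D", 121.871, 137.651, "more", "during"),
]


def reported_trend_tests() -> pd.DataFrame:
    """Per-patient published Mann-Kendall outcomes for the three indicators."""
    return pd.DataFrame(
        _TREND_ROWS,
        columns=[
            "patient", "episode_type", "indicator",
            "z", "tau", "n", "p", "p_is_upper_bound", "direction",
        ],
    )


def reported_mean_activity(period: str = "pre_onset") -> pd.DataFrame:
    """Published mean-activity comparisons (``period`` = 'pre_onset' or 'during')."""
    df = pd.DataFrame(
        _MEAN_ACTIVITY_ROWS,
        columns=["patient", "episode_type", "euthymic_mean", "comparison_mean", "label", "period"],
    )
    if period not in ("pre_onset", "during"):
        raise ValueError("period must be 'pre_onset' or 'during'")
    return df[df["period"] == period].reset_index(drop=True)
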