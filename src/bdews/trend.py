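"""Mann-Kendall monotonic-trend test and Fisher combination of p-values.

The Mann-Kendall test scores every ordered pair of a daily indicator series:

    S = Σ_{i<j} sign(x_j − x_i)

Under the no-trend null, S has mean 0 and a ties-corrected variance

    Var(S) = [ n(n−1)(2n+5) − Σ_t t(t−1)(2t+5) ] / 18,

with t running over tie-group sizes.  The normal deviate uses the standard
continuity correction, z = (S ∓ 1)/√Var(S) (z = 0 when S = 0), and p is the
two-sided normal tail.  The reported correlation is classical tau-a,
S / (n(n−1)/2).  The test is a rank statistic: strictly increasing
transforms of the values leave every output unchanged, and reversing the
series negates S, z and tau while preserving p.

Group-level evidence across patients combines one p-value per patient per
indicator through Fisher's method, −2 Σ ln p ~ χ² with 2k degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MannKendallResult",
    "FisherResult",
    "mann_kendall",
    "fisher_combine",
    "significance_label",
]


@dataclass
class MannKendallResult:
    S: int
    var_s: float
    z: float
    tau: float
    n: int
    p: float
    direction: str  # "increase" | "decrease" | "none"


@dataclass
class FisherResult:
    chi2: float
    df: int
    p: float


def mann_kendall(values: Sequence[float]) -> MannKendallResult:
    """Two-sided Mann-Kendall trend test with tie correction.

    Missing (NaN) entries are dropped, preserving order; at least 3
    non-missing values are required.  A fully tied series yields S = 0,
    z = 0, p = 1.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 3:
        raise ValueError("Mann-Kendall test needs at least 3 non-missing values")

    diff = x[None, :] - x[:, None]
    iu = np.triu_indices(n, k=1)
    S = int(np.sign(diff[iu]).sum())

    _, tie_counts = np.unique(x, return_counts=True)
    ties = tie_counts[tie_counts > 1]
    var_s = (
        n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))
    ) / 18.0

    if S == 0 or var_s == 0.0:
        z = 0.0
    elif S > 0:
        z = (S - 1) / np.sqrt(var_s)
    else:
        z = (S + 1) / np.sqrt(var_s)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    tau = S / (n * (n - 1) / 2.0)
    direction = "increase" if S > 0 else ("decrease" if S < 0 else "none")
    return MannKendallResult(S=S, var_s=float(var_s), z=float(z), tau=float(tau), n=n, p=float(p), direction=direction)


def fisher_combine(pvalues: Sequence[float]) -> FisherResult:
    """Fisher's method: χ² = −2 Σ ln p on 2k degrees of freedom.

    All inputs must lie in (0, 1].  Decreasing any input p decreases the
    combined p; for a single input the combined p equals it.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return FisherResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


def significance_label(p: float) -> str:
    """Report-table marker: ``**`` for p ≤ 0.01, ``*`` for p ≤ 0.05, else empty."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""
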