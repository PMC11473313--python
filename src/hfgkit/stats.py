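"""Statistical primitives for case-control fusion recurrence analysis.

The core test is the pooled-variance two-proportion Z-test, two-sided,
with no continuity correction:

    z = (p1 - p2) / sqrt(p(1-p) (1/n1 + 1/n2)),   p = (x1 + x2)/(n1 + n2)

where p1 = x1/n1 and p2 = x2/n2 are the per-cohort recurrence
frequencies (fraction of distinct patients positive for a fusion).
A fusion is significant when |z| >= z_{alpha/2}; with the default
alpha = 0.01 the critical value is 2.576.

Also here: fold enrichment with a pseudo-count convention for
zero-control fusions, the somatic-origin coincidence probability
(rate^k for k independent patients acquiring the identical junction
somatically), and the genetic-vs-environmental contribution split
derived from the HFG and EFG mean-frequency fold ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "critical_z",
    "two_proportion_ztest",
    "fold_enrichment",
    "SomaticOriginModel",
    "somatic_origin_probability",
    "contribution_split",
]


def critical_z(alpha: float) -> float:
    """Two-sided critical value: the upper alpha/2 standard-normal quantile.

    ``critical_z(0.01)`` is 2.576 (3 d.p.).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(sps.norm.ppf(1.0 - alpha / 2.0))


def two_proportion_ztest(x1, n1, x2, n2):
    """Pooled two-proportion Z-test, two-sided, no continuity correction.

    Accepts scalars or array-likes (broadcast together).  Returns
    ``(z, p_value)`` with the same shape as the inputs.  When the pooled
    proportion is degenerate (0 or 1) there is no variance to test
    against and z = 0, p = 1 by convention.
    """
    x1 = np.asarray(x1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    scalar = all(a.ndim == 0 for a in (x1, n1, x2, n2))
    x1, n1, x2, n2 = np.broadcast_arrays(x1, n1, x2, n2)

    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("cohort sizes must be positive")
    if np.any(x1 < 0) or np.any(x1 > n1) or np.any(x2 < 0) or np.any(x2 > n2):
        raise ValueError("counts must satisfy 0 <= x <= n in each cohort")

    p1 = x1 / n1
    p2 = x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (p1 - p2) / np.sqrt(var), 0.0)
    p = np.where(var > 0, 2.0 * sps.norm.sf(np.abs(z)), 1.0)
    if scalar:
        return float(z), float(p)
    return z, p


def fold_enrichment(
    x1: int, n1: int, x2: int, n2: int, zero_pseudocount: int = 1
) -> float:
    """Case/control frequency ratio ``(x1/n1) / (x2/n2)``.

    A fusion absent from controls (``x2 = 0``) gets ``zero_pseudocount``
    substituted for ``x2`` so the fold stays finite — with the default
    pseudo-count of one positive control, 18/122 cases vs 0/252 controls
    yields 37.2.  Absent from both cohorts the fold is undefined (NaN).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("cohort sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n in each cohort")
    if x1 == 0 and x2 == 0:
        return float("nan")
    if x2 == 0:
        x2 = zero_pseudocount
    return (x1 / n1) / (x2 / n2)


@dataclass(frozen=True)
class SomaticOriginModel:
    """Parameters for the somatic-coincidence argument.

    ``per_individual_rate`` is the probability that a structural variant
    generates a given fusion gene in one individual (literature value
    3.6e-2); ``k`` is the number of patients required to carry the
    identical fusion (the recurrence filter, 5); ``n`` is the cohort
    size over which the expected number of such coincidences is scaled.
    """

    per_individual_rate: float = 3.6e-2
    k: int = 5
    n: int = 252

    def __post_init__(self) -> None:
        if not 0 < self.per_individual_rate < 1:
            raise ValueError("per_individual_rate must be in (0, 1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def somatic_origin_probability(model: SomaticOriginModel) -> tuple[float, float]:
    """Probability that >= k individuals independently acquire one fusion.

    Returns ``(coincidence_probability, expected_per_cohort)`` where the
    coincidence probability is ``rate**k`` and the expectation scales it
    by cohort size n.  At rate 3.6e-2 and k = 5 the coincidence
    probability is 6e-8; over 252 controls the expectation is 1.5e-5 —
    small enough that recurrent fusions in non-cancerous tissue cannot
    plausibly be independent somatic events and must be germline.
    """
    p = model.per_individual_rate**model.k
    return p, model.n * p


def contribution_split(
    hfg_fold_ratio: float, efg_fold_ratio: float
) -> tuple[float, float]:
    """Apportion disease contribution between genetic and environmental axes.

    Given the case/control mean-frequency fold ratio of genomic (HFG)
    fusions and of readthrough (EFG) fusions, the genetic share is
    ``100 * r / (r + 1)`` with ``r = hfg / efg``; the environmental
    share is the complement.  The two percentages sum to exactly 100.
    """
    if hfg_fold_ratio <= 0 or efg_fold_ratio <= 0:
        raise ValueError("fold ratios must be positive")
    r = hfg_fold_ratio / efg_fold_ratio
    genetic = 100.0 * r / (r + 1.0)
    return genetic, 100.0 - genetic
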