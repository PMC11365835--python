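"""Group statistics for reorientation accuracy.

Per clock position the two simulated cohorts are compared on |ΔASA| with
Student's unpaired (pooled-variance) two-sample t test at alpha = 0.05,
implemented directly from the textbook formula. Because thirteen positions
are tested, a Holm-adjusted p-value column is reported alongside the
unadjusted one (the unadjusted column is the primary read-out).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError
from .measure import DeltaProfile

__all__ = ["GroupComparison", "two_sample_t", "compare_groups",
           "holm_adjust", "power_two_sample_t"]


def two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Student's unpaired t statistic and two-sided p (pooled variance).

    With zero variance in both groups the test is undefined: returns
    (0, 1) for identical means and (+/-inf, nan) otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ConfigurationError("need at least two observations per group")
    m1, m2 = a.mean(), b.mean()
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0.0:
        if m1 == m2:
            return 0.0, 1.0
        return float(np.sign(m1 - m2) * np.inf), float("nan")
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), n1 + n2 - 2)
    return float(t), float(p)


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment; NaNs pass through unadjusted."""
    p = np.asarray(pvals, float)
    adj = np.full_like(p, np.nan)
    ok = np.flatnonzero(np.isfinite(p))
    if len(ok) == 0:
        return adj
    order = ok[np.argsort(p[ok])]
    m = len(order)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


@dataclass(frozen=True)
class GroupComparison:
    """Per-clock-position summary of two cohorts' reorientation error."""

    positions: tuple[str, ...]
    mean_a: np.ndarray
    sd_a: np.ndarray
    mean_b: np.ndarray
    sd_b: np.ndarray
    n_a: int
    n_b: int
    t_stat: np.ndarray
    p_value: np.ndarray
    p_holm: np.ndarray
    alpha: float = 0.05
    label_a: str = "previous"
    label_b: str = "fiducial"
    signed: bool = False

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.p_value < self.alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": list(self.positions),
            f"mean_abs_dasa_{self.label_a}": self.mean_a,
            f"sd_{self.label_a}": self.sd_a,
            f"mean_abs_dasa_{self.label_b}": self.mean_b,
            f"sd_{self.label_b}": self.sd_b,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
            "p_holm": self.p_holm,
            "significant": self.significant,
        })


def _delta_matrix(cohort, positions) -> np.ndarray:
    rows = []
    for case in cohort:
        prof: DeltaProfile = case.delta_profile if hasattr(case, "delta_profile") else case
        if tuple(prof.positions) != tuple(positions):
            raise ConfigurationError("cohort measured on a different clock face")
        rows.append(prof.values_deg)
    return np.array(rows)


def compare_groups(cohort_a, cohort_b, position_set: Sequence[str] | None = None,
                   signed: bool = False, alpha: float = 0.05,
                   label_a: str = "previous", label_b: str = "fiducial"
                   ) -> GroupComparison:
    """Student's unpaired t test on |ΔASA| (or signed ΔASA) per position.

    Cohorts are sequences of case results (anything with a
    ``delta_profile``) or bare :class:`DeltaProfile` objects; all must share
    one clock face.
    """
    first = cohort_a[0]
    prof = first.delta_profile if hasattr(first, "delta_profile") else first
    positions = tuple(position_set) if position_set is not None else tuple(prof.positions)
    A = _delta_matrix(cohort_a, prof.positions)
    B = _delta_matrix(cohort_b, prof.positions)
    cols = [prof.positions.index(p) for p in positions]
    A, B = A[:, cols], B[:, cols]
    if not signed:
        A, B = np.abs(A), np.abs(B)
    t = np.empty(len(positions))
    p = np.empty(len(positions))
    for j in range(len(positions)):
        t[j], p[j] = two_sample_t(A[:, j], B[:, j])
    return GroupComparison(
        positions=positions,
        mean_a=A.mean(axis=0), sd_a=A.std(axis=0, ddof=1),
        mean_b=B.mean(axis=0), sd_b=B.std(axis=0, ddof=1),
        n_a=len(A), n_b=len(B),
        t_stat=t, p_value=p, p_holm=holm_adjust(p),
        alpha=alpha, label_a=label_a, label_b=label_b, signed=signed)


def power_two_sample_t(n_per_group: int, effect_size_d: float,
                       alpha: float = 0.05, tails: int = 2) -> float:
    """Power of the two-sample t test via the noncentral t distribution.

    ``effect_size_d`` is Cohen's d; the noncentrality parameter is
    d * sqrt(n/2) with 2n - 2 degrees of freedom.
    """
    if n_per_group < 2:
        raise ConfigurationError("need n >= 2 per group")
    if effect_size_d <= 0:
        raise ConfigurationError("effect size must be positive")
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must lie in (0, 1)")
    if tails not in (1, 2):
        raise ConfigurationError("tails must be 1 or 2")
    df = 2 * n_per_group - 2
    nc = effect_size_d * np.sqrt(n_per_group / 2.0)
    tcrit = sps.t.ppf(1.0 - alpha / tails, df)
    power = sps.nct.sf(tcrit, df, nc)
    if tails == 2:
        power += sps.nct.cdf(-tcrit, df, nc)
    return float(power)
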