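"""Treatment-vs-vehicle profiles: Welch tests and Bonferroni tiers.

Every treatment arm is compared behavior-by-behavior to the single
vehicle-control arm with Welch's unequal-variance t-test (two-sided,
Welch-Satterthwaite degrees of freedom).  Significance is reported in
three Bonferroni-corrected tiers with family levels 0.05, 0.01 and
0.001, each divided by the number of comparisons ``m`` -- the number
of treatment arms, not treatments x behaviors.  With m = 30 the tier-1
threshold is 0.05/30 = 1.67e-3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, InsufficientDataError
from .features import BEHAVIOR_LABELS
from .matrix import ProfileMatrix
from .tracks import TreatmentArm, vehicle_arm

#: Family-wise alpha levels defining significance tiers 1, 2, 3.
TIER_FAMILY_ALPHAS = (0.05, 0.01, 0.001)

_TINY_P = 5e-324  # smallest positive float; the p -> 0 degenerate limit


@dataclass(frozen=True)
class WelchResult:
    t_stat: float
    df: float
    p: float
    degenerate: bool = False


def welch_test(x, y) -> WelchResult:
    """Welch's unequal-variance t-test, two-sided.

    t = (mean_x - mean_y) / sqrt(s2_x/n_x + s2_y/n_y) with
    Welch-Satterthwaite degrees of freedom.  When both sample
    variances are zero the test degenerates: equal means give
    (t=0, p=1); unequal means are reported at the p -> 0 limit with
    ``degenerate=True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError(
            f"welch_test needs >=2 values per sample, got {n1} and {n2}"
        )
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        if x.mean() == y.mean():
            return WelchResult(0.0, float(n1 + n2 - 2), 1.0)
        sign = 1.0 if x.mean() > y.mean() else -1.0
        return WelchResult(sign * math.inf, float(n1 + n2 - 2), _TINY_P,
                           degenerate=True)
    res = sps.ttest_ind(x, y, equal_var=False)
    p = float(res.pvalue)
    if p <= 0.0:
        p = _TINY_P
    return WelchResult(float(res.statistic), float(res.df), min(p, 1.0))


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-comparison threshold family_alpha / m (exact division)."""
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    if not 0.0 < family_alpha < 1.0:
        raise ConfigurationError("family_alpha must lie in (0, 1)")
    return family_alpha / m


def sig_tier(p: float, m: int,
             family_alphas=TIER_FAMILY_ALPHAS) -> int:
    """Tier 0-3: the number of Bonferroni thresholds the p-value beats."""
    return sum(p < bonferroni_alpha(fa, m) for fa in family_alphas)


def build_profiles(
    features: pd.DataFrame,
    arms: list[TreatmentArm],
    m_comparisons: int | None = None,
    behavior_labels=None,
) -> ProfileMatrix:
    """Profile every treatment arm against the vehicle control.

    ``features`` is the per-larva table (arm_id + one column per
    behavior).  delta[t, b] = mean(treatment t, b) - mean(control, b);
    p-values from :func:`welch_test` on the per-larva values, dropping
    missing entries per behavior, so behaviors may have different
    effective sample sizes.  ``m_comparisons`` defaults to the number
    of treatment arms.
    """
    control = vehicle_arm(arms)
    treatment_arms = [a for a in arms if a.role != "vehicle_control"]
    if m_comparisons is None:
        m_comparisons = len(treatment_arms)
    if behavior_labels is None:
        behavior_labels = [
            c for c in features.columns if c in BEHAVIOR_LABELS
        ] or [c for c in features.columns if c not in ("arm_id", "well_id")]

    grouped = {str(arm): g for arm, g in features.groupby("arm_id")}
    if control.name not in grouped:
        raise ConfigurationError(f"no rows for control arm {control.name!r}")

    delta = pd.DataFrame(index=[a.name for a in treatment_arms],
                         columns=behavior_labels, dtype=float)
    pvals = delta.copy()
    tiers = pd.DataFrame(0, index=delta.index, columns=behavior_labels, dtype=int)
    for arm in treatment_arms:
        if arm.name not in grouped:
            raise ConfigurationError(f"no rows for arm {arm.name!r}")
        for b in behavior_labels:
            x = grouped[arm.name][b].dropna().to_numpy()
            y = grouped[control.name][b].dropna().to_numpy()
            res = welch_test(x, y)
            delta.loc[arm.name, b] = x.mean() - y.mean()
            pvals.loc[arm.name, b] = res.p
            tiers.loc[arm.name, b] = sig_tier(res.p, m_comparisons)
    return ProfileMatrix(delta=delta, sig_tier=tiers, p_value=pvals)


def count_significant(tier_row: pd.Series, tier_min: int = 1) -> int:
    """Number of behaviors at or above a significance tier."""
    if tier_min not in (1, 2, 3):
        raise ConfigurationError("tier_min must be 1, 2 or 3")
    return int((np.asarray(tier_row) >= tier_min).sum())
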