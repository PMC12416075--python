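"""Combination-vs-single synergy statistics.

Two complementary readouts compare a half-dose drug combination with
the full-dose single drug:

* **Count delta** -- the number of significantly changed behaviors of
  the combination minus that of the single drug (e.g. 12 - 16 = -4).
  Positive values mean the combination perturbs more behaviors than
  the drug alone.
* **Magnitude percent change** -- the percent change in the mean
  absolute per-behavior delta from single to combination (e.g. a
  10.71-point single-drug magnitude dropping by 0.95 points gives
  -0.95/10.71 = -8.9%).  Positive values read as potentiation.

The magnitude is reported in its per-behavior (mean) form; the raw
sum over behaviors differs only by the fixed factor n_behaviors, so
the percent change is identical under either form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DimensionError, UndefinedResultError, UnknownLabelError
from .matrix import ProfileMatrix
from .profile_stats import count_significant


@dataclass(frozen=True)
class SynergyReport:
    combination_label: str
    single_label: str
    n_sig_combo: int
    n_sig_single: int
    count_delta: int
    mag_combo: float
    mag_single: float
    mag_pct_change: float


def _check_labels(a: pd.Series, b: pd.Series) -> None:
    if list(a.index) != list(b.index):
        raise DimensionError("rows do not share behavior labels")


def count_delta(combo_tiers: pd.Series, single_tiers: pd.Series,
                tier_min: int = 1) -> int:
    """Significant-behavior count of the combination minus the single."""
    _check_labels(combo_tiers, single_tiers)
    return count_significant(combo_tiers, tier_min) - count_significant(
        single_tiers, tier_min
    )


def magnitude(row: pd.Series, form: str = "mean") -> float:
    """Absolute average behavioral change of one profile row.

    ``form="mean"`` (primary) averages |delta| over behaviors;
    ``form="sum"`` returns the raw total.  Downstream percent changes
    are identical under either form.
    """
    values = np.asarray(row, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise UndefinedResultError("empty profile row")
    if form == "mean":
        return float(np.abs(values).mean())
    if form == "sum":
        return float(np.abs(values).sum())
    raise ValueError(f"unknown magnitude form {form!r}")


def magnitude_pct_change(combo_row: pd.Series, single_row: pd.Series) -> float:
    """100 x (magnitude(combo) - magnitude(single)) / magnitude(single)."""
    _check_labels(combo_row, single_row)
    m_single = magnitude(single_row)
    if m_single == 0.0:
        raise UndefinedResultError(
            "single-treatment magnitude is zero; percent change undefined"
        )
    return 100.0 * (magnitude(combo_row) - m_single) / m_single


def synergy_table(
    profiles: ProfileMatrix,
    pairs: list[tuple[str, str]],
    tier_min: int = 1,
) -> list[SynergyReport]:
    """One report per (combination, single) pair, in the given order."""
    reports: list[SynergyReport] = []
    for combo, single in pairs:
        for label in (combo, single):
            if label not in profiles.delta.index:
                raise UnknownLabelError(label)
        combo_tiers = profiles.tiers(combo)
        single_tiers = profiles.tiers(single)
        combo_row = profiles.row(combo)
        single_row = profiles.row(single)
        reports.append(
            SynergyReport(
                combination_label=combo,
                single_label=single,
                n_sig_combo=count_significant(combo_tiers, tier_min),
                n_sig_single=count_significant(single_tiers, tier_min),
                count_delta=count_delta(combo_tiers, single_tiers, tier_min),
                mag_combo=magnitude(combo_row),
                mag_single=magnitude(single_row),
                mag_pct_change=magnitude_pct_change(combo_row, single_row),
            )
        )
    return reports


def synergy_frame(reports: list[SynergyReport]) -> pd.DataFrame:
    """Tabular form of the synergy reports (percent changes full precision;
    round to 1 decimal for display)."""
    return pd.DataFrame([r.__dict__ for r in reports])


def write_synergy(reports: list[SynergyReport], path) -> None:
    synergy_frame(reports).to_csv(path, index=False)
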