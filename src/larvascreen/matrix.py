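"""Treatment-profile matrices: per-behavior deltas vs the vehicle control.

The behavioral profile (fingerprint) of a treatment is the vector of
mean per-behavior differences, in percentage points, between that
treatment arm and the vehicle control.  A :class:`ProfileMatrix`
stacks those vectors for all treatments and carries, cell-aligned, the
Welch-test p-values (when the per-larva data are available) and an
integer significance tier per cell: 0 = not significant, 1/2/3 = the
three Bonferroni-corrected family levels (0.05, 0.01, 0.001 divided by
the number of comparisons).

On disk a profile matrix is a delimited table with the treatment label
in the first column and one column per behavior, plus optional
companion tables ``<stem>_sig`` (integer tiers) and ``<stem>_p``
(p-values) of identical shape.  Published supplementary matrices that
ship only delta values with significance annotations load the same
way: the p-value table is simply absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DimensionError, UnknownLabelError

logger = logging.getLogger(__name__)


@dataclass
class ProfileMatrix:
    delta: pd.DataFrame
    sig_tier: pd.DataFrame
    p_value: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for name, table in (("sig_tier", self.sig_tier), ("p_value", self.p_value)):
            if table is None:
                continue
            if table.shape != self.delta.shape:
                raise DimensionError(
                    f"{name} shape {table.shape} != delta shape {self.delta.shape}"
                )
            if list(table.index) != list(self.delta.index) or list(
                table.columns
            ) != list(self.delta.columns):
                raise DimensionError(f"{name} labels do not match delta labels")
        bad = set(np.unique(self.sig_tier.to_numpy())) - {0, 1, 2, 3}
        if bad:
            raise DimensionError(f"sig_tier contains values outside {{0,1,2,3}}: {bad}")

    @property
    def treatments(self) -> list[str]:
        return list(self.delta.index)

    @property
    def behaviors(self) -> list[str]:
        return list(self.delta.columns)

    def row(self, treatment: str) -> pd.Series:
        """Delta profile of one treatment."""
        if treatment not in self.delta.index:
            raise UnknownLabelError(treatment)
        return self.delta.loc[treatment]

    def tiers(self, treatment: str) -> pd.Series:
        if treatment not in self.sig_tier.index:
            raise UnknownLabelError(treatment)
        return self.sig_tier.loc[treatment]


def _companion(path: Path, suffix: str) -> Path:
    return path.with_name(path.stem + suffix + path.suffix)


def write_profile_matrix(pm: ProfileMatrix, path) -> None:
    path = Path(path)
    pm.delta.to_csv(path, index_label="treatment")
    pm.sig_tier.to_csv(_companion(path, "_sig"), index_label="treatment")
    if pm.p_value is not None:
        pm.p_value.to_csv(_companion(path, "_p"), index_label="treatment")


def read_profile_matrix(path) -> ProfileMatrix:
    """Load a profile matrix plus whatever companion tables exist.

    Unknown behavior columns are retained in their file order; nothing
    here assumes a fixed behavior set.
    """
    path = Path(path)
    delta = pd.read_csv(path, index_col=0, float_precision="round_trip")
    delta.index = delta.index.astype(str)

    p_path = _companion(path, "_p")
    p_value = None
    if p_path.exists():
        p_value = pd.read_csv(p_path, index_col=0, float_precision="round_trip")
        p_value.index = p_value.index.astype(str)

    sig_path = _companion(path, "_sig")
    if sig_path.exists():
        sig = pd.read_csv(sig_path, index_col=0).astype(int)
        sig.index = sig.index.astype(str)
    else:
        logger.warning(
            "no significance companion for %s; all tiers set to 0", path
        )
        sig = pd.DataFrame(
            0, index=delta.index, columns=delta.columns, dtype=int
        )
    return ProfileMatrix(delta=delta, sig_tier=sig, p_value=p_value)
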