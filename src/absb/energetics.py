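"""Phosphorylation energetics of salt-bridged vs bridge-free conformers.

Each conformer carries a pair of electronic energies: with (``E_phos``) and
without (``E_nonphos``) a phosphate on Ser8.  The per-conformer
phosphorylation energy is ``dE = E_phos - E_nonphos`` (hartrees); conformers
are grouped by their salt-bridge content (both Arg5-Glu3 and Arg5-Asp7
bridges, Arg5-Asp7 only, or neither = control) and the group contrast

    ddE_group = mean(dE_group) - mean(dE_control)

measures how much phosphorylation destabilises bridged conformers relative to
bridge-free ones (positive = relative destabilisation).  Energies are consumed
from tables; no quantum chemistry is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

__all__ = [
    "ConformerEnergy",
    "GroupComparison",
    "GroupStats",
    "group_stats",
    "hartree_to_kjmol",
    "HARTREE_TO_KJMOL",
    "GROUPS",
    "CONTROL_GROUP",
]

#: CODATA conversion, kJ/mol per hartree
HARTREE_TO_KJMOL = 2625.4996

GROUPS = ("test_both_bridges", "test_d7_only", "control")
CONTROL_GROUP = "control"


@dataclass(frozen=True)
class ConformerEnergy:
    """Energies of one conformer in phosphorylated and unmodified form."""

    conformer_id: str
    group: str
    e_phos: float
    e_nonphos: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.e_phos) and np.isfinite(self.e_nonphos)):
            raise InvalidParameterError(
                f"non-finite energy for conformer {self.conformer_id}"
            )

    @property
    def delta_e(self) -> float:
        """Phosphorylation energy E_phos - E_nonphos, hartrees."""
        return self.e_phos - self.e_nonphos


@dataclass
class GroupStats:
    """Per-group summary of the phosphorylation energy dE."""

    group: str
    n: int
    mean_de: float
    sd_de: float  # NaN when n == 1 (undefined)


@dataclass
class GroupComparison:
    """Group means of dE and their contrasts against the control group."""

    groups: dict[str, GroupStats]
    dde_hartree: dict[str, float]  # group -> mean(dE_group) - mean(dE_control)
    dde_kjmol: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, g in self.groups.items():
            rows.append(
                {
                    "group": name,
                    "n": g.n,
                    "mean_dE_hartree": g.mean_de,
                    "sd_dE_hartree": g.sd_de,
                    "ddE_hartree": self.dde_hartree.get(name, np.nan),
                    "ddE_kJ_per_mol": self.dde_kjmol.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)


def hartree_to_kjmol(x: float) -> float:
    """Convert hartrees to kJ/mol (1 hartree = 2625.4996 kJ/mol)."""
    if not np.isfinite(x):
        raise InvalidParameterError("input must be finite")
    return x * HARTREE_TO_KJMOL


def group_stats(
    records: Iterable[ConformerEnergy], control_group: str = CONTROL_GROUP
) -> GroupComparison:
    """Group means/sds of dE and contrasts ddE against the control group.

    Every group present in ``records`` is summarised; ddE is reported for each
    non-control group (and is exactly 0 for the control against itself).  The
    sd of a single-member group is undefined and reported as NaN.

    Raises
    ------
    InvalidParameterError
        If the control group is empty.
    """
    recs = list(records)
    by_group: dict[str, list[float]] = {}
    for r in recs:
        by_group.setdefault(r.group, []).append(r.delta_e)
    if control_group not in by_group:
        raise InvalidParameterError(f"control group {control_group!r} is empty")
    groups: dict[str, GroupStats] = {}
    for name, des in by_group.items():
        arr = np.asarray(des)
        groups[name] = GroupStats(
            group=name,
            n=arr.size,
            mean_de=float(arr.mean()),
            sd_de=float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan"),
        )
    control_mean = groups[control_group].mean_de
    dde_h = {name: g.mean_de - control_mean for name, g in groups.items()}
    dde_kj = {name: hartree_to_kjmol(v) for name, v in dde_h.items()}
    return GroupComparison(groups=groups, dde_hartree=dde_h, dde_kjmol=dde_kj)


def group_stats_from_frame(
    df: pd.DataFrame, control_group: str = CONTROL_GROUP
) -> GroupComparison:
    """As :func:`group_stats`, from a DataFrame with the documented columns."""
    records = [
        ConformerEnergy(
            conformer_id=str(row.conformer_id),
            group=str(row.group),
            e_phos=float(row.E_phos_hartree),
            e_nonphos=float(row.E_nonphos_hartree),
        )
        for row in df.itertuples()
    ]
    return group_stats(records, control_group=control_group)
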