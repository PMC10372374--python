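"""Study design: a 2 (group) x 2 (sex) unbalanced layout plus QC-pool and blank runs.

The default mirrors the diabetic-pregnancy pig study this package emulates:
wild-type piglets born to hyperglycemic (PHG) or normoglycemic (PNG) sows,
PNG with 6 females + 4 males, PHG with 5 females + 4 males, 5 pooled-QC
injections and 3 extraction blanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Tuple

import pandas as pd

ROLE_BIOLOGICAL = "biological"
ROLE_POOL = "qc_pool"
ROLE_BLANK = "blank"

DEFAULT_CELLS: Mapping[Tuple[str, str], int] = {
    ("PNG", "F"): 6,
    ("PNG", "M"): 4,
    ("PHG", "F"): 5,
    ("PHG", "M"): 4,
}


@dataclass(frozen=True)
class StudyDesign:
    """Counts per group x sex cell plus the number of QC-pool and blank samples."""

    groups: Tuple[str, str] = ("PHG", "PNG")
    sexes: Tuple[str, str] = ("F", "M")
    n_per_cell: Mapping[Tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_CELLS)
    )
    n_pool: int = 5
    n_blank: int = 3

    def __post_init__(self) -> None:
        for cell, n in self.n_per_cell.items():
            if n < 0:
                raise ValueError(f"negative count for cell {cell}")
            g, s = cell
            if g not in self.groups or s not in self.sexes:
                raise ValueError(f"cell {cell} not covered by groups/sexes")
        if self.n_pool < 0 or self.n_blank < 0:
            raise ValueError("pool/blank counts must be >= 0")

    @property
    def n_biological(self) -> int:
        return sum(self.n_per_cell.values())

    def group_sizes(self) -> dict:
        sizes: dict = {g: 0 for g in self.groups}
        for (g, _), n in self.n_per_cell.items():
            sizes[g] += n
        return sizes

    def require_testable(self) -> None:
        """Each group needs >= 2 samples for any downstream variance estimate."""
        for g, n in self.group_sizes().items():
            if n < 2:
                raise ValueError(f"group {g!r} has {n} samples; need >= 2")

    def sample_table(self) -> pd.DataFrame:
        """Long design table: sample, group, sex, role."""
        rows = []
        for (g, s), n in self.n_per_cell.items():
            for i in range(n):
                rows.append((f"{g}_{s}{i + 1:02d}", g, s, ROLE_BIOLOGICAL))
        for i in range(self.n_pool):
            rows.append((f"pool{i + 1:02d}", "", "", ROLE_POOL))
        for i in range(self.n_blank):
            rows.append((f"blank{i + 1:02d}", "", "", ROLE_BLANK))
        return pd.DataFrame(rows, columns=["sample", "group", "sex", "role"])


def biological_samples(design: pd.DataFrame) -> pd.DataFrame:
    return design[design["role"] == ROLE_BIOLOGICAL]


def pool_samples(design: pd.DataFrame) -> list:
    return design.loc[design["role"] == ROLE_POOL, "sample"].tolist()


def blank_samples(design: pd.DataFrame) -> list:
    return design.loc[design["role"] == ROLE_BLANK, "sample"].tolist()
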