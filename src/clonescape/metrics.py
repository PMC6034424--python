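"""Clone-size tables, D20, top-N rankings, cut-off curves, and the
DNA-input sampling estimators.

The sampling estimators translate nanograms of B-cell genomic DNA into a
ceiling on the number of distinct heavy-chain rearrangements one could
possibly observe, using 1,000 pg/ng, an average of 1.4 VDJ
rearrangements per cell, and 6.7 pg of DNA per cell.  They provide the
sanity check against which observed unique-sequence and clone counts are
compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

METRICS = ("copies", "instances", "uniques")


@dataclass
class SamplingConstants:
    pg_per_ng: float = 1000.0
    rearr_per_cell: float = 1.4
    pg_per_cell: float = 6.7


@dataclass
class CloneSizeTable:
    """Per-clone size metrics (copies c_i, instances, uniques) as aligned
    arrays, with totals."""

    clone_ids: np.ndarray
    copies: np.ndarray
    instances: np.ndarray
    uniques: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.clone_ids)
        for name in METRICS:
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if len(arr) != n:
                raise ValueError("ragged clone size table")
            setattr(self, name, arr)
        self.clone_ids = np.asarray(self.clone_ids)

    @classmethod
    def from_clones(cls, clones: Sequence) -> "CloneSizeTable":
        return cls(
            clone_ids=np.array([c.clone_id for c in clones]),
            copies=np.array([c.copies for c in clones], dtype=np.int64),
            instances=np.array([c.instances for c in clones], dtype=np.int64),
            uniques=np.array([c.uniques for c in clones], dtype=np.int64),
        )

    def metric(self, name: str) -> np.ndarray:
        if name not in METRICS:
            raise ValueError(f"unknown metric {name!r}; expected one of {METRICS}")
        return getattr(self, name)

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    @property
    def T(self) -> int:
        """Total copy count over all clones."""
        return int(self.copies.sum())


def d20(table: CloneSizeTable, metric: str = "copies", n: int = 20) -> float:
    """Fraction of a size metric's total contributed by the ``n`` largest
    clones (D20 for the default n=20, on copies).

    With fewer than ``n`` clones the sum runs over all of them, giving 1.
    """
    values = table.metric(metric)
    total = values.sum()
    if total <= 0:
        raise ValueError("metric total must be positive")
    top = np.sort(values)[::-1][:n]
    return float(top.sum() / total)


def rank_top_n(
    table: CloneSizeTable, metric: str = "copies", n: int = 20
) -> list[tuple[object, int, float]]:
    """Top-``n`` clones by a metric as (clone_id, value, fraction-of-total).

    Ties are broken by the other two metrics (copies, then instances,
    then uniques) and finally by clone id, so rankings are reproducible.
    """
    values = table.metric(metric)
    total = values.sum()
    if total <= 0:
        raise ValueError("metric total must be positive")
    order = sorted(
        range(table.n_clones),
        key=lambda i: (
            -values[i],
            -table.copies[i],
            -table.instances[i],
            -table.uniques[i],
            table.clone_ids[i],
        ),
    )
    def plain(x):
        return x.item() if isinstance(x, np.generic) else x

    return [
        (plain(table.clone_ids[i]), int(values[i]), float(values[i] / total))
        for i in order[:n]
    ]


def cutoff_counts(
    table: CloneSizeTable, metric: str, cutoffs: Sequence[int]
) -> list[int]:
    """Number of clones whose metric is >= k, for each cut-off k.

    A cut-off of 1 returns the richness (every clone has size >= 1).
    """
    values = table.metric(metric)
    if any(k < 1 for k in cutoffs):
        raise ValueError("cutoffs must be >= 1")
    return [int((values >= k).sum()) for k in cutoffs]


def copies_retained_fraction(
    table: CloneSizeTable, cutoffs: Sequence[int]
) -> list[float]:
    """Fraction of total copies retained when clones below each copy-number
    cut-off are discarded; 1.0 at k=1 and non-increasing in k."""
    total = table.T
    if total <= 0:
        raise ValueError("total copies must be positive")
    return [float(table.copies[table.copies >= k].sum() / total) for k in cutoffs]


def max_rearrangements(
    ng_dna: float, consts: SamplingConstants = SamplingConstants()
) -> int:
    """Ceiling on distinct rearrangements obtainable from ``ng_dna``
    nanograms of B-cell genomic DNA, floored to an integer:

        ng × 1000 pg/ng × 1.4 rearrangements/cell ÷ 6.7 pg/cell
    """
    if ng_dna < 0:
        raise ValueError("ng_dna must be >= 0")
    return math.floor(
        ng_dna * consts.pg_per_ng * consts.rearr_per_cell / consts.pg_per_cell
    )


def cells_per_ng(consts: SamplingConstants = SamplingConstants()) -> int:
    """Approximate B cells per nanogram of pure B-cell DNA (1000/6.7,
    rounded to the nearest ten → the familiar "1 ng ≈ 150 cells")."""
    return int(round(consts.pg_per_ng / consts.pg_per_cell / 10.0)) * 10


def input_dna_for_b_cells(target_ng_b_dna: float, b_fraction: float) -> float:
    """Total input DNA (ng) needed so that ``target_ng_b_dna`` nanograms
    come from B cells, given the flow-cytometric B-cell fraction.

    Reported truncated to one decimal (50/0.35 → 142.8); the exact value
    is simply ``target_ng_b_dna / b_fraction``.
    """
    if not (0.0 < b_fraction <= 1.0):
        raise ValueError("b_fraction must be in (0, 1]")
    return math.floor(target_ng_b_dna / b_fraction * 10.0) / 10.0
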