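"""Post-annotation validity filters applied before subject-level collapsing.

These rules discard sequences with poor germline support (<60% V
identity), remove the primer-proximal 5' region (IMGT positions 1-150)
from mutation-bearing consideration, drop sequences with cross-family
V-gene ties (likely hybrid PCR products), and flag replicate libraries
whose valid-read yield is at least five-fold lower than their siblings.
All filters are pure predicates and commute with one another.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .io import AnnotatedRearrangement

MIN_V_IDENTITY = 0.60
IMGT_TRIM_POSITION = 150
IMBALANCE_FOLD = 5

_GAPS = ".-"


@dataclass
class LibraryStats:
    """Per-replicate read accounting used by the imbalance check."""

    replicate_id: str
    total_reads: int
    valid_reads: int

    def __post_init__(self) -> None:
        if self.valid_reads > self.total_reads:
            raise ValueError(
                f"{self.replicate_id}: valid_reads exceeds total_reads"
            )

    @property
    def valid_fraction(self) -> float:
        return self.valid_reads / self.total_reads if self.total_reads else 0.0


def filter_v_identity(
    rearr: AnnotatedRearrangement, min_identity: float = MIN_V_IDENTITY
) -> bool:
    """Keep predicate: discard iff germline V identity is strictly below
    ``min_identity`` (default 60%)."""
    if rearr.v_identity is None:
        raise ValueError(f"{rearr.sequence_id}: v_identity missing")
    return rearr.v_identity >= min_identity


def first_aligned_position(sequence: str) -> int:
    """1-based IMGT position of the first non-gap character."""
    for i, ch in enumerate(sequence):
        if ch not in _GAPS:
            return i + 1
    raise ValueError("sequence contains no aligned positions")


def trim_to_imgt_150(
    rearr: AnnotatedRearrangement, position: int = IMGT_TRIM_POSITION
) -> Optional[AnnotatedRearrangement]:
    """Remove IMGT positions 1-150 from mutation-bearing consideration.

    The FR1 amplification primers sit in this region, so mutations there
    cannot be distinguished from primer sequence.  Returns a copy whose
    ``sequence`` (and germline, when present) starts at position 151, or
    ``None`` for a rearrangement whose first aligned position is after
    150 ("after" is strict: a sequence starting exactly at 150 is kept).
    """
    if not rearr.sequence:
        raise ValueError(f"{rearr.sequence_id}: positional alignment missing")
    if first_aligned_position(rearr.sequence) > position:
        return None
    germ = rearr.germline[position:] if rearr.germline else rearr.germline
    return replace(rearr, sequence=rearr.sequence[position:], germline=germ)


_FAMILY_RE = re.compile(r"^([A-Za-z]+\d+)")


def v_family(gene: str) -> str:
    """IMGT family token of a gene name: the locus prefix plus subgroup
    digit (``IGHV3-23*01`` → ``IGHV3``)."""
    name = gene.split("*")[0]
    m = _FAMILY_RE.match(name)
    return m.group(1) if m else name


def filter_cross_family_v(rearr: AnnotatedRearrangement) -> bool:
    """Keep predicate: discard iff the V-call tie set spans two or more
    gene families.  Cross-family J ties are always kept (several human
    J genes are near-identical), so only V calls are inspected."""
    families = {v_family(g) for g in rearr.v_call}
    return len(families) < 2


def replicate_imbalance(stats: Sequence[LibraryStats]) -> list[str]:
    """Flag replicates whose valid-read count is five or more times lower
    than the best sibling replicate of the same subject.

    A replicate is flagged when ``valid_reads <= max(other valid)/5``.
    With fewer than two replicates nothing can be flagged.
    """
    if len(stats) < 2:
        return []
    flagged = []
    for s in stats:
        best_other = max(o.valid_reads for o in stats if o is not s)
        if s.valid_reads * IMBALANCE_FOLD <= best_other:
            flagged.append(s.replicate_id)
    return flagged
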