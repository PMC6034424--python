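"""Subject-level collapsing of identical sequences with N-tolerant equality.

Two sequences are considered the same if they differ only at positions
where either carries an N (an uncertain base call).  Because that
relation is not transitive ("ANG"~"AAG" and "ANG"~"ACG" but "AAG"≁"ACG"),
grouping is performed greedily: records are visited in descending copy
order and each joins the first seed it matches, which makes the
partition deterministic and copy-weighted.

Collapsing happens across *all* replicates of one subject, which is what
lets a sequence seen once in each of two libraries reach a subject-wide
copy number of 2 (the low-copy rescue of clonal inference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .io import AnnotatedRearrangement


def sequences_equal_n(a: str, b: str) -> bool:
    """N-tolerant equality: equal length and per-position agreement where a
    position matches if the bases are identical or either is N."""
    if len(a) != len(b):
        return False
    return all(x == y or x == "N" or y == "N" for x, y in zip(a, b))


@dataclass
class UniqueSequence:
    """A subject-level collapsed sequence.

    ``total_copies`` sums the copy numbers of all collapsed input records;
    ``instances`` counts the replicates in which the sequence was seen.
    The representative ``sequence`` is the member with the fewest N's so
    that the CDR3 translation stays maximally informative.
    """

    useq_id: str
    subject_id: str
    sequence: str
    v_call: frozenset[str]
    j_call: frozenset[str]
    cdr3_nt: str
    cdr3_aa: str
    copies_by_replicate: dict[str, int]
    v_identity: Optional[float] = None
    germline: Optional[str] = None
    member_ids: list[str] = field(default_factory=list)

    @property
    def total_copies(self) -> int:
        return sum(self.copies_by_replicate.values())

    @property
    def instances(self) -> int:
        return sum(1 for c in self.copies_by_replicate.values() if c > 0)


def _representative(
    members: Sequence[AnnotatedRearrangement],
) -> AnnotatedRearrangement:
    # fewest N's, then highest copies, then lexicographically smallest sequence
    return min(members, key=lambda r: (r.sequence.count("N"), -r.copies, r.sequence))


def collapse_subject(
    rearrs: Sequence[AnnotatedRearrangement],
) -> list[UniqueSequence]:
    """Collapse one subject's rearrangements into unique sequences.

    Records are grouped under N-tolerant equality against each group's
    seed, visiting records in descending copy order (ties broken by
    sequence then sequence_id, so the result is independent of input
    order).  Total input copies are conserved exactly.
    """
    subjects = {r.subject_id for r in rearrs}
    if len(subjects) > 1:
        raise ValueError(f"collapse_subject requires one subject, got {sorted(subjects)}")

    ordered = sorted(rearrs, key=lambda r: (-r.copies, r.sequence, r.sequence_id))
    seeds: list[str] = []
    groups: list[list[AnnotatedRearrangement]] = []
    # exact-match index to avoid the quadratic scan for identical sequences
    exact: dict[str, int] = {}
    for rec in ordered:
        idx = exact.get(rec.sequence)
        if idx is None:
            for i, seed in enumerate(seeds):
                if sequences_equal_n(rec.sequence, seed):
                    idx = i
                    break
        if idx is None:
            seeds.append(rec.sequence)
            groups.append([rec])
            exact[rec.sequence] = len(seeds) - 1
        else:
            groups[idx].append(rec)
            exact.setdefault(rec.sequence, idx)

    uniques: list[UniqueSequence] = []
    for members in groups:
        rep = _representative(members)
        by_rep: dict[str, int] = {}
        for m in members:
            by_rep[m.replicate_id] = by_rep.get(m.replicate_id, 0) + m.copies
        uniques.append(
            UniqueSequence(
                useq_id=rep.sequence_id,
                subject_id=rep.subject_id,
                sequence=rep.sequence,
                v_call=rep.v_call,
                j_call=rep.j_call,
                cdr3_nt=rep.cdr3_nt,
                cdr3_aa=rep.cdr3_aa,
                copies_by_replicate=by_rep,
                v_identity=rep.v_identity,
                germline=rep.germline,
                member_ids=[m.sequence_id for m in members],
            )
        )
    return uniques
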