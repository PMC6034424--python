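"""Clonal inference: eligibility filtering and greedy complete-linkage
grouping of unique sequences into clones.

A clone is a set of unique sequences sharing V gene (or an intersecting
gene-tie set), J gene, and CDR3 nucleotide length, in which every pair
of members has at least 85% CDR3 amino-acid similarity (Hamming).  To
keep spurious clones out, sequences with subject-wide copy number below
2, a stop codon in the CDR3, or a 30-nt window of the aligned V region
falling below 60% germline identity (a likely uncorrected indel) are
excluded beforehand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence

from .collapse import UniqueSequence

logger = logging.getLogger(__name__)

MIN_COPIES = 2
MIN_CDR3_SIMILARITY = 0.85
INDEL_WINDOW = 30
MIN_WINDOW_IDENTITY = 0.60

_GAPS = ".-"


@dataclass
class EligibilityReport:
    useq_id: str
    excluded_reason: str  # one of {"low_copy", "cdr3_stop", "indel_window", "none"}

    @property
    def eligible(self) -> bool:
        return self.excluded_reason == "none"


def window_identity_ok(
    sequence: str,
    germline: str,
    window: int = INDEL_WINDOW,
    min_identity: float = MIN_WINDOW_IDENTITY,
) -> bool:
    """Check that no ``window``-nt stretch of the aligned V region falls
    below ``min_identity`` germline identity.

    N's (and alignment gaps) are excluded from both numerator and
    denominator; windows with an empty denominator are skipped.  The
    comparison runs over the region where both strings are defined.
    """
    span = min(len(sequence), len(germline))
    if span < window:
        return True
    # exact rational threshold so a window at exactly min_identity passes
    thr = Fraction(str(min_identity))
    informative = []
    match = []
    for i in range(span):
        s, g = sequence[i], germline[i]
        ok = s != "N" and g != "N" and s not in _GAPS and g not in _GAPS
        informative.append(1 if ok else 0)
        match.append(1 if ok and s == g else 0)
    denom = sum(informative[:window])
    num = sum(match[:window])
    for start in range(span - window + 1):
        if start:
            denom += informative[start + window - 1] - informative[start - 1]
            num += match[start + window - 1] - match[start - 1]
        if denom and num * thr.denominator < thr.numerator * denom:
            return False
    return True


def eligible(
    useq: UniqueSequence,
    germline: Optional[str] = None,
    min_copies: int = MIN_COPIES,
    window: int = INDEL_WINDOW,
    min_window_identity: float = MIN_WINDOW_IDENTITY,
) -> EligibilityReport:
    """Decide whether a unique sequence may enter clonal assignment.

    Exclusion reasons, checked in order: subject-wide copy number below
    ``min_copies``; a stop codon (``*``) in the CDR3 amino-acid sequence;
    a low-identity 30-nt window against the aligned germline.  When no
    germline is available the window check is skipped with a warning.
    """
    if useq.total_copies < min_copies:
        return EligibilityReport(useq.useq_id, "low_copy")
    if "*" in useq.cdr3_aa:
        return EligibilityReport(useq.useq_id, "cdr3_stop")
    germ = germline if germline is not None else useq.germline
    if germ is None:
        logger.warning(
            "no germline alignment for %s; indel-window check skipped", useq.useq_id
        )
    elif not window_identity_ok(
        useq.sequence, germ, window=window, min_identity=min_window_identity
    ):
        return EligibilityReport(useq.useq_id, "indel_window")
    return EligibilityReport(useq.useq_id, "none")


def filter_eligible(
    useqs: Sequence[UniqueSequence], min_copies: int = MIN_COPIES
) -> tuple[list[UniqueSequence], list[EligibilityReport]]:
    """Partition unique sequences into the clonally eligible subset and a
    per-sequence report."""
    reports = [eligible(u, min_copies=min_copies) for u in useqs]
    kept = [u for u, r in zip(useqs, reports) if r.eligible]
    return kept, reports


def cdr3_similarity(a: str, b: str) -> float:
    """Fraction of matching positions between two equal-length CDR3
    amino-acid strings (1 − normalised Hamming distance).

    A position where either symbol is ``X`` (ambiguous translation, e.g.
    from a masked nucleotide) counts as a match, mirroring N-tolerance at
    the nucleotide level.
    """
    if len(a) != len(b) or not a:
        raise ValueError("CDR3 similarity requires equal nonzero lengths")
    mismatches = sum(
        1 for x, y in zip(a, b) if x != y and x != "X" and y != "X"
    )
    return 1.0 - mismatches / len(a)


@dataclass
class Clone:
    """A clone: unique sequences from one subject grouped by the V/J/CDR3
    rule, with the three size metrics."""

    clone_id: int
    subject_id: str
    v_gene: frozenset[str]
    j_gene: frozenset[str]
    cdr3_len_nt: int
    members: list[UniqueSequence] = field(default_factory=list)

    @property
    def copies(self) -> int:
        """Total read copies across all members and replicates."""
        return sum(m.total_copies for m in self.members)

    @property
    def instances(self) -> int:
        """Unique-sequence × replicate occurrences."""
        return sum(m.instances for m in self.members)

    @property
    def uniques(self) -> int:
        """Number of distinct member sequences."""
        return len(self.members)

    @property
    def replicate_presence(self) -> frozenset[str]:
        return frozenset(
            rep
            for m in self.members
            for rep, c in m.copies_by_replicate.items()
            if c > 0
        )

    @property
    def cdr3_aa(self) -> str:
        """CDR3 of the highest-copy member, as the clone representative."""
        best = max(self.members, key=lambda m: (m.total_copies, m.sequence))
        return best.cdr3_aa


def assign_clones(
    useqs: Sequence[UniqueSequence], min_sim: float = MIN_CDR3_SIMILARITY
) -> list[Clone]:
    """Group eligible unique sequences of one subject into clones.

    Within each bucket keyed by J gene compatibility and CDR3 nucleotide
    length, sequences are visited in descending subject-wide copy order
    (ties broken by sequence, then id).  A sequence joins the first clone
    whose V- and J-tie sets it intersects and whose *every* current
    member it matches at >= ``min_sim`` CDR3 amino-acid similarity
    (complete linkage); otherwise it founds a new clone.  The clone's V/J
    gene sets are the running intersections of its members' tie sets.
    Clone ids follow discovery order.
    """
    ordered = sorted(
        useqs, key=lambda u: (-u.total_copies, u.sequence, u.useq_id)
    )
    clones: list[Clone] = []
    # candidate clones indexed by CDR3 nt length to skip impossible buckets
    by_len: dict[int, list[Clone]] = {}
    for u in ordered:
        key = len(u.cdr3_nt)
        placed = False
        for clone in by_len.get(key, ()):
            if not (clone.v_gene & u.v_call) or not (clone.j_gene & u.j_call):
                continue
            if all(
                cdr3_similarity(u.cdr3_aa, m.cdr3_aa) >= min_sim
                for m in clone.members
            ):
                clone.members.append(u)
                clone.v_gene &= u.v_call
                clone.j_gene &= u.j_call
                placed = True
                break
        if not placed:
            clone = Clone(
                clone_id=len(clones) + 1,
                subject_id=u.subject_id,
                v_gene=frozenset(u.v_call),
                j_gene=frozenset(u.j_call),
                cdr3_len_nt=key,
                members=[u],
            )
            clones.append(clone)
            by_len.setdefault(key, []).append(clone)
    return clones


def rescue_low_copy(useqs: Sequence[UniqueSequence]) -> list[UniqueSequence]:
    """Report which sequences were rescued by subject-wide collapsing.

    A sequence seen once in each of two libraries has subject-wide copy
    number 2 and passes the low-copy filter even though no single library
    supports it twice.  Collapsing across the subject implements the
    rescue implicitly; this reports the sequences it saved
    (``total_copies >= 2`` but maximum per-replicate copy count of 1).
    """
    return [
        u
        for u in useqs
        if u.total_copies >= MIN_COPIES
        and max(u.copies_by_replicate.values()) == 1
    ]
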