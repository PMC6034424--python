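"""Readers and writers for repertoire sequencing data.

Handles FASTQ with Sanger (Phred+33) qualities, the AIRR Rearrangement
TSV dialect used throughout the pipeline, and run-level quality-control
records.  Sequences are never case-normalised and ``N`` characters are
preserved verbatim: downstream collapsing relies on them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FastqParseError(ValueError):
    """A FASTQ record was malformed (e.g. base/quality length mismatch)."""


class MissingColumnError(KeyError):
    """A required column is absent from an AIRR Rearrangement TSV."""

    def __init__(self, missing: Sequence[str]):
        self.missing = list(missing)
        super().__init__(f"missing required AIRR column(s): {', '.join(self.missing)}")


@dataclass
class QualityRead:
    """A raw sequencing read with per-base Phred quality scores."""

    read_id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise FastqParseError(
                f"record {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        if any(q < 0 for q in self.quals):
            raise ValueError(f"record {self.read_id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AnnotatedRearrangement:
    """A V/J-annotated heavy-chain sequence tied to a subject and replicate.

    ``v_call``/``j_call`` are sets because the annotator may assign gene
    ties.  ``copies`` carries the within-replicate duplicate count.
    """

    sequence_id: str
    subject_id: str
    replicate_id: str
    v_call: frozenset[str]
    j_call: frozenset[str]
    sequence: str
    cdr3_nt: str
    cdr3_aa: str
    v_identity: Optional[float] = None
    copies: int = 1
    germline: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.v_call:
            raise ValueError(f"{self.sequence_id}: empty v_call")
        if self.copies < 1:
            raise ValueError(f"{self.sequence_id}: copies must be >= 1")


@dataclass
class RunQCRecord:
    """Run-level Illumina quality metrics, both as percentages in [0, 100]."""

    pct_pass_filter: float
    pct_q30: float

    def __post_init__(self) -> None:
        for name in ("pct_pass_filter", "pct_q30"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must be in [0, 100], got {v}")


@dataclass
class RunQCResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)


#: Minimum percentage of clusters passing the instrument filter.
MIN_PCT_PASS_FILTER = 90.0
#: Minimum percentage of bases at or above Phred Q30.
MIN_PCT_Q30 = 70.0


def check_run_quality(rec: RunQCRecord) -> RunQCResult:
    """Evaluate a sequencing run against the %PF >= 90 and %Q30 >= 70 cut-offs.

    Both boundaries are inclusive ("90% or greater").  On failure the
    result lists every violated threshold.
    """
    reasons = []
    if rec.pct_pass_filter < MIN_PCT_PASS_FILTER:
        reasons.append(
            f"%PF {rec.pct_pass_filter:g} below threshold {MIN_PCT_PASS_FILTER:g}"
        )
    if rec.pct_q30 < MIN_PCT_Q30:
        reasons.append(f"%Q30 {rec.pct_q30:g} below threshold {MIN_PCT_Q30:g}")
    return RunQCResult(passed=not reasons, reasons=reasons)


def read_fastq(path: str | Path) -> Iterator[QualityRead]:
    """Stream ``QualityRead`` records from a Sanger (Phred+33) FASTQ file.

    Raises :class:`FastqParseError` on malformed records, naming the
    offending record where the underlying parser identifies it.
    """
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield QualityRead(
                read_id=rec.id,
                bases=str(rec.seq),
                quals=list(rec.letter_annotations["phred_quality"]),
            )
    except ValueError as exc:
        raise FastqParseError(str(exc)) from exc


def write_fastq(reads: Iterable[QualityRead], path: str | Path) -> int:
    """Write reads as Sanger FASTQ; returns the number of records written."""
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            rec = SeqRecord(Seq(r.bases), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = list(r.quals)
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n


# AIRR Rearrangement v1 column names used by this pipeline.
_REQUIRED = ("sequence_id", "v_call", "j_call", "cdr3", "cdr3_aa")


def _split_calls(value: str) -> frozenset[str]:
    return frozenset(tok.strip() for tok in str(value).split(",") if tok.strip())


def read_airr(
    path: str | Path,
    replicate_column: str = "repertoire_id",
    replicate_id: Optional[str] = None,
    subject_column: str = "subject_id",
) -> list[AnnotatedRearrangement]:
    """Read an AIRR Rearrangement TSV into annotated rearrangements.

    ``v_call``/``j_call`` may be comma-separated gene ties.  The
    ``duplicate_count`` column is optional (default 1).  The replicate
    label is read from ``replicate_column``; when that column is absent a
    constant ``replicate_id`` must be supplied instead.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if replicate_column not in df.columns and replicate_id is None:
        missing.append(replicate_column)
    if missing:
        raise MissingColumnError(missing)

    records: list[AnnotatedRearrangement] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        seq = d.get("sequence_alignment") or d.get("sequence") or ""
        v_id = d.get("v_identity", "")
        records.append(
            AnnotatedRearrangement(
                sequence_id=d["sequence_id"],
                subject_id=d.get(subject_column) or "subject",
                replicate_id=(
                    d[replicate_column] if replicate_column in d else replicate_id
                ),
                v_call=_split_calls(d["v_call"]),
                j_call=_split_calls(d["j_call"]),
                sequence=seq,
                cdr3_nt=d["cdr3"],
                cdr3_aa=d["cdr3_aa"],
                v_identity=float(v_id) if v_id not in ("", None) else None,
                copies=int(float(d.get("duplicate_count") or 1)),
                germline=d.get("germline_alignment") or None,
            )
        )
    return records


def write_airr(
    records: Iterable[AnnotatedRearrangement],
    path: str | Path,
    replicate_column: str = "repertoire_id",
) -> int:
    """Write rearrangements back to AIRR Rearrangement TSV."""
    rows = []
    for r in records:
        rows.append(
            {
                "sequence_id": r.sequence_id,
                "subject_id": r.subject_id,
                replicate_column: r.replicate_id,
                "v_call": ",".join(sorted(r.v_call)),
                "j_call": ",".join(sorted(r.j_call)),
                "sequence_alignment": r.sequence,
                "germline_alignment": r.germline or "",
                "cdr3": r.cdr3_nt,
                "cdr3_aa": r.cdr3_aa,
                "v_identity": "" if r.v_identity is None else repr(r.v_identity),
                "duplicate_count": r.copies,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return len(rows)
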