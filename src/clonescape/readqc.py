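"""Read-level quality control: sliding-window trimming, low-quality base
masking, and N-count / length filtering.

The three operations are applied in that order by :func:`qc_pipeline`,
mirroring a pRESTO-style ``trimqual`` → ``maskqual`` → ``missing``/``length``
filter chain for already-merged reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .io import QualityRead

DEFAULT_WINDOW = 10
DEFAULT_QUAL = 20
DEFAULT_MAX_N = 10
DEFAULT_MIN_LEN = 100


def trim_sliding_window(
    read: QualityRead, window: int = DEFAULT_WINDOW, threshold: float = DEFAULT_QUAL
) -> QualityRead:
    """Truncate a read at the first low-quality sliding window.

    Windows of ``window`` bases are scanned 5'→3' at every start position
    (step 1).  At the first window whose mean quality falls below
    ``threshold`` the read is truncated so that nothing at or beyond that
    window's start remains.  Reads shorter than the window are returned
    unchanged.  The mean comparison is exact (``sum < threshold*window``)
    so that float ties cannot occur.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(read)
    if n < window:
        return read
    limit = threshold * window
    running = sum(read.quals[:window])
    if running < limit:
        return QualityRead(read.read_id, "", [])
    for start in range(1, n - window + 1):
        running += read.quals[start + window - 1] - read.quals[start - 1]
        if running < limit:
            return QualityRead(read.read_id, read.bases[:start], read.quals[:start])
    return read


def mask_low_quality(read: QualityRead, threshold: int = DEFAULT_QUAL) -> QualityRead:
    """Replace every base with quality strictly below ``threshold`` by N.

    Qualities and read length are unchanged.
    """
    bases = "".join(
        "N" if q < threshold else b for b, q in zip(read.bases, read.quals)
    )
    return QualityRead(read.read_id, bases, list(read.quals))


def filter_read(
    read: QualityRead, max_n: int = DEFAULT_MAX_N, min_len: int = DEFAULT_MIN_LEN
) -> bool:
    """Keep predicate: discard iff more than ``max_n`` N's or shorter than
    ``min_len`` bases.  Returns True when the read is kept."""
    return read.bases.count("N") <= max_n and len(read) >= min_len


@dataclass
class QCSummary:
    input: int = 0
    trimmed: int = 0
    masked_bases: int = 0
    discarded: int = 0
    kept: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.input,
            "trimmed": self.trimmed,
            "masked_bases": self.masked_bases,
            "discarded": self.discarded,
            "kept": self.kept,
        }


def qc_pipeline(
    reads: Iterable[QualityRead],
    window: int = DEFAULT_WINDOW,
    qual: int = DEFAULT_QUAL,
    max_n: int = DEFAULT_MAX_N,
    min_len: int = DEFAULT_MIN_LEN,
) -> tuple[list[QualityRead], QCSummary]:
    """Apply trim → mask → filter to a read stream.

    Returns the kept reads (input order preserved) and summary counters:
    reads seen, reads shortened by trimming, bases masked, reads
    discarded, reads kept.  The pipeline is deterministic and idempotent.
    """
    kept: list[QualityRead] = []
    summary = QCSummary()
    for read in reads:
        summary.input += 1
        trimmed = trim_sliding_window(read, window=window, threshold=qual)
        if len(trimmed) < len(read):
            summary.trimmed += 1
        masked = mask_low_quality(trimmed, threshold=qual)
        summary.masked_bases += sum(
            1 for b, m in zip(trimmed.bases, masked.bases) if b != m
        )
        if filter_read(masked, max_n=max_n, min_len=min_len):
            summary.kept += 1
            kept.append(masked)
        else:
            summary.discarded += 1
    return kept, summary
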