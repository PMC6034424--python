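"""Rarefaction, clonal overlap, and clone-tracking presence matrices.

Individual-based rarefaction gives the expected clone richness in a
random subsample of n sequence copies; sample-based rarefaction gives
the expected richness across a random subset of t replicate libraries.
Both use the exact hypergeometric expectation

    E[S] = Σ_i [1 − C(N−N_i, n) / C(N, n)],

evaluated with log-binomials for numerical stability (no resampling).
Stratifying the sample-based curves by clone size and asking which
stratum's curve levels off tells you how large a clone must be before
the replicates sample it reliably — the power calculation behind clone
tracking and overlap analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln


def _log_comb(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(k + 1) - gammaln(np.asarray(n) - k + 1)


def _expected_richness(group_sizes: np.ndarray, total: int, n: int) -> float:
    """Hypergeometric E[number of groups represented in a subsample of n]."""
    if n == 0:
        return 0.0
    sizes = np.asarray(group_sizes, dtype=float)
    absent = np.zeros_like(sizes)
    can_miss = total - sizes >= n
    if np.any(can_miss):
        absent[can_miss] = np.exp(
            _log_comb(total - sizes[can_miss], n) - _log_comb(float(total), n)
        )
    return float(np.sum(1.0 - absent))


def individual_rarefaction(counts: Sequence[int], n: int) -> float:
    """Expected clone richness in a random draw of ``n`` of the N copies.

    ``counts`` are per-clone copy numbers; requires 0 <= n <= N = Σcounts.
    At n = N this returns the observed richness exactly.
    """
    counts = [c for c in counts if c > 0]
    total = sum(counts)
    if not 0 <= n <= total:
        raise ValueError(f"subsample size {n} outside [0, {total}]")
    return _expected_richness(np.array(counts), total, n)


@dataclass
class PresenceMatrix:
    """Boolean clones × replicates incidence matrix for clone tracking."""

    matrix: np.ndarray
    clone_ids: list
    replicate_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.shape != (len(self.clone_ids), len(self.replicate_ids)):
            raise ValueError("matrix shape does not match labels")

    @classmethod
    def from_clones(
        cls, clones: Sequence, replicate_ids: Optional[Sequence[str]] = None
    ) -> "PresenceMatrix":
        if replicate_ids is None:
            replicate_ids = sorted(
                {rep for c in clones for rep in c.replicate_presence}
            )
        reps = list(replicate_ids)
        idx = {r: j for j, r in enumerate(reps)}
        m = np.zeros((len(clones), len(reps)), dtype=bool)
        for i, c in enumerate(clones):
            for rep in c.replicate_presence:
                m[i, idx[rep]] = True
        return cls(m, [c.clone_id for c in clones], reps)

    @property
    def T(self) -> int:
        """Number of replicate libraries."""
        return self.matrix.shape[1]

    @property
    def row_sums(self) -> np.ndarray:
        """T_i: the number of replicates containing each clone."""
        return self.matrix.sum(axis=1)


def sample_rarefaction(m: PresenceMatrix, t: int) -> float:
    """Expected clone richness over a random subset of ``t`` of the T
    replicate libraries (sample-based rarefaction)."""
    if not 1 <= t <= m.T:
        raise ValueError(f"t must be in [1, {m.T}]")
    rows = m.row_sums
    rows = rows[rows > 0]
    return _expected_richness(rows.astype(float), m.T, t)


@dataclass
class RarefactionCurve:
    sizes: np.ndarray
    values: np.ndarray
    label: Optional[int] = None  # instance cut-off for stratified curves


def individual_rarefaction_curve(
    counts: Sequence[int], sizes: Optional[Sequence[int]] = None
) -> RarefactionCurve:
    total = sum(c for c in counts if c > 0)
    if sizes is None:
        sizes = np.unique(np.linspace(0, total, 21).astype(int))
    return RarefactionCurve(
        np.asarray(sizes),
        np.array([individual_rarefaction(counts, int(n)) for n in sizes]),
    )


def stratified_sample_rarefaction(
    m: PresenceMatrix, cutoffs: Sequence[int]
) -> list[RarefactionCurve]:
    """Sample-based rarefaction curves over t = 1..T for clone strata.

    For each cut-off k, the matrix is restricted to clones present in at
    least k replicates (clone size measured as replicate presence) and
    the expected-richness curve is computed.  An empty stratum yields an
    all-zero curve.
    """
    if any(k < 1 for k in cutoffs):
        raise ValueError("cutoffs must be >= 1")
    rows = m.row_sums
    ts = np.arange(1, m.T + 1)
    curves = []
    for k in cutoffs:
        strat = rows[rows >= k].astype(float)
        if strat.size:
            vals = np.array([_expected_richness(strat, m.T, int(t)) for t in ts])
        else:
            vals = np.zeros(len(ts))
        curves.append(RarefactionCurve(ts.copy(), vals, label=int(k)))
    return curves


def plateau_cutoff(
    curves: Sequence[RarefactionCurve], epsilon: float = 0.01
) -> Optional[int]:
    """Smallest stratum cut-off whose rarefaction curve levels off.

    The visual "levels off" judgement is made reproducible as a relative
    increment criterion: the curve has plateaued when the gain from the
    last added replicate, (S(T) − S(T−1)) / S(T), is below ``epsilon``
    (default 1%).  Empty strata never plateau.  Returns None when no
    curve qualifies.
    """
    best = None
    for curve in sorted(curves, key=lambda c: (c.label is None, c.label)):
        v = curve.values
        if len(v) < 2 or v[-1] <= 0:
            continue
        if (v[-1] - v[-2]) / v[-1] < epsilon:
            best = curve.label
            break
    return best


def cosine_similarity(
    a: Mapping[object, float] | Sequence[float],
    b: Mapping[object, float] | Sequence[float],
) -> float:
    """Cosine similarity Σ A_i B_i / (√ΣA_i² √ΣB_i²) between two clone
    abundance vectors.

    Mappings are aligned on the union of clone ids (absent clones count
    as 0); sequences must already be aligned.  Identical samples score 1,
    disjoint clone sets score 0, and the measure is invariant to overall
    abundance scale.
    """
    if isinstance(a, Mapping) and isinstance(b, Mapping):
        keys = sorted(set(a) | set(b), key=repr)
        va = np.array([a.get(k, 0.0) for k in keys], dtype=float)
        vb = np.array([b.get(k, 0.0) for k in keys], dtype=float)
    else:
        va = np.asarray(a, dtype=float)
        vb = np.asarray(b, dtype=float)
        if va.shape != vb.shape:
            raise ValueError("aligned abundance vectors must have equal length")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for an all-zero vector")
    return float(np.dot(va, vb) / (na * nb))


@dataclass
class OverlapSummary:
    """Venn-style presence accounting over per-sample clone sets."""

    exactly_k: dict[int, int]
    at_least_k: dict[int, int]
    shared_clones: list


def overlap_counts(
    clone_sets: Mapping[str, set],
    sizes: Optional[Mapping[object, float]] = None,
) -> OverlapSummary:
    """Count clones by the number of samples they appear in.

    ``exactly_k[k]`` / ``at_least_k[k]`` count clones present in exactly /
    at least k samples.  ``shared_clones`` lists clones found in two or
    more samples, sorted by presence (descending), then by the optional
    ``sizes`` metric (descending), then by id.
    """
    presence: dict[object, int] = {}
    for s in clone_sets.values():
        for cid in s:
            presence[cid] = presence.get(cid, 0) + 1
    n_samples = len(clone_sets)
    exactly = {k: 0 for k in range(1, n_samples + 1)}
    for count in presence.values():
        exactly[count] += 1
    at_least = {
        k: sum(v for kk, v in exactly.items() if kk >= k)
        for k in range(1, n_samples + 1)
    }
    sizes = sizes or {}
    shared = sorted(
        (cid for cid, cnt in presence.items() if cnt >= 2),
        key=lambda cid: (-presence[cid], -sizes.get(cid, 0), repr(cid)),
    )
    return OverlapSummary(exactly, at_least, shared)
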