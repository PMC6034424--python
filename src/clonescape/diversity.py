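"""Hill-number diversity profiles and descriptive diversity/evenness
metrics over clone abundance vectors.

The true diversity of order q (Hill number) is

    ᵠD = (Σ_i p_i^q)^(1/(1-q)),

where p_i is the proportional abundance of clone i under a chosen size
metric (copies, instances, or unique sequences).  Order 0 counts clones
(richness); the q→1 limit is exp(Shannon entropy); order 2 is the
inverse Simpson concentration.  Larger q weights large clones more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

_Q_ONE_TOL = 1e-9


@dataclass
class AbundanceVector:
    """Proportional clone abundances p_i under one size metric.

    All entries are strictly positive and sum to 1 (zero-abundance clones
    are excluded before construction, so 0·ln 0 never arises).
    """

    p: np.ndarray
    metric_label: str = "copies"

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1 or len(self.p) == 0:
            raise ValueError("abundance vector must be a nonempty 1-D array")
        if np.any(self.p <= 0):
            raise ValueError("all abundances must be strictly positive")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")

    @classmethod
    def from_counts(
        cls, counts: Iterable[float], metric_label: str = "copies"
    ) -> "AbundanceVector":
        c = np.asarray(list(counts), dtype=float)
        c = c[c > 0]
        if c.size == 0:
            raise ValueError("no positive counts")
        return cls(c / c.sum(), metric_label)

    @property
    def R(self) -> int:
        """Richness: the number of clones."""
        return len(self.p)


@dataclass
class DiversityProfile:
    orders: np.ndarray
    values: np.ndarray


def hill_diversity(p: AbundanceVector, q: float) -> float:
    """True diversity of order ``q``; exact richness at q=0 and the
    continuous exp(H) limit within 1e-9 of q=1."""
    if q < 0:
        raise ValueError("order q must be >= 0")
    if q == 0:
        return float(p.R)
    if abs(q - 1.0) <= _Q_ONE_TOL:
        return float(np.exp(shannon(p)))
    return float(np.sum(p.p**q) ** (1.0 / (1.0 - q)))


def default_orders(stop: float = 4.0, step: float = 0.1) -> np.ndarray:
    """The default order grid: 0 to ``stop`` in steps of ``step`` (which
    already contains the integer Hill numbers)."""
    return np.round(np.arange(0.0, stop + step / 2, step), 10)


def diversity_profile(
    p: AbundanceVector, orders: Optional[Sequence[float]] = None
) -> DiversityProfile:
    """Hill diversity evaluated on an ascending grid of orders.

    The profile is non-increasing in q and constant for a uniform
    abundance vector.
    """
    q = default_orders() if orders is None else np.asarray(orders, dtype=float)
    if np.any(np.diff(q) < 0):
        raise ValueError("orders must be sorted ascending")
    return DiversityProfile(q, np.array([hill_diversity(p, v) for v in q]))


def shannon(p: AbundanceVector) -> float:
    """Shannon entropy H = −Σ p_i ln p_i (natural log)."""
    return float(-np.sum(p.p * np.log(p.p)))


def simpson(p: AbundanceVector) -> float:
    """Simpson concentration λ = Σ p_i²: the probability that two randomly
    drawn copies/instances/unique sequences belong to the same clone.
    Equals 1 / hill_diversity(p, 2)."""
    return float(np.sum(p.p**2))


def pielou(p: AbundanceVector) -> Optional[float]:
    """Pielou's evenness J = H / ln R, in [0, 1]; 1 means all clones have
    equal size.  Undefined for a single clone (ln 1 = 0): returns None."""
    if p.R < 2:
        return None
    return shannon(p) / math.log(p.R)


def clonality(p: AbundanceVector) -> Optional[float]:
    """Clonality C = 1 − Pielou evenness: 0 for a maximally even
    repertoire, approaching 1 as it becomes monoclonal.

    Implemented as the normalised complement of entropy (1 − H/ln R),
    the usual repertoire convention for a [0, 1]-bounded loss-of-diversity
    score.  Undefined (None) for a single clone.
    """
    j = pielou(p)
    return None if j is None else 1.0 - j


def abundance_from_clones(
    clones: Sequence,
    metric: str = "copies",
    min_instances_cutoff: int = 1,
) -> AbundanceVector:
    """Build an abundance vector from clones, applying an instance cut-off.

    Clones with fewer than ``min_instances_cutoff`` instances are dropped
    and the chosen metric is renormalised over the survivors.
    """
    if metric not in ("copies", "instances", "uniques"):
        raise ValueError(f"unknown metric {metric!r}")
    kept = [c for c in clones if c.instances >= min_instances_cutoff]
    if not kept:
        raise ValueError(
            f"no clones meet the instance cut-off {min_instances_cutoff}"
        )
    return AbundanceVector.from_counts(
        (getattr(c, metric) for c in kept), metric_label=metric
    )
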