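"""Synthetic multi-replicate repertoire generator with ground truth.

Emulates a bulk gDNA heavy-chain sequencing experiment on one subject:
clones drawn from a heavy-tailed cell-count distribution, each assigned
a germline V/J pair (from a small bundled *synthetic* germline FASTA)
and a random in-frame CDR3; somatic-hypermutation variants within each
clone; multinomial cell sampling per replicate library; lognormal PCR
amplification noise on copy numbers; and per-base sequencing error on
the emitted reads.  Ground truth (true clone of every emitted sequence,
true cell counts) is retained so that pipeline recovery can be scored.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .clones import Clone
from .io import AnnotatedRearrangement, QualityRead, write_airr, write_fastq

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-design parameters of the simulated experiment.

    Defaults mirror a survey-level two-replicate amplification of one
    subject: a few hundred clones with lognormal cell counts, ~5% SHM
    divergence among lineage variants, modest lognormal PCR bias, and an
    Illumina-like 1e-3 per-base miscall rate.
    """

    seed: int = 0
    n_clones: int = 200
    size_distribution: str = "lognormal"  # or "powerlaw"
    lognormal_mu: float = 2.0
    lognormal_sigma: float = 1.0
    powerlaw_alpha: float = 2.5
    shm_rate: float = 0.05
    mean_extra_variants: float = 2.0
    n_replicates: int = 2
    cells_sampled_per_replicate: int = 1000
    pcr_lognormal_sigma: float = 0.5
    seq_error_rate: float = 0.001
    mean_quality: int = 35
    low_quality_fraction: float = 0.02
    cdr3_codon_range: tuple[int, int] = (12, 20)

    def validate(self) -> None:
        if self.n_clones < 1 or self.n_replicates < 1:
            raise ValueError("need at least one clone and one replicate")
        if self.cells_sampled_per_replicate < 1:
            raise ValueError("cells_sampled_per_replicate must be >= 1")
        for name in ("shm_rate", "seq_error_rate", "low_quality_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    """True clonal provenance of the simulated data."""

    clone_of_sequence: dict[str, int]
    cells_per_clone: dict[int, int]
    sampled_cells: dict[str, dict[int, int]]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "clone_of_sequence": self.clone_of_sequence,
                    "cells_per_clone": {str(k): v for k, v in self.cells_per_clone.items()},
                    "sampled_cells": {
                        rep: {str(k): v for k, v in d.items()}
                        for rep, d in self.sampled_cells.items()
                    },
                },
                fh,
                indent=1,
            )


@dataclass
class SimulationResult:
    rearrangements: list[AnnotatedRearrangement]
    reads: dict[str, list[QualityRead]]
    truth: GroundTruth
    config: SimulationConfig


def load_germline() -> tuple[dict[str, str], dict[str, str]]:
    """Load the bundled synthetic IGHV/IGHJ-like germline segments.

    These are randomly generated stop-free in-frame stand-ins, not real
    germline alleles; clone inference only needs gene labels and CDR3s.
    """
    v: dict[str, str] = {}
    j: dict[str, str] = {}
    ref = resources.files("clonescape.data") / "synthetic_germline.fasta"
    with ref.open() as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            (v if rec.id.startswith("IGHV") else j)[rec.id] = str(rec.seq)
    return v, j


def _draw_clone_cells(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.size_distribution == "lognormal":
        cells = rng.lognormal(cfg.lognormal_mu, cfg.lognormal_sigma, cfg.n_clones)
    elif cfg.size_distribution == "powerlaw":
        cells = rng.pareto(cfg.powerlaw_alpha - 1.0, cfg.n_clones) + 1.0
    else:
        raise ValueError(f"unknown size_distribution {cfg.size_distribution!r}")
    return np.maximum(1, np.round(cells)).astype(int)


def _random_cdr3(n_codons: int, rng: np.random.Generator) -> str:
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(_BASES, 3))
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)


def _mutate(
    seq: str, rate: float, rng: np.random.Generator, stop: Optional[int] = None
) -> str:
    """Substitute each position (up to ``stop``) with probability ``rate``."""
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1").copy()
    limit = len(arr) if stop is None else min(stop, len(arr))
    hits = np.nonzero(rng.random(limit) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _quality_string(n: int, cfg: SimulationConfig, rng: np.random.Generator) -> list[int]:
    quals = np.clip(np.round(rng.normal(cfg.mean_quality, 3.0, n)), 2, 41).astype(int)
    low = rng.random(n) < cfg.low_quality_fraction
    quals[low] = rng.integers(2, 16, int(low.sum()))
    return quals.tolist()


def simulate_repertoire(cfg: SimulationConfig) -> SimulationResult:
    """Simulate one subject's multi-replicate repertoire.

    Identical configurations (including the seed) reproduce byte-identical
    output.  SHM variants mutate the V segment of the lineage; the
    junction is inherited from the clone's founding rearrangement, which
    is what makes CDR3-based clone inference a well-posed target on this
    data.  Sequencing error, by contrast, hits every position.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    v_germ, j_germ = load_germline()
    v_names = sorted(v_germ)
    j_names = sorted(j_germ)

    cells_per_clone = _draw_clone_cells(cfg, rng)
    # per-variant flat arrays
    var_seq: list[str] = []
    var_clone: list[int] = []
    var_cells: list[int] = []
    var_vgene: list[str] = []
    var_jgene: list[str] = []
    var_vlen: list[int] = []
    var_cdr3len: list[int] = []
    for clone_id in range(1, cfg.n_clones + 1):
        vg = v_names[rng.integers(len(v_names))]
        jg = j_names[rng.integers(len(j_names))]
        n_codons = int(rng.integers(cfg.cdr3_codon_range[0], cfg.cdr3_codon_range[1] + 1))
        cdr3 = _random_cdr3(n_codons, rng)
        vseq = v_germ[vg]
        founder = vseq + cdr3 + j_germ[jg]
        n_cells = int(cells_per_clone[clone_id - 1])
        k_extra = min(int(rng.poisson(cfg.mean_extra_variants)), max(n_cells - 1, 0))
        variants = [founder]
        for _ in range(k_extra):
            variants.append(_mutate(founder, cfg.shm_rate, rng, stop=len(vseq)))
        # founder-weighted split of the clone's cells over its variants
        weights = rng.dirichlet([5.0] + [1.0] * k_extra)
        counts = rng.multinomial(n_cells, weights)
        for seq, cnt in zip(variants, counts):
            if cnt == 0:
                continue
            var_seq.append(seq)
            var_clone.append(clone_id)
            var_cells.append(int(cnt))
            var_vgene.append(vg)
            var_jgene.append(jg)
            var_vlen.append(len(vseq))
            var_cdr3len.append(len(cdr3))

    cell_counts = np.array(var_cells, dtype=float)
    p = cell_counts / cell_counts.sum()

    rearrangements: list[AnnotatedRearrangement] = []
    reads: dict[str, list[QualityRead]] = {}
    clone_of_sequence: dict[str, int] = {}
    sampled_cells: dict[str, dict[int, int]] = {}

    for r in range(1, cfg.n_replicates + 1):
        rep = f"R{r}"
        reads[rep] = []
        sampled = rng.multinomial(cfg.cells_sampled_per_replicate, p)
        per_clone: dict[int, int] = {}
        seq_counter = 0
        observed: Counter[tuple[int, str]] = Counter()
        for vi in np.nonzero(sampled)[0]:
            clone_id = var_clone[vi]
            per_clone[clone_id] = per_clone.get(clone_id, 0) + int(sampled[vi])
            factor = rng.lognormal(0.0, cfg.pcr_lognormal_sigma)
            copies = max(1, int(round(sampled[vi] * factor)))
            template = var_seq[vi]
            for _ in range(copies):
                read_seq = (
                    _mutate(template, cfg.seq_error_rate, rng)
                    if cfg.seq_error_rate > 0
                    else template
                )
                observed[(vi, read_seq)] += 1
        # deterministic emission order: by variant index then sequence
        for (vi, read_seq), dup in sorted(observed.items()):
            seq_counter += 1
            sid = f"{rep}_{seq_counter:06d}"
            clone_id = var_clone[vi]
            vlen, c3len = var_vlen[vi], var_cdr3len[vi]
            vg = var_vgene[vi]
            cdr3_nt = read_seq[vlen : vlen + c3len]
            germ_v = v_germ[vg]
            matches = sum(1 for a, b in zip(read_seq[:vlen], germ_v) if a == b)
            rearrangements.append(
                AnnotatedRearrangement(
                    sequence_id=sid,
                    subject_id="sim_subject",
                    replicate_id=rep,
                    v_call=frozenset({vg}),
                    j_call=frozenset({var_jgene[vi]}),
                    sequence=read_seq,
                    cdr3_nt=cdr3_nt,
                    cdr3_aa=str(Seq(cdr3_nt).translate()),
                    v_identity=matches / vlen,
                    copies=dup,
                    germline=germ_v,
                )
            )
            clone_of_sequence[sid] = clone_id
            for k in range(dup):
                reads[rep].append(
                    QualityRead(
                        read_id=f"{sid}.{k + 1}",
                        bases=read_seq,
                        quals=_quality_string(len(read_seq), cfg, rng),
                    )
                )
        sampled_cells[rep] = per_clone

    truth = GroundTruth(
        clone_of_sequence=clone_of_sequence,
        cells_per_clone={
            i + 1: int(c) for i, c in enumerate(cells_per_clone)
        },
        sampled_cells=sampled_cells,
    )
    return SimulationResult(rearrangements, reads, truth, cfg)


def write_simulation(result: SimulationResult, out_dir: str | Path) -> None:
    """Write per-replicate AIRR TSVs and FASTQs plus the ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_rep: dict[str, list[AnnotatedRearrangement]] = {}
    for rec in result.rearrangements:
        by_rep.setdefault(rec.replicate_id, []).append(rec)
    for rep, recs in sorted(by_rep.items()):
        write_airr(recs, out / f"{rep}.tsv")
    for rep, rds in sorted(result.reads.items()):
        write_fastq(rds, out / f"{rep}.fastq")
    result.truth.to_json(out / "truth.json")


@dataclass
class RecoveryReport:
    precision: float
    recall: float
    f1: float
    n_sequences: int
    true_pairs: int
    predicted_pairs: int


def evaluate_recovery(
    truth: GroundTruth, inferred: Sequence[Clone]
) -> RecoveryReport:
    """Pairwise precision/recall/F1 of inferred clones against the truth.

    Each clustered unique sequence gets a true clone label (majority vote
    over its collapsed members).  Over all pairs of clustered sequences,
    precision is the fraction of same-inferred-clone pairs that are truly
    clonal, recall the fraction of truly clonal pairs grouped together.
    With no pairs on either side the scores degenerate to 1.
    """
    pred_labels: list[int] = []
    true_labels: list[int] = []
    for ci, clone in enumerate(inferred):
        for m in clone.members:
            votes = Counter(
                truth.clone_of_sequence[sid]
                for sid in m.member_ids
                if sid in truth.clone_of_sequence
            )
            if not votes:
                continue
            pred_labels.append(ci)
            true_labels.append(votes.most_common(1)[0][0])

    contingency: Counter[tuple[int, int]] = Counter(zip(pred_labels, true_labels))
    pred_sizes: Counter[int] = Counter(pred_labels)
    true_sizes: Counter[int] = Counter(true_labels)

    def pairs(counter: Counter) -> int:
        return sum(v * (v - 1) // 2 for v in counter.values())

    tp = pairs(contingency)
    pred_pairs = pairs(pred_sizes)
    true_pairs = pairs(true_sizes)
    precision = tp / pred_pairs if pred_pairs else 1.0
    recall = tp / true_pairs if true_pairs else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return RecoveryReport(
        precision, recall, f1, len(pred_labels), true_pairs, pred_pairs
    )
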