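"""Simulation framework: synthetic germline sets, labeled repertoires, ROC evaluation.

Simulated repertoires are the calibration bed for the detector: each dataset
contains an exact (rounded) number of chimeric sequences, every sequence is a
uniformly mutated copy of one reference (or a breakpoint join of two), and the
emitted AIRR table carries perfect alignments so detection runs with no
external aligner.  The difference-from-reference (DFR) knob stands in for
sequencing error (TCR) or somatic hypermutation (BCR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .airr_io import NT_CODE, QueryRecord, ReferenceMSA

logger = logging.getLogger(__name__)

_BASES = np.array([NT_CODE[b] for b in "ACGT"], dtype=np.uint8)
_CODE_TO_CHAR = np.array(list("ACGT-N"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated repertoire.

    Defaults mirror the standard benchmark design: 10,000 sequences with a 5%
    chimerism rate (500 chimeric, 9,500 non-chimeric), one breakpoint per
    chimera, uniform mutation at ``dfr`` and a uniform breakpoint.
    """

    n_total: int = 10_000
    chimera_rate: float = 0.05
    dfr: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.chimera_rate <= 1):
            raise ValueError("chimera_rate must lie in [0, 1]")
        if not (0 <= self.dfr < 0.75):
            raise ValueError("dfr must lie in [0, 0.75)")
        if self.n_total < 1:
            raise ValueError("n_total must be positive")


@dataclass
class SimRecord:
    """One simulated sequence with its ground truth."""

    sequence_id: str
    sequence: str  # gapped, MSA length L
    is_chimera: bool
    parents: tuple[str, ...]  # 1 or 2 allele names
    breakpoint: int | None  # 1-based MSA column of the first parent-2 column
    n_mutations: int

    def __post_init__(self):
        if self.is_chimera != (len(self.parents) == 2) or self.is_chimera != (
            self.breakpoint is not None
        ):
            raise ValueError("chimera flag, parent count and breakpoint disagree")


def _parse_allele(name: str) -> tuple[str, str]:
    if "*" not in name:
        raise ValueError(f"allele name {name!r} is not of the form gene*allele")
    gene, allele = name.split("*", 1)
    return gene, allele


def build_genotype(records: Sequence[tuple[str, str]], seed: int) -> list[tuple[str, str]]:
    """Sample a genotype: one allele per gene, chosen uniformly.

    ``records`` are (name, sequence) pairs with names of the form
    ``gene*allele``.  Deterministic for a fixed seed; gene order follows first
    appearance in the input.
    """
    rng = np.random.default_rng(seed)
    by_gene: dict[str, list[tuple[str, str]]] = {}
    for name, seq in records:
        gene, _ = _parse_allele(name)
        by_gene.setdefault(gene, []).append((name, seq))
    return [alleles[rng.integers(len(alleles))] for alleles in by_gene.values()]


def _divergence_to_branch(p: float) -> float:
    """Per-branch substitution rate so two branches realize pairwise divergence p.

    Two sequences independently mutated from a common ancestor at rate e
    differ per site with probability 2e(1-e) + (2/3)e^2; invert for e.
    """
    if p == 0:
        return 0.0
    return 0.75 * (1.0 - np.sqrt(1.0 - 4.0 * p / 3.0))


def mutate(seq: str, dfr: float, rng: np.random.Generator) -> str:
    """Substitute each non-gap site independently with probability dfr.

    Substitutions are uniform over the three other bases; gaps are untouched.
    """
    if dfr == 0:
        return seq
    chars = np.array(list(seq))
    editable = np.flatnonzero(chars != "-")
    hit = editable[rng.random(editable.size) < dfr]
    for i in hit:
        others = [b for b in "ACGT" if b != chars[i]]
        chars[i] = others[rng.integers(3)]
    return "".join(chars)


def _mutate_codes(codes: np.ndarray, dfr: float, rng: np.random.Generator) -> np.ndarray:
    """Vectorized uniform mutation on a uint8-coded row (gap code 4 untouched)."""
    out = codes.copy()
    editable = np.flatnonzero(codes < 4)
    if dfr == 0 or editable.size == 0:
        return out
    hit = editable[rng.random(editable.size) < dfr]
    # add 1..3 mod 4: always lands on a different base
    out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def synth_germline_set(
    n_genes: int = 50,
    families: int = 7,
    within_div: float = 0.06,
    between_div: float = 0.30,
    L: int = 300,
    seed: int = 0,
) -> ReferenceMSA:
    """Generate a gap-free family-structured germline V set.

    One root sequence per family (pairwise divergence ~ ``between_div``), then
    genes within each family at pairwise divergence ~ ``within_div``.  Names
    follow the IMGT convention ``IGHV<family>-<gene>*01`` so family extraction
    (token before '-') works downstream.  Defaults emulate an IGHV-like
    genotype: ~50 genes in 7 families over ~300 alignment columns.
    """
    for d in (within_div, between_div):
        if not (0 <= d < 0.75):
            raise ValueError("divergences must lie in [0, 0.75)")
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, 4, size=L).astype(np.uint8)
    e_between = _divergence_to_branch(between_div)
    e_within = _divergence_to_branch(within_div)
    roots = [_mutate_codes(ancestor, e_between, rng) for _ in range(families)]
    records: list[tuple[str, str]] = []
    for g in range(n_genes):
        fam = g % families
        gene_codes = _mutate_codes(roots[fam], e_within, rng)
        name = f"IGHV{fam + 1}-{g + 1}*01"
        records.append((name, "".join(_CODE_TO_CHAR[gene_codes])))
    return ReferenceMSA.from_records(records)


def simulate_dataset(
    refs: ReferenceMSA, config: SimConfig
) -> tuple[list[SimRecord], pd.DataFrame, pd.DataFrame]:
    """Simulate a labeled repertoire from a reference set.

    Returns (records, airr_table, truth_table).  Chimeras join two uniformly
    mutated distinct references at a uniform breakpoint on [2, L] (parent 1
    contributes columns < breakpoint); non-chimeras are single mutated
    references.  The AIRR table carries a perfect pairwise alignment against
    parent 1, so threading reconstructs the simulated sequence exactly.
    """
    n_chim = round(config.n_total * config.chimera_rate)
    if n_chim > 0 and refs.N < 2:
        raise ValueError("chimera simulation requires at least two references")
    rng = np.random.default_rng(config.seed)
    L = refs.L
    codes = refs.codes
    labels = np.zeros(config.n_total, dtype=bool)
    labels[:n_chim] = True
    rng.shuffle(labels)

    records: list[SimRecord] = []
    for i, is_chim in enumerate(labels):
        sid = f"sim-{i + 1:06d}"
        if is_chim:
            p1, p2 = rng.choice(refs.N, size=2, replace=False)
            m1 = _mutate_codes(codes[p1], config.dfr, rng)
            m2 = _mutate_codes(codes[p2], config.dfr, rng)
            bp = int(rng.integers(2, L + 1))  # uniform on [2, L]
            seq_codes = np.concatenate([m1[: bp - 1], m2[bp - 1 :]])
            template = np.concatenate([codes[p1][: bp - 1], codes[p2][bp - 1 :]])
            n_mut = int(np.sum((seq_codes != template) & (template < 4)))
            records.append(
                SimRecord(
                    sequence_id=sid,
                    sequence="".join(_CODE_TO_CHAR[seq_codes]),
                    is_chimera=True,
                    parents=(refs.names[p1], refs.names[p2]),
                    breakpoint=bp,
                    n_mutations=n_mut,
                )
            )
        else:
            p1 = int(rng.integers(refs.N))
            m1 = _mutate_codes(codes[p1], config.dfr, rng)
            n_mut = int(np.sum((m1 != codes[p1]) & (codes[p1] < 4)))
            records.append(
                SimRecord(
                    sequence_id=sid,
                    sequence="".join(_CODE_TO_CHAR[m1]),
                    is_chimera=False,
                    parents=(refs.names[p1],),
                    breakpoint=None,
                    n_mutations=n_mut,
                )
            )

    airr_rows = []
    truth_rows = []
    for rec in records:
        parent1 = rec.parents[0]
        germ_row = refs.row(parent1)
        qchars = []
        gchars = []
        for qc, gc in zip(rec.sequence, germ_row):
            if qc == "-" and gc == "-":
                continue
            qchars.append(qc)
            gchars.append(gc)
        airr_rows.append(
            {
                "sequence_id": rec.sequence_id,
                "v_call": parent1,
                "v_sequence_alignment": "".join(qchars),
                "v_germline_alignment": "".join(gchars),
                "v_germline_start": 1,
                "v_germline_end": len(germ_row) - germ_row.count("-"),
            }
        )
        truth_rows.append(
            {
                "sequence_id": rec.sequence_id,
                "is_chimera": "T" if rec.is_chimera else "F",
                "parent1": rec.parents[0],
                "parent2": rec.parents[1] if rec.is_chimera else "",
                "breakpoint": rec.breakpoint if rec.is_chimera else "",
                "dfr": config.dfr,
                "n_mutations": rec.n_mutations,
            }
        )
    logger.info(
        "simulated %d sequences (%d chimeric, %d non-chimeric) at DFR %.3f",
        config.n_total,
        n_chim,
        config.n_total - n_chim,
        config.dfr,
    )
    return records, pd.DataFrame(airr_rows), pd.DataFrame(truth_rows)


def airr_records_from_frame(airr: pd.DataFrame) -> list[QueryRecord]:
    """Convert a simulated AIRR table to QueryRecords without a file round trip."""
    out = []
    for row in airr.astype(str).to_dict(orient="records"):
        out.append(
            QueryRecord(
                sequence_id=row["sequence_id"],
                v_call=row["v_call"],
                v_sequence_alignment=row["v_sequence_alignment"],
                v_germline_alignment=row["v_germline_alignment"],
                v_germline_start=int(row["v_germline_start"]),
                v_germline_end=int(row["v_germline_end"]),
                passthrough=dict(row),
            )
        )
    return out


def evaluate(
    posteriors: Sequence[float], truth: Sequence[bool], threshold: float = 0.95
) -> dict:
    """ROC AUC (rank statistic, tie-averaged) plus confusion counts at >= threshold.

    With single-class truth the AUC is undefined and reported as NaN with a
    warning; confusion counts are always returned.
    """
    scores = np.asarray(posteriors, dtype=float)
    labels = np.asarray(truth, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("posteriors and truth must have equal length")
    called = scores >= threshold
    tp = int(np.sum(called & labels))
    fp = int(np.sum(called & ~labels))
    fn = int(np.sum(~called & labels))
    tn = int(np.sum(~called & ~labels))
    if labels.all() or not labels.any():
        logger.warning("single-class truth: AUC undefined")
        auc = float("nan")
    else:
        auc = float(roc_auc_score(labels, scores))
    n_pos = max(tp + fn, 1)
    n_neg = max(fp + tn, 1)
    return {
        "auc": auc,
        "tpr": tp / n_pos,
        "fpr": fp / n_neg,
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "threshold": threshold,
    }
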