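"""Reading/writing of germline MSAs and AIRR Rearrangement tables, and query threading.

The detector never runs an aligner.  Queries arrive with a pairwise alignment
against their assigned germline V (the ``v_sequence_alignment`` /
``v_germline_alignment`` pair produced by standard annotators), and that
alignment is *threaded* onto the reference multiple sequence alignment so that
every query becomes one observation symbol per MSA column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: integer codes used throughout the numeric kernels
NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 5}
CODE_NT = "ACGT-N"

REQUIRED_AIRR_COLUMNS = (
    "sequence_id",
    "v_call",
    "v_sequence_alignment",
    "v_germline_alignment",
    "v_germline_start",
    "v_germline_end",
)


class NotAnAlignmentError(ValueError):
    """Raised when FASTA records claimed to be an MSA have unequal lengths."""


class UnknownReferenceError(KeyError):
    """Raised when a query's v_call allele is absent from the reference MSA."""


class MalformedRecordError(ValueError):
    """Raised when an AIRR record's alignment is internally inconsistent."""


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T/-/N string as a uint8 code array."""
    out = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    table = np.full(128, 255, dtype=np.uint8)
    for ch, code in NT_CODE.items():
        table[ord(ch)] = code
    codes = table[out]
    if np.any(codes == 255):
        bad = int(np.argmax(codes == 255))
        raise ValueError(f"invalid symbol {seq[bad]!r} at position {bad + 1}")
    return codes


@dataclass
class ReferenceMSA:
    """An aligned germline V database.

    ``col_map[name][p-1]`` gives the 1-based MSA column holding ungapped
    germline position ``p`` (1-based) of reference ``name``.
    """

    names: list[str]
    rows: list[str]
    L: int
    col_map: dict[str, np.ndarray]
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def N(self) -> int:
        return len(self.names)

    @property
    def codes(self) -> np.ndarray:
        """(N, L) uint8 matrix of the gapped rows."""
        if self._codes is None:
            self._codes = np.vstack([encode(r) for r in self.rows])
        return self._codes

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    @classmethod
    def from_records(cls, records: Sequence[tuple[str, str]]) -> "ReferenceMSA":
        if not records:
            raise ValueError("reference MSA contains no records")
        names: list[str] = []
        rows: list[str] = []
        L = len(records[0][1])
        for name, seq in records:
            if not name:
                raise ValueError("reference record with empty name")
            if name in names:
                raise ValueError(f"duplicate reference name {name!r}")
            seq = _normalize_seq(seq)
            if len(seq) != L:
                raise NotAnAlignmentError(
                    f"not an alignment: record {name!r} has length {len(seq)}, "
                    f"expected {L}"
                )
            for pos, ch in enumerate(seq):
                if ch not in NT_CODE:
                    raise ValueError(
                        f"record {name!r}: invalid symbol {ch!r} at column {pos + 1}"
                    )
            names.append(name)
            rows.append(seq)
        col_map = {
            name: np.flatnonzero(np.frombuffer(row.encode(), dtype=np.uint8) != ord("-")).astype(np.int64) + 1
            for name, row in zip(names, rows)
        }
        return cls(names=names, rows=rows, L=L, col_map=col_map)


def read_reference_msa(path) -> ReferenceMSA:
    """Read a gapped FASTA of germline V alleles as a :class:`ReferenceMSA`."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    msa = ReferenceMSA.from_records(records)
    logger.info("read %d aligned references (L=%d) from %s", msa.N, msa.L, path)
    return msa


@dataclass
class QueryRecord:
    """One AIRR Rearrangement row.

    ``passthrough`` keeps every input column verbatim (raw strings, original
    order) so that output files reproduce input cells byte-for-byte; the typed
    fields are parsed copies of the required columns.
    """

    sequence_id: str
    v_call: str
    v_sequence_alignment: str
    v_germline_alignment: str
    v_germline_start: int
    v_germline_end: int
    passthrough: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if len(self.v_sequence_alignment) != len(self.v_germline_alignment):
            raise MalformedRecordError(
                f"{self.sequence_id}: v_sequence_alignment and "
                "v_germline_alignment lengths differ"
            )
        if not (1 <= self.v_germline_start <= self.v_germline_end):
            raise MalformedRecordError(
                f"{self.sequence_id}: invalid germline coordinates "
                f"[{self.v_germline_start}, {self.v_germline_end}]"
            )
        ungapped = len(self.v_germline_alignment) - self.v_germline_alignment.count("-")
        if ungapped != self.v_germline_end - self.v_germline_start + 1:
            raise MalformedRecordError(
                f"{self.sequence_id}: germline alignment spans {ungapped} bases "
                f"but coordinates span "
                f"{self.v_germline_end - self.v_germline_start + 1}"
            )


def read_airr(path) -> list[QueryRecord]:
    """Read an AIRR Rearrangement TSV into :class:`QueryRecord` objects.

    Rows with an empty ``v_sequence_alignment`` are skipped with a logged
    count; a missing required column is fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_AIRR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"AIRR file {path} is missing required columns: {', '.join(missing)}")
    records: list[QueryRecord] = []
    n_empty = 0
    for row in df.to_dict(orient="records"):
        if not row["v_sequence_alignment"]:
            n_empty += 1
            continue
        records.append(
            QueryRecord(
                sequence_id=row["sequence_id"],
                v_call=row["v_call"],
                v_sequence_alignment=_normalize_seq(row["v_sequence_alignment"]),
                v_germline_alignment=_normalize_seq(row["v_germline_alignment"]),
                v_germline_start=int(row["v_germline_start"]),
                v_germline_end=int(row["v_germline_end"]),
                passthrough=dict(row),
            )
        )
    if n_empty:
        logger.warning("%s: skipped %d rows with empty v_sequence_alignment", path, n_empty)
    if not records:
        logger.warning("%s: no usable records", path)
    logger.info("%s: read %d usable records", path, len(records))
    return records


@dataclass
class ThreadedQuery:
    """A query projected onto MSA column space: one symbol per column."""

    sequence_id: str
    obs: str
    assigned_v: str


def thread_query(q: QueryRecord, msa: ReferenceMSA) -> ThreadedQuery:
    """Project a query onto the reference MSA using its existing alignment.

    The pairwise alignment is walked with a germline-position counter starting
    at ``v_germline_start``; each germline-consuming column places the query
    symbol at that germline position's MSA column.  Query insertions (germline
    gaps) are dropped; uncovered MSA columns stay ``-`` (emission-neutral).
    """
    allele = q.v_call.split(",")[0].strip()
    if allele not in msa.col_map:
        raise UnknownReferenceError(allele)
    q.validate()
    cmap = msa.col_map[allele]
    obs = ["-"] * msa.L
    pos = q.v_germline_start  # 1-based ungapped germline position
    for gc, qc in zip(q.v_germline_alignment, q.v_sequence_alignment):
        if gc == "-":
            continue  # insertion in the query: no MSA column to place it in
        if pos > len(cmap):
            raise MalformedRecordError(
                f"{q.sequence_id}: alignment extends past the end of {allele}"
            )
        if qc in ("A", "C", "G", "T", "-"):
            obs[cmap[pos - 1] - 1] = qc
        else:
            obs[cmap[pos - 1] - 1] = "N"
        pos += 1
    return ThreadedQuery(sequence_id=q.sequence_id, obs="".join(obs), assigned_v=allele)


def thread_queries(
    records: Iterable[QueryRecord], msa: ReferenceMSA, strict: bool = False
) -> tuple[list[QueryRecord], list[ThreadedQuery], int]:
    """Thread many records, skipping (or failing on) unknown v_call alleles.

    Returns (retained records, threaded queries, number skipped).
    """
    kept: list[QueryRecord] = []
    threaded: list[ThreadedQuery] = []
    n_skipped = 0
    for rec in records:
        try:
            tq = thread_query(rec, msa)
        except UnknownReferenceError as exc:
            if strict:
                raise
            n_skipped += 1
            logger.debug("skipping %s: unknown reference %s", rec.sequence_id, exc)
            continue
        kept.append(rec)
        threaded.append(tq)
    if n_skipped:
        logger.warning("skipped %d records with v_call absent from the MSA", n_skipped)
    return kept, threaded, n_skipped


@dataclass
class ChimeraCall:
    """Per-query detection result.

    ``segments`` holds Viterbi ``(allele, rate_class, start_col, end_col)``
    tuples (1-based MSA columns) when the Viterbi pass was run; ``breakpoints``
    the columns at which the parent reference changes.
    """

    posterior: float
    is_chimera: bool
    segments: list[tuple[str, int, int, int]] | None = None
    breakpoints: list[int] | None = None


def _format_segments(segments: list[tuple[str, int, int, int]]) -> str:
    # merge adjacent same-allele runs (rate-class switches are not breakpoints)
    merged: list[tuple[str, int, int]] = []
    for allele, _k, start, end in segments:
        if merged and merged[-1][0] == allele:
            merged[-1] = (allele, merged[-1][1], end)
        else:
            merged.append((allele, start, end))
    return ";".join(f"{a}:{s}-{e}" for a, s, e in merged)


def write_detect_output(
    records: Sequence[QueryRecord], calls: Sequence[ChimeraCall], path
) -> None:
    """Write the AIRR table back out with appended chimera columns.

    Input columns are preserved byte-for-byte and in order; appended columns
    are ``chimera_probability`` (>= 6 significant digits), ``chimera``
    ("T"/"F"), and — when any call carries a Viterbi result —
    ``chimera_segments`` and ``chimera_breakpoints``.
    """
    if len(records) != len(calls):
        raise ValueError(
            f"got {len(records)} records but {len(calls)} calls"
        )
    rows = [dict(rec.passthrough) for rec in records]
    have_viterbi = any(c.segments is not None for c in calls)
    for row, call in zip(rows, calls):
        row["chimera_probability"] = f"{call.posterior:.6g}"
        row["chimera"] = "T" if call.is_chimera else "F"
        if have_viterbi:
            row["chimera_segments"] = (
                _format_segments(call.segments) if call.segments is not None else ""
            )
            row["chimera_breakpoints"] = (
                ";".join(str(b) for b in call.breakpoints)
                if call.breakpoints is not None
                else ""
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
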