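"""End-to-end chimera detection: presets, orchestration, recombination tables.

``detect`` wires together threading (airr_io), the Forward posterior (hmm or
baumwelch) and output writing, and optionally tabulates which germline gene
pairs recombine — the raw counts behind the usual left-gene x right-gene
diagnostic heatmaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import airr_io
from .airr_io import ChimeraCall, ReferenceMSA, ThreadedQuery
from .baumwelch import BWConfig, fit_bw
from .hmm import (
    ModelConfig,
    ViterbiResult,
    build_state_space,
    db_rate_grid,
    forward_many,
    viterbi_linear,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReceptorPreset:
    """Receptor-specific defaults.

    IG data carries somatic hypermutation, so the per-reference mutation rate
    is fitted (BW mode, initialized at 0.05).  TCR data lacks SHM; a fixed
    0.005 rate (DB mode, single class) absorbs sequencing error.
    """

    receptor: str
    method: str
    rates: tuple[float, ...]
    init_rate: float | None = None


def receptor_preset(receptor: str) -> ReceptorPreset:
    receptor = receptor.upper()
    if receptor == "IG":
        return ReceptorPreset(receptor="IG", method="BW", rates=(0.05,), init_rate=0.05)
    if receptor == "TR":
        return ReceptorPreset(receptor="TR", method="DB", rates=(0.005,))
    raise ValueError("receptor must be 'IG' or 'TR'")


@dataclass
class RecombinationTable:
    """Counts of single-recombination chimeras keyed by (left gene, right gene)."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"left_gene": l, "right_gene": r, "count": c}
            for (l, r), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["left_gene", "right_gene", "count"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def gene_of(allele: str) -> str:
    """Allele name truncated at '*' (IMGT gene)."""
    return allele.split("*")[0]


def family_of(gene: str) -> str:
    """Token before the first '-'; genes without '-' form their own family."""
    return gene.split("-")[0]


def tabulate_recombinations(viterbi_results) -> RecombinationTable:
    """Count left-gene/right-gene pairs over single-recombination chimeras.

    Results whose Viterbi path changes reference more (or less) than exactly
    once are excluded.
    """
    table = RecombinationTable()
    for res in viterbi_results:
        if len(res.breakpoints) != 1:
            continue
        refs = []
        for allele, _k, _s, _e in res.segments:
            if not refs or refs[-1] != allele:
                refs.append(allele)
        key = (gene_of(refs[0]), gene_of(refs[1]))
        table.counts[key] = table.counts.get(key, 0) + 1
    return table


def same_family_fraction(table: RecombinationTable) -> float:
    """Fraction of tabulated count mass with left and right genes in one family."""
    if table.total == 0:
        raise ValueError("empty recombination table")
    same = sum(
        c for (l, r), c in table.counts.items() if family_of(l) == family_of(r)
    )
    return same / table.total


def _resolve_config(
    receptor: str | None,
    method: str | None,
    mutation_rate: float | None,
    k: int | None,
    min_rate: float | None,
    max_rate: float | None,
    init_rate: float | None,
    psi: float,
    mu: float,
    threshold: float,
) -> tuple[ModelConfig, BWConfig | None]:
    """Merge the receptor preset with explicit overrides (overrides win)."""
    preset = receptor_preset(receptor) if receptor else None
    method = method or (preset.method if preset else "DB")
    if method == "BW":
        bw = BWConfig(init_rate=init_rate if init_rate is not None else
                      (preset.init_rate if preset and preset.init_rate else 0.05))
        cfg = ModelConfig(
            psi=psi, mu=0.0, rates=(bw.init_rate,), method="BW", threshold=threshold
        )
        return cfg, bw
    if mutation_rate is not None:
        rates: tuple[float, ...] = (mutation_rate,)
    elif k is not None:
        rates = db_rate_grid(
            k,
            min_rate if min_rate is not None else 0.0,
            max_rate if max_rate is not None else 0.25,
        )
    elif preset is not None:
        rates = preset.rates
    else:
        rates = db_rate_grid()
    eff_mu = mu if len(rates) > 1 else 0.0
    cfg = ModelConfig(
        psi=psi, mu=eff_mu, rates=rates, method="DB", threshold=threshold
    )
    return cfg, None


def detect(
    airr_path,
    msa_path,
    out_path,
    receptor: str | None = None,
    method: str | None = None,
    mutation_rate: float | None = None,
    k: int | None = None,
    min_rate: float | None = None,
    max_rate: float | None = None,
    init_rate: float | None = None,
    psi: float = 1e-4,
    mu: float = 1e-3,
    threshold: float = 0.95,
    viterbi_all: bool = False,
    recomb_path=None,
    strict: bool = False,
) -> dict:
    """Run chimera detection end to end.

    Reads the reference MSA and AIRR table, threads every query, computes the
    Forward posterior (DB: fixed rate grid; BW: rates fitted by EM over the
    dataset), calls chimeras at ``threshold``, runs Viterbi on called chimeras
    (or on all queries with ``viterbi_all``), writes the annotated AIRR table
    and optionally the recombination-pair table.  Returns summary counts.
    """
    msa = airr_io.read_reference_msa(msa_path)
    records = airr_io.read_airr(airr_path)
    total = len(records)
    kept, threaded, n_skipped = airr_io.thread_queries(records, msa, strict=strict)
    if not threaded:
        raise ValueError("no analyzable queries after threading")
    cfg, bw = _resolve_config(
        receptor, method, mutation_rate, k, min_rate, max_rate, init_rate,
        psi, mu, threshold,
    )
    space = build_state_space(msa, cfg)
    per_ref_rates = None
    if cfg.method == "BW":
        fit = fit_bw(threaded, msa, bw, cfg)
        posteriors = fit.posteriors
        per_ref_rates = fit.rates.reshape(-1, 1)
    else:
        posteriors = forward_many(threaded, msa, cfg)

    calls: list[ChimeraCall] = []
    viterbi_results: list[ViterbiResult] = []
    for q, post in zip(threaded, posteriors):
        is_chim = bool(post >= cfg.threshold)
        call = ChimeraCall(posterior=float(post), is_chimera=is_chim)
        if viterbi_all or is_chim:
            vr = viterbi_linear(q, msa, space, cfg, rates=per_ref_rates)
            call.segments = vr.segments
            call.breakpoints = vr.breakpoints
            if is_chim:
                viterbi_results.append(vr)
        calls.append(call)

    airr_io.write_detect_output(kept, calls, out_path)
    if recomb_path is not None:
        tabulate_recombinations(viterbi_results).write_tsv(recomb_path)
    summary = {
        "total": total,
        "analyzed": len(threaded),
        "skipped": total - len(threaded),
        "chimeric": int(sum(c.is_chimera for c in calls)),
    }
    logger.info("detect summary: %s", summary)
    return summary
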