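"""CDS filtering, GC computation, isochore binning and expression tests.

Coding sequences are kept when they are at least 100 bp, contain only
A/C/G/T, start with ATG, end with a stop codon (TAA/TAG/TGA) and — by
default — have a length divisible by three.  Kept sequences are binned
by GC% into four isochore classes at user-supplied cutpoints (half-open
[low, high) intervals; a value exactly at a cutpoint goes to the upper
bin) and per-bin expression levels are compared with a tie-corrected
Kruskal-Wallis test plus a Mann-Whitney test between two designated
"main" bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .group_stats import RankTestResult, mann_whitney

logger = logging.getLogger(__name__)

__all__ = [
    "CdsRecord",
    "IsochoreBinning",
    "FastaParseError",
    "ExpressionTestResult",
    "read_cds_fasta",
    "write_cds_fasta",
    "filter_cds",
    "gc_fraction",
    "assign_bins",
    "attach_expression",
    "expression_by_bin",
]

UNAMBIGUOUS = frozenset("ACGT")
STOP_CODONS = ("TAA", "TAG", "TGA")


class FastaParseError(ValueError):
    pass


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence with optional expression level and isochore bin."""

    cds_id: str
    sequence: str
    expression: float | None = None
    bin: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float | None:
        """(G+C)/length; None for ambiguous or empty sequences."""
        if not self.sequence or set(self.sequence) - UNAMBIGUOUS:
            return None
        return gc_fraction(self.sequence)


def read_cds_fasta(path: str | Path) -> list[CdsRecord]:
    """Read CDSs from a FASTA file; sequences are upper-cased.

    The id is the header token before the first whitespace.  Duplicate
    ids and malformed files (sequence data before the first header,
    headers with no id) raise :class:`FastaParseError` with the
    offending line number.
    """
    path = Path(path)
    records: list[CdsRecord] = []
    seen: dict[str, int] = {}
    cur_id: str | None = None
    chunks: list[str] = []

    def flush():
        if cur_id is not None:
            records.append(CdsRecord(cds_id=cur_id, sequence="".join(chunks)))

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                cur_id = line[1:].split()[0] if line[1:].split() else ""
                if not cur_id:
                    raise FastaParseError(f"{path}: line {lineno}: header with no id")
                if cur_id in seen:
                    raise FastaParseError(
                        f"{path}: line {lineno}: duplicate id {cur_id!r} "
                        f"(first at line {seen[cur_id]})"
                    )
                seen[cur_id] = lineno
                chunks = []
            else:
                if cur_id is None:
                    raise FastaParseError(
                        f"{path}: line {lineno}: sequence data before first '>' header"
                    )
                chunks.append(line.strip().upper())
    flush()
    if not records:
        logger.warning("no records in %s", path)
    return records


def write_cds_fasta(records: Iterable[CdsRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.cds_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def filter_cds(
    records: Sequence[CdsRecord],
    *,
    min_length: int = 100,
    require_codon_multiple: bool = True,
) -> tuple[list[CdsRecord], list[tuple[CdsRecord, str]]]:
    """Partition CDSs into kept and rejected (with the first failing rule).

    Rules, in order: length >= ``min_length``; only A/C/G/T; ATG start;
    TAA/TAG/TGA stop; length divisible by 3 (toggleable).
    """
    kept: list[CdsRecord] = []
    rejected: list[tuple[CdsRecord, str]] = []
    for rec in records:
        seq = rec.sequence
        if len(seq) < min_length:
            rejected.append((rec, "length"))
        elif set(seq) - UNAMBIGUOUS:
            rejected.append((rec, "ambiguous"))
        elif not seq.startswith("ATG"):
            rejected.append((rec, "no_start"))
        elif seq[-3:] not in STOP_CODONS:
            rejected.append((rec, "no_stop"))
        elif require_codon_multiple and len(seq) % 3 != 0:
            rejected.append((rec, "frame"))
        else:
            kept.append(rec)
    logger.info("filter_cds: kept %d / %d", len(kept), len(records))
    return kept, rejected


def gc_fraction(sequence: str) -> float:
    """(#G + #C) / length of an unambiguous nucleotide sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - UNAMBIGUOUS
    if bad:
        raise ValueError(f"ambiguous characters in sequence: {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class IsochoreBinning:
    """Three ascending GC% cutpoints defining four isochore classes."""

    cutpoints: tuple[float, float, float]
    labels: tuple[str, str, str, str] = ("L", "H1", "H2", "H3")

    def __post_init__(self):
        if len(self.labels) != len(self.cutpoints) + 1:
            raise ValueError("need exactly one more label than cutpoints")
        if list(self.cutpoints) != sorted(self.cutpoints) or len(
            set(self.cutpoints)
        ) != len(self.cutpoints):
            raise ValueError(f"cutpoints must be strictly ascending: {self.cutpoints}")

    def bin_of(self, gc_percent: float) -> str:
        idx = int(np.searchsorted(self.cutpoints, gc_percent, side="right"))
        return self.labels[idx]


def assign_bins(
    records: Sequence[CdsRecord], binning: IsochoreBinning
) -> list[CdsRecord]:
    """Assign each unambiguous CDS its isochore bin from GC% = 100*gc_fraction."""
    out = []
    counts: dict[str, int] = {lab: 0 for lab in binning.labels}
    for rec in records:
        gc = rec.gc_fraction
        if gc is None:
            out.append(rec)
            continue
        label = binning.bin_of(100.0 * gc)
        counts[label] += 1
        out.append(replace(rec, bin=label))
    logger.info("bin counts: %s", counts)
    return out


def attach_expression(
    records: Sequence[CdsRecord],
    expression: Mapping[str, float],
    *,
    log_transform: bool = False,
) -> list[CdsRecord]:
    """Merge per-CDS expression levels (consumed already log-transformed
    unless ``log_transform`` is set)."""
    out = []
    for rec in records:
        if rec.cds_id in expression:
            val = float(expression[rec.cds_id])
            if log_transform:
                val = float(np.log(val))
            out.append(replace(rec, expression=val))
        else:
            out.append(rec)
    return out


@dataclass
class ExpressionTestResult:
    kw_h: float
    kw_p: float
    bin_counts: dict
    bin_medians: dict
    main_bins: tuple[str, str]
    main_bin_test: RankTestResult | None


def expression_by_bin(
    records: Sequence[CdsRecord],
    main_bins: tuple[str, str] = ("H1", "H2"),
) -> ExpressionTestResult:
    """Kruskal-Wallis across all non-empty bins plus the main-bin Mann-Whitney.

    Only records carrying both a bin and an expression value enter the
    tests; at least two non-empty bins are required.
    """
    by_bin: dict[str, list[float]] = {}
    for rec in records:
        if rec.bin is not None and rec.expression is not None:
            by_bin.setdefault(rec.bin, []).append(rec.expression)
    if len(by_bin) < 2:
        raise ValueError("need expression values in at least 2 bins")
    groups = [np.asarray(v, dtype=float) for v in by_bin.values()]
    kw = stats.kruskal(*groups)
    main_test = None
    if main_bins[0] in by_bin and main_bins[1] in by_bin:
        main_test = mann_whitney(
            by_bin[main_bins[0]], by_bin[main_bins[1]], alternative="two_sided"
        )
    else:
        logger.warning("main bins %s not both populated", (main_bins,))
    return ExpressionTestResult(
        kw_h=float(kw.statistic),
        kw_p=float(kw.pvalue),
        bin_counts={k: len(v) for k, v in by_bin.items()},
        bin_medians={k: float(np.median(v)) for k, v in by_bin.items()},
        main_bins=tuple(main_bins),
        main_bin_test=main_test,
    )
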