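"""Genic annotation: map SNPs to genes within a fixed window.

A SNP is "genic" when it lies within 10 kb (default) of a gene's genomic
envelope.  Gene intervals come from refFlat or BED files; isoforms of one
symbol are merged to a single min-start/max-end envelope.  Coordinates are
held 0-based half-open internally; SNP positions arrive 1-based (the usual
SNP-table convention) and are converted at the boundary.  Chromosome names
are normalised by stripping any ``chr`` prefix.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GeneRecord",
    "SnpLocus",
    "load_genes",
    "genic_snps",
]

GENIC_WINDOW_BP = 10_000


@dataclass(frozen=True)
class GeneRecord:
    """A gene envelope: 0-based half-open [start, end) on a chromosome."""

    symbol: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError("empty chromosome")
        if not self.start < self.end:
            raise ValueError(f"gene {self.symbol!r}: start must be < end")


@dataclass(frozen=True)
class SnpLocus:
    """A SNP position, 1-based as in common SNP tables."""

    snp_id: str
    chromosome: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"SNP {self.snp_id!r}: position must be >= 1")


def _norm_chrom(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def _merge_isoforms(records: Iterable[GeneRecord]) -> list[GeneRecord]:
    envelope: dict[tuple[str, str], GeneRecord] = {}
    for rec in records:
        key = (rec.symbol, rec.chromosome)
        prev = envelope.get(key)
        if prev is None:
            envelope[key] = rec
        else:
            envelope[key] = GeneRecord(
                rec.symbol, rec.chromosome,
                min(prev.start, rec.start), max(prev.end, rec.end), prev.strand,
            )
    return list(envelope.values())


def load_genes(path: str | Path, format: str = "refFlat") -> list[GeneRecord]:
    """Read gene intervals from a refFlat or BED file.

    refFlat rows are ``geneName transcriptName chrom strand txStart txEnd
    ...`` with 0-based half-open transcript bounds; BED rows are ``chrom
    start end name [score] [strand]``, likewise 0-based half-open.  Isoforms
    sharing a symbol are merged to their envelope interval.
    """
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        try:
            if format == "refFlat":
                if len(f) < 6:
                    raise ValueError("fewer than 6 columns")
                records.append(
                    GeneRecord(f[0], _norm_chrom(f[2]), int(f[4]), int(f[5]), f[3])
                )
            elif format == "BED":
                if len(f) < 4:
                    raise ValueError("fewer than 4 columns")
                strand = f[5] if len(f) >= 6 else "+"
                records.append(
                    GeneRecord(f[3], _norm_chrom(f[0]), int(f[1]), int(f[2]), strand)
                )
            else:
                raise ValueError(f"unknown gene file format {format!r}")
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed {format} line ({exc})") from None
    return _merge_isoforms(records)


def genic_snps(
    snps: Sequence[SnpLocus],
    genes: Sequence[GeneRecord],
    window: int = GENIC_WINDOW_BP,
) -> dict[str, list[str]]:
    """Map each SNP to every gene within ``window`` bp of its envelope.

    A SNP at 0-based position p matches gene [start, end) when
    start - window <= p < end + window, i.e. up to exactly ``window`` bases
    outside either edge; strand is ignored.  SNPs matching nothing map to an
    empty list (intergenic).  ``window=0`` reduces to gene-body overlap.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    chrom_styles = {g.chromosome != _norm_chrom(g.chromosome) for g in genes} | {
        s.chromosome != _norm_chrom(s.chromosome) for s in snps
    }
    if chrom_styles == {True, False}:
        warnings.warn("mixed 'chr1'/'1' chromosome naming; normalising to bare names")
    for g in genes:
        lo, hi = g.start - window, g.end + window
        trees[_norm_chrom(g.chromosome)].addi(lo, hi, g.symbol)
    out: dict[str, list[str]] = {}
    for s in snps:
        hits = trees[_norm_chrom(s.chromosome)][s.position - 1]
        out[s.snp_id] = sorted({h.data for h in hits})
    return out
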