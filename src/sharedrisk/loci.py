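"""Association loci, lead-variant windows, and cross-disease window overlap.

A locus is any run of adjacent associated variants on one chromosome in
which consecutive positions differ by at most ``merge_gap`` (250 kb by
default; "within" is read as inclusive).  Each locus is then represented by
the fixed-width window centered on its lead variant (lowest p-value member),
500 kb by default, half-open and clipped at zero.  Two windows overlap iff
they share a chromosome and intersect as half-open intervals — for equal
width windows, iff their centers are less than one window width apart.

The background for window-overlap enrichment is the number of same-width
blocks the genome divides into: round(genome_length / block), which for the
GRCh38.p14 length 3,298,912,062 bp and 500 kb blocks is 6598.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .summary_io import VariantAssociation

log = logging.getLogger(__name__)

MERGE_GAP_BP = 250_000
WINDOW_BP = 500_000
#: GRCh38.p14 total sequence length in base pairs.
GRCH38_LENGTH_BP = 3_298_912_062


def normalize_chrom(chrom: str) -> str:
    """Normalize chromosome labels so "chr1" == "1" and "chrX" == "X"."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper()


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = normalize_chrom(chrom)
    return (0, f"{int(c):02d}") if c.isdigit() else (1, c)


@dataclass(frozen=True)
class Locus:
    """A merged run of associated variants; closed 1-based [start, end]."""

    chrom: str
    start: int
    end: int
    lead: VariantAssociation
    members: tuple[VariantAssociation, ...]

    @property
    def name(self) -> str:
        return self.lead.variant_id


@dataclass(frozen=True)
class Window:
    """Fixed-width half-open interval [start, end) centered on a lead variant."""

    chrom: str
    start: int
    end: int
    center: int
    name: str = ""

    def intersects(self, other: "Window") -> bool:
        return (normalize_chrom(self.chrom) == normalize_chrom(other.chrom)
                and self.start < other.end and other.start < self.end)


def build_loci(records: Sequence[VariantAssociation],
               merge_gap: int = MERGE_GAP_BP) -> list[Locus]:
    """Merge adjacent associated variants within ``merge_gap`` bp into loci.

    Records are sorted by (chromosome, position); merging is transitive, so
    a chain of variants each <= merge_gap from the next forms one locus.
    The result is independent of input order.  Records without a usable
    position are rejected with a diagnostic.
    """
    usable = []
    for r in records:
        if r.chrom is None or r.pos is None:
            log.warning("record %s rejected: missing chrom/pos", r.variant_id)
            continue
        usable.append(r)
    usable.sort(key=lambda r: (_chrom_sort_key(r.chrom), r.pos, r.variant_id))
    loci: list[Locus] = []
    run: list[VariantAssociation] = []

    def close(run):
        lead = min(run, key=lambda r: (r.log10_p, r.variant_id))
        return Locus(chrom=normalize_chrom(run[0].chrom), start=run[0].pos,
                     end=run[-1].pos, lead=lead, members=tuple(run))

    for r in usable:
        if run and (normalize_chrom(r.chrom) != normalize_chrom(run[-1].chrom)
                    or r.pos - run[-1].pos > merge_gap):
            loci.append(close(run))
            run = []
        run.append(r)
    if run:
        loci.append(close(run))
    return loci


def make_windows(loci: Sequence[Locus], window_size: int = WINDOW_BP) -> list[Window]:
    """One window per locus, centered on the lead variant, clipped at 0."""
    if window_size <= 0 or window_size % 2:
        raise ValueError(f"window_size must be positive and even, got {window_size}")
    half = window_size // 2
    return [Window(chrom=locus.chrom, start=max(0, locus.lead.pos - half),
                   end=locus.lead.pos + half, center=locus.lead.pos,
                   name=locus.name)
            for locus in loci]


@dataclass(frozen=True)
class OverlapSummary:
    """k = number of query windows hitting >= 1 subject window, plus the
    full list of intersecting (query index, subject index) pairs."""

    k: int
    pairs: tuple[tuple[int, int], ...]


def count_window_overlaps(a: Sequence[Window], b: Sequence[Window]) -> OverlapSummary:
    """Count query windows (in ``a``) that intersect any subject window (in
    ``b``).  k is the number of distinct query windows with a hit — the
    hypergeometric draw count — not the number of intersecting pairs."""
    pairs = [(i, j) for i, wa in enumerate(a) for j, wb in enumerate(b)
             if wa.intersects(wb)]
    k = len({i for i, _ in pairs})
    return OverlapSummary(k=k, pairs=tuple(pairs))


def genome_block_count(genome_length: int = GRCH38_LENGTH_BP,
                       block: int = WINDOW_BP) -> int:
    """Number of ``block``-sized bins in the genome, rounded to the nearest
    integer (half away from zero).  Default arguments give 6598."""
    if genome_length <= 0 or block <= 0:
        raise ValueError("genome_length and block must be positive")
    return int(genome_length / block + 0.5)


def loci_to_bed(items: Sequence[Locus | Window], path=None) -> list[str]:
    """Render loci or windows as BED4 lines (0-based, half-open).

    Closed 1-based locus coordinates [s, e] map to BED [s-1, e); windows are
    already half-open 0-based and pass through unchanged.
    """
    lines = ["# BED4: chrom start end name"]
    for it in items:
        if isinstance(it, Locus):
            lines.append(f"{it.chrom}\t{it.start - 1}\t{it.end}\t{it.name}")
        else:
            lines.append(f"{it.chrom}\t{it.start}\t{it.end}\t{it.name}")
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
    return lines
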