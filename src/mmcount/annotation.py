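"""Gene annotation parsing and positional lookup.

A gene is modelled as the union of the exons of all its transcripts on one
strand of one chromosome; its introns are the gaps of that union.  For fast
candidate lookup when alignments are not position-sorted, the genome is cut
into fixed-width bins and each bin stores the index of the first gene
starting in or after it, so a query scans only a short suffix of the
position-sorted gene vector.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


class AnnotationError(ValueError):
    """Raised for unparseable or inconsistent annotation input."""


def merge_intervals(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    """Union of half-open intervals as a sorted, disjoint tuple."""
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for start, end in ivs:
        if end <= start:
            continue
        if merged and start <= merged[-1][1]:
            if end > merged[-1][1]:
                merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return tuple(merged)


@dataclass(frozen=True)
class GeneModel:
    """A named gene: exon union on one strand, 0-based half-open coordinates.

    ``exons`` must be sorted, disjoint and non-empty; ``introns`` are the
    maximal gaps between consecutive exons.
    """

    gene_id: str
    chrom: str
    strand: str  # '+', '-' or '.' (unstranded)
    exons: tuple[Interval, ...]
    introns: tuple[Interval, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id!r} has no exons")
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if not (s0 < e0 <= s1 < e1):
                raise AnnotationError(
                    f"gene {self.gene_id!r}: exons not sorted/disjoint"
                )
        if self.exons[-1][0] >= self.exons[-1][1]:
            raise AnnotationError(f"gene {self.gene_id!r}: empty exon")
        introns = tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )
        object.__setattr__(self, "introns", introns)

    @property
    def span_start(self) -> int:
        return self.exons[0][0]

    @property
    def span_end(self) -> int:
        return self.exons[-1][1]

    @property
    def span_length(self) -> int:
        return self.span_end - self.span_start


def parse_annotation(
    path: str | Path,
    feature_type: str = "exon",
    id_attribute: str = "gene_id",
) -> list[GeneModel]:
    """Parse a GTF/GFF file into exon-union gene models.

    GTF is the reference dialect (1-based closed coordinates, repeated
    ``gene_id`` across transcripts); GFF3 files work by pointing
    ``id_attribute`` at the attribute that carries the gene identifier.
    Coordinates are converted to 0-based half-open at parse time.

    Raises
    ------
    AnnotationError
        On an unparseable line (with its line number), on a gene id that
        appears on two chromosomes or strands, or if no gene is found.
    """
    exons_by_gene: dict[str, list[Interval]] = {}
    location: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9 or not (
                fields[3].isdigit() and fields[4].isdigit()
            ):
                raise AnnotationError(
                    f"{path}: cannot parse line {lineno}: expected 9 "
                    "tab-separated fields with numeric coordinates"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises bare ValueError
                raise AnnotationError(
                    f"{path}: cannot parse line {lineno}: {exc}"
                ) from exc
            if feat.featuretype != feature_type:
                continue
            try:
                gene_id = feat.attributes[id_attribute][0]
            except (KeyError, IndexError):
                raise AnnotationError(
                    f"{path}: line {lineno}: missing attribute "
                    f"{id_attribute!r}"
                ) from None
            strand = feat.strand if feat.strand in "+-" else "."
            loc = (feat.seqid, strand)
            prev = location.setdefault(gene_id, loc)
            if prev != loc:
                raise AnnotationError(
                    f"gene {gene_id!r} occurs on {prev} and {loc}; "
                    "a gene must live on one chromosome and strand"
                )
            # GTF/GFF are 1-based closed; internal coordinates half-open.
            exons_by_gene.setdefault(gene_id, []).append(
                (feat.start - 1, feat.end)
            )
    if not exons_by_gene:
        raise AnnotationError(
            f"{path}: no {feature_type!r} features with {id_attribute!r} found"
        )
    genes = [
        GeneModel(gene_id, *location[gene_id], merge_intervals(ivs))
        for gene_id, ivs in exons_by_gene.items()
    ]
    genes.sort(key=lambda g: (g.chrom, g.span_start, g.span_end, g.gene_id))
    return genes


@dataclass
class _ChromIndex:
    genes: list[GeneModel]  # sorted by (span_start, span_end, gene_id)
    starts: list[int]
    first_in_bin: list[int]  # bin ordinal -> index of first gene at/after bin
    max_span: int


class BinIndex:
    """Fixed-width genome bin index over position-sorted gene models.

    Each bin stores the index of the first gene starting in or after it;
    a query starts scanning one maximum-gene-length upstream of the query
    start, which guarantees no overlapping gene is missed.
    """

    def __init__(self, genes: Sequence[GeneModel], bin_size: int = 10_000):
        if bin_size < 1:
            raise ValueError(f"bin_size must be >= 1, got {bin_size}")
        if not genes:
            raise ValueError("cannot index an empty gene set")
        self.bin_size = bin_size
        self._chroms: dict[str, _ChromIndex] = {}
        self._warned: set[str] = set()
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: (g.span_start, g.span_end, g.gene_id))
            starts = [g.span_start for g in gs]
            n_bins = starts[-1] // bin_size + 1
            first = [
                bisect.bisect_left(starts, b * bin_size)
                for b in range(n_bins)
            ]
            self._chroms[chrom] = _ChromIndex(
                gs, starts, first, max(g.span_length for g in gs)
            )

    def candidates(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose span overlaps [start, end), sorted by span then id."""
        if start >= end:
            raise ValueError(f"empty query interval [{start}, {end})")
        ci = self._chroms.get(chrom)
        if ci is None:
            if chrom not in self._warned:
                self._warned.add(chrom)
                logger.warning(
                    "chromosome %r absent from the annotation; "
                    "check annotation/alignment naming", chrom,
                )
            return []
        b = max(0, start - ci.max_span) // self.bin_size
        i = ci.first_in_bin[b] if b < len(ci.first_in_bin) else len(ci.genes)
        hits = []
        while i < len(ci.genes) and ci.starts[i] < end:
            if ci.genes[i].span_end > start:
                hits.append(ci.genes[i])
            i += 1
        hits.sort(key=lambda g: (g.span_start, g.gene_id))
        return hits


def build_bin_index(
    genes: Sequence[GeneModel], bin_size: int = 10_000
) -> BinIndex:
    """Build a :class:`BinIndex` over ``genes``."""
    return BinIndex(genes, bin_size)


def candidate_genes(
    index: BinIndex, chrom: str, start: int, end: int
) -> list[GeneModel]:
    """Genes of ``index`` whose span overlaps [start, end)."""
    return index.candidates(chrom, start, end)
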