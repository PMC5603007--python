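"""Self-contained synthetic GTF + SAM scenarios for testing and demos.

A :class:`ToyScenario` is a declarative layout of genes and read placements
that can be written out as a GTF annotation and a SAM alignment file, and
that carries its own ground truth: a brute-force oracle that recomputes
every attribution with per-base position sets and a direct evaluation of
the discard rules, independently of the interval code in the pipeline.

Two generators are provided: the six-read worked example over three genes
(two of them overlapping), and a seeded random generator with controlled
gene duplication for property testing.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pysam

from .alignment import LibraryConfig
from .overlap import QuantConfig

Interval = tuple[int, int]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]  # 0-based half-open, sorted, disjoint


@dataclass(frozen=True)
class HitSpec:
    """One alignment of one mate: leftmost 0-based position and CIGAR."""

    chrom: str
    pos: int
    cigar: str
    strand: str = "+"


@dataclass(frozen=True)
class ReadSpec:
    name: str
    hits1: tuple[HitSpec, ...]
    hits2: tuple[HitSpec, ...] = ()  # parallel to hits1 for paired reads


def _parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if not ops or sum(n for _, n in ops) == 0:
        raise ValueError(f"bad CIGAR {cigar!r}")
    return ops


def cigar_position_sets(pos: int, cigar: str) -> tuple[set[int], set[int], int]:
    """Aligned-base positions, N-skip positions and aligned size of a hit.

    This is the per-base view the oracle works with; it never touches the
    interval arithmetic used by the pipeline.
    """
    aligned: set[int] = set()
    skipped: set[int] = set()
    ref = pos
    size = 0
    for op, length in _parse_cigar(cigar):
        if op in "M=X":
            aligned.update(range(ref, ref + length))
            ref += length
            size += length
        elif op == "D":
            ref += length
        elif op == "N":
            skipped.update(range(ref, ref + length))
            ref += length
        # I, S, H, P consume no reference
    return aligned, skipped, size


def _read_bases(cigar: str) -> int:
    return sum(
        length for op, length in _parse_cigar(cigar) if op in "MIS=X"
    )


@dataclass
class ToyScenario:
    """Genes + reads + per-read expected attribution (at default settings)."""

    genes: list[GeneSpec]
    reads: list[ReadSpec]
    chrom_lengths: dict[str, int]
    paired: bool = False
    seed: int | None = None
    expected: dict[str, tuple[str, ...] | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.expected:
            self.expected = self.oracle_attributions()

    # ----------------------------------------------------------- writers

    def write_gtf(self, path: str | Path) -> None:
        lines = []
        for g in self.genes:
            for start, end in g.exons:
                attrs = (
                    f'gene_id "{g.gene_id}"; '
                    f'transcript_id "{g.gene_id}.1";'
                )
                lines.append(
                    f"{g.chrom}\tfixtures\texon\t{start + 1}\t{end}\t.\t"
                    f"{g.strand}\t.\t{attrs}"
                )
        Path(path).write_text("\n".join(lines) + "\n")

    def write_sam(
        self, path: str | Path, bam: bool = False, sort: bool = False
    ) -> None:
        chroms = sorted(self.chrom_lengths)
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate" if sort else "unsorted"},
            "SQ": [
                {"SN": c, "LN": self.chrom_lengths[c]} for c in chroms
            ],
        }
        tid = {c: i for i, c in enumerate(chroms)}
        records = []
        for read in self.reads:
            nh = len(read.hits1)
            if read.hits2:
                for i, (h1, h2) in enumerate(zip(read.hits1, read.hits2)):
                    records.append(
                        self._segment(read.name, h1, tid, nh, i > 0,
                                      mate=1, other=h2)
                    )
                    records.append(
                        self._segment(read.name, h2, tid, nh, i > 0,
                                      mate=2, other=h1)
                    )
            else:
                for i, h in enumerate(read.hits1):
                    records.append(
                        self._segment(read.name, h, tid, nh, i > 0)
                    )
        if sort:
            records.sort(
                key=lambda r: (r.reference_id, r.reference_start)
            )
        mode = "wb" if bam else "w"
        hdr = pysam.AlignmentHeader.from_dict(header)
        with pysam.AlignmentFile(str(path), mode, header=hdr) as out:
            for rec in records:
                out.write(rec)

    def _segment(
        self,
        name: str,
        hit: HitSpec,
        tid: dict[str, int],
        nh: int,
        secondary: bool,
        mate: int = 0,
        other: HitSpec | None = None,
    ) -> pysam.AlignedSegment:
        hdr = pysam.AlignmentHeader.from_dict(
            {"SQ": [
                {"SN": c, "LN": self.chrom_lengths[c]}
                for c in sorted(self.chrom_lengths)
            ]}
        )
        seg = pysam.AlignedSegment(hdr)
        seg.query_name = name
        flag = 0
        if hit.strand == "-":
            flag |= 0x10
        if secondary:
            flag |= 0x100
        if other is not None:
            flag |= 0x1 | 0x2
            flag |= 0x40 if mate == 1 else 0x80
            if other.strand == "-":
                flag |= 0x20
        seg.flag = flag
        seg.reference_id = tid[hit.chrom]
        seg.reference_start = hit.pos
        seg.mapping_quality = 255
        seg.cigarstring = hit.cigar
        seg.query_sequence = "A" * _read_bases(hit.cigar)
        if other is not None:
            seg.next_reference_id = tid[other.chrom]
            seg.next_reference_start = other.pos
        seg.set_tag("NH", nh)
        return seg

    # ------------------------------------------------------------ oracle

    def oracle_attributions(
        self,
        config: QuantConfig | None = None,
        lib: LibraryConfig | None = None,
    ) -> dict[str, tuple[str, ...] | None]:
        """Ground-truth attribution per read, by exhaustive per-base search.

        Every gene is tested against every mapping location with Python
        position sets; the matching rule and the discard rules are applied
        literally as written.  No pipeline code is reused.
        """
        config = config or QuantConfig()
        lib = lib or LibraryConfig(paired=self.paired)
        exon_sets = {
            g.gene_id: set().union(
                *(set(range(s, e)) for s, e in g.exons)
            )
            for g in self.genes
        }
        intron_sets = {}
        for g in self.genes:
            introns = set()
            for (_, e0), (s1, _) in zip(g.exons, g.exons[1:]):
                introns.update(range(e0, s1))
            intron_sets[g.gene_id] = introns
        out: dict[str, tuple[str, ...] | None] = {}
        for read in self.reads:
            if read.hits2:
                fragments = list(zip(read.hits1, read.hits2))
            else:
                fragments = [(h,) for h in read.hits1]
            pooled_n: dict[str, int] = {}
            pooled_ni: dict[str, int] = {}
            union_genes: set[str] = set()
            spliced_any = False
            for frag in fragments:
                mates = [
                    cigar_position_sets(h.pos, h.cigar) for h in frag
                ]
                s = sum(m[2] for m in mates)
                spliced = any(m[1] for m in mates)
                strand1 = frag[0].strand
                per_gene: dict[str, tuple[int, int]] = {}
                for g in self.genes:
                    if g.chrom != frag[0].chrom:
                        continue
                    if lib.strandedness != "none" and g.strand in "+-":
                        same = strand1 == g.strand
                        want_same = lib.strandedness == "forward"
                        if same != want_same:
                            continue
                    n = sum(
                        len(m[0] & exon_sets[g.gene_id]) for m in mates
                    )
                    ni = sum(
                        len(m[1] & intron_sets[g.gene_id]) for m in mates
                    )
                    l = config.overlap
                    if l <= 0:
                        ok = n == s
                    elif l >= 1:
                        ok = n >= l
                    else:
                        ok = n >= l * s
                    if ok:
                        per_gene[g.gene_id] = (n, ni)
                if not per_gene:
                    continue
                if config.resolve_scope == "per-locus":
                    union_genes.update(
                        _oracle_resolve(per_gene, config, spliced)
                    )
                else:
                    spliced_any = spliced_any or spliced
                    for gid, (n, ni) in per_gene.items():
                        pn, pni = pooled_n.get(gid, 0), pooled_ni.get(gid, 0)
                        pooled_n[gid] = max(pn, n)
                        pooled_ni[gid] = max(pni, ni)
            if config.resolve_scope == "per-locus":
                out[read.name] = (
                    tuple(sorted(union_genes)) if union_genes else None
                )
            elif pooled_n:
                merged = {
                    g: (pooled_n[g], pooled_ni[g]) for g in pooled_n
                }
                out[read.name] = tuple(
                    sorted(_oracle_resolve(merged, config, spliced_any))
                )
            else:
                out[read.name] = None
        return out

    def oracle_counts(
        self,
        config: QuantConfig | None = None,
        lib: LibraryConfig | None = None,
    ) -> dict[str, int]:
        """Ground-truth count table (observed rows only)."""
        config = config or QuantConfig()
        counts: dict[str, int] = {}
        for genes in self.oracle_attributions(config, lib).values():
            if genes is None:
                continue
            name = config.separator.join(sorted(genes))
            counts[name] = counts.get(name, 0) + 1
        return counts


def _oracle_resolve(
    per_gene: dict[str, tuple[int, int]],
    config: QuantConfig,
    spliced: bool,
) -> list[str]:
    def survivors(vals: dict[str, int]) -> list[str]:
        vmax = max(vals.values())
        return [
            g for g, v in vals.items()
            if not (
                vmax > v + config.diff_threshold
                or vmax > v * config.ratio_threshold
            )
        ]

    keep = survivors({g: nv[0] for g, nv in per_gene.items()})
    if len(keep) > 1 and spliced:
        keep = survivors({g: per_gene[g][1] for g in keep})
    return keep


# ------------------------------------------------------- worked example


def make_worked_example_scenario() -> ToyScenario:
    """The six-read toy configuration over genes A, B, C (A and B overlap).

    Read 1 maps uniquely inside A; read 2 maps twice, in A and in C;
    read 3 is intergenic; read 4 maps in A and in an intergenic region;
    read 5 sits in the A/B overlap; read 6 maps in the A/B overlap and in
    C.  Expected attributions at defaults: A, A--C, none, A, A--B,
    A--B--C; multi-hit reads carry NH=2.
    """
    chrom = "chr1"
    genes = [
        GeneSpec("A", chrom, "+", ((1000, 2000),)),
        GeneSpec("B", chrom, "+", ((1800, 2800),)),
        GeneSpec("C", chrom, "+", ((5000, 6000),)),
    ]
    m = "100M"
    reads = [
        ReadSpec("read1", (HitSpec(chrom, 1100, m),)),
        ReadSpec("read2", (HitSpec(chrom, 1300, m),
                           HitSpec(chrom, 5100, m))),
        ReadSpec("read3", (HitSpec(chrom, 3500, m),)),
        ReadSpec("read4", (HitSpec(chrom, 1500, m),
                           HitSpec(chrom, 3700, m))),
        ReadSpec("read5", (HitSpec(chrom, 1850, m),)),
        ReadSpec("read6", (HitSpec(chrom, 1860, m),
                           HitSpec(chrom, 5300, m))),
    ]
    return ToyScenario(
        genes=genes,
        reads=reads,
        chrom_lengths={chrom: 10_000},
        expected={
            "read1": ("A",),
            "read2": ("A", "C"),
            "read3": None,
            "read4": ("A",),
            "read5": ("A", "B"),
            "read6": ("A", "B", "C"),
        },
    )


# ------------------------------------------------------ random scenarios

_SLOT_PITCH = 10_000
_SLOT_BASE = 2_000
_READ_LEN = 100


def _transcript_blocks(
    exons: Sequence[Interval], t_start: int, t_end: int
) -> list[Interval]:
    """Project a spliced-coordinate interval onto genomic blocks."""
    blocks: list[Interval] = []
    offset = 0
    for s, e in exons:
        length = e - s
        lo = max(t_start, offset)
        hi = min(t_end, offset + length)
        if lo < hi:
            blocks.append((s + lo - offset, s + hi - offset))
        offset += length
    return blocks


def _blocks_to_cigar(blocks: Sequence[Interval]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            parts.append(f"{s - blocks[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def make_random_scenario(
    seed: int,
    n_genes: int = 12,
    n_reads: int = 60,
    duplication_rate: float = 0.3,
    paired: bool = False,
    overlap_rate: float = 0.25,
    intergenic_rate: float = 0.1,
) -> ToyScenario:
    """Seeded random genes-and-reads layout with controlled duplication.

    Each gene family has 1-3 exons; a duplicated family gets a second copy
    of the same exon structure at a distant locus, and reads drawn from it
    are emitted at every copy with NH set accordingly.  A fraction of
    primary loci receive an overlapping single-exon companion gene, so
    that co-located ambiguity (and the N/P margins) is exercised alongside
    multi-locus ambiguity.  Deterministic for a given seed.
    """
    if n_genes < 1 or n_reads < 1:
        raise ValueError("n_genes and n_reads must be positive")
    rng = random.Random(seed)
    chrom = "chrS"
    genes: list[GeneSpec] = []
    families: list[dict] = []
    slot = 0
    for f in range(n_genes):
        n_ex = rng.randint(1, 3)
        exon_lens = [rng.randint(200, 500) for _ in range(n_ex)]
        intron_lens = [rng.randint(60, 200) for _ in range(n_ex - 1)]
        rel: list[Interval] = []
        off = 0
        for i, el in enumerate(exon_lens):
            rel.append((off, off + el))
            off += el
            if i < len(intron_lens):
                off += intron_lens[i]
        strand = rng.choice("+-")
        copies = 2 if rng.random() < duplication_rate else 1
        starts = []
        for c in range(copies):
            base = _SLOT_BASE + slot * _SLOT_PITCH + rng.randint(0, 400)
            slot += 1
            starts.append(base)
            gid = f"G{f:02d}" if c == 0 else f"G{f:02d}D"
            genes.append(GeneSpec(
                gid, chrom, strand,
                tuple((base + s, base + e) for s, e in rel),
            ))
        if rng.random() < overlap_rate:
            # companion gene overlapping the first copy's first exon
            shift = rng.randint(50, 150)
            length = rng.randint(200, 600)
            cs = starts[0] + shift
            genes.append(GeneSpec(
                f"G{f:02d}X", chrom, rng.choice("+-"),
                ((cs, cs + length),),
            ))
        families.append({
            "rel_exons": rel,
            "tlen": sum(exon_lens),
            "starts": starts,
            "strand": strand,
        })
    chrom_len = _SLOT_BASE + (slot + 1) * _SLOT_PITCH
    L = _READ_LEN
    reads: list[ReadSpec] = []
    for r in range(n_reads):
        name = f"r{r:04d}"
        if rng.random() < intergenic_rate:
            gap_slot = rng.randrange(slot)
            pos = _SLOT_BASE + gap_slot * _SLOT_PITCH + rng.randint(
                4000, 8000
            )
            strand = rng.choice("+-")
            if paired:
                reads.append(ReadSpec(
                    name,
                    (HitSpec(chrom, pos, f"{L}M", strand),),
                    (HitSpec(chrom, pos + L + 50, f"{L}M",
                             "-" if strand == "+" else "+"),),
                ))
            else:
                reads.append(ReadSpec(
                    name, (HitSpec(chrom, pos, f"{L}M", strand),)
                ))
            continue
        fam = families[rng.randrange(n_genes)]
        tlen = fam["tlen"]
        strand1 = (
            fam["strand"] if rng.random() < 0.8
            else ("-" if fam["strand"] == "+" else "+")
        )
        if paired:
            gap = rng.randint(0, 150)
            span = min(tlen, 2 * L + gap)
            t0 = rng.randint(0, tlen - span)
            up = (t0, t0 + L)
            down = (t0 + span - L, t0 + span)
            # FR layout: the forward-strand mate is upstream
            if strand1 == "+":
                r1, r2 = up, down
            else:
                r1, r2 = down, up
            strand2 = "-" if strand1 == "+" else "+"
            hits1, hits2 = [], []
            for start in fam["starts"]:
                exons = [(start + s, start + e)
                         for s, e in fam["rel_exons"]]
                b1 = _transcript_blocks(exons, *r1)
                b2 = _transcript_blocks(exons, *r2)
                # re-base to absolute coordinates already done via exons
                hits1.append(HitSpec(
                    chrom, b1[0][0], _blocks_to_cigar(b1), strand1
                ))
                hits2.append(HitSpec(
                    chrom, b2[0][0], _blocks_to_cigar(b2), strand2
                ))
            reads.append(ReadSpec(name, tuple(hits1), tuple(hits2)))
        else:
            t0 = rng.randint(0, tlen - L)
            hits = []
            for start in fam["starts"]:
                exons = [(start + s, start + e)
                         for s, e in fam["rel_exons"]]
                b = _transcript_blocks(exons, t0, t0 + L)
                hits.append(HitSpec(
                    chrom, b[0][0], _blocks_to_cigar(b), strand1
                ))
            reads.append(ReadSpec(name, tuple(hits)))
    return ToyScenario(
        genes=genes,
        reads=reads,
        chrom_lengths={chrom: chrom_len},
        paired=paired,
        seed=seed,
    )
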