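"""SAM/BAM streaming: hit groups, fragments and library geometry.

Aligners report every mapping location of a multi-mapping read as a separate
record and declare the total in the NH tag.  Counting a read once therefore
requires re-assembling its complete hit set before any attribution decision.
With position-sorted input this is done in a streaming fashion: a read is
buffered only until its declared number of hits has been seen.  Records
without NH tags fall back to name-keyed accumulation over the whole file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pysam

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

# CIGAR operation codes (pysam numeric encoding)
_REF_ALIGNED = {0, 7, 8}  # M, =, X
_DELETION = 2             # D
_REF_SKIP = 3             # N


@dataclass(frozen=True)
class ReadHit:
    """One alignment record: the reference intervals one read copy covers.

    ``blocks`` are the 0-based half-open reference intervals of aligned
    bases (CIGAR M/=/X); ``skips`` are the reference intervals of CIGAR N
    operations (introns of the read).  Deletions split blocks but are
    recorded in neither.  ``read_size`` is the number of aligned read bases.
    """

    read_name: str
    chrom: str
    strand: str  # '+' or '-'
    blocks: tuple[Interval, ...]
    skips: tuple[Interval, ...]
    read_size: int
    mate: int  # 1 or 2
    nh: int | None
    mapped: bool = True

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


@dataclass
class HitGroup:
    """All hits of one read (or read pair) across its mapping locations."""

    read_name: str
    hits1: list[ReadHit] = field(default_factory=list)
    hits2: list[ReadHit] = field(default_factory=list)
    complete: bool = False

    @property
    def multimapped(self) -> bool:
        return any((h.nh or 1) > 1 for h in self.hits1 + self.hits2)

    @property
    def n_mates(self) -> int:
        return (1 if self.hits1 else 0) + (1 if self.hits2 else 0)


@dataclass(frozen=True)
class LibraryConfig:
    """Sequencing-library geometry and record filters.

    ``orientation`` is only meaningful for paired data: 'fr' (forward-
    reverse, the common Illumina layout), 'rf', 'ff', or 'any'.
    ``strandedness`` ties read strand to gene strand at matching time:
    'forward' requires mate 1 on the gene strand, 'reverse' the opposite,
    'none' ignores strand.
    """

    paired: bool = False
    orientation: str = "fr"
    strandedness: str = "none"
    require_both_mates: bool = True
    discard_chimeric: bool = True
    min_mapq: int = 0
    skip_supplementary: bool = True
    skip_duplicates: bool = True

    def __post_init__(self) -> None:
        if self.orientation not in ("fr", "rf", "ff", "any"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.strandedness not in ("none", "forward", "reverse"):
            raise ValueError(f"bad strandedness {self.strandedness!r}")


@dataclass(frozen=True)
class FragmentHit:
    """One mapping location of a fragment: one hit per mate present."""

    chrom: str
    hits: tuple[ReadHit, ...]

    @property
    def blocks(self) -> tuple[Interval, ...]:
        return tuple(b for h in self.hits for b in h.blocks)

    @property
    def skips(self) -> tuple[Interval, ...]:
        return tuple(s for h in self.hits for s in h.skips)

    @property
    def size(self) -> int:
        """Total aligned bases over both mates (the s of the overlap rule)."""
        return sum(h.read_size for h in self.hits)

    @property
    def spliced(self) -> bool:
        return any(h.skips for h in self.hits)

    @property
    def strand1(self) -> str:
        """Alignment strand of mate 1 (or of the only mate present)."""
        for h in self.hits:
            if h.mate == 1:
                return h.strand
        return self.hits[0].strand

    @property
    def start(self) -> int:
        return min(h.start for h in self.hits)

    @property
    def end(self) -> int:
        return max(h.end for h in self.hits)


def _cigar_intervals(
    pos: int, cigartuples: list[tuple[int, int]]
) -> tuple[tuple[Interval, ...], tuple[Interval, ...], int]:
    """Aligned blocks, N-skip intervals and aligned-base count of a record."""
    blocks: list[Interval] = []
    skips: list[Interval] = []
    ref = pos
    block_start: int | None = None
    size = 0
    for op, length in cigartuples:
        if op in _REF_ALIGNED:
            if block_start is None:
                block_start = ref
            ref += length
            size += length
        elif op == _DELETION:
            if block_start is not None:
                blocks.append((block_start, ref))
                block_start = None
            ref += length
        elif op == _REF_SKIP:
            if block_start is not None:
                blocks.append((block_start, ref))
                block_start = None
            skips.append((ref, ref + length))
            ref += length
        # I, S, H, P consume no reference
    if block_start is not None:
        blocks.append((block_start, ref))
    return tuple(blocks), tuple(skips), size


def _hit_from_record(rec: pysam.AlignedSegment) -> ReadHit:
    blocks, skips, size = _cigar_intervals(
        rec.reference_start, rec.cigartuples or []
    )
    nh = rec.get_tag("NH") if rec.has_tag("NH") else None
    return ReadHit(
        read_name=rec.query_name,
        chrom=rec.reference_name,
        strand="-" if rec.is_reverse else "+",
        blocks=blocks,
        skips=skips,
        read_size=size,
        mate=2 if rec.is_read2 else 1,
        nh=nh,
    )


class _Pending:
    __slots__ = ("group", "nh", "expect", "no_nh")

    def __init__(self, name: str):
        self.group = HitGroup(name)
        self.nh: dict[int, int | None] = {1: None, 2: None}
        self.expect: set[int] = set()
        self.no_nh = False

    def add(self, rec: pysam.AlignedSegment) -> None:
        hit = _hit_from_record(rec)
        (self.group.hits1 if hit.mate == 1 else self.group.hits2).append(hit)
        self.expect.add(hit.mate)
        if rec.is_paired and not rec.mate_is_unmapped:
            self.expect.add(1 if hit.mate == 2 else 2)
        if hit.nh is None:
            self.no_nh = True
        elif self.nh[hit.mate] is None:
            self.nh[hit.mate] = hit.nh

    def seen(self, mate: int) -> int:
        return len(self.group.hits1 if mate == 1 else self.group.hits2)

    @property
    def complete(self) -> bool:
        if self.no_nh or not self.expect:
            return False
        return all(
            self.nh[m] is not None and self.seen(m) >= self.nh[m]
            for m in self.expect
        )


class HitGroupStream:
    """Iterate a SAM/BAM file as :class:`HitGroup` objects.

    A group is emitted as soon as its NH budget is exhausted (so position-
    sorted files stream with a small buffer) or at end of file otherwise.
    Unmapped records never contribute.  ``max_pending`` records the high-
    water mark of simultaneously buffered incomplete groups.
    """

    def __init__(self, path: str | Path, lib: LibraryConfig | None = None):
        self.path = str(path)
        self.lib = lib or LibraryConfig()
        self.max_pending = 0
        self._warned_no_nh = False

    def _keep(self, rec: pysam.AlignedSegment) -> bool:
        lib = self.lib
        if rec.is_unmapped:
            return False
        if lib.skip_supplementary and rec.is_supplementary:
            return False
        if lib.skip_duplicates and rec.is_duplicate:
            return False
        if rec.mapping_quality < lib.min_mapq:
            return False
        return True

    def __iter__(self) -> Iterator[HitGroup]:
        pending: dict[str, _Pending] = {}
        with pysam.AlignmentFile(
            self.path, check_sq=False, require_index=False
        ) as fh:
            for rec in fh:
                if not self._keep(rec):
                    continue
                p = pending.get(rec.query_name)
                if p is None:
                    p = pending[rec.query_name] = _Pending(rec.query_name)
                p.add(rec)
                if p.no_nh and not self._warned_no_nh:
                    self._warned_no_nh = True
                    logger.warning(
                        "%s: records without NH tag; buffering reads by "
                        "name until end of file", self.path,
                    )
                if p.complete:
                    p.group.complete = True
                    del pending[rec.query_name]
                    yield p.group
                self.max_pending = max(self.max_pending, len(pending))
        # leftovers: NH-less reads, filtered hits, or lying NH tags
        for name in sorted(pending):
            p = pending[name]
            p.group.complete = p.complete
            yield p.group


def stream_hit_groups(
    path: str | Path, lib: LibraryConfig | None = None
) -> Iterator[HitGroup]:
    """Yield one :class:`HitGroup` per distinct mapped read name."""
    return iter(HitGroupStream(path, lib))


def _orientation_ok(h1: ReadHit, h2: ReadHit, mode: str) -> bool:
    if mode == "any":
        return True
    if mode == "ff":
        return h1.strand == h2.strand
    if h1.strand == h2.strand:
        return False
    fwd, rev = (h1, h2) if h1.strand == "+" else (h2, h1)
    if mode == "fr":
        return fwd.start <= rev.start
    return rev.start <= fwd.start  # 'rf'


def pair_fragments(group: HitGroup, lib: LibraryConfig) -> list[FragmentHit]:
    """Join the mates of a hit group into fragments.

    SAM does not say which mate-1 hit goes with which mate-2 hit of a
    multi-mapper, so mates are paired deterministically: each mate-1 hit
    takes the unused same-chromosome, orientation-compatible mate-2 hit
    with the smallest fragment hull.  Single-end hits are their own
    fragments.
    """
    if not lib.paired:
        return [
            FragmentHit(h.chrom, (h,)) for h in group.hits1 + group.hits2
        ]
    fragments: list[FragmentHit] = []
    used2: set[int] = set()
    leftover1: list[ReadHit] = []
    for h1 in group.hits1:
        best: tuple[int, int] | None = None
        for j, h2 in enumerate(group.hits2):
            if j in used2 or h2.chrom != h1.chrom:
                continue
            if not _orientation_ok(h1, h2, lib.orientation):
                continue
            hull = max(h1.end, h2.end) - min(h1.start, h2.start)
            if best is None or (hull, j) < best:
                best = (hull, j)
        if best is None:
            leftover1.append(h1)
        else:
            j = best[1]
            used2.add(j)
            fragments.append(FragmentHit(h1.chrom, (h1, group.hits2[j])))
    if not lib.require_both_mates:
        leftovers = leftover1 + [
            h for j, h in enumerate(group.hits2) if j not in used2
        ]
        for h in leftovers:
            others = group.hits2 if h.mate == 1 else group.hits1
            chimeric = bool(others) and all(o.chrom != h.chrom for o in others)
            if lib.discard_chimeric and chimeric:
                continue
            fragments.append(FragmentHit(h.chrom, (h,)))
    return fragments
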