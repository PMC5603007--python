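"""Fragment-gene overlap computation and the matching rule.

The exonic overlap n of a fragment with a gene is the number of aligned
reference bases of the fragment (both mates summed) that fall inside the
gene's exon union; the intronic overlap n' is the number of reference bases
of the fragment's CIGAR-N skips shared with the gene's introns.  Whether an
overlap counts as a *match* is controlled by a single parameter l:

* l <= 0: the fragment must be totally included in the gene's exons;
* l >= 1: n >= l base pairs;
* 0 < l < 1: n >= l * s, where s is the fragment's aligned size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .alignment import FragmentHit
from .annotation import GeneModel, Interval


@dataclass(frozen=True)
class QuantConfig:
    """Quantification parameters.

    Parameters
    ----------
    overlap
        The l matching parameter (see module docstring).  Default 1.0:
        a single shared base pair suffices, the union-mode analog.
    diff_threshold
        N of the ambiguity resolution rule: a weaker gene is discarded when
        the best overlap exceeds it by more than N bases.  Default 30.
    ratio_threshold
        P of the resolution rule: discard when the best overlap exceeds the
        weaker one by more than a factor P.  Default 2.
    bin_size
        Genome bin width of the candidate-lookup index, in bp.
    separator
        String joining member ids in a merged-gene name.
    keep_zeros
        Emit a zero row for every annotation gene (stable row set for
        downstream differential-expression tools).
    resolve_scope
        'pooled' applies the N/P rules to per-gene best overlaps pooled
        over all mapping locations; 'per-locus' resolves each location
        independently and unions the survivors.
    """

    overlap: float = 1.0
    diff_threshold: float = 30.0
    ratio_threshold: float = 2.0
    bin_size: int = 10_000
    separator: str = "--"
    keep_zeros: bool = True
    resolve_scope: str = "pooled"

    def __post_init__(self) -> None:
        if self.diff_threshold < 0:
            raise ValueError("diff_threshold (N) must be >= 0")
        if self.ratio_threshold < 1:
            raise ValueError("ratio_threshold (P) must be >= 1")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.resolve_scope not in ("pooled", "per-locus"):
            raise ValueError(f"bad resolve_scope {self.resolve_scope!r}")
        if math.isnan(self.overlap):
            raise ValueError("overlap (l) must be a real number")


@dataclass(frozen=True)
class OverlapResult:
    """Overlap of one fragment with one gene."""

    gene_id: str
    n: int          # exonic overlap, bp
    n_intron: int   # intronic overlap n', bp
    included: bool  # every aligned base inside the gene's exons
    s: int          # fragment aligned size


def _intersection_size(
    a: Sequence[Interval], b: Sequence[Interval]
) -> int:
    """Total overlap in bp of two sorted disjoint interval lists."""
    total = i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def overlap(fragment: FragmentHit, gene: GeneModel) -> OverlapResult:
    """Exonic and intronic overlap of ``fragment`` with ``gene``.

    Positions covered by both mates of a pair are counted once per mate
    (the overlaps of the two mates are summed).
    """
    n = sum(
        _intersection_size(h.blocks, gene.exons) for h in fragment.hits
    )
    n_intron = sum(
        _intersection_size(h.skips, gene.introns) for h in fragment.hits
    )
    s = fragment.size
    return OverlapResult(gene.gene_id, n, n_intron, n == s, s)


def matches(result: OverlapResult, config: QuantConfig) -> bool:
    """Apply the three-regime l rule to an overlap."""
    l = config.overlap
    if l <= 0:
        return result.included
    if l >= 1:
        return result.n >= l
    return result.n >= l * result.s


def strand_compatible(
    fragment_strand1: str, gene: GeneModel, strandedness: str
) -> bool:
    """Does mate 1's alignment strand agree with the gene under the
    library's strandedness mode?  Unstranded genes match anything."""
    if strandedness == "none" or gene.strand == ".":
        return True
    if strandedness == "forward":
        return fragment_strand1 == gene.strand
    return fragment_strand1 != gene.strand  # 'reverse'
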