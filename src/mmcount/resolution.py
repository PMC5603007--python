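"""Ambiguity resolution: from matching genes to a final attribution.

A fragment that matches several genes is not discarded and not split:
either the ambiguity is resolved by the overlap margins, or the matching
genes are fused into a *merged gene* that receives the count.  Two rules
discard a weaker gene g against the best overlap n_max:

* difference rule: n_max > n_g + N (default N = 30 bp);
* ratio rule:      n_max > n_g * P (default P = 2).

Either margin suffices (the rules combine as OR).  If more than one gene
survives and the fragment is spliced, the same two rules are re-applied to
the intronic overlaps n' among the survivors, so a read whose intron
coincides with one gene's intron wins over an intronless competitor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .alignment import HitGroup, LibraryConfig, pair_fragments
from .annotation import BinIndex
from .overlap import (
    OverlapResult,
    QuantConfig,
    matches,
    overlap,
    strand_compatible,
)


@dataclass(frozen=True)
class Attribution:
    """The gene set a fragment is finally counted under."""

    genes: tuple[str, ...]  # lexicographically sorted, duplicate-free

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("an attribution needs at least one gene")
        if list(self.genes) != sorted(set(self.genes)):
            raise ValueError(f"genes not sorted/unique: {self.genes}")

    @property
    def is_merged(self) -> bool:
        return len(self.genes) > 1


def _survivors(
    values: dict[str, float], diff: float, ratio: float
) -> list[str]:
    vmax = max(values.values())
    return [
        g for g, v in values.items()
        if not (vmax > v + diff or vmax > v * ratio)
    ]


def resolve(
    overlaps: Sequence[OverlapResult],
    config: QuantConfig,
    spliced: bool = False,
) -> Attribution | None:
    """Reduce matching overlaps (one per gene, pooled over locations) to an
    attribution, or ``None`` when nothing matched.

    Stage 1 discards genes by the N/P rules on exonic overlap; stage 2,
    reached only when several genes survive and the fragment is spliced,
    repeats the rules on intronic overlap (a gene with no intron under the
    read's skip scores n' = 0 there).
    """
    if not overlaps:
        return None
    n_by_gene = {r.gene_id: float(r.n) for r in overlaps}
    if len(n_by_gene) != len(overlaps):
        raise ValueError("resolve expects one OverlapResult per gene")
    keep = _survivors(
        n_by_gene, config.diff_threshold, config.ratio_threshold
    )
    if len(keep) > 1 and spliced:
        np_by_gene = {
            r.gene_id: float(r.n_intron)
            for r in overlaps if r.gene_id in keep
        }
        keep = _survivors(
            np_by_gene, config.diff_threshold, config.ratio_threshold
        )
    return Attribution(tuple(sorted(keep)))


def attribution_for_group(
    group: HitGroup,
    index: BinIndex,
    config: QuantConfig,
    lib: LibraryConfig,
) -> Attribution | None:
    """Full attribution of one read/fragment across all mapping locations.

    Pairs mates into fragments, looks up candidate genes per location,
    keeps the matching ones (strandedness enforced before overlap), pools
    per-gene best overlaps over locations, and resolves.  Locations that
    match nothing contribute nothing; a fragment matching nothing anywhere
    is left unattributed.
    """
    fragments = pair_fragments(group, lib)
    pooled_n: dict[str, int] = {}
    pooled_ni: dict[str, int] = {}
    per_locus_genes: set[str] = set()
    any_spliced = False
    for frag in fragments:
        matched: list[OverlapResult] = []
        for gene in index.candidates(frag.chrom, frag.start, frag.end):
            if not strand_compatible(frag.strand1, gene, lib.strandedness):
                continue
            result = overlap(frag, gene)
            if matches(result, config):
                matched.append(result)
        if not matched:
            continue
        if config.resolve_scope == "per-locus":
            attr = resolve(matched, config, spliced=frag.spliced)
            if attr is not None:
                per_locus_genes.update(attr.genes)
        else:
            any_spliced = any_spliced or frag.spliced
            for r in matched:
                pooled_n[r.gene_id] = max(pooled_n.get(r.gene_id, 0), r.n)
                pooled_ni[r.gene_id] = max(
                    pooled_ni.get(r.gene_id, 0), r.n_intron
                )
    if config.resolve_scope == "per-locus":
        if not per_locus_genes:
            return None
        return Attribution(tuple(sorted(per_locus_genes)))
    pooled = [
        OverlapResult(g, n, pooled_ni[g], included=False, s=0)
        for g, n in pooled_n.items()
    ]
    return resolve(pooled, config, spliced=any_spliced)
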