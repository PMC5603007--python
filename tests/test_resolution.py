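"""Ambiguity resolution: the N/P discard rules and the intron stage."""

import math

import pytest
from hypothesis import given, strategies as st

from mmcount.alignment import HitGroup, LibraryConfig, ReadHit
from mmcount.annotation import GeneModel, build_bin_index
from mmcount.overlap import OverlapResult, QuantConfig
from mmcount.resolution import Attribution, attribution_for_group, resolve

INF = math.inf


def ov(gene_id, n, n_intron=0, s=100):
    return OverlapResult(gene_id, n, n_intron, included=(n == s), s=s)


def cfg(N=30.0, P=2.0):
    return QuantConfig(diff_threshold=N, ratio_threshold=P)


class TestResolve:
    def test_tied_inclusion_merges(self):
        attr = resolve([ov("A", 100), ov("B", 100)], cfg())
        assert attr.genes == ("A", "B") and attr.is_merged

    def test_both_rules_fire(self):
        assert resolve([ov("A", 80), ov("B", 40)], cfg()).genes == ("A",)

    def test_three_genes_partial_discard(self):
        # C loses on both margins, B survives both -> merged A--B
        attr = resolve([ov("A", 70), ov("B", 50), ov("C", 20)], cfg())
        assert attr.genes == ("A", "B")

    def test_empty_input_is_unattributed(self):
        assert resolve([], cfg()) is None

    def test_duplicate_gene_entries_rejected(self):
        with pytest.raises(ValueError):
            resolve([ov("A", 50), ov("A", 60)], cfg())

    def test_intron_agreement_breaks_exonic_tie(self):
        # read skip coincides with A's intron (60 bp); B intronless there
        overlaps = [ov("A", 100, n_intron=60), ov("B", 100, n_intron=0)]
        assert resolve(overlaps, cfg(), spliced=True).genes == ("A",)

    def test_unspliced_fragment_never_reaches_intron_stage(self):
        overlaps = [ov("A", 100, n_intron=60), ov("B", 100, n_intron=0)]
        attr = resolve(overlaps, cfg(), spliced=False)
        assert attr.genes == ("A", "B")

    def test_all_zero_intron_overlaps_keep_everyone(self):
        overlaps = [ov("A", 100), ov("B", 100)]
        attr = resolve(overlaps, cfg(), spliced=True)
        assert attr.genes == ("A", "B")

    @given(st.permutations([("A", 70), ("B", 50), ("C", 20), ("D", 65)]))
    def test_permutation_invariance(self, items):
        # n_max = 70: C fails both margins; B and D stay within both
        attr = resolve([ov(g, n) for g, n in items], cfg())
        assert attr.genes == ("A", "B", "D")

    @given(
        ns=st.dictionaries(
            st.sampled_from("ABCDEF"), st.integers(1, 300),
            min_size=1, max_size=6,
        ),
        thresholds=st.tuples(
            st.sampled_from([0.0, 10.0, 30.0, 100.0, INF]),
            st.sampled_from([1.0, 1.5, 2.0, 4.0, INF]),
        ),
    )
    def test_survivors_contain_argmax_and_grow_with_thresholds(
        self, ns, thresholds
    ):
        N, P = thresholds
        overlaps = [ov(g, n) for g, n in ns.items()]
        best = max(ns, key=lambda g: (ns[g], g))
        attr = resolve(overlaps, cfg(N, P))
        assert best in attr.genes
        wider = resolve(overlaps, cfg(N + 10, P + 1))
        assert set(attr.genes) <= set(wider.genes)

    @given(
        ns=st.lists(st.integers(1, 300), min_size=2, max_size=6,
                    unique=True)
    )
    def test_zero_thresholds_emulate_largest_overlap(self, ns):
        """N=0, P=1 with distinct overlaps keeps only the argmax gene."""
        overlaps = [ov(f"G{i}", n) for i, n in enumerate(ns)]
        attr = resolve(overlaps, cfg(N=0, P=1))
        assert len(attr.genes) == 1
        assert attr.genes[0] == f"G{ns.index(max(ns))}"

    def test_infinite_thresholds_never_discard(self):
        overlaps = [ov("A", 300), ov("B", 1)]
        assert resolve(overlaps, cfg(N=INF, P=INF)).genes == ("A", "B")


class TestAttribution:
    def test_invariants(self):
        with pytest.raises(ValueError):
            Attribution(())
        with pytest.raises(ValueError):
            Attribution(("B", "A"))
        with pytest.raises(ValueError):
            Attribution(("A", "A"))
        assert not Attribution(("A",)).is_merged
        assert Attribution(("A", "B")).is_merged


class TestAttributionForGroup:
    def hit(self, blocks, mate=1, nh=1, strand="+"):
        return ReadHit("r", "c1", strand, tuple(blocks), (),
                       sum(e - s for s, e in blocks), mate, nh)

    def test_two_hits_in_same_gene_count_once(self):
        gene = GeneModel("A", "c1", "+", ((0, 10_000),))
        index = build_bin_index([gene])
        group = HitGroup("r", [
            self.hit([(100, 200)], nh=2),
            self.hit([(5_000, 5_100)], nh=2),
        ], [], complete=True)
        attr = attribution_for_group(
            group, index, QuantConfig(), LibraryConfig()
        )
        assert attr.genes == ("A",)  # never A--A

    def test_no_candidates_means_unattributed(self):
        gene = GeneModel("A", "c1", "+", ((0, 1_000),))
        index = build_bin_index([gene])
        group = HitGroup("r", [self.hit([(5_000, 5_100)])], [],
                         complete=True)
        assert attribution_for_group(
            group, index, QuantConfig(), LibraryConfig()
        ) is None

    def test_per_locus_scope_unions_local_survivors(self):
        # locus 1: A dominates X locally; locus 2: B alone.
        genes = [
            GeneModel("A", "c1", "+", ((0, 1_000),)),
            GeneModel("X", "c1", "+", ((900, 2_000),)),
            GeneModel("B", "c1", "+", ((50_000, 51_000),)),
        ]
        index = build_bin_index(genes)
        group = HitGroup("r", [
            self.hit([(800, 950)], nh=2),    # A:150, X:50 -> A wins locally
            self.hit([(50_100, 50_250)], nh=2),
        ], [], complete=True)
        pooled = attribution_for_group(
            group, index, QuantConfig(resolve_scope="pooled"),
            LibraryConfig(),
        )
        per_locus = attribution_for_group(
            group, index, QuantConfig(resolve_scope="per-locus"),
            LibraryConfig(),
        )
        assert pooled.genes == ("A", "B")
        assert per_locus.genes == ("A", "B")
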