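# Methods

## Model and assumptions

mmcount counts RNA-seq fragments per gene, where a *gene* is the union of
the exons of all its transcripts on one strand of one chromosome, and the
gene's *introns* are the maximal gaps of that union. Transcript-level
structure, UTR/CDS distinctions and annotation editing are out of scope.
All internal coordinates are 0-based half-open; GTF/GFF input (1-based
closed) is converted at parse time, which makes annotation and SAM record
coordinates directly comparable.

The central assumption is that an aligner has already enumerated every
plausible mapping location of each read and declared the count in the SAM
`NH` tag. mmcount consumes *all* of those locations: a read is one counting
unit regardless of how many places it maps, and ambiguity that the overlap
margins cannot resolve is preserved explicitly as a merged gene rather than
resolved by dropping, weighting or inference.

## Matching

For a fragment with aligned size *s* (aligned bases of both mates summed)
and a gene with exon union E, the exonic overlap *n* is the number of
aligned reference positions (CIGAR `M/=/X`) inside E, each mate counted
separately, so a position covered by both mates contributes twice — the
pair's overlaps are sums. Insertions and clips contribute nothing;
deletions (`D`) split aligned blocks and count toward neither *n* nor the
intronic overlap. The ℓ parameter selects the matching regime (inclusion /
absolute bp / fraction of *s*); the inequality n ≥ ℓ (and n ≥ ℓ·s) is
non-strict. "Totally included" means every aligned base lies in E; a
spliced read's skips are *not* required to coincide with gene introns for
inclusion — intron agreement only arbitrates ambiguity.

Strandedness is enforced before any overlap is computed: in `forward` mode
mate 1 must align on the gene's strand, in `reverse` mode on the opposite
one; unstranded genes (`.`) match regardless.

## Resolution

Let n_max be the best exonic overlap among matching genes. A gene *g* is
discarded iff

    n_max > n_g + N   or   n_max > n_g * P

with strict inequalities (defaults N = 30 bp, P = 2). The published rule
set is stated pairwise; comparison against the best is the minimal
consistent extension to k genes and is what this package implements. If
more than one gene survives and the fragment is spliced, the same predicate
is re-applied to the intronic overlaps n′ among the survivors; a gene with
no intron under the read's skip has n′ = 0 there, so an exactly matching
intron longer than N wins outright. Unspliced fragments never reach the
intron stage. The survivor set always contains the argmax-n gene, and
raising N or P can only grow it.

By default the rules operate on per-gene *best* overlaps pooled over all
mapping locations of the fragment (`resolve_scope="pooled"`), so they
arbitrate between loci as well as between co-located genes; whether the
original formulation restricts the rules to one locus is not specified, so
`resolve_scope="per-locus"` resolves each location independently and unions
the survivors. On typical layouts (duplicated copies far apart, reads
equally good at every copy) the two coincide.

## Mate pairing

SAM does not link a specific mate-1 hit to a specific mate-2 hit of a
multi-mapper. Mates are paired deterministically: each mate-1 hit takes
the unused mate-2 hit on the same chromosome that satisfies the configured
orientation (`fr` by default) and minimizes the fragment hull, ties broken
by record order. Unpairable mates are dropped by default
(`require_both_mates`), and single mates whose partner mapped to another
chromosome are additionally dropped by `discard_chimeric` — together these
defaults mirror a featureCounts `-p -B -C`-style setup. Secondary
alignments (flag 0x100) are ordinary hits, because they carry the extra
mapping locations the method exists to use; supplementary (0x800) and
duplicate-flagged records are skipped.

## Streaming and lookup

Records are grouped by read name; a group is emitted as soon as every
expected mate has delivered its NH-declared number of hits, so
position-sorted input streams with a buffer bounded by the reads whose hit
sets span the current window. Files without NH tags fall back to name-keyed
buffering until end of file (one warning). Output never depends on record
order.

Candidate genes per location come from a binned index: genes are sorted by
(chromosome, span start), the genome is cut into fixed bins (default
10 kb — around the scale of a mammalian gene, so a typical query scans a
handful of genes) and each bin stores the index of the first gene starting
in or after it. A query starts one maximum-gene-length (recorded per
chromosome at build time) upstream of the query start, which guarantees no
overlapping gene is missed; the candidate list is then span-filtered
exactly.

## Defaults

| parameter | default | meaning |
|---|---|---|
| ℓ (`-l`) | 1 | match on ≥ 1 bp exonic overlap (union analog) |
| N (`-N`) | 30 bp | difference discard margin |
| P (`-P`) | 2 | ratio discard margin |
| strand | none | library strandedness |
| orientation | fr | paired mate layout |
| bin size | 10 000 bp | lookup index granularity |
| separator | `--` | merged-gene name joiner |

ℓ, N, P and the bin size carry the method's published defaults; the
separator, strandedness default and orientation default are this package's
own choices (`--` keeps merged names safe for downstream tools that treat
`-` as arithmetic).

## Synthetic data

The fixture generator emulates exactly what the counter consumes: gene
families with 1–3 exons (exons 200–500 bp, introns 60–200 bp — long enough
that an exactly matching intron clears the default N), optional duplicated
copies with identical exon structure at distant loci (reads from a
duplicated family are emitted at every copy with the correct NH), optional
overlapping single-exon companion genes, ~10% intergenic reads, 100 bp
reads, and FR mate pairs for paired mode. Loci sit in 10 kb slots so that
mate pairing and candidate lookup are unambiguous by construction. It does
**not** simulate sequencing errors, base qualities, soft-clipping,
indels, coverage biases or realistic expression levels; passing tests
therefore demonstrate the correctness of the counting and resolution logic
on well-formed alignments, not robustness to aligner artifacts.

Every scenario carries its own ground truth: a brute-force oracle that
re-derives each attribution with per-base Python position sets, an
exhaustive scan over all genes and a literal evaluation of the discard
predicate — sharing no code with the pipeline's interval arithmetic,
binned lookup or streaming grouping. The test suite checks
pipeline/oracle agreement over 200+ seeded (scenario × parameter)
combinations spanning ℓ regimes, N/P extremes (0/1 and ∞), strandedness
modes, both resolve scopes, and single/paired ends; scenario sizes
(10–20 genes, 50–200 reads) keep the whole suite in the seconds range
while every code path above is exercised.

## Numerical and degenerate-input choices

All quantities are integer base counts; there is no floating-point
tolerance anywhere in the method (ℓ, N, P may be real-valued, and ∞
disables a rule cleanly). Degenerate inputs are hard errors: empty
annotation, a gene on two chromosomes/strands, an unparseable annotation
line (reported with its line number), empty exons, bin size < 1, N < 0,
P < 1. An unknown chromosome in a query warns once and returns no
candidates; zero attributed fragments warns but still writes the table.
Zero-count annotation genes are emitted by default so the row set is stable
across samples for differential-expression tools; merged-gene rows are
data-dependent by construction and appear only when observed.

## Known limitations

* CRAM input, UMIs and mapping-quality handling beyond a simple
  `--min-mapq` gate are unsupported.
* The htseq-count *intersection-nonempty* mode has no ℓ equivalent and is
  not emulated.
* Fractional/EM reassignment of multi-mappers is deliberately absent.
* Counting is per gene; the feature-level extension (miRNA/tRNA classes)
  is not implemented.
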