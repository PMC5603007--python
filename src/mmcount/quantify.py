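"""Pipeline driver: per-sample counting over genes and merged genes.

The counting unit is the fragment (a read pair counts once).  Each fragment
contributes exactly 1 to exactly one row of the count table — a plain gene
or a merged gene named by its lexicographically sorted members — or to
nothing when it matches no gene.  Merged-gene rows are created on demand;
annotation genes keep a stable (zero-filled) row set by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .alignment import HitGroupStream, LibraryConfig
from .annotation import GeneModel, build_bin_index
from .overlap import QuantConfig
from .resolution import attribution_for_group

logger = logging.getLogger(__name__)


def canonical_name(genes: Sequence[str], separator: str = "--") -> str:
    """Canonical row name of a gene set: sorted ids joined by ``separator``.

    A merged gene over {B, A} is always displayed as ``A--B``, never
    ``B--A``.
    """
    if not genes:
        raise ValueError("empty gene list")
    if len(set(genes)) != len(genes):
        raise ValueError(f"duplicate gene ids in {list(genes)}")
    return separator.join(sorted(genes))


@dataclass
class AssignmentStats:
    """Per-sample bookkeeping of where the fragments went."""

    sample: str
    total_reads: int = 0        # mates seen (2 per fragment when paired)
    total_fragments: int = 0
    attributed: int = 0
    unattributed: int = 0
    multimapped: int = 0        # fragments with NH > 1
    merged: int = 0             # fragments attributed to a merged gene

    def as_dict(self) -> dict[str, int | str]:
        return {
            "sample": self.sample,
            "total_reads": self.total_reads,
            "total_fragments": self.total_fragments,
            "attributed": self.attributed,
            "unattributed": self.unattributed,
            "multimapped": self.multimapped,
            "merged": self.merged,
        }


class CountTable:
    """Gene/merged-gene fragment counts, one column per sample.

    Rows are ordered lexicographically by canonical name.  ``to_frame``
    exposes the table as a pandas DataFrame indexed by gene name.
    """

    def __init__(self, counts: dict[str, list[int]], samples: list[str]):
        self._counts = dict(sorted(counts.items()))
        self.samples = list(samples)

    def __getitem__(self, name: str) -> list[int]:
        return self._counts[name]

    def __contains__(self, name: str) -> bool:
        return name in self._counts

    def __len__(self) -> int:
        return len(self._counts)

    @property
    def names(self) -> list[str]:
        return list(self._counts)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(
            self._counts, orient="index", columns=self.samples, dtype=int
        )
        df.index.name = "Gene"
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def column_sum(self, sample: str) -> int:
        j = self.samples.index(sample)
        return sum(v[j] for v in self._counts.values())


def write_stats_tsv(
    stats: Sequence[AssignmentStats], path: str | Path
) -> None:
    pd.DataFrame([s.as_dict() for s in stats]).to_csv(
        path, sep="\t", index=False
    )


def quantify(
    annotation: Sequence[GeneModel],
    samples: Sequence[str | Path],
    config: QuantConfig | None = None,
    lib: LibraryConfig | None = None,
) -> tuple[CountTable, list[AssignmentStats]]:
    """Count fragments per gene/merged gene for one or more samples.

    Samples are processed sequentially and independently; output is
    deterministic for fixed inputs regardless of record order within each
    file.
    """
    config = config or QuantConfig()
    lib = lib or LibraryConfig()
    if not annotation:
        raise ValueError("empty annotation")
    if not samples:
        raise ValueError("at least one sample is required")
    index = build_bin_index(annotation, config.bin_size)
    sample_names = [Path(p).name for p in samples]
    if len(set(sample_names)) != len(sample_names):
        sample_names = [str(p) for p in samples]
    per_sample: list[dict[str, int]] = []
    stats: list[AssignmentStats] = []
    for path, name in zip(samples, sample_names):
        counter: dict[str, int] = {}
        st = AssignmentStats(sample=name)
        try:
            for group in HitGroupStream(path, lib):
                st.total_fragments += 1
                st.total_reads += group.n_mates
                if group.multimapped:
                    st.multimapped += 1
                attr = attribution_for_group(group, index, config, lib)
                if attr is None:
                    st.unattributed += 1
                    continue
                st.attributed += 1
                if attr.is_merged:
                    st.merged += 1
                row = canonical_name(attr.genes, config.separator)
                counter[row] = counter.get(row, 0) + 1
        except (OSError, ValueError) as exc:
            raise RuntimeError(f"sample {path}: {exc}") from exc
        per_sample.append(counter)
        stats.append(st)
    names: set[str] = set()
    if config.keep_zeros:
        names.update(g.gene_id for g in annotation)
    for counter in per_sample:
        names.update(counter)
    counts = {
        name: [counter.get(name, 0) for counter in per_sample]
        for name in names
    }
    if all(st.attributed == 0 for st in stats):
        logger.warning("no fragment was attributed to any gene")
    return CountTable(counts, sample_names), stats
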