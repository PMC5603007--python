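import random
from pathlib import Path

import pytest
from hypothesis import settings

from mmcount import (
    LibraryConfig,
    QuantConfig,
    HitGroupStream,
    attribution_for_group,
    build_bin_index,
    parse_annotation,
    quantify,
)
from mmcount.fixtures import ToyScenario, make_worked_example_scenario

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def worked_scenario() -> ToyScenario:
    return make_worked_example_scenario()


@pytest.fixture
def worked_files(worked_scenario, tmp_path):
    gtf = tmp_path / "example.gtf"
    sam = tmp_path / "example.sam"
    worked_scenario.write_gtf(gtf)
    worked_scenario.write_sam(sam)
    return gtf, sam


def write_scenario(scenario: ToyScenario, dirpath: Path, sort=False):
    gtf = dirpath / "genes.gtf"
    sam = dirpath / "reads.sam"
    scenario.write_gtf(gtf)
    scenario.write_sam(sam, sort=sort)
    return gtf, sam


def pipeline_attributions(
    scenario: ToyScenario,
    dirpath: Path,
    config: QuantConfig | None = None,
    lib: LibraryConfig | None = None,
):
    """Per-read attribution via the full file-based pipeline."""
    config = config or QuantConfig()
    lib = lib or LibraryConfig(paired=scenario.paired)
    gtf, sam = write_scenario(scenario, dirpath)
    index = build_bin_index(parse_annotation(gtf), config.bin_size)
    out = {}
    for group in HitGroupStream(sam, lib):
        attr = attribution_for_group(group, index, config, lib)
        out[group.read_name] = attr.genes if attr else None
    return out


def pipeline_counts(
    scenario: ToyScenario,
    dirpath: Path,
    config: QuantConfig | None = None,
    lib: LibraryConfig | None = None,
):
    """Observed (non-zero) count rows via quantify on written files."""
    config = config or QuantConfig(keep_zeros=False)
    lib = lib or LibraryConfig(paired=scenario.paired)
    gtf, sam = write_scenario(scenario, dirpath)
    table, stats = quantify(parse_annotation(gtf), [sam], config, lib)
    counts = {n: table[n][0] for n in table.names if table[n][0]}
    return counts, stats[0]


def shuffle_sam(path: Path, out: Path, seed: int = 17) -> None:
    lines = path.read_text().splitlines(keepends=True)
    header = [l for l in lines if l.startswith("@")]
    body = [l for l in lines if not l.startswith("@")]
    random.Random(seed).shuffle(body)
    out.write_text("".join(header + body))
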