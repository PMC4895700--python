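"""Shared fixtures: one small synthetic world reused across the suite."""

import pytest

from mirnome.mapping import ReferenceSet
from mirnome.qc import process_reads
from mirnome.simulate import simulate_world

WORLD_SEED = 1234
WORLD_KW = dict(
    genome_length=60_000,
    n_known=10,
    n_novel=10,
    n_reads=20_000,
)


@pytest.fixture(scope="session")
def world():
    """Default synthetic study: 10 known + 10 novel hairpins, three
    conditions at 20k reads each, nine Ago-RIP datasets."""
    return simulate_world(seed=WORLD_SEED, **WORLD_KW)


@pytest.fixture(scope="session")
def refset(world):
    return ReferenceSet(
        {world.genome.chrom_name: world.genome.sequence},
        world.mrna_seqs,
        world.known_annotations(),
    )


@pytest.fixture(scope="session")
def annotated_by_condition(world, refset):
    """QC + placement + annotation of each condition's library."""
    out = {}
    for cond in world.conditions:
        tags, report = process_reads(world.libraries[cond])
        out[cond] = (refset.annotate_library(tags), report)
    return out


@pytest.fixture(scope="session")
def decoy_world():
    """Negative control: same shape, novel loci without star arms."""
    return simulate_world(seed=WORLD_SEED + 1, decoy_novel=True, **WORLD_KW)
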