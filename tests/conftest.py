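import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from dupincompat.genome import Chromosome, DuplicatedGeneSpec, GeneCopy, GenomeMap

FOUNDERS = ("An-1", "Col-0", "Cvi-0", "Kyo")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_genome():
    chroms = [
        Chromosome("chr1", 2_000_000, 1.0),
        Chromosome("chr2", 2_000_000, 1.0),
    ]
    markers = {
        c.id: np.linspace(0, c.length_bp - 1, 50, dtype=np.int64) for c in chroms
    }
    return GenomeMap(chroms, markers)


@pytest.fixture
def founders():
    return FOUNDERS


def make_hpa_like_gene(founders=FOUNDERS, penetrance=1.0):
    """Reciprocal pseudofunctionalization: all founders but the last carry a
    functional copy1 and a LoF copy2; the last lacks copy1 and carries a
    functional copy2 (the histidine-pathway archetype)."""
    copies = [
        GeneCopy("copy1", "chr1", 999_000, 1_001_000, tss_bp=999_100),
        GeneCopy("copy2", "chr2", 999_000, 1_001_000, tss_bp=999_100),
    ]
    states = {f: {"copy1": "functional", "copy2": "lof"} for f in founders[:-1]}
    states[founders[-1]] = {"copy1": "absent", "copy2": "functional"}
    return DuplicatedGeneSpec(
        "hpa_like", copies, states, essential=True, penetrance=penetrance
    )


@pytest.fixture
def hpa_gene():
    return make_hpa_like_gene()
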