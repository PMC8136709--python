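import numpy as np
import pytest

from replichron import GeneAnnot, GenomeModel, Origin, SignalTrack


@pytest.fixture
def toy_genome():
    return GenomeModel((("chr1", 10_000), ("chr2", 6_000)))


@pytest.fixture
def toy_track(toy_genome):
    """Deterministic pseudo-random positive track on the toy genome."""
    rng = np.random.default_rng(7)
    data = {
        c: rng.uniform(0.5, 5.0, toy_genome.n_bins(c, 200))
        for c in toy_genome.names
    }
    return SignalTrack(toy_genome, 200, data, time=0.0, kind="enrichment")


@pytest.fixture
def toy_origins():
    return [
        Origin("oriA", "chr1", 2_000, 10.0),
        Origin("oriB", "chr1", 8_000, 30.0),
        Origin("oriC", "chr2", 3_000, 20.0),
    ]


@pytest.fixture
def toy_genes():
    return [
        GeneAnnot("g1", "chr1", 1_000, 2_600, "+", 5.0),
        GeneAnnot("g2", "chr1", 3_000, 4_200, "-", 50.0),
        GeneAnnot("g3", "chr1", 5_000, 5_400, "+", 0.5),
        GeneAnnot("g4", "chr2", 500, 3_500, "-", 20.0),
    ]
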