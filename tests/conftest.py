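import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/_oracles.py

from cleftscan import SimulationConfig, simulate_all
from cleftscan.pipeline import default_config


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """One seeded synthetic dataset shared by the session."""
    outdir = tmp_path_factory.mktemp("sim")
    manifest = simulate_all(SimulationConfig(seed=7), outdir)
    return manifest


@pytest.fixture(scope="session")
def sim_config(sim):
    return default_config(sim)


def make_peakset(triples, names=None, genome=None, fe=10.0, q=0.01):
    """PeakSet from (chrom, start, end) triples; convenience for tests."""
    from cleftscan import GenomicInterval, Peak, PeakSet

    peaks = []
    for i, (c, s, e) in enumerate(triples):
        name = names[i] if names else f"p{i}"
        peaks.append(
            Peak(GenomicInterval(c, s, e, name=name), fold_enrichment=fe, fdr_q=q)
        )
    return PeakSet(peaks, genome=genome)
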