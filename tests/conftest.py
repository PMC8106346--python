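import numpy as np
import pytest

from npomics import pipeline
from npomics.genome import CoverageTrack, Gene
from npomics.synth import TruthBundle


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """A seeded synthetic run directory shared across tests (read-only)."""
    indir = tmp_path_factory.mktemp("sim") / "inputs"
    pipeline.simulate(7, indir)
    return indir


@pytest.fixture(scope="session")
def sim_truth(sim):
    return TruthBundle.load(str(sim / "truth.json"))


def make_track(scaffold="s1", length=20_000, depth=0):
    return CoverageTrack(scaffold, np.full(length, depth, dtype=np.int64))


def make_gene(gid="g1", scaffold="s1", start=1_000, end=1_999, **kwargs):
    return Gene(id=gid, scaffold=scaffold, start=start, end=end, **kwargs)
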