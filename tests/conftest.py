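import numpy as np
import pytest

from nifscape import preprocess as pp
from nifscape import synthcomm as sc


@pytest.fixture(scope="session")
def panel():
    """A 10-taxon two-cluster panel plus outgroup."""
    return sc.generate_reference_panel(10, divergence=0.15, seed=1)


@pytest.fixture(scope="session")
def noiseless_dataset(panel):
    """Two samples of 100 error-free reads each, with ground truth."""
    spec = sc.CommunitySpec(
        habitats=[sc.HabitatSpec("soil", richness=5, n_replicates=2, depth_range=(100, 100))],
        error_model=sc.ErrorModel(),
        seed=11,
    )
    return sc.simulate_reads(panel, spec), spec


def make_fragment(read_id, sample, peptide, corrections=0):
    return pp.PeptideFragment(read_id, sample, peptide, corrections, (0, len(peptide)))


def random_peptides(rng, n, length, alphabet="ACDE"):
    """Short random peptides over a small alphabet (tie-rich distances)."""
    return ["".join(rng.choice(list(alphabet), size=length)) for _ in range(n)]
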