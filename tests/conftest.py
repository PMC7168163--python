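import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the shared oracles module

from mytikit.datasets import load_reference_frame, load_reference_peptides, perna_peptides
from mytikit.io_formats import Peptide
from mytikit.synthetic_data import SyntheticConfig, make_family_cohort


@pytest.fixture(scope="session")
def table1_frame():
    return load_reference_frame()


@pytest.fixture(scope="session")
def table1_peptides():
    return load_reference_peptides()


@pytest.fixture(scope="session")
def perna():
    return perna_peptides()


@pytest.fixture(scope="session")
def family_cohort():
    """One synthetic mytilin family: (ancestor, annotation, members, annotations)."""
    config = SyntheticConfig(seed=101, n_mytilins=20)
    return make_family_cohort(config, prefix="cohort")


def mature_peptides(members, annotations):
    return [
        Peptide(p.id, p.residues[a.mature[0] - 1 : a.mature[1]], provenance="synthetic")
        for p, a in zip(members, annotations)
    ]
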