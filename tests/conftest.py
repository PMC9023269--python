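import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from amplicas.refmodel import locate_protospacer
from amplicas.simulate import make_reference

TOY_PROTOSPACER = "GATTACAGGATCCGGCTGCA"
TOY_REF = "ACGTACGTAC" + TOY_PROTOSPACER + "TGG" + "CTTAAGCTTA"


@pytest.fixture(scope="session")
def toy_site():
    """Hand-constructed 43-nt amplicon: pam_start=30, cut_pos=27, strand '+'."""
    return locate_protospacer(TOY_REF, TOY_PROTOSPACER)


@pytest.fixture(scope="session")
def sim_site():
    """Default 240-nt simulated amplicon with planted MMEJ repeats."""
    ref, site = make_reference(seed=1)
    return site


@pytest.fixture(scope="session")
def ccs_reference():
    """Long amplicon (4862 nt) with the cut near the middle, for CCS tests."""
    ref, site = make_reference(length=4862, site_offset=2400, seed=3)
    return ref, site
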