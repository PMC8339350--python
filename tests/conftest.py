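import pytest

from ddscan import load_reference_profile
from ddscan.classify import DDLineageClassifier


@pytest.fixture(scope="session")
def ref():
    return load_reference_profile()


@pytest.fixture(scope="session")
def clf(ref):
    return DDLineageClassifier(reference=ref).fit()


@pytest.fixture()
def two_record_fasta(tmp_path):
    p = tmp_path / "two.fasta"
    p.write_text(">s1 first\nMSVTIYVTQY\n>s2 second\nmaeleqkale*\n")
    return p


@pytest.fixture(scope="session")
def standin_structures(tmp_path_factory):
    """Synthetic crystal-entry stand-ins written once per session."""
    from ddscan.standins import (
        write_synthetic_rii_dimer,
        write_synthetic_spa17_crystal,
    )

    d = tmp_path_factory.mktemp("structures")
    spa17 = d / "synthetic_spa17_crystal.pdb"
    rii = d / "synthetic_rii_dimer.pdb"
    write_synthetic_spa17_crystal(spa17)
    write_synthetic_rii_dimer(rii)
    return {"spa17": spa17, "rii": rii}
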