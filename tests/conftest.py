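import pytest

from regassoc.fixture import load_paper_fixture
from regassoc.qc import run_qc
from regassoc.simulate import reconstruct_paper_cohort


@pytest.fixture(scope="session")
def paper_fx():
    return load_paper_fixture()


@pytest.fixture(scope="session")
def recon():
    """Cohort reconstructed from the printed per-variant counts."""
    return reconstruct_paper_cohort()


@pytest.fixture(scope="session")
def recon_rarity(recon):
    gm, phen, _ = recon
    return {r.variant_id: r.rarity for r in run_qc(gm, phen)}
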