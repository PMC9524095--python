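import numpy as np
import pytest

from sodnox.config import MotifSpec, PipelineConfig, RuleSet
from sodnox.references import nox2_reference, reference_panels
from sodnox.seqio import DomainHit
from sodnox.synthetic_data import make_domain_library


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig(bootstrap_reps=100, rng_seed=0)


@pytest.fixture(scope="session")
def rules() -> RuleSet:
    return RuleSet()


@pytest.fixture(scope="session")
def motif_spec() -> MotifSpec:
    return MotifSpec()


@pytest.fixture(scope="session")
def library():
    return make_domain_library()


@pytest.fixture(scope="session")
def nox2_ref():
    return nox2_reference()


@pytest.fixture(scope="session")
def panels():
    return reference_panels()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20220930)


def make_hit(
    seq_id="s1",
    domain="Sod_Cu",
    accession="PF00080",
    start=1,
    end=100,
    score=100.0,
    i_evalue=1e-20,
) -> DomainHit:
    return DomainHit(
        seq_id=seq_id,
        domain=domain,
        accession=accession,
        env_start=start,
        env_end=end,
        score=score,
        i_evalue=i_evalue,
    )
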