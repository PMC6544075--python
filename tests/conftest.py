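import numpy as np
import pytest

from splicevet import synthetic_fixtures as sf
from splicevet.splice_info import SiteGeometry, build_model


@pytest.fixture(scope="session")
def model_set():
    """Strong-profile donor/acceptor models trained on 1000 sampled sites."""
    return sf.generate_models("strong", 1000, seed=7)


@pytest.fixture(scope="session")
def toy_model():
    """A 3-position donor-like model small enough for exhaustive checks."""
    rng = np.random.default_rng(42)
    probs = np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.1, 0.7, 0.1], [0.25, 0.25, 0.25, 0.25]])
    bases = np.array(list("ACGT"))
    seqs = [
        "".join(bases[rng.choice(4, p=probs[l])] for l in range(3)) for _ in range(200)
    ]
    return build_model(seqs, "donor", geometry=SiteGeometry(-1, 2), pseudocount=0.25), seqs


@pytest.fixture(scope="session")
def skip_bundle():
    return sf.generate_case(sf.scenario(sf.NATURAL_LOSS_EXON_SKIP, seed=3))


@pytest.fixture(scope="session")
def inclusion_bundle():
    return sf.generate_case(sf.scenario(sf.NATURAL_LOSS_INTRON_INCLUSION, seed=3))


@pytest.fixture(scope="session")
def cryptic_bundle():
    return sf.generate_case(sf.scenario(sf.CRYPTIC_ACTIVATION, seed=3))


@pytest.fixture(scope="session")
def snp_bundle():
    return sf.generate_case(sf.scenario(sf.COMMON_SNP_BENIGN, seed=3))


@pytest.fixture(scope="session")
def masquerade_bundle():
    return sf.generate_case(sf.scenario(sf.ALT_SPLICED_CONTROL_MASQUERADE, seed=3))
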