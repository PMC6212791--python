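import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

from metclo import default_enzymes, default_methylases
from metclo.planner import DEFAULT_SCHEME


@pytest.fixture(scope="session")
def enzymes():
    return default_enzymes()


@pytest.fixture(scope="session")
def methylases():
    return default_methylases()


@pytest.fixture(scope="session")
def bsai(enzymes):
    return enzymes["BsaI"]


@pytest.fixture(scope="session")
def osp(methylases):
    return methylases["M.Osp807II"]


@pytest.fixture(scope="session")
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture(scope="session")
def test_plasmid(bsai, osp):
    """The blocking-assay test plasmid: head-to-head switchable pair sharing
    one cut interval + one non-switchable site ~600 bp away on a 4.9 kb circle."""
    from metclo import make_methylation_test_plasmid

    return make_methylation_test_plasmid(bsai, osp, seed=1)


@pytest.fixture(scope="session")
def four_donor_pot(bsai, osp, methylases, scheme):
    """A Start acceptor plus four chained donors (p-a-b-c-q), ready to pot."""
    import numpy as np
    from metclo import apply_strain, make_acceptor, make_donor, switch_strain

    acc = make_acceptor("Start", ("p", "a"), scheme, bsai, osp, seed=2)
    rng = np.random.default_rng(3)
    letters = ["p", "a", "b", "c", "q"]
    donors = [
        make_donor(bsai, osp, scheme.seq(letters[i]), scheme.seq(letters[i + 1]),
                   insert_len=300, seed=rng, mol_id=f"D{i+1}")
        for i in range(4)
    ]
    vector = apply_strain(acc, switch_strain(osp), methylases)
    return acc, vector, donors
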