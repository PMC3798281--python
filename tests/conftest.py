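import numpy as np
import pytest

from aprstat.records import APRInterval, SequenceRecord
from aprstat.synthetic import SyntheticSpec, make_toy_structure


@pytest.fixture(scope="session")
def toy_bundle():
    """Deterministic three-helix bundle + tail with designated segments."""
    return make_toy_structure(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def toy_bundle_asa(toy_bundle):
    from aprstat.structure import compute_asa

    model, segments = toy_bundle
    return model, segments, compute_asa(model)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_seqs():
    return [
        SequenceRecord("s1", "MKTAYIAKQRVVVVVVQDEGHK"),
        SequenceRecord("s2", "ACDEFGHIKLMNPQRSTVWY"),
        SequenceRecord("s3", "AAAAAAAAAAAA"),
    ]


@pytest.fixture
def line_chain():
    """Straight CA chain, 3.8 A spacing: only sequence neighbours contact."""
    from aprstat.structure import StructureModel

    n = 30
    coords = np.column_stack([
        3.8 * np.arange(n, dtype=float), np.zeros(n), np.zeros(n)
    ])
    return StructureModel(
        chain_ids=np.array(["A"] * n),
        res_ids=np.arange(1, n + 1),
        icodes=np.array([""] * n),
        res_names=np.array(["ALA"] * n),
        atom_names=np.array(["CA"] * n),
        elements=np.array(["C"] * n),
        coords=coords,
    )
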