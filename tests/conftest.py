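import numpy as np
import pytest
from hypothesis import settings

from himme import KmerStateSpace, build_emission_manual, learn_transition_model

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from himme.simulate import synthetic_reference


@pytest.fixture(scope="session")
def reference_100kb() -> str:
    """Patterned pseudo-genome used as the training reference."""
    return synthetic_reference(100_000, order=3, concentration=0.5, seed=11)


@pytest.fixture(scope="session")
def reference_20kb(reference_100kb) -> str:
    return reference_100kb[:20_000]


@pytest.fixture(scope="session")
def space3() -> KmerStateSpace:
    return KmerStateSpace(3)


@pytest.fixture(scope="session")
def model_k3(reference_100kb):
    """Transition model trained at k=3 on the session reference."""
    return learn_transition_model(reference_100kb, KmerStateSpace(3), pseudocount=1.0)


@pytest.fixture(scope="session")
def emission_085():
    return build_emission_manual(0.85)


def random_transition_model(space: KmerStateSpace, rng: np.random.Generator):
    """A valid random TransitionModel (Dirichlet rows), for oracle tests."""
    from himme import TransitionModel

    card = space.cardinality
    return TransitionModel(
        space=space,
        pi0=rng.dirichlet(np.ones(card)),
        trans=rng.dirichlet(np.ones(card), size=card),
        training_meta={"source": "random"},
    )


def random_emission_model(rng: np.random.Generator):
    from himme import EmissionModel

    return EmissionModel(rng.dirichlet(np.ones(4), size=4), source="manual")


def write_fasta(path, records):
    from himme.io import write_fasta

    write_fasta(records, path)
    return path
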