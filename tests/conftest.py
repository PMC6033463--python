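import numpy as np
import pytest

from xldisc import (
    deduplicate,
    make_reference_conformations,
    table1_identifications,
)


@pytest.fixture(scope="session")
def table1_restraints():
    """The 22 unique restraints of the packaged identification fixture."""
    return deduplicate(table1_identifications())


@pytest.fixture(scope="session")
def reference_confs():
    return make_reference_conformations()


@pytest.fixture(scope="session")
def built_models():
    """Annealed monomer models shared across the expensive test groups.

    Five seeds per (variant, hinge) combination used by the model-generation
    and accessibility properties.
    """
    from xldisc.builder import build_model

    seeds = (1, 2, 3, 4, 5)
    out = {}
    for variant, hinge in [
        ("opened", (186, 193)),
        ("opened", (164, 168)),
        ("compact", (186, 193)),
    ]:
        for seed in seeds:
            model, result = build_model(variant, hinge, seed=seed)
            out[(variant, hinge, seed)] = (model, result)
    return out


def random_rotation(rng):
    """A uniform-ish random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))
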