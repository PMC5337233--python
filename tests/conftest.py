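import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from isolabel import FractionVector, MoietySpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def two_atom_spec() -> MoietySpec:
    """Homonuclear two-atom, single-shift moiety (the worked example)."""
    return MoietySpec.homonuclear("A", 2, 1)


@pytest.fixture
def worked_isotopomer(two_atom_spec) -> FractionVector:
    """The standard worked-example vector over (0,0),(0,1),(1,0),(1,1)."""
    return FractionVector("isotopomer", np.array([0.4, 0.3, 0.2, 0.1]), two_atom_spec)


def random_isotopomer(spec: MoietySpec, rng: np.random.Generator) -> FractionVector:
    """Dirichlet-random isotopomer vector respecting the surplus-state rule."""
    caps = tuple(a.max_shift + 1 for a in spec.atoms)
    dense = rng.dirichlet(np.ones(int(np.prod(caps)))).reshape(caps)
    full = np.zeros((spec.m + 1,) * spec.n)
    full[np.ix_(*[range(c) for c in caps])] = dense
    return FractionVector("isotopomer", full.reshape(-1), spec)
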