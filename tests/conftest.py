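import pytest

from metasyn.synthgen import SynthConfig, generate
from metasyn.vocab import AtomTuple, build_atoms

DIS = frozenset({"Disorders"})

# a six-atom concept of headache terms in two sources: the canonical
# worked example for identifiers, rules and similarity
HEADACHE_ROWS = [
    ("Headache", "MSH", "M0009824"),
    ("Headaches", "MSH", "M0009824"),
    ("Cranial Pains", "MSH", "M0009824"),
    ("Cephalodynia", "MSH", "M0009824"),
    ("Cephalodynia", "SNOMEDCT_US", "25064002"),
    ("Headache (finding)", "SNOMEDCT_US", "25064002"),
]


@pytest.fixture(scope="session")
def headache_atoms():
    tuples = [AtomTuple(t, s, c, DIS) for t, s, c in HEADACHE_ROWS]
    return build_atoms(tuples)


@pytest.fixture(scope="session")
def small_corpus():
    """50-concept synthetic corpus for unit-level tests."""
    return generate(SynthConfig(seed=11, n_concepts=50))


@pytest.fixture(scope="session")
def demo_corpus():
    """500-concept corpus at the generator's default study conditions."""
    return generate(SynthConfig(seed=7))
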