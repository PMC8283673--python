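import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from svdscore import (  # noqa: E402
    QuartetTree,
    SubstitutionModel,
    site_pattern_distribution,
)

#: Newick of the reference JC69 worked-example tree (ab|cd split, long a/c
#: terminals); its discordant ac|bd squared score is the basis of the
#: site-count approximations.
REFERENCE_TREE_NEWICK = "((a:0.5,b:0.05):0.05,(c:0.5,d:0.05):0.05);"


@pytest.fixture(scope="session")
def jc69():
    return SubstitutionModel.jc69()


@pytest.fixture(scope="session")
def reference_tree():
    return QuartetTree.from_newick(REFERENCE_TREE_NEWICK)


@pytest.fixture(scope="session")
def reference_distribution(reference_tree, jc69):
    """Exact JC69 site-pattern distribution on the reference tree."""
    return site_pattern_distribution(reference_tree, jc69)


@pytest.fixture(scope="session")
def generic_tree():
    """A quartet with generic (asymmetric) branch lengths."""
    return QuartetTree.from_lengths("ab|cd", 0.13, 0.27, 0.08, 0.41, 0.19)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
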