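import numpy as np
import pytest

from vertmark.alignment import Alignment
from vertmark.model import equal_rates_model, lg_model
from vertmark import treeio


@pytest.fixture(scope="session")
def lg_g4():
    return lg_model(alpha=0.7, K=4)


@pytest.fixture(scope="session")
def eq_model():
    return equal_rates_model()


@pytest.fixture
def toy_alignment():
    return Alignment(
        ["a", "b", "c", "d"],
        np.array([list("ACDEFGHIKL"),
                  list("ACDEFGHIKM"),
                  list("ACDEYGHIKL"),
                  list("ACDEFG-IKL")]),
    )


@pytest.fixture
def quartet_tree():
    return treeio.parse_newick("((a:0.1,b:0.2):0.15,c:0.3,d:0.25);")


@pytest.fixture
def two_domain_tree():
    return treeio.parse_newick("((A_1:1,A_2:1):2,(B_1:1,B_2:1):0);")


@pytest.fixture
def two_domain_map():
    return treeio.domain_map_from_prefixes(["A_1", "A_2", "B_1", "B_2"])
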