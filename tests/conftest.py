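import numpy as np
import pytest

import plchron as pc
from plchron.alignment_stats import AlignmentMatrix
from plchron.branch_lengths import SubstitutionModel


@pytest.fixture(scope="session")
def template():
    return pc.template_chronogram(50.0)


@pytest.fixture(scope="session")
def gtr_model():
    return SubstitutionModel(
        exchangeabilities=(1.5, 4.0, 0.8, 1.2, 5.0, 1.0),
        frequencies=(0.3, 0.2, 0.2, 0.3),
        alpha=0.7,
        p_inv=0.15,
    )


@pytest.fixture
def small_alignment():
    return AlignmentMatrix.from_strings(
        [("A", "ACGTACGT"), ("B", "ACGTACGA"), ("C", "ACG-ACGA")]
    )


def random_phylogram(rng, n_taxa=6, max_len=0.3):
    """Random rooted binary tree with random branch lengths (newick text)."""

    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [f"{lab}:{rng.uniform(0.01, max_len):.6f}" for lab in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        nodes.append(f"({a},{b}):{rng.uniform(0.01, max_len):.6f}")
    return f"({nodes[0]},{nodes[1]});"
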