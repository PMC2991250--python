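import numpy as np
import pytest

from ontoweave.ontology import InteractionOntology, Term


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def small_ontology():
    """root -> {physical -> {phosphorylation(directed)}, pathway}."""
    return InteractionOntology({
        "root": Term("root", "functional relationship"),
        "physical": Term("physical", "physical interaction", parent="root"),
        "phos": Term("phos", "phosphorylation", directed=True, parent="physical"),
        "pathway": Term("pathway", "pathway relationship", parent="root"),
    })
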