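import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from coexmod.io import ExpressionMatrix
from coexmod.ontology import build_annotation_index, load_obo

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

TOY_OBO = """format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: root_process
namespace: biological_process

[Term]
id: GO:0000002
name: term_a
namespace: biological_process
is_a: GO:0000001 ! root_process

[Term]
id: GO:0000003
name: parent_p
namespace: biological_process
is_a: GO:0000001 ! root_process

[Term]
id: GO:0000004
name: sibling_1
namespace: biological_process
is_a: GO:0000003 ! parent_p

[Term]
id: GO:0000005
name: sibling_2
namespace: biological_process
is_a: GO:0000003 ! parent_p
"""

# 8-gene corpus: term_a covers 4 genes (Ic 1 bit), parent_p covers 4
# (two via its leaf children, Ic 1 bit), each sibling leaf covers 1
# gene (Ic 3 bits), the root covers all 8 (Ic 0).
TOY_ANNOTATIONS = [
    ("g1", "GO:0000002"), ("g2", "GO:0000002"),
    ("g3", "GO:0000002"), ("g4", "GO:0000002"),
    ("g5", "GO:0000004"), ("g6", "GO:0000005"),
    ("g7", "GO:0000003"), ("g8", "GO:0000003"),
]


@pytest.fixture(scope="session")
def toy_ontology(tmp_path_factory):
    p = tmp_path_factory.mktemp("onto") / "toy.obo"
    p.write_text(TOY_OBO)
    return load_obo(p)


@pytest.fixture(scope="session")
def toy_annotation_index(toy_ontology):
    return build_annotation_index(TOY_ANNOTATIONS, toy_ontology, "BP")


def make_expression(values, gene_ids=None, classes=None):
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(values.shape[0])]
    cols = [f"s{j + 1}" for j in range(values.shape[1])]
    data = pd.DataFrame(values, index=pd.Index(gene_ids, name="GENE"),
                        columns=cols)
    sample_class = None
    if classes is not None:
        sample_class = pd.Series(classes, index=cols, name="class")
    return ExpressionMatrix(data=data, sample_class=sample_class)


@pytest.fixture
def expr_factory():
    return make_expression
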