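import io

import pytest

from hporank.annotations import AnnotationIndex
from hporank.ontology import load_ontology

# Chain (root -> A -> B), diamond (root -> X, root -> Y, X,Y -> Z), an
# alt_id on A and one obsolete term.
TOY_OBO = """\
format-version: 1.2

[Term]
id: HP:0000001
name: root

[Term]
id: HP:0000002
name: A
alt_id: HP:0000099
is_a: HP:0000001

[Term]
id: HP:0000003
name: B
is_a: HP:0000002

[Term]
id: HP:0000004
name: X
is_a: HP:0000001

[Term]
id: HP:0000005
name: Y
is_a: HP:0000001

[Term]
id: HP:0000006
name: Z
is_a: HP:0000004
is_a: HP:0000005

[Term]
id: HP:0000007
name: gone
is_obsolete: true
"""

ROOT, A, B, X, Y, Z = (f"HP:000000{i}" for i in range(1, 7))

TOY_DIRECT = {
    "g1": {B},
    "g2": {A},
    "g3": {Z},
    "g4": {X},
}


@pytest.fixture(scope="session")
def toy_ontology():
    return load_ontology(io.StringIO(TOY_OBO))


@pytest.fixture(scope="session")
def toy_index(toy_ontology):
    return AnnotationIndex(toy_ontology, TOY_DIRECT)


def parent_map(ontology):
    """Plain parent-edge map for the brute-force oracles."""
    return {
        t: term.parents
        for t, term in ontology.terms.items()
        if not term.obsolete
    }
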