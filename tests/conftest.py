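import pytest

from gmoget import build_paper_fixture, default_donor_registry
from gmoget.registries import default_prefix_registry


@pytest.fixture(scope="session")
def donors():
    return default_donor_registry()


@pytest.fixture(scope="session")
def prefixes():
    return default_prefix_registry()


@pytest.fixture()
def paper():
    """A fresh copy of the packaged worked-example thesaurus."""
    return build_paper_fixture()


def brute_force_expand(thesaurus, term_id: str) -> set[str]:
    """Independent reflexive-transitive closure by repeated edge expansion.

    Works only from parent links, never from the children index, so it
    cross-checks the production path rather than repeating it.
    """
    edges = [
        (t.parent_id, t.term_id)
        for t in thesaurus
        if t.parent_id is not None
    ]
    closure = {term_id}
    changed = True
    while changed:
        changed = False
        for parent, child in edges:
            if parent in closure and child not in closure:
                closure.add(child)
                changed = True
    return closure


def brute_force_ancestors(thesaurus, term_id: str) -> set[str]:
    out = set()
    cur = thesaurus.terms[term_id]
    while cur.parent_id is not None:
        out.add(cur.parent_id)
        cur = thesaurus.terms[cur.parent_id]
    return out
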