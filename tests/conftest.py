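import pytest

from ciotools import builtin_cio
from ciotools.fixtures import toy_eco


@pytest.fixture(scope="session")
def eco():
    return toy_eco()


@pytest.fixture(scope="session")
def cio():
    return builtin_cio()


def bfs_ancestors(ont, term_id):
    """Brute-force reachability over the parents data, independent of the
    library's graph traversal: plain BFS on OntologyTerm.parents."""
    seen = set()
    frontier = list(ont.terms[term_id].parents)
    while frontier:
        nxt = frontier.pop()
        if nxt in seen:
            continue
        seen.add(nxt)
        frontier.extend(ont.terms[nxt].parents)
    return {a for a in seen if not ont.terms[a].obsolete}
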