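"""Minimal OBO flat-file support: parse, query and write ``[Term]`` stanza graphs.

Only the subset of OBO 1.2/1.4 that subsumption queries need is modelled:
term id, name, ``is_a`` parents, obsolescence and synonyms.  All other tags
and stanza types (``[Typedef]``, ...) are parsed and discarded, because the
confidence-aggregation logic downstream uses only the is_a hierarchy.

The graph queries (acyclicity, transitive reachability) are delegated to
:mod:`networkx`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "OntologyTerm",
    "Ontology",
    "OboParseError",
    "UnknownTermError",
    "parse_obo",
    "write_obo",
]


class OboParseError(ValueError):
    """Raised for malformed OBO documents (missing ids, dangling is_a, cycles)."""


class UnknownTermError(KeyError):
    """Raised when a term id is looked up that the ontology does not contain."""

    def __str__(self) -> str:  # KeyError repr-quotes its message; keep it readable
        return self.args[0] if self.args else ""


@dataclass(frozen=True)
class OntologyTerm:
    """One ontology term: a CURIE-like id, a label, and its is_a parents."""

    id: str
    name: str = ""
    parents: frozenset[str] = field(default_factory=frozenset)
    obsolete: bool = False
    synonyms: tuple[str, ...] = ()


class Ontology:
    """A set of terms connected by an acyclic is_a graph.

    Parameters
    ----------
    terms
        The terms to hold.  Ids must be unique; every parent reference must
        resolve to a term in the same collection; the is_a graph must be
        acyclic.  Violations raise :class:`OboParseError`.
    """

    def __init__(self, terms: "list[OntologyTerm] | dict[str, OntologyTerm]"):
        if isinstance(terms, dict):
            terms = list(terms.values())
        self.terms: dict[str, OntologyTerm] = {}
        for t in terms:
            if t.id in self.terms:
                raise OboParseError(f"duplicate term id {t.id!r}")
            self.terms[t.id] = t
        dangling = sorted(
            {p for t in self.terms.values() for p in t.parents if p not in self.terms}
        )
        if dangling:
            raise OboParseError(
                "is_a targets not defined in this ontology: " + ", ".join(dangling)
            )
        # Graph direction child -> parent, so "descendants" in networkx terms
        # are the ancestors of a term.
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for p in t.parents:
                g.add_edge(t.id, p)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OboParseError(f"is_a graph contains a cycle: {cycle}")
        self._graph = g

    @property
    def roots(self) -> set[str]:
        """Ids of non-obsolete terms with no parents."""
        return {
            t.id for t in self.terms.values() if not t.parents and not t.obsolete
        }

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, term_id: str) -> OntologyTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise UnknownTermError(f"unknown term id {term_id!r}") from None

    def id_for_name(self, name: str) -> str | None:
        """Return the id of the term with this label (case-insensitive), or None."""
        low = name.strip().lower()
        for t in self.terms.values():
            if t.name.lower() == low:
                return t.id
        return None

    def ancestors(self, term_id: str) -> set[str]:
        """All ids reachable by transitive is_a traversal, excluding the term itself.

        Obsolete terms never appear in the result.
        """
        if term_id not in self.terms:
            raise UnknownTermError(f"unknown term id {term_id!r}")
        reach = nx.descendants(self._graph, term_id)
        return {a for a in reach if not self.terms[a].obsolete}

    def children(self, term_id: str) -> set[str]:
        """Direct is_a children of a term (non-obsolete)."""
        if term_id not in self.terms:
            raise UnknownTermError(f"unknown term id {term_id!r}")
        return {
            c
            for c in self._graph.predecessors(term_id)
            if not self.terms[c].obsolete
        }

    def leaves(self) -> set[str]:
        """Non-obsolete terms with no non-obsolete children."""
        return {
            i
            for i, t in self.terms.items()
            if not t.obsolete and not self.children(i)
        }

    def subsumes(self, general: str, specific: str) -> bool:
        """True iff *general* equals *specific* or is one of its ancestors."""
        if general not in self.terms:
            raise UnknownTermError(f"unknown term id {general!r}")
        if specific not in self.terms:
            raise UnknownTermError(f"unknown term id {specific!r}")
        return general == specific or general in self.ancestors(specific)


def ancestors(ont: Ontology, term_id: str) -> set[str]:
    """Functional alias for :meth:`Ontology.ancestors`."""
    return ont.ancestors(term_id)


def subsumes(ont: Ontology, general: str, specific: str) -> bool:
    """Functional alias for :meth:`Ontology.subsumes`."""
    return ont.subsumes(general, specific)


_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"')


def _strip_comment(value: str) -> str:
    # OBO trailing comments start at " ! " outside quotes; none of the tags we
    # honor carry quoted strings except synonym, handled separately.
    idx = value.find(" ! ")
    if idx >= 0:
        value = value[:idx]
    if value.endswith(" !"):
        value = value[:-2]
    return value.strip()


def parse_obo(text: str) -> Ontology:
    """Parse an OBO 1.2/1.4 document into an :class:`Ontology`.

    Only ``[Term]`` stanzas are honored, and within them only the tags
    ``id``, ``name``, ``is_a``, ``is_obsolete`` and ``synonym``; all other
    tags and stanza types are silently ignored.  Obsolete terms are retained.

    Raises
    ------
    OboParseError
        If a ``[Term]`` stanza lacks an id (the error names the stanza
        index), if an ``is_a`` target is not defined in the document, or if
        the is_a graph is cyclic.
    """
    terms: list[OntologyTerm] = []
    stanza_type: str | None = None
    stanza_index = 0
    cur: dict | None = None

    def flush() -> None:
        if cur is None:
            return
        if cur.get("id") is None:
            raise OboParseError(
                f"[Term] stanza #{stanza_index} has no id tag"
            )
        terms.append(
            OntologyTerm(
                id=cur["id"],
                name=cur.get("name", ""),
                parents=frozenset(cur.get("is_a", ())),
                obsolete=cur.get("obsolete", False),
                synonyms=tuple(cur.get("synonyms", ())),
            )
        )

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("[") and line.endswith("]"):
            flush()
            cur = None
            stanza_type = line[1:-1]
            if stanza_type == "Term":
                stanza_index += 1
                cur = {"is_a": [], "synonyms": []}
            continue
        if cur is None or ":" not in line:
            continue
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.strip()
        if tag == "id":
            cur["id"] = _strip_comment(value)
        elif tag == "name":
            cur["name"] = _strip_comment(value)
        elif tag == "is_a":
            cur["is_a"].append(_strip_comment(value))
        elif tag == "is_obsolete":
            cur["obsolete"] = _strip_comment(value).lower() == "true"
        elif tag == "synonym":
            m = _SYNONYM_RE.match(value)
            if m:
                cur["synonyms"].append(m.group("text").replace('\\"', '"'))
        # every other tag is ignored without error
    flush()
    return Ontology(terms)


def write_obo(ont: Ontology) -> str:
    """Serialize an :class:`Ontology` as an OBO 1.2 document.

    ``parse_obo(write_obo(ont))`` reproduces the ontology term-for-term on
    (id, name, parents, obsolete, synonyms).  Stanzas are emitted in sorted
    id order for deterministic output.
    """
    out = ["format-version: 1.2", ""]
    for tid in sorted(ont.terms):
        t = ont.terms[tid]
        out.append("[Term]")
        out.append(f"id: {t.id}")
        if t.name:
            out.append(f"name: {t.name}")
        for syn in t.synonyms:
            escaped = syn.replace('"', '\\"')
            out.append(f'synonym: "{escaped}" RELATED []')
        for p in sorted(t.parents):
            parent_name = ont.terms[p].name
            suffix = f" ! {parent_name}" if parent_name else ""
            out.append(f"is_a: {p}{suffix}")
        if t.obsolete:
            out.append("is_obsolete: true")
        out.append("")
    return "\n".join(out)
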