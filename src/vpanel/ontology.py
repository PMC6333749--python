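"""Phenotype ontology handling.

Parses the OBO 1.2 subset needed for phenotype matching (``[Term]`` stanzas
with ``id``/``name``/``is_a``/``alt_id``/``is_obsolete``/``replaced_by``) into
a directed acyclic graph of terms, and answers the closure queries that drive
virtual-panel construction: a broad patient phenotype such as "Puberty and
gonadal disorders" is satisfied by any disease annotation inside its
descendant closure.

Only ``is_a`` edges contribute to the hierarchy; other ``relationship:``
edges (``part_of`` etc.) are ignored, following the convention of
HPO-based phenotype matching. Multiple parents are allowed (the ontology is
a DAG, not a tree).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional, Union

import networkx as nx

__all__ = [
    "OntologyError",
    "UnknownTermError",
    "ObsoleteTermError",
    "Term",
    "Ontology",
    "normalize_term_id",
    "parse_obo",
]

#: ``PREFIX:digits`` — prefix compared case-insensitively, digits exactly.
_TERM_ID_RE = re.compile(r"^([A-Za-z][A-Za-z0-9_]*):(\d+)$")


class OntologyError(ValueError):
    """Structural problem in an ontology (cycle, dangling parent, ...)."""


class UnknownTermError(OntologyError, KeyError):
    """A term id that does not occur in the ontology at all."""

    def __str__(self) -> str:  # KeyError quotes its args otherwise
        return ValueError.__str__(self)


class ObsoleteTermError(OntologyError):
    """An obsolete term without a replacement was queried."""


def normalize_term_id(value: str) -> str:
    """Validate and canonicalize a term id (uppercase prefix, digits kept).

    Raises :class:`OntologyError` if *value* does not look like
    ``PREFIX:digits``.
    """
    m = _TERM_ID_RE.match(value.strip())
    if m is None:
        raise OntologyError(f"not a valid term id: {value!r}")
    prefix, digits = m.groups()
    return f"{prefix.upper()}:{digits}"


@dataclass(frozen=True)
class Term:
    id: str
    name: str = ""
    parents: frozenset[str] = field(default_factory=frozenset)
    alt_ids: frozenset[str] = field(default_factory=frozenset)
    obsolete: bool = False
    replaced_by: Optional[str] = None

    def __post_init__(self) -> None:
        if self.id in self.alt_ids:
            raise OntologyError(f"term {self.id}: id listed among its own alt_ids")
        if not self.obsolete and self.replaced_by is not None:
            raise OntologyError(
                f"term {self.id}: replaced_by on a non-obsolete term"
            )


class Ontology:
    """An immutable DAG of phenotype terms with memoized closure queries."""

    def __init__(self, terms: dict[str, Term]):
        self.terms = terms
        self._alt: dict[str, str] = {}
        for t in terms.values():
            for a in t.alt_ids:
                if a in terms:
                    raise OntologyError(f"alt_id {a} collides with a primary id")
                if a in self._alt and self._alt[a] != t.id:
                    raise OntologyError(
                        f"alt_id {a} maps to both {self._alt[a]} and {t.id}"
                    )
                self._alt[a] = t.id
        # edges run child -> parent; closure queries reverse them
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        for t in terms.values():
            for p in t.parents:
                if p not in terms:
                    raise OntologyError(
                        f"term {t.id}: is_a references unknown term {p}"
                    )
                g.add_edge(t.id, p)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            raise OntologyError(
                f"is_a graph contains a cycle through {cycle[0][0]}"
            )
        self._graph = g
        self.roots: frozenset[str] = frozenset(
            t.id for t in terms.values() if not t.parents and not t.obsolete
        )
        self._down: dict[str, frozenset[str]] = {}
        self._up: dict[str, frozenset[str]] = {}

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        try:
            tid = normalize_term_id(term_id)
        except OntologyError:
            return False
        return tid in self.terms or tid in self._alt

    def resolve(self, term_id: str, allow_obsolete: bool = False) -> str:
        """Map any known id (primary, alt, obsolete) to its primary live id.

        Follows ``replaced_by`` one step. Idempotent on its own output.
        Obsolete terms with no replacement raise :class:`ObsoleteTermError`
        unless *allow_obsolete* is set.
        """
        tid = normalize_term_id(term_id)
        tid = self._alt.get(tid, tid)
        term = self.terms.get(tid)
        if term is None:
            raise UnknownTermError(f"unknown term id: {term_id}")
        if term.obsolete:
            if term.replaced_by is not None:
                return self.resolve(term.replaced_by, allow_obsolete=allow_obsolete)
            if not allow_obsolete:
                raise ObsoleteTermError(
                    f"term {tid} is obsolete and has no replacement"
                )
        return tid

    def descendants_or_self(self, term_id: str) -> frozenset[str]:
        """Reflexive-transitive closure below *term_id* (more specific terms)."""
        tid = self.resolve(term_id)
        cached = self._down.get(tid)
        if cached is None:
            cached = frozenset(nx.ancestors(self._graph, tid)) | {tid}
            self._down[tid] = cached
        return cached

    def ancestors_or_self(self, term_id: str) -> frozenset[str]:
        """Reflexive-transitive closure above *term_id* (broader terms)."""
        tid = self.resolve(term_id)
        cached = self._up.get(tid)
        if cached is None:
            cached = frozenset(nx.descendants(self._graph, tid)) | {tid}
            self._up[tid] = cached
        return cached


def _iter_lines(stream: Union[str, IO[str], Iterable[str]]) -> Iterator[str]:
    if isinstance(stream, str):
        yield from io.StringIO(stream)
    else:
        yield from stream


def parse_obo(stream: Union[str, IO[str], Iterable[str]]) -> Ontology:
    """Parse OBO 1.2 text (string or line stream) into an :class:`Ontology`.

    Only ``[Term]`` stanzas are interpreted; unknown tag lines are ignored.
    Obsolete terms are retained and flagged. Duplicate primary ids, dangling
    ``is_a`` references and ``is_a`` cycles are hard errors.
    """
    terms: dict[str, Term] = {}
    in_term = False
    cur: Optional[dict] = None

    def flush() -> None:
        nonlocal cur
        if cur is None:
            return
        tid = cur.get("id")
        if tid is None:
            raise OntologyError("[Term] stanza without an id")
        if tid in terms:
            raise OntologyError(f"duplicate primary id: {tid}")
        terms[tid] = Term(
            id=tid,
            name=cur.get("name", ""),
            parents=frozenset(cur["is_a"]),
            alt_ids=frozenset(cur["alt_id"]),
            obsolete=cur.get("obsolete", False),
            replaced_by=cur.get("replaced_by"),
        )
        cur = None

    for raw in _iter_lines(stream):
        line = raw.split(" ! ")[0].strip()
        if not line:
            continue
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            cur = {"is_a": [], "alt_id": []} if in_term else None
            continue
        if not in_term or cur is None or ":" not in line:
            continue
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key == "id":
            cur["id"] = normalize_term_id(value)
        elif key == "name":
            cur["name"] = value
        elif key == "is_a":
            cur["is_a"].append(normalize_term_id(value.split()[0]))
        elif key == "alt_id":
            cur["alt_id"].append(normalize_term_id(value))
        elif key == "is_obsolete":
            cur["obsolete"] = value.lower() == "true"
        elif key == "replaced_by":
            cur["replaced_by"] = normalize_term_id(value)
        # every other tag is ignored by design
    flush()
    return Ontology(terms)
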