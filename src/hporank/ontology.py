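"""Ontology loading and ancestor closure.

The ontology is a rooted directed acyclic graph of terms connected by
``is_a`` edges (child to parent).  Only ``is_a`` relations are modelled:
phenotype ontologies such as the HPO are strict is-a hierarchies.  Each
term's *proper ancestors* (excluding the term itself, including the root)
are precomputed as a transitive closure over parent edges; every downstream
computation — true-path annotation propagation, most-informative-common-
ancestor similarity, imprecision simulation — reads from that closure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies (cycles, bad roots)."""


@dataclass(frozen=True)
class Term:
    """A single ontology term.

    Attributes
    ----------
    id : str
        Primary accession, e.g. ``"HP:0000118"``.
    name : str
        Human-readable label.
    parents : frozenset[str]
        Accessions of direct ``is_a`` parents (empty only for the root and
        for obsolete terms).
    obsolete : bool
        Obsolete terms are retained so their accessions resolve, but they
        carry no annotations and take no part in similarity.
    """

    id: str
    name: str = ""
    parents: frozenset[str] = field(default_factory=frozenset)
    obsolete: bool = False


class Ontology:
    """A rooted is-a DAG with precomputed ancestor closure.

    Parameters
    ----------
    terms : mapping of accession -> Term
        Must contain exactly one non-obsolete term with no parents (the
        root) and be acyclic.
    alt_ids : mapping of alternate accession -> primary accession, optional

    Notes
    -----
    ``ancestors(t)`` returns the *proper* ancestors of ``t``: the term
    itself is excluded, the root is included for every non-root term.
    """

    def __init__(
        self,
        terms: Mapping[str, Term],
        alt_ids: Mapping[str, str] | None = None,
    ) -> None:
        self.terms: dict[str, Term] = dict(terms)
        self.alt_ids: dict[str, str] = dict(alt_ids or {})

        graph = nx.DiGraph()
        active = {tid for tid, t in self.terms.items() if not t.obsolete}
        graph.add_nodes_from(active)
        for tid in active:
            for parent in self.terms[tid].parents:
                if parent not in self.terms:
                    raise OntologyError(
                        f"term {tid!r} references unknown parent {parent!r}"
                    )
                graph.add_edge(tid, parent)

        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            child, parent = cycle[0][0], cycle[0][1]
            raise OntologyError(
                f"ontology contains a cycle through edge {child!r} is_a {parent!r}"
            )

        roots = sorted(tid for tid in active if not self.terms[tid].parents)
        if len(roots) != 1:
            raise OntologyError(
                f"expected exactly one root term, found {len(roots)}: {roots[:5]}"
            )
        self.root: str = roots[0]

        # Transitive closure in a single topological pass, leaves last so
        # each term's ancestors are its parents plus the parents' closures.
        self._ancestors: dict[str, frozenset[str]] = {}
        for tid in reversed(list(nx.topological_sort(graph))):
            anc: set[str] = set()
            for parent in self.terms[tid].parents:
                anc.add(parent)
                anc |= self._ancestors[parent]
            self._ancestors[tid] = frozenset(anc)

    # -- lookups -----------------------------------------------------------

    def resolve(self, accession: str) -> str:
        """Map an accession (primary or alt_id) to its primary term id."""
        if accession in self.terms:
            return accession
        if accession in self.alt_ids:
            return self.alt_ids[accession]
        raise KeyError(f"unknown term accession {accession!r}")

    def __contains__(self, accession: str) -> bool:
        return accession in self.terms or accession in self.alt_ids

    def __len__(self) -> int:
        return len(self.terms)

    def ancestors(self, accession: str) -> frozenset[str]:
        """Proper ancestors of a term (term excluded, root included)."""
        return self._ancestors[self.resolve(accession)]

    def ancestors_or_self(self, accession: str) -> frozenset[str]:
        tid = self.resolve(accession)
        return self._ancestors[tid] | {tid}

    def is_obsolete(self, accession: str) -> bool:
        return self.terms[self.resolve(accession)].obsolete

    def active_terms(self) -> list[str]:
        """All non-obsolete term accessions, sorted."""
        return sorted(t for t, term in self.terms.items() if not term.obsolete)


def load_ontology(obo_source: str | IO[str]) -> Ontology:
    """Parse an OBO 1.2 flat file into an :class:`Ontology`.

    ``[Term]`` stanzas are read with their ``id``, ``name``, ``is_a``,
    ``alt_id`` and ``is_obsolete`` tags.  Obsolete terms are retained but
    flagged; alternate accessions resolve to their primary term.  A cycle
    or an ambiguous root is a fatal error.

    Parameters
    ----------
    obo_source : path or readable text stream
    """
    graph = obonet.read_obo(obo_source, ignore_obsolete=False)
    terms: dict[str, Term] = {}
    alt_ids: dict[str, str] = {}
    for tid, data in graph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        parents = frozenset() if obsolete else frozenset(data.get("is_a", []))
        terms[tid] = Term(
            id=tid,
            name=data.get("name", ""),
            parents=parents,
            obsolete=obsolete,
        )
        for alt in data.get("alt_id", []):
            alt_ids[alt] = tid
    if not terms:
        raise OntologyError("no [Term] stanzas found in OBO source")
    return Ontology(terms, alt_ids)


def ontology_to_obo(ontology: Ontology) -> str:
    """Serialize an :class:`Ontology` back to OBO 1.2 text.

    Used to materialize synthetic fixtures for the command-line surface;
    round-trips through :func:`load_ontology`.
    """
    lines = ["format-version: 1.2", "ontology: hporank-fixture", ""]
    alt_by_primary: dict[str, list[str]] = {}
    for alt, primary in ontology.alt_ids.items():
        alt_by_primary.setdefault(primary, []).append(alt)
    for tid in sorted(ontology.terms):
        term = ontology.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {term.id}")
        if term.name:
            lines.append(f"name: {term.name}")
        for alt in sorted(alt_by_primary.get(tid, [])):
            lines.append(f"alt_id: {alt}")
        for parent in sorted(term.parents):
            lines.append(f"is_a: {parent}")
        if term.obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    return "\n".join(lines)
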