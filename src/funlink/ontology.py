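"""Minimal ontology DAG and gene-annotation corpus.

The ontology is the is_a skeleton of a GO-style vocabulary: terms with
names and an aspect (BP/MF/CC), and child -> parent ``is_a`` edges.
Annotations are up-propagated through the is_a closure before any set
comparison ("a gene annotated to a term is annotated to all its
ancestors"), and predicted terms may be matched against known ones
through the descendant (more-specific) direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import networkx as nx

ASPECTS = ("BP", "MF", "CC")
#: GAF single-letter aspect codes.
GAF_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}
ASPECT_TO_GAF = {v: k for k, v in GAF_ASPECT.items()}
#: OBO namespace strings.
OBO_NAMESPACE = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}
ASPECT_TO_OBO = {v: k for k, v in OBO_NAMESPACE.items()}


@dataclass(frozen=True)
class Term:
    id: str
    name: str
    aspect: str


class OntologyError(ValueError):
    pass


class OntologyDag:
    """An acyclic is_a hierarchy split into the three GO aspects."""

    def __init__(self, terms: Iterable[Term], is_a: Mapping[str, Iterable[str]]):
        self.terms: dict[str, Term] = {}
        for t in terms:
            if t.aspect not in ASPECTS:
                raise OntologyError(f"unknown aspect {t.aspect!r} for term {t.id}")
            if t.id in self.terms:
                raise OntologyError(f"duplicate term id {t.id}")
            self.terms[t.id] = t
        self._parents: dict[str, frozenset[str]] = {t: frozenset() for t in self.terms}
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parents in is_a.items():
            if child not in self.terms:
                raise OntologyError(f"is_a child {child!r} is not a declared term")
            ps = frozenset(parents)
            for p in ps:
                if p not in self.terms:
                    raise OntologyError(f"is_a parent {p!r} is not a declared term")
                if self.terms[p].aspect != self.terms[child].aspect:
                    raise OntologyError(
                        f"is_a edge {child}->{p} crosses aspects"
                    )
                g.add_edge(child, p)
            self._parents[child] = ps
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise OntologyError(f"ontology contains an is_a cycle: {cyc}")
        self._graph = g
        self._children: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, ps in self._parents.items():
            for p in ps:
                self._children[p].add(child)
        # every non-root term must reach its aspect root
        roots = self.roots()
        for tid, term in self.terms.items():
            if tid in roots.values():
                continue
            anc = self.ancestors(tid)
            if roots.get(term.aspect) not in anc:
                raise OntologyError(
                    f"term {tid} has no is_a path to its aspect root"
                )

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def roots(self) -> dict[str, str]:
        """One root per aspect (the unique parent-less term)."""
        out: dict[str, str] = {}
        for tid, term in self.terms.items():
            if not self._parents[tid]:
                if term.aspect in out:
                    raise OntologyError(
                        f"aspect {term.aspect} has multiple roots "
                        f"({out[term.aspect]}, {tid})"
                    )
                out[term.aspect] = tid
        return out

    def parents(self, term_id: str) -> frozenset[str]:
        return self._parents[term_id]

    def children(self, term_id: str) -> frozenset[str]:
        return frozenset(self._children[term_id])

    def ancestors(self, term_id: str, include_self: bool = False) -> frozenset[str]:
        """Transitive is_a closure upward (excluding the term itself by
        default)."""
        if term_id not in self.terms:
            raise KeyError(f"unknown term {term_id!r}")
        out = self._ancestors_cached(term_id)
        return out | {term_id} if include_self else out

    @lru_cache(maxsize=None)
    def _ancestors_cached(self, term_id: str) -> frozenset[str]:
        acc: set[str] = set()
        for p in self._parents[term_id]:
            acc.add(p)
            acc |= self._ancestors_cached(p)
        return frozenset(acc)

    def descendants(self, term_id: str, include_self: bool = False) -> frozenset[str]:
        """Transitive closure downward: the term's more specific terms."""
        if term_id not in self.terms:
            raise KeyError(f"unknown term {term_id!r}")
        out = self._descendants_cached(term_id)
        return out | {term_id} if include_self else out

    @lru_cache(maxsize=None)
    def _descendants_cached(self, term_id: str) -> frozenset[str]:
        acc: set[str] = set()
        for c in self._children[term_id]:
            acc.add(c)
            acc |= self._descendants_cached(c)
        return frozenset(acc)

    def leaves(self, aspect: str | None = None) -> list[str]:
        return sorted(
            t
            for t in self.terms
            if not self._children[t]
            and (aspect is None or self.terms[t].aspect == aspect)
        )


@dataclass
class AnnotationCorpus:
    """Gene -> ontology-term annotations, partitioned by aspect.

    ``by_aspect[aspect][gene]`` is the set of term ids annotated to the
    gene in that aspect.  ``dates`` optionally records an annotation
    date string per ``(gene, term)`` pair (GAF column 14 style,
    YYYYMMDD), which time-split evaluation uses.
    """

    by_aspect: dict[str, dict[str, set[str]]] = field(
        default_factory=lambda: {a: {} for a in ASPECTS}
    )
    dates: dict[tuple[str, str], str] = field(default_factory=dict)

    def add(self, gene: str, term: str, aspect: str, date: str | None = None) -> None:
        if aspect not in ASPECTS:
            raise ValueError(f"unknown aspect {aspect!r}")
        self.by_aspect.setdefault(aspect, {}).setdefault(gene, set()).add(term)
        if date is not None:
            self.dates[(gene, term)] = date

    def genes(self, aspect: str | None = None) -> set[str]:
        if aspect is not None:
            return set(self.by_aspect.get(aspect, {}))
        out: set[str] = set()
        for d in self.by_aspect.values():
            out |= set(d)
        return out

    def terms_of(self, gene: str, aspect: str) -> set[str]:
        return set(self.by_aspect.get(aspect, {}).get(gene, set()))

    def n_annotations(self) -> int:
        return sum(
            len(ts) for d in self.by_aspect.values() for ts in d.values()
        )

    def validate_against(self, dag: OntologyDag) -> None:
        """Every annotated term must exist in the companion ontology and
        sit in the aspect it is filed under."""
        for aspect, d in self.by_aspect.items():
            for gene, ts in d.items():
                for t in ts:
                    if t not in dag:
                        raise OntologyError(
                            f"annotation {gene}->{t} refers to unknown term"
                        )
                    if dag.terms[t].aspect != aspect:
                        raise OntologyError(
                            f"annotation {gene}->{t} filed under {aspect} but "
                            f"term aspect is {dag.terms[t].aspect}"
                        )

    def propagate(self, dag: OntologyDag) -> "AnnotationCorpus":
        """Up-propagate every annotation through the is_a closure.

        The returned corpus contains, per gene and aspect, the union of
        the direct terms and all their ancestors.  Dates carry over for
        direct annotations only (propagated ancestors have no date of
        their own).
        """
        out = AnnotationCorpus(dates=dict(self.dates))
        for aspect, d in self.by_aspect.items():
            for gene, ts in d.items():
                closed: set[str] = set()
                for t in ts:
                    closed |= dag.ancestors(t, include_self=True)
                out.by_aspect.setdefault(aspect, {})[gene] = closed
        return out


def balanced_tree_ontology(
    depth: int = 4,
    branching: int = 3,
    aspects: Iterable[str] = ASPECTS,
    prefix: str = "T",
) -> OntologyDag:
    """A balanced is_a tree per aspect — handy as a synthetic GO stand-in.

    Term ids look like ``T:BP:0``, the per-aspect root being node 0 of a
    balanced tree of the given depth and branching factor.
    """
    terms: list[Term] = []
    is_a: dict[str, list[str]] = {}
    for aspect in aspects:
        n = sum(branching**d for d in range(depth))
        for i in range(n):
            tid = f"{prefix}:{aspect}:{i}"
            terms.append(Term(tid, f"{aspect} term {i}", aspect))
            if i > 0:
                parent = (i - 1) // branching
                is_a[tid] = [f"{prefix}:{aspect}:{parent}"]
    return OntologyDag(terms, is_a)
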