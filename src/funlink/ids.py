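"""Gene identifiers, canonical unordered pairs, and identifier mapping.

All genes are referred to by a single canonical string identifier
(by convention a namespaced accession such as ``"RGD:2004"``, but any
non-empty string works).  Undirected gene pairs are always stored in
canonical (sorted) order so that ``(a, b)`` and ``(b, a)`` denote the
same edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

GeneId = str
Pair = tuple[str, str]


def canonical_pair(a: GeneId, b: GeneId) -> Pair:
    """Return the canonical (sorted) form of an unordered gene pair.

    Raises
    ------
    ValueError
        If the two identifiers are equal (self-pairs are not valid
        undirected edges) or either identifier is empty.
    """
    if not a or not b:
        raise ValueError("gene identifiers must be non-empty strings")
    if a == b:
        raise ValueError(f"self-pair is not a valid gene pair: {a!r}")
    return (a, b) if a < b else (b, a)


def canonical_pairs(pairs: Iterable[tuple[GeneId, GeneId]]) -> list[Pair]:
    """Canonicalize an iterable of pairs, de-duplicating while keeping order."""
    seen: set[Pair] = set()
    out: list[Pair] = []
    for a, b in pairs:
        p = canonical_pair(a, b)
        if p not in seen:
            seen.add(p)
            out.append(p)
    return out


@dataclass(frozen=True)
class MappingResult:
    """Outcome of mapping foreign identifiers to canonical gene ids.

    ``mapped`` preserves the input order of the (de-duplicated) queries;
    ``unmapped`` lists queries with no entry in the map; ``collisions``
    records groups of distinct foreign ids that resolved to the same
    canonical id (the canonical id is kept once).
    """

    mapped: list[GeneId]
    unmapped: list[str]
    collisions: dict[GeneId, list[str]] = field(default_factory=dict)


class IdMap:
    """A user-supplied table mapping foreign identifiers to canonical ids.

    Entries are keyed by ``(namespace, foreign_id)``.  Lookup without a
    namespace searches all namespaces and reports an ambiguity (treated
    as unmapped) when different namespaces disagree on the target.
    """

    def __init__(self, entries: Mapping[tuple[str, str], GeneId]):
        self._entries: dict[tuple[str, str], GeneId] = {}
        for (ns, fid), gid in entries.items():
            if not gid:
                raise ValueError(f"empty target id for {(ns, fid)!r}")
            self._entries[(ns, fid)] = gid
        self._by_foreign: dict[str, set[GeneId]] = {}
        for (ns, fid), gid in self._entries.items():
            self._by_foreign.setdefault(fid, set()).add(gid)

    @property
    def namespaces(self) -> set[str]:
        return {ns for ns, _ in self._entries}

    def __len__(self) -> int:
        return len(self._entries)

    def lookup(self, foreign_id: str, namespace: str | None = None) -> GeneId | None:
        """Resolve one foreign id; ``None`` if absent or ambiguous."""
        if namespace is not None:
            return self._entries.get((namespace, foreign_id))
        targets = self._by_foreign.get(foreign_id)
        if targets is None or len(targets) != 1:
            if targets:
                logger.warning("ambiguous id %r maps to %d targets", foreign_id, len(targets))
            return None
        return next(iter(targets))


def identity_map(ids: Iterable[GeneId], namespace: str = "canonical") -> IdMap:
    """An IdMap sending every listed id to itself (useful default)."""
    return IdMap({(namespace, g): g for g in ids})


def map_ids(ids: Iterable[str], idmap: IdMap, namespace: str | None = None) -> MappingResult:
    """Map a list of foreign identifiers to canonical gene ids.

    Queries are de-duplicated preserving first occurrence.  Distinct
    foreign ids that collapse onto one canonical id are reported in
    ``collisions`` (and logged); the canonical id appears once in
    ``mapped``.
    """
    seen_query: set[str] = set()
    mapped: list[GeneId] = []
    unmapped: list[str] = []
    sources: dict[GeneId, list[str]] = {}
    for q in ids:
        if q in seen_query:
            continue
        seen_query.add(q)
        gid = idmap.lookup(q, namespace)
        if gid is None:
            unmapped.append(q)
        else:
            sources.setdefault(gid, []).append(q)
            if len(sources[gid]) == 1:
                mapped.append(gid)
    collisions = {g: src for g, src in sources.items() if len(src) > 1}
    for gid, src in collisions.items():
        logger.info("foreign ids %s all map to %s; kept once", src, gid)
    return MappingResult(mapped=mapped, unmapped=unmapped, collisions=collisions)
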