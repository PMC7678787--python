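"""Readers and writers for every external format the toolkit touches.

All tabular inputs are plain TSV with a header row.  The GO-style
formats are GAF 2.x for annotations and OBO for the ontology skeleton
(parsed with :mod:`obonet`; only ``is_a`` edges are kept).  Every
writer/reader pair round-trips the in-memory object exactly.

Malformed lines raise :class:`FormatError` carrying the 1-based line
number.  Cross-reference problems that are recoverable (e.g. a GAF row
naming a term absent from the companion ontology) are skipped with a
warning and counted in a :class:`LoadReport`.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import obonet
import pandas as pd

from .ids import GeneId, Pair, canonical_pair
from .network import Interactome
from .ontology import (
    ASPECT_TO_GAF,
    ASPECT_TO_OBO,
    GAF_ASPECT,
    OBO_NAMESPACE,
    AnnotationCorpus,
    OntologyDag,
    OntologyError,
    Term,
)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file did not conform to its declared format."""

    def __init__(self, path: str | os.PathLike, line: int, message: str):
        self.path = str(path)
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


@dataclass
class LoadReport:
    """Bookkeeping for recoverable problems while loading a file."""

    n_rows: int = 0
    n_loaded: int = 0
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def skip(self, line: int, reason: str) -> None:
        self.skipped.append((line, reason))
        logger.warning("line %d skipped: %s", line, reason)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def _read_tsv(path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message
        raise FormatError(path, 0, str(exc)) from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(path, 1, f"missing required columns {missing}")
    return df


def _parse_float(path, line: int, text: str, what: str) -> float:
    try:
        v = float(text)
    except ValueError:
        raise FormatError(path, line, f"bad {what} {text!r}") from None
    if not np.isfinite(v):
        raise FormatError(path, line, f"non-finite {what} {text!r}")
    return v


# ---------------------------------------------------------------- interactions
def write_interactions(net: Interactome, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\torigin\n")
        for (a, b), w, o in net.edges():
            fh.write(f"{a}\t{b}\t{w!r}\t{o}\n")
        for g in net.nodes:
            if net.degree(g) == 0:
                fh.write(f"{g}\t-\t0.0\tpredicted\n")


def read_interactions(path) -> Interactome:
    """Interaction TSV (gene_a, gene_b, weight, origin) -> Interactome.

    A row with ``gene_b == "-"`` declares an isolated node.
    """
    df = _read_tsv(path, ["gene_a", "gene_b", "weight", "origin"])
    net = Interactome()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.gene_b == "-":
            net.add_node(row.gene_a)
            continue
        w = _parse_float(path, i, row.weight, "weight")
        try:
            net.add_edge(row.gene_a, row.gene_b, w, row.origin)
        except ValueError as exc:
            raise FormatError(path, i, str(exc)) from exc
    return net


# ------------------------------------------------------------------------ GAF
#: GAF 2.x column names (17 columns).
GAF_COLUMNS = [
    "db", "db_object_id", "db_object_symbol", "qualifier", "go_id",
    "db_reference", "evidence_code", "with_from", "aspect",
    "db_object_name", "synonym", "db_object_type", "taxon", "date",
    "assigned_by", "annotation_extension", "gene_product_form_id",
]


def write_gaf(corpus: AnnotationCorpus, path, db: str = "FUNLINK") -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        rows = []
        for aspect, d in corpus.by_aspect.items():
            for gene, ts in d.items():
                for t in sorted(ts):
                    rows.append((gene, t, aspect))
        for gene, t, aspect in sorted(rows):
            date = corpus.dates.get((gene, t), "20170101")
            cols = [""] * 17
            cols[0] = db
            cols[1] = gene
            cols[2] = gene
            cols[4] = t
            cols[5] = "REF:0"
            cols[6] = "IEA"
            cols[8] = ASPECT_TO_GAF[aspect]
            cols[11] = "protein"
            cols[12] = "taxon:10116"
            cols[13] = date
            cols[14] = db
            fh.write("\t".join(cols) + "\n")


def read_gaf(
    path, dag: OntologyDag | None = None
) -> tuple[AnnotationCorpus, LoadReport]:
    """GAF 2.x -> AnnotationCorpus.

    The gene id is taken from DB_Object_ID verbatim.  When a companion
    ``dag`` is given, rows naming unknown terms (or terms filed under
    the wrong aspect) are skipped with a warning and counted in the
    returned :class:`LoadReport`; without a dag every row is kept.
    """
    corpus = AnnotationCorpus()
    report = LoadReport()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 15:
                raise FormatError(
                    path, lineno, f"expected >=15 GAF columns, got {len(cols)}"
                )
            report.n_rows += 1
            gene, term, aspect_code, date = cols[1], cols[4], cols[8], cols[13]
            if not gene or not term:
                raise FormatError(path, lineno, "empty gene or term id")
            if aspect_code not in GAF_ASPECT:
                raise FormatError(path, lineno, f"bad aspect code {aspect_code!r}")
            aspect = GAF_ASPECT[aspect_code]
            if dag is not None:
                if term not in dag:
                    report.skip(lineno, f"unknown term {term}")
                    continue
                if dag.terms[term].aspect != aspect:
                    report.skip(lineno, f"term {term} aspect mismatch")
                    continue
            corpus.add(gene, term, aspect, date or None)
            report.n_loaded += 1
    return corpus, report


# ------------------------------------------------------------------------ OBO
def write_obo(dag: OntologyDag, path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("ontology: funlink\n")
        for tid in sorted(dag.terms):
            term = dag.terms[tid]
            fh.write("\n[Term]\n")
            fh.write(f"id: {tid}\n")
            fh.write(f"name: {term.name}\n")
            fh.write(f"namespace: {ASPECT_TO_OBO[term.aspect]}\n")
            for p in sorted(dag.parents(tid)):
                fh.write(f"is_a: {p} ! {dag.terms[p].name}\n")


def read_obo(path) -> OntologyDag:
    """OBO 1.2/1.4 -> OntologyDag (is_a edges only; cycles are an error)."""
    graph = obonet.read_obo(path)
    terms: list[Term] = []
    is_a: dict[str, list[str]] = {}
    for tid, data in graph.nodes(data=True):
        ns = data.get("namespace", "")
        if ns not in OBO_NAMESPACE:
            raise OntologyError(f"term {tid} has unknown namespace {ns!r}")
        terms.append(Term(tid, data.get("name", tid), OBO_NAMESPACE[ns]))
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            is_a.setdefault(child, []).append(parent)
    return OntologyDag(terms, is_a)  # raises OntologyError on cycles


# ----------------------------------------------------------------- matrices
def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_expression(path) -> pd.DataFrame:
    """Expression TSV (genes x samples, real-valued)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(path, 0, f"duplicate gene row {dup!r}")
    return df.astype(float)


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.astype(int).to_csv(path, sep="\t", index_label="gene")


def read_profiles(path) -> pd.DataFrame:
    """Phylogenetic profile TSV (genes x species, entries 0/1)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise FormatError(path, 0, "profile entries must be 0 or 1")
    return df.astype(np.int8)


# -------------------------------------------------- two-column assignments
def write_assignments(assign: Mapping[str, Iterable[str]], path,
                      value_name: str = "value") -> None:
    with open(path, "w") as fh:
        fh.write(f"gene\t{value_name}\n")
        for gene in sorted(assign):
            for v in sorted(assign[gene]):
                fh.write(f"{gene}\t{v}\n")


def read_assignments(path) -> dict[str, set[str]]:
    """Two-column TSV (gene, value) -> gene -> set of values.

    Used for gene->compartment and gene->domain tables.
    """
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header or "\t" not in header:
            raise FormatError(path, 1, "expected a two-column TSV header")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise FormatError(path, lineno, f"expected 2 fields, got {line!r}")
            out.setdefault(parts[0], set()).add(parts[1])
    return out


# ------------------------------------------------------- domain-pair scores
def write_domain_scores(scores: Mapping[tuple[str, str], float], path) -> None:
    with open(path, "w") as fh:
        fh.write("domain_a\tdomain_b\tscore\n")
        for (da, db) in sorted(scores):
            fh.write(f"{da}\t{db}\t{scores[(da, db)]!r}\n")


def read_domain_scores(path) -> dict[tuple[str, str], float]:
    """Domain-pair score TSV -> {(domain_a, domain_b) sorted: score}."""
    df = _read_tsv(path, ["domain_a", "domain_b", "score"])
    out: dict[tuple[str, str], float] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        key = tuple(sorted((row.domain_a, row.domain_b)))
        out[key] = _parse_float(path, i, row.score, "score")
    return out


# ----------------------------------------------------------- ortholog data
@dataclass
class OrthologData:
    """Per reference species: a gene -> ortholog map and the set of
    ortholog pairs reported to interact in that species."""

    maps: dict[str, dict[GeneId, set[str]]] = field(default_factory=dict)
    interactions: dict[str, set[Pair]] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return sorted(set(self.maps) | set(self.interactions))

    def add_ortholog(self, species: str, gene: GeneId, ortholog: str) -> None:
        self.maps.setdefault(species, {}).setdefault(gene, set()).add(ortholog)

    def add_interaction(self, species: str, a: str, b: str) -> None:
        self.interactions.setdefault(species, set()).add(canonical_pair(a, b))

    def has_orthologs(self, gene: GeneId) -> bool:
        return any(gene in m for m in self.maps.values())


def write_ortholog_data(data: OrthologData, map_path, interactions_path) -> None:
    with open(map_path, "w") as fh:
        fh.write("species\tgene\tortholog\n")
        for sp in sorted(data.maps):
            for gene in sorted(data.maps[sp]):
                for o in sorted(data.maps[sp][gene]):
                    fh.write(f"{sp}\t{gene}\t{o}\n")
    with open(interactions_path, "w") as fh:
        fh.write("species\tortholog_a\tortholog_b\n")
        for sp in sorted(data.interactions):
            for a, b in sorted(data.interactions[sp]):
                fh.write(f"{sp}\t{a}\t{b}\n")


def read_ortholog_data(map_path, interactions_path) -> OrthologData:
    """Ortholog map + reference-species interaction list -> OrthologData."""
    data = OrthologData()
    df = _read_tsv(map_path, ["species", "gene", "ortholog"])
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if not row.species or not row.gene or not row.ortholog:
            raise FormatError(map_path, i, "empty field in ortholog map")
        data.add_ortholog(row.species, row.gene, row.ortholog)
    df = _read_tsv(interactions_path, ["species", "ortholog_a", "ortholog_b"])
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            data.add_interaction(row.species, row.ortholog_a, row.ortholog_b)
        except ValueError as exc:
            raise FormatError(interactions_path, i, str(exc)) from exc
    return data


# -------------------------------------------------------------- gene lists
def write_gene_list(genes: Iterable[GeneId], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_list(path) -> list[GeneId]:
    """One id per line; blank lines ignored; order preserved."""
    out: list[GeneId] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            g = raw.strip()
            if not g:
                continue
            if "\t" in g or " " in g:
                raise FormatError(path, lineno, f"expected one id per line, got {g!r}")
            out.append(g)
    return out


# ---------------------------------------------------------------- id maps
def write_id_map(entries: Mapping[tuple[str, str], GeneId], path) -> None:
    with open(path, "w") as fh:
        fh.write("namespace\tforeign_id\tgene_id\n")
        for ns, fid in sorted(entries):
            fh.write(f"{ns}\t{fid}\t{entries[(ns, fid)]}\n")


def read_id_map(path):
    """ID-mapping TSV (namespace, foreign_id, gene_id) -> IdMap."""
    from .ids import IdMap

    df = _read_tsv(path, ["namespace", "foreign_id", "gene_id"])
    entries: dict[tuple[str, str], GeneId] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if not row.foreign_id or not row.gene_id:
            raise FormatError(path, i, "empty id in mapping row")
        entries[(row.namespace, row.foreign_id)] = row.gene_id
    return IdMap(entries)
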