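"""Benchmarking interactomes by neighbor-based gene function prediction.

Protocol: for every target gene (one that gained at least one new
annotation after a cutoff date), take its first-degree network
neighbors as a gene set, run hypergeometric over-representation
against the annotation corpus, and sweep the enrichment p-value
cutoff.  At each cutoff the micro-aggregated counts are

- N: terms predicted across all target genes,
- X: predicted terms that match the target's known annotations or
  their more specific (descendant) terms,
- Y: new annotations recovered — the new term itself or one of its
  descendants was predicted,

giving precision = X / N and recall = Y / (total new annotations);
the recall denominator is the fixed count of new annotations, never a
per-cutoff quantity.  Interactomes are ranked by the area under the
(recall, precision) sweep (trapezoidal AUPR).

The enrichment step is an in-package one-sided hypergeometric test on
is_a-propagated annotations; it stands in for the external enrichment
service the protocol was originally run through, and is declared as
such rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .ids import GeneId
from .network import Interactome
from .ontology import AnnotationCorpus, OntologyDag

#: Default p-value sweep, loose -> strict.
DEFAULT_CUTOFFS = (
    0.5, 0.2, 0.1, 0.05, 0.01, 1e-3, 1e-4, 1e-5, 1e-6, 1e-8, 1e-10, 1e-12,
)


@dataclass
class TimeSplitCorpus:
    """Annotations split by a cutoff date.

    ``corpus`` holds *all* annotations (the "known" side includes the
    new ones, matching the protocol's bookkeeping); ``new`` is the
    subset of direct (gene, term) annotations added after the cutoff.
    Target genes are exactly the genes with at least one new
    annotation.
    """

    corpus: AnnotationCorpus
    new: set[tuple[GeneId, str]]
    aspect: str = "BP"
    cutoff_date: str = "20180101"

    def __post_init__(self) -> None:
        universe = {
            (g, t)
            for g, ts in self.corpus.by_aspect.get(self.aspect, {}).items()
            for t in ts
        }
        stray = self.new - universe
        if stray:
            raise ValueError(f"{len(stray)} new annotations missing from the corpus")

    @property
    def target_genes(self) -> list[GeneId]:
        return sorted({g for g, _ in self.new})

    @property
    def n_new(self) -> int:
        return len(self.new)

    @classmethod
    def from_dates(
        cls, corpus: AnnotationCorpus, cutoff_date: str = "20180101", aspect: str = "BP"
    ) -> "TimeSplitCorpus":
        """Split on the per-annotation date records (GAF column 14)."""
        new = {
            (g, t)
            for g, ts in corpus.by_aspect.get(aspect, {}).items()
            for t in ts
            if corpus.dates.get((g, t), "") >= cutoff_date
        }
        return cls(corpus=corpus, new=new, aspect=aspect, cutoff_date=cutoff_date)


def neighbor_gene_set(interactome: Interactome, gene: GeneId) -> set[GeneId]:
    """All first-degree neighbors of the gene (the gene itself excluded)."""
    return interactome.neighbors(gene) - {gene}


def enrich_terms(
    gene_set: set[GeneId],
    corpus: AnnotationCorpus,
    dag: OntologyDag,
    background: set[GeneId] | None = None,
    aspect: str = "BP",
    propagated: AnnotationCorpus | None = None,
    term_members: dict[str, set[GeneId]] | None = None,
) -> list[tuple[str, float]]:
    """One-sided hypergeometric over-representation per term.

    Annotations are up-propagated before counting.  For each term with
    at least one hit in the gene set, the p-value is the upper tail of
    the hypergeometric distribution (probability of at least the
    observed overlap).  Results are ordered by (p, term id) so the
    output is deterministic.  ``term_members`` (term -> annotated
    background genes, propagated) may be precomputed by callers that
    sweep many gene sets.
    """
    if not gene_set:
        return []
    prop = propagated if propagated is not None else corpus.propagate(dag)
    ann = prop.by_aspect.get(aspect, {})
    if background is None:
        background = set(ann)
    M = len(background)
    genes_in = gene_set & background
    n = len(genes_in)
    if n == 0:
        return []
    if term_members is None:
        term_members = {}
        for g in background:
            for t in ann.get(g, ()):  # background genes only
                term_members.setdefault(t, set()).add(g)
    out = []
    for t, members in term_members.items():
        k = len(members & genes_in)
        if k == 0:
            continue
        p = float(hypergeom.sf(k - 1, M, len(members), n))
        out.append((t, min(p, 1.0)))
    out.sort(key=lambda tp: (tp[1], tp[0]))
    return out


def descendant_match(term: str, truth_terms: set[str], dag: OntologyDag) -> bool:
    """True iff the term is a truth term or a more specific descendant
    of one."""
    if term not in dag:
        raise KeyError(f"unknown term {term!r}")
    if term in truth_terms:
        return True
    return bool(dag.ancestors(term) & truth_terms)


@dataclass
class PREvalResult:
    """Per-cutoff (N, X, Y, precision, recall) sweep with its AUPR."""

    table: pd.DataFrame
    aupr: float
    n_new: int
    n_targets_evaluated: int = 0


def pr_sweep(
    interactome: Interactome,
    split: TimeSplitCorpus,
    dag: OntologyDag,
    cutoffs=DEFAULT_CUTOFFS,
) -> PREvalResult:
    """Micro-aggregated precision/recall over the enrichment p sweep."""
    cutoffs = list(cutoffs)
    if any(b >= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be sorted strictly descending (loose -> strict)")
    prop = split.corpus.propagate(dag)
    ann = prop.by_aspect.get(split.aspect, {})
    direct = split.corpus.by_aspect.get(split.aspect, {})
    background = set(ann)
    targets = [
        g
        for g in split.target_genes
        if interactome.has_node(g) and neighbor_gene_set(interactome, g)
    ]
    if not targets:
        raise ValueError("nothing to evaluate: no target gene has network neighbors")
    new_by_gene: dict[GeneId, set[str]] = {}
    for g, t in split.new:
        new_by_gene.setdefault(g, set()).add(t)

    term_members: dict[str, set[GeneId]] = {}
    for g in background:
        for t in ann.get(g, ()):
            term_members.setdefault(t, set()).add(g)

    # per-gene enrichment once, thresholded per cutoff afterwards
    per_gene: list[tuple[GeneId, list[tuple[str, float]]]] = []
    for g in targets:
        preds = enrich_terms(
            neighbor_gene_set(interactome, g),
            split.corpus,
            dag,
            background=background,
            aspect=split.aspect,
            propagated=prop,
            term_members=term_members,
        )
        per_gene.append((g, preds))

    desc_cache: dict[str, frozenset[str]] = {}

    def descendants_plus_self(t: str) -> frozenset[str]:
        if t not in desc_cache:
            desc_cache[t] = dag.descendants(t, include_self=True)
        return desc_cache[t]

    rows = []
    for cutoff in cutoffs:
        N = X = Y = 0
        for g, preds in per_gene:
            predicted = {t for t, p in preds if p <= cutoff}
            if not predicted:
                continue
            # match against the gene's direct annotations: a predicted
            # term counts when it is one of them or a more specific
            # descendant (the propagated closure would trivially match
            # everything through the aspect root)
            known = direct.get(g, set())
            N += len(predicted)
            X += sum(1 for t in predicted if descendant_match(t, known, dag))
            for t_new in new_by_gene.get(g, ()):  # new term or a descendant predicted
                if predicted & descendants_plus_self(t_new):
                    Y += 1
        precision = X / N if N else np.nan
        recall = Y / split.n_new if split.n_new else 0.0
        rows.append(
            {"cutoff": cutoff, "N": N, "X": X, "Y": Y,
             "precision": precision, "recall": recall}
        )
    table = pd.DataFrame.from_records(rows)
    valid = table.dropna(subset=["precision"]).sort_values("recall")
    if len(valid) >= 2:
        aupr = float(np.trapezoid(valid["precision"], valid["recall"]))
    else:
        aupr = 0.0
    return PREvalResult(
        table=table, aupr=aupr, n_new=split.n_new, n_targets_evaluated=len(targets)
    )


@dataclass
class InteractomeComparison:
    """Ranked AUPR table plus the per-network PR sweeps."""

    ranking: pd.DataFrame
    results: dict[str, PREvalResult] = field(default_factory=dict)

    def plot(self, ax=None):
        """Precision-recall curves, one per interactome."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name in self.ranking["interactome"]:
            t = self.results[name].table.dropna(subset=["precision"])
            ax.plot(t["recall"], t["precision"], marker="o", label=name)
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
        ax.legend()
        return ax


def compare_interactomes(
    interactomes: dict[str, Interactome],
    split: TimeSplitCorpus,
    dag: OntologyDag,
    cutoffs=DEFAULT_CUTOFFS,
) -> InteractomeComparison:
    """Run the PR sweep on each network and rank by AUPR (descending)."""
    results = {
        name: pr_sweep(net, split, dag, cutoffs) for name, net in interactomes.items()
    }
    ranking = pd.DataFrame.from_records(
        [
            {"interactome": name, "aupr": r.aupr,
             "n_targets": r.n_targets_evaluated}
            for name, r in results.items()
        ]
    ).sort_values(["aupr", "interactome"], ascending=[False, True], ignore_index=True)
    return InteractomeComparison(ranking=ranking, results=results)
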