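"""The evidence compendium: all six evidence layers for one gene universe.

Layers (any gene may be absent from any layer — that is the
missing-data case the feature computation handles):

- expression: genes x samples real matrix
- annotations: AnnotationCorpus + companion OntologyDag
- localization: gene -> set of subcellular compartments
- domains: gene -> set of protein domains, plus a domain-pair score table
- profiles: genes x species binary phylogenetic presence/absence matrix
- orthologs: per reference species, ortholog map + interacting pairs
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as fio
from .ids import GeneId
from .io import OrthologData
from .ontology import AnnotationCorpus, OntologyDag


@dataclass
class EvidenceCompendium:
    genes: list[GeneId]
    expression: pd.DataFrame | None = None
    annotations: AnnotationCorpus = field(default_factory=AnnotationCorpus)
    ontology: OntologyDag | None = None
    localization: dict[GeneId, set[str]] = field(default_factory=dict)
    domains: dict[GeneId, set[str]] = field(default_factory=dict)
    ddi_scores: dict[tuple[str, str], float] = field(default_factory=dict)
    profiles: pd.DataFrame | None = None
    orthologs: OrthologData = field(default_factory=OrthologData)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene universe contains duplicates")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    # Fixed per-directory filenames so a compendium can live on disk as
    # a plain folder of text files.
    _FILES = {
        "genes": "genes.txt",
        "expression": "expression.tsv",
        "gaf": "annotations.gaf",
        "obo": "ontology.obo",
        "localization": "localization.tsv",
        "domains": "domains.tsv",
        "ddi": "ddi_scores.tsv",
        "profiles": "profiles.tsv",
        "ortho_map": "ortholog_map.tsv",
        "ortho_int": "ortholog_interactions.tsv",
    }

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        fio.write_gene_list(self.genes, d / self._FILES["genes"])
        if self.expression is not None:
            fio.write_expression(self.expression, d / self._FILES["expression"])
        fio.write_gaf(self.annotations, d / self._FILES["gaf"])
        if self.ontology is not None:
            fio.write_obo(self.ontology, d / self._FILES["obo"])
        fio.write_assignments(
            self.localization, d / self._FILES["localization"], "compartment"
        )
        fio.write_assignments(self.domains, d / self._FILES["domains"], "domain")
        fio.write_domain_scores(self.ddi_scores, d / self._FILES["ddi"])
        if self.profiles is not None:
            fio.write_profiles(self.profiles, d / self._FILES["profiles"])
        fio.write_ortholog_data(
            self.orthologs, d / self._FILES["ortho_map"], d / self._FILES["ortho_int"]
        )

    @classmethod
    def load(cls, directory) -> "EvidenceCompendium":
        d = Path(directory)
        genes = fio.read_gene_list(d / cls._FILES["genes"])
        ontology = None
        if os.path.exists(d / cls._FILES["obo"]):
            ontology = fio.read_obo(d / cls._FILES["obo"])
        corpus, _ = fio.read_gaf(d / cls._FILES["gaf"], dag=ontology)
        expr = None
        if os.path.exists(d / cls._FILES["expression"]):
            expr = fio.read_expression(d / cls._FILES["expression"])
        profiles = None
        if os.path.exists(d / cls._FILES["profiles"]):
            profiles = fio.read_profiles(d / cls._FILES["profiles"])
        return cls(
            genes=genes,
            expression=expr,
            annotations=corpus,
            ontology=ontology,
            localization=fio.read_assignments(d / cls._FILES["localization"]),
            domains=fio.read_assignments(d / cls._FILES["domains"]),
            ddi_scores=fio.read_domain_scores(d / cls._FILES["ddi"]),
            profiles=profiles,
            orthologs=fio.read_ortholog_data(
                d / cls._FILES["ortho_map"], d / cls._FILES["ortho_int"]
            ),
        )
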