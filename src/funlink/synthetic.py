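"""Synthetic evidence generator with planted functional modules.

The generator emulates the six evidence layers the predictor consumes
— co-expression, shared GO-style annotation, co-localization,
domain–domain interaction, phylogenetic profiles and interologs — for
a gene universe in which disjoint functional modules are planted.
Within-module gene pairs are the ground-truth positive interactions; a
configured fraction of them is withheld from training to emulate a
publication-date split.  Every layer's planted signal strength and
missingness rate is tunable, and a signal of zero makes the layer
statistically indistinguishable between planted and background pairs.

All randomness flows from ``FixtureConfig.seed`` through independent
per-layer streams, so changing one layer's parameters never perturbs
another layer's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd

from .compendium import EvidenceCompendium
from .ids import GeneId, Pair, canonical_pair
from .io import OrthologData
from .network import Interactome
from .ontology import ASPECTS, AnnotationCorpus, balanced_tree_ontology

EVIDENCE_LAYERS = (
    "expression",
    "annotation",
    "localization",
    "domain",
    "phylogenetic",
    "interolog",
)


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic compendium.

    Signal levels are per evidence layer: the within-module expression
    correlation, and planting probabilities for annotation sharing,
    co-localization, domain-pair scoring, phylogenetic profile
    agreement and interologs.  ``missingness`` removes a gene from a
    layer entirely with the given per-layer probability.
    """

    n_genes: int = 200
    n_modules: int = 6
    module_size_range: tuple[int, int] = (4, 6)
    n_samples: int = 20
    n_terms_per_aspect: int = 40
    n_species: int = 20
    n_ref_species: int = 3
    n_domains: int = 40
    n_compartments: int = 12
    expression_rho: float = 0.7
    annotation_sharing: float = 0.8
    colocalization: float = 0.7
    ddi_planting: float = 0.7
    profile_agreement: float = 0.85
    interolog: float = 0.5
    ortholog_coverage: float = 0.8
    heldout_fraction: float = 0.3
    missingness: dict = field(
        default_factory=lambda: {layer: 0.1 for layer in EVIDENCE_LAYERS}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.module_size_range
        if lo < 2 or hi < lo:
            raise ValueError("module sizes must satisfy 2 <= min <= max")
        if self.n_samples < 3:
            raise ValueError("need at least 3 expression samples")
        for name in (
            "expression_rho",
            "annotation_sharing",
            "colocalization",
            "ddi_planting",
            "profile_agreement",
            "interolog",
            "ortholog_coverage",
            "heldout_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for layer, r in self.missingness.items():
            if layer not in EVIDENCE_LAYERS:
                raise ValueError(f"unknown evidence layer {layer!r}")
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missingness[{layer!r}] must be in [0, 1]")

    def with_signals(self, **levels: float) -> "FixtureConfig":
        """Convenience: a copy with some signal levels replaced."""
        return replace(self, **levels)


@dataclass
class PlantedTruth:
    """Ground truth for a generated compendium."""

    genes: list[GeneId]
    module_of: dict[GeneId, int]
    modules: dict[int, list[GeneId]]
    positives: set[Pair]
    heldout: set[Pair]
    module_terms: dict[int, dict[str, str]]

    def __post_init__(self) -> None:
        if self.positives & self.heldout:
            raise ValueError("training and held-out positives overlap")

    @property
    def all_positives(self) -> set[Pair]:
        return self.positives | self.heldout

    def background_pairs(self, n: int, seed: int = 0) -> list[Pair]:
        """Sample n non-positive pairs uniformly (without replacement)."""
        rng = np.random.default_rng(seed)
        genes = self.genes
        pos = self.all_positives
        out: set[Pair] = set()
        n_total = len(genes) * (len(genes) - 1) // 2
        if n > n_total - len(pos):
            raise ValueError("not enough background pairs")
        while len(out) < n:
            i, j = rng.integers(0, len(genes), size=2)
            if i == j:
                continue
            p = canonical_pair(genes[i], genes[j])
            if p not in pos:
                out.add(p)
        return sorted(out)


def _module_layout(cfg: FixtureConfig, rng: np.random.Generator):
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    lo, hi = cfg.module_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_modules)
    if int(sizes.sum()) > cfg.n_genes:
        raise ValueError(
            f"modules need {int(sizes.sum())} genes but universe has {cfg.n_genes}"
        )
    modules: dict[int, list[GeneId]] = {}
    module_of: dict[GeneId, int] = {}
    cursor = 0
    for m, s in enumerate(sizes):
        block = genes[cursor : cursor + int(s)]
        modules[m] = block
        for g in block:
            module_of[g] = m
        cursor += int(s)
    return genes, modules, module_of


def _missing_genes(genes, rate: float, rng: np.random.Generator) -> set[GeneId]:
    return {g for g in genes if rng.random() < rate}


def generate_compendium(cfg: FixtureConfig) -> tuple[EvidenceCompendium, PlantedTruth]:
    """Generate all six evidence layers plus planted ground truth."""
    streams = np.random.SeedSequence(cfg.seed).spawn(10)
    rng_layout, rng_expr, rng_ann, rng_loc, rng_dom, rng_phy, rng_orth, rng_split, rng_missing, _ = (
        np.random.default_rng(s) for s in streams
    )

    genes, modules, module_of = _module_layout(cfg, rng_layout)

    # ground truth: every within-module pair interacts; a fraction is
    # withheld to stand in for interactions published after the cutoff
    all_pos = sorted(
        canonical_pair(a, b)
        for block in modules.values()
        for a, b in combinations(block, 2)
    )
    n_held = int(round(cfg.heldout_fraction * len(all_pos)))
    held_idx = set(
        rng_split.choice(len(all_pos), size=n_held, replace=False).tolist()
    )
    heldout = {p for i, p in enumerate(all_pos) if i in held_idx}
    positives = set(all_pos) - heldout

    miss = {
        layer: _missing_genes(genes, cfg.missingness.get(layer, 0.0), rng_missing)
        for layer in EVIDENCE_LAYERS
    }

    # ---- expression: module genes mix a shared latent sample profile
    samples = [f"S{j:02d}" for j in range(cfg.n_samples)]
    latent = rng_expr.standard_normal((cfg.n_modules, cfg.n_samples))
    rows = {}
    for g in genes:
        noise = rng_expr.standard_normal(cfg.n_samples)
        m = module_of.get(g)
        if m is not None and cfg.expression_rho > 0:
            x = np.sqrt(cfg.expression_rho) * latent[m] + np.sqrt(
                1 - cfg.expression_rho
            ) * noise
        else:
            x = noise
        if g not in miss["expression"]:
            rows[g] = x
    expression = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    expression.index.name = "gene"

    # ---- annotations: a balanced is_a tree per aspect; each module owns
    # one leaf term per aspect
    branching, depth = 3, 2
    while sum(branching**d for d in range(depth)) < cfg.n_terms_per_aspect:
        depth += 1
    dag = balanced_tree_ontology(depth=depth, branching=branching)
    module_terms: dict[int, dict[str, str]] = {}
    corpus = AnnotationCorpus()
    for aspect in ASPECTS:
        leaves = dag.leaves(aspect)
        if len(leaves) < cfg.n_modules:
            raise ValueError("ontology too small for the number of modules")
        for m in modules:
            module_terms.setdefault(m, {})[aspect] = leaves[m]
        for g in genes:
            if g in miss["annotation"]:
                continue
            m = module_of.get(g)
            if m is not None and rng_ann.random() < cfg.annotation_sharing:
                corpus.add(g, module_terms[m][aspect], aspect, "20170101")
            if rng_ann.random() < 0.6:
                t = leaves[int(rng_ann.integers(0, len(leaves)))]
                corpus.add(g, t, aspect, "20170101")

    # ---- localization: each module has a home compartment
    compartments = [f"C{j:02d}" for j in range(cfg.n_compartments)]
    localization: dict[GeneId, set[str]] = {}
    for g in genes:
        if g in miss["localization"]:
            continue
        comps: set[str] = set()
        m = module_of.get(g)
        if m is not None and rng_loc.random() < cfg.colocalization:
            comps.add(compartments[m % cfg.n_compartments])
        comps.add(compartments[int(rng_loc.integers(0, cfg.n_compartments))])
        if rng_loc.random() < 0.3:
            comps.add(compartments[int(rng_loc.integers(0, cfg.n_compartments))])
        localization[g] = comps

    # ---- domains: each module owns a scored domain pair; background
    # domains and a sprinkle of background DDI scores
    n_reserved = 2 * cfg.n_modules
    if cfg.n_domains <= n_reserved:
        raise ValueError("n_domains must exceed 2 * n_modules")
    domain_names = [f"D{j:03d}" for j in range(cfg.n_domains)]
    background_domains = domain_names[n_reserved:]
    domains: dict[GeneId, set[str]] = {}
    for g in genes:
        if g in miss["domain"]:
            continue
        ds: set[str] = set()
        m = module_of.get(g)
        if m is not None:
            if rng_dom.random() < cfg.ddi_planting:
                ds.add(domain_names[2 * m])
            if rng_dom.random() < cfg.ddi_planting:
                ds.add(domain_names[2 * m + 1])
        k = int(rng_dom.integers(1, 4))
        for j in rng_dom.integers(0, len(background_domains), size=k):
            ds.add(background_domains[int(j)])
        domains[g] = ds
    ddi_scores: dict[tuple[str, str], float] = {}
    for m in modules:
        key = tuple(sorted((domain_names[2 * m], domain_names[2 * m + 1])))
        ddi_scores[key] = float(rng_dom.uniform(0.6, 1.0))
    n_noise_ddi = max(1, len(background_domains) // 2)
    for _ in range(n_noise_ddi):
        i, j = rng_dom.integers(0, len(background_domains), size=2)
        if i == j:
            continue
        key = tuple(sorted((background_domains[int(i)], background_domains[int(j)])))
        ddi_scores.setdefault(key, float(rng_dom.uniform(0.0, 1.0)))

    # ---- phylogenetic profiles: gene copies its module's profile with
    # per-species probability `profile_agreement`, else draws fresh
    species = [f"Sp{j:02d}" for j in range(cfg.n_species)]
    module_profiles = rng_phy.integers(0, 2, size=(cfg.n_modules, cfg.n_species))
    prof_rows = {}
    for g in genes:
        fresh = rng_phy.integers(0, 2, size=cfg.n_species)
        keep = rng_phy.random(cfg.n_species) < cfg.profile_agreement
        m = module_of.get(g)
        if m is not None:
            prof = np.where(keep, module_profiles[m], fresh)
        else:
            prof = fresh
        if g not in miss["phylogenetic"]:
            prof_rows[g] = prof
    profiles = pd.DataFrame.from_dict(prof_rows, orient="index", columns=species)
    profiles.index.name = "gene"
    profiles = profiles.astype(np.int8)

    # ---- interologs: reference species with orthologs of planted pairs
    # reported to interact
    ref_species = [f"R{j}" for j in range(cfg.n_ref_species)]
    ortho = OrthologData()
    ortho_name: dict[tuple[str, GeneId], str] = {}
    for sp in ref_species:
        for g in genes:
            if g in miss["interolog"]:
                continue
            if rng_orth.random() < cfg.ortholog_coverage:
                name = f"{sp}|{g}"
                ortho.add_ortholog(sp, g, name)
                ortho_name[(sp, g)] = name
    for a, b in all_pos:
        for sp in ref_species:
            if rng_orth.random() < cfg.interolog:
                na, nb = ortho_name.get((sp, a)), ortho_name.get((sp, b))
                if na and nb:
                    ortho.add_interaction(sp, na, nb)
    # background interolog noise on a few random non-planted pairs
    pos_set = set(all_pos)
    for _ in range(max(1, cfg.n_genes // 2)):
        i, j = rng_orth.integers(0, cfg.n_genes, size=2)
        if i == j:
            continue
        p = canonical_pair(genes[int(i)], genes[int(j)])
        if p in pos_set:
            continue
        sp = ref_species[int(rng_orth.integers(0, cfg.n_ref_species))]
        na, nb = ortho_name.get((sp, p[0])), ortho_name.get((sp, p[1]))
        if na and nb:
            ortho.add_interaction(sp, na, nb)

    compendium = EvidenceCompendium(
        genes=genes,
        expression=expression,
        annotations=corpus,
        ontology=dag,
        localization=localization,
        domains=domains,
        ddi_scores=ddi_scores,
        profiles=profiles,
        orthologs=ortho,
    )
    truth = PlantedTruth(
        genes=genes,
        module_of=module_of,
        modules=modules,
        positives=positives,
        heldout=heldout,
        module_terms=module_terms,
    )
    return compendium, truth


def truth_network(truth: PlantedTruth, which: str = "all") -> Interactome:
    """The planted interactome (all genes as nodes, planted pairs as edges)."""
    pairs = {
        "all": truth.all_positives,
        "train": truth.positives,
        "heldout": truth.heldout,
    }[which]
    net = Interactome.from_edges(
        ((a, b, 1.0, "experimental") for a, b in sorted(pairs)), nodes=truth.genes
    )
    return net


def generate_scg(
    truth: PlantedTruth,
    process: set[GeneId],
    n: int,
    contamination: float = 0.0,
    seed: int = 0,
) -> list[GeneId]:
    """Draw a synthetic set of changed genes (SCG).

    ``(1 - contamination) * n`` genes come from the module(s) wired to
    the given process gene set (modules sharing at least one gene with
    it); the remainder is drawn uniformly from the rest of the
    universe.
    """
    if not 0.0 <= contamination <= 1.0:
        raise ValueError("contamination must be in [0, 1]")
    rng = np.random.default_rng(seed)
    linked = sorted(
        {m for m, block in truth.modules.items() if set(block) & process}
    )
    pool = sorted({g for m in linked for g in truth.modules[m]})
    rest = sorted(set(truth.genes) - set(pool))
    n_pool = int(round((1.0 - contamination) * n))
    n_rest = n - n_pool
    if n > len(truth.genes):
        raise ValueError(f"requested {n} genes from a universe of {len(truth.genes)}")
    if n_pool > len(pool):
        raise ValueError(
            f"requested {n_pool} module genes but only {len(pool)} are wired to the process"
        )
    if n_rest > len(rest):
        raise ValueError(f"requested {n_rest} background genes, only {len(rest)} exist")
    scg = [pool[i] for i in rng.choice(len(pool), size=n_pool, replace=False)]
    scg += [rest[i] for i in rng.choice(len(rest), size=n_rest, replace=False)]
    return sorted(scg)


def generate_time_split(
    compendium: EvidenceCompendium,
    new_fraction: float = 0.3,
    seed: int = 0,
    aspect: str = "BP",
    cutoff_date: str = "20180101",
):
    """Flag a random fraction of direct annotations as post-cutoff.

    Returns a :class:`funlink.funcpred.TimeSplitCorpus` whose corpus
    contains *all* annotations (known) with the flagged subset dated
    after the cutoff; target genes are those with >=1 new annotation.
    """
    from .funcpred import TimeSplitCorpus

    rng = np.random.default_rng(seed)
    corpus = AnnotationCorpus(dates=dict(compendium.annotations.dates))
    new: set[tuple[str, str]] = set()
    d = compendium.annotations.by_aspect.get(aspect, {})
    for gene in sorted(d):
        for term in sorted(d[gene]):
            is_new = rng.random() < new_fraction
            date = "20190101" if is_new else "20170101"
            corpus.add(gene, term, aspect, date)
            if is_new:
                new.add((gene, term))
    # carry over the other aspects untouched
    for a, dd in compendium.annotations.by_aspect.items():
        if a == aspect:
            continue
        for gene, ts in dd.items():
            for t in ts:
                corpus.add(gene, t, a)
    return TimeSplitCorpus(corpus=corpus, new=new, aspect=aspect, cutoff_date=cutoff_date)
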