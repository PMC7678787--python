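"""Per-pair feature vectors from the six evidence categories.

Category layout (default 18 features):

- ``annotation`` (3): Jaccard index of the is_a-propagated GO term
  sets, one per aspect (BP, MF, CC).
- ``coexpression`` (2): Pearson correlation of the expression vectors,
  and mutual-rank similarity ``1/sqrt(rank_ab * rank_ba)`` where
  ``rank_ab`` is the rank of gene b among gene a's correlations over
  the whole universe (1 = best, ties averaged).
- ``colocalization`` (4): any-shared-compartment indicator, Jaccard of
  the compartment sets, shared-compartment count, and a specificity
  score ``max(-log f)`` over shared compartments (f = compartment
  frequency in the universe; 0 when nothing is shared).
- ``domain`` (5 per score source): over all cross domain pairs
  ``(d_a, d_b)``: count of scored pairs, scored fraction, max score,
  mean score over scored pairs, sum of scores.
- ``phylogenetic`` (3): phi correlation of the binary profiles,
  Jaccard of the presence sets, and mutual information of the 2x2
  presence table (natural log).
- ``interolog`` (1): number of reference species in which orthologs of
  the two genes are reported to interact (a species counts once
  regardless of paralog fan-out).

Missing-data rule: when the data a category needs are absent for a
pair (a gene missing from the layer, a zero-variance expression
vector, a constant profile, ...), every feature of that category is
set to exactly zero and the pair's missing mask is raised for the
category.  The rule is applied per category, not per feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .compendium import EvidenceCompendium
from .ids import GeneId, Pair, canonical_pair
from .io import OrthologData
from .ontology import ASPECTS, AnnotationCorpus, OntologyDag

CATEGORIES = (
    "annotation",
    "coexpression",
    "colocalization",
    "domain",
    "phylogenetic",
    "interolog",
)

DOMAIN_AGGREGATES = ("count", "fraction", "max", "mean", "sum")


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered feature descriptors: (category, name) per feature.

    The domain category repeats its five aggregates once per score
    source, which is how the family extends beyond the default five
    (one source) toward larger domain-feature sets.
    """

    domain_sources: tuple[str, ...] = ("ddi",)
    descriptors: tuple[tuple[str, str], ...] = field(init=False)

    def __post_init__(self) -> None:
        desc: list[tuple[str, str]] = []
        desc += [("annotation", f"ann_jaccard_{a.lower()}") for a in ASPECTS]
        desc += [("coexpression", "coexpr_pearson"), ("coexpression", "coexpr_mutual_rank")]
        desc += [
            ("colocalization", "loc_shared"),
            ("colocalization", "loc_jaccard"),
            ("colocalization", "loc_count"),
            ("colocalization", "loc_specificity"),
        ]
        for src in self.domain_sources:
            desc += [("domain", f"{src}_{agg}") for agg in DOMAIN_AGGREGATES]
        desc += [
            ("phylogenetic", "phylo_phi"),
            ("phylogenetic", "phylo_jaccard"),
            ("phylogenetic", "phylo_mi"),
        ]
        desc += [("interolog", "interolog_species")]
        names = [n for _, n in desc]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        object.__setattr__(self, "descriptors", tuple(desc))

    @property
    def names(self) -> list[str]:
        return [n for _, n in self.descriptors]

    @property
    def categories(self) -> list[str]:
        return [c for c, _ in self.descriptors]

    @property
    def n_features(self) -> int:
        return len(self.descriptors)


@dataclass
class FeatureMatrix:
    """Pairs x features values with per-category missingness mask."""

    pairs: list[Pair]
    values: np.ndarray
    missing_mask: np.ndarray
    feature_names: list[str]
    feature_categories: list[str]
    category_names: list[str] = field(default_factory=lambda: list(CATEGORIES))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != (len(self.pairs), len(self.feature_names)):
            raise ValueError("values shape does not match pairs x features")
        if self.missing_mask.shape != (len(self.pairs), len(self.category_names)):
            raise ValueError("mask shape does not match pairs x categories")
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")
        # zero-consistency: masked categories carry exactly-zero values
        for j, cat in enumerate(self.category_names):
            cols = [k for k, c in enumerate(self.feature_categories) if c == cat]
            if cols and self.missing_mask[:, j].any():
                sub = self.values[np.ix_(self.missing_mask[:, j], cols)]
                if sub.size and np.any(sub != 0.0):
                    raise ValueError(f"masked {cat} values are not all zero")
        self._index = {p: i for i, p in enumerate(self.pairs)}

    def row(self, pair: Pair) -> np.ndarray:
        return self.values[self._index[canonical_pair(*pair)]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "gene_a", [a for a, _ in self.pairs])
        df.insert(1, "gene_b", [b for _, b in self.pairs])
        for j, cat in enumerate(self.category_names):
            df[f"missing_{cat}"] = self.missing_mask[:, j].astype(int)
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        mask_cols = [c for c in df.columns if c.startswith("missing_")]
        feat_cols = [
            c for c in df.columns if c not in ("gene_a", "gene_b") and c not in mask_cols
        ]
        spec = FeatureSpec()
        name_to_cat = dict(zip(spec.names, spec.categories))
        cats = [name_to_cat.get(c, "domain") for c in feat_cols]
        return cls(
            pairs=[canonical_pair(a, b) for a, b in zip(df["gene_a"], df["gene_b"])],
            values=df[feat_cols].to_numpy(float),
            missing_mask=df[mask_cols].to_numpy(bool),
            feature_names=feat_cols,
            feature_categories=cats,
            category_names=[c.removeprefix("missing_") for c in mask_cols],
        )


# --------------------------------------------------------------- helpers
def _jaccard(a: set, b: set) -> float:
    if not a or not b:
        return 0.0
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)


# --------------------------------------- standalone per-category features
def coexpression_features(
    expr: pd.DataFrame, pair: tuple[GeneId, GeneId]
) -> tuple[np.ndarray, bool]:
    """(Pearson r, mutual-rank similarity); missing when either gene is
    absent from the matrix or has a zero-variance expression vector."""
    a, b = canonical_pair(*pair)
    if expr is None:
        return np.zeros(2), True
    ok = expr.std(axis=1, ddof=0) > 0
    present = set(expr.index[ok])
    if a not in present or b not in present:
        return np.zeros(2), True
    sub = expr.loc[sorted(present)]
    corr = np.corrcoef(sub.to_numpy(float))
    idx = {g: i for i, g in enumerate(sub.index)}
    ia, ib = idx[a], idx[b]
    r = float(corr[ia, ib])
    f2 = _mutual_rank_from_corr(corr, ia, ib)
    return np.array([r, f2]), False


def _mutual_rank_from_corr(corr: np.ndarray, ia: int, ib: int) -> float:
    n = corr.shape[0]
    if n < 2:
        return 0.0
    mask_a = np.ones(n, bool)
    mask_a[ia] = False
    ranks_a = rankdata(-corr[ia, mask_a], method="average")
    rank_ab = ranks_a[np.flatnonzero(mask_a) == ib][0] if n > 1 else np.nan
    mask_b = np.ones(n, bool)
    mask_b[ib] = False
    ranks_b = rankdata(-corr[ib, mask_b], method="average")
    rank_ba = ranks_b[np.flatnonzero(mask_b) == ia][0]
    return float(1.0 / math.sqrt(rank_ab * rank_ba))


def shared_annotation_features(
    corpus: AnnotationCorpus, dag: OntologyDag, pair: tuple[GeneId, GeneId]
) -> tuple[np.ndarray, bool]:
    """Per-aspect Jaccard of the is_a-propagated term sets.

    The category is missing only when one gene carries no annotation in
    any aspect; a gene unannotated in a single aspect simply scores 0
    there.
    """
    a, b = canonical_pair(*pair)
    if not corpus.genes() & {a} or not corpus.genes() & {b}:
        return np.zeros(len(ASPECTS)), True
    vals = []
    for aspect in ASPECTS:
        sa = _closure(corpus.terms_of(a, aspect), dag)
        sb = _closure(corpus.terms_of(b, aspect), dag)
        vals.append(_jaccard(sa, sb))
    return np.array(vals), False


def _closure(terms: set[str], dag: OntologyDag) -> set[str]:
    out: set[str] = set()
    for t in terms:
        out |= dag.ancestors(t, include_self=True)
    return out


def colocalization_features(
    loc: dict[GeneId, set[str]],
    pair: tuple[GeneId, GeneId],
    frequencies: dict[str, float] | None = None,
) -> tuple[np.ndarray, bool]:
    """(any-shared, Jaccard, shared count, specificity)."""
    a, b = canonical_pair(*pair)
    sa, sb = loc.get(a), loc.get(b)
    if not sa or not sb:
        return np.zeros(4), True
    if frequencies is None:
        frequencies = compartment_frequencies(loc)
    shared = sa & sb
    spec = max((-math.log(frequencies[c]) for c in shared), default=0.0)
    return (
        np.array([1.0 if shared else 0.0, _jaccard(sa, sb), float(len(shared)), spec]),
        False,
    )


def compartment_frequencies(loc: dict[GeneId, set[str]]) -> dict[str, float]:
    """Fraction of localized genes assigned to each compartment."""
    n = sum(1 for v in loc.values() if v)
    counts: dict[str, int] = {}
    for v in loc.values():
        for c in v:
            counts[c] = counts.get(c, 0) + 1
    return {c: k / n for c, k in counts.items()}


def domain_features(
    domains: dict[GeneId, set[str]],
    ddi: dict[tuple[str, str], float],
    pair: tuple[GeneId, GeneId],
) -> tuple[np.ndarray, bool]:
    """(count, fraction, max, mean, sum) over scored cross domain pairs."""
    a, b = canonical_pair(*pair)
    da, db = domains.get(a), domains.get(b)
    if not da or not db:
        return np.zeros(len(DOMAIN_AGGREGATES)), True
    scores = []
    n_cross = len(da) * len(db)
    for x in da:
        for y in db:
            s = ddi.get((x, y) if x <= y else (y, x))
            if s is not None:
                scores.append(s)
    if not scores:
        return np.zeros(len(DOMAIN_AGGREGATES)), False
    arr = np.array(scores, float)
    return (
        np.array(
            [len(arr), len(arr) / n_cross, arr.max(), arr.mean(), arr.sum()]
        ),
        False,
    )


def phylo_features(
    profiles: pd.DataFrame, pair: tuple[GeneId, GeneId]
) -> tuple[np.ndarray, bool]:
    """(phi correlation, presence Jaccard, 2x2 mutual information)."""
    a, b = canonical_pair(*pair)
    if profiles is None or a not in profiles.index or b not in profiles.index:
        return np.zeros(3), True
    va = profiles.loc[a].to_numpy(int)
    vb = profiles.loc[b].to_numpy(int)
    if va.min() == va.max() or vb.min() == vb.max():
        return np.zeros(3), True
    return np.array(_phylo_from_counts(*_two_by_two(va, vb))), False


def _two_by_two(va: np.ndarray, vb: np.ndarray) -> tuple[int, int, int, int]:
    n11 = int(((va == 1) & (vb == 1)).sum())
    n10 = int(((va == 1) & (vb == 0)).sum())
    n01 = int(((va == 0) & (vb == 1)).sum())
    n00 = int(((va == 0) & (vb == 0)).sum())
    return n11, n10, n01, n00


def _phylo_from_counts(n11: int, n10: int, n01: int, n00: int):
    n = n11 + n10 + n01 + n00
    r1, r0 = n11 + n10, n01 + n00
    c1, c0 = n11 + n01, n10 + n00
    phi = (n11 * n00 - n10 * n01) / math.sqrt(float(r1) * r0 * c1 * c0)
    jac = n11 / (n11 + n10 + n01) if (n11 + n10 + n01) else 0.0
    mi = 0.0
    for nij, ni, nj in (
        (n11, r1, c1),
        (n10, r1, c0),
        (n01, r0, c1),
        (n00, r0, c0),
    ):
        if nij > 0:
            mi += (nij / n) * math.log(nij * n / (ni * nj))
    return phi, jac, max(mi, 0.0)


def interolog_feature(
    ortho: OrthologData, pair: tuple[GeneId, GeneId]
) -> tuple[np.ndarray, bool]:
    """Number of reference species whose orthologs of the pair interact."""
    a, b = canonical_pair(*pair)
    if not ortho.has_orthologs(a) or not ortho.has_orthologs(b):
        return np.zeros(1), True
    count = 0
    for sp in ortho.species:
        amap = ortho.maps.get(sp, {})
        oa, ob = amap.get(a), amap.get(b)
        if not oa or not ob:
            continue
        ints = ortho.interactions.get(sp, set())
        hit = any(
            ((x, y) if x <= y else (y, x)) in ints for x in oa for y in ob if x != y
        )
        if hit:
            count += 1
    return np.array([float(count)]), False


# ------------------------------------------------------- batch computation
class FeatureComputer:
    """Precomputes per-layer structures once, then scores pairs fast.

    The expensive pieces — the expression correlation and mutual-rank
    matrices, propagated annotation sets and compartment frequencies —
    are built at construction; ``pair_features`` is then cheap enough
    to sweep hundreds of thousands of pairs.
    """

    def __init__(self, compendium: EvidenceCompendium, spec: FeatureSpec | None = None):
        self.compendium = compendium
        self.spec = spec or FeatureSpec()
        self.universe = set(compendium.genes)

        expr = compendium.expression
        self._expr_idx: dict[GeneId, int] = {}
        if expr is not None and len(expr) >= 2:
            ok = expr.std(axis=1, ddof=0) > 0
            sub = expr.loc[expr.index[ok]]
            if len(sub) >= 2:
                self._expr_idx = {g: i for i, g in enumerate(sub.index)}
                self._corr = np.corrcoef(sub.to_numpy(float))
                self._ranks = self._rank_matrix(self._corr)

        self._ann: dict[str, dict[GeneId, set[str]]] = {}
        if compendium.ontology is not None:
            prop = compendium.annotations.propagate(compendium.ontology)
        else:
            prop = compendium.annotations
        for aspect in ASPECTS:
            self._ann[aspect] = {
                g: set(ts) for g, ts in prop.by_aspect.get(aspect, {}).items()
            }
        self._annotated = set().union(*(set(d) for d in self._ann.values()))

        self._loc = {g: s for g, s in compendium.localization.items() if s}
        self._freq = compartment_frequencies(self._loc) if self._loc else {}

        self._domains = {g: s for g, s in compendium.domains.items() if s}
        self._ddi = compendium.ddi_scores

        self._prof_idx: dict[GeneId, int] = {}
        if compendium.profiles is not None and len(compendium.profiles):
            P = compendium.profiles.to_numpy(int)
            variable = P.min(axis=1) != P.max(axis=1)
            self._prof_idx = {
                g: i
                for i, (g, v) in enumerate(zip(compendium.profiles.index, variable))
                if v
            }
            self._prof = P

        self._ortho = compendium.orthologs
        self._has_ortho = {
            g for m in self._ortho.maps.values() for g in m
        }

    @staticmethod
    def _rank_matrix(corr: np.ndarray) -> np.ndarray:
        n = corr.shape[0]
        ranks = np.empty((n, n))
        ranks.fill(np.nan)
        for i in range(n):
            mask = np.ones(n, bool)
            mask[i] = False
            ranks[i, mask] = rankdata(-corr[i, mask], method="average")
        return ranks

    # -- per-category, index-based fast paths ------------------------
    def _coexpression(self, a: GeneId, b: GeneId):
        ia, ib = self._expr_idx.get(a), self._expr_idx.get(b)
        if ia is None or ib is None:
            return np.zeros(2), True
        r = float(self._corr[ia, ib])
        mr = 1.0 / math.sqrt(self._ranks[ia, ib] * self._ranks[ib, ia])
        return np.array([r, mr]), False

    def _annotation(self, a: GeneId, b: GeneId):
        if a not in self._annotated or b not in self._annotated:
            return np.zeros(len(ASPECTS)), True
        vals = [
            _jaccard(
                self._ann[aspect].get(a, set()), self._ann[aspect].get(b, set())
            )
            for aspect in ASPECTS
        ]
        return np.array(vals), False

    def _colocalization(self, a: GeneId, b: GeneId):
        sa, sb = self._loc.get(a), self._loc.get(b)
        if not sa or not sb:
            return np.zeros(4), True
        shared = sa & sb
        spec = max((-math.log(self._freq[c]) for c in shared), default=0.0)
        return (
            np.array(
                [1.0 if shared else 0.0, _jaccard(sa, sb), float(len(shared)), spec]
            ),
            False,
        )

    def _domain(self, a: GeneId, b: GeneId):
        return domain_features(self._domains, self._ddi, (a, b))

    def _phylogenetic(self, a: GeneId, b: GeneId):
        ia, ib = self._prof_idx.get(a), self._prof_idx.get(b)
        if ia is None or ib is None:
            return np.zeros(3), True
        return (
            np.array(
                _phylo_from_counts(*_two_by_two(self._prof[ia], self._prof[ib]))
            ),
            False,
        )

    def _interolog(self, a: GeneId, b: GeneId):
        if a not in self._has_ortho or b not in self._has_ortho:
            return np.zeros(1), True
        return interolog_feature(self._ortho, (a, b))

    _DISPATCH = {
        "annotation": "_annotation",
        "coexpression": "_coexpression",
        "colocalization": "_colocalization",
        "domain": "_domain",
        "phylogenetic": "_phylogenetic",
        "interolog": "_interolog",
    }

    def pair_features(self, pair: tuple[GeneId, GeneId]) -> tuple[np.ndarray, np.ndarray]:
        """Feature vector and per-category missing mask for one pair."""
        a, b = canonical_pair(*pair)
        for g in (a, b):
            if g not in self.universe:
                raise KeyError(f"gene {g!r} is not in the compendium universe")
        chunks: list[np.ndarray] = []
        mask = np.zeros(len(CATEGORIES), bool)
        for j, cat in enumerate(CATEGORIES):
            if cat == "domain":
                # repeated per score source; single built-in source here
                vals, miss = self._domain(a, b)
                reps = len(self.spec.domain_sources)
                vals = np.tile(vals, reps)
            else:
                vals, miss = getattr(self, self._DISPATCH[cat])(a, b)
            if miss:
                vals = np.zeros_like(vals)
            chunks.append(vals)
            mask[j] = miss
        return np.concatenate(chunks), mask


def build_feature_matrix(
    compendium: EvidenceCompendium,
    pairs,
    spec: FeatureSpec | None = None,
    computer: FeatureComputer | None = None,
) -> FeatureMatrix:
    """Compute the pairs x features matrix with the missing->zero rule."""
    comp = computer or FeatureComputer(compendium, spec)
    cpairs = [canonical_pair(*p) for p in pairs]
    n = len(cpairs)
    values = np.zeros((n, comp.spec.n_features))
    mask = np.zeros((n, len(CATEGORIES)), bool)
    for i, p in enumerate(cpairs):
        values[i], mask[i] = comp.pair_features(p)
    return FeatureMatrix(
        pairs=cpairs,
        values=values,
        missing_mask=mask,
        feature_names=comp.spec.names,
        feature_categories=comp.spec.categories,
    )
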