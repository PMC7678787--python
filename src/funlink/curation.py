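"""Gold-standard curation of experimentally reported interactions.

A gene pair qualifies as a gold-standard (training-positive)
interaction when it is supported by more than one independent study,
at least one of which was a low-throughput experiment.  "Independent
study" means a distinct publication identifier; the low-throughput
flag is taken as given per evidence row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ids import Pair, canonical_pair
from .io import FormatError, _read_tsv


@dataclass
class EvidenceRecord:
    """All study-level evidence for one unordered gene pair."""

    pair: Pair
    study_ids: set[str] = field(default_factory=set)
    low_throughput: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pair = canonical_pair(*self.pair)
        if not self.study_ids:
            raise ValueError(f"evidence record for {self.pair} has no studies")
        missing = self.study_ids - set(self.low_throughput)
        if missing:
            raise ValueError(f"studies {missing} lack a throughput flag")

    @property
    def n_studies(self) -> int:
        return len(self.study_ids)

    @property
    def any_low_throughput(self) -> bool:
        return any(self.low_throughput[s] for s in self.study_ids)


def curate_gold_standard(records: list[EvidenceRecord]) -> set[Pair]:
    """Retain pairs with >1 independent study, >=1 of them low-throughput."""
    retained: set[Pair] = set()
    for rec in records:
        if rec.n_studies >= 2 and rec.any_low_throughput:
            retained.add(rec.pair)
    return retained


def read_evidence_table(path) -> list[EvidenceRecord]:
    """Evidence TSV with one row per (pair, study).

    Columns: gene_a, gene_b, study_id, low_throughput (0/1).  Rows for
    the same unordered pair are merged into one record.
    """
    df = _read_tsv(path, ["gene_a", "gene_b", "study_id", "low_throughput"])
    acc: dict[Pair, dict[str, bool]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pair = canonical_pair(row.gene_a, row.gene_b)
        except ValueError as exc:
            raise FormatError(path, i, str(exc)) from exc
        if not row.study_id:
            raise FormatError(path, i, "empty study id")
        if row.low_throughput not in ("0", "1"):
            raise FormatError(
                path, i, f"low_throughput must be 0 or 1, got {row.low_throughput!r}"
            )
        flags = acc.setdefault(pair, {})
        # a study seen with both flags counts as low-throughput evidence
        flags[row.study_id] = flags.get(row.study_id, False) or row.low_throughput == "1"
    return [
        EvidenceRecord(pair=p, study_ids=set(flags), low_throughput=flags)
        for p, flags in sorted(acc.items())
    ]


def write_pairs(pairs, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(canonical_pair(a, b) for a, b in pairs):
            fh.write(f"{a}\t{b}\n")


def read_pairs(path) -> set[Pair]:
    df = _read_tsv(path, ["gene_a", "gene_b"])
    out: set[Pair] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.add(canonical_pair(row.gene_a, row.gene_b))
        except ValueError as exc:
            raise FormatError(path, i, str(exc)) from exc
    return out
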