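"""Gene order, strand distribution, and overlap / intergenic-spacer ledgers.

Adjacency is computed on start-sorted features.  For consecutive features
``prev`` and ``next`` the signed gap is ``next.start - prev.end - 1``:
negative gaps are overlaps, positive gaps are spacers.  The control region
is the unannotated remainder and is excluded from adjacency; the wrap pair
(last annotated gene back to the first, through the control region) is
reported separately and never enters the summary counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome_model import Direction, GeneFeature, feature_length
from .vocabulary import ANCESTRAL_INSECT_ORDER, GeneType

__all__ = [
    "AdjacencyRecord",
    "AdjacencyLedger",
    "GeneOrder",
    "intergenic_ledger",
    "overlap_summary",
    "spacer_summary",
    "strand_distribution",
    "gene_order",
    "compare_gene_order",
    "ledger_report",
    "ancestral_gene_order",
]


@dataclass(frozen=True)
class AdjacencyRecord:
    prev: str
    next: str
    gap: int  # signed: <0 overlap, >0 spacer, 0 abutting


@dataclass
class AdjacencyLedger:
    records: list[AdjacencyRecord]
    wrap_record: AdjacencyRecord | None = None

    @property
    def overlaps(self) -> list[AdjacencyRecord]:
        return [r for r in self.records if r.gap < 0]

    @property
    def spacers(self) -> list[AdjacencyRecord]:
        return [r for r in self.records if r.gap > 0]


def intergenic_ledger(features: Sequence[GeneFeature],
                      genome_length: int | None = None) -> AdjacencyLedger:
    """Build the adjacency ledger over start-sorted, non-control features."""
    feats = sorted(
        (f for f in features if f.gene_type is not GeneType.CONTROL),
        key=lambda f: (f.start, f.end, f.name),
    )
    if any(f.wraps_origin for f in feats):
        raise ValueError("wrapping features not supported in adjacency ledger; "
                         "linearize the genome first")
    records = [
        AdjacencyRecord(a.name, b.name, b.start - a.end - 1)
        for a, b in zip(feats, feats[1:])
    ]
    wrap = None
    if genome_length is not None and len(feats) >= 2:
        last, first = feats[-1], feats[0]
        wrap = AdjacencyRecord(last.name, first.name,
                               genome_length - last.end + first.start - 1)
    return AdjacencyLedger(records=records, wrap_record=wrap)


def overlap_summary(l: AdjacencyLedger) -> tuple[int, int, tuple[str, str] | None]:
    """(number of overlapping pairs, max overlap bp, pair attaining it)."""
    ov = l.overlaps
    if not ov:
        return 0, 0, None
    best = max(ov, key=lambda r: (-r.gap, r.prev))
    return len(ov), -best.gap, (best.prev, best.next)


def spacer_summary(l: AdjacencyLedger) -> tuple[int, int, tuple[str, str] | None]:
    """(number of spacers, max spacer bp, pair attaining it)."""
    sp = l.spacers
    if not sp:
        return 0, 0, None
    best = max(sp, key=lambda r: (r.gap, r.prev))
    return len(sp), best.gap, (best.prev, best.next)


def strand_distribution(features: Iterable[GeneFeature]) -> dict[str, dict[str, int]]:
    """Cross-tab of counts by gene type x direction, plus totals."""
    out: dict[str, dict[str, int]] = {}
    for f in features:
        if f.gene_type is GeneType.CONTROL:
            continue
        row = out.setdefault(f.gene_type.value, {"forward": 0, "reverse": 0})
        row[f.direction.value] += 1
    totals = {"forward": 0, "reverse": 0}
    for row in out.values():
        totals["forward"] += row["forward"]
        totals["reverse"] += row["reverse"]
    out["total"] = totals
    return out


@dataclass(frozen=True)
class GeneOrder:
    """Circular ordered list of (gene name, is_forward)."""

    order: tuple[tuple[str, bool], ...]

    def __post_init__(self) -> None:
        names = [g for g, _ in self.order]
        if len(names) != len(set(names)):
            raise ValueError("gene order contains a repeated gene")

    def rotations(self):
        n = len(self.order)
        for k in range(n):
            yield self.order[k:] + self.order[:k]


def gene_order(features: Sequence[GeneFeature]) -> GeneOrder:
    feats = sorted(
        (f for f in features if f.gene_type is not GeneType.CONTROL),
        key=lambda f: (f.start, f.end, f.name),
    )
    return GeneOrder(tuple((f.name, f.direction is Direction.FORWARD) for f in feats))


def ancestral_gene_order() -> GeneOrder:
    return GeneOrder(ANCESTRAL_INSECT_ORDER)


def compare_gene_order(a: GeneOrder, b: GeneOrder) -> tuple[bool, int | None]:
    """Circular, direction-sensitive identity test (reflection NOT allowed).

    Identity is tested under every rotation of ``a``.  When the orders
    differ, the reported position is the 1-based index of the first
    mismatch of the un-rotated comparison (None when identical).
    """
    if len(a.order) == len(b.order):
        for rot in a.rotations():
            if rot == b.order:
                return True, None
    first_diff = 1
    for i, (x, y) in enumerate(zip(a.order, b.order), start=1):
        first_diff = i
        if x != y:
            break
    return False, first_diff


def ledger_report(features: Sequence[GeneFeature],
                  genome_length: int | None = None,
                  codons: dict[str, str] | None = None) -> str:
    """TSV ledger mirroring the annotation-table layout:
    gene, start, end, size, strand, direction, intergenic, codons."""
    feats = sorted(features, key=lambda f: (f.start, f.end, f.name))
    ledger = intergenic_ledger(feats, genome_length)
    gap_before = {r.next: r.gap for r in ledger.records}
    lines = ["gene\tstart\tend\tsize\tstrand\tdirection\tintergenic\tcodons"]
    for f in feats:
        gap = gap_before.get(f.name, 0)
        codon = (codons or {}).get(f.name, "")
        lines.append(
            f"{f.name}\t{f.start}\t{f.end}\t{feature_length(f, genome_length)}\t"
            f"{f.strand_label}\t{f.direction.value}\t{gap}\t{codon}"
        )
    return "\n".join(lines) + "\n"
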