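"""Codon counting and relative synonymous codon usage (RSCU).

RSCU(c) = count(c) * family_size / sum(counts over the synonymous family),
where a family is the set of codons translating to the same amino acid under
the active genetic code.  Stop codons are tallied separately and excluded
from families by default.  Families with zero total are reported as
undefined (None), not 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Iterable

from Bio.Data import CodonTable

__all__ = [
    "CodonUsageTable",
    "genetic_code",
    "synonymous_families",
    "codon_counts",
    "rscu",
    "top_codons",
    "rscu_report",
]

BASES = "ACGT"
ALL_CODONS = tuple("".join(p) for p in product(BASES, repeat=3))


@lru_cache(maxsize=None)
def genetic_code(code_id: int) -> tuple[dict[str, str], frozenset[str]]:
    """(codon -> amino acid map, stop codon set) with T-alphabet codons."""
    table = CodonTable.unambiguous_dna_by_id[code_id]
    return dict(table.forward_table), frozenset(table.stop_codons)


@lru_cache(maxsize=None)
def synonymous_families(code_id: int, include_stops: bool = False) -> dict[str, tuple[str, ...]]:
    """Amino acid -> codon family (alphabetical) under ``code_id``."""
    fwd, stops = genetic_code(code_id)
    fams: dict[str, list[str]] = {}
    for codon, aa in fwd.items():
        fams.setdefault(aa, []).append(codon)
    if include_stops:
        fams["*"] = sorted(stops)
    return {aa: tuple(sorted(cods)) for aa, cods in fams.items()}


@dataclass
class CodonUsageTable:
    genetic_code_id: int
    counts: dict[str, int] = field(default_factory=dict)
    stop_counts: dict[str, int] = field(default_factory=dict)
    rscu: dict[str, float | None] = field(default_factory=dict)
    n_excluded_codons: int = 0
    include_stops: bool = False

    def amino_acid(self, codon: str) -> str:
        fwd, stops = genetic_code(self.genetic_code_id)
        return "*" if codon in stops else fwd[codon]

    def amino_acid_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for codon, n in self.counts.items():
            aa = self.amino_acid(codon)
            totals[aa] = totals.get(aa, 0) + n
        return totals


def codon_counts(cds_set: Iterable[str], code: int = 5) -> CodonUsageTable:
    """Count codons over a set of in-frame CDSs.

    Trailing incomplete codons are dropped; codons containing ambiguity are
    excluded and counted in ``n_excluded_codons``; stops are tallied apart.
    """
    fwd, stops = genetic_code(code)
    t = CodonUsageTable(genetic_code_id=code)
    for cds in cds_set:
        cds = cds.upper()
        if len(cds) < 3:
            warnings.warn("CDS shorter than one codon skipped", stacklevel=2)
            continue
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i : i + 3]
            if codon in stops:
                t.stop_counts[codon] = t.stop_counts.get(codon, 0) + 1
            elif codon in fwd:
                t.counts[codon] = t.counts.get(codon, 0) + 1
            else:
                t.n_excluded_codons += 1
    return t


def rscu(t: CodonUsageTable, include_stops: bool = False) -> CodonUsageTable:
    """Fill per-codon RSCU values in place and return the table."""
    fams = synonymous_families(t.genetic_code_id, include_stops)
    counts = dict(t.counts)
    if include_stops:
        counts.update(t.stop_counts)
    t.include_stops = include_stops
    t.rscu = {}
    for aa, codons in fams.items():
        total = sum(counts.get(c, 0) for c in codons)
        for c in codons:
            t.rscu[c] = None if total == 0 else counts.get(c, 0) * len(codons) / total
    return t


def top_codons(t: CodonUsageTable, k: int = 5) -> list[tuple[str, str, float]]:
    """Top-k (codon, amino acid, RSCU) ranked by RSCU, ties alphabetical."""
    if not t.rscu:
        raise ValueError("RSCU not computed; call rscu() first")
    defined = [(c, v) for c, v in t.rscu.items() if v is not None]
    defined.sort(key=lambda cv: (-cv[1], cv[0]))
    return [(c, t.amino_acid(c), v) for c, v in defined[:k]]


def rscu_report(t: CodonUsageTable) -> str:
    """TSV: codon, amino acid, count, RSCU, family size."""
    fams = synonymous_families(t.genetic_code_id, t.include_stops)
    size_of = {c: len(codons) for codons in fams.values() for c in codons}
    lines = ["codon\tamino_acid\tcount\trscu\tfamily_size"]
    for codon in sorted(size_of):
        count = t.counts.get(codon, 0)
        if t.include_stops:
            count += t.stop_counts.get(codon, 0)
        v = t.rscu.get(codon)
        lines.append(
            f"{codon}\t{t.amino_acid(codon)}\t{count}\t"
            f"{'NA' if v is None else f'{v:.4f}'}\t{size_of[codon]}"
        )
    return "\n".join(lines) + "\n"
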