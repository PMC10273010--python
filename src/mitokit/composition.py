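"""Base composition, AT/GC skew, and start/stop codon typing.

Skews follow AT-skew = (A-T)/(A+T) and GC-skew = (G-C)/(G+C).  Reported
values are rounded half-away-from-zero: 1 decimal for percentages, 2
decimals for skews.  Ambiguity codes are excluded from the four base counts
and from skew denominators; they are tallied in ``n_ambiguous``.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

from .genome_model import MitoGenome, extract_sequence
from .vocabulary import GeneType

__all__ = [
    "CompositionProfile",
    "CodonAnnotation",
    "round_half_away",
    "base_composition",
    "at_skew",
    "gc_skew",
    "per_gene_composition",
    "start_stop_codons",
    "composition_report",
]


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (0.125 -> 0.13, -0.125 -> -0.13 at 2 dp)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class CompositionProfile:
    counts: dict[str, int]      # raw counts of A, C, G, T
    n_ambiguous: int
    a_pct: float
    t_pct: float
    g_pct: float
    c_pct: float
    at_content: float           # A% + T%
    at_skew: float | None       # None when A+T = 0
    gc_skew: float | None       # None when G+C = 0

    def rounded(self, pct_dp: int = 1, skew_dp: int = 2) -> "CompositionProfile":
        rd = lambda v, d: None if v is None else round_half_away(v, d)
        return CompositionProfile(
            counts=self.counts,
            n_ambiguous=self.n_ambiguous,
            a_pct=rd(self.a_pct, pct_dp),
            t_pct=rd(self.t_pct, pct_dp),
            g_pct=rd(self.g_pct, pct_dp),
            c_pct=rd(self.c_pct, pct_dp),
            at_content=rd(self.at_content, pct_dp),
            at_skew=rd(self.at_skew, skew_dp),
            gc_skew=rd(self.gc_skew, skew_dp),
        )


def at_skew(a: float, t: float) -> float | None:
    """(A-T)/(A+T); arguments may be counts or percentages. None if A+T=0."""
    if a + t == 0:
        return None
    return (a - t) / (a + t)


def gc_skew(g: float, c: float) -> float | None:
    """(G-C)/(G+C). None if G+C=0."""
    if g + c == 0:
        return None
    return (g - c) / (g + c)


def base_composition(seq: str) -> CompositionProfile:
    """Composition over unambiguous A/C/G/T; skews computed from counts."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    n = sum(counts.values())
    n_amb = len(seq) - n
    if n == 0:
        raise ValueError("sequence contains no unambiguous bases")
    pct = {b: 100.0 * counts[b] / n for b in "ACGT"}
    return CompositionProfile(
        counts=counts,
        n_ambiguous=n_amb,
        a_pct=pct["A"],
        t_pct=pct["T"],
        g_pct=pct["G"],
        c_pct=pct["C"],
        at_content=pct["A"] + pct["T"],
        at_skew=at_skew(counts["A"], counts["T"]),
        gc_skew=gc_skew(counts["G"], counts["C"]),
    )


def per_gene_composition(g: MitoGenome) -> dict[str, CompositionProfile]:
    """One profile per feature, computed on the oriented gene sequence."""
    return {f.name: base_composition(extract_sequence(g, f)) for f in g.features}


@dataclass(frozen=True)
class CodonAnnotation:
    gene: str
    start_codon: str
    stop_codon: str      # "TAA", "TAG", "T-" or "TA-"
    complete: bool
    canonical_start: bool  # ATN / TTG / GTG


_CANONICAL_START_PREFIXES = ("AT", "TTG", "GTG")


def _annotate_cds(name: str, cds: str) -> CodonAnnotation:
    if len(cds) < 6:
        raise ValueError(f"{name}: CDS shorter than 6 nt")
    start = cds[:3]
    rem = len(cds) % 3
    if rem == 0:
        stop, complete = cds[-3:], True
    else:
        stop, complete = cds[-rem:] + "-", False
    canonical = start.startswith("AT") or start in ("TTG", "GTG")
    return CodonAnnotation(name, start, stop, complete, canonical)


def start_stop_codons(g: MitoGenome) -> list[CodonAnnotation]:
    """Start/stop codon typing for every PCG, in feature order.

    The stop is the final full codon when length % 3 == 0, otherwise the
    remainder nucleotides suffixed with "-" (incomplete stop completed by
    polyadenylation).
    """
    out = []
    for f in g.features:
        if f.gene_type is GeneType.PCG:
            out.append(_annotate_cds(f.name, extract_sequence(g, f)))
    return out


_REPORT_COLUMNS = ("name", "size_bp", "A", "T", "G", "C", "A+T%", "AT-skew", "GC-skew")


def composition_report(profiles: dict[str, tuple[int, CompositionProfile]],
                       pct_dp: int = 1, skew_dp: int = 2) -> str:
    """TSV report with the whole-genome column set plus gene-level rows.

    ``profiles`` maps row name -> (size in bp, profile).
    """
    lines = ["\t".join(_REPORT_COLUMNS)]
    for name, (size, prof) in profiles.items():
        r = prof.rounded(pct_dp, skew_dp)
        fmt = lambda v: "NA" if v is None else f"{v:g}"
        lines.append("\t".join([
            name, str(size), fmt(r.a_pct), fmt(r.t_pct), fmt(r.g_pct),
            fmt(r.c_pct), fmt(r.at_content), fmt(r.at_skew), fmt(r.gc_skew),
        ]))
    return "\n".join(lines) + "\n"
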