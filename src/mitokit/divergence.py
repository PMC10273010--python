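"""Pairwise molecular-evolution statistics: nucleotide diversity (Pi) and
Ka/Ks by the Nei-Gojobori (1986) counting method with Jukes-Cantor
correction.

Site counting: each codon position contributes a synonymous-site fraction
equal to (synonymous single-base changes) / (single-base changes that do
not create a stop codon); the nonsynonymous fraction is the complement, so
every codon contributes exactly 3 sites.  Pathway counting between two
codons averages synonymous/nonsynonymous difference tallies over all
orderings of the mismatched positions whose intermediates are not stop
codons; when every pathway is blocked the average falls back to all
orderings (with a warning).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from .codon_usage import BASES, genetic_code

__all__ = [
    "DivergenceResult",
    "pairwise_pi",
    "mean_pairwise_pi",
    "ng86_site_counts",
    "ng86_path_differences",
    "ka_ks",
    "divergence_table",
    "divergence_report",
]

_AMBIG = set("RYSWKMBDHVN")
_GAPS = set("-.?")


def _comparable(x: str, y: str) -> bool:
    return x in "ACGT" and y in "ACGT"


def pairwise_pi(a: str, b: str) -> float | None:
    """Proportion of differing sites over positions where both sequences are
    unambiguous and ungapped.  None when no site is comparable."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    a, b = a.upper(), b.upper()
    n = diff = 0
    for x, y in zip(a, b):
        if _comparable(x, y):
            n += 1
            diff += x != y
    return None if n == 0 else diff / n


def mean_pairwise_pi(seqs: list[str]) -> float | None:
    """Average pairwise_pi over all sequence pairs (DnaSP-style Pi)."""
    vals = [
        v
        for i in range(len(seqs))
        for j in range(i + 1, len(seqs))
        if (v := pairwise_pi(seqs[i], seqs[j])) is not None
    ]
    return sum(vals) / len(vals) if vals else None


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str, code: int = 5) -> tuple[float, float]:
    """(synonymous sites, nonsynonymous sites) for one codon; sums to 3."""
    fwd, stops = genetic_code(code)
    codon = codon.upper()
    if codon in stops or codon not in fwd:
        raise ValueError(f"stop or ambiguous codon {codon!r} has no site counts")
    aa = fwd[codon]
    syn = 0.0
    for pos in range(3):
        s = valid = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut in stops:
                continue
            valid += 1
            s += fwd[mut] == aa
        if valid:
            syn += s / valid
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def ng86_path_differences(a: str, b: str, code: int = 5) -> tuple[float, float]:
    """(synonymous diffs, nonsynonymous diffs) averaged over mutational
    pathways between codons ``a`` and ``b``."""
    fwd, stops = genetic_code(code)
    a, b = a.upper(), b.upper()
    for c in (a, b):
        if c in stops or c not in fwd:
            raise ValueError(f"stop or ambiguous codon {c!r}")
    pos = [i for i in range(3) if a[i] != b[i]]
    if not pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[int, int] | None:
        cur = a
        syn = non = 0
        for i in order:
            nxt = cur[:i] + b[i] + cur[i + 1 :]
            if nxt in stops and not allow_stops:
                return None
            # a stop intermediate (fallback mode) is a nonsynonymous step
            if nxt in stops or cur in stops or fwd[nxt] != fwd[cur]:
                non += 1
            else:
                syn += 1
            cur = nxt
        return syn, non

    results = [r for order in permutations(pos)
               if (r := walk(order, allow_stops=False)) is not None]
    if not results:
        warnings.warn(
            f"all mutational pathways between {a} and {b} pass through stop "
            "codons; averaging over unrestricted pathways", stacklevel=2)
        results = [walk(order, allow_stops=True) for order in permutations(pos)]
    s = sum(r[0] for r in results) / len(results)
    n = sum(r[1] for r in results) / len(results)
    return s, n


def jukes_cantor(p: float) -> float | None:
    """JC69 distance d = -(3/4) ln(1 - 4p/3); None at saturation (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class DivergenceResult:
    gene: str
    pi: float | None
    ka: float | None
    ks: float | None
    ratio: float | None            # None when ks == 0 or saturated
    n_sites_compared: int          # nucleotide sites entering Pi
    n_codons_compared: int
    n_syn_sites: float
    n_nonsyn_sites: float
    saturated: bool = False


def _clean_codon_pairs(a: str, b: str, code: int) -> list[tuple[str, str]]:
    """Pairwise-complete codon pairs: gaps/ambiguity/stops excluded; the
    shared terminal stop (if any) is trimmed."""
    fwd, stops = genetic_code(code)
    n = min(len(a), len(b))
    n -= n % 3
    pairs = []
    internal_stop = False
    codons = [(a[i : i + 3].upper(), b[i : i + 3].upper()) for i in range(0, n, 3)]
    # trim terminal stops
    while codons and (codons[-1][0] in stops or codons[-1][1] in stops):
        codons.pop()
    for ca, cb in codons:
        if any(ch in _GAPS or ch in _AMBIG for ch in ca + cb):
            continue
        if ca in stops or cb in stops:
            internal_stop = True
            continue
        if ca not in fwd or cb not in fwd:
            continue
        pairs.append((ca, cb))
    if internal_stop:
        warnings.warn("internal stop codon(s) excluded from Ka/Ks", stacklevel=3)
    return pairs


def ka_ks(a: str, b: str, code: int = 5, gene: str = "") -> DivergenceResult:
    """NG86 Ka, Ks and Ka/Ks for an aligned in-frame CDS pair.

    Site totals are averaged over the two sequences; both substitution
    classes receive the Jukes-Cantor correction.  The ratio is None when
    Ks is 0 or either class is saturated.
    """
    if len(a) != len(b):
        raise ValueError("CDS pair must be aligned to equal length")
    pairs = _clean_codon_pairs(a, b, code)
    pi = pairwise_pi(a, b)
    if not pairs:
        return DivergenceResult(gene, pi, None, None, None, 0, 0, 0.0, 0.0)
    S = N = Sd = Nd = 0.0
    for ca, cb in pairs:
        sa, na = ng86_site_counts(ca, code)
        sb, nb = ng86_site_counts(cb, code)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = ng86_path_differences(ca, cb, code)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    saturated = ks is None or ka is None
    ratio = None
    if not saturated and ks and ks > 0:
        ratio = ka / ks
    return DivergenceResult(
        gene=gene,
        pi=pi,
        ka=ka,
        ks=ks,
        ratio=ratio,
        n_sites_compared=3 * len(pairs),
        n_codons_compared=len(pairs),
        n_syn_sites=S,
        n_nonsyn_sites=N,
        saturated=saturated,
    )


def divergence_table(pcgs_a: dict[str, str], pcgs_b: dict[str, str],
                     code: int = 5) -> list[DivergenceResult]:
    """Per-gene divergence for the PCGs shared by two genomes.

    Equal-length orthologs are compared positionally; unequal lengths are
    codon-aligned first via the supermatrix aligner.
    """
    shared = [g for g in pcgs_a if g in pcgs_b]
    if not shared:
        raise ValueError("no shared protein-coding genes")
    out = []
    for gname in shared:
        sa, sb = pcgs_a[gname], pcgs_b[gname]
        if len(sa) != len(sb):
            from .supermatrix import align_gene

            aln = align_gene({"a": sa, "b": sb}, code=code)
            sa, sb = aln["a"], aln["b"]
        out.append(ka_ks(sa, sb, code=code, gene=gname))
    return out


def divergence_report(results: list[DivergenceResult]) -> str:
    """TSV: gene, pi, ka, ks, ka/ks, site counts."""
    fmt = lambda v: "NA" if v is None else f"{v:.4f}"
    lines = ["gene\tpi\tka\tks\tka_ks\tn_codons\tsyn_sites\tnonsyn_sites"]
    for r in results:
        lines.append(
            f"{r.gene}\t{fmt(r.pi)}\t{fmt(r.ka)}\t{fmt(r.ks)}\t{fmt(r.ratio)}\t"
            f"{r.n_codons_compared}\t{r.n_syn_sites:.2f}\t{r.n_nonsyn_sites:.2f}"
        )
    return "\n".join(lines) + "\n"
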