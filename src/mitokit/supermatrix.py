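"""Concatenated 13-PCG codon alignment (supermatrix) construction.

Pipeline: per-gene codon-aware alignment (global affine alignment of the
translated sequences, progressive pairwise-to-profile in input taxon order,
codons threaded back so gaps come in multiples of 3), strict trimming (every
codon column containing any gap or ambiguity is dropped), concatenation in
the canonical gene order with a partition map, and a desk-scale
neighbor-joining tree from p-distance or K2P distances.

All tie-breaks are deterministic so outputs are reproducible byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio.Align import substitution_matrices

from .codon_usage import genetic_code
from .vocabulary import PCG_ORDER

__all__ = [
    "Supermatrix",
    "DistanceMatrix",
    "complete_stop",
    "translate",
    "align_gene",
    "trim_alignment",
    "concatenate",
    "distance_matrix",
    "nj_tree",
    "write_phylip",
    "write_nexus",
    "write_partitions",
]


def complete_stop(cds: str) -> str:
    """Pad a terminal incomplete stop (T or TA at the gene boundary) with
    'A' characters up to a full TAA; complete CDSs are returned unchanged."""
    rem = len(cds) % 3
    return cds if rem == 0 else cds + "A" * (3 - rem)


def translate(cds: str, code: int = 5) -> str:
    fwd, stops = genetic_code(code)
    aa = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3].upper()
        if codon in stops:
            aa.append("*")
        else:
            aa.append(fwd.get(codon, "X"))
    return "".join(aa)


# ---------------------------------------------------------------------------
# Progressive protein-guided alignment
# ---------------------------------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_GAP_OPEN = -10.0
_GAP_EXTEND = -0.5
_NEG = -1e30


def _char_score(x: str, y: str) -> float:
    if x == "-" or y == "-":
        return 0.0
    try:
        return float(_BLOSUM62[x, y])
    except (KeyError, IndexError):
        return float(_BLOSUM62["X", "X"]) if x == "X" or y == "X" else -1.0


def _col_score(col_a: tuple[str, ...], col_b: tuple[str, ...]) -> float:
    total = 0.0
    for x in col_a:
        for y in col_b:
            total += _char_score(x, y)
    return total / (len(col_a) * len(col_b))


def _align_profiles(prof_a: list[str], prof_b: list[str]) -> tuple[list[str], list[str]]:
    """Global affine (Gotoh) alignment of two gap-containing profiles.

    Ties prefer diagonal, then a gap in profile B, then a gap in profile A.
    Returns the two profiles with alignment gap columns inserted.
    """
    cols_a = list(zip(*prof_a)) if prof_a[0] else []
    cols_b = list(zip(*prof_b)) if prof_b[0] else []
    n, m = len(cols_a), len(cols_b)
    # M: match state, X: gap in B (consume A), Y: gap in A (consume B)
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = _GAP_OPEN + (i - 1) * _GAP_EXTEND
    for j in range(1, m + 1):
        Y[0][j] = _GAP_OPEN + (j - 1) * _GAP_EXTEND
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _col_score(cols_a[i - 1], cols_b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + _GAP_OPEN, X[i - 1][j] + _GAP_EXTEND)
            Y[i][j] = max(M[i][j - 1] + _GAP_OPEN, Y[i][j - 1] + _GAP_EXTEND)
    # traceback; stored optima equal one candidate exactly, so float
    # equality against the candidates is safe
    i, j = n, m
    best = max(M[n][m], X[n][m], Y[n][m])
    state = "M" if M[n][m] == best else ("X" if X[n][m] == best else "Y")
    steps: list[str] = []
    while (i, j) != (0, 0):
        if state == "M":
            steps.append("D")
            i, j = i - 1, j - 1
            mx = max(M[i][j], X[i][j], Y[i][j])
            state = "M" if M[i][j] == mx else ("X" if X[i][j] == mx else "Y")
        elif state == "X":
            steps.append("U")
            state = "M" if M[i - 1][j] + _GAP_OPEN >= X[i - 1][j] + _GAP_EXTEND else "X"
            i -= 1
        else:
            steps.append("L")
            state = "M" if M[i][j - 1] + _GAP_OPEN >= Y[i][j - 1] + _GAP_EXTEND else "Y"
            j -= 1
    steps.reverse()
    out_a = ["" for _ in prof_a]
    out_b = ["" for _ in prof_b]
    ia = ib = 0
    for step in steps:
        if step in ("D", "U"):
            for r, row in enumerate(prof_a):
                out_a[r] += row[ia]
            ia += 1
        else:
            for r in range(len(prof_a)):
                out_a[r] += "-"
        if step in ("D", "L"):
            for r, row in enumerate(prof_b):
                out_b[r] += row[ib]
            ib += 1
        else:
            for r in range(len(prof_b)):
                out_b[r] += "-"
    return out_a, out_b


def align_proteins(seqs: Sequence[str]) -> list[str]:
    """Progressive global alignment in input order (deterministic)."""
    if not seqs:
        return []
    profile = [seqs[0]]
    for nxt in seqs[1:]:
        profile, new = _align_profiles(profile, [nxt])
        profile = profile + new
    return profile


def align_gene(orthologs: dict[str, str], code: int = 5) -> dict[str, str]:
    """Codon-aware multiple alignment of per-taxon CDSs.

    The protein guide alignment is computed on the stop-completed,
    terminal-stop-trimmed translations; original codons are threaded back so
    removing gaps from any row reproduces that taxon's input CDS exactly.
    Taxa whose CDS has an internal stop after trimming are excluded with a
    warning entry (key dropped).
    """
    import warnings as _w

    if len(orthologs) < 2:
        raise ValueError("need at least two taxa")
    _, stops = genetic_code(code)
    usable: dict[str, tuple[str, str, str]] = {}  # taxon -> (cds, protein, tail)
    for taxon, cds in orthologs.items():
        cds = cds.upper()
        padded = complete_stop(cds)
        prot = translate(padded, code)
        if prot.endswith("*"):
            prot = prot[:-1]
        if "*" in prot:
            _w.warn(f"{taxon}: internal stop codon; excluded from alignment",
                    stacklevel=2)
            continue
        n_res = len(prot)
        usable[taxon] = (cds, prot, cds[3 * n_res:])
    if len(usable) < 2:
        raise ValueError("fewer than two translatable CDSs")
    taxa = list(usable)
    aligned_prot = align_proteins([usable[t][1] for t in taxa])
    max_tail = max(len(usable[t][2]) for t in taxa)
    tail_width = 3 * math.ceil(max_tail / 3)
    out: dict[str, str] = {}
    for t, aln in zip(taxa, aligned_prot):
        cds, _, tail = usable[t]
        codons, k = [], 0
        for ch in aln:
            if ch == "-":
                codons.append("---")
            else:
                codons.append(cds[3 * k : 3 * k + 3])
                k += 1
        out[t] = "".join(codons) + tail + "-" * (tail_width - len(tail))
    return out


def trim_alignment(aln: dict[str, str]) -> tuple[dict[str, str], dict]:
    """Drop every codon column containing any gap or ambiguity in any taxon.

    Returns (trimmed alignment, log) where the log records kept/removed codon
    column indices (0-based) and the retained fraction.
    """
    rows = list(aln.values())
    if not rows:
        raise ValueError("empty alignment")
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("rows differ in length")
    if L % 3:
        raise ValueError("alignment length not a multiple of 3")
    kept, removed = [], []
    for c in range(0, L, 3):
        ok = all(set(r[c : c + 3]) <= set("ACGT") for r in rows)
        (kept if ok else removed).append(c // 3)
    if not kept:
        raise ValueError("all codon columns removed by trimming")
    trimmed = {
        t: "".join(r[3 * c : 3 * c + 3] for c in kept) for t, r in aln.items()
    }
    log = {
        "kept_codon_columns": kept,
        "removed_codon_columns": removed,
        "retained_fraction": len(kept) / (L // 3),
    }
    return trimmed, log


# ---------------------------------------------------------------------------
# Concatenation
# ---------------------------------------------------------------------------

@dataclass
class Supermatrix:
    taxa: list[str]
    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]  # (gene, start, end), 1-based incl.
    missing: dict[str, list[str]] = field(default_factory=dict)  # gene -> taxa
    trimming_log: dict[str, dict] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def codon_partitions(self) -> list[tuple[str, int, int, int]]:
        """Gene x codon-position scheme: (name, start, end, step=3)."""
        out = []
        for gene, start, end in self.partitions:
            for pos in (1, 2, 3):
                out.append((f"{gene}_pos{pos}", start + pos - 1, end, 3))
        return out

    def write_fasta(self, path: str | Path) -> None:
        from .genome_model import write_fasta

        write_fasta(self.rows, path)


def concatenate(gene_alignments: dict[str, dict[str, str]],
                gene_order: Sequence[str] | None = None) -> Supermatrix:
    """Join per-gene alignments in canonical order into a Supermatrix.

    Taxa missing from a gene get an all-gap row for that gene (flagged).
    """
    if not gene_alignments:
        raise ValueError("no gene alignments")
    if gene_order is None:
        canon = [g for g in PCG_ORDER if g in gene_alignments]
        extra = sorted(g for g in gene_alignments if g not in PCG_ORDER)
        gene_order = canon + extra
    taxa: list[str] = []
    for aln in gene_alignments.values():
        for t in aln:
            if t in taxa:
                continue
            taxa.append(t)
    if len(taxa) != len(set(taxa)):
        raise ValueError("duplicated taxon name")
    rows = {t: [] for t in taxa}
    partitions: list[tuple[str, int, int]] = []
    missing: dict[str, list[str]] = {}
    pos = 0
    for gene in gene_order:
        aln = gene_alignments[gene]
        lengths = {len(s) for s in aln.values()}
        if len(lengths) != 1:
            raise ValueError(f"{gene}: rows differ in length")
        L = lengths.pop()
        for t in taxa:
            if t in aln:
                rows[t].append(aln[t])
            else:
                rows[t].append("-" * L)
                missing.setdefault(gene, []).append(t)
        partitions.append((gene, pos + 1, pos + L))
        pos += L
    return Supermatrix(
        taxa=taxa,
        rows={t: "".join(parts) for t, parts in rows.items()},
        partitions=partitions,
        missing=missing,
    )


# ---------------------------------------------------------------------------
# Distances and neighbor joining
# ---------------------------------------------------------------------------

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: list[list[float]]
    model: str

    def get(self, a: str, b: str) -> float:
        return self.d[self.taxa.index(a)][self.taxa.index(b)]


def _pair_distance(a: str, b: str, model: str) -> float:
    n = p = q = 0
    for x, y in zip(a, b):
        if x in "ACGT" and y in "ACGT":
            n += 1
            if x != y:
                if (x, y) in _TRANSITIONS:
                    p += 1
                else:
                    q += 1
    if n == 0:
        raise ValueError("zero comparable sites")
    if model == "p-distance":
        return (p + q) / n
    if model == "K2P":
        P, Q = p / n, q / n
        inner = (1 - 2 * P - Q) * math.sqrt(1 - 2 * Q)
        if inner <= 0:
            raise ValueError("K2P distance undefined (saturation)")
        return -0.5 * math.log(inner)
    raise ValueError(f"unknown model {model!r}")


def distance_matrix(m: Supermatrix, model: str = "p-distance") -> DistanceMatrix:
    taxa = m.taxa
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    k = len(taxa)
    d = [[0.0] * k for _ in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            d[i][j] = d[j][i] = _pair_distance(m.rows[taxa[i]], m.rows[taxa[j]], model)
    return DistanceMatrix(taxa=taxa, d=d, model=model)


class _Node:
    __slots__ = ("label", "children")  # children: list of (node, branch length)

    def __init__(self, label: str | None, children=None):
        self.label = label
        self.children = children or []

    def sort_key(self) -> str:
        if self.label is not None:
            return self.label
        return min(c.sort_key() for c, _ in self.children)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.12g}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(dm: DistanceMatrix) -> str:
    """Canonical neighbor joining; returns unrooted Newick text.

    Ties in the Q criterion break on the lexicographically smallest label
    pair; negative branch lengths are clamped to 0 with the deficit moved to
    the sibling branch.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least three taxa")
    for row in dm.d:
        for v in row:
            if v is None or math.isnan(v):
                raise ValueError("distance matrix has undefined entries")
    nodes: list[_Node] = [_Node(t) for t in dm.taxa]
    d = {(i, j): dm.d[i][j] for i in range(n) for j in range(n)}
    active = list(range(n))
    next_id = n

    def dist(i: int, j: int) -> float:
        return 0.0 if i == j else d[(min(i, j), max(i, j))]

    node_of: dict[int, _Node] = {i: nodes[i] for i in range(n)}
    while len(active) > 2:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                key = tuple(sorted((node_of[i].sort_key(), node_of[j].sort_key())))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = (q, key, i, j)
        _, _, i, j = best
        dij = dist(i, j)
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        u = _Node(None, [(node_of[i], li), (node_of[j], lj)])
        node_of[next_id] = u
        for k in active:
            if k in (i, j):
                continue
            d[(min(k, next_id), max(k, next_id))] = (
                dist(i, k) + dist(j, k) - dij
            ) / 2.0
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    i, j = active
    root = _Node(None, [(node_of[i], 0.0), (node_of[j], max(dist(i, j), 0.0))])
    return root.newick() + ";"


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_phylip(m: Supermatrix, path: str | Path) -> None:
    """Relaxed PHYLIP (names space-separated, not truncated)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f" {len(m.taxa)} {m.length}\n")
        for t in m.taxa:
            fh.write(f"{t}  {m.rows[t]}\n")


def write_nexus(m: Supermatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(m.taxa)} NCHAR={m.length};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
        for t in m.taxa:
            fh.write(f"    {t}  {m.rows[t]}\n")
        fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
        for gene, start, end in m.partitions:
            fh.write(f"  CHARSET {gene} = {start}-{end};\n")
        for name, start, end, step in m.codon_partitions():
            fh.write(f"  CHARSET {name} = {start}-{end}\\{step};\n")
        fh.write("END;\n")


def write_partitions(m: Supermatrix, path: str | Path, scheme: str = "gene") -> None:
    """RAxML-style partition file; scheme 'gene' or 'gene_codon'."""
    lines = []
    if scheme == "gene":
        for gene, start, end in m.partitions:
            lines.append(f"DNA, {gene} = {start}-{end}")
    elif scheme == "gene_codon":
        for name, start, end, step in m.codon_partitions():
            lines.append(f"DNA, {name} = {start}-{end}\\{step}")
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
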