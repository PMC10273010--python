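"""Synthetic mitogenome generator with recorded ground truth.

Emits circular ~15 kb genomes carrying the 37-gene ancestral insect
arrangement with realistic gene sizes, A/T-biased composition with positive
AT-skew and negative GC-skew on the majority strand, valid PCG reading
frames (ATN/TTG starts, complete TAA/TAG or incomplete T/TA stops), and a
control region filling the remainder.  ``evolve_pair`` produces two
descendant genomes whose protein-coding genes evolved under a per-gene
dN/dS enforced by acceptance-rejection (synonymous proposals always accepted,
nonsynonymous accepted with probability omega, stops always rejected), with
realized substitution counts recorded — ground truth for estimator tests.

All randomness flows from the mandatory config seed; identical seed and
config give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codon_usage import genetic_code
from .fixtures import PORRECTUS_TABLE, porrectus_features, sordidus_features
from .genome_model import (
    Direction,
    GeneFeature,
    MitoGenome,
    reverse_complement,
    write_feature_table,
)
from .vocabulary import ANCESTRAL_INSECT_ORDER, GENE_TYPES, GeneType

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_ancestor",
    "evolve_pair",
    "delete_random_codons",
    "write_fixture_tables",
    "DEFAULT_GENE_SIZES",
]

#: Default per-gene sizes (bp) for the simulator: the OP793792 layout.
DEFAULT_GENE_SIZES: dict[str, int] = {
    row[0]: row[2] - row[1] + 1 for row in PORRECTUS_TABLE
}

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    seed: int
    genome_length: int = 15174
    arrangement: tuple[tuple[str, bool], ...] = ANCESTRAL_INSECT_ORDER
    gene_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENE_SIZES))
    composition: tuple[float, float, float, float] = (0.427, 0.318, 0.097, 0.158)
    omega: float | dict[str, float] = 0.2
    syn_branch_length: float = 0.15
    kappa: float = 1.0  # transition/transversion proposal ratio
    indel_rate: float = 0.0
    spacer: int = 2     # bp between consecutive genes
    origin_shift: int = 0
    genetic_code_id: int = 5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition proportions must sum to 1")
        omegas = self.omega.values() if isinstance(self.omega, dict) else [self.omega]
        if any(w <= 0 for w in omegas):
            raise ValueError("omega must be > 0")

    def omega_for(self, gene: str) -> float:
        if isinstance(self.omega, dict):
            return self.omega.get(gene, 0.2)
        return self.omega


@dataclass
class SimTruth:
    features: list[GeneFeature]
    target_composition: tuple[float, float, float, float]
    omega: dict[str, float]
    syn_branch_length: float
    # gene -> {"syn": n, "nonsyn": n}, summed over both descendant branches
    realized: dict[str, dict[str, int]] = field(default_factory=dict)


def _complement_probs(p: tuple[float, float, float, float]) -> tuple[float, ...]:
    a, t, g, c = p
    return (t, a, c, g)  # A<->T, G<->C


def _draw_bases(rng: np.random.Generator, n: int, probs) -> str:
    """Draw ``n`` bases; ``probs`` ordered (A, T, G, C)."""
    a, t, g, c = probs
    return "".join(rng.choice(_BASES, size=n, p=[a, c, g, t]))


def _draw_codon(rng: np.random.Generator, probs, stops: frozenset[str]) -> str:
    while True:
        codon = _draw_bases(rng, 3, probs)
        if codon not in stops:
            return codon


def _generate_cds(rng: np.random.Generator, size: int, probs,
                  stops: frozenset[str], start_pool: tuple[str, ...]) -> str:
    """In-frame CDS of exactly ``size`` bp: start codon, stop-free interior,
    then TAA/TAG or an incomplete T/TA stop when size % 3 != 0."""
    if size < 9:
        raise ValueError("PCG size must be >= 9 bp")
    rem = size % 3
    n_codons = size // 3
    start = start_pool[rng.integers(len(start_pool))]
    if rem == 0:
        interior = [_draw_codon(rng, probs, stops) for _ in range(n_codons - 2)]
        stop = "TAA" if rng.random() < 0.75 else "TAG"
        return start + "".join(interior) + stop
    interior = [_draw_codon(rng, probs, stops) for _ in range(n_codons - 1)]
    return start + "".join(interior) + ("T" if rem == 1 else "TA")


def simulate_ancestor(cfg: SimConfig) -> tuple[MitoGenome, SimTruth]:
    """Generate the ancestral annotated genome plus its truth record."""
    rng = np.random.default_rng(cfg.seed)
    _, stops = genetic_code(cfg.genetic_code_id)
    p_fwd = cfg.composition
    parts: list[str] = []
    features: list[GeneFeature] = []
    cur = 1
    for gene, forward in cfg.arrangement:
        size = cfg.gene_sizes[gene]
        gt = GENE_TYPES[gene]
        probs = p_fwd if forward else _complement_probs(p_fwd)
        if gt is GeneType.PCG:
            start_pool = ("TTG",) if gene in ("cox1", "nad4l") else \
                ("ATT", "ATA", "ATG", "ATC")
            oriented = _generate_cds(rng, size, probs, stops, start_pool)
            segment = oriented if forward else reverse_complement(oriented)
        else:
            segment = _draw_bases(rng, size, p_fwd)
        parts.append(segment)
        features.append(GeneFeature(
            name=gene,
            gene_type=gt,
            start=cur,
            end=cur + size - 1,
            strand_label="N" if forward else "J",
            direction=Direction.FORWARD if forward else Direction.REVERSE,
        ))
        cur += size
        if cfg.spacer:
            parts.append(_draw_bases(rng, cfg.spacer, p_fwd))
            cur += cfg.spacer
    annotated_end = features[-1].end
    if cfg.spacer:
        parts.pop()  # trailing spacer merges into the control region
    control_len = cfg.genome_length - annotated_end
    if control_len < 1:
        raise ValueError(
            f"infeasible config: genes need {annotated_end} bp, "
            f"genome_length is {cfg.genome_length}")
    parts.append(_draw_bases(rng, control_len, p_fwd))
    sequence = "".join(parts)
    assert len(sequence) == cfg.genome_length
    genome = MitoGenome(
        accession=f"SIM{cfg.seed}",
        sequence=sequence,
        features=features,
        genetic_code_id=cfg.genetic_code_id,
    )
    if cfg.origin_shift:
        genome = rotate_genome(genome, cfg.origin_shift)
    truth = SimTruth(
        features=list(genome.features),
        target_composition=cfg.composition,
        omega={f.name: cfg.omega_for(f.name) for f in features
               if f.gene_type is GeneType.PCG},
        syn_branch_length=cfg.syn_branch_length,
    )
    return genome, truth


def rotate_genome(g: MitoGenome, shift: int) -> MitoGenome:
    """Rotate the circular sequence so old position ``shift + 1`` becomes 1;
    features crossing the new origin become wrapping features."""
    n = g.length
    shift %= n
    seq = g.sequence[shift:] + g.sequence[:shift]

    def move(pos: int) -> int:
        return (pos - 1 - shift) % n + 1

    feats = []
    for f in g.features:
        s, e = move(f.start), move(f.end)
        feats.append(GeneFeature(
            name=f.name, gene_type=f.gene_type, start=s, end=e,
            strand_label=f.strand_label, direction=f.direction,
            wraps_origin=e < s,
        ))
    return MitoGenome(accession=g.accession, sequence=seq, features=feats,
                      genetic_code_id=g.genetic_code_id)


# ---------------------------------------------------------------------------
# Descendant evolution
# ---------------------------------------------------------------------------

def _propose_base(rng: np.random.Generator, base: str, kappa: float) -> str:
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    others = [b for b in "ACGT" if b != base and b != transitions[base]]
    total = kappa + 2.0
    r = rng.random() * total
    if r < kappa:
        return transitions[base]
    return others[0] if r < kappa + 1.0 else others[1]


def _evolve_cds(rng: np.random.Generator, cds: str, omega: float,
                branch: float, kappa: float,
                stops: frozenset[str], fwd: dict[str, str]) -> tuple[str, int, int]:
    """One branch of codon evolution; returns (new cds, syn count, nonsyn count).

    The start codon and the terminal (complete or incomplete) stop are frozen.
    """
    n_codons = len(cds) // 3
    rem = len(cds) % 3
    last_mutable = n_codons - (1 if rem == 0 else 0)  # freeze complete stop
    codons = [cds[3 * i : 3 * i + 3] for i in range(n_codons)]
    tail = cds[3 * n_codons :]
    syn = non = 0
    for i in range(1, last_mutable):
        for pos in range(3):
            if rng.random() >= branch:
                continue
            cod = codons[i]
            nb = _propose_base(rng, cod[pos], kappa)
            new = cod[:pos] + nb + cod[pos + 1 :]
            if new in stops:
                continue
            if fwd[new] == fwd[cod]:
                codons[i] = new
                syn += 1
            elif rng.random() < omega:
                codons[i] = new
                non += 1
    return "".join(codons) + tail, syn, non


def _evolve_neutral(rng: np.random.Generator, seq: str, branch: float,
                    kappa: float) -> str:
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < branch)[0]
    for i in hits:
        out[i] = _propose_base(rng, out[i], kappa)
    return "".join(out)


def evolve_pair(ancestor: MitoGenome, cfg: SimConfig) -> tuple[MitoGenome, MitoGenome, SimTruth]:
    """Evolve two independent descendants from ``ancestor``.

    PCGs evolve at codon resolution under the per-gene omega acceptance
    rule; everything else evolves neutrally.  Realized synonymous and
    nonsynonymous substitution counts (summed over both branches) are
    recorded per gene.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    fwd, stops = genetic_code(cfg.genetic_code_id)
    truth = SimTruth(
        features=list(ancestor.features),
        target_composition=cfg.composition,
        omega={f.name: cfg.omega_for(f.name) for f in ancestor.features
               if f.gene_type is GeneType.PCG},
        syn_branch_length=cfg.syn_branch_length,
        realized={f.name: {"syn": 0, "nonsyn": 0} for f in ancestor.features
                  if f.gene_type is GeneType.PCG},
    )
    pcgs = [f for f in ancestor.features if f.gene_type is GeneType.PCG]
    in_pcg = np.zeros(ancestor.length, dtype=bool)
    for f in pcgs:
        if f.wraps_origin:
            in_pcg[f.start - 1 :] = True
            in_pcg[: f.end] = True
        else:
            in_pcg[f.start - 1 : f.end] = True

    descendants = []
    for _branch_idx in range(2):
        seq = list(ancestor.sequence)
        for f in pcgs:
            from .genome_model import extract_sequence

            cds = extract_sequence(ancestor, f)
            new_cds, syn, non = _evolve_cds(
                rng, cds, cfg.omega_for(f.name), cfg.syn_branch_length,
                cfg.kappa, stops, fwd)
            truth.realized[f.name]["syn"] += syn
            truth.realized[f.name]["nonsyn"] += non
            placed = new_cds if f.direction is Direction.FORWARD \
                else reverse_complement(new_cds)
            if f.wraps_origin:
                head = ancestor.length - (f.start - 1)
                seq[f.start - 1 :] = placed[:head]
                seq[: f.end] = placed[head:]
            else:
                seq[f.start - 1 : f.end] = placed
        # neutral background on all non-PCG positions
        bg_idx = np.nonzero(~in_pcg)[0]
        bg = _evolve_neutral(rng, "".join(seq[i] for i in bg_idx),
                             cfg.syn_branch_length, cfg.kappa)
        for i, ch in zip(bg_idx, bg):
            seq[i] = ch
        descendants.append(MitoGenome(
            accession=f"{ancestor.accession}_D{_branch_idx + 1}",
            sequence="".join(seq),
            features=list(ancestor.features),
            genetic_code_id=ancestor.genetic_code_id,
        ))
    return descendants[0], descendants[1], truth


def delete_random_codons(cds: str, rng: np.random.Generator,
                         rate: float) -> str:
    """Drop whole interior codons with probability ``rate`` each — a clean
    frame-preserving indel generator for alignment tests."""
    n = len(cds) // 3
    kept = [cds[3 * i : 3 * i + 3] for i in range(n)
            if i in (0, n - 1) or rng.random() >= rate]
    return "".join(kept) + cds[3 * n :]


def write_fixture_tables(outdir: str | Path) -> dict[str, Path]:
    """Emit the two reference annotation tables as feature-table TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, feats in (("porrectus", porrectus_features()),
                        ("sordidus", sordidus_features())):
        p = outdir / f"{name}_features.tsv"
        write_feature_table(feats, p)
        paths[name] = p
    return paths
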