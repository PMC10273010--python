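# mitokit

Comparative analytics for annotated insect mitochondrial genomes (~15 kb,
37 genes + control region):

- **genome model** — GenBank / FASTA / feature-table IO, 1-based inclusive
  coordinates, circular (origin-wrapping) features, canonical gene-name
  vocabulary with synonym resolution, annotation validation.
- **composition** — base content, A+T%, AT-skew `(A−T)/(A+T)` and GC-skew
  `(G−C)/(G+C)` for whole genomes and per gene; start/stop codon typing
  including incomplete `T–`/`TA–` stops.
- **codon usage** — codon counts and RSCU over the concatenated 13 PCGs
  (invertebrate mitochondrial code by default, `--code` to override).
- **architecture** — gene-overlap and intergenic-spacer ledgers, strand
  distribution cross-tabs, circular gene-order comparison against the
  ancestral insect arrangement.
- **divergence** — pairwise nucleotide diversity (Pi) and Ka/Ks via
  Nei–Gojobori (1986) pathway counting with Jukes–Cantor correction.
- **supermatrix** — codon-aware progressive alignment (protein-guided,
  affine gaps, deterministic), strict gap-free-codon-column trimming,
  concatenation with gene and gene×codon partition maps, FASTA / relaxed
  PHYLIP / NEXUS / partition-file writers, p-distance / K2P distances and a
  neighbor-joining tree.
- **synthetic data** — a seeded mitogenome simulator with recorded ground
  truth (gene layout, composition targets, per-gene dN/dS via
  acceptance-rejection codon evolution), used throughout the test suite.

## CLI

```bash
mitokit simulate --seed 1 --out sim/            # synthetic genome + diverged pair + truth
mitokit profile --genbank sim/ancestor.gb --out prof/   # composition, ledger, RSCU, strands
mitokit profile --fasta genome.fasta --features genes.tsv --out prof/
mitokit compare sim/descendant_a.gb sim/descendant_b.gb --out cmp/   # per-gene Pi/Ka/Ks
mitokit supermatrix g1.gb g2.gb g3.gb --out sm/  # alignment, partitions, NJ tree
mitokit validate --genbank sim/ancestor.gb       # 37-gene vocabulary check
```

Common flags: `--code` (NCBI translation table, default 5), `--precision`,
`--out`, `--verbose`, and `--config config.yaml` (file supplies defaults,
command line wins). Feature tables are TSV with required header
`gene  start  end  strand  direction`.

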