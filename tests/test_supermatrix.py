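import itertools
import math

import dendropy
import numpy as np
import pytest

from mitokit.genome_model import read_fasta
from mitokit.supermatrix import (
    DistanceMatrix,
    Supermatrix,
    align_gene,
    complete_stop,
    concatenate,
    distance_matrix,
    nj_tree,
    translate,
    trim_alignment,
    write_nexus,
    write_partitions,
    write_phylip,
)
from mitokit.supermatrix import align_proteins
from mitokit.synthetic_data import SimConfig, delete_random_codons, evolve_pair, simulate_ancestor


class TestCompleteStop:
    def test_mod1_appends_aa(self):
        assert complete_stop("ATGAAAT") == "ATGAAATAA"

    def test_mod2_appends_a(self):
        assert complete_stop("ATGAAATA") == "ATGAAATAA"

    def test_complete_unchanged(self):
        assert complete_stop("ATGAAATAA") == "ATGAAATAA"


class TestAlignment:
    def test_identical_no_gaps(self):
        aln = align_gene({"a": "ATGAAACCC", "b": "ATGAAACCC"})
        assert aln == {"a": "ATGAAACCC", "b": "ATGAAACCC"}

    def test_protein_guide_gap(self):
        # "MKV" vs "MV": single residue gap at position 2
        prot = align_proteins(["MKV", "MV"])
        assert prot == ["MKV", "M-V"]

    def test_clean_codon_deletion_restored(self):
        cds = "ATGAAACCCGGGTTTACATTA"
        short = cds[:9] + cds[12:]  # drop codon 4 (GGG)
        aln = align_gene({"x": cds, "y": short})
        assert aln["x"] == cds
        assert aln["y"].count("-") == 3
        assert aln["y"].replace("-", "") == short

    def test_back_threading_reproduces_inputs(self, sim_pair):
        a, b, _ = sim_pair
        rng = np.random.default_rng(5)
        for gene in ("nad2", "cox1", "nad4l"):
            sa = a.gene_sequence(gene)
            sb = delete_random_codons(b.gene_sequence(gene), rng, 0.05)
            aln = align_gene({"a": sa, "b": sb})
            assert aln["a"].replace("-", "") == sa
            assert aln["b"].replace("-", "") == sb
            assert len(aln["a"]) == len(aln["b"])
            for row in aln.values():  # gaps only in whole-codon runs
                assert len(row) % 3 == 0

    def test_internal_stop_excluded(self):
        good = "ATGAAACCCGGGTTT"
        bad = "ATGTAACCCGGGTTT"  # internal stop after start
        with pytest.warns(UserWarning, match="internal stop"):
            with pytest.raises(ValueError):
                align_gene({"a": good, "b": bad})

    def test_needs_two_taxa(self):
        with pytest.raises(ValueError):
            align_gene({"a": "ATGAAA"})


class TestTrim:
    def test_gapless_unchanged(self):
        aln = {"a": "ATGAAA", "b": "ATGAAA"}
        out, log = trim_alignment(aln)
        assert out == aln
        assert log["retained_fraction"] == 1.0

    def test_gap_column_removed(self):
        aln = {"a": "ATGAAACCC", "b": "ATG---CCC"}
        out, log = trim_alignment(aln)
        assert out == {"a": "ATGCCC", "b": "ATGCCC"}
        assert log["removed_codon_columns"] == [1]

    def test_retained_fraction_matches_recount(self, sim_pair):
        a, b, _ = sim_pair
        rng = np.random.default_rng(9)
        sa = a.gene_sequence("nad5")
        sb = delete_random_codons(b.gene_sequence("nad5"), rng, 0.10)
        aln = align_gene({"a": sa, "b": sb})
        out, log = trim_alignment(aln)
        # independent recount of gap-free codon columns
        n_cols = len(aln["a"]) // 3
        clean = sum(
            1 for c in range(n_cols)
            if all(set(row[3 * c : 3 * c + 3]) <= set("ACGT")
                   for row in aln.values())
        )
        assert log["retained_fraction"] == pytest.approx(clean / n_cols)
        assert len(out["a"]) == 3 * clean

    def test_all_removed_errors(self):
        with pytest.raises(ValueError):
            trim_alignment({"a": "---", "b": "ATG"})


class TestConcatenate:
    def test_two_genes(self):
        m = concatenate({
            "nad2": {"a": "A" * 300, "b": "C" * 300},
            "cox1": {"a": "G" * 600, "b": "T" * 600},
        })
        assert m.length == 900
        assert m.partitions == [("nad2", 1, 300), ("cox1", 301, 900)]

    def test_single_gene_identity(self):
        aln = {"a": "ATGAAA", "b": "ATGCCC"}
        m = concatenate({"nad2": aln})
        assert m.rows == aln

    def test_canonical_gene_order(self, sim_pair):
        a, b, _ = sim_pair
        alns = {g: align_gene({"a": sa, "b": b.gene_sequence(g)})
                for g, sa in a.pcg_sequences().items()}
        m = concatenate(alns)
        assert [p[0] for p in m.partitions] == [
            "nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
            "nad5", "nad4", "nad4l", "nad6", "cob", "nad1"]
        assert len(m.partitions) == 13
        assert len(m.codon_partitions()) == 39

    def test_partitions_tile_exactly(self, sim_pair):
        a, b, _ = sim_pair
        alns = {g: align_gene({"a": sa, "b": b.gene_sequence(g)})
                for g, sa in a.pcg_sequences().items()}
        m = concatenate(alns)
        covered = []
        for _, start, end in m.partitions:
            covered.extend(range(start, end + 1))
        assert covered == list(range(1, m.length + 1))
        assert m.length == sum(len(next(iter(v.values()))) for v in alns.values())

    def test_missing_taxon_gap_filled(self):
        m = concatenate({
            "nad2": {"a": "ATG", "b": "ATG"},
            "cox1": {"a": "AAA"},
        })
        assert m.rows["b"] == "ATG---"
        assert m.missing == {"cox1": ["b"]}


class TestDistances:
    def _matrix(self, rows):
        return Supermatrix(taxa=list(rows), rows=rows,
                           partitions=[("nad2", 1, len(next(iter(rows.values()))))])

    def test_identical_zero(self):
        dm = distance_matrix(self._matrix({"a": "ACGT", "b": "ACGT"}))
        assert dm.get("a", "b") == 0.0

    def test_p_distance(self):
        dm = distance_matrix(self._matrix({"a": "AAAA", "b": "AATT"}))
        assert dm.get("a", "b") == 0.5

    def test_k2p_closed_form(self):
        # 2 transitions (A<->G), 1 transversion (A<->T) over 10 sites
        a = "AAAAAAAAAA"
        b = "GGTAAAAAAA"
        dm = distance_matrix(self._matrix({"a": a, "b": b}), model="K2P")
        P, Q = 0.2, 0.1
        expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
        assert dm.get("a", "b") == pytest.approx(expected)

    def test_zero_comparable_sites_errors(self):
        with pytest.raises(ValueError):
            distance_matrix(self._matrix({"a": "NNNN", "b": "ACGT"}))


def random_additive_matrix(rng, n_taxa):
    """Random additive distances built by random cluster joins (oracle-side,
    independent of the NJ implementation)."""
    taxa = [f"T{i}" for i in range(n_taxa)]
    depth = {t: {t: 0.0} for t in taxa}  # cluster -> leaf -> depth
    clusters = [[t] for t in taxa]
    depths = [{t: 0.0} for t in taxa]
    d = {}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        la, lb = rng.uniform(0.1, 1.0, size=2)
        for x in clusters[i]:
            for y in clusters[j]:
                d[frozenset((x, y))] = depths[i][x] + la + lb + depths[j][y]
        merged = clusters[i] + clusters[j]
        mdepth = {x: depths[i][x] + la for x in clusters[i]}
        mdepth.update({y: depths[j][y] + lb for y in clusters[j]})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        depths = [dp for k, dp in enumerate(depths) if k not in (i, j)] + [mdepth]
    mat = [[0.0] * n_taxa for _ in range(n_taxa)]
    for a, b in itertools.combinations(range(n_taxa), 2):
        mat[a][b] = mat[b][a] = d[frozenset((taxa[a], taxa[b]))]
    return taxa, mat


def patristic(newick, taxa):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    name = {t.label: t for t in tree.taxon_namespace}
    out = {}
    for a, b in itertools.combinations(taxa, 2):
        out[(a, b)] = pdm.patristic_distance(name[a], name[b])
    return out


class TestNJ:
    def test_four_taxon_additive(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive matrix
        taxa = ["A", "B", "C", "D"]
        D = {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
             ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7}
        mat = [[0.0] * 4 for _ in range(4)]
        for (a, b), v in D.items():
            i, j = taxa.index(a), taxa.index(b)
            mat[i][j] = mat[j][i] = float(v)
        nwk = nj_tree(DistanceMatrix(taxa, mat, "p-distance"))
        got = patristic(nwk, taxa)
        for pair, v in D.items():
            assert got[pair] == pytest.approx(v, abs=1e-9)
        # split AB|CD: patristic AB and CD are both smaller than cross pairs
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        splits = {frozenset(l.taxon.label for l in e.leaf_nodes())
                  for e in tree.preorder_node_iter()}
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_three_taxa(self):
        mat = [[0.0, 2.0, 3.0], [2.0, 0.0, 4.0], [3.0, 4.0, 0.0]]
        nwk = nj_tree(DistanceMatrix(["a", "b", "c"], mat, "p-distance"))
        got = patristic(nwk, ["a", "b", "c"])
        assert got[("a", "b")] == pytest.approx(2.0)
        assert got[("a", "c")] == pytest.approx(3.0)
        assert got[("b", "c")] == pytest.approx(4.0)

    def test_needs_three(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], [[0, 1], [1, 0]], "p-distance"))

    def test_100_random_additive_trees(self):
        rng = np.random.default_rng(123)
        for rep in range(100):
            n = int(rng.integers(4, 9))
            taxa, mat = random_additive_matrix(rng, n)
            nwk = nj_tree(DistanceMatrix(taxa, mat, "p-distance"))
            got = patristic(nwk, taxa)
            for a, b in itertools.combinations(range(n), 2):
                assert got[(taxa[a], taxa[b])] == pytest.approx(
                    mat[a][b], abs=1e-8), (rep, taxa[a], taxa[b])

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        taxa, mat = random_additive_matrix(rng, 6)
        dm = DistanceMatrix(taxa, mat, "p-distance")
        assert nj_tree(dm) == nj_tree(dm)


class TestWriters:
    @pytest.fixture()
    def matrix(self):
        return concatenate({
            "nad2": {"a": "ATGAAA", "b": "ATGCCC", "c": "ATGAAA"},
            "cox1": {"a": "TTTGGGAAA", "b": "TTTGGGAAA", "c": "TTTGGCAAA"},
        })

    def test_fasta_round_trip(self, matrix, tmp_path):
        p = tmp_path / "m.fasta"
        matrix.write_fasta(p)
        back = read_fasta(p)
        assert back == matrix.rows

    def test_phylip(self, matrix, tmp_path):
        p = tmp_path / "m.phy"
        write_phylip(matrix, p)
        header, *rows = p.read_text().strip().splitlines()
        assert header.split() == ["3", "15"]
        parsed = dict(r.split() for r in rows)
        assert parsed == matrix.rows

    def test_nexus(self, matrix, tmp_path):
        p = tmp_path / "m.nex"
        write_nexus(matrix, p)
        text = p.read_text()
        assert "NTAX=3 NCHAR=15" in text
        assert "CHARSET nad2 = 1-6;" in text
        assert "CHARSET cox1_pos2 = 8-15\\3;" in text
        for t, row in matrix.rows.items():
            assert row in text

    def test_partition_files(self, matrix, tmp_path):
        p1 = tmp_path / "genes.txt"
        write_partitions(matrix, p1, scheme="gene")
        assert p1.read_text() == "DNA, nad2 = 1-6\nDNA, cox1 = 7-15\n"
        p2 = tmp_path / "codon.txt"
        write_partitions(matrix, p2, scheme="gene_codon")
        assert len(p2.read_text().strip().splitlines()) == 6


def test_simulated_quartet_nj_recovery():
    """Two pairs evolved from two distant ancestors: NJ must pair siblings."""
    cfg1 = SimConfig(seed=31, omega=0.2, syn_branch_length=0.05)
    cfg2 = SimConfig(seed=32, omega=0.2, syn_branch_length=0.05)
    anc1, _ = simulate_ancestor(cfg1)
    anc2, _ = simulate_ancestor(cfg2)
    a1, b1, _ = evolve_pair(anc1, cfg1)
    a2, b2, _ = evolve_pair(anc2, cfg2)
    taxa = {"p1": a1, "p2": b1, "q1": a2, "q2": b2}
    alns = {}
    for gene in ("nad2", "cox1", "cob"):
        aln = align_gene({t: g.gene_sequence(gene) for t, g in taxa.items()})
        alns[gene], _ = trim_alignment(aln)
    m = concatenate(alns)
    nwk = nj_tree(distance_matrix(m))
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    splits = {frozenset(l.taxon.label for l in e.leaf_nodes())
              for e in tree.preorder_node_iter() if not e.is_leaf()}
    assert frozenset({"p1", "p2"}) in splits or frozenset({"q1", "q2"}) in splits
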