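import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from paleochron.supermatrix import (
    GeneAlignment, concatenate, read_gene_alignments,
    count_parsimony_informative, gc_content, rscu, rscu_pca, codon_counts,
    build_partition_schemes, filter_taxa_by_gene_count, _FAMILIES)
from conftest import write_fasta


class TestReadAndConcatenate:
    def test_reads_one_record_per_gene(self, tmp_path):
        p1 = write_fasta(tmp_path / "nad1.fasta",
                         [("A", "ATGAAA"), ("B", "ATGAAG"), ("C", "ATGAAT")])
        p2 = write_fasta(tmp_path / "cox1.fasta",
                         [("A", "GGGCCC"), ("B", "GGACCC"), ("C", "GGGCCA")])
        genes = read_gene_alignments([p1, p2])
        assert [g.name for g in genes] == ["nad1", "cox1"]
        assert all(len(g.taxa) == 3 for g in genes)

    def test_rejects_non_codon_length(self, tmp_path):
        p = write_fasta(tmp_path / "bad.fasta", [("A", "ATGAAATTTC")])
        with pytest.raises(ValueError, match="not multiple of 3"):
            read_gene_alignments([p])

    def test_rejects_duplicate_taxon(self):
        with pytest.raises(ValueError, match="duplicate taxon"):
            GeneAlignment("g", ["A", "A"], ["ATG", "ATG"])

    def test_concatenation_boundaries_and_gap_fill(self, toy_genes):
        m = concatenate(toy_genes)
        assert m.n_sites == 15
        assert m.gene_boundaries == [("gene1", 0, 6), ("gene2", 6, 15)]
        # taxon C absent from gene2 -> gap-filled there
        assert m.sequence("C") == "ATGAAT" + "-" * 9

    def test_single_gene_concatenation_is_identity(self):
        g = GeneAlignment("g", ["A", "B"], ["ATGCCC", "ATGCCA"])
        m = concatenate([g])
        assert m.sequence("A") == "ATGCCC"
        assert m.sequence("B") == "ATGCCA"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            concatenate([])

    def test_gene_slice_round_trip(self, toy_genes):
        m = concatenate(toy_genes)
        back = m.gene_slice("gene1")
        assert back.sequences[:3] == ["ATGAAA", "ATGAAG", "ATGAAT"]

    def test_codon_positions_cycle_within_genes(self, toy_matrix):
        pos = toy_matrix.codon_position
        assert list(pos[:6]) == [1, 2, 3, 1, 2, 3]
        assert list(pos[6:9]) == [1, 2, 3]

    def test_min_gene_filter(self, toy_genes):
        kept = filter_taxa_by_gene_count(toy_genes, min_genes=2)
        assert all("C" not in g.taxa for g in kept)


class TestParsimonyInformative:
    def test_column_with_two_state_pairs_is_informative(self):
        g = GeneAlignment("g", list("wxyz"), ["AAA", "AAA", "CAA", "CAA"])
        m = concatenate([g])
        counts = count_parsimony_informative(m)
        assert counts[1] == 1 and counts[2] == 0 and counts[3] == 0
        assert counts["total"] == 1

    def test_all_singleton_states_not_informative(self):
        g = GeneAlignment("g", list("wxyz"), ["AAA", "CAA", "GAA", "TAA"])
        m = concatenate([g])
        assert count_parsimony_informative(m)["total"] == 0

    def test_gaps_do_not_count_as_states(self):
        g = GeneAlignment("g", list("wxyz"), ["AAA", "AAA", "-AA", "-AA"])
        m = concatenate([g])
        assert count_parsimony_informative(m)["total"] == 0

    def test_per_position_counts_sum_to_total(self, rng):
        seqs = ["".join(rng.choice(list("ACGT-"), 30)) for _ in range(6)]
        m = concatenate([GeneAlignment("g", [f"t{i}" for i in range(6)],
                                       seqs)])
        c = count_parsimony_informative(m)
        assert c["total"] == c[1] + c[2] + c[3]

    def test_empty_filter_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            count_parsimony_informative(toy_matrix, positions=())


class TestGCContent:
    def test_pure_gc_sequence(self):
        g = GeneAlignment("g", ["A"], ["GGCCGC"])
        table, _ = gc_content(concatenate([g]))
        assert table.loc["A", "gc_all"] == 1.0

    def test_balanced_sequence(self):
        g = GeneAlignment("g", ["A"], ["ATGCAT"])
        table, _ = gc_content(concatenate([g]))
        assert table.loc["A", "gc_all"] == pytest.approx(2 / 6)

    def test_gc_all_is_count_weighted_combination(self, rng):
        seqs = ["".join(rng.choice(list("ACGT-N"), 60)) for _ in range(4)]
        m = concatenate([GeneAlignment("g", list("wxyz"), seqs)])
        table, _ = gc_content(m)
        for t in m.taxa:
            r = table.loc[t]
            num = sum(r[f"gc_{p}"] * r[f"n_{p}"] for p in (1, 2, 3)
                      if r[f"n_{p}"] > 0)
            den = sum(r[f"n_{p}"] for p in (1, 2, 3))
            assert r["gc_all"] == pytest.approx(num / den)

    def test_all_gap_taxon_flagged_nan_and_excluded_from_means(self):
        g = GeneAlignment("g", ["A", "B"], ["GGG", "---"])
        m = concatenate([g], lineage_of={"A": "L", "B": "L"})
        table, means = gc_content(m)
        assert np.isnan(table.loc["B", "gc_all"])
        assert means.loc["L", "gc_all"] == 1.0

    def test_lineage_means_are_unweighted(self):
        g = GeneAlignment("g", ["A", "B"], ["GGGGGG", "GGGAT-"])
        m = concatenate([g], lineage_of={"A": "L", "B": "L"})
        _, means = gc_content(m)
        assert means.loc["L", "gc_all"] == pytest.approx((1.0 + 3 / 5) / 2)


class TestRSCU:
    def test_uniform_usage_gives_all_ones(self):
        # every codon of the Phe family (TTT/TTC) used once each, etc.
        seq = "".join(c for cs in _FAMILIES.values() for c in cs)
        g = GeneAlignment("g", ["A"], [seq])
        table = rscu(concatenate([g]))
        assert np.allclose(table.loc["A"], 1.0)

    def test_two_codon_family_three_to_one(self):
        # Phe: TTT x3, TTC x1 -> RSCU 1.5 / 0.5
        g = GeneAlignment("g", ["A"], ["TTTTTTTTTTTC"])
        table = rscu(concatenate([g]))
        assert table.loc["A", "TTT"] == pytest.approx(1.5)
        assert table.loc["A", "TTC"] == pytest.approx(0.5)

    def test_matches_hand_tally_on_toy_gene(self):
        # hand-counted: GGG x2, GGA x1 (Gly, k=4); AAA x1 (Lys, k=2)
        seqs = {"A": "GGGGGGGGAAAA", "B": "GGAGGAGGAAAG",
                "C": "GGGAAAAAGAAA"}
        g = GeneAlignment("g", list(seqs), list(seqs.values()))
        table = rscu(concatenate([g]))
        # A: Gly counts GGG=2 GGA=1 -> RSCU(GGG)=4*2/3, RSCU(GGA)=4/3
        assert table.loc["A", "GGG"] == pytest.approx(8 / 3)
        assert table.loc["A", "GGA"] == pytest.approx(4 / 3)
        # A: Lys AAA=1, AAG=0 -> 2.0 / 0.0
        assert table.loc["A", "AAA"] == pytest.approx(2.0)
        assert table.loc["A", "AAG"] == 0.0
        # C: Lys AAA=2, AAG=1 -> 4/3, 2/3
        assert table.loc["C", "AAA"] == pytest.approx(4 / 3)
        assert table.loc["C", "AAG"] == pytest.approx(2 / 3)

    def test_ambiguous_codons_skipped(self):
        g = GeneAlignment("g", ["A"], ["TTTNNNTT-"])
        counts = codon_counts(concatenate([g]))
        assert counts.loc["A"].sum() == 1      # only the complete TTT

    def test_family_means_equal_one_when_observed(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 300)) for _ in range(3)]
        table = rscu(concatenate([GeneAlignment("g", list("abc"), seqs)]))
        counts = codon_counts(concatenate(
            [GeneAlignment("g", list("abc"), seqs)]))
        for taxon in table.index:
            for aa, codons in _FAMILIES.items():
                if counts.loc[taxon, codons].sum() > 0:
                    assert table.loc[taxon, codons].mean() == \
                        pytest.approx(1.0)

    def test_no_complete_codons_rejected(self):
        g = GeneAlignment("g", ["A"], ["---"])
        with pytest.raises(ValueError, match="no complete codons"):
            rscu(concatenate([g]))


class TestRscuPCA:
    def test_identical_taxa_identical_coordinates(self):
        t = pd.DataFrame([[1.5, 0.5, 1.0], [1.5, 0.5, 1.0],
                          [0.5, 1.5, 1.0]], index=list("abc"))
        coords, _ = rscu_pca(t)
        assert np.allclose(coords.loc["a"], coords.loc["b"])

    def test_explained_variance_sums_to_one(self, rng):
        t = pd.DataFrame(rng.random((6, 10)))
        _, frac = rscu_pca(t)
        assert frac.sum() == pytest.approx(1.0)

    def test_constant_table_degenerate(self):
        t = pd.DataFrame(np.ones((4, 5)))
        coords, frac = rscu_pca(t)
        assert np.allclose(coords, 0.0)

    def test_pc1_separates_two_gc_groups(self):
        from paleochron.likelihood import SubstModel
        from paleochron.synthetic import (bd_for_target, simulate_alignment,
                                          simulate_bd_tree,
                                          simulate_branch_rates)
        tree = simulate_bd_tree(bd_for_target(8, 1500.0), 1500.0, 8, seed=42)
        left, right = tree.children[tree.root]
        lineages = {tree.taxon_names[t]: "hi" for t in tree.tips_below(left)}
        lineages |= {tree.taxon_names[t]: "lo"
                     for t in tree.tips_below(right)}
        rates = simulate_branch_rates(tree, 0.1, 0.0, seed=1)
        matrix = simulate_alignment(
            tree, rates, SubstModel(), 3000, seed=2, lineage_of=lineages,
            composition_map={"hi": 0.7, "lo": 0.3})
        table = rscu(matrix)
        coords, _ = rscu_pca(table)
        hi = coords.loc[[t for t, l in lineages.items() if l == "hi"], "PC1"]
        lo = coords.loc[[t for t, l in lineages.items() if l == "lo"], "PC1"]
        # linear separability along PC1 (positive silhouette)
        assert hi.min() > lo.max() or lo.min() > hi.max()


class TestPartitionSchemes:
    def test_block_counts_for_g_genes(self, rng):
        genes = [GeneAlignment(f"g{i}", ["A", "B"],
                               ["".join(rng.choice(list("ACGT"), 6))] * 2)
                 for i in range(5)]
        schemes = build_partition_schemes(concatenate(genes))
        assert [s.n_blocks for s in schemes] == [1, 2, 3, 5, 10, 15]

    def test_single_gene_block_counts(self, rng):
        m = concatenate([GeneAlignment("g", ["A"], ["ATGCCCAAA"])])
        schemes = build_partition_schemes(m)
        assert [s.n_blocks for s in schemes] == [1, 2, 3, 1, 2, 3]

    def test_blocks_disjointly_cover_all_columns(self, toy_matrix):
        for scheme in build_partition_schemes(toy_matrix):
            assert scheme.validate_covers(toy_matrix.n_sites)

    def test_fine_schemes_refine_coarse(self, toy_matrix):
        schemes = {s.name: s for s in build_partition_schemes(toy_matrix)}
        pairs = [("unpartitioned", "by_gene"),
                 ("pos12_vs_3", "by_gene_pos12_vs_3"),
                 ("by_position", "by_gene_and_position")]
        for coarse, fine in pairs:
            for _, cols in schemes[coarse].blocks:
                cset = set(cols.tolist())
                used = set()
                for _, fcols in schemes[fine].blocks:
                    fset = set(fcols.tolist())
                    if fset <= cset:
                        used |= fset
                assert used == cset

    def test_raxml_format(self, tmp_path, toy_matrix):
        scheme = build_partition_schemes(toy_matrix)[2]   # by position
        out = tmp_path / "parts.txt"
        scheme.to_raxml(out)
        lines = out.read_text().strip().splitlines()
        assert lines[0].startswith("DNA, pos1 = ")
        assert "\\3" in lines[0]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=5), min_size=1,
                    max_size=6))
    def test_any_gene_structure_covers_columns(self, codon_counts_):
        rng = np.random.default_rng(sum(codon_counts_))
        genes = [GeneAlignment(f"g{i}", ["A", "B"],
                               ["".join(rng.choice(list("ACGT"), 3 * k))] * 2)
                 for i, k in enumerate(codon_counts_)]
        m = concatenate(genes)
        for scheme in build_partition_schemes(m):
            assert scheme.validate_covers(m.n_sites)


class TestIO:
    def test_fasta_phylip_round_trip(self, tmp_path, toy_matrix):
        from Bio import AlignIO
        fp = tmp_path / "m.fasta"
        toy_matrix.to_fasta(fp)
        aln = AlignIO.read(fp, "fasta")
        assert len(aln) == toy_matrix.n_taxa
        pp = tmp_path / "m.phy"
        toy_matrix.to_phylip(pp)
        aln2 = AlignIO.read(pp, "phylip-relaxed")
        assert str(aln2[0].seq) == toy_matrix.sequence(toy_matrix.taxa[0])
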