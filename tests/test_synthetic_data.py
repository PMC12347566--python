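import numpy as np
import pytest

from rbcskit.codons import CODON_TO_AA, is_stop
from rbcskit.errors import InputError, PlanError
from rbcskit.io_core import read_newick
from rbcskit.promoter_cre import default_motif_library, find_paired_ibox, scan_motifs
from rbcskit.synthetic_data import (
    SimulationConfig,
    make_expression_matrix,
    make_genome_with_arrays,
    make_promoters,
    make_toy_complex,
    simulate_codon_evolution,
)


def translate(seq: str) -> str:
    return "".join(CODON_TO_AA[seq[i:i + 3]] for i in range(0, len(seq), 3))


class TestGenomeWithArrays:
    def test_cluster_span_arithmetic(self):
        cfg = SimulationConfig(seed=1, array_size=5, array_gap=50_000,
                               gene_length=1_000)
        _, genes = make_genome_with_arrays(cfg)
        cluster = [g for g in genes if "arr" in g.gene_id]
        span = max(g.end for g in cluster) - min(g.start for g in cluster) + 1
        assert span == 5 * 1_000 + 4 * 50_000

    def test_no_cluster_when_array_size_zero(self):
        cfg = SimulationConfig(seed=1, array_size=0, dispersed_copies=1)
        _, genes = make_genome_with_arrays(cfg)
        assert len(genes) == 1
        assert "disp" in genes[0].gene_id

    def test_determinism_under_seed(self):
        cfg = SimulationConfig(seed=7)
        chrom1, genes1 = make_genome_with_arrays(cfg)
        chrom2, genes2 = make_genome_with_arrays(cfg)
        assert chrom1.sequence == chrom2.sequence
        assert [(g.gene_id, g.start, g.end) for g in genes1] == [
            (g.gene_id, g.start, g.end) for g in genes2
        ]

    def test_layout_error_when_genes_exceed_chromosome(self):
        cfg = SimulationConfig(seed=1, chromosome_length=100_000,
                               array_size=5, array_gap=50_000)
        with pytest.raises(Exception, match="beyond|overlap"):
            make_genome_with_arrays(cfg)


class TestPromoters:
    def test_plant_and_recover_pair(self):
        cfg = SimulationConfig(
            seed=5, motif_plan=[("I-box", -150, "+")], spacer=25
        )
        (prom,) = make_promoters(cfg)
        hits = scan_motifs(prom, default_motif_library())
        starts = {h.tss_offset_start for h in hits if h.motif_name == "I-box"
                  and h.strand_of_hit == "+"}
        assert -150 in starts
        pairs = find_paired_ibox(hits)
        assert pairs and pairs[0].spacer_bp == 25

    def test_background_hit_count_near_binomial_expectation(self):
        # I-box consensus GATAAG: per-position match probability 4^-6 on
        # each strand of a uniform background.
        cfg = SimulationConfig(seed=11, n_promoters=50, promoter_length=2_000)
        proms = make_promoters(cfg)
        lib = [m for m in default_motif_library() if m.name == "I-box"]
        total = sum(len(scan_motifs(p, lib)) for p in proms)
        n_positions = 50 * (2_000 - 6 + 1) * 2  # both strands
        expected = n_positions * 0.25 ** 6
        sd = np.sqrt(n_positions * 0.25 ** 6)
        assert abs(total - expected) < 5 * sd + 5

    def test_off_window_spacer_yields_no_pair(self):
        cfg = SimulationConfig(seed=5, spacer=40)
        (prom,) = make_promoters(cfg)
        hits = scan_motifs(prom, default_motif_library())
        assert find_paired_ibox(hits, spacer_min=20, spacer_max=30) == []

    def test_overlapping_plan_rejected(self):
        cfg = SimulationConfig(
            seed=5, motif_plan=[("I-box", -100, "+"), ("G-box", -102, "+")]
        )
        with pytest.raises(PlanError):
            make_promoters(cfg)

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=13, spacer=25)
        assert make_promoters(cfg)[0].sequence == make_promoters(cfg)[0].sequence


class TestCodonEvolution:
    def test_omega_zero_preserves_protein(self, two_leaf_tree):
        cfg = SimulationConfig(seed=2, n_codons=200, mu_t=0.3,
                               omega_map={"default": 0.0})
        tips = simulate_codon_evolution(two_leaf_tree, cfg,
                                        root_sequence="ATG" + "GGC" * 199)
        root_protein = translate("ATG" + "GGC" * 199)
        for tip in tips:
            assert translate(tip.sequence) == root_protein

    def test_zero_branch_lengths_keep_root(self):
        tree = read_newick("(a:0,b:0);")
        cfg = SimulationConfig(seed=2, n_codons=50)
        root = "ATG" + "AAA" * 49
        tips = simulate_codon_evolution(tree, cfg, root_sequence=root)
        assert all(t.sequence == root for t in tips)

    def test_no_stop_codons_at_tips(self, two_leaf_tree):
        cfg = SimulationConfig(seed=9, n_codons=300, mu_t=0.5,
                               omega_map={"default": 1.0})
        for tip in simulate_codon_evolution(two_leaf_tree, cfg):
            codons = [tip.sequence[i:i + 3]
                      for i in range(0, len(tip.sequence), 3)]
            assert not any(is_stop(c) for c in codons)

    def test_root_stop_rejected(self, two_leaf_tree):
        cfg = SimulationConfig(seed=1, n_codons=2)
        with pytest.raises(InputError):
            simulate_codon_evolution(two_leaf_tree, cfg,
                                     root_sequence="ATGTAA")

    def test_branch_group_omega_lookup(self):
        # fg edge free to change protein, bg edge frozen
        tree = read_newick("(a#fg:0.5,b#bg:0.5);")
        cfg = SimulationConfig(seed=4, n_codons=200, mu_t=0.3,
                               omega_map={"fg": 1.0, "bg": 0.0})
        root = "ATG" + "GGC" * 199
        tips = {t.id: t for t in simulate_codon_evolution(tree, cfg,
                                                          root_sequence=root)}
        assert translate(tips["b"].sequence) == translate(root)
        assert translate(tips["a"].sequence) != translate(root)


class TestExpressionMatrix:
    def test_shapes_groups_and_determinism(self):
        cfg = SimulationConfig(seed=3)
        df1, groups = make_expression_matrix(cfg)
        df2, _ = make_expression_matrix(cfg)
        assert df1.shape == (cfg.n_family_genes, cfg.n_winter + cfg.n_spring)
        assert (df1.to_numpy() == df2.to_numpy()).all()
        assert sum(v == "winter" for v in groups.values()) == cfg.n_winter
        assert (df1.to_numpy() > 0).all()

    def test_zero_sd_single_samples_give_zero_percent_difference(self):
        cfg = SimulationConfig(seed=1, n_family_genes=1, n_winter=1,
                               n_spring=1, tpm_log_sd=0.0,
                               group_multiplier=1.0)
        df, groups = make_expression_matrix(cfg)
        w = df[[s for s, g in groups.items() if g == "winter"]].sum().mean()
        s = df[[s for s, g in groups.items() if g == "spring"]].sum().mean()
        assert 100.0 * (w - s) / w == 0.0

    def test_multiplier_two_gives_fifty_percent_difference(self):
        diffs = []
        for seed in range(50):
            cfg = SimulationConfig(seed=seed, group_multiplier=2.0,
                                   tpm_log_sd=0.3)
            df, groups = make_expression_matrix(cfg)
            sums = df.sum(axis=0)
            w = sums[[s for s, g in groups.items() if g == "winter"]].mean()
            s = sums[[s for s, g in groups.items() if g == "spring"]].mean()
            diffs.append(100.0 * (w - s) / w)
        assert abs(np.mean(diffs) - 50.0) < 5.0


class TestToyComplex:
    def test_planted_distance_is_exact(self):
        atoms = make_toy_complex({59: 3.5})
        s59 = [a for a in atoms if a.chain_id == "S" and a.residue_index == 59]
        l_atoms = [a for a in atoms if a.chain_id == "L"]
        dmin = min(
            np.sqrt((a.x - b.x) ** 2 + (a.y - b.y) ** 2 + (a.z - b.z) ** 2)
            for a in s59 for b in l_atoms
        )
        assert dmin == pytest.approx(3.5, abs=1e-12)

    def test_far_residues_at_least_ten_angstrom(self):
        atoms = make_toy_complex({10: 4.0})
        l_xyz = [(a.x, a.y, a.z) for a in atoms if a.chain_id == "L"]
        for a in atoms:
            if a.chain_id == "S" and a.residue_index != 10:
                dmin = min(
                    np.sqrt((a.x - x) ** 2 + (a.y - y) ** 2 + (a.z - z) ** 2)
                    for x, y, z in l_xyz
                )
                assert dmin >= 10.0

    def test_negative_distance_rejected(self):
        with pytest.raises(InputError):
            make_toy_complex({5: -1.0})
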