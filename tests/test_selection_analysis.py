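import itertools
import math

import numpy as np
import pytest

from rbcskit.codons import (
    CODON_TO_AA,
    SENSE_CODONS,
    pathway_differences,
    synonymous_site_fractions,
)
from rbcskit.errors import InputError, SaturationError
from rbcskit.io_core import read_newick
from rbcskit.selection_analysis import (
    BranchModelRecord,
    chisq_sf,
    group_omega_summary,
    likelihood_ratio_test,
    ng86_pairwise,
    read_branch_models,
)
from rbcskit.synthetic_data import SimulationConfig, simulate_codon_evolution

PAD = "ATG" + "GGC" * 19  # 20 identical codons of harmless background


class TestLikelihoodRatioTest:
    def test_one_ratio_vs_two_branch(self):
        r = likelihood_ratio_test(
            BranchModelRecord("two_branch", 2, -8841.77),
            BranchModelRecord("one_ratio", 1, -8845.89),
        )
        assert r.two_delta_L == pytest.approx(8.24, abs=1e-9)
        assert r.df == 1
        assert r.p_value == pytest.approx(0.0041, abs=0.0005)

    def test_chr5_model_a_vs_null(self):
        r = likelihood_ratio_test(
            BranchModelRecord("modelA", 4, -8818.62),
            BranchModelRecord("null", 3, -8820.80),
        )
        assert r.two_delta_L == pytest.approx(4.36, abs=1e-9)
        assert r.p_value == pytest.approx(0.0367, abs=0.0005)

    def test_c4_model_a_vs_null_highly_significant(self):
        r = likelihood_ratio_test(
            BranchModelRecord("modelA", 4, -8802.28),
            BranchModelRecord("null", 3, -8810.99),
        )
        assert r.two_delta_L == pytest.approx(17.42, abs=1e-9)
        assert r.p_value < 0.0001

    def test_identical_likelihoods_give_p_one(self):
        r = likelihood_ratio_test(
            BranchModelRecord("a", 2, -100.0), BranchModelRecord("b", 1, -100.0)
        )
        assert r.two_delta_L == 0.0 and r.p_value == 1.0

    def test_negative_two_delta_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            r = likelihood_ratio_test(
                BranchModelRecord("a", 2, -101.0),
                BranchModelRecord("b", 1, -100.0),
            )
        assert r.two_delta_L == 0.0 and r.p_value == 1.0

    def test_non_nested_parameter_counts_rejected(self):
        with pytest.raises(InputError):
            likelihood_ratio_test(
                BranchModelRecord("a", 1, -1.0), BranchModelRecord("b", 2, -2.0)
            )

    def test_bundled_model_table_loads(self):
        from rbcskit import packaged_branch_models_path

        models = read_branch_models(packaged_branch_models_path())
        assert models["one_ratio"].np == 1
        assert models["modelA_C4"].lnL == -8802.28


class TestChisqSf:
    def test_zero_statistic(self):
        assert chisq_sf(0.0, 1) == 1.0

    def test_standard_quantile(self):
        assert chisq_sf(3.841, 1) == pytest.approx(0.05, abs=5e-4)

    def test_df1_matches_erfc_closed_form(self):
        for x in np.linspace(0.01, 40.0, 200):
            assert chisq_sf(x, 1) == pytest.approx(
                math.erfc(math.sqrt(x / 2.0)), abs=1e-10
            )

    def test_monotone_decreasing_in_x(self):
        values = [chisq_sf(x, 3) for x in np.linspace(0, 30, 50)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_negative_statistic_rejected(self):
        with pytest.raises(InputError):
            chisq_sf(-1.0, 1)


class TestNg86:
    def test_identical_sequences(self):
        est = ng86_pairwise(PAD, PAD)
        assert est.dN == est.dS == 0.0
        assert est.omega is None and not est.omega_defined

    def test_synonymous_single_difference_counts(self):
        a = PAD + "TTT"
        b = PAD + "TTC"
        est = ng86_pairwise(a, b)
        assert est.Sd == 1.0 and est.Nd == 0.0
        assert est.dS > 0 and est.dN == 0.0

    def test_single_difference_counts_match_code_enumeration(self):
        # oracle: for any single-nucleotide codon difference the step is
        # synonymous iff both codons translate identically
        rng = np.random.default_rng(5)
        for _ in range(100):
            codon = rng.choice(SENSE_CODONS)
            pos = int(rng.integers(3))
            alt = rng.choice([n for n in "ACGT" if n != codon[pos]])
            other = codon[:pos] + alt + codon[pos + 1:]
            if other not in SENSE_CODONS:
                continue
            sd, nd = pathway_differences(codon, other)
            assert sd + nd == 1.0
            expected_syn = CODON_TO_AA[codon] == CODON_TO_AA[other]
            assert (sd == 1.0) == expected_syn

    def test_site_counts_sum_to_sequence_length(self):
        rng = np.random.default_rng(8)
        codons = rng.choice(SENSE_CODONS, size=40)
        a = "".join(codons)
        est = ng86_pairwise(a, a)
        assert est.N_sites + est.S_sites == pytest.approx(len(a), abs=1e-9)

    def test_symmetry(self):
        a = PAD + "TTTGCTAAA"
        b = PAD + "TTCGGTAGA"
        ea, eb = ng86_pairwise(a, b), ng86_pairwise(b, a)
        assert (ea.dN, ea.dS, ea.Nd, ea.Sd) == (eb.dN, eb.dS, eb.Nd, eb.Sd)

    def test_ambiguous_codons_excluded_pairwise(self):
        a = PAD + "NNN"
        b = PAD + "TTT"
        est = ng86_pairwise(a, b)
        assert est.n_codons_excluded == 1
        assert est.n_codons_compared == 20

    def test_stop_codon_rejected(self):
        with pytest.raises(InputError):
            ng86_pairwise(PAD + "TAA", PAD + "TAA")

    def test_saturated_comparison_raises(self):
        with pytest.raises(SaturationError):
            ng86_pairwise("TTT", "TTC")  # 1 syn diff over ~1 syn site

    def test_omega_zero_simulations_give_zero_dn(self, two_leaf_tree):
        for seed in range(3):
            cfg = SimulationConfig(seed=seed, n_codons=300, mu_t=0.2,
                                   omega_map={"default": 0.0})
            tips = simulate_codon_evolution(two_leaf_tree, cfg)
            assert ng86_pairwise(tips[0], tips[1]).dN == 0.0

    def test_neutral_omega_recovered(self, two_leaf_tree):
        omegas = []
        for seed in range(40):
            cfg = SimulationConfig(seed=seed, kappa=1.0, mu_t=0.15,
                                   n_codons=1000, omega_map={"default": 1.0})
            tips = simulate_codon_evolution(two_leaf_tree, cfg)
            omegas.append(ng86_pairwise(tips[0], tips[1]).omega)
        assert np.mean(omegas) == pytest.approx(1.0, abs=0.1)

    def test_pathway_symmetry_over_all_two_diff_pairs(self):
        sample = [c for c in SENSE_CODONS[::7]]
        for a, b in itertools.combinations(sample, 2):
            assert pathway_differences(a, b) == pathway_differences(b, a)
            sd, nd = pathway_differences(a, b)
            ndiff = sum(x != y for x, y in zip(a, b))
            assert sd + nd == pytest.approx(ndiff, abs=1e-9)


class TestGroupOmegaSummary:
    def make_alignment(self, seed=0, omega_fg=0.2, omega_bg=0.05):
        tree = read_newick(
            "((f1#fg:0.2,f2#fg:0.2)a1#fg:0.05,(b1#bg:0.2,b2#bg:0.2)a2#bg:0.05);"
        )
        cfg = SimulationConfig(
            seed=seed, n_codons=400, mu_t=0.15,
            omega_map={"fg": omega_fg, "bg": omega_bg},
        )
        return simulate_codon_evolution(tree, cfg), tree

    def test_single_group_equals_mean_of_all_pairs(self):
        alignment, tree = self.make_alignment()
        groups = {leaf: "all" for leaf in tree.leaf_labels()}
        summary, _ = group_omega_summary(alignment, tree, groups)
        by_id = {r.id: r for r in alignment}
        expected = np.mean([
            ng86_pairwise(by_id[x], by_id[y]).omega
            for x, y in itertools.combinations(tree.leaf_labels(), 2)
        ])
        assert summary.iloc[0]["mean_omega"] == pytest.approx(expected)

    def test_foreground_exceeds_background_on_average(self):
        wins = 0
        for seed in range(20):
            alignment, tree = self.make_alignment(seed=seed)
            summary, contrasts = group_omega_summary(alignment, tree)
            means = dict(zip(summary["group"], summary["mean_omega"]))
            wins += means["fg"] > means["bg"]
        assert wins >= 18

    def test_single_leaf_group_skipped_with_warning(self):
        alignment, tree = self.make_alignment()
        groups = {"f1": "solo", "f2": "rest", "b1": "rest", "b2": "rest"}
        with pytest.warns(UserWarning, match="solo"):
            summary, _ = group_omega_summary(alignment, tree, groups)
        assert summary["group"].tolist() == ["rest"]
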