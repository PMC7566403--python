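"""Synthetic data: determinism, stationarity, trace oracle, planted terms."""

from math import comb

import numpy as np
import pytest
from scipy.stats import chisquare

from owlscan.codon import build_codon_space
from owlscan.enrich import hypergeometric_test, merge_annotations
from owlscan.models import BranchModel
from owlscan.qc import remove_missing_codon_sites
from owlscan.simulate import (SimulationScenario, plant_enrichment,
                              simulate_gene, simulate_gene_set)
from owlscan.tree import parse_newick_labeled


class TestSimulateGene:
    def test_zero_branch_lengths_copy_root(self, small_tree):
        tree = small_tree.with_uniform_lengths(0.0)
        scn = SimulationScenario(tree=tree, regime="null", n_codons=40,
                                 seed=1, mask_rate=0.0, gap_column_rate=0.0)
        aln, _ = simulate_gene(scn)
        assert len(set(aln.seqs)) == 1

    def test_stationary_frequencies_on_long_branch(self):
        tree = parse_newick_labeled("(A:50.0,B:0.01,C:0.01);")
        scn = SimulationScenario(tree=tree, regime="null", omega_bg=1.0,
                                 kappa=1.0, n_codons=5000, seed=6,
                                 mask_rate=0.0, gap_column_rate=0.0)
        aln, _ = simulate_gene(scn)
        space = build_codon_space(1)
        row = aln.taxon_index("A")
        counts = np.zeros(61)
        for s in range(aln.n_codons):
            counts[space.index[aln.codon(row, s)]] += 1
        stat = chisquare(counts)
        assert stat.pvalue > 1e-3  # consistent with uniform over 61 codons

    def test_trace_counts_show_foreground_selection(self, small_tree):
        scn = SimulationScenario(tree=small_tree, regime="branch",
                                 omega_bg=0.15, omega_fg=5.0, n_codons=150,
                                 seed=7, mask_rate=0.0, gap_column_rate=0.0)
        aln, truth = simulate_gene(scn, trace=True)
        space = build_codon_space(1)
        idx = truth["tree_index"]
        fg_ns = fg_s = bg_ns = bg_s = 0
        for branch, _site, frm, to in truth["events"]:
            nonsyn = space.aa[space.codons[frm]] != space.aa[space.codons[to]]
            if idx.foreground[branch]:
                fg_ns += nonsyn
                fg_s += not nonsyn
            else:
                bg_ns += nonsyn
                bg_s += not nonsyn
        assert fg_s > 0 and bg_s > 0
        assert fg_ns / fg_s > bg_ns / bg_s  # selection enriches nonsyn changes

    def test_masking_leaves_unmasked_residues_untouched(self, small_tree):
        base = SimulationScenario(tree=small_tree, regime="null", n_codons=80,
                                  seed=5, mask_rate=0.0, gap_column_rate=0.0)
        masked = SimulationScenario(tree=small_tree, regime="null", n_codons=80,
                                    seed=5, mask_rate=0.3, gap_column_rate=0.0)
        a0, _ = simulate_gene(base)
        a1, _ = simulate_gene(masked)
        n_masked = 0
        for s0, s1 in zip(a0.seqs, a1.seqs):
            for c0, c1 in zip(s0, s1):
                if c1 == "N":
                    n_masked += 1
                else:
                    assert c0 == c1
        assert n_masked > 0

    def test_site_class_proportions(self, small_tree):
        scn = SimulationScenario(tree=small_tree, regime="branch_site",
                                 omega_bg=0.2, omega_fg=4.0,
                                 site_class_props=(0.6, 0.2),
                                 n_codons=4000, seed=9)
        _, truth = simulate_gene(scn)
        observed = np.bincount(truth["site_class"], minlength=4) / 4000
        expected = truth["site_class_props"]
        assert np.abs(observed - expected).max() < 0.03

    def test_regime_parameter_validation(self, small_tree):
        with pytest.raises(ValueError, match="omega_fg"):
            SimulationScenario(tree=small_tree, regime="branch")
        with pytest.raises(ValueError, match="regime"):
            SimulationScenario(tree=small_tree, regime="weird")


class TestGeneSet:
    def test_deterministic_regime_counts(self, small_tree):
        scn = SimulationScenario(tree=small_tree, regime="null", n_codons=30,
                                 omega_fg=4.0)
        _, truth = simulate_gene_set(100, {"null": 0.8, "branch": 0.2}, scn,
                                     seed=1)
        counts = truth["regime"].value_counts()
        assert counts["null"] == 80 and counts["branch"] == 20

    def test_byte_identical_reruns(self, small_tree, tmp_path):
        scn = SimulationScenario(tree=small_tree, regime="null", n_codons=40)
        for d in ("a", "b"):
            simulate_gene_set(5, {"null": 1.0}, scn, seed=11,
                              out_dir=tmp_path / d)
        for name in ("g0000.fasta", "g0004.fasta", "truth.tsv", "tree.nwk"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_pure_null_truth_log(self, small_tree):
        scn = SimulationScenario(tree=small_tree, regime="null", n_codons=30)
        _, truth = simulate_gene_set(50, {"null": 1.0}, scn, seed=2)
        assert len(truth) == 50 and (truth["regime"] == "null").all()


class TestRoundTrip:
    def test_kappa_omega_recovery_at_large_length(self, small_tree):
        scn = SimulationScenario(tree=small_tree, regime="null", omega_bg=0.3,
                                 kappa=2.0, n_codons=2000, seed=14)
        aln, _ = simulate_gene(scn)
        fit = BranchModel(remove_missing_codon_sites(aln), small_tree,
                          restarts=1).fit("H0")
        assert fit.params["kappa"] == pytest.approx(2.0, rel=0.2)
        assert fit.params["omega"] == pytest.approx(0.3, rel=0.2)


class TestPlantEnrichment:
    def test_exact_planted_term_minimal_p(self):
        targets = [f"g{i:04d}" for i in range(10)]
        pairs, _ = plant_enrichment(500, 30, (10, 40), targets, ["T000"],
                                    seed=3, odds_ratio=float("inf"))
        db = merge_annotations(pairs, pairs.iloc[0:0])
        assert db.term_to_genes["T000"] == frozenset(targets)
        bg = db.background
        p = hypergeometric_test(set(targets) & bg, db.term_to_genes["T000"], bg)
        assert p == pytest.approx(1 / comb(len(bg), 10), rel=1e-9)

    def test_neutral_odds_ratio_indistinguishable(self):
        """At odds ratio 1 the planted term's p-value is not systematically
        extreme across replicates."""
        targets = [f"g{i:04d}" for i in range(15)]
        small_ps = 0
        n_rep = 20
        for r in range(n_rep):
            pairs, _ = plant_enrichment(200, 15, (10, 30), targets, ["T000"],
                                        seed=100 + r, odds_ratio=1.0)
            db = merge_annotations(pairs, pairs.iloc[0:0])
            cand = set(targets) & db.background
            if len(cand) < 2:
                continue
            p = hypergeometric_test(cand, db.term_to_genes.get("T000", set()),
                                    db.background)
            small_ps += p < 0.05
        assert small_ps <= 5  # ~binomial(20, 0.05) upper range

    def test_zero_planted_terms(self):
        pairs, truth = plant_enrichment(100, 10, (5, 20), [], [], seed=1)
        assert truth["planted_terms"] == []
        assert pairs["term_id"].nunique() == 10

    def test_infeasible_inputs(self):
        with pytest.raises(ValueError):
            plant_enrichment(100, 10, (5, 20), ["nope"], [], seed=1)
        with pytest.raises(ValueError):
            plant_enrichment(100, 10, (5, 200), [], [], seed=1)
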