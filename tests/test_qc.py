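"""Alignment QC filters, entropy screen, CMD diagnostic, association tests."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from owlscan.qc import (cmd_count, entropy_scan, kendall_tau_b,
                        permutation_welch_test, qc_gene,
                        remove_missing_codon_sites)
from owlscan.simulate import SimulationScenario, simulate_gene
from conftest import make_alignment


class TestRemoveMissing:
    def test_gap_free_unchanged(self):
        aln = make_alignment("g", "ab", [["ATG", "AAA"], ["ATG", "AAG"]])
        assert remove_missing_codon_sites(aln) is aln

    def test_masked_column_removed(self):
        aln = make_alignment("g", "abc",
                             [["ATG", "AAA", "CCC"],
                              ["ATG", "ANA", "CCC"],
                              ["ATG", "AAA", "CCC"]])
        out = remove_missing_codon_sites(aln)
        assert out.n_codons == 2
        assert out.seqs[0] == "ATGCCC"

    def test_masks_in_different_taxa(self):
        rows = [["AAA"] * 10 for _ in range(3)]
        rows[0][2] = "NNN"
        rows[1][7] = "A-A"
        aln = make_alignment("g", "abc", rows)
        assert remove_missing_codon_sites(aln).n_codons == 8

    def test_idempotent(self):
        rows = [["AAA", "NNN", "CCC"], ["AAA", "AAA", "CCC"]]
        aln = make_alignment("g", "ab", rows)
        once = remove_missing_codon_sites(aln)
        assert remove_missing_codon_sites(once) is once


class TestQcGene:
    def test_short_invariant_fails_both(self):
        aln = make_alignment("g", "ab", [["AAA"] * 19, ["AAA"] * 19])
        report = qc_gene(aln)
        assert not report.passed
        assert set(report.fail_reasons) == {"min_codons", "no_variable_sites"}

    def test_minimal_pass(self):
        rows = [["AAA"] * 20, ["AAA"] * 20]
        rows[1][4] = "AAG"
        report = qc_gene(make_alignment("g", "ab", rows))
        assert report.passed
        assert report.pct_variable_sites == pytest.approx(0.05)

    def test_simulated_matches_column_scan(self):
        scn = SimulationScenario(regime="null", n_codons=100, seed=33,
                                 mask_rate=0.0, gap_column_rate=0.0)
        aln, _ = simulate_gene(scn)
        report = qc_gene(aln)
        brute = sum(1 for s in range(aln.n_codons)
                    if len({aln.codon(i, s) for i in range(aln.n_taxa)}) > 1)
        assert report.pct_variable_sites == pytest.approx(brute / 100)


class TestEntropyScan:
    def test_invariant_never_flagged(self):
        aln = make_alignment("g", "abcd", [["ATG"] * 10] * 4)
        flagged, windows, smoothed = entropy_scan(aln)
        assert not flagged and windows == [] and smoothed.max() == 0.0

    def test_all_distinct_column_entropy_one(self):
        # four distinct amino acids: M, K, P, W
        rows = [["ATG"], ["AAA"], ["CCC"], ["TGG"]]
        _, _, smoothed = entropy_scan(make_alignment("g", "abcd", rows),
                                      window=1)
        assert smoothed[0] == pytest.approx(1.0)

    def test_block_flagged_and_matches_direct_recomputation(self):
        # 5-column all-distinct block inside invariant flanks
        distinct = [["ATG", "AAA", "CCC", "TGG"][i] for i in range(4)]
        rows = [["ATG"] * 4 + [distinct[i]] * 5 + ["ATG"] * 4 for i in range(4)]
        aln = make_alignment("g", "abcd", rows)
        flagged, windows, smoothed = entropy_scan(aln, threshold=0.5, window=3)
        assert flagged
        assert any(a <= 6 <= b for a, b in windows)  # block centre flagged
        # direct oracle: per-column entropy then centered mean
        raw = []
        for s in range(aln.n_codons):
            col = [aln.codon(i, s) for i in range(4)]
            _, counts = np.unique(col, return_counts=True)
            p = counts / counts.sum()
            raw.append(float(-(p * np.log(p)).sum() / math.log(4)))
        for s in range(aln.n_codons):
            lo, hi = max(0, s - 1), min(aln.n_codons, s + 2)
            assert smoothed[s] == pytest.approx(np.mean(raw[lo:hi]))

    def test_smoothing_never_increases_maximum(self, rng):
        space_codons = ["ATG", "AAA", "CCC", "TGG", "GGG", "TTT"]
        for _ in range(10):
            rows = [[space_codons[rng.integers(6)] for _ in range(15)]
                    for _ in range(5)]
            aln = make_alignment("g", "abcde", rows)
            _, _, smooth3 = entropy_scan(aln, window=3)
            _, _, raw = entropy_scan(aln, window=1)
            assert smooth3.max() <= raw.max() + 1e-12
            assert np.all((raw >= 0) & (raw <= 1))

    def test_stop_codon_warns_and_is_ignored(self):
        rows = [["ATG", "TAA"], ["ATG", "TAA"], ["ATG", "TAA"]]
        with pytest.warns(UserWarning, match="stop"):
            _, _, smoothed = entropy_scan(make_alignment("g", "abc", rows))
        assert smoothed[1] == 0.0


class TestCmdCount:
    def test_identical_queries(self):
        aln = make_alignment("g", ["ref", "q1"], [["AAA"] * 7, ["AAA"] * 7])
        assert cmd_count(aln, "ref", ["q1"]) == (0, 7)

    def test_single_double_difference(self):
        ref = ["AAA"] * 10
        q = ["AAA"] * 10
        q[3] = "AGG"  # two positions differ
        aln = make_alignment("g", ["ref", "q"], [ref, q])
        cmds, evaluated = cmd_count(aln, "ref", ["q"])
        assert (cmds, evaluated) == (1, 10)
        assert cmds / evaluated == pytest.approx(0.1)

    def test_single_difference_not_counted(self):
        ref, q = ["AAA"] * 5, ["AAA"] * 5
        q[0] = "AAG"
        aln = make_alignment("g", ["ref", "q"], [ref, q])
        assert cmd_count(aln, "ref", ["q"]) == (0, 5)

    def test_random_alignment_matches_brute_force(self):
        scn = SimulationScenario(regime="null", n_codons=50, seed=91,
                                 omega_bg=0.6, mask_rate=0.05)
        aln, _ = simulate_gene(scn)
        ref = "Gallus_gallus"
        queries = [t for t in aln.taxa if t.startswith(("Strix", "Bubo", "Tyto"))]
        got = cmd_count(aln, ref, queries)
        # brute-force tally straight off the matrix
        acgt = set("ACGT")
        ref_row = aln.taxon_index(ref)
        n_eval = n_cmd = 0
        for s in range(aln.n_codons):
            rc = aln.codon(ref_row, s)
            if set(rc) - acgt:
                continue
            n_eval += 1
            hit = False
            for q in queries:
                qc_ = aln.codon(aln.taxon_index(q), s)
                if set(qc_) - acgt:
                    continue
                if sum(a != b for a, b in zip(rc, qc_)) >= 2:
                    hit = True
            n_cmd += hit
        assert got == (n_cmd, n_eval)

    def test_taxon_order_invariance(self):
        scn = SimulationScenario(regime="null", n_codons=30, seed=5)
        aln, _ = simulate_gene(scn)
        queries = ["Tyto_alba", "Strix_uralensis", "Bubo_bubo"]
        assert cmd_count(aln, "Gallus_gallus", queries) == \
            cmd_count(aln, "Gallus_gallus", list(reversed(queries)))

    def test_missing_reference_errors(self):
        aln = make_alignment("g", "ab", [["AAA"], ["AAA"]])
        with pytest.raises(KeyError):
            cmd_count(aln, "nope", ["a"])


class TestPermutationWelch:
    def test_identical_groups(self):
        res = permutation_welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], seed=0)
        assert res.welch_t == 0.0 and res.perm_p == 1.0

    def test_exhaustive_enumeration(self):
        res = permutation_welch_test([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert res.n_permutations == 20
        assert res.perm_p == pytest.approx(2 / 20)

    def test_null_calibration(self):
        rng = np.random.default_rng(77)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a, b = rng.normal(size=30), rng.normal(size=30)
            res = permutation_welch_test(a, b, n_perm=400, seed=int(rng.integers(2**31)))
            rejections += res.perm_p <= 0.05
        # binomial CI around 0.05 with 200 replicates
        assert 0.01 <= rejections / n_rep <= 0.10

    def test_perm_p_lower_bound(self):
        res = permutation_welch_test([0.0, 0.1], [10.0, 10.1, 10.2, 10.3],
                                     n_perm=5, seed=1)
        assert res.perm_p >= 1 / (res.n_permutations + 1)


class TestKendall:
    def test_perfect_concordance_and_reversal(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert kendall_tau_b(x, x)[0] == pytest.approx(1.0)
        assert kendall_tau_b(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_matches_pair_enumeration(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        tau, _ = kendall_tau_b(x, y)
        conc = disc = 0
        for (i, j) in combinations(range(5), 2):
            s = (x[i] - x[j]) * (y[i] - y[j])
            conc += s > 0
            disc += s < 0
        assert tau == pytest.approx((conc - disc) / 10)

    def test_tie_correction_matches_formula(self, rng):
        x = rng.integers(0, 4, size=25).astype(float)
        y = (x + rng.integers(0, 3, size=25)).astype(float)
        tau, _ = kendall_tau_b(x, y)
        conc = disc = 0
        tx = ty = 0
        n = len(x)
        for i, j in combinations(range(n), 2):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            else:
                conc += dx * dy > 0
                disc += dx * dy < 0
        n0 = n * (n - 1) / 2
        # tau-b denominator from tie counts per variable
        def tie_sum(v):
            _, c = np.unique(v, return_counts=True)
            return float((c * (c - 1) / 2).sum())
        denom = math.sqrt((n0 - tie_sum(x)) * (n0 - tie_sum(y)))
        assert tau == pytest.approx((conc - disc) / denom)

    def test_all_tied_errors(self):
        with pytest.raises(ValueError):
            kendall_tau_b([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
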