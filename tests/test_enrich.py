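"""Overrepresentation: hypergeometric tail, permutation FWERs, reports."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from owlscan.alignment import CandidateList
from owlscan.datasets import reference_candidate_fits, reference_candidate_list
from owlscan.enrich import (AnnotationDB, candidate_report, fwer_permutation,
                            hypergeometric_test, merge_annotations)
from owlscan.scan import ScanConfig, ScanResults


def pairs_df(mapping):
    rows = [(g, t) for t, genes in mapping.items() for g in genes]
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])


class TestMerge:
    def test_identical_tables_idempotent(self):
        a = pairs_df({"T1": ["g1", "g2"], "T2": ["g2"]})
        db = merge_annotations(a, a.copy())
        assert db.term_to_genes == {"T1": frozenset({"g1", "g2"}),
                                    "T2": frozenset({"g2"})}

    def test_disjoint_terms_sum(self):
        a = pairs_df({"T1": ["g1"]})
        b = pairs_df({"T2": ["g2"], "T3": ["g3"]})
        assert merge_annotations(a, b).n_terms == 3

    def test_overlapping_pairs_deduplicated(self):
        a = pairs_df({"T1": ["g1", "g2"]})
        b = pairs_df({"T1": ["g2", "g3"]})
        db = merge_annotations(a, b)
        assert db.term_to_genes["T1"] == frozenset({"g1", "g2", "g3"})
        assert db.background == frozenset({"g1", "g2", "g3"})


class TestHypergeometric:
    BG = {f"g{i}" for i in range(20)}

    def test_no_overlap_gives_one(self):
        p = hypergeometric_test({"g0", "g1"}, {"g5", "g6"}, self.BG)
        assert p == pytest.approx(1.0)

    def test_term_covering_background_gives_one(self):
        p = hypergeometric_test({"g0", "g1", "g2"}, self.BG, self.BG)
        assert p == pytest.approx(1.0)

    def test_exact_tail_oracle(self):
        term = {f"g{i}" for i in range(5)}           # K = 5
        cand = {"g0", "g1", "g2", "g10", "g11"}      # n = 5, k = 3
        p = hypergeometric_test(cand, term, self.BG)
        want = sum(comb(5, j) * comb(15, 5 - j) for j in range(3, 6)) / comb(20, 5)
        assert p == pytest.approx(want, rel=1e-12)

    def test_matches_scipy_tail(self):
        rng = np.random.default_rng(11)
        genes = sorted(self.BG)
        for _ in range(20):
            term = set(rng.choice(genes, size=rng.integers(1, 15), replace=False))
            cand = set(rng.choice(genes, size=rng.integers(1, 10), replace=False))
            k = len(term & cand)
            p = hypergeometric_test(cand, term, self.BG)
            assert p == pytest.approx(
                hypergeom.sf(k - 1, 20, len(term), len(cand)), rel=1e-10)

    def test_monotone_in_background_size(self):
        # fixed k, n, K; growing N makes the overlap more surprising
        last = 1.1
        for extra in (0, 10, 50, 200):
            bg = self.BG | {f"x{i}" for i in range(extra)}
            p = hypergeometric_test({"g0", "g1", "g2"}, {"g0", "g1", "g4"}, bg)
            assert p <= last + 1e-15
            last = p

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            hypergeometric_test(set(), {"g0"}, self.BG)

    def test_candidates_outside_background_error(self):
        with pytest.raises(ValueError):
            hypergeometric_test({"nope"}, {"g0"}, self.BG)


class TestFwer:
    def test_two_term_fwer_matches_subset_enumeration(self):
        small = AnnotationDB({"T1": frozenset({"g0", "g1", "g2", "g3", "g4"}),
                              "all": frozenset({f"g{i}" for i in range(10)})})
        table = fwer_permutation({"g0", "g1", "g2"}, small, n_perm=2000, seed=4,
                                 min_term_size=5)
        row = table.set_index("term_id").loc["T1"]
        # oracle: exhaustive enumeration over all candidate subsets
        genes = sorted(small.background)
        term = small.term_to_genes["T1"]
        allset = small.term_to_genes["all"]
        hits = total = 0
        p_obs = row["p"]
        for cand in combinations(genes, 3):
            cand = set(cand)
            p_t1 = hypergeom.sf(len(cand & term) - 1, 10, 5, 3)
            p_all = hypergeom.sf(len(cand & allset) - 1, 10, 10, 3)
            hits += min(p_t1, p_all) <= p_obs + 1e-12
            total += 1
        assert row["fwer"] == pytest.approx(hits / total, abs=0.03)

    def test_exhaustive_tiny_db(self):
        """8 genes, 2 terms: Monte-Carlo FWER matches complete enumeration."""
        db = AnnotationDB({"T1": frozenset({"g0", "g1", "g2"}),
                           "T2": frozenset({"g3", "g4", "g5", "g6", "g7"})})
        cand = {"g0", "g1", "g3"}
        table = fwer_permutation(cand, db, n_perm=4000, seed=9)
        genes = sorted(db.background)
        for _, row in table.iterrows():
            hits = total = 0
            for sub in combinations(genes, 3):
                sub = set(sub)
                mins = min(
                    hypergeom.sf(len(sub & db.term_to_genes[t]) - 1, 8,
                                 len(db.term_to_genes[t]), 3)
                    for t in ("T1", "T2"))
                hits += mins <= row["p"] + 1e-12
                total += 1
            assert row["fwer"] == pytest.approx(hits / total, abs=0.03)

    def test_fwer_dominates_per_term_permutation_p(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(30)]
        db = AnnotationDB({f"T{j}": frozenset(rng.choice(genes, size=8,
                                                         replace=False))
                           for j in range(5)})
        cand = set(rng.choice(sorted(db.background), size=6, replace=False))
        table = fwer_permutation(cand, db, n_perm=1500, seed=12)
        # per-term permutation p on an independent draw stream
        rng2 = np.random.default_rng(99)
        bg = sorted(db.background)
        for _, row in table.iterrows():
            term = db.term_to_genes[row["term_id"]]
            hits = 0
            n_perm = 1500
            for _ in range(n_perm):
                sub = set(rng2.choice(bg, size=len(cand), replace=False))
                hits += hypergeom.sf(len(sub & term) - 1, len(bg), len(term),
                                     len(cand)) <= row["p"] + 1e-12
            per_term_p = (1 + hits) / (n_perm + 1)
            assert row["fwer"] >= per_term_p - 0.03


class TestCandidateReport:
    def _reference_results(self):
        fits = reference_candidate_fits()
        branch = pd.DataFrame({
            "gene_id": fits["gene_id"], "lnL0": 0.0, "lnL1": 0.0,
            "omega0": fits["omega0"], "omega_fg": fits["omega1"],
            "lrt": fits["branch_lrt"], "p": 0.01, "q": 0.05,
            "excluded": False, "category": "none",
        })
        bs = pd.DataFrame({
            "gene_id": fits["gene_id"], "lnL0": 0.0, "lnL1": 0.0,
            "omega0": fits["bs_omega0"], "omega_fg": fits["bs_omega2"],
            "lrt": fits["bs_lrt"], "p": 0.01, "q": 0.05,
            "excluded": False, "category": "none",
        })
        status = pd.DataFrame({"gene_id": fits["gene_id"], "status": "ok"})
        return ScanResults(branch, bs, status, ScanConfig())

    def test_reference_counts(self):
        results = self._reference_results()
        table, summary = candidate_report(results, reference_candidate_list())
        assert summary["per_category_branch"] == {
            "vision": 21, "hearing": 10, "feather": 2, "circadian": 5}
        assert summary["branch_site_significant"] == 3
        assert summary["dual_model"] == 1
        assert summary["total_significant"] == 40
        assert summary["expected_by_chance"] == 13
        assert len(table) == 40

    def test_empty_candidate_list(self):
        results = self._reference_results()
        table, summary = candidate_report(results, CandidateList({}))
        assert table.empty
        assert summary["total_significant"] == 0
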