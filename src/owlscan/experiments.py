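"""Simulation studies validating the scan end to end.

These are the package's own power/calibration experiments: type-I error of
the branch and branch-site LRTs under the null, parameter recovery under
planted selection, planted-term recovery in the enrichment stage, and the
false-discovery behaviour of the full scan. They are shared between the
test suite and the reproduction script; replicate counts are arguments so
callers choose the study size.

All studies derive per-replicate seeds from one master seed and use a single
optimizer start per hypothesis (the fits are warm-started along the model
hierarchy, which the round-trip tests show is sufficient at these data
sizes).
"""

from __future__ import annotations

import numpy as np

from .codon import build_codon_space, rate_matrix_eig, transition_probs
from .enrich import fwer_permutation, merge_annotations
from .likelihood import PruningEngine
from .models import LRT_CRITICAL_05, BranchModel, BranchSiteModel
from .qc import remove_missing_codon_sites
from .scan import ScanConfig, run_scan
from .simulate import (SimulationScenario, gene_seed, plant_enrichment,
                       simulate_gene)
from .tree import owl_species_tree, parse_newick_labeled
from .alignment import CodonAlignment

__all__ = [
    "likelihood_oracle_check",
    "branch_null_calibration",
    "branch_site_null_calibration",
    "branch_power_study",
    "kappa_recovery",
    "enrichment_planted_recovery",
    "null_scan_fdr",
]


def likelihood_oracle_check(seed: int = 0) -> float:
    """Max relative error of pruning vs exhaustive internal-state enumeration
    on a 4-taxon, 3-codon alignment (two free internal nodes, 61² terms)."""
    space = build_codon_space(1)
    tree = parse_newick_labeled("((A:0.2,B:0.15)#1:0.1,C:0.3,D:0.25);")
    rng = np.random.default_rng(seed)
    codons = [space.codons[i] for i in rng.integers(0, space.n, size=12)]
    seqs = tuple("".join(codons[3 * i: 3 * i + 3]) for i in range(4))
    aln = CodonAlignment("oracle", ("A", "B", "C", "D"), seqs)
    pi = np.full(space.n, 1.0 / space.n)
    kappa, w_bg, w_fg = 2.0, 0.3, 1.5

    engine = PruningEngine(aln, tree, pi)
    lnl = engine.lnl_branch(kappa, w_bg, w_fg)

    eig_bg = rate_matrix_eig(space, kappa, w_bg, pi)
    eig_fg = rate_matrix_eig(space, kappa, w_fg, pi)
    p_a = transition_probs(eig_bg, 0.2)
    p_b = transition_probs(eig_bg, 0.15)
    p_u = transition_probs(eig_fg, 0.1)
    p_c = transition_probs(eig_bg, 0.3)
    p_d = transition_probs(eig_bg, 0.25)
    total = 0.0
    for s in range(3):
        a, b, c, d = (space.index[aln.codon(i, s)] for i in range(4))
        site = 0.0
        for r in range(space.n):          # state at the C/D-adjacent node
            for u in range(space.n):      # state at the A/B-adjacent node
                site += (pi[r] * p_u[r, u] * p_a[u, a] * p_b[u, b]
                         * p_c[r, c] * p_d[r, d])
        total += np.log(site)
    return abs(lnl - total) / abs(total)


def _null_scenario(n_codons: int, seed: int) -> SimulationScenario:
    return SimulationScenario(regime="null", omega_bg=0.2, n_codons=n_codons,
                              seed=seed)


def branch_null_calibration(n_rep: int, n_codons: int = 300,
                            seed: int = 0) -> dict:
    """Empirical type-I error of the branch-model LRT at the χ²₁ 0.05 cut."""
    rejections = 0
    lrts = []
    for r in range(n_rep):
        scn = _null_scenario(n_codons, gene_seed(seed, f"bn{r}"))
        aln, _ = simulate_gene(scn, f"bn{r}")
        res = BranchModel(remove_missing_codon_sites(aln), scn.tree,
                          restarts=1).fit()
        lrts.append(res.lrt_stat)
        rejections += res.lrt_stat > LRT_CRITICAL_05
    return {"rate": rejections / n_rep, "rejections": rejections,
            "n_rep": n_rep, "lrts": np.array(lrts)}


def branch_site_null_calibration(n_rep: int, n_codons: int = 300,
                                 seed: int = 0) -> dict:
    """Empirical rejection rate of the branch-site LRT under the null.

    The χ²₁ reference is conservative here (the true null distribution is a
    boundary mixture), so the rate is expected at or below the nominal level.
    """
    rejections = 0
    lrts = []
    for r in range(n_rep):
        scn = _null_scenario(n_codons, gene_seed(seed, f"bsn{r}"))
        aln, _ = simulate_gene(scn, f"bsn{r}")
        res = BranchSiteModel(remove_missing_codon_sites(aln), scn.tree,
                              restarts=1).fit()
        lrts.append(res.lrt_stat)
        rejections += res.lrt_stat > LRT_CRITICAL_05
    return {"rate": rejections / n_rep, "rejections": rejections,
            "n_rep": n_rep, "lrts": np.array(lrts)}


def branch_power_study(n_rep: int, n_codons: int = 500, omega_bg: float = 0.2,
                       omega_fg: float = 4.0, seed: int = 0) -> dict:
    """Branch-model recovery under foreground selection."""
    omega_hats, hits = [], 0
    for r in range(n_rep):
        scn = SimulationScenario(regime="branch", omega_bg=omega_bg,
                                 omega_fg=omega_fg, n_codons=n_codons,
                                 seed=gene_seed(seed, f"bp{r}"))
        aln, _ = simulate_gene(scn, f"bp{r}")
        res = BranchModel(remove_missing_codon_sites(aln), scn.tree,
                          restarts=1).fit()
        omega_hats.append(res.omega1)
        hits += (res.lrt_stat > LRT_CRITICAL_05) and (res.omega1 > 1.0)
    return {"power": hits / n_rep, "median_omega_fg": float(np.median(omega_hats)),
            "omega_hats": np.array(omega_hats), "n_rep": n_rep}


def branch_site_power_study(n_rep: int, n_codons: int = 500,
                            omega_bg: float = 0.2, omega2: float = 8.0,
                            site_class_props=(0.8, 0.1), seed: int = 0) -> dict:
    """Branch-site model A recovery with a planted ω2 site class."""
    omega2_hats, hits = [], 0
    for r in range(n_rep):
        scn = SimulationScenario(regime="branch_site", omega_bg=omega_bg,
                                 omega_fg=omega2,
                                 site_class_props=site_class_props,
                                 n_codons=n_codons,
                                 seed=gene_seed(seed, f"bsp{r}"))
        aln, _ = simulate_gene(scn, f"bsp{r}")
        res = BranchSiteModel(remove_missing_codon_sites(aln), scn.tree,
                              restarts=1).fit()
        omega2_hats.append(res.omega2)
        hits += (res.lrt_stat > LRT_CRITICAL_05) and (res.omega2 > 1.0)
    return {"power": hits / n_rep,
            "median_omega2": float(np.median(omega2_hats)), "n_rep": n_rep}


def kappa_recovery(n_rep: int = 5, n_codons: int = 2000, kappa: float = 2.0,
                   seed: int = 0) -> dict:
    """Transition/transversion ratio recovery at large gene length."""
    hats = []
    for r in range(n_rep):
        scn = SimulationScenario(regime="null", omega_bg=0.3, kappa=kappa,
                                 n_codons=n_codons,
                                 seed=gene_seed(seed, f"kr{r}"))
        aln, _ = simulate_gene(scn, f"kr{r}")
        res = BranchModel(remove_missing_codon_sites(aln), scn.tree,
                          restarts=1).fit("H0")
        hats.append(res.params["kappa"])
    hats = np.array(hats)
    return {"kappa_hats": hats, "mean_kappa": float(hats.mean()),
            "true_kappa": kappa,
            "max_rel_error": float(np.abs(hats / kappa - 1).max()),
            "n_rep": n_rep}


def enrichment_planted_recovery(seed: int = 0, n_perm: int = 10_000,
                                n_genes: int = 500, n_terms: int = 40,
                                odds_ratio: float = 8.0) -> dict:
    """Planted-term recovery: does the enriched term attain the minimum FWER?"""
    rng = np.random.default_rng(seed)
    universe = [f"g{i:04d}" for i in range(n_genes)]
    targets = list(rng.choice(universe, size=25, replace=False))
    pairs, truth = plant_enrichment(n_genes, n_terms, (10, 50), targets,
                                    ["T000"], seed=seed + 1,
                                    odds_ratio=odds_ratio)
    db = merge_annotations(pairs, pairs.iloc[0:0])
    # candidates: the planted target genes that are annotated at all
    cand = [g for g in targets if g in db.background]
    table = fwer_permutation(cand, db, n_perm=n_perm, seed=seed + 2)
    best = table.iloc[0]
    planted = table[table["term_id"] == "T000"].iloc[0]
    return {"planted_term": "T000", "planted_fwer": float(planted["fwer"]),
            "min_fwer": float(table["fwer"].min()),
            "planted_is_min": bool(planted["fwer"] <= table["fwer"].min()),
            "best_term": str(best["term_id"]), "n_perm": n_perm}


def null_scan_fdr(n_rep: int, n_genes: int, n_codons: int = 150,
                  seed: int = 0, q_level: float = 0.05) -> dict:
    """False-discovery behaviour of the full scan under a global null.

    Every gene is simulated without foreground selection, so every q ≤ level
    discovery is false. Reports the expected proportion of gene×model tests
    flagged as discoveries (the quantity the per-model FDR step bounds under
    a global null) and, secondarily, the per-replicate indicator of any
    false discovery averaged over replicates.
    """
    tree = owl_species_tree()
    per_rep_v = []
    n_tests = 0
    for r in range(n_rep):
        genes = []
        for g in range(n_genes):
            scn = _null_scenario(n_codons, gene_seed(seed, f"fdr{r}_{g}"))
            aln, _ = simulate_gene(scn, f"g{g:03d}")
            genes.append(aln)
        results = run_scan(genes, tree, ScanConfig(restarts=1))
        v = 0
        for table in (results.branch, results.branch_site):
            if table.empty:
                continue
            n_tests += len(table)
            disc = table[(~table["excluded"]) & (table["q"] <= q_level)
                         & (table["category"] != "none")]
            v += len(disc)
        per_rep_v.append(v)
    total_v = int(sum(per_rep_v))
    return {
        "discovery_proportion": total_v / max(n_tests, 1),
        "any_discovery_rate": float(np.mean([1.0 if v else 0.0
                                             for v in per_rep_v])),
        "total_false_discoveries": total_v,
        "n_tests": n_tests, "n_rep": n_rep, "n_genes": n_genes,
    }
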