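"""Gene-set orchestration of the selection tests.

Runs QC and the paired branch / branch-site fits over a set of gene
alignments, applies the foreground-ω cap filter and per-model FDR
correction, classifies genes into the three reporting lists, and offers an
all-branch specificity scan that asks whether a selection signal is unique
to the designated focal branch.

Lists: ``list_i`` — strong positive selection on the foreground
(branch model significant, ω0 ≤ 1 < ω1); ``list_ii`` — weak positive or
relaxed purifying selection (branch model significant, ω0 < ω1 < 1);
``list_iii`` — positive selection at specific sites (branch-site model
significant, ω2 > 1). A gene may be in a branch list and list iii at once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .alignment import CodonAlignment
from .models import (LRT_CRITICAL_05, BranchModel, BranchSiteModel)
from .qc import entropy_scan, qc_gene, remove_missing_codon_sites
from .tree import PhyloTree

__all__ = [
    "ScanConfig",
    "ScanResults",
    "classify_gene",
    "apply_omega_cap",
    "fdr_correct",
    "expected_by_chance",
    "run_scan",
    "scan_all_branches",
]

MODEL_COLUMNS = ["gene_id", "lnL0", "lnL1", "omega0", "omega_fg",
                 "lrt", "p", "q", "excluded", "category"]


@dataclass(frozen=True)
class ScanConfig:
    """Thresholds and fitting options shared across the scan."""

    alpha: float = 0.05
    lrt_critical: float = LRT_CRITICAL_05
    omega_cap: float = 500.0
    fdr_level: float = 0.05
    freq_method: str = "F3x4"
    restarts: int = 3
    lengths: str = "scale"
    min_codons: int = 20
    entropy_threshold: float = 0.5
    entropy_window: int = 3
    run_entropy_filter: bool = True
    cap_only_significant: bool = False
    models: tuple = ("branch", "branch_site")
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.omega_cap <= 1:
            raise ValueError("omega_cap must exceed 1")


def classify_gene(branch_summary: dict | None,
                  branch_site_summary: dict | None,
                  config: ScanConfig = ScanConfig()) -> set[str]:
    """Reporting lists for one gene from its fit summaries.

    ``branch_summary`` needs keys ``omega0``, ``omega1``, ``lrt`` (optionally
    ``excluded``); ``branch_site_summary`` needs ``omega2``, ``lrt``. Either
    may be None when that model was not run.
    """
    lists: set[str] = set()
    crit = config.lrt_critical
    if branch_summary and not branch_summary.get("excluded", False):
        w0, w1 = branch_summary["omega0"], branch_summary["omega1"]
        if branch_summary["lrt"] > crit:
            if w0 <= 1.0 < w1:
                lists.add("list_i")
            elif w0 < w1 < 1.0:
                lists.add("list_ii")
    if branch_site_summary and not branch_site_summary.get("excluded", False):
        if (branch_site_summary["lrt"] > crit
                and branch_site_summary["omega2"] > 1.0):
            lists.add("list_iii")
    return lists


def apply_omega_cap(table: pd.DataFrame,
                    config: ScanConfig = ScanConfig()) -> pd.DataFrame:
    """Flag records whose foreground ω estimate exceeds the cap.

    Extreme foreground ω values signal a synonymous rate estimate near zero,
    i.e. an unreliable ratio; such genes are excluded before the FDR step and
    receive no category. With ``cap_only_significant`` only nominally
    significant records are flagged (the stricter alternative reading).
    """
    out = table.copy()
    over = out["omega_fg"] > config.omega_cap
    if config.cap_only_significant:
        over &= out["lrt"] > config.lrt_critical
    out["excluded"] = over.fillna(False)
    return out


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, order-stable)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def expected_by_chance(n_tests: int, alpha: float) -> int:
    """Number of significant tests expected under the global null,
    rounded half-up to the nearest integer."""
    if n_tests < 0:
        raise ValueError("n_tests must be non-negative")
    return int(math.floor(n_tests * alpha + 0.5))


@dataclass
class ScanResults:
    """Per-model result tables plus per-gene status lines."""

    branch: pd.DataFrame
    branch_site: pd.DataFrame
    gene_status: pd.DataFrame
    config: ScanConfig

    def categories(self) -> dict[str, set[str]]:
        """gene_id → set of assigned lists (union over models)."""
        out: dict[str, set[str]] = {}
        for table, key in ((self.branch, ("list_i", "list_ii")),
                           (self.branch_site, ("list_iii",))):
            for _, row in table.iterrows():
                if row["category"] in key:
                    out.setdefault(row["gene_id"], set()).add(row["category"])
        return out


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=MODEL_COLUMNS)


def run_scan(genes, tree: PhyloTree, config: ScanConfig = ScanConfig(),
             log=None) -> ScanResults:
    """Full per-gene pipeline: QC → branch and branch-site fits → LRTs →
    ω-cap filter → per-model FDR → list classification.

    ``genes`` is an iterable of :class:`CodonAlignment`. Genes failing QC are
    recorded in ``gene_status`` with the reason, never silently dropped.
    """
    log = log if log is not None else (lambda msg: None)
    branch_rows, bs_rows, status_rows = [], [], []
    for aln in genes:
        degapped = remove_missing_codon_sites(aln)
        report = qc_gene(degapped, min_codons=config.min_codons,
                         gene_id=aln.gene_id)
        report.n_codons_input = aln.n_codons
        if report.passed and config.run_entropy_filter:
            flagged, _, _ = entropy_scan(degapped,
                                         threshold=config.entropy_threshold,
                                         window=config.entropy_window)
            if flagged:
                report.fail_reasons.append("entropy")
                report.passed = False
        if not report.passed:
            reason = "failed_qc: " + ",".join(report.fail_reasons)
            status_rows.append({"gene_id": aln.gene_id, "status": reason,
                                "n_codons": report.n_codons_retained})
            log(f"{aln.gene_id}\t{reason}")
            continue
        status_rows.append({"gene_id": aln.gene_id, "status": "ok",
                            "n_codons": degapped.n_codons})

        shared_lengths = None
        if "branch" in config.models:
            bm = BranchModel(degapped, tree, freq_method=config.freq_method,
                             lengths=config.lengths, restarts=config.restarts)
            res = bm.fit()
            shared_lengths = bm.branch_lengths
            branch_rows.append({
                "gene_id": aln.gene_id, "lnL0": res.lnL0, "lnL1": res.lnL1,
                "omega0": res.omega0, "omega_fg": res.omega1,
                "lrt": res.lrt_stat, "p": res.p_value,
            })
            log(f"{aln.gene_id}\tbranch\tlrt={res.lrt_stat:.4f}")
        if "branch_site" in config.models:
            bs = BranchSiteModel(degapped, tree, freq_method=config.freq_method,
                                 lengths=config.lengths,
                                 restarts=config.restarts,
                                 branch_lengths=shared_lengths)
            res = bs.fit()
            bs_rows.append({
                "gene_id": aln.gene_id, "lnL0": res.lnL0, "lnL1": res.lnL1,
                "omega0": res.omega0, "omega_fg": res.omega2,
                "lrt": res.lrt_stat, "p": res.p_value,
            })
            log(f"{aln.gene_id}\tbranch_site\tlrt={res.lrt_stat:.4f}")

    branch = pd.DataFrame(branch_rows) if branch_rows else _empty_table()
    bs = pd.DataFrame(bs_rows) if bs_rows else _empty_table()

    def finalize(table: pd.DataFrame, model: str) -> pd.DataFrame:
        if table.empty:
            return _empty_table()
        table = apply_omega_cap(table, config)
        table["q"] = np.nan
        keep = ~table["excluded"]
        if keep.any():
            table.loc[keep, "q"] = fdr_correct(table.loc[keep, "p"].to_numpy())
        cats = []
        for _, row in table.iterrows():
            summary = {"omega0": row["omega0"], "lrt": row["lrt"],
                       "excluded": row["excluded"]}
            if model == "branch":
                summary["omega1"] = row["omega_fg"]
                lists = classify_gene(summary, None, config)
            else:
                summary["omega2"] = row["omega_fg"]
                lists = classify_gene(None, summary, config)
            cats.append(sorted(lists)[0] if lists else "none")
        table["category"] = cats
        return table[MODEL_COLUMNS]

    return ScanResults(finalize(branch, "branch"), finalize(bs, "branch_site"),
                       pd.DataFrame(status_rows), config)


def scan_all_branches(aln: CodonAlignment, tree: PhyloTree,
                      config: ScanConfig = ScanConfig()):
    """Branch-model scan over every branch as a candidate foreground.

    No a priori foreground is assumed: each branch in turn is labeled
    foreground and tested against the shared one-ω null, with a Bonferroni
    threshold of ``alpha / n_branches``. The verdict is ``focal-specific``
    exactly when the focal branch (the foreground branch flagged on the
    input tree) is the only significant branch after correction.

    Returns ``(per_branch_table, verdict)``.
    """
    internal = [b for b in tree.branches() if not b.is_leaf]
    if len(internal) < 2:
        raise ValueError("all-branch scan needs a tree with >= 2 internal branches")
    focal = tree.foreground_branches()
    if len(focal) != 1:
        raise ValueError("input tree must flag exactly one focal branch")
    all_leaves = frozenset(tree.leaf_names)
    focal_split = tree.leaf_set_below(focal[0])
    focal_split = min(focal_split, all_leaves - focal_split, key=sorted)

    branches = tree.branches()
    n_branches = len(branches)
    threshold = chi2.isf(config.alpha / n_branches, df=1)
    rows = []
    degapped = remove_missing_codon_sites(aln)
    for node in branches:
        split = tree.leaf_set_below(node)
        split = min(split, all_leaves - split, key=sorted)
        fg_tree = tree.set_foreground_clade(split)
        bm = BranchModel(degapped, fg_tree, freq_method=config.freq_method,
                         lengths=config.lengths, restarts=config.restarts)
        res = bm.fit()
        rows.append({
            "branch": "|".join(sorted(split)),
            "is_focal": split == focal_split,
            "omega0": res.omega0, "omega_fg": res.omega1,
            "lrt": res.lrt_stat, "p": res.p_value,
            "significant": res.lrt_stat > threshold,
        })
    table = pd.DataFrame(rows).drop_duplicates(subset="branch")
    sig = table[table["significant"]]
    verdict = ("focal-specific"
               if len(sig) >= 1 and sig["is_focal"].all() and sig["is_focal"].any()
               else "negative")
    return table, verdict
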