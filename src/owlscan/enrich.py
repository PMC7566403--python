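"""Candidate-versus-background functional overrepresentation.

Per-term hypergeometric enrichment of a candidate gene set against the set
of tested genes, with family-wise error rates from the permutation
distribution of the minimum p-value across terms (so all terms share one
null sample), and the candidate-gene report with per-category counts.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .alignment import CandidateList, CANDIDATE_CATEGORIES
from .scan import ScanConfig, ScanResults, classify_gene, expected_by_chance

__all__ = [
    "AnnotationDB",
    "EnrichmentResult",
    "read_annotation_table",
    "merge_annotations",
    "hypergeometric_test",
    "fwer_permutation",
    "run_enrichment",
    "candidate_report",
]


@dataclass
class AnnotationDB:
    """Gene↔term map plus optional term labels; background = annotated genes."""

    term_to_genes: dict[str, frozenset]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.term_to_genes = {t: frozenset(g) for t, g in self.term_to_genes.items()
                              if g}
        self.background = frozenset().union(*self.term_to_genes.values()) \
            if self.term_to_genes else frozenset()

    @property
    def n_terms(self) -> int:
        return len(self.term_to_genes)

    def restricted(self, genes) -> "AnnotationDB":
        """Database intersected with a gene universe (empty terms dropped)."""
        genes = frozenset(genes)
        return AnnotationDB(
            {t: g & genes for t, g in self.term_to_genes.items() if g & genes},
            dict(self.term_names),
        )


def read_annotation_table(path: str | os.PathLike) -> pd.DataFrame:
    """Two-column TSV ``gene_id\tterm_id`` (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene_id", "term_id"]:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                         names=["gene_id", "term_id"])
    return df[["gene_id", "term_id"]]


def merge_annotations(source_a: pd.DataFrame, source_b: pd.DataFrame,
                      term_names: dict | None = None) -> AnnotationDB:
    """Union of two gene↔term tables, deduplicated pair-wise.

    This mirrors building one custom background from two species' annotation
    sources: a pair present in both contributes once, and the background is
    the union of all annotated genes.
    """
    pairs = pd.concat([source_a, source_b], ignore_index=True)
    pairs = pairs.drop_duplicates()
    term_to_genes: dict[str, set] = {}
    for gene, term in pairs.itertuples(index=False):
        term_to_genes.setdefault(term, set()).add(gene)
    return AnnotationDB({t: frozenset(g) for t, g in term_to_genes.items()},
                        dict(term_names or {}))


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _hyper_sf_table(N: int, K: int, n: int) -> np.ndarray:
    """P(X ≥ k) for k = 0..min(n, K), by exact log-space summation."""
    kmax = min(n, K)
    ks = np.arange(kmax + 1)
    with np.errstate(divide="ignore"):
        logpmf = (_log_comb(K, ks) + _log_comb(N - K, n - ks) - _log_comb(N, n))
    pmf = np.exp(logpmf)
    pmf[np.isnan(pmf)] = 0.0
    tail = np.cumsum(pmf[::-1])[::-1]
    return np.minimum(tail, 1.0)


def hypergeometric_test(candidates, term_genes, background) -> float:
    """Upper-tail hypergeometric enrichment p-value P(X ≥ k).

    ``k`` = candidates carrying the term, drawn without replacement
    (``n`` candidates) from a background of ``N`` genes of which ``K`` carry
    the term. Exact summation with log-space binomial coefficients.
    """
    background = frozenset(background)
    candidates = frozenset(candidates)
    if not candidates:
        raise ValueError("empty candidate set")
    if not candidates <= background:
        raise ValueError("candidates must be a subset of the background")
    term_genes = frozenset(term_genes) & background
    N, K, n = len(background), len(term_genes), len(candidates)
    k = len(candidates & term_genes)
    return float(_hyper_sf_table(N, K, n)[k])


def fwer_permutation(candidates, db: AnnotationDB, n_perm: int = 10_000,
                     seed: int | None = None,
                     min_term_size: int = 3) -> pd.DataFrame:
    """Per-term enrichment with min-p permutation family-wise error rates.

    Each permutation redraws a random candidate set of the same size from the
    background; the FWER of a term is the fraction of permutations whose
    *smallest* p-value across all terms is at least as extreme as the term's
    observed p (with the +1 finite-sample correction). Terms with fewer than
    ``min_term_size`` background genes are skipped as untestable.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives coarse FWERs",
                      stacklevel=2)
    background = sorted(db.background)
    candidates = frozenset(candidates)
    if not candidates < frozenset(background):
        raise ValueError("candidates must be a proper subset of the background")
    N, n = len(background), len(candidates)
    terms = [t for t, g in sorted(db.term_to_genes.items())
             if len(g) >= min_term_size]
    if not terms:
        return pd.DataFrame(columns=["term_id", "name", "k", "n", "K", "N",
                                     "p", "fwer"])
    incidence = np.zeros((len(terms), N), dtype=np.int64)
    gene_pos = {g: i for i, g in enumerate(background)}
    for ti, t in enumerate(terms):
        for g in db.term_to_genes[t]:
            incidence[ti, gene_pos[g]] = 1
    sf_tables = [_hyper_sf_table(N, int(incidence[ti].sum()), n)
                 for ti in range(len(terms))]

    cand_mask = np.zeros(N, dtype=np.int64)
    cand_mask[[gene_pos[g] for g in candidates]] = 1
    k_obs = incidence @ cand_mask
    p_obs = np.array([sf_tables[ti][k] for ti, k in enumerate(k_obs)])

    rng = np.random.default_rng(seed)
    min_p = np.empty(n_perm)
    mask = np.zeros(N, dtype=np.int64)
    for r in range(n_perm):
        perm = rng.choice(N, size=n, replace=False)
        mask[:] = 0
        mask[perm] = 1
        ks = incidence @ mask
        min_p[r] = min(sf_tables[ti][k] for ti, k in enumerate(ks))
    fwer = np.array([(1 + (min_p <= p + 1e-15).sum()) / (n_perm + 1)
                     for p in p_obs])
    out = pd.DataFrame({
        "term_id": terms,
        "name": [db.term_names.get(t, "") for t in terms],
        "k": k_obs.astype(int), "n": n,
        "K": incidence.sum(axis=1).astype(int), "N": N,
        "p": p_obs, "fwer": fwer,
    })
    return out.sort_values(["fwer", "p", "term_id"]).reset_index(drop=True)


def run_enrichment(results: ScanResults, db: AnnotationDB,
                   list_selector: str, n_perm: int = 10_000,
                   seed: int | None = None,
                   min_term_size: int = 3,
                   background: str = "tested") -> pd.DataFrame:
    """Overrepresentation of one scan category against the tested genes.

    ``list_selector`` is one of ``list_i``, ``list_ii``, ``list_iii`` or
    ``genome_wide_significant`` (q ≤ FDR level in either model). The
    background is the set of genes the scan actually tested (annotation
    restricted to them) unless ``background="annotation"``.
    """
    cats = results.categories()
    tested = set(results.branch["gene_id"]) | set(results.branch_site["gene_id"])
    if list_selector in ("list_i", "list_ii", "list_iii"):
        cand = {g for g, ls in cats.items() if list_selector in ls}
    elif list_selector == "genome_wide_significant":
        cand = set()
        for table in (results.branch, results.branch_site):
            if not table.empty:
                sig = table[(~table["excluded"])
                            & (table["q"] <= results.config.fdr_level)
                            & (table["category"] != "none")]
                cand |= set(sig["gene_id"])
    else:
        raise ValueError(f"unknown selector {list_selector!r}")
    use_db = db.restricted(tested) if background == "tested" else db
    cand &= use_db.background
    if not cand:
        warnings.warn(f"selector {list_selector!r} matches no annotated gene",
                      stacklevel=2)
        return pd.DataFrame(columns=["term_id", "name", "k", "n", "K", "N",
                                     "p", "fwer"])
    return fwer_permutation(cand, use_db, n_perm=n_perm, seed=seed,
                            min_term_size=min_term_size)


def candidate_report(results: ScanResults, candidates: CandidateList,
                     config: ScanConfig | None = None):
    """Per-candidate-gene report and per-category significance counts.

    Returns ``(gene_table, summary)``: the gene table lists, for every
    candidate gene present in the scan, its ω estimates, LRTs and assigned
    lists; the summary counts branch-model-significant genes per functional
    category, the branch-site-significant genes, dual-model genes, and the
    number of significant tests expected by chance at level α.
    """
    config = config or results.config
    if len(candidates) == 0:
        return (pd.DataFrame(columns=["gene_id", "candidate_category", "lists",
                                      "omega0", "omega1", "branch_lrt",
                                      "omega2", "branch_site_lrt"]),
                {"per_category_branch": {c: 0 for c in CANDIDATE_CATEGORIES},
                 "branch_site_significant": 0, "dual_model": 0,
                 "total_significant": 0,
                 "expected_by_chance": expected_by_chance(0, config.alpha)})
    branch = results.branch.set_index("gene_id") if not results.branch.empty \
        else pd.DataFrame()
    bs = results.branch_site.set_index("gene_id") if not results.branch_site.empty \
        else pd.DataFrame()
    rows = []
    per_cat = {c: 0 for c in CANDIDATE_CATEGORIES}
    n_bs = n_dual = 0
    for gene, category in candidates.entries.items():
        b = branch.loc[gene] if gene in getattr(branch, "index", []) else None
        s = bs.loc[gene] if gene in getattr(bs, "index", []) else None
        if b is None and s is None:
            continue
        bsum = (None if b is None else
                {"omega0": b["omega0"], "omega1": b["omega_fg"],
                 "lrt": b["lrt"], "excluded": b["excluded"]})
        ssum = (None if s is None else
                {"omega2": s["omega_fg"], "lrt": s["lrt"],
                 "excluded": s["excluded"]})
        lists = classify_gene(bsum, ssum, config)
        in_branch = bool(lists & {"list_i", "list_ii"})
        in_bs = "list_iii" in lists
        per_cat[category] += in_branch
        n_bs += in_bs
        n_dual += in_branch and in_bs
        rows.append({
            "gene_id": gene, "candidate_category": category,
            "lists": " and ".join(sorted(lists)) if lists else "none",
            "omega0": None if b is None else b["omega0"],
            "omega1": None if b is None else b["omega_fg"],
            "branch_lrt": None if b is None else b["lrt"],
            "omega2": None if s is None else s["omega_fg"],
            "branch_site_lrt": None if s is None else s["lrt"],
        })
    gene_table = pd.DataFrame(rows)
    summary = {
        "per_category_branch": per_cat,
        "branch_site_significant": n_bs,
        "dual_model": n_dual,
        "total_significant": int(
            sum(1 for r in rows if r["lists"] != "none")),
        "expected_by_chance": expected_by_chance(len(candidates), config.alpha),
    }
    return gene_table, summary
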