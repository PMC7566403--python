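"""Per-gene alignment quality control and the CMD diagnostic.

Filters applied before any selection test: removal of codon columns with
missing data, minimum-length and variable-site requirements, and an
entropy-based screen for high-variability blocks that typically indicate
misalignment or sequencing error. The module also quantifies codons with
multiple nucleotide differences relative to a reference taxon (CMDs) — a
proxy for multinucleotide mutation events that are known to inflate
branch-site tests — together with the two association tests used to relate
CMD load to test outcomes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .alignment import CodonAlignment
from .codon import build_codon_space

__all__ = [
    "QCReport",
    "AssociationResult",
    "remove_missing_codon_sites",
    "qc_gene",
    "entropy_scan",
    "cmd_count",
    "permutation_welch_test",
    "kendall_tau_b",
]

_ACGT = frozenset("ACGT")


@dataclass
class QCReport:
    """Per-gene QC summary accumulated across the filter stages."""

    gene_id: str
    n_codons_input: int
    n_codons_retained: int
    pct_variable_sites: float = 0.0
    passed: bool = False
    fail_reasons: list = field(default_factory=list)
    entropy_flagged: bool = False
    flagged_windows: list = field(default_factory=list)
    cmd_count: int = 0
    cmd_sites_evaluated: int = 0

    @property
    def cmd_proportion(self) -> float:
        if self.cmd_sites_evaluated == 0:
            return 0.0
        return self.cmd_count / self.cmd_sites_evaluated


@dataclass
class AssociationResult:
    """Outcome of the CMD-vs-test-result association checks."""

    welch_t: float
    perm_p: float
    n_permutations: int
    kendall_tau_b: float | None = None
    kendall_p: float | None = None


def _resolved(codon: str) -> bool:
    return all(c in _ACGT for c in codon)


def remove_missing_codon_sites(aln: CodonAlignment) -> CodonAlignment:
    """Drop every codon column containing any character outside {A,C,G,T}.

    Idempotent; preserves column order; may return a 0-codon alignment.
    """
    keep = [s for s in range(aln.n_codons)
            if all(_resolved(aln.codon(i, s)) for i in range(aln.n_taxa))]
    if len(keep) == aln.n_codons:
        return aln
    return aln.select_codons(keep)


def qc_gene(aln: CodonAlignment, min_codons: int = 20,
            gene_id: str | None = None) -> QCReport:
    """Length and variability filter on an already-degapped alignment.

    Fails when fewer than ``min_codons`` codon columns remain or when no
    column is variable. ``pct_variable_sites`` is the fraction of retained
    codon columns at which not all taxa carry the same codon.
    """
    n = aln.n_codons
    variable = sum(1 for s in range(n) if len(set(aln.column(s))) > 1)
    report = QCReport(gene_id or aln.gene_id, n_codons_input=n, n_codons_retained=n,
                      pct_variable_sites=(variable / n if n else 0.0))
    if n < min_codons:
        report.fail_reasons.append("min_codons")
    if variable == 0:
        report.fail_reasons.append("no_variable_sites")
    report.passed = not report.fail_reasons
    return report


def entropy_scan(aln: CodonAlignment, threshold: float = 0.5, window: int = 3):
    """Flag high-entropy (low-quality) blocks of codon columns.

    Each column is translated to amino acids; its Shannon entropy over the
    observed residues is normalized by ln(n_taxa) to [0, 1] and smoothed by a
    centered moving average of ``window`` columns (truncated at the ends).
    Columns whose smoothed score exceeds ``threshold`` are flagged and merged
    into intervals; a gene with any flagged column is excluded upstream.
    Columns containing a stop codon are treated as missing for the entropy
    (with a warning).

    Returns ``(entropy_flagged, flagged_windows, smoothed_scores)``.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    space = build_codon_space(1)
    n = aln.n_codons
    n_taxa = aln.n_taxa
    raw = np.zeros(n)
    saw_stop = False
    for s in range(n):
        residues = []
        for i in range(n_taxa):
            codon = aln.codon(i, s)
            if not _resolved(codon):
                continue
            if space.is_stop(codon):
                saw_stop = True
                continue
            residues.append(space.translate(codon))
        if len(residues) < 2 or n_taxa < 2:
            raw[s] = 0.0
            continue
        _, counts = np.unique(residues, return_counts=True)
        p = counts / counts.sum()
        raw[s] = min(1.0, max(0.0, float(-(p * np.log(p)).sum()
                                         / math.log(n_taxa))))
    if saw_stop:
        warnings.warn(
            f"stop codon(s) in {aln.gene_id!r} ignored in entropy columns",
            stacklevel=2,
        )
    half = window // 2
    smoothed = np.array([
        raw[max(0, s - half): s + half + 1].mean() for s in range(n)
    ])
    flagged = smoothed > threshold
    intervals: list[tuple[int, int]] = []
    start = None
    for s in range(n):
        if flagged[s] and start is None:
            start = s
        elif not flagged[s] and start is not None:
            intervals.append((start, s - 1))
            start = None
    if start is not None:
        intervals.append((start, n - 1))
    return bool(flagged.any()), intervals, smoothed


def cmd_count(aln: CodonAlignment, reference_taxon: str,
              query_taxa) -> tuple[int, int]:
    """Count codon sites with multiple differences (CMDs) to a reference.

    A codon column is *evaluated* when the reference codon is fully resolved;
    it counts as one CMD when at least one query taxon carries a fully
    resolved codon differing from the reference at two or more of its three
    positions. Each column counts at most once, however many query taxa
    qualify.
    """
    ref_row = aln.taxon_index(reference_taxon)
    query_rows = [aln.taxon_index(t) for t in query_taxa]
    evaluated = 0
    cmds = 0
    for s in range(aln.n_codons):
        ref = aln.codon(ref_row, s)
        if not _resolved(ref):
            continue
        evaluated += 1
        for row in query_rows:
            q = aln.codon(row, s)
            if not _resolved(q):
                continue
            if sum(a != b for a, b in zip(ref, q)) >= 2:
                cmds += 1
                break
    return cmds, evaluated


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    denom = math.sqrt(va / a.size + vb / b.size)
    diff = a.mean() - b.mean()
    if denom == 0:
        # zero variance in both groups: equal means are maximally
        # unsurprising, distinct means maximally separated
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return float(diff / denom)


def permutation_welch_test(group_a, group_b, n_perm: int = 10_000,
                           seed: int | None = None) -> AssociationResult:
    """Two-sample permutation test on the Welch t statistic.

    Labels are permuted ``n_perm`` times (or all label arrangements are
    enumerated when there are no more than ``n_perm`` of them, in which case
    the p-value is exact without the +1 correction); the two-sided p-value
    compares |t| against the permutation distribution.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must contain finite values")
    t_obs = _welch_t(a, b)
    pooled = np.concatenate([a, b])
    n_a, n_tot = a.size, pooled.size
    n_arrangements = math.comb(n_tot, n_a)
    tol = 1e-12
    if n_arrangements <= n_perm:
        hits = 0
        for idx_a in combinations(range(n_tot), n_a):
            mask = np.zeros(n_tot, dtype=bool)
            mask[list(idx_a)] = True
            if abs(_welch_t(pooled[mask], pooled[~mask])) >= abs(t_obs) - tol:
                hits += 1
        return AssociationResult(t_obs, hits / n_arrangements, n_arrangements)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_tot)
        if abs(_welch_t(pooled[perm[:n_a]], pooled[perm[n_a:]])) >= abs(t_obs) - tol:
            hits += 1
    return AssociationResult(t_obs, (1 + hits) / (n_perm + 1), n_perm)


def kendall_tau_b(x, y) -> tuple[float, float]:
    """Kendall's τ-b with tie correction; p from the normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("tau is undefined when all x or all y are tied")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
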