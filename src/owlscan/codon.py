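"""Codon state space, equilibrium frequencies and the Goldman–Yang-style
rate matrix parameterized by the transition/transversion ratio κ and the
nonsynonymous/synonymous rate ratio ω = dN/dS.

Codons are ordered alphabetically over A,C,G,T with stop codons removed
(61 sense codons for the standard code). The instantaneous rate from codon
i to j is zero unless they differ at exactly one position, and otherwise

    q_ij ∝ π_j · κ^[transition] · ω^[nonsynonymous],

with the diagonal set to minus the row sum and the whole matrix rescaled so
that Σ_i π_i (−q_ii) = 1, i.e. branch lengths are expected substitutions per
codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .alignment import CodonAlignment

__all__ = [
    "CodonSpace",
    "build_codon_space",
    "estimate_codon_freqs",
    "build_rate_matrix",
    "rate_matrix_eig",
    "transition_probs",
]

_NUC = "ACGT"
_NUC_INDEX = {c: i for i, c in enumerate(_NUC)}
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}

# standard genetic code (code 1), codon -> one-letter amino acid, '*' = stop
_STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class CodonSpace:
    """Sense-codon state space for one genetic code."""

    code_id: int
    codons: tuple[str, ...]
    index: dict
    aa: dict
    # single-difference structure, precomputed for rate-matrix assembly:
    # boolean (n,n) masks over codon pairs
    one_diff: np.ndarray
    is_transition: np.ndarray
    is_nonsyn: np.ndarray

    @property
    def n(self) -> int:
        return len(self.codons)

    def translate(self, codon: str) -> str:
        """Amino acid for a sense codon; '*' for a stop codon."""
        return _STANDARD_CODE.get(codon, "X")

    def is_stop(self, codon: str) -> bool:
        return _STANDARD_CODE.get(codon) == "*"


@lru_cache(maxsize=None)
def build_codon_space(code_id: int = 1) -> CodonSpace:
    """Construct the codon space for a genetic code (only code 1 supported)."""
    if code_id != 1:
        raise ValueError(f"unsupported genetic code: {code_id}")
    codons = tuple(
        a + b + c
        for a in _NUC for b in _NUC for c in _NUC
        if _STANDARD_CODE[a + b + c] != "*"
    )
    n = len(codons)
    aa = {c: _STANDARD_CODE[c] for c in codons}
    one_diff = np.zeros((n, n), dtype=bool)
    is_ti = np.zeros((n, n), dtype=bool)
    is_ns = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            one_diff[i, j] = True
            is_ti[i, j] = frozenset(diffs[0]) in _TRANSITIONS
            is_ns[i, j] = aa[ci] != aa[cj]
    return CodonSpace(code_id, codons, {c: i for i, c in enumerate(codons)},
                      aa, one_diff, is_ti, is_ns)


def estimate_codon_freqs(aln: CodonAlignment, method: str = "F3x4",
                         space: CodonSpace | None = None) -> np.ndarray:
    """Equilibrium codon frequencies from observed nucleotide counts.

    ``uniform`` gives 1/61 each; ``F1x4`` uses pooled nucleotide frequencies;
    ``F3x4`` uses codon-position-specific nucleotide frequencies. Both
    empirical variants renormalize the product over the sense codons only.
    Characters outside A,C,G,T (missing data, gaps) are ignored in the counts.
    """
    space = space or build_codon_space(1)
    if aln.n_codons == 0:
        raise ValueError("cannot estimate codon frequencies from an empty alignment")
    if method == "uniform":
        return np.full(space.n, 1.0 / space.n)
    counts = np.zeros((3, 4))
    for seq in aln.seqs:
        for i, ch in enumerate(seq):
            k = _NUC_INDEX.get(ch)
            if k is not None:
                counts[i % 3, k] += 1
    if counts.sum() == 0:
        raise ValueError("alignment contains no resolved nucleotides")
    if method == "F1x4":
        pooled = counts.sum(axis=0)
        pos = np.tile(pooled / pooled.sum(), (3, 1))
    elif method == "F3x4":
        totals = counts.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise ValueError("a codon position has no resolved nucleotides")
        pos = counts / totals
    else:
        raise ValueError(f"unknown frequency method: {method!r}")
    pi = np.array([
        pos[0, _NUC_INDEX[c[0]]] * pos[1, _NUC_INDEX[c[1]]] * pos[2, _NUC_INDEX[c[2]]]
        for c in space.codons
    ])
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate nucleotide frequencies: no sense codon has mass")
    return pi / total


def build_rate_matrix(space: CodonSpace, kappa: float, omega: float,
                      pi: np.ndarray) -> np.ndarray:
    """The scaled generator Q for given κ, ω and equilibrium frequencies."""
    if kappa < 0 or omega < 0:
        raise ValueError("kappa and omega must be non-negative")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (space.n,):
        raise ValueError(f"pi must have length {space.n}")
    rate = np.where(space.one_diff, 1.0, 0.0)
    rate = rate * np.where(space.is_transition, kappa, 1.0)
    rate = rate * np.where(space.is_nonsyn, omega, 1.0)
    q = rate * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -(pi * np.diag(q)).sum()
    if mean_rate <= 0:
        raise ValueError("degenerate rate matrix (zero mean substitution rate)")
    return q / mean_rate


_PI_FLOOR = 1e-10


def mean_rate(space: CodonSpace, kappa: float, omega: float, pi: np.ndarray) -> float:
    """Expected substitution rate Σ_i π_i Σ_{j≠i} q_ij of the *unscaled*
    generator (q_ij = π_j κ^[ti] ω^[ns] on single-difference pairs).

    Used to put the site classes of a mixture model on a common per-branch
    scale: each class matrix is divided by the proportion-weighted average of
    these rates, so branch lengths stay expected substitutions per codon
    averaged over classes while high-ω classes evolve faster.
    """
    pi = np.asarray(pi, dtype=float)
    rate = np.where(space.one_diff, 1.0, 0.0)
    rate = rate * np.where(space.is_transition, kappa, 1.0)
    rate = rate * np.where(space.is_nonsyn, omega, 1.0)
    return float(pi @ rate @ pi)


def rate_matrix_eig(space: CodonSpace, kappa: float, omega: float, pi: np.ndarray):
    """Symmetric eigendecomposition of Q exploiting reversibility.

    Zero frequencies are floored at 1e-10 (and renormalized) so the
    similarity transform is defined; the flooring is also applied to the
    matrix itself so the decomposition is exact for the floored model.
    Returns ``(left, eigvals, right)`` with ``P(t) = left @ diag(exp(λ t)) @ right``.
    """
    pi = np.asarray(pi, dtype=float)
    if np.any(pi < _PI_FLOOR):
        pi = np.maximum(pi, _PI_FLOOR)
        pi = pi / pi.sum()
    q = build_rate_matrix(space, kappa, omega, pi)
    sq = np.sqrt(pi)
    sym = q * (sq[:, None] / sq[None, :])
    sym = 0.5 * (sym + sym.T)  # enforce exact symmetry against rounding
    eigvals, u = np.linalg.eigh(sym)
    left = u / sq[:, None]
    right = u.T * sq[None, :]
    return left, eigvals, right


def transition_probs(q_or_eig, t: float) -> np.ndarray:
    """P(t) = exp(Qt).

    Accepts either a raw generator matrix (dense matrix exponential via
    scipy) or the decomposition returned by :func:`rate_matrix_eig` (fast
    path used by the pruning engine). Rows sum to 1; tiny negative entries
    from rounding are clamped to zero.
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if isinstance(q_or_eig, np.ndarray):
        from scipy.linalg import expm

        p = expm(q_or_eig * t)
    else:
        left, eigvals, right = q_or_eig
        p = (left * np.exp(eigvals * t)[None, :]) @ right
    np.clip(p, 0.0, None, out=p)
    return p
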