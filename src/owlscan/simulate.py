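"""Synthetic codon alignments and annotation tables with known ground truth.

Every input the scan consumes can be generated here: codon alignments evolved
along the labeled species tree under a shared-ω (null), branch, or
branch-site regime — with per-taxon masking and occasional gap columns
emulating zero-coverage masking and alignment gaps — plus gene↔term
annotation tables with planted enriched terms.

Evolution draws child states from the transition probabilities P(t) down the
tree (fast path); an event-level trace mode simulates the embedded jump chain
explicitly so tests can count synonymous/nonsynonymous changes per branch
against the recorded ancestral states.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import CodonAlignment, write_codon_fasta
from .codon import (build_codon_space, build_rate_matrix, mean_rate,
                    rate_matrix_eig, transition_probs)
from .likelihood import TreeIndex
from .tree import PhyloTree, owl_species_tree, write_newick_labeled

__all__ = [
    "SimulationScenario",
    "simulate_gene",
    "simulate_gene_set",
    "plant_enrichment",
    "gene_seed",
]

REGIMES = ("null", "branch", "branch_site")


@dataclass
class SimulationScenario:
    """Generative conditions for one gene.

    Defaults mirror the study conditions: the 20-taxon owl/outgroup tree with
    the owl-ancestor foreground branch and uniform 0.1 branch lengths, κ = 2,
    uniform codon frequencies, and light missing-data masking.
    """

    tree: PhyloTree | None = None
    kappa: float = 2.0
    pi: np.ndarray | str = "uniform"
    regime: str = "null"
    omega_bg: float = 0.2
    omega_fg: float | None = None
    site_class_props: tuple[float, float] = (0.75, 0.15)  # (p0, p1); rest split 2a/2b
    n_codons: int = 300
    mask_rate: float = 0.02
    gap_column_rate: float = 0.005
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.tree is None:
            self.tree = owl_species_tree()
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime != "null" and self.omega_fg is None:
            raise ValueError(f"regime {self.regime!r} requires omega_fg")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        for name, rate in (("mask_rate", self.mask_rate),
                           ("gap_column_rate", self.gap_column_rate)):
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.regime == "branch_site":
            p0, p1 = self.site_class_props
            if p0 < 0 or p1 < 0 or p0 + p1 > 1 or p0 + p1 <= 0:
                raise ValueError("invalid site_class_props")

    def resolved_pi(self, space) -> np.ndarray:
        if isinstance(self.pi, str):
            if self.pi != "uniform":
                raise ValueError(f"unknown pi spec {self.pi!r}")
            return np.full(space.n, 1.0 / space.n)
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (space.n,) or abs(pi.sum() - 1) > 1e-9:
            raise ValueError("pi must be a length-61 probability vector")
        return pi


def _site_class_omegas(scn: SimulationScenario):
    """Per-class (bg ω, fg ω) pairs and proportions for the branch-site regime."""
    p0, p1 = scn.site_class_props
    rest = 1.0 - p0 - p1
    p2a = rest * p0 / (p0 + p1)
    p2b = rest * p1 / (p0 + p1)
    w0, w2 = scn.omega_bg, scn.omega_fg
    pairs = [(w0, w0), (1.0, 1.0), (w0, w2), (1.0, w2)]
    return pairs, np.array([p0, p1, p2a, p2b])


def _sample_markov(parent_states: np.ndarray, cum_p: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    u = rng.random(parent_states.shape[0])
    return (cum_p[parent_states] < u[:, None]).sum(axis=1)


def _gillespie_branch(states: np.ndarray, q: np.ndarray, t: float,
                      rng: np.random.Generator, events: list, branch_id: int):
    """Exact jump-chain simulation for one branch; mutates nothing, returns
    the child states and appends (branch, site, from, to) events."""
    out = states.copy()
    exit_rate = -np.diag(q)
    for site in range(out.size):
        s = int(out[site])
        time = 0.0
        while True:
            rate = exit_rate[s]
            if rate <= 0:
                break
            time += rng.exponential(1.0 / rate)
            if time >= t:
                break
            probs = q[s].copy()
            probs[s] = 0.0
            probs = probs / probs.sum()
            nxt = int(rng.choice(probs.size, p=probs))
            events.append((branch_id, site, s, nxt))
            s = nxt
        out[site] = s
    return out


def simulate_gene(scenario: SimulationScenario, gene_id: str = "gene",
                  trace: bool = False):
    """Evolve one gene along the scenario tree.

    Returns ``(CodonAlignment, truth)`` where ``truth`` records the regime,
    the generating parameters, per-site classes (branch-site regime), and —
    in trace mode — the list of substitution events ``(branch_leafset, site,
    from_codon, to_codon)`` plus the states at every internal node.
    """
    scn = scenario
    space = build_codon_space(1)
    pi = scn.resolved_pi(space)
    tree = scn.tree
    idx = TreeIndex(tree, tree.leaf_names, root_at_fg_parent=False)

    ss = np.random.SeedSequence(scn.seed if scn.seed is not None else 0)
    rng_evo, rng_mask, rng_gap = (np.random.default_rng(c) for c in ss.spawn(3))

    n = scn.n_codons
    if scn.regime == "branch_site":
        pairs, props = _site_class_omegas(scn)
        site_class = rng_evo.choice(4, size=n, p=props)
    else:
        pairs, props, site_class = None, None, None

    if scn.regime == "branch_site":
        # common per-branch scale across site classes (matching the fitted
        # model): each class generator Q(ω)/m(ω) runs on an effective length
        # t·m(ω)/f, with f the proportion-weighted mean rate on that branch
        rates = {w: mean_rate(space, scn.kappa, w, np.maximum(pi, 1e-10)
                              / np.maximum(pi, 1e-10).sum())
                 for w in {scn.omega_bg, 1.0, scn.omega_fg}}
        f_bg = sum(props[c] * rates[pairs[c][0]] for c in range(4))
        f_fg = sum(props[c] * rates[pairs[c][1]] for c in range(4))

    def branch_omegas(is_fg: bool):
        """Per-site (ω, length multiplier) on one branch."""
        if scn.regime == "null":
            return np.full(n, scn.omega_bg), np.ones(n)
        if scn.regime == "branch":
            w = scn.omega_fg if is_fg else scn.omega_bg
            return np.full(n, w), np.ones(n)
        side = 1 if is_fg else 0
        f = f_fg if is_fg else f_bg
        w = np.array([pairs[c][side] for c in site_class])
        return w, np.array([rates[x] / f for x in w])

    # root draw
    states = {idx.root: rng_evo.choice(space.n, size=n, p=pi)}
    events: list = []
    qs: dict[float, np.ndarray] = {}
    eigs: dict[float, tuple] = {}
    # traverse parents before children
    for node in reversed(idx.order):
        if node == idx.root:
            continue
        parent_states = states[idx.parent[node]]
        omegas, mults = branch_omegas(bool(idx.foreground[node]))
        t = idx.length[node]
        child = np.empty(n, dtype=np.int64)
        for w, mult in sorted({(float(a), float(b))
                               for a, b in zip(omegas, mults)}):
            sel = (omegas == w) & (mults == mult)
            if trace:
                if w not in qs:
                    qs[w] = build_rate_matrix(space, scn.kappa, w, pi)
                child[sel] = _gillespie_branch(parent_states[sel], qs[w],
                                               t * mult, rng_evo, events, node)
            else:
                if w not in eigs:
                    eigs[w] = rate_matrix_eig(space, scn.kappa, w, pi)
                p = transition_probs(eigs[w], t * mult)
                cum = np.cumsum(p, axis=1)
                child[sel] = _sample_markov(parent_states[sel], cum, rng_evo)
        states[node] = child

    # build sequences for leaves
    taxa = tree.leaf_names
    leaf_states = {}
    for node in range(idx.n_nodes):
        if idx.leaf_row[node] >= 0:
            leaf_states[taxa[idx.leaf_row[node]]] = states[node]
    seqs = {t: [space.codons[s] for s in leaf_states[t]] for t in taxa}

    # masking (per taxon-codon) then gap columns; unmasked residues untouched
    if scn.mask_rate > 0:
        mask = rng_mask.random((len(taxa), n)) < scn.mask_rate
        for r, t in enumerate(taxa):
            for s in np.nonzero(mask[r])[0]:
                seqs[t][s] = "NNN"
    if scn.gap_column_rate > 0:
        gap_cols = np.nonzero(rng_gap.random(n) < scn.gap_column_rate)[0]
        for s in gap_cols:
            t = taxa[rng_gap.integers(len(taxa))]
            seqs[t][s] = "---"

    aln = CodonAlignment(gene_id, tuple(taxa),
                         tuple("".join(seqs[t]) for t in taxa))
    truth = {
        "gene_id": gene_id,
        "regime": scn.regime,
        "kappa": scn.kappa,
        "omega_bg": scn.omega_bg,
        "omega_fg": scn.omega_fg,
        "n_codons": n,
        "seed": scn.seed,
    }
    if site_class is not None:
        truth["site_class"] = site_class
        truth["site_class_props"] = _site_class_omegas(scn)[1]
    if trace:
        truth["events"] = events
        truth["node_states"] = states
        truth["tree_index"] = idx
    return aln, truth


def gene_seed(master_seed: int, gene_id: str) -> int:
    """Deterministic per-gene seed derived from a master seed and gene id."""
    import zlib

    return (int(master_seed) * 1_000_003 + zlib.crc32(gene_id.encode())) % (2**31 - 1)


def simulate_gene_set(n_genes: int, mix: dict, scenario: SimulationScenario,
                      seed: int, out_dir: str | os.PathLike | None = None):
    """Simulate a gene set with regimes assigned deterministically by proportion.

    ``mix`` maps regime name → proportion (summing to 1). Counts use largest-
    remainder rounding and genes are assigned in blocks in ``mix`` order.
    Returns ``(alignments, truth_df)``; when ``out_dir`` is given, also writes
    one FASTA per gene, the tagged newick, and the truth table as TSV.
    """
    props = {k: float(v) for k, v in mix.items()}
    if abs(sum(props.values()) - 1) > 1e-9:
        raise ValueError("mix proportions must sum to 1")
    for k in props:
        if k not in REGIMES:
            raise ValueError(f"unknown regime {k!r}")
    raw = {k: v * n_genes for k, v in props.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n_genes - sum(counts.values())
    for k in sorted(props, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1

    alignments, rows = [], []
    i = 0
    for regime, count in counts.items():
        for _ in range(count):
            gid = f"g{i:04d}"
            scn = replace(scenario, regime=regime, seed=gene_seed(seed, gid))
            if regime == "null":
                scn = replace(scn, omega_fg=None)
            elif scn.omega_fg is None:
                raise ValueError(f"scenario template needs omega_fg for {regime!r}")
            aln, truth = simulate_gene(scn, gene_id=gid)
            alignments.append(aln)
            rows.append({k: truth[k] for k in
                         ("gene_id", "regime", "kappa", "omega_bg",
                          "omega_fg", "n_codons", "seed")})
            i += 1
    truth_df = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for aln in alignments:
            write_codon_fasta(aln, out / f"{aln.gene_id}.fasta")
        (out / "tree.nwk").write_text(write_newick_labeled(scenario.tree) + "\n")
        truth_df.to_csv(out / "truth.tsv", sep="\t", index=False)
    return alignments, truth_df


def plant_enrichment(n_genes: int, n_terms: int, term_size_range: tuple[int, int],
                     target_genes: list[str], planted_terms: list[str],
                     seed: int, odds_ratio: float = 8.0):
    """Random gene↔term annotation table with planted enriched terms.

    Background terms get uniformly random gene sets with sizes drawn from
    ``term_size_range``. Each planted term keeps the background membership
    odds for non-target genes but multiplies the membership odds of
    ``target_genes`` by ``odds_ratio`` (``inf`` plants the term as exactly
    the target set). Returns ``(pairs_df, truth)`` where ``pairs_df`` has
    columns gene_id/term_id and ``truth`` records the planted design.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    lo, hi = term_size_range
    if not (1 <= lo <= hi <= n_genes):
        raise ValueError("invalid term_size_range")
    rng = np.random.default_rng(seed)
    universe = [f"g{i:04d}" for i in range(n_genes)]
    targets = set(target_genes)
    unknown = targets - set(universe)
    if unknown:
        raise ValueError(f"target genes outside the universe: {sorted(unknown)}")
    term_ids = [f"T{j:03d}" for j in range(n_terms)]
    unknown_terms = set(planted_terms) - set(term_ids)
    if unknown_terms:
        raise ValueError(f"planted terms not generated: {sorted(unknown_terms)}")

    pairs = []
    for term in term_ids:
        size = int(rng.integers(lo, hi + 1))
        if term in planted_terms:
            if np.isinf(odds_ratio):
                members = sorted(targets)
            else:
                q0 = size / n_genes
                odds1 = odds_ratio * q0 / (1 - q0)
                q1 = odds1 / (1 + odds1)
                if q1 >= 1:
                    raise ValueError("odds ratio infeasible for this term size")
                members = [g for g in universe
                           if rng.random() < (q1 if g in targets else q0)]
        else:
            members = list(rng.choice(universe, size=size, replace=False))
        pairs.extend((g, term) for g in members)
    df = pd.DataFrame(pairs, columns=["gene_id", "term_id"])
    truth = {
        "universe": universe,
        "planted_terms": list(planted_terms),
        "target_genes": sorted(targets),
        "odds_ratio": odds_ratio,
    }
    return df, truth
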