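"""Felsenstein pruning over an unrooted tree for codon models.

The engine compresses alignment columns into unique site patterns, roots the
traversal at an arbitrary internal node (the likelihood is invariant to the
choice under reversible models), and computes per-pattern log-likelihoods
with per-node rescaling to avoid underflow on deep trees.

For branch-site mixtures with a single foreground branch the traversal is
rooted at the parent of that branch, so the four site classes share the two
background pruning passes (background ω0 and ω=1) and differ only in the
transition matrix crossed on the foreground branch.
"""

from __future__ import annotations

import warnings

import numpy as np

from .alignment import CodonAlignment
from .codon import (CodonSpace, build_codon_space, mean_rate, rate_matrix_eig,
                    transition_probs)
from .tree import PhyloTree, TreeNode

__all__ = ["encode_patterns", "TreeIndex", "PruningEngine"]

_LOG_ZERO = -1e300


def encode_patterns(aln: CodonAlignment, space: CodonSpace | None = None,
                    taxa_order: list[str] | None = None):
    """Collapse alignment columns to unique codon site patterns.

    Returns ``(patterns, counts)`` where ``patterns`` is an
    ``(n_taxa, n_patterns)`` integer array of codon indices (−1 for any
    unresolved codon: gaps, Ns, or stop codons, the latter with a warning)
    and ``counts`` the column multiplicities.
    """
    space = space or build_codon_space(1)
    taxa = taxa_order or list(aln.taxa)
    rows = [aln.taxon_index(t) for t in taxa]
    n_sites = aln.n_codons
    mat = np.empty((len(taxa), n_sites), dtype=np.int16)
    saw_stop = False
    for out_row, row in enumerate(rows):
        seq = aln.seqs[row]
        for s in range(n_sites):
            codon = seq[3 * s : 3 * s + 3]
            idx = space.index.get(codon)
            if idx is None:
                if space.is_stop(codon):
                    saw_stop = True
                idx = -1
            mat[out_row, s] = idx
    if saw_stop:
        warnings.warn(
            f"stop codon(s) in alignment {aln.gene_id!r} treated as missing data",
            stacklevel=2,
        )
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return patterns, counts.astype(float)


class TreeIndex:
    """Oriented traversal structure over an unrooted tree.

    ``order`` lists node ids children-first; ``parent``, ``length`` and
    ``foreground`` describe the branch above each node (the root has none).
    """

    def __init__(self, tree: PhyloTree, taxa: list[str], root_at_fg_parent: bool = True):
        if tree.n_leaves < 2:
            raise ValueError("likelihood computations need at least 2 leaves")
        tree_leaves = set(tree.leaf_names)
        if set(taxa) != tree_leaves:
            raise ValueError(
                "alignment taxa and tree leaves differ: "
                f"only-in-alignment={sorted(set(taxa) - tree_leaves)}, "
                f"only-in-tree={sorted(tree_leaves - set(taxa))}"
            )
        nodes: list[TreeNode] = tree.preorder()
        ids = {id(n): i for i, n in enumerate(nodes)}
        adj: dict[int, list[tuple[int, float, bool]]] = {i: [] for i in range(len(nodes))}
        for node in nodes:
            for child in node.children:
                a, b = ids[id(node)], ids[id(child)]
                adj[a].append((b, child.length, child.foreground))
                adj[b].append((a, child.length, child.foreground))

        fg_edges = [(ids[id(n)], n.foreground) for n in tree.branches() if n.foreground]
        root = None
        if root_at_fg_parent and len(fg_edges) == 1:
            fg_node = fg_edges[0][0]
            # the parent endpoint of the foreground edge in the stored orientation
            stored_parent = next(
                i for i, n in enumerate(nodes)
                if any(id(c) == id(nodes[fg_node]) for c in n.children)
            )
            root = stored_parent if len(adj[stored_parent]) >= 2 else fg_node
        if root is None:
            root = next(i for i in range(len(nodes)) if len(adj[i]) >= 2)

        n = len(nodes)
        self.n_nodes = n
        self.root = root
        self.parent = np.full(n, -1, dtype=int)
        self.length = np.zeros(n)
        self.foreground = np.zeros(n, dtype=bool)
        bfs = [root]
        seen = {root}
        for node_id in bfs:
            for other, elen, efg in adj[node_id]:
                if other not in seen:
                    seen.add(other)
                    self.parent[other] = node_id
                    self.length[other] = elen
                    self.foreground[other] = efg
                    bfs.append(other)
        if len(bfs) != n:
            raise ValueError("tree is not connected")
        self.order = bfs[::-1]  # children before parents
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if self.parent[i] >= 0:
                self.children[self.parent[i]].append(i)
        taxon_row = {t: r for r, t in enumerate(taxa)}
        self.leaf_row = np.full(n, -1, dtype=int)
        for node in nodes:
            if node.is_leaf:
                self.leaf_row[ids[id(node)]] = taxon_row[node.name]
        self.branch_ids = [i for i in range(n) if i != root]
        fg_children = [i for i in self.branch_ids if self.foreground[i]]
        self.fg_child = fg_children[0] if len(fg_children) == 1 else None


class PruningEngine:
    """Per-gene likelihood evaluator binding one alignment to one tree."""

    def __init__(self, aln: CodonAlignment, tree: PhyloTree,
                 pi: np.ndarray, space: CodonSpace | None = None):
        self.space = space or build_codon_space(1)
        self.index = TreeIndex(tree, list(aln.taxa))
        self.patterns, self.counts = encode_patterns(aln, self.space, list(aln.taxa))
        self.n_sites = int(self.counts.sum())
        self.n_patterns = self.patterns.shape[1]
        self.set_pi(pi)
        self.base_lengths = self.index.length.copy()

    def set_pi(self, pi: np.ndarray) -> None:
        pi = np.asarray(pi, dtype=float)
        if np.any(pi < 1e-10):  # keep in sync with the eigendecomposition floor
            pi = np.maximum(pi, 1e-10)
            pi = pi / pi.sum()
        self.pi = pi

    # -- internals -----------------------------------------------------------

    def _edge_p(self, eig, t: float, cache: dict, key) -> np.ndarray:
        full_key = (key, round(t, 15))
        p = cache.get(full_key)
        if p is None:
            p = transition_probs(eig, t)
            # 62nd column: unit likelihood for unresolved (missing) states
            p = np.hstack([p, np.ones((p.shape[0], 1))])
            cache[full_key] = p
        return p

    def _pass(self, eigs_for_edge, lengths, skip_edge=None):
        """One pruning pass. Returns (partials dict, logscale per pattern,
        root message product excluding ``skip_edge``'s subtree)."""
        idx = self.index
        npat = self.n_patterns
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros(npat)
        for node in idx.order:
            if not idx.children[node]:
                continue
            prod = None
            for child in idx.children[node]:
                if node == idx.root and child == skip_edge:
                    continue
                msg = self._message(child, eigs_for_edge, lengths, partial)
                prod = msg if prod is None else prod * msg
                if child in partial:
                    del partial[child]
            if prod is None:  # root whose only child is skipped (star interior)
                prod = np.ones((self.space.n, npat))
            if node != idx.root or skip_edge is None:
                scale = prod.max(axis=0)
                scale[scale == 0] = 1.0
                prod = prod / scale
                logscale += np.log(scale)
            partial[node] = prod
        return partial, logscale

    def _message(self, child, eigs_for_edge, lengths, partial):
        p = eigs_for_edge(child, lengths[child])
        if self.index.leaf_row[child] >= 0:
            states = self.patterns[self.index.leaf_row[child]]
            return p[:, states]  # missing (-1) selects the unit column
        return p[:, : self.space.n] @ partial[child]

    def _root_lnl(self, partial_root, logscale):
        site = self.pi @ partial_root
        with np.errstate(divide="ignore"):
            log_site = np.log(site)
        log_site[~np.isfinite(log_site)] = _LOG_ZERO
        return log_site + logscale

    # -- public evaluators ---------------------------------------------------

    def lnl_single(self, kappa: float, omega: float, scale: float = 1.0,
                   lengths: np.ndarray | None = None) -> float:
        """One ω on every branch."""
        return self.lnl_branch(kappa, omega, omega, scale, lengths)

    def lnl_branch(self, kappa: float, omega_bg: float, omega_fg: float,
                   scale: float = 1.0, lengths: np.ndarray | None = None) -> float:
        """Branch model: ω_fg on foreground branches, ω_bg elsewhere."""
        lens = (self.base_lengths if lengths is None else lengths) * scale
        cache: dict = {}
        eig_bg = rate_matrix_eig(self.space, kappa, omega_bg, self.pi)
        eig_fg = (eig_bg if omega_fg == omega_bg
                  else rate_matrix_eig(self.space, kappa, omega_fg, self.pi))

        def edge_p(child, t):
            if self.index.foreground[child]:
                return self._edge_p(eig_fg, t, cache, "fg")
            return self._edge_p(eig_bg, t, cache, "bg")

        partial, logscale = self._pass(edge_p, lens)
        log_site = self._root_lnl(partial[self.index.root], logscale)
        return float(self.counts @ log_site)

    def lnl_branch_site(self, kappa: float, p0: float, p1: float,
                        omega0: float, omega2: float, scale: float = 1.0,
                        lengths: np.ndarray | None = None) -> float:
        """Branch-site model A mixture likelihood.

        Site classes (proportion: background ω / foreground ω):
        ``p0: ω0/ω0``, ``p1: 1/1``, ``p2a: ω0/ω2``, ``p2b: 1/ω2`` with
        ``p2a = (1−p0−p1)·p0/(p0+p1)`` and ``p2b = (1−p0−p1)·p1/(p0+p1)``.
        """
        idx = self.index
        if idx.fg_child is None:
            raise ValueError("branch-site model requires exactly one foreground branch")
        lens = (self.base_lengths if lengths is None else lengths) * scale
        if p0 < 0 or p1 < 0 or p0 + p1 > 1 + 1e-12 or p0 + p1 <= 0:
            raise ValueError("invalid site-class proportions")
        rest = max(0.0, 1.0 - p0 - p1)
        p2a = rest * p0 / (p0 + p1)
        p2b = rest * p1 / (p0 + p1)
        weights = np.array([p0, p1, p2a, p2b])

        eig = {
            "w0": rate_matrix_eig(self.space, kappa, omega0, self.pi),
            "w1": rate_matrix_eig(self.space, kappa, 1.0, self.pi),
        }
        eig["w2"] = eig["w1"] if omega2 == 1.0 else rate_matrix_eig(
            self.space, kappa, omega2, self.pi)

        # Site classes share one scale factor per branch (the proportion-
        # weighted mean rate over the classes active on that branch), so a
        # branch length is the class-averaged expected substitutions per
        # codon and high-ω classes genuinely evolve faster. Each (scaled)
        # class generator is Q(ω)/m(ω) from the decomposition, so dividing
        # by the common factor amounts to multiplying branch lengths by
        # m(ω)/f.
        m = {k: mean_rate(self.space, kappa, w, self.pi)
             for k, w in (("w0", omega0), ("w1", 1.0), ("w2", omega2))}
        f_bg = ((weights[0] + weights[2]) * m["w0"]
                + (weights[1] + weights[3]) * m["w1"])
        f_fg = (weights[0] * m["w0"] + weights[1] * m["w1"]
                + (weights[2] + weights[3]) * m["w2"])

        fg = idx.fg_child
        t_fg = lens[fg]
        # One background pass per background ω. Skipping the foreground edge
        # at the root keeps partial[fg] (and its rescaling contributions, which
        # live in the shared logscale) available for per-class reuse.
        bg_state = {}
        for bg_key in ("w0", "w1"):
            cache: dict = {}
            mult = m[bg_key] / f_bg

            def edge_p(child, t, _k=bg_key, _c=cache, _m=mult):
                return self._edge_p(eig[_k], t * _m, _c, _k)

            partial, logscale = self._pass(edge_p, lens, skip_edge=fg)
            bg_state[bg_key] = (partial, logscale, cache)

        classes = [("w0", "w0"), ("w1", "w1"), ("w0", "w2"), ("w1", "w2")]
        log_site_by_class = []
        for (bg_key, fg_key), w in zip(classes, weights):
            if w == 0.0:
                log_site_by_class.append(np.full(self.n_patterns, _LOG_ZERO))
                continue
            partial, logscale, cache = bg_state[bg_key]
            p_fg = self._edge_p(eig[fg_key], t_fg * m[fg_key] / f_fg, cache, fg_key)
            if idx.leaf_row[fg] >= 0:
                states = self.patterns[idx.leaf_row[fg]]
                msg = p_fg[:, states]
            else:
                msg = p_fg[:, : self.space.n] @ partial[fg]
            root_prod = partial[idx.root] * msg
            log_site_by_class.append(self._root_lnl(root_prod, logscale))

        # weighted logsumexp over the four classes
        with np.errstate(divide="ignore"):
            logw = np.where(weights > 0, np.log(np.maximum(weights, 1e-300)),
                            _LOG_ZERO)
        shifted = np.stack(log_site_by_class) + logw[:, None]
        m = shifted.max(axis=0)
        site = m + np.log(np.exp(shifted - m[None, :]).sum(axis=0))
        return float(self.counts @ site)

    def _in_subtree(self, node: int, ancestor: int) -> bool:
        while node >= 0:
            if node == ancestor:
                return True
            node = self.index.parent[node]
        return False
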