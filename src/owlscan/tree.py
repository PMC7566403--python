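"""Unrooted phylogenies with labeled foreground branches.

Trees are stored rooted at an arbitrary internal node purely for traversal;
all likelihood computations are invariant to that choice under reversible
models. Foreground status is a property of a *branch* and is recorded on the
node below the branch. The newick dialect accepts PAML-style ``#<int>`` tags
attached to a leaf or to a closing parenthesis to mark foreground branches,
e.g. ``(((A,B)#1,C),D);`` marks the internal branch above the clade {A,B}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "TreeNode",
    "PhyloTree",
    "NewickError",
    "parse_newick_labeled",
    "write_newick_labeled",
    "owl_species_tree",
    "OWL_TAXA",
    "OUTGROUP_TAXA",
]

DEFAULT_BRANCH_LENGTH = 0.1


class NewickError(ValueError):
    """Malformed newick input."""


@dataclass
class TreeNode:
    name: str = ""
    length: float = DEFAULT_BRANCH_LENGTH  # length of the branch above this node
    foreground: bool = False               # branch above this node is foreground
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """An unrooted tree over named leaves with branch lengths and foreground flags."""

    def __init__(self, root: TreeNode):
        root = _suppress_root_unifurcation(root)
        self.root = root
        names = [n.name for n in self.leaves()]
        if len(set(names)) != len(names):
            raise NewickError("duplicate leaf names")
        if any(not n for n in names):
            raise NewickError("unnamed leaf")
        self.root.foreground = False
        self.root.length = 0.0

    # -- traversal -----------------------------------------------------------

    def preorder(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def postorder(self) -> list[TreeNode]:
        # children precede parents (reverse of preorder), which is all the
        # pruning recursion requires
        return list(reversed(self.preorder()))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def branches(self) -> list[TreeNode]:
        """All branches, identified by the node below each (root excluded)."""
        return [n for n in self.preorder() if n is not self.root]

    @property
    def n_branches(self) -> int:
        return len(self.branches())

    def foreground_branches(self) -> list[TreeNode]:
        return [n for n in self.branches() if n.foreground]

    # -- editing -------------------------------------------------------------

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            return TreeNode(node.name, node.length, node.foreground,
                            [clone(c) for c in node.children])
        return PhyloTree(clone(self.root))

    def with_uniform_lengths(self, length: float) -> "PhyloTree":
        tree = self.copy()
        for node in tree.branches():
            node.length = length
        return tree

    def clear_foreground(self) -> "PhyloTree":
        tree = self.copy()
        for node in tree.branches():
            node.foreground = False
        return tree

    def leaf_set_below(self, node: TreeNode) -> frozenset[str]:
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.name)
            stack.extend(n.children)
        return frozenset(out)

    def set_foreground_clade(self, leaf_names) -> "PhyloTree":
        """Return a copy whose single foreground branch separates ``leaf_names``
        from the remaining taxa (either orientation of the bipartition accepted)."""
        target = frozenset(leaf_names)
        all_leaves = frozenset(self.leaf_names)
        missing = target - all_leaves
        if missing:
            raise ValueError(f"unknown leaves: {sorted(missing)}")
        tree = self.clear_foreground()
        for node in tree.branches():
            below = tree.leaf_set_below(node)
            if below == target or (all_leaves - below) == target:
                node.foreground = True
                return tree
        raise ValueError(
            f"no branch induces the bipartition {sorted(target)} | rest"
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloTree({self.n_leaves} leaves, fg={len(self.foreground_branches())})"


def _suppress_root_unifurcation(root: TreeNode) -> TreeNode:
    """Collapse a degree-2 root (rooted newick) into the unrooted representation:
    the two root-adjacent branches are a single branch of summed length."""
    while len(root.children) == 2:
        u, v = root.children
        if u.is_leaf and v.is_leaf:
            break  # 2-leaf tree: keep a single connecting branch on v
        if u.is_leaf:
            u, v = v, u
        # graft v under u with the merged branch
        v.length = u.length + v.length
        v.foreground = u.foreground or v.foreground
        u.children.append(v)
        u.length = 0.0
        u.foreground = False
        root = u
    return root


# -- newick ------------------------------------------------------------------

def _tokenize(text: str):
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in "(),;:":
            yield c
            i += 1
        else:
            j = i
            while j < n and text[j] not in "(),;:" and not text[j].isspace():
                j += 1
            yield text[i:j]
            i = j


def parse_newick_labeled(text: str,
                         default_length: float = DEFAULT_BRANCH_LENGTH) -> PhyloTree:
    """Parse newick with optional PAML-style ``#<int>`` foreground branch tags.

    Tags may be fused to the label (``A#1``) or stand alone after a token
    (``(A,B)#1``); branch lengths are optional and default to
    ``default_length`` (the input topology is typically used ignoring lengths,
    which are re-estimated during model fitting).
    """
    tokens = list(_tokenize(text))
    if not tokens:
        raise NewickError("empty newick string")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise NewickError("unexpected end of newick string")
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_label(node: TreeNode, allow_name: bool) -> None:
        nonlocal pos
        tok = peek()
        if tok is not None and tok not in "(),;:":
            take()
            name = tok
            if "#" in name:
                name, _, tag = name.partition("#")
                if not tag.isdigit():
                    raise NewickError(f"malformed branch tag in {tok!r}")
                node.foreground = True
            if name:
                if allow_name:
                    node.name = name
                # internal-node labels other than tags are ignored
        if peek() == ":":
            take()
            num = take()
            if num.startswith("#"):
                raise NewickError("branch tag cannot follow ':'")
            try:
                node.length = float(num)
            except ValueError:
                raise NewickError(f"bad branch length {num!r}") from None
        # tolerate a trailing standalone tag after the length
        tok = peek()
        if tok is not None and tok.startswith("#") and tok[1:].isdigit():
            take()
            node.foreground = True

    def parse_clade() -> TreeNode:
        node = TreeNode(length=default_length)
        if peek() == "(":
            take()
            while True:
                node.children.append(parse_clade())
                tok = take()
                if tok == ")":
                    break
                if tok != ",":
                    raise NewickError(f"expected ',' or ')', got {tok!r}")
            parse_label(node, allow_name=False)
        else:
            parse_label(node, allow_name=True)
            if not node.name:
                raise NewickError("expected a leaf name")
        return node

    root = parse_clade()
    if peek() == ";":
        take()
    if peek() is not None:
        raise NewickError(f"trailing content after tree: {peek()!r}")
    if root.is_leaf:
        raise NewickError("newick describes a single leaf, not a tree")
    root.length = 0.0
    return PhyloTree(root)


def write_newick_labeled(tree: PhyloTree, lengths: bool = True) -> str:
    """Serialize a tree in the same tagged-newick dialect (inverse of the parser)."""

    def fmt(node: TreeNode, is_root: bool) -> str:
        if node.is_leaf:
            s = node.name
        else:
            s = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
        if not is_root:
            if node.foreground:
                s += "#1"
            if lengths:
                s += f":{node.length:g}"
        return s

    return fmt(tree.root, True) + ";"


# -- the default 20-taxon study tree ----------------------------------------

#: The eleven owl (Strigiformes) taxa of the default study tree.
OWL_TAXA = (
    "Tyto_alba",
    "Strix_occidentalis", "Strix_uralensis", "Strix_nebulosa",
    "Bubo_bubo", "Bubo_scandiacus",
    "Athene_cunicularia", "Athene_noctua", "Surnia_ulula",
    "Asio_otus", "Asio_flammeus",
)

#: The nine diurnal outgroup taxa (Coraciimorphae, Accipitriformes,
#: Falconiformes, Passeriformes, Galliformes).
OUTGROUP_TAXA = (
    "Apaloderma_vittatum", "Leptosomus_discolor", "Colius_striatus",
    "Picoides_pubescens", "Cathartes_aura", "Haliaeetus_leucocephalus",
    "Falco_peregrinus", "Taeniopygia_guttata", "Gallus_gallus",
)

# Unrooted 20-taxon species topology around the owl radiation: barn owl
# (Tytonidae) sister to the Strigidae, Coraciimorphae as owl sister group,
# diurnal raptors, falcon+passerine, and chicken. The branch subtending the
# owl ancestor carries the foreground tag.
_OWLS_CLADE = (
    "(Tyto_alba,"
    "(((Bubo_bubo,Bubo_scandiacus),"
    "(Strix_occidentalis,(Strix_uralensis,Strix_nebulosa))),"
    "(((Athene_cunicularia,Athene_noctua),Surnia_ulula),"
    "(Asio_otus,Asio_flammeus))))"
)

_OWL_TREE_NEWICK = (
    "(Gallus_gallus,"
    "(Falco_peregrinus,Taeniopygia_guttata),"
    "((Cathartes_aura,Haliaeetus_leucocephalus),"
    "((Colius_striatus,(Leptosomus_discolor,"
    "(Apaloderma_vittatum,Picoides_pubescens))),"
    + _OWLS_CLADE + "#1)));"
)


def owl_species_tree(branch_length: float = DEFAULT_BRANCH_LENGTH) -> PhyloTree:
    """The default 20-taxon owl/outgroup species tree.

    Eleven owls and nine diurnal outgroups; the single foreground branch is
    the stem of the owl clade (the owl ancestor). All branch lengths are set
    to ``branch_length`` since the topology is used ignoring lengths.
    """
    return parse_newick_labeled(_OWL_TREE_NEWICK, default_length=branch_length)
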