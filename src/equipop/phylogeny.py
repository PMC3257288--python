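"""Parsimony analysis of genotype-coded SNP characters.

Genotypes are coded as unordered characters (AA=0, AB=1, BB=2, missing
treated as full ambiguity) and scored with the two-pass Fitch algorithm;
an ordered (Wagner) option scores |i-j| steps between states via
Sankoff dynamic programming.  Tree search is multi-start hill-climbing:
random-addition starting trees improved first by subtree
pruning-regrafting (SPR) and then by tree bisection-reconnection (TBR)
until no rearrangement improves the score.  This replaces the
"new technology" machinery of dedicated parsimony programs (sectorial
searches, tree fusing, tree drifting); at desk scale the hill-climber is
verified against exhaustive enumeration instead.

Bootstrap support resamples characters with replacement, re-runs a
reduced search per pseudoreplicate, and reports for each bipartition of
the reference tree the percentage of replicate best trees containing it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .panel import MISSING, GenotypePanel

__all__ = [
    "CharacterMatrix",
    "Tree",
    "encode_snp_characters",
    "fitch_score",
    "parsimony_search",
    "bootstrap_support",
    "all_unrooted_topologies",
    "strict_consensus_bipartitions",
]


@dataclass
class CharacterMatrix:
    """Taxa x characters matrix over states {0, 1, 2}, -1 missing."""

    taxa: list[str]
    states: np.ndarray  # int8 (n_taxa, n_chars)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape[0] != len(self.taxa):
            raise ValueError("row count does not match taxa")
        bad = ~np.isin(self.states, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError(f"invalid character states: {np.unique(self.states[bad])}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return self.states.shape[1]

    def informative_mask(self) -> np.ndarray:
        """Characters with at least two observed states (parsimony can
        only be influenced by these; others are flagged, not removed)."""
        out = np.zeros(self.n_chars, dtype=bool)
        for j in range(self.n_chars):
            col = self.states[:, j]
            out[j] = len(set(col[col != MISSING].tolist())) >= 2
        return out


def encode_snp_characters(
    panel: GenotypePanel, min_call_rate: float = 0.9, min_maf: float = 0.05
) -> CharacterMatrix:
    """Dosage-code autosomal SNPs passing call-rate and MAF thresholds.

    Keeps loci with call rate >= ``min_call_rate`` and MAF >=
    ``min_maf`` (panel-wide); missing calls are preserved as missing
    states.  Raises if nothing survives.
    """
    auto = panel.autosomal_mask()
    called = panel.calls != MISSING
    rate = called.mean(axis=0)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, np.where(called, panel.calls, 0).sum(axis=0) / (2.0 * n_called), 0.0)
    maf = np.minimum(p, 1 - p)
    keep = auto & (rate >= min_call_rate) & (maf >= min_maf)
    if not keep.any():
        raise ValueError("no loci survive the character-coding filters")
    return CharacterMatrix(taxa=panel.sample_ids, states=panel.calls[:, keep])


# ---------------------------------------------------------------------------
# unrooted binary trees
# ---------------------------------------------------------------------------


@dataclass
class Tree:
    """Unrooted binary tree: leaves 0..n-1, internal nodes of degree 3."""

    n_taxa: int
    adj: dict[int, set[int]] = field(default_factory=dict)
    _next_id: int = 0

    @classmethod
    def star3(cls, a: int, b: int, c: int, n_taxa: int) -> "Tree":
        t = cls(n_taxa=n_taxa, _next_id=n_taxa)
        hub = t._fresh()
        t.adj = {a: {hub}, b: {hub}, c: {hub}, hub: {a, b, c}}
        return t

    def _fresh(self) -> int:
        self._next_id = max(self._next_id, self.n_taxa)
        nid = self._next_id
        self._next_id += 1
        return nid

    def copy(self) -> "Tree":
        t = Tree(n_taxa=self.n_taxa, _next_id=self._next_id)
        t.adj = {k: set(v) for k, v in self.adj.items()}
        return t

    def edges(self) -> list[tuple[int, int]]:
        out = []
        for u, nbrs in self.adj.items():
            for v in nbrs:
                if u < v:
                    out.append((u, v))
        return out

    def leaves(self) -> list[int]:
        return [u for u in self.adj if u < self.n_taxa]

    def add_leaf_on_edge(self, leaf: int, u: int, v: int) -> None:
        """Attach ``leaf`` in the middle of edge (u, v)."""
        mid = self._fresh()
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        self.adj[u].add(mid)
        self.adj[v].add(mid)
        self.adj[mid] = {u, v, leaf}
        self.adj[leaf] = {mid}

    def _component(self, start: int, blocked: int) -> set[int]:
        """Nodes reachable from ``start`` without crossing ``blocked``."""
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for w in self.adj[u]:
                if w != blocked and w not in seen:
                    seen.add(w)
                    stack.append(w)
        return seen

    def bipartitions(self) -> set[frozenset[int]]:
        """Non-trivial splits, each as the taxon set not containing taxon 0."""
        out = set()
        for u, v in self.edges():
            side = {x for x in self._component(v, u) if x < self.n_taxa}
            if 0 in side:
                side = set(range(self.n_taxa)) - side
            if 2 <= len(side) <= self.n_taxa - 2:
                out.add(frozenset(side))
        return out

    # -- newick ----------------------------------------------------------
    def newick(
        self,
        taxa: list[str],
        outgroup: int | None = None,
        support: dict[frozenset[int], float] | None = None,
    ) -> str:
        """Newick string, rooted at ``outgroup`` (leaf index) when given,
        otherwise at leaf 0.  Branch supports, when supplied as a
        bipartition -> percentage map, become internal-node labels."""
        root_leaf = outgroup if outgroup is not None else 0
        anchor = next(iter(self.adj[root_leaf]))
        all_taxa = frozenset(range(self.n_taxa))

        def label_for(node: int, parent: int) -> str:
            if support is None:
                return ""
            side = frozenset(x for x in self._component(node, parent) if x < self.n_taxa)
            key = side if 0 not in side else all_taxa - side
            val = support.get(key)
            return "" if val is None else f"{val:.0f}"

        def rec(node: int, parent: int) -> str:
            if node < self.n_taxa:
                return taxa[node].replace(" ", "_")
            kids = [w for w in self.adj[node] if w != parent]
            inner = ",".join(rec(w, node) for w in sorted(kids, key=lambda w: min(
                x for x in self._component(w, node) if x < self.n_taxa)))
            return f"({inner}){label_for(node, parent)}"

        return f"({taxa[root_leaf].replace(' ', '_')},{rec(anchor, root_leaf)});"


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

_STATE_MASK = np.array([0b001, 0b010, 0b100], dtype=np.uint8)


def _postorder(tree: Tree, root_leaf: int = 0) -> list[tuple[int, int]]:
    """(node, parent) pairs in postorder, rooted at ``root_leaf``."""
    order: list[tuple[int, int]] = []
    stack = [(root_leaf, -1)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for w in tree.adj[node]:
            if w != parent:
                stack.append((w, node))
    order.reverse()
    return order


def fitch_score(tree: Tree, matrix: CharacterMatrix, ordered: bool = False) -> int:
    """Parsimony length of ``tree`` on ``matrix``.

    Unordered (Fitch) by default; ``ordered=True`` scores linear
    (Wagner) step costs |i-j| via Sankoff dynamic programming.  Missing
    states are fully ambiguous and never add cost.
    """
    if set(tree.leaves()) != set(range(matrix.n_taxa)):
        raise ValueError("tree leaf set does not match character matrix taxa")
    return _score_any(tree, matrix, ordered)


def _score_any(tree: Tree, matrix: CharacterMatrix, ordered: bool = False) -> int:
    """Score a tree whose leaves may be any subset of the matrix taxa."""
    root = min(tree.leaves())
    order = _postorder(tree, root_leaf=root)
    if ordered:
        return _sankoff_score(tree, matrix, order, root)

    masks: dict[int, np.ndarray] = {}
    changes = np.zeros(matrix.n_chars, dtype=np.int64)
    for node, parent in order:
        if node < matrix.n_taxa:
            col = matrix.states[node]
            m = np.where(col == MISSING, np.uint8(0b111), _STATE_MASK[np.clip(col, 0, 2)])
            masks[node] = m.astype(np.uint8)
        else:
            kids = [w for w in tree.adj[node] if w != parent]
            m = masks[kids[0]]
            for w in kids[1:]:
                inter = m & masks[w]
                union = m | masks[w]
                hit = inter == 0
                changes += hit
                m = np.where(hit, union, inter)
            masks[node] = m
    # close the root edge (root is a leaf)
    anchor = next(iter(tree.adj[root]))
    inter = masks[root] & masks[anchor]
    changes += inter == 0
    return int(changes.sum())


def _sankoff_score(tree: Tree, matrix: CharacterMatrix, order, root: int) -> int:
    big = np.float64(1e18)
    step = np.abs(np.subtract.outer(np.arange(3), np.arange(3))).astype(np.float64)
    cost: dict[int, np.ndarray] = {}
    for node, parent in order:
        if node < matrix.n_taxa:
            col = matrix.states[node]
            c = np.full((3, matrix.n_chars), big)
            for s in range(3):
                c[s] = np.where((col == s) | (col == MISSING), 0.0, big)
            cost[node] = c
        else:
            kids = [w for w in tree.adj[node] if w != parent]
            c = np.zeros((3, matrix.n_chars))
            for w in kids:
                child = cost[w]  # (3, chars)
                c += (step[:, :, None] + child[None, :, :]).min(axis=1)
            cost[node] = c
    anchor = next(iter(tree.adj[root]))
    total = (step[:, :, None] + cost[anchor][None, :, :]).min(axis=1) + cost[root]
    total = np.where(total > 1e17, np.inf, total)
    return int(total.min(axis=0).sum())


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------


def _random_addition_tree(matrix: CharacterMatrix, rng: np.random.Generator,
                          ordered: bool = False) -> Tree:
    """Greedy stepwise addition in random taxon order."""
    n = matrix.n_taxa
    taxa_order = rng.permutation(n)
    t = Tree.star3(int(taxa_order[0]), int(taxa_order[1]), int(taxa_order[2]), n_taxa=n)
    for leaf in taxa_order[3:]:
        best = None
        for u, v in t.edges():
            cand = t.copy()
            cand.add_leaf_on_edge(int(leaf), u, v)
            s = _score_any(cand, matrix, ordered)
            if best is None or s < best[0]:
                best = (s, cand)
        t = best[1]
    return t


def _prune_subtree(tree: Tree, u: int, v: int) -> tuple[Tree, Tree, int]:
    """Split ``tree`` on edge (u, v): returns (remainder with degree-2
    node suppressed, pruned subtree rooted at v, attachment node of the
    pruned part)."""
    rem = tree.copy()
    rem.adj[u].discard(v)
    rem.adj[v].discard(u)
    comp_v = rem._component(v, -1)
    sub = Tree(n_taxa=tree.n_taxa, _next_id=tree._next_id)
    sub.adj = {x: set(rem.adj[x]) for x in comp_v}
    for x in comp_v:
        del rem.adj[x]
    # suppress u if now degree 2
    if len(rem.adj.get(u, ())) == 2:
        a, b = rem.adj[u]
        rem.adj[a].discard(u)
        rem.adj[b].discard(u)
        rem.adj[a].add(b)
        rem.adj[b].add(a)
        del rem.adj[u]
    return rem, sub, v


def _reattach(rem: Tree, sub: Tree, attach: int, edge: tuple[int, int]) -> Tree:
    """Glue ``sub`` (attachment node ``attach``) into ``rem`` on ``edge``.

    A fresh junction subdivides the target edge and links to ``attach``,
    so ``attach`` (a lone leaf or the pruned subtree's degree-2 stub
    node) ends with its proper degree.
    """
    t = rem.copy()
    t._next_id = max(max(t.adj, default=0), max(sub.adj, default=0), t._next_id) + 1
    for x, nbrs in sub.adj.items():
        t.adj[x] = set(nbrs)
    u, v = edge
    mid = t._fresh()
    t.adj[u].discard(v)
    t.adj[v].discard(u)
    t.adj[u].add(mid)
    t.adj[v].add(mid)
    t.adj[mid] = {u, v, attach}
    t.adj[attach].add(mid)
    return t


def _subtree_reroots(sub: Tree, attach: int) -> list[tuple[Tree, int]]:
    """All rerootings of a pruned subtree (for TBR): reattachment may use
    any edge of the subtree, realized by moving the attachment point."""
    out = [(sub, attach)]
    nbrs = list(sub.adj[attach])
    if attach >= sub.n_taxa and len(nbrs) == 2:
        # detach the old junction and expose each subtree edge
        core = sub.copy()
        a, b = nbrs
        core.adj[a].discard(attach)
        core.adj[b].discard(attach)
        core.adj[a].add(b)
        core.adj[b].add(a)
        del core.adj[attach]
        for u, v in core.edges():
            re = core.copy()
            mid = re._fresh()
            re.adj[u].discard(v)
            re.adj[v].discard(u)
            re.adj[u].add(mid)
            re.adj[v].add(mid)
            re.adj[mid] = {u, v}
            out.append((re, mid))
    return out


def _rearrangement_neighbors(tree: Tree, tbr: bool):
    """Yield SPR (and, when ``tbr``, TBR) neighbours of ``tree``."""
    for u, v in tree.edges():
        for src, dst in ((u, v), (v, u)):
            rem, sub, attach = _prune_subtree(tree, src, dst)
            if len(rem.adj) < 2:
                continue
            variants = _subtree_reroots(sub, attach) if tbr else [(sub, attach)]
            for sub_v, att_v in variants:
                for edge in rem.edges():
                    yield _reattach(rem, sub_v, att_v, edge)


def _canonical(tree: Tree) -> frozenset[frozenset[int]]:
    return frozenset(tree.bipartitions())


def parsimony_search(
    matrix: CharacterMatrix,
    n_starts: int = 10,
    seed: int = 0,
    ordered: bool = False,
    use_tbr: bool = True,
) -> tuple[int, list[Tree]]:
    """Multi-start SPR(+TBR) hill-climbing parsimony search.

    Each start builds a random-addition tree and applies
    best-improvement SPR passes until stuck, then TBR passes when
    ``use_tbr``.  Returns the best score found and every distinct
    co-optimal topology encountered.
    """
    if matrix.n_taxa < 4:
        raise ValueError("tree search needs at least 4 taxa")
    rng = np.random.default_rng(seed)
    best_score: int | None = None
    best_trees: dict[frozenset, Tree] = {}
    for _ in range(n_starts):
        tree = _random_addition_tree(matrix, rng, ordered)
        score = fitch_score(tree, matrix, ordered)
        for tbr_phase in ([False, True] if use_tbr else [False]):
            improved = True
            while improved:
                improved = False
                for cand in _rearrangement_neighbors(tree, tbr=tbr_phase):
                    s = fitch_score(cand, matrix, ordered)
                    if s < score:
                        tree, score = cand, s
                        improved = True
                        break
        if best_score is None or score < best_score:
            best_score = score
            best_trees = {_canonical(tree): tree}
        elif score == best_score:
            best_trees.setdefault(_canonical(tree), tree)
    return int(best_score), list(best_trees.values())


def all_unrooted_topologies(n_taxa: int):
    """Exhaustively enumerate unrooted binary topologies (oracle use;
    3 taxa -> 1 tree, 6 taxa -> 105)."""
    base = Tree.star3(0, 1, 2, n_taxa=n_taxa)
    trees = [base]
    for leaf in range(3, n_taxa):
        nxt = []
        for t in trees:
            for u, v in t.edges():
                c = t.copy()
                c.add_leaf_on_edge(leaf, u, v)
                nxt.append(c)
        trees = nxt
    return trees


def strict_consensus_bipartitions(trees: list[Tree]) -> set[frozenset[int]]:
    """Bipartitions present in every tree (strict consensus)."""
    if not trees:
        return set()
    out = trees[0].bipartitions()
    for t in trees[1:]:
        out &= t.bipartitions()
    return out


def bootstrap_support(
    matrix: CharacterMatrix,
    replicates: int = 500,
    seed: int = 0,
    reference: Tree | None = None,
    n_starts: int = 2,
    ordered: bool = False,
) -> tuple[Tree, dict[frozenset[int], float]]:
    """Character-resampling bootstrap support for a parsimony tree.

    Resamples columns with replacement ``replicates`` times, runs a
    reduced search (SPR only) per pseudoreplicate, and reports for each
    bipartition of the reference tree the percentage of replicates whose
    best tree contains it.  The reference defaults to a full search on
    the original matrix.
    """
    if replicates < 50:
        raise ValueError("use at least 50 bootstrap pseudoreplicates")
    rng = np.random.default_rng(seed)
    if reference is None:
        _, trees = parsimony_search(matrix, n_starts=max(n_starts, 5), seed=seed, ordered=ordered)
        reference = trees[0]
    ref_bips = reference.bipartitions()
    hits = {b: 0 for b in ref_bips}
    for _ in range(replicates):
        cols = rng.integers(0, matrix.n_chars, size=matrix.n_chars)
        rep = CharacterMatrix(taxa=matrix.taxa, states=matrix.states[:, cols])
        _, trees = parsimony_search(
            rep, n_starts=n_starts, seed=int(rng.integers(0, 2**31 - 1)),
            ordered=ordered, use_tbr=False,
        )
        rep_bips = trees[0].bipartitions()
        for b in ref_bips:
            if b in rep_bips:
                hits[b] += 1
    support = {b: 100.0 * h / replicates for b, h in hits.items()}
    return reference, support
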