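"""Fixed-topology likelihoods, constrained search and the SH topology test.

The likelihood engine is Felsenstein pruning under a reversible model
(GTR for nucleotides, any loaded empirical exchangeability matrix for
proteins) with a +I+G rate mixture: a point mass at rate 0 plus four
equal-weight discrete-gamma categories, jointly normalized to mean rate 1.
Branch lengths are optimized edge-by-edge by Brent iterations on the
exact per-edge likelihood factorization; topology search is either
exhaustive (small trees) or NNI hill-climbing from a neighbor-joining
start. The Shimodaira-Hasegawa test resamples per-site log-likelihoods
(RELL) with mean-centering — the classic unweighted variant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize_scalar

from . import gtr

__all__ = [
    "Alignment",
    "CoreAlignment",
    "LikelihoodModel",
    "TopologyTestResult",
    "Tree",
    "read_fasta_alignment",
    "prune_hotspots",
    "site_loglik",
    "total_loglik",
    "optimize_branch_lengths",
    "is_monophyletic",
    "best_tree_under_constraint",
    "sh_test",
    "rf_distance",
    "neighbor_joining",
    "load_paml_matrix",
]

_NT_CODE = {c: i for i, c in enumerate(gtr.NT_ORDER)}
_AA_CODE = {c: i for i, c in enumerate(gtr.AA_ORDER)}
MISSING = -1


# ---------------------------------------------------------------------------
# alignments

@dataclass
class Alignment:
    """Rectangular alignment: integer state codes, MISSING for gap/N/X."""

    taxa: list
    matrix: np.ndarray  # (n_taxa, n_sites) int8
    alphabet: str = "nt"

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_states(self) -> int:
        return 4 if self.alphabet == "nt" else 20


@dataclass
class CoreAlignment(Alignment):
    excluded_regions: list = field(default_factory=list)  # (name, (start1, end1))


def read_fasta_alignment(source: Union[str, Path], alphabet: str = "nt") -> Alignment:
    """Parse aligned FASTA from a path or raw text."""
    text = source if isinstance(source, str) and source.lstrip().startswith(">") \
        else Path(source).read_text()
    taxa, rows, cur = [], [], []
    for line in text.splitlines():
        if line.startswith(">"):
            if cur:
                rows.append("".join(cur))
                cur = []
            taxa.append(line[1:].split()[0])
        elif line.strip():
            cur.append(line.strip().upper())
    if cur:
        rows.append("".join(cur))
    if not taxa or len(set(len(r) for r in rows)) != 1:
        raise ValueError("alignment empty or not rectangular")
    code = _NT_CODE if alphabet == "nt" else _AA_CODE
    mat = np.full((len(taxa), len(rows[0])), MISSING, dtype=np.int8)
    for i, row in enumerate(rows):
        for j, ch in enumerate(row.replace("U", "T") if alphabet == "nt" else row):
            mat[i, j] = code.get(ch, MISSING)
    return Alignment(taxa=taxa, matrix=mat, alphabet=alphabet)


def prune_hotspots(alignment: Alignment, region_annotations: Iterable[tuple]) -> CoreAlignment:
    """Drop mutational-hotspot columns (1-based inclusive spans).

    Overlapping regions remove each column once; taxon order is preserved
    and every removal is recorded.
    """
    regions = list(region_annotations)
    drop = np.zeros(alignment.n_sites, dtype=bool)
    for name, (s, e) in regions:
        if not (1 <= s <= e <= alignment.n_sites):
            raise ValueError(f"region {name!r} span ({s},{e}) outside alignment")
        drop[s - 1 : e] = True
    return CoreAlignment(
        taxa=list(alignment.taxa),
        matrix=alignment.matrix[:, ~drop].copy(),
        alphabet=alignment.alphabet,
        excluded_regions=regions,
    )


# ---------------------------------------------------------------------------
# models

@dataclass(frozen=True)
class LikelihoodModel:
    """Reversible substitution model with a +I+G rate mixture."""

    exchangeabilities: tuple
    frequencies: tuple
    gamma_shape: float = 1.0
    p_invariant: float = 0.0
    n_categories: int = 4
    alphabet: str = "nt"

    def machinery(self):
        freqs = np.asarray(self.frequencies, dtype=float)
        Q = gtr.rate_matrix(np.asarray(self.exchangeabilities, dtype=float), freqs)
        w, U, Uinv = gtr.spectral(Q, freqs)
        rates, weights = gtr.mixture_rates(self.gamma_shape, self.p_invariant,
                                           self.n_categories)
        return freqs, (w, U, Uinv), rates, weights


def jc_model() -> LikelihoodModel:
    return LikelihoodModel((1.0,) * 6, (0.25,) * 4, gamma_shape=1.0,
                           p_invariant=0.0, n_categories=1)


def load_paml_matrix(path: Union[str, Path]) -> LikelihoodModel:
    """Load a protein exchangeability file: 19 lower-triangle rows of
    whitespace-separated rates followed by a 20-value frequency line."""
    vals = [float(x) for x in Path(path).read_text().split()]
    n_tri = 19 * 20 // 2
    if len(vals) < n_tri + 20:
        raise ValueError("matrix file too short for 20x20 lower triangle + frequencies")
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = vals[k]
            k += 1
    freqs = np.array(vals[k : k + 20])
    freqs = freqs / freqs.sum()
    return LikelihoodModel(tuple(S[np.triu_indices(20, 1)]), tuple(freqs),
                           alphabet="aa")


# ---------------------------------------------------------------------------
# trees

class _Node:
    __slots__ = ("children", "parent", "length", "label")

    def __init__(self, label=None, length=0.0):
        self.children: list[_Node] = []
        self.parent: Optional[_Node] = None
        self.length = length
        self.label = label

    def add(self, child: "_Node"):
        child.parent = self
        self.children.append(child)


class Tree:
    """Rooted view of an unrooted tree (root = a basal multifurcation).

    All likelihood quantities are invariant under the rooting because the
    models are reversible.
    """

    def __init__(self, root: _Node):
        self.root = root

    # -- construction -------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        s = newick.strip().rstrip(";")
        pos = 0

        def parse() -> _Node:
            nonlocal pos
            node = _Node()
            if s[pos] == "(":
                pos += 1
                while True:
                    node.add(parse())
                    if s[pos] == ",":
                        pos += 1
                    else:
                        break
                if s[pos] != ")":
                    raise ValueError(f"bad newick near offset {pos}")
                pos += 1
            # label
            start = pos
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            label = s[start:pos]
            if label and not node.children:
                node.label = label
            elif label and ":" not in label and node.children:
                pass  # internal support label, ignored
            if pos < len(s) and s[pos] == ":":
                pos += 1
                start = pos
                while pos < len(s) and s[pos] not in ",()":
                    pos += 1
                node.length = float(s[start:pos])
            return node

        tree = cls(parse())
        return tree

    def to_newick(self, lengths: bool = True) -> str:
        def fmt(node: _Node) -> str:
            if not node.children:
                base = node.label or ""
            else:
                base = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if lengths and node.parent is not None:
                base += f":{node.length:.10g}"
            return base

        return fmt(self.root) + ";"

    def copy(self) -> "Tree":
        def cp(node: _Node) -> _Node:
            m = _Node(node.label, node.length)
            for c in node.children:
                m.add(cp(c))
            return m

        return Tree(cp(self.root))

    # -- traversal ----------------------------------------------------
    def postorder(self) -> list[_Node]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out[::-1]

    def leaves(self) -> list[_Node]:
        return [n for n in self.postorder() if not n.children]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def edges(self) -> list[_Node]:
        """Every node below the root; each carries the edge to its parent."""
        return [n for n in self.postorder() if n.parent is not None]

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits as frozensets of the smaller-or-canonical side."""
        all_leaves = frozenset(self.leaf_labels())
        splits = set()
        below: dict[_Node, frozenset] = {}
        for n in self.postorder():
            if not n.children:
                below[n] = frozenset([n.label])
            else:
                below[n] = frozenset().union(*(below[c] for c in n.children))
            if n.parent is not None and 1 < len(below[n]) < len(all_leaves) - 1:
                side = below[n]
                other = all_leaves - side
                splits.add(min(side, other, key=lambda x: (len(x), sorted(x))))
        return splits

    def suppress_unifurcations(self):
        def walk(node: _Node):
            for c in list(node.children):
                walk(c)
            if node.parent is not None and len(node.children) == 1:
                child = node.children[0]
                child.length += node.length
                p = node.parent
                p.children[p.children.index(node)] = child
                child.parent = p

        walk(self.root)
        while len(self.root.children) == 1 and self.root.children[0].children:
            new_root = self.root.children[0]
            new_root.parent = None
            self.root = new_root


def is_monophyletic(tree: Union[Tree, str], taxon_set: Iterable[str]) -> bool:
    """True iff some edge bipartition separates *taxon_set* from the rest."""
    if isinstance(tree, str):
        tree = Tree.from_newick(tree)
    want = frozenset(taxon_set)
    all_leaves = frozenset(tree.leaf_labels())
    if not want <= all_leaves:
        raise ValueError("taxon set contains unknown leaves")
    if not 1 < len(want) < len(all_leaves):
        raise ValueError("taxon set must be a proper subset of size > 1")
    canon = min(want, all_leaves - want, key=lambda x: (len(x), sorted(x)))
    return canon in tree.bipartitions()


def rf_distance(tree1: Union[Tree, str], tree2: Union[Tree, str]) -> int:
    """Robinson-Foulds distance: splits present in exactly one tree."""
    if isinstance(tree1, str):
        tree1 = Tree.from_newick(tree1)
    if isinstance(tree2, str):
        tree2 = Tree.from_newick(tree2)
    if set(tree1.leaf_labels()) != set(tree2.leaf_labels()):
        raise ValueError("trees must share a leaf set")
    return len(tree1.bipartitions() ^ tree2.bipartitions())


# ---------------------------------------------------------------------------
# likelihood

def _site_loglik_cats(alignment: Alignment, tree: Tree, freqs, spec, rates, weights):
    """Per-site log-likelihood, mixture over rate categories."""
    w, U, Uinv = spec
    k = len(freqs)
    mat = alignment.matrix
    row = {t: i for i, t in enumerate(alignment.taxa)}
    order = tree.postorder()
    tree_leaves = set(tree.leaf_labels())
    if tree_leaves != set(alignment.taxa):
        missing = sorted(tree_leaves - set(alignment.taxa))
        extra = sorted(set(alignment.taxa) - tree_leaves)
        raise ValueError(f"tree/alignment taxon mismatch: tree-only={missing}, "
                         f"alignment-only={extra}")
    n_sites = alignment.n_sites
    site_mix = np.zeros(n_sites)
    eye = np.eye(k)
    for rate, wt in zip(rates, weights):
        if wt == 0.0:
            continue
        partial: dict[_Node, np.ndarray] = {}
        for n in order:
            if not n.children:
                states = mat[row[n.label]]
                P = eye if n.length * rate == 0 else gtr.transition_matrix(
                    w, U, Uinv, n.length * rate)
                L = np.ones((n_sites, k))
                obs = states >= 0
                L[obs] = P[:, states[obs]].T
                partial[n] = L
            else:
                prod = None
                for c in partial_children(n, partial):
                    prod = c if prod is None else prod * c
                if n.parent is None:
                    partial[n] = prod
                else:
                    P = eye if n.length * rate == 0 else gtr.transition_matrix(
                        w, U, Uinv, n.length * rate)
                    partial[n] = prod @ P.T
            for c in n.children:
                partial.pop(c, None)
        site_mix += wt * (partial[tree.root] @ freqs)
    return np.log(site_mix)


def partial_children(n: _Node, partial: dict):
    for c in n.children:
        yield partial[c]


def site_loglik(alignment: Alignment, tree: Union[Tree, str], model: LikelihoodModel) -> np.ndarray:
    """Per-site log-likelihoods by Felsenstein pruning under the +I+G
    mixture; gaps and ambiguous states contribute flat partials."""
    if isinstance(tree, str):
        tree = Tree.from_newick(tree)
    for n in tree.edges():
        if n.length < 0:
            raise ValueError("negative branch length")
    freqs, spec, rates, weights = model.machinery()
    return _site_loglik_cats(alignment, tree, freqs, spec, rates, weights)


def total_loglik(alignment: Alignment, tree: Union[Tree, str], model: LikelihoodModel) -> float:
    return float(site_loglik(alignment, tree, model).sum())


def _leaf_partials(alignment: Alignment, tree: Tree, k: int):
    row = {t: i for i, t in enumerate(alignment.taxa)}
    n_sites = alignment.n_sites
    out = {}
    for leaf in tree.leaves():
        states = alignment.matrix[row[leaf.label]]
        L = np.ones((n_sites, k))
        obs = states >= 0
        L[obs] = 0.0
        L[obs, states[obs]] = 1.0
        out[leaf] = L
    return out


def optimize_branch_lengths(
    alignment: Alignment,
    tree: Union[Tree, str],
    model: LikelihoodModel,
    max_passes: int = 100,
    rel_tol: float = 1e-6,
    t_max: float = 20.0,
) -> tuple[Tree, float]:
    """Coordinate-wise Brent optimization of every branch length.

    Post-order edge sweeps; per-edge likelihood uses the exact
    factorization L(t) = sum_x A(x) (P(t) d)(x) with A the root-side and
    d the subtree partials, so Brent iterations are cheap. Stops when a
    full pass improves the total log-likelihood by less than *rel_tol*
    in relative terms.
    """
    if isinstance(tree, str):
        tree = Tree.from_newick(tree)
    else:
        tree = tree.copy()
    freqs, spec, rates, weights = model.machinery()
    w, U, Uinv = spec
    k = len(freqs)
    leafP = _leaf_partials(alignment, tree, k)
    n_sites = alignment.n_sites
    eye = np.eye(k)

    def P_of(t: float) -> np.ndarray:
        return eye if t <= 0 else gtr.transition_matrix(w, U, Uinv, t)

    def edge_factors(target: _Node):
        """Per-category (A, d): root-side partial at the parent and subtree
        partial at *target*, with every other edge already folded in."""
        out = []
        for rate in rates:
            down = {}
            for n in tree.postorder():
                if not n.children:
                    down[n] = leafP[n]
                else:
                    prod = None
                    for c in n.children:
                        msg = down[c] @ P_of(c.length * rate).T
                        prod = msg if prod is None else prod * msg
                    down[n] = prod
            A = {tree.root: np.broadcast_to(freqs, (n_sites, k))}
            node = target
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            for p, child in zip(path[::-1], path[-2::-1]):
                # A[p] is a function of the state at p's parent; push it
                # through p's own edge before folding in the siblings
                base = A[p] if p.parent is None else A[p] @ P_of(p.length * rate)
                prod = base.copy()
                for s in p.children:
                    if s is not child:
                        prod *= down[s] @ P_of(s.length * rate).T
                A[child] = prod
            out.append((rate, A[target], down[target]))
        return out

    def edge_ll(factors, t: float) -> float:
        mix = np.zeros(n_sites)
        for (rate, A, d), wt in zip(factors, weights):
            if wt == 0:
                continue
            mix += wt * np.einsum("sk,sk->s", A, d @ P_of(t * rate).T)
        return float(np.log(np.maximum(mix, 1e-300)).sum())

    prev = -np.inf
    ll = prev
    for _ in range(max_passes):
        for n in tree.postorder():
            if n.parent is None:
                continue
            factors = edge_factors(n)
            res = minimize_scalar(lambda t: -edge_ll(factors, t),
                                  bounds=(1e-9, t_max), method="bounded",
                                  options={"xatol": 1e-8})
            if -res.fun > edge_ll(factors, n.length):
                n.length = float(res.x)
            ll = max(-res.fun, edge_ll(factors, n.length))
        if np.isfinite(prev) and abs(ll - prev) <= rel_tol * max(abs(prev), 1.0):
            break
        prev = ll
    return tree, total_loglik(alignment, tree, model)


# ---------------------------------------------------------------------------
# distances / NJ start

def _jc_distance_matrix(alignment: Alignment) -> np.ndarray:
    mat = alignment.matrix
    n = len(alignment.taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = mat[i], mat[j]
            ok = (a >= 0) & (b >= 0)
            if ok.sum() == 0:
                d = 3.0
            else:
                p = (a[ok] != b[ok]).mean()
                p = min(p, 0.74)
                d = -0.75 * np.log(1 - 4.0 * p / 3.0)
            D[i, j] = D[j, i] = d
    return D


def neighbor_joining(names: Sequence[str], D: np.ndarray) -> Tree:
    """Classic NJ; returns an unrooted tree (trifurcating root)."""
    nodes = [_Node(label=nm) for nm in names]
    D = D.astype(float).copy()
    active = list(range(len(names)))
    nxt = {i: nodes[i] for i in active}
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i][j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * D[i][j] - r[i] - r[j]
                if best is None or q < best[0]:
                    best = (q, i, j)
        _q, i, j = best
        vi = 0.5 * D[i][j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = D[i][j] - vi
        parent = _Node()
        ci, cj = nxt[i], nxt[j]
        ci.length = max(vi, 1e-8)
        cj.length = max(vj, 1e-8)
        parent.add(ci)
        parent.add(cj)
        new = i
        for x in active:
            if x not in (i, j):
                D[new][x] = D[x][new] = 0.5 * (D[i][x] + D[j][x] - D[i][j])
        active.remove(j)
        nxt[new] = parent
    root = _Node()
    for x in active:
        child = nxt[x]
        rest = [y for y in active if y != x]
        child.length = max(0.5 * (D[x][rest[0]] + D[x][rest[1]] - D[rest[0]][rest[1]]), 1e-8)
        root.add(child)
    return Tree(root)


# ---------------------------------------------------------------------------
# topology search

def _all_topologies(labels: Sequence[str]):
    """All unrooted binary topologies by stepwise addition (<= 8 leaves)."""
    labels = list(labels)
    if len(labels) > 8:
        raise ValueError("exhaustive search limited to 8 leaves")

    def newicks(sub: list) -> list[str]:
        if len(sub) == 3:
            return [f"({sub[0]}:0.1,{sub[1]}:0.1,{sub[2]}:0.1);"]
        out = []
        head, last = sub[:-1], sub[-1]
        for nk in newicks(head):
            tree = Tree.from_newick(nk)
            for edge_node in tree.edges():
                t2 = tree.copy()
                # find corresponding node by traversal index
                idx = tree.edges().index(edge_node)
                target = t2.edges()[idx]
                p = target.parent
                mid = _Node(length=target.length / 2)
                target.length /= 2
                p.children[p.children.index(target)] = mid
                mid.parent = p
                mid.add(target)
                leaf = _Node(label=last, length=0.1)
                mid.add(leaf)
                out.append(t2.to_newick())
        return out

    return newicks(labels)


def _nni_neighbors(tree: Tree):
    """Yield copies of *tree* one NNI move away (internal edges only)."""
    edges = [n for n in tree.edges() if n.children]
    for idx, node in enumerate(edges):
        if len(node.children) != 2:
            continue
        parent = node.parent
        siblings = [c for c in parent.children if c is not node]
        if not siblings:
            continue
        sib = siblings[0]
        for swap_child in range(2):
            t2 = tree.copy()
            edges2 = [n for n in t2.edges() if n.children]
            node2 = edges2[idx]
            parent2 = node2.parent
            sib2 = [c for c in parent2.children if c is not node2][0]
            child2 = node2.children[swap_child]
            # swap sib2 <-> child2
            parent2.children[parent2.children.index(sib2)] = child2
            node2.children[swap_child] = sib2
            child2.parent, sib2.parent = parent2, node2
            yield t2


def _constrained_start(alignment: Alignment, taxon_set) -> Tree:
    names = alignment.taxa
    D = _jc_distance_matrix(alignment)
    tree = neighbor_joining(names, D)
    if taxon_set is None or is_monophyletic(tree, taxon_set):
        return tree
    idx = {nm: i for i, nm in enumerate(names)}
    inside = sorted(taxon_set)
    outside = sorted(set(names) - set(taxon_set))

    def sub_nj(group: list) -> _Node:
        if len(group) == 1:
            return _Node(label=group[0], length=0.1)
        if len(group) == 2:
            n = _Node(length=0.1)
            n.add(_Node(label=group[0], length=0.1))
            n.add(_Node(label=group[1], length=0.1))
            return n
        sub = neighbor_joining(group, D[np.ix_([idx[g] for g in group],
                                               [idx[g] for g in group])])
        sub.root.length = 0.1
        return sub.root

    # degree-2 root: the root edge is exactly the inside|outside split
    root = _Node()
    root.add(sub_nj(inside))
    root.add(sub_nj(outside))
    return Tree(root)


def best_tree_under_constraint(
    alignment: Alignment,
    model: LikelihoodModel,
    taxon_set: Optional[Iterable[str]] = None,
    search: str = "nni",
    seed: int = 0,
    coarse_passes: int = 3,
) -> tuple[Tree, float]:
    """Maximum-likelihood topology, optionally restricted to trees where
    *taxon_set* is monophyletic.

    ``exhaustive`` scans every unrooted topology (<= 8 leaves);
    ``nni`` hill-climbs from a neighbor-joining start that respects the
    constraint, scoring candidates with a coarse branch-length fit and
    polishing the winner. Deterministic for fixed inputs.
    """
    taxon_set = frozenset(taxon_set) if taxon_set is not None else None
    if taxon_set is not None and not 1 < len(taxon_set) < len(alignment.taxa):
        raise ValueError("constraint must be a proper subset of size > 1")

    if search == "exhaustive":
        best = None
        for nk in _all_topologies(alignment.taxa):
            if taxon_set is not None and not is_monophyletic(nk, taxon_set):
                continue
            t, ll = optimize_branch_lengths(alignment, nk, model)
            if best is None or ll > best[1] + 1e-12:
                best = (t, ll)
        if best is None:
            raise ValueError("no topology satisfies the constraint")
        return best

    if search != "nni":
        raise ValueError(f"unknown search mode {search!r}")

    current = _constrained_start(alignment, taxon_set)
    current, cur_ll = optimize_branch_lengths(alignment, current, model,
                                              max_passes=coarse_passes * 2)
    while True:
        best_move = None
        for cand in _nni_neighbors(current):
            if taxon_set is not None and not is_monophyletic(cand, taxon_set):
                continue
            cand_opt, ll = optimize_branch_lengths(alignment, cand, model,
                                                   max_passes=coarse_passes)
            if ll > cur_ll + 1e-6 and (best_move is None or ll > best_move[1]):
                best_move = (cand_opt, ll)
        if best_move is None:
            break
        current, cur_ll = best_move
    current, cur_ll = optimize_branch_lengths(alignment, current, model)
    return current, cur_ll


# ---------------------------------------------------------------------------
# SH test

@dataclass
class TopologyTestResult:
    log_likelihoods: np.ndarray  # per topology
    deltas: np.ndarray  # max_j L_j - L_k
    p_values: np.ndarray
    n_replicates: int
    seed: int
    constraint_satisfied: Optional[list] = None

    def best_index(self) -> int:
        return int(np.argmax(self.log_likelihoods))


def sh_test(site_logliks: np.ndarray, n_replicates: int = 10000, seed: int = 0) -> TopologyTestResult:
    """Shimodaira-Hasegawa test from a (K topologies x n sites) matrix of
    per-site log-likelihoods, with RELL resampling and mean-centering.

    p_k = fraction of replicates whose centered statistic
    max_j(L~_j) - L~_k reaches the observed delta_k.
    """
    M = np.asarray(site_logliks, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need a (K >= 2) x n_sites matrix")
    K, n = M.shape
    L = M.sum(axis=1)
    delta = L.max() - L
    rng = np.random.default_rng(seed)
    count = np.zeros(K)
    chunk = max(1, min(n_replicates, 2_000_000 // max(n, 1)))
    done = 0
    Ls = np.empty((K, n_replicates))
    while done < n_replicates:
        b = min(chunk, n_replicates - done)
        idx = rng.integers(0, n, size=(b, n))
        for k in range(K):
            Ls[k, done : done + b] = M[k][idx].sum(axis=1)
        done += b
    Lc = Ls - Ls.mean(axis=1, keepdims=True)
    S = Lc.max(axis=0)[np.newaxis, :] - Lc
    p = (S >= delta[:, np.newaxis]).mean(axis=1)
    return TopologyTestResult(
        log_likelihoods=L,
        deltas=delta,
        p_values=p,
        n_replicates=n_replicates,
        seed=seed,
    )
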