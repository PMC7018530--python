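"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration or closed form,
deliberately avoiding the algorithms used by the package (dynamic
programming, Kruskal, pathway permutation averaging, neighbor joining).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

_STOPS = set(standard_dna_table.stop_codons)
_FORWARD = standard_dna_table.forward_table


def brute_force_local_score(a: str, b: str, score_fn, gap_open: int,
                            gap_extend: int) -> float:
    """Optimal local-alignment score by explicit path enumeration.

    Enumerates every alignment (operation string over match/insert/delete)
    of every substring pair and scores it with affine gaps: the first
    residue of a gap run costs ``gap_open``, later residues ``gap_extend``.
    Exponential; only for sequences of length <= ~5.
    """
    best = 0.0

    def extend(i: int, j: int, sub_a: str, sub_b: str, score: float,
               state: str) -> None:
        nonlocal best
        if i == len(sub_a) and j == len(sub_b):
            best = max(best, score)
            return
        if i < len(sub_a) and j < len(sub_b):
            extend(i + 1, j + 1, sub_a, sub_b,
                   score + score_fn(sub_a[i], sub_b[j]), "M")
        if i < len(sub_a):
            cost = gap_extend if state == "D" else gap_open
            extend(i + 1, j, sub_a, sub_b, score + cost, "D")
        if j < len(sub_b):
            cost = gap_extend if state == "I" else gap_open
            extend(i, j + 1, sub_a, sub_b, score + cost, "I")

    for i1 in range(len(a)):
        for j1 in range(i1 + 1, len(a) + 1):
            for i2 in range(len(b)):
                for j2 in range(i2 + 1, len(b) + 1):
                    extend(0, 0, a[i1:j1], b[i2:j2], 0.0, "start")
    return best


def enumerate_min_spanning_tree_distance(n_nodes: int,
                                         edges: dict[tuple[int, int], float]
                                         ) -> float | None:
    """Minimum total distance over all spanning trees, by enumeration.

    ``edges`` maps node pairs to distances; returns None if the graph is
    not connected.  Only for graphs of <= ~7 nodes.
    """
    pairs = list(edges)
    best = None
    for subset in combinations(pairs, n_nodes - 1):
        parent = list(range(n_nodes))

        def find(x: int) -> int:
            while parent[x] != x:
                x = parent[x]
            return x

        acyclic = True
        for u, v in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                acyclic = False
                break
            parent[ru] = rv
        if not acyclic:
            continue
        if len({find(x) for x in range(n_nodes)}) != 1:
            continue
        total = sum(edges[p] for p in subset)
        if best is None or total < best:
            best = total
    return best


def pathway_counts_recursive(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Nei–Gojobori pathway-averaged counts by depth-first path collection.

    Collects complete minimal pathways recursively (a different traversal
    from the permutation-based implementation), drops pathways whose
    intermediates are stop codons, and averages; if all pathways cross a
    stop, averages over all of them.
    """

    def paths(cur: str, allow_stops: bool) -> list[tuple[int, int]]:
        diffs = [i for i in range(3) if cur[i] != codon_b[i]]
        if not diffs:
            return [(0, 0)]
        out = []
        for i in diffs:
            nxt = cur[:i] + codon_b[i] + cur[i + 1:]
            if nxt in _STOPS and not allow_stops:
                continue
            syn_step = (nxt not in _STOPS and cur not in _STOPS
                        and _FORWARD[cur] == _FORWARD[nxt])
            for s, n in paths(nxt, allow_stops):
                out.append((s + (1 if syn_step else 0),
                            n + (0 if syn_step else 1)))
        return out

    results = paths(codon_a, allow_stops=False)
    if not results:
        results = paths(codon_a, allow_stops=True)
    syn = sum(r[0] for r in results) / len(results)
    nonsyn = sum(r[1] for r in results) / len(results)
    return syn, nonsyn


def random_additive_tree(n_leaves: int, rng: np.random.Generator
                         ) -> tuple[list[str], np.ndarray]:
    """Random binary tree with positive branch lengths -> leaf distance matrix.

    Grown by random leaf attachment; distances are path sums, hence exactly
    additive.  Labels are t0..t{n-1}.
    """
    # adjacency with branch lengths; nodes 0..; leaves tracked separately
    adj: dict[int, list[tuple[int, float]]] = {}

    def link(u: int, v: int, w: float) -> None:
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    next_node = 0

    def new_node() -> int:
        nonlocal next_node
        n = next_node
        next_node += 1
        return n

    leaves = [new_node(), new_node()]
    link(leaves[0], leaves[1], float(rng.uniform(0.1, 1.0)))
    while len(leaves) < n_leaves:
        # split a random existing edge and hang a new leaf off it
        u = int(rng.choice(list(adj)))
        v, w = adj[u][int(rng.integers(len(adj[u])))]
        adj[u] = [(x, d) for x, d in adj[u] if x != v]
        adj[v] = [(x, d) for x, d in adj[v] if x != u]
        mid = new_node()
        cut = float(rng.uniform(0.2, 0.8))
        link(u, mid, w * cut)
        link(mid, v, w * (1 - cut))
        leaf = new_node()
        link(mid, leaf, float(rng.uniform(0.1, 1.0)))
        leaves.append(leaf)

    def dist_from(src: int) -> dict[int, float]:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nxt, w in adj[cur]:
                if nxt not in seen:
                    seen[nxt] = seen[cur] + w
                    stack.append(nxt)
        return seen

    labels = [f"t{i}" for i in range(len(leaves))]
    mat = np.zeros((len(leaves), len(leaves)))
    for i, leaf in enumerate(leaves):
        d = dist_from(leaf)
        for j, other in enumerate(leaves):
            mat[i, j] = d[other]
    np.fill_diagonal(mat, 0.0)
    return labels, mat


def newick_leaf_distances(newick: str) -> dict[frozenset[str], float]:
    """Patristic distances between leaf pairs of a newick tree (via dendropy)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1, t2 in combinations(tree.taxon_namespace, 2):
        out[frozenset((t1.label, t2.label))] = pdm.patristic_distance(t1, t2)
    return out
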