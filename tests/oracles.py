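"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately avoids the code paths under test: cliques come
from exhaustive subset enumeration over bitmasks, contact edges from a plain
double loop over atom pairs, rank-sum p-values from pairwise win counting
over every label assignment, and the clique-class table is a frozen literal.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np

# Frozen class table: (clique size, run-length partition) -> class index.
CLASS_TABLE_LITERAL = {
    (3, (3,)): 1, (3, (2, 1)): 2, (3, (1, 1, 1)): 3,
    (4, (4,)): 4, (4, (3, 1)): 5, (4, (2, 2)): 6, (4, (2, 1, 1)): 7,
    (4, (1, 1, 1, 1)): 8,
    (5, (5,)): 9, (5, (4, 1)): 10, (5, (3, 2)): 11, (5, (3, 1, 1)): 12,
    (5, (2, 2, 1)): 13, (5, (2, 1, 1, 1)): 14, (5, (1, 1, 1, 1, 1)): 15,
    (6, (6,)): 16, (6, (5, 1)): 17, (6, (4, 2)): 18, (6, (4, 1, 1)): 19,
    (6, (3, 3)): 20, (6, (3, 2, 1)): 21, (6, (3, 1, 1, 1)): 22,
    (6, (2, 2, 2)): 23, (6, (2, 2, 1, 1)): 24, (6, (2, 1, 1, 1, 1)): 25,
    (6, (1, 1, 1, 1, 1, 1)): 26,
}


def exhaustive_maximal_cliques(n_nodes: int, edges) -> set[frozenset[int]]:
    """Every maximal clique of size >= 2 by testing all vertex subsets."""
    adj = [0] * n_nodes
    for i, j in edges:
        adj[i] |= 1 << j
        adj[j] |= 1 << i

    def is_clique(mask: int) -> bool:
        m = mask
        while m:
            v = (m & -m).bit_length() - 1
            if (mask & ~(1 << v)) & ~adj[v]:
                return False
            m &= m - 1
        return True

    cliques = [mask for mask in range(1, 1 << n_nodes)
               if bin(mask).count("1") >= 2 and is_clique(mask)]
    maximal = set()
    for mask in cliques:
        grown = False
        for v in range(n_nodes):
            if not (mask >> v) & 1 and is_clique(mask | (1 << v)):
                grown = True
                break
        if not grown:
            maximal.add(frozenset(v for v in range(n_nodes) if (mask >> v) & 1))
    return maximal


def runs_partition(positions) -> tuple[int, ...]:
    """Run-length partition, written independently of the implementation."""
    pos = sorted(positions)
    lengths, current = [], 1
    for a, b in zip(pos, pos[1:]):
        if b == a + 1:
            current += 1
        else:
            lengths.append(current)
            current = 1
    lengths.append(current)
    return tuple(sorted(lengths, reverse=True))


def rcc_counts_by_oracle(n_nodes: int, edges, seq_indices) -> list[int]:
    """26 class counts from the exhaustive clique oracle and frozen table."""
    counts = [0] * 26
    for clique in exhaustive_maximal_cliques(n_nodes, edges):
        k = len(clique)
        if 3 <= k <= 6:
            part = runs_partition(seq_indices[v] for v in clique)
            counts[CLASS_TABLE_LITERAL[(k, part)] - 1] += 1
    return counts


def brute_force_contact_edges(per_residue_coords, cutoff: float) -> set[tuple[int, int]]:
    """Contact edges from a double loop over residue and atom pairs."""
    n = len(per_residue_coords)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            best = np.inf
            for a in per_residue_coords[i]:
                for b in per_residue_coords[j]:
                    best = min(best, float(np.linalg.norm(np.asarray(a) - np.asarray(b))))
            if best <= cutoff:
                edges.add((i, j))
    return edges


def ranksum_p_by_enumeration(x, y) -> float:
    """Two-sided rank-sum p over all label assignments, via win counting.

    The statistic is U = #{(i, j): x_i > y_j} + 0.5 #{ties}, recomputed from
    raw values for every assignment; the two-sided p counts assignments whose
    U deviates from mn/2 at least as much as the observed one.
    """
    pooled = [float(v) for v in list(x) + list(y)]
    n1, n2 = len(x), len(y)

    def u_stat(group1_idx):
        g1 = [pooled[i] for i in group1_idx]
        g2 = [pooled[i] for i in range(n1 + n2) if i not in group1_idx]
        u = 0.0
        for a in g1:
            for b in g2:
                u += 1.0 if a > b else 0.5 if a == b else 0.0
        return u

    mid = n1 * n2 / 2.0
    dev_obs = abs(u_stat(set(range(n1))) - mid)
    hits = sum(
        1 for idx in combinations(range(n1 + n2), n1)
        if abs(u_stat(set(idx)) - mid) >= dev_obs - 1e-9
    )
    return hits / comb(n1 + n2, n1)
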