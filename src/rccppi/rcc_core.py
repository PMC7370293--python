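"""Residue cluster classes (RCC).

An RCC vector summarises a residue contact graph by its maximal cliques of
3-6 residues.  Each clique is classified by the integer partition induced by
maximal runs of consecutive sequence positions among its members: residues
whose sequence indices differ by exactly 1 are "sequence proximal", anything
two or more positions apart is not.  A clique of three residues scattered
along the sequence is class [1,1,1]; three consecutive residues form [3].

There are 3 partitions of 3, 5 of 4, 7 of 5 and 11 of 6, giving the 26
classes RCC1..RCC26.  Class order is canonical: clique sizes ascending, and
within a size the partitions in descending lexicographic order ([k] first,
[1,...,1] last).  Maximal cliques larger than six residues fall outside the
class table and are discarded (a count of discards is available for audit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .contact_graph import ATOM_MODES, CUTOFF_GRID, ContactGraph, build_contact_graph
from .structure_io import ProteinStructure

logger = logging.getLogger(__name__)

#: Number of residue cluster classes.
N_CLASSES = 26

#: Clique sizes that contribute to the RCC vector.
COUNTED_SIZES = (3, 4, 5, 6)


def _partitions_desc(k: int) -> list[tuple[int, ...]]:
    """All partitions of k as non-increasing tuples, descending lexicographic."""

    def gen(remaining: int, cap: int) -> list[tuple[int, ...]]:
        if remaining == 0:
            return [()]
        out = []
        for first in range(min(cap, remaining), 0, -1):
            out.extend((first, *rest) for rest in gen(remaining - first, first))
        return out

    return gen(k, k)


def _build_class_table() -> dict[tuple[int, tuple[int, ...]], int]:
    table: dict[tuple[int, tuple[int, ...]], int] = {}
    idx = 1
    for k in COUNTED_SIZES:
        for part in _partitions_desc(k):
            table[(k, part)] = idx
            idx += 1
    assert idx - 1 == N_CLASSES
    return table


#: (clique size, partition) -> class index 1..26.
PARTITION_CLASS_TABLE: dict[tuple[int, tuple[int, ...]], int] = _build_class_table()


@dataclass(frozen=True)
class Clique:
    """A maximal clique with the sequence positions of its members."""

    members: tuple[int, ...]
    seq_positions: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class RCCVector:
    """26 non-negative clique-class counts plus provenance."""

    counts: tuple[int, ...]
    cutoff: float | str = "external"
    atom_mode: str = "external"
    structure_id: str = ""

    def __post_init__(self) -> None:
        if len(self.counts) != N_CLASSES:
            raise ValueError(f"RCC vector must have {N_CLASSES} counts")
        if any(c < 0 for c in self.counts):
            raise ValueError("RCC counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(self.counts, dtype=int)


def enumerate_maximal_cliques(graph: ContactGraph) -> list[Clique]:
    """All maximal cliques of size >= 2, sorted by member tuples.

    Uses Bron-Kerbosch with pivoting (networkx ``find_cliques``).  Isolated
    vertices are maximal singleton cliques but carry no cluster information
    and are dropped.
    """
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_nodes))
    g.add_edges_from(graph.edges)
    cliques = []
    for members in nx.find_cliques(g):
        if len(members) < 2:
            continue
        members = tuple(sorted(members))
        cliques.append(
            Clique(
                members=members,
                seq_positions=tuple(graph.seq_indices[m] for m in members),
            )
        )
    cliques.sort(key=lambda c: c.members)
    return cliques


def sequence_partition(seq_positions) -> tuple[int, ...]:
    """Partition induced by maximal runs of consecutive sequence positions.

    ``{5, 6, 9} -> (2, 1)``; ``{1, 2, 3} -> (3,)``; ``{2, 4, 6} -> (1, 1, 1)``.
    """
    positions = sorted(seq_positions)
    if not positions:
        raise ValueError("seq_positions must be non-empty")
    if len(set(positions)) != len(positions):
        raise ValueError("seq_positions must be distinct")
    runs = [1]
    for prev, cur in zip(positions, positions[1:]):
        if cur - prev == 1:
            runs[-1] += 1
        else:
            runs.append(1)
    return tuple(sorted(runs, reverse=True))


def class_index(k: int, partition) -> int:
    """Map (clique size, partition) to the class index 1..26."""
    if k not in COUNTED_SIZES:
        raise ValueError(f"unsupported clique size: {k}")
    part = tuple(partition)
    if sum(part) != k:
        raise ValueError(f"partition {part} does not sum to clique size {k}")
    if tuple(sorted(part, reverse=True)) != part:
        raise ValueError(f"partition {part} is not non-increasing")
    return PARTITION_CLASS_TABLE[(k, part)]


def compute_rcc(graph: ContactGraph) -> RCCVector:
    """Fold the maximal cliques of a contact graph into the 26 class counts.

    Cliques of fewer than 3 or more than 6 residues contribute nothing.
    """
    counts = [0] * N_CLASSES
    n_oversize = 0
    for clique in enumerate_maximal_cliques(graph):
        k = len(clique)
        if k < 3:
            continue
        if k > 6:
            n_oversize += 1
            continue
        part = sequence_partition(clique.seq_positions)
        counts[class_index(k, part) - 1] += 1
    if n_oversize:
        logger.debug("discarded %d maximal clique(s) larger than 6 residues", n_oversize)
    return RCCVector(
        counts=tuple(counts), cutoff=graph.cutoff, atom_mode=graph.atom_mode
    )


def rcc_from_structure(
    structure: ProteinStructure,
    cutoff: float,
    atom_mode: str = "SC",
    numbering: str = "sequential",
) -> RCCVector:
    """Contact graph followed by clique classification, with provenance."""
    graph = build_contact_graph(structure, cutoff, atom_mode, numbering=numbering)
    rcc = compute_rcc(graph)
    return RCCVector(
        counts=rcc.counts,
        cutoff=float(cutoff),
        atom_mode=atom_mode,
        structure_id=structure.structure_id,
    )


def rcc_grid(
    structure: ProteinStructure,
    cutoffs=CUTOFF_GRID,
    atom_modes=ATOM_MODES,
) -> list[RCCVector]:
    """One RCC vector per (cutoff, atom mode) cell; 12 x 2 = 24 by default."""
    return [
        rcc_from_structure(structure, cutoff, mode)
        for cutoff in cutoffs
        for mode in atom_modes
    ]
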