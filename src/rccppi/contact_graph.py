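"""Residue contact graphs.

A contact graph joins two residues whenever the minimum Euclidean distance
over their selected atom sets is within a cutoff (inclusive).  Sequence
neighbours are eligible contacts like any other pair; their cliques are
absorbed by the sequence-proximity partition classes downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ProteinStructure, StructureError, select_atoms

#: Distance cutoffs scanned for the per-protein representation grid, in Å.
CUTOFF_GRID: tuple[int, ...] = tuple(range(4, 16))

ATOM_MODES: tuple[str, str] = ("SC", "noSC")


@dataclass(frozen=True)
class ContactGraph:
    """Symmetric residue-residue adjacency with per-node sequence indices."""

    n_nodes: int
    seq_indices: tuple[int, ...]
    edges: frozenset[tuple[int, int]]
    cutoff: float | str = "external"
    atom_mode: str = "external"

    def __post_init__(self) -> None:
        if len(self.seq_indices) != self.n_nodes:
            raise ValueError("seq_indices length must equal n_nodes")
        if any(b <= a for a, b in zip(self.seq_indices, self.seq_indices[1:])):
            raise ValueError("seq_indices must be strictly increasing")
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-edges are not allowed")
            if not (0 <= i < j < self.n_nodes):
                raise ValueError(f"edge ({i}, {j}) out of range or unordered")

    def neighbors(self, node: int) -> set[int]:
        out = set()
        for i, j in self.edges:
            if i == node:
                out.add(j)
            elif j == node:
                out.add(i)
        return out

    def adjacency(self) -> np.ndarray:
        mat = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for i, j in self.edges:
            mat[i, j] = mat[j, i] = True
        return mat


def build_contact_graph(
    structure: ProteinStructure,
    cutoff: float,
    atom_mode: str = "SC",
    numbering: str = "sequential",
) -> ContactGraph:
    """Build the residue contact graph of a single chain.

    Edge rule: residues i != j are in contact iff min over atom pairs
    (a in residue i, b in residue j) of ||a - b|| <= cutoff, using the atom
    subsets of ``select_atoms`` for ``atom_mode``.

    ``numbering`` chooses the sequence positions carried by the nodes:
    ``"sequential"`` (1..L after filtering, the default) or ``"author"``
    (numbers as printed in the source file, which must be strictly
    increasing).
    """
    if len(structure) == 0:
        raise StructureError("empty chain")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    per_res = select_atoms(structure, atom_mode)

    coords = np.concatenate(per_res, axis=0)
    owner = np.concatenate(
        [np.full(len(block), idx, dtype=int) for idx, block in enumerate(per_res)]
    )
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=float(cutoff), output_type="ndarray")
    edges: set[tuple[int, int]] = set()
    for a, b in pairs:
        ri, rj = owner[a], owner[b]
        if ri != rj:
            edges.add((min(ri, rj), max(ri, rj)))

    if numbering == "sequential":
        seq = tuple(r.seq_index for r in structure.residues)
    elif numbering == "author":
        seq = tuple(r.author_number for r in structure.residues)
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise StructureError(
                "author numbering is not strictly increasing; use sequential numbering"
            )
    else:
        raise ValueError(f"unknown numbering: {numbering!r}")
    return ContactGraph(
        n_nodes=len(structure),
        seq_indices=seq,
        edges=frozenset(edges),
        cutoff=float(cutoff),
        atom_mode=atom_mode,
    )


def graph_from_adjacency(
    adjacency: np.ndarray, seq_indices: list[int] | tuple[int, ...]
) -> ContactGraph:
    """Wrap a precomputed symmetric boolean adjacency matrix.

    Provenance fields are recorded as ``"external"``.
    """
    adjacency = np.asarray(adjacency, dtype=bool)
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if adjacency.diagonal().any():
        raise ValueError("adjacency diagonal must be zero (no self-contacts)")
    if not np.array_equal(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    n = adjacency.shape[0]
    if len(seq_indices) != n:
        raise ValueError("seq_indices length must match adjacency size")
    ii, jj = np.nonzero(np.triu(adjacency, k=1))
    edges = frozenset((int(i), int(j)) for i, j in zip(ii, jj))
    return ContactGraph(n_nodes=n, seq_indices=tuple(int(s) for s in seq_indices), edges=edges)
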