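"""Desk-scale synthetic inputs: pseudo-polypeptide chains, random contact
graphs, and labelled PPI count datasets.

The chain generator emits CA-only pseudo-residues with the canonical 3.8 Å
consecutive-CA spacing (random self-avoiding walk, ideal-helix or fully
extended geometry), optionally with one pseudo-sidechain atom per residue.
The PPI simulator draws non-negative integer count vectors per class from
independent Poissons whose means decay with feature index and whose
high-index tail is structurally zero — mimicking the sparse, small-count
statistics of RCC features — with a class-conditional mean shift on a
designated feature block controlling how separable the classes are.

Every generator is a pure function of its spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import networkx as nx
import numpy as np

from .contact_graph import ContactGraph
from .dataset_sampling import PPIDataset
from .ppi_features import NEGATIVE, POSITIVE
from .structure_io import AtomRecord, ProteinStructure, Residue, read_structure

#: Canonical consecutive-CA distance in an all-trans polypeptide, Å.
CA_STEP = 3.8

GEOMETRIES = ("random-walk", "helix", "extended")


@dataclass(frozen=True)
class ChainSpec:
    n_residues: int
    step: float = CA_STEP
    min_separation: float = 3.0  # excluded-volume radius for non-consecutive residues
    seed: int = 0
    geometry: str = "random-walk"
    pseudo_sidechains: bool = False

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.min_separation >= self.step:
            raise ValueError("min_separation must be smaller than step")
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")


@dataclass(frozen=True)
class PPISimSpec:
    n_pos: int = 200
    n_neg: int = 200
    dim: int = 26
    base_rates: tuple[float, ...] | None = None  # default: 6 exp(-i/5)
    shift: float = 4.0  # class-conditional mean displacement on shifted features
    n_shift_features: int = 10
    sparsity: float = 0.15  # fraction of structurally-zero high-index features
    test_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class counts must be >= 1")
        if self.dim not in (26, 52):
            raise ValueError("dim must be 26 or 52")
        if not 0.0 <= self.sparsity <= 1.0:
            raise ValueError("sparsity must lie in [0, 1]")
        if self.base_rates is not None and (
            len(self.base_rates) != self.dim or any(r < 0 for r in self.base_rates)
        ):
            raise ValueError("base_rates must be dim non-negative means")

    def resolved_rates(self) -> np.ndarray:
        if self.base_rates is not None:
            return np.asarray(self.base_rates, dtype=float)
        return 6.0 * np.exp(-np.arange(self.dim) / 5.0)


def _chain_coords(spec: ChainSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    n, step = spec.n_residues, spec.step
    if spec.geometry == "extended":
        return np.column_stack(
            [step * np.arange(n), np.zeros(n), np.zeros(n)]
        )
    if spec.geometry == "helix":
        # ideal alpha-helix CA trace: ~100 deg twist, 1.5 Å rise, radius set
        # so that the consecutive-CA distance equals `step`
        twist = np.deg2rad(100.0)
        rise = 1.5 * step / CA_STEP
        radius = np.sqrt(step**2 - rise**2) / (2 * np.sin(twist / 2))
        t = np.arange(n)
        return np.column_stack(
            [radius * np.cos(twist * t), radius * np.sin(twist * t), rise * t]
        )
    # self-avoiding random walk
    coords = [np.zeros(3)]
    max_retries = 2000
    for _ in range(1, n):
        for attempt in range(max_retries):
            v = rng.normal(size=3)
            v *= step / np.linalg.norm(v)
            cand = coords[-1] + v
            prior = np.array(coords[:-1]) if len(coords) > 1 else None
            if prior is None or np.min(
                np.linalg.norm(prior - cand, axis=1)
            ) >= spec.min_separation:
                coords.append(cand)
                break
        else:
            raise RuntimeError("chain generation failed; relax min_separation")
    return np.array(coords)


def generate_chain(spec: ChainSpec) -> ProteinStructure:
    """A pseudo-polypeptide of CA atoms (optionally with a CB pseudo-sidechain).

    Consecutive residues sit exactly ``spec.step`` apart; non-consecutive
    residues never come closer than ``spec.min_separation``.  Residues are
    alanines so the structure round-trips through standard PDB I/O.
    """
    coords = _chain_coords(spec)
    rng = np.random.default_rng(spec.seed + 1)
    residues = []
    for i, xyz in enumerate(coords, start=1):
        atoms = [AtomRecord(name="CA", element="C", coords=tuple(xyz))]
        if spec.pseudo_sidechains:
            v = rng.normal(size=3)
            v *= 1.5 / np.linalg.norm(v)
            atoms.append(AtomRecord(name="CB", element="C", coords=tuple(xyz + v)))
        residues.append(
            Residue(seq_index=i, author_number=i, res_name="ALA", atoms=tuple(atoms))
        )
    return ProteinStructure(
        structure_id=f"synthetic_{spec.geometry}_{spec.n_residues}_{spec.seed}",
        chain_id="A",
        residues=tuple(residues),
    )


def generate_contact_graph(n: int, edge_prob: float, seed: int = 0) -> ContactGraph:
    """Erdős–Rényi contact graph with sequence indices 1..n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must lie in [0, 1]")
    g = nx.gnp_random_graph(n, edge_prob, seed=seed)
    edges = frozenset((min(u, v), max(u, v)) for u, v in g.edges())
    return ContactGraph(n_nodes=n, seq_indices=tuple(range(1, n + 1)), edges=edges)


def generate_ppi_dataset(spec: PPISimSpec) -> tuple[PPIDataset, PPIDataset]:
    """Labelled Poisson-count PPI instances, split 70/30 train/test.

    Negatives draw feature j from Poisson(rate_j); positives add ``shift``
    to the first ``n_shift_features`` non-sparse rates.  The last
    ceil(sparsity * dim) features are structurally zero in both classes.
    """
    rng = np.random.default_rng(spec.seed)
    rates = spec.resolved_rates()
    n_sparse = int(np.ceil(spec.sparsity * spec.dim))
    live = spec.dim - n_sparse
    pos_rates = rates.copy()
    n_shift = min(spec.n_shift_features, live)
    pos_rates[:n_shift] += spec.shift

    def draw(n: int, lam: np.ndarray, label: str):
        lam = lam.copy()
        if n_sparse:
            lam[live:] = 0.0
        X = rng.poisson(lam, size=(n, spec.dim)).astype(float)
        if n_sparse:
            X[:, live:] = 0.0
        return X, np.full(n, label, dtype=object)

    Xp, yp = draw(spec.n_pos, pos_rates, POSITIVE)
    Xn, yn = draw(spec.n_neg, rates, NEGATIVE)
    X = np.concatenate([Xp, Xn])
    y = np.concatenate([yp, yn])
    order = rng.permutation(len(y))
    X, y = X[order], y[order]
    n_test = int(round(spec.test_fraction * len(y)))
    prov = {"generator": "poisson-ppi", "shift": spec.shift, "seed": spec.seed}
    test = PPIDataset(X[:n_test], y[:n_test], provenance=dict(prov, split="test"))
    train = PPIDataset(X[n_test:], y[n_test:], provenance=dict(prov, split="train"))
    return train, test


def write_fixture_pdb(structure: ProteinStructure, path: str | Path) -> Path:
    """Write a minimal legal PDB file readable by :func:`read_structure`.

    Coordinates survive the round trip to the PDB format's 1e-3 Å precision.
    """
    path = Path(path)
    st = gemmi.Structure()
    st.name = structure.structure_id
    model = gemmi.Model("1")
    chain = gemmi.Chain(structure.chain_id)
    for res in structure.residues:
        gres = gemmi.Residue()
        gres.name = res.res_name
        gres.seqid = gemmi.SeqId(res.author_number, res.insertion_code or " ")
        for atom in res.atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.coords)
            ga.occ = atom.occupancy
            ga.altloc = atom.altloc or "\0"
            gres.add_atom(ga)
        chain.add_residue(gres)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
    return path


def roundtrip_chain(structure: ProteinStructure, path: str | Path) -> ProteinStructure:
    """Write a structure to PDB and read it back (testing convenience)."""
    write_fixture_pdb(structure, path)
    return read_structure(path, chain=structure.chain_id)
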