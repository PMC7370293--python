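"""Read protein structures from PDB files into a per-chain residue model.

One protein here is one chain: each interacting partner in a PPI pair is a
single polypeptide chain whose residues are renumbered sequentially after
filtering.  Only the 20 standard amino acids are kept; hydrogens, waters and
heteroatoms are dropped.  The sidechain/no-sidechain distinction used by the
contact-map step is expressed through :func:`select_atoms`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: PDB backbone atom names (carbonyl O included).
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

#: Three-letter codes of the 20 standard amino acids.
STANDARD_RESIDUES = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)


class StructureError(ValueError):
    """Raised for unreadable, empty or inconsistent structure input."""


@dataclass(frozen=True)
class AtomRecord:
    """A single heavy atom of a residue."""

    name: str
    element: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coords)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(
                f"occupancy {self.occupancy} outside [0, 1] for atom {self.name}"
            )


@dataclass(frozen=True)
class Residue:
    """One amino-acid residue with its surviving heavy atoms.

    ``seq_index`` is the 1-based position along the *filtered* chain;
    ``author_number`` preserves the residue number printed in the source file.
    """

    seq_index: int
    author_number: int
    res_name: str
    atoms: tuple[AtomRecord, ...]
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if self.seq_index < 1:
            raise StructureError("seq_index must be >= 1")
        if not self.atoms:
            raise StructureError(
                f"residue {self.res_name} {self.author_number} has no atoms"
            )
        if not any(a.is_backbone for a in self.atoms):
            raise StructureError(
                f"residue {self.res_name} {self.author_number} has no backbone atom"
            )


@dataclass(frozen=True)
class ProteinStructure:
    """Ordered residues of one chain of one structure."""

    structure_id: str
    chain_id: str
    residues: tuple[Residue, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        expected = list(range(1, len(self.residues) + 1))
        if [r.seq_index for r in self.residues] != expected:
            raise StructureError("residues must be numbered sequentially 1..L")

    def __len__(self) -> int:
        return len(self.residues)


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties prefer altloc 'A', then lexicographic."""

    def key(a: gemmi.Atom):
        alt = a.altloc or ""
        return (-a.occ, 0 if alt in ("", "A") else 1, alt)

    return sorted(atoms, key=key)[0]


def read_structure(
    path: str | Path,
    chain: str | None = None,
    altloc_policy: str = "highest-occupancy",
) -> ProteinStructure:
    """Parse one chain of a PDB (or mmCIF) file.

    Parameters
    ----------
    path
        Structure file.  Only ``ATOM`` records are used; the first model of
        multi-model (NMR) files is taken.
    chain
        Chain identifier.  ``None`` selects the first chain in the file.
    altloc_policy
        ``"highest-occupancy"`` (alias ``"best"``) keeps the conformer with
        the largest occupancy per atom name, or a single letter keeps that
        alternate location (blank altlocs always pass).

    Returns
    -------
    ProteinStructure
        Standard amino acids only, heavy atoms only, residues renumbered
        1..L in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    model = st[0]
    chain_names = [ch.name for ch in model]
    if chain is None:
        if not chain_names:
            raise StructureError(f"no chains in {path}")
        chain = chain_names[0]
    if chain not in chain_names:
        raise StructureError(
            f"chain not found: {chain!r} (file has {', '.join(chain_names) or 'none'})"
        )
    gchain = model[chain]

    residues: list[Residue] = []
    n_dropped_nonstandard = 0
    for gres in gchain:
        if gres.name not in STANDARD_RESIDUES:
            if gres.het_flag != "W" and gres.name != "HOH":
                n_dropped_nonstandard += 1
            continue
        # group heavy atoms by name, resolve altlocs
        by_name: dict[str, list[gemmi.Atom]] = {}
        for atom in gres:
            if atom.element.is_hydrogen:
                continue
            by_name.setdefault(atom.name, []).append(atom)
        atoms: list[AtomRecord] = []
        for name, group in by_name.items():
            if len(group) == 1:
                chosen = group[0]
            elif altloc_policy in ("highest-occupancy", "best"):
                chosen = _pick_altloc(group)
            elif len(altloc_policy) == 1:
                keep = [a for a in group if (a.altloc or "") in ("", altloc_policy)]
                if not keep:
                    continue
                chosen = keep[0]
            else:
                raise ValueError(f"unknown altloc policy: {altloc_policy!r}")
            atoms.append(
                AtomRecord(
                    name=name,
                    element=chosen.element.name,
                    coords=(chosen.pos.x, chosen.pos.y, chosen.pos.z),
                    occupancy=min(max(chosen.occ, 0.0), 1.0),
                    altloc=chosen.altloc or "",
                )
            )
        if not atoms or not any(a.is_backbone for a in atoms):
            continue
        residues.append(
            Residue(
                seq_index=len(residues) + 1,
                author_number=gres.seqid.num,
                insertion_code=gres.seqid.icode.strip(),
                res_name=gres.name,
                atoms=tuple(atoms),
            )
        )
    if n_dropped_nonstandard:
        logger.warning(
            "%s chain %s: dropped %d non-standard residue(s)",
            path.name, chain, n_dropped_nonstandard,
        )
    if not residues:
        raise StructureError(f"empty chain: no standard residues in chain {chain} of {path}")
    return ProteinStructure(
        structure_id=f"{path.stem}_{chain}", chain_id=chain, residues=tuple(residues)
    )


def select_atoms(structure: ProteinStructure, mode: str) -> list[np.ndarray]:
    """Return per-residue coordinate arrays for the contact computation.

    ``mode="SC"`` keeps every heavy atom; ``mode="noSC"`` keeps only the
    backbone atoms N, CA, C, O.  Glycine yields identical sets in both modes.
    """
    if mode not in ("SC", "noSC"):
        raise ValueError(f"atom mode must be 'SC' or 'noSC', got {mode!r}")
    out: list[np.ndarray] = []
    for res in structure.residues:
        if mode == "SC":
            kept = res.atoms
        else:
            kept = tuple(a for a in res.atoms if a.is_backbone)
        if not kept:
            raise StructureError(
                f"atom selection empty for residue {res.res_name} {res.author_number}"
            )
        out.append(np.array([a.coords for a in kept], dtype=float))
    return out
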