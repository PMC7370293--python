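import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from rccppi import ChainSpec, generate_chain
from rccppi.synthetic_data import write_fixture_pdb


def atom_line(serial, name, altloc, resname, chain, resseq, x, y, z,
              occ=1.0, element="C", record="ATOM"):
    return (
        f"{record:<6s}{serial:5d} {name:^4s}{altloc:1s}{resname:<3s} {chain:1s}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture(scope="session")
def fixture_pdb(tmp_path_factory) -> Path:
    """Hand-built PDB: 3 standard residues in chain A with an altloc pair,
    a hydrogen, a gap in author numbering, an MSE residue, a water, and a
    second chain B."""
    lines = []
    # chain A, residue 10: ALA with full backbone + CB in two conformers + H
    backbone = [("N", -1.2), ("CA", 0.0), ("C", 1.2), ("O", 2.0)]
    serial = 1
    for name, dx in backbone:
        lines.append(atom_line(serial, name, " ", "ALA", "A", 10, dx, 0.0, 0.0,
                               element="N" if name == "N" else "O" if name == "O" else "C"))
        serial += 1
    lines.append(atom_line(serial, "CB", "A", "ALA", "A", 10, 0.0, 1.5, 0.0, occ=0.60)); serial += 1
    lines.append(atom_line(serial, "CB", "B", "ALA", "A", 10, 0.0, -1.5, 0.0, occ=0.40)); serial += 1
    lines.append(atom_line(serial, "HA", " ", "ALA", "A", 10, 0.3, 0.3, 0.3, element="H")); serial += 1
    # residue 11: ALA shifted +3.8 in x
    for name, dx in backbone + [("CB", 0.0)]:
        y = 1.5 if name == "CB" else 0.0
        lines.append(atom_line(serial, name, " ", "ALA", "A", 11, dx + 3.8, y, 0.0,
                               element="N" if name == "N" else "O" if name == "O" else "C"))
        serial += 1
    # residue 15 (gap in author numbering): GLY, backbone only
    for name, dx in backbone:
        lines.append(atom_line(serial, name, " ", "GLY", "A", 15, dx + 7.6, 0.0, 0.0,
                               element="N" if name == "N" else "O" if name == "O" else "C"))
        serial += 1
    # MSE (non-standard) residue: should be dropped
    for name, dx in backbone:
        lines.append(atom_line(serial, name, " ", "MSE", "A", 16, dx + 30.0, 0.0, 0.0,
                               record="HETATM",
                               element="N" if name == "N" else "O" if name == "O" else "C"))
        serial += 1
    # water
    lines.append(atom_line(serial, "O", " ", "HOH", "A", 101, 50.0, 50.0, 50.0,
                           record="HETATM", element="O")); serial += 1
    # chain B: two ALA residues
    for resseq, xoff in [(1, 0.0), (2, 3.8)]:
        for name, dx in backbone:
            lines.append(atom_line(serial, name, " ", "ALA", "B", resseq,
                                   dx + xoff, 20.0, 0.0,
                                   element="N" if name == "N" else "O" if name == "O" else "C"))
            serial += 1
    lines.append("END")
    path = tmp_path_factory.mktemp("pdb") / "fixture.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def walk_chain_pdb(tmp_path_factory) -> Path:
    """A 15-residue self-avoiding random walk with pseudo-sidechains."""
    st = generate_chain(ChainSpec(n_residues=15, seed=42, pseudo_sidechains=True))
    path = tmp_path_factory.mktemp("walk") / "walk.pdb"
    write_fixture_pdb(st, path)
    return path
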