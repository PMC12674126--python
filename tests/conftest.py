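"""Shared fixtures: hand-written PDB snippets and synthetic conformers."""

from __future__ import annotations

import numpy as np
import pytest

from actinmetrics import (
    AtomRecord,
    ChainModel,
    ConformerSpec,
    ResidueRecord,
    StructureModel,
    make_conformer,
)


def atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    xyz,
    occ: float = 1.00,
    altloc: str = " ",
    element: str = "C",
    record: str = "ATOM",
) -> str:
    """One fixed-width PDB coordinate record."""
    field = name if len(name) >= 4 else f" {name:<3}"
    x, y, z = xyz
    return (
        f"{record:<6}{serial:>5} {field}{altloc}{resname:>3} {chain}"
        f"{resseq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2}"
    )


@pytest.fixture
def minimal_pdb(tmp_path):
    """Three atoms, one residue, one chain."""
    lines = [
        atom_line(1, "N", "ALA", "A", 1, (0.0, 0.0, 0.0), element="N"),
        atom_line(2, "CA", "ALA", "A", 1, (1.458, 0.0, 0.0)),
        atom_line(3, "C", "ALA", "A", 1, (2.0, 1.4, 0.0)),
        "END",
    ]
    path = tmp_path / "minimal.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    """One CA with altlocs A (occ 0.6) and B (occ 0.4)."""
    lines = [
        atom_line(1, "N", "SER", "A", 5, (0.0, 0.0, 0.0), element="N"),
        atom_line(2, "CA", "SER", "A", 5, (1.0, 0.0, 0.0), occ=0.60, altloc="A"),
        atom_line(3, "CA", "SER", "A", 5, (1.2, 0.3, 0.0), occ=0.40, altloc="B"),
        "END",
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def multimodel_pdb(tmp_path):
    """Five MODEL blocks, one chain, frame-tagged x coordinate."""
    lines = []
    for i in range(5):
        lines.append(f"MODEL     {i + 1:>4}")
        for r in range(3):
            lines.append(
                atom_line(3 * i + r + 1, "CA", "GLY", "g", r + 1, (float(i), float(r), 0.0))
            )
        lines.append("ENDMDL")
    lines.append("END")
    path = tmp_path / "traj.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def two_chain_pdb(tmp_path):
    """Chains A and B plus a HETATM ligand and a water."""
    lines = [
        atom_line(1, "CA", "ALA", "A", 1, (0.0, 0.0, 0.0)),
        atom_line(2, "CA", "ALA", "A", 2, (3.8, 0.0, 0.0)),
        atom_line(3, "CA", "GLY", "B", 1, (0.0, 8.0, 0.0)),
        atom_line(4, "CA", "GLY", "B", 2, (3.8, 8.0, 0.0)),
        atom_line(5, "PB", "ADP", "A", 401, (10.0, 10.0, 0.0), element="P", record="HETATM"),
        atom_line(6, "O", "HOH", "A", 501, (12.0, 12.0, 0.0), element="O", record="HETATM"),
        "END",
    ]
    path = tmp_path / "twochain.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def make_ca_chain(
    numbers, chain_id: str = "A", coords=None, seed: int = 0
) -> ChainModel:
    """A chain of CA-only residues at given (or random) positions."""
    numbers = list(numbers)
    if coords is None:
        rng = np.random.default_rng(seed)
        coords = rng.normal(scale=10.0, size=(len(numbers), 3))
    residues = [
        ResidueRecord(n, "ALA", [AtomRecord("CA", "C", c)])
        for n, c in zip(numbers, coords)
    ]
    return ChainModel(chain_id, residues)


@pytest.fixture
def reference_conformer() -> StructureModel:
    """A twisted (G-like) synthetic conformer, noise-free."""
    return make_conformer(ConformerSpec(phi_target=-23.6, seed=42))


@pytest.fixture
def flattened_conformer() -> StructureModel:
    """A flattened (F-like) synthetic conformer from the same seed."""
    return make_conformer(ConformerSpec(phi_target=-6.2, seed=42))
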