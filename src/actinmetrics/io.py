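"""Reading and writing coordinate files.

PDB (fixed-width v3.3) and mmCIF parsing is delegated to Bio.PDB; this
module converts the parsed entities into the package's
:class:`~actinmetrics.model.StructureModel`. Author residue numbering is
preserved. Hydrogens are dropped at parse time and waters/hetero groups
(ADP, ions, ...) are diverted to ``hetero_records``, because all protein
metrics in this package are defined over non-hydrogen polymer atoms only.

Output is PDB; multi-frame structures become one MODEL block per frame.
Residue numbers above 9999 do not fit the fixed-width format and are
refused rather than silently wrapped.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path

import numpy as np
from Bio.PDB import MMCIFParser, PDBIO, PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder

from .errors import FormatError, ParseError, WriteError
from .model import AtomRecord, ChainModel, ResidueRecord, StructureModel

logger = logging.getLogger(__name__)

_PDB_SUFFIXES = {".pdb", ".ent", ".pdb1"}
_CIF_SUFFIXES = {".cif", ".mmcif"}


def _sniff_format(path: Path) -> str:
    if path.suffix.lower() in _PDB_SUFFIXES:
        return "pdb"
    if path.suffix.lower() in _CIF_SUFFIXES:
        return "mmcif"
    head = path.read_text(errors="replace")[:4096]
    if head.lstrip().startswith("data_") or "_atom_site." in head:
        return "mmcif"
    return "pdb"


def load_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Parse a PDB or mmCIF file into a StructureModel.

    ``format`` is one of ``pdb``, ``mmcif``, ``auto`` (extension, then
    content sniffing). Alternate locations are all retained; use
    :func:`~actinmetrics.model.resolve_altlocs` to collapse them.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    if format == "auto":
        format = _sniff_format(path)
    if format == "pdb":
        parser = PDBParser(QUIET=True, PERMISSIVE=True)
    elif format == "mmcif":
        parser = MMCIFParser(QUIET=True)
    else:
        raise FormatError(f"unknown format {format!r} (expected pdb, mmcif or auto)")
    try:
        bio = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio raises assorted exception types
        raise ParseError(f"cannot parse {path} as {format}: {exc}") from exc
    return _from_biopython(bio, identifier=path.stem)


def _from_biopython(bio, identifier: str) -> StructureModel:
    frames: list[dict[str, ChainModel]] = []
    hetero: list[list[tuple[str, ResidueRecord]]] = []
    n_polymer = n_hetero = n_hydrogen = 0
    for bio_model in bio:
        chains: dict[str, ChainModel] = {}
        frame_het: list[tuple[str, ResidueRecord]] = []
        for bio_chain in bio_model:
            residues: list[ResidueRecord] = []
            for bio_res in bio_chain:
                hetfield, resseq, icode = bio_res.get_id()
                atoms: list[AtomRecord] = []
                for bio_atom in bio_res.get_unpacked_list():
                    element = (bio_atom.element or "").strip() or bio_atom.get_name()[:1]
                    if element.upper() in ("H", "D"):
                        n_hydrogen += 1
                        continue
                    occ = bio_atom.get_occupancy()
                    occ = 1.0 if occ is None else min(max(float(occ), 0.0), 1.0)
                    atoms.append(
                        AtomRecord(
                            atom_name=bio_atom.get_name(),
                            element=element,
                            coords=np.asarray(bio_atom.get_coord(), dtype=float),
                            occupancy=occ,
                            altloc=bio_atom.get_altloc().strip(),
                        )
                    )
                if not atoms:
                    continue
                record = ResidueRecord(
                    author_number=int(resseq),
                    name=bio_res.get_resname().strip(),
                    atoms=atoms,
                    insertion_code=icode.strip(),
                )
                if hetfield.strip():  # 'W' for waters, 'H_XXX' for hetero
                    frame_het.append((bio_chain.id, record))
                    n_hetero += len(atoms)
                else:
                    residues.append(record)
                    n_polymer += len(atoms)
            if residues:
                chains[bio_chain.id] = ChainModel(bio_chain.id, residues)
        frames.append(chains)
        hetero.append(frame_het)
    logger.info(
        "parsed %s: %d frame(s), %d polymer atoms, %d hetero atoms, %d hydrogens dropped",
        identifier, len(frames), n_polymer, n_hetero, n_hydrogen,
    )
    return StructureModel(identifier, frames, hetero)


def _atom_fullname(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return (" " + name).ljust(4)
    return name.ljust(4)


def _to_biopython(structure: StructureModel):
    sb = StructureBuilder()
    sb.init_structure(structure.identifier or "xxxx")
    for mi, frame in enumerate(structure.models):
        sb.init_model(mi, mi)
        for cid in sorted(frame):
            chain = frame[cid]
            if len(cid) != 1:
                raise WriteError(f"chain id {cid!r} does not fit the one-column PDB field")
            sb.init_chain(cid)
            sb.init_seg("    ")
            for res in chain.residues:
                if res.author_number > 9999 or res.author_number < -999:
                    raise WriteError(
                        f"residue number {res.author_number} does not fit fixed-width PDB"
                    )
                sb.init_residue(res.name, " ", res.author_number, res.insertion_code or " ")
                for a in res.atoms:
                    sb.init_atom(
                        a.atom_name,
                        np.asarray(a.coords, dtype=np.float64),
                        0.0,
                        a.occupancy,
                        a.altloc or " ",
                        _atom_fullname(a.atom_name, a.element),
                        element=a.element.upper(),
                    )
        het_frame = (
            structure.hetero_records[mi] if mi < len(structure.hetero_records) else []
        )
        for cid, res in het_frame:
            sb.init_chain(cid)
            sb.init_seg("    ")
            hetfield = "W" if res.name in ("HOH", "WAT") else f"H_{res.name}"
            sb.init_residue(res.name, hetfield, res.author_number, res.insertion_code or " ")
            for a in res.atoms:
                sb.init_atom(
                    a.atom_name,
                    np.asarray(a.coords, dtype=np.float64),
                    0.0,
                    a.occupancy,
                    a.altloc or " ",
                    _atom_fullname(a.atom_name, a.element),
                    element=a.element.upper(),
                )
    return sb.get_structure()


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write the structure as fixed-width PDB (one MODEL block per frame).

    Round-trip guarantee: ``load_structure(write_pdb(s))`` reproduces
    coordinates to 0.001 A, the format's column precision.
    """
    bio = _to_biopython(structure)
    writer = PDBIO()
    writer.set_structure(bio)
    try:
        writer.save(str(path), write_end=True)
    except (OSError, IOError) as exc:
        raise WriteError(f"cannot write {path}: {exc}") from exc


def pdb_string(structure: StructureModel) -> str:
    """Serialize to PDB format in memory (used by tests and the CLI)."""
    bio = _to_biopython(structure)
    writer = PDBIO()
    writer.set_structure(bio)
    buf = _io.StringIO()
    writer.save(buf, write_end=True)
    return buf.getvalue()
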