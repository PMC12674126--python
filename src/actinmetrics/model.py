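"""In-memory coordinate model: chains -> residues -> atoms.

The model addresses residues by *author* numbering (as deposited), because
the canonical actin subdomain ranges (SD1 7-31/74-136/347-364, ...) are
author numbers shared across actin depositions. Hydrogens, waters and
hetero groups (ADP, ATP, Ca, Mg, ...) are kept out of the polymer chains
and excluded from all protein metrics; hetero groups live in
``StructureModel.hetero_records``.

A multi-model file is represented as an ordered list of frames, each a dict
of chains; trajectory analysis iterates frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

from .elements import atomic_mass
from .errors import ChainLookupError, DegenerateGeometryError


@dataclass
class AtomRecord:
    """One atom: PDB-style name, element, coordinates in Angstrom."""

    atom_name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    mass: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.atom_name}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.atom_name}: occupancy {self.occupancy} outside [0,1]")
        if self.mass is None:
            self.mass = atomic_mass(self.element)
        if self.mass <= 0:
            raise ValueError(f"atom {self.atom_name}: non-positive mass")

    def moved(self, coords: np.ndarray) -> "AtomRecord":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class ResidueRecord:
    """One residue, addressed by (author_number, insertion_code)."""

    author_number: int
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def key(self) -> tuple[int, str]:
        return (self.author_number, self.insertion_code)

    def atom(self, atom_name: str, altloc: str | None = None) -> AtomRecord | None:
        """First atom with this name (optionally a specific altloc), or None."""
        for a in self.atoms:
            if a.atom_name == atom_name and (altloc is None or a.altloc == altloc):
                return a
        return None

    def has_altlocs(self) -> bool:
        return any(a.altloc for a in self.atoms)


@dataclass
class ChainModel:
    """An ordered polymer chain."""

    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residues = sorted(self.residues, key=lambda r: r.key)
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError(f"chain {self.chain_id}: duplicate residue keys")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[ResidueRecord]:
        return iter(self.residues)

    def residue(self, author_number: int, insertion_code: str = "") -> ResidueRecord | None:
        for r in self.residues:
            if r.key == (author_number, insertion_code):
                return r
        return None

    def residue_numbers(self) -> set[int]:
        return {r.author_number for r in self.residues}

    def atoms(self) -> Iterator[AtomRecord]:
        for r in self.residues:
            yield from r.atoms

    def coords(self) -> np.ndarray:
        """(N, 3) array over all atoms in residue order."""
        pts = [a.coords for a in self.atoms()]
        if not pts:
            return np.zeros((0, 3))
        return np.vstack(pts)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ChainModel":
        """Copy of the chain with x -> R x + t applied to every atom."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        residues = [
            ResidueRecord(
                r.author_number,
                r.name,
                [a.moved(R @ a.coords + t) for a in r.atoms],
                r.insertion_code,
            )
            for r in self.residues
        ]
        return ChainModel(self.chain_id, residues)


@dataclass
class StructureModel:
    """A structure: one or more frames, each a set of chains.

    ``hetero_records`` holds non-polymer groups (nucleotide, ions, waters)
    per frame as plain ResidueRecords tagged with their chain id; they are
    never included in protein metrics.
    """

    identifier: str
    models: list[dict[str, ChainModel]] = field(default_factory=list)
    hetero_records: list[list[tuple[str, ResidueRecord]]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.models and len(self.models) > 1:
            ids0 = set(self.models[0])
            for i, frame in enumerate(self.models[1:], start=1):
                if set(frame) != ids0:
                    raise ValueError(
                        f"frame {i} chain ids {sorted(frame)} differ from frame 0 {sorted(ids0)}"
                    )
        while len(self.hetero_records) < len(self.models):
            self.hetero_records.append([])

    @property
    def n_frames(self) -> int:
        return len(self.models)

    def chain_ids(self, frame: int = 0) -> list[str]:
        return sorted(self.models[frame])

    def frames(self) -> Iterator[dict[str, ChainModel]]:
        return iter(self.models)


def select_chain(structure: StructureModel, chain_id: str, frame: int = 0) -> ChainModel:
    """Return one polymer chain from one frame; hetero groups are excluded.

    Raises :class:`ChainLookupError` listing the available ids if absent.
    """
    try:
        frame_chains = structure.models[frame]
    except IndexError:
        raise ChainLookupError(
            f"frame {frame} out of range (structure has {structure.n_frames} frames)"
        ) from None
    try:
        return frame_chains[chain_id]
    except KeyError:
        raise ChainLookupError(
            f"chain {chain_id!r} not in frame {frame}; available: {sorted(frame_chains)}"
        ) from None


def resolve_altlocs(chain: ChainModel, policy: str = "highest_occupancy") -> ChainModel:
    """Collapse alternate locations to one atom per atom name.

    ``highest_occupancy`` keeps the highest-occupancy record, ties broken by
    altloc letter order; ``prefer_A`` keeps altloc 'A' (or blank) when
    present, else the alphabetically first.
    """
    if policy not in ("highest_occupancy", "prefer_A"):
        raise ValueError(f"unknown altloc policy {policy!r}")
    residues = []
    for res in chain.residues:
        by_name: dict[str, list[AtomRecord]] = {}
        for a in res.atoms:
            by_name.setdefault(a.atom_name, []).append(a)
        order = {id(a): i for i, a in enumerate(res.atoms)}
        kept = []
        for name, group in by_name.items():
            if len(group) == 1:
                kept.append(group[0])
            elif policy == "highest_occupancy":
                kept.append(min(group, key=lambda a: (-a.occupancy, a.altloc)))
            else:
                kept.append(min(group, key=lambda a: a.altloc))
        kept.sort(key=lambda a: order[id(a)])
        residues.append(ResidueRecord(res.author_number, res.name, kept, res.insertion_code))
    return ChainModel(chain.chain_id, residues)


def chain_center(chain: ChainModel) -> np.ndarray:
    """Mass-weighted center of a whole chain (convenience)."""
    from .geometry import center_of_mass

    return center_of_mass(list(chain.atoms()))


def single_chain_structure(chain: ChainModel, identifier: str = "synthetic") -> StructureModel:
    return StructureModel(identifier, [{chain.chain_id: chain}])


def gather_atoms(chain: ChainModel, residue_numbers: Iterable[int]) -> list[AtomRecord]:
    """All atoms of the chain whose residues fall in the given numbers."""
    wanted = set(residue_numbers)
    out: list[AtomRecord] = []
    for res in chain.residues:
        if res.author_number in wanted:
            out.extend(res.atoms)
    return out


def require_atom(chain: ChainModel, resnum: int, atom_name: str, what: str = "") -> AtomRecord:
    """Fetch a named atom or raise a gate-metric error naming it."""
    from .errors import GateMetricError

    res = chain.residue(resnum)
    atom = res.atom(atom_name) if res is not None else None
    if atom is None:
        label = f" ({what})" if what else ""
        raise GateMetricError(
            f"chain {chain.chain_id}: missing atom {atom_name} in residue {resnum}{label}"
        )
    return atom
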