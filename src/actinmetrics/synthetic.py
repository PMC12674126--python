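"""Synthetic actin-like fixtures with controlled conformational parameters.

Nothing here is a physical model of actin. The generator produces
pseudo-atom clusters that (i) carry real author residue numbers inside the
canonical subdomain ranges, so the same partitioning/lookup code paths run
on synthetic and deposited structures, and (ii) realize exactly
controllable observables:

* a conformer whose subdomain-center flattening dihedral equals
  ``phi_target`` exactly before noise,
* Tyr143/Gly168/Tyr169 gate atoms at an exactly prescribed gate distance,
* a twist series interpolating the dihedral by rotating the SD1+SD2 block
  about the SD1-SD3 center-of-mass hinge (the torsion axis, so the
  measured dihedral moves by exactly the applied angle even under noise),
* two-state (iid or Markov) gate trajectories at a prescribed open
  probability, with the true state sequence retained for testing,
* trimers assembled from rigid copies of a subunit.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .conformer import DEFAULT_SCHEME, SubdomainScheme, assign_subdomains, flattening_dihedral
from .errors import SpecError
from .geometry import center_of_mass, torsion
from .model import AtomRecord, ChainModel, ResidueRecord, StructureModel

# inter-center geometry, Angstrom / degrees; loosely actin-sized
_D_SD1_SD3 = 24.0     # hinge length
_R_SD2 = 13.0         # SD1 -> SD2 center distance
_R_SD4 = 13.0         # SD3 -> SD4 center distance
_POLAR = np.radians(105.0)  # off-axis angle of SD2/SD4 from the hinge

# side-chain / carbonyl atoms expected by the contact metrics, placed next
# to the residue's CA: (residue, name, element, local offset)
_SPECIAL_ATOMS = {
    113: ("N", "N", np.array([0.8, 0.5, 0.3])),     # Lys113 main-chain N
    168: ("O", "O", np.array([-0.6, 0.9, 0.2])),    # Gly168 carbonyl O
    195: ("O", "O", np.array([0.4, -0.8, 0.6])),    # Glu195 carbonyl O
}

_RESNAMES = {113: "LYS", 143: "TYR", 168: "GLY", 169: "TYR", 195: "GLU", 244: "ASP"}


@dataclass(frozen=True)
class ConformerSpec:
    """Recipe for one synthetic conformer."""

    phi_target: float = -15.0
    subdomain_atom_counts: dict[str, int] | None = None
    noise_sigma: float = 0.0
    seed: int = 0
    gate_distance: float = 3.5      # Tyr143 OH - Gly168 O, Angstrom
    ca_distance: float = 11.2       # Tyr143 CA - Tyr169 CA, Angstrom
    cluster_spread: float = 3.0     # sd of atom offsets around each center
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if not np.isfinite(self.phi_target) or abs(self.phi_target) > 180.0:
            raise SpecError(f"phi_target {self.phi_target} outside [-180, 180]")
        if self.noise_sigma < 0:
            raise SpecError("noise_sigma must be >= 0")
        if self.gate_distance <= 0 or self.ca_distance <= 0:
            raise SpecError("gate distances must be positive")
        if self.subdomain_atom_counts is not None:
            for sd, n in self.subdomain_atom_counts.items():
                if n < 1:
                    raise SpecError(f"{sd}: atom count must be >= 1")


def _wrap(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


def _center_sites(phi_target: float) -> dict[str, np.ndarray]:
    """Four center sites whose SD2-SD1-SD3-SD4 torsion is exactly phi."""
    q2 = np.zeros(3)                      # SD1
    q3 = np.array([0.0, 0.0, _D_SD1_SD3])  # SD3
    q1 = q2 + _R_SD2 * np.array([np.sin(_POLAR), 0.0, -np.cos(_POLAR)])  # SD2
    for sign in (1.0, -1.0):
        az = np.radians(sign * phi_target)
        q4 = q3 + _R_SD4 * np.array(
            [np.sin(_POLAR) * np.cos(az), np.sin(_POLAR) * np.sin(az), np.cos(_POLAR)]
        )
        if abs(_wrap(torsion(q1, q2, q3, q4) - phi_target)) < 1e-9:
            return {"SD1": q2, "SD2": q1, "SD3": q3, "SD4": q4}
    raise SpecError(f"cannot realize torsion {phi_target}")  # pragma: no cover


def _build_sd_residues(
    sd: str,
    center: np.ndarray,
    scheme: SubdomainScheme,
    n_atoms: int | None,
    rng: np.random.Generator,
    spread: float,
) -> list[ResidueRecord]:
    # residues the contact/gate metrics rely on come first, so they exist
    # even for small per-subdomain atom counts
    priority = {113, 168, 169, 195, 244}
    numbers = sorted(scheme.residues(sd), key=lambda n: (n not in priority, n))
    n_priority = sum(1 for n in numbers if n in priority)
    if n_atoms is None:
        n_atoms = len(numbers)
    n_atoms = max(n_atoms, n_priority)
    # round-robin: every residue gets a CA first, then extra carbons
    extra_names = ["CB", "CG", "CD", "CE", "CZ"]
    assignments: list[tuple[int, str, str]] = []
    k = 0
    while len(assignments) < n_atoms:
        resnum = numbers[k % len(numbers)]
        cycle = k // len(numbers)
        name = "CA" if cycle == 0 else extra_names[(cycle - 1) % len(extra_names)]
        assignments.append((resnum, name, "C"))
        k += 1
    offsets = rng.normal(scale=spread, size=(len(assignments), 3))
    atoms_by_res: dict[int, list[AtomRecord]] = {}
    records: list[tuple[float, np.ndarray]] = []
    for (resnum, name, element), off in zip(assignments, offsets):
        atom = AtomRecord(atom_name=name, element=element, coords=center + off)
        atoms_by_res.setdefault(resnum, []).append(atom)
        records.append(atom)
    # side-chain/carbonyl atoms needed by the contact metrics
    for resnum, (name, element, local) in _SPECIAL_ATOMS.items():
        if resnum in atoms_by_res:
            ca = atoms_by_res[resnum][0]
            atom = AtomRecord(atom_name=name, element=element, coords=ca.coords + local)
            atoms_by_res[resnum].append(atom)
            records.append(atom)
    # recenter so the mass-weighted center of mass equals `center` exactly
    w = np.array([a.mass for a in records])
    X = np.vstack([a.coords for a in records])
    shift = (w[:, None] * X).sum(axis=0) / w.sum() - center
    for a in records:
        a.coords = a.coords - shift
    out = []
    for resnum in sorted(atoms_by_res):
        out.append(
            ResidueRecord(resnum, _RESNAMES.get(resnum, "ALA"), atoms_by_res[resnum])
        )
    return out


def make_conformer(
    spec: ConformerSpec, scheme: SubdomainScheme = DEFAULT_SCHEME
) -> StructureModel:
    """Build a single-chain conformer realizing the spec.

    The four subdomain centers of mass realize ``phi_target`` exactly;
    isotropic Gaussian noise (``noise_sigma``) is then added to the
    subdomain atoms, perturbing the measured dihedral by the center-of-mass
    averaging error only. The Tyr143 gate atoms are placed last, relative
    to the final Gly168 O / Tyr169 CA positions, so the gate distances are
    exact regardless of noise.
    """
    rng = np.random.default_rng(spec.seed)
    sites = _center_sites(spec.phi_target)
    counts = spec.subdomain_atom_counts or {}
    residues: list[ResidueRecord] = []
    for sd in scheme.subdomains:
        residues.extend(
            _build_sd_residues(sd, sites[sd], scheme, counts.get(sd), rng, spec.cluster_spread)
        )
    if spec.noise_sigma > 0:
        for res in residues:
            for a in res.atoms:
                a.coords = a.coords + rng.normal(scale=spec.noise_sigma, size=3)
    # gate cluster: Tyr143 sits outside every subdomain range, so these
    # atoms never perturb the subdomain centers of mass
    by_num = {r.author_number: r for r in residues}
    o168 = by_num[168].atom("O").coords
    ca169 = by_num[169].atom("CA").coords
    u = o168 - sites["SD3"]
    u = u / np.linalg.norm(u)
    oh143 = o168 + spec.gate_distance * u
    w_dir = oh143 - ca169
    nw = np.linalg.norm(w_dir)
    w_dir = w_dir / nw if nw > 1e-9 else np.array([1.0, 0.0, 0.0])
    ca143 = ca169 + spec.ca_distance * w_dir
    residues.append(
        ResidueRecord(
            143,
            "TYR",
            [
                AtomRecord("CA", "C", ca143),
                AtomRecord("OH", "O", oh143),
            ],
        )
    )
    chain = ChainModel(spec.chain_id, residues)
    model = StructureModel(
        f"synthetic-phi{spec.phi_target:+.1f}", [{spec.chain_id: chain}]
    )
    model.metadata["spec"] = spec
    return model


def twist_series(
    phi_start: float,
    phi_end: float,
    n_steps: int,
    spec: ConformerSpec | None = None,
    scheme: SubdomainScheme = DEFAULT_SCHEME,
) -> list[StructureModel]:
    """Conformers with the dihedral linearly interpolated between two
    endpoints, realized by rotating the SD1+SD2 block about the SD1-SD3
    center-of-mass hinge of a single base conformer.

    Because that hinge is the torsion axis, each rotation shifts the
    *measured* dihedral by exactly the applied angle, so the series is
    exactly linear even for noisy base conformers.
    """
    if n_steps < 2:
        raise SpecError("n_steps must be >= 2")
    spec = replace(spec or ConformerSpec(), phi_target=phi_start)
    base = make_conformer(spec, scheme)
    chain = base.models[0][spec.chain_id]
    part = assign_subdomains(chain, scheme)
    centers = {
        sd: center_of_mass(part.atoms(chain, sd)) for sd in ("SD1", "SD3")
    }
    axis = centers["SD3"] - centers["SD1"]
    axis = axis / np.linalg.norm(axis)
    pivot = centers["SD1"]
    phi_base = flattening_dihedral(part, chain)
    # sign of the torsion response to a rotation about the hinge
    probe = _rotate_block(chain, scheme, axis, pivot, 1.0)
    dphi = _wrap(flattening_dihedral(assign_subdomains(probe, scheme), probe) - phi_base)
    sense = 1.0 if dphi > 0 else -1.0

    targets = np.linspace(phi_start, phi_end, n_steps)
    out = []
    for k, target in enumerate(targets):
        delta = sense * _wrap(target - phi_base)
        rotated = _rotate_block(chain, scheme, axis, pivot, delta)
        model = StructureModel(f"{base.identifier}-step{k}", [{spec.chain_id: rotated}])
        model.metadata["spec"] = replace(spec, phi_target=float(target))
        model.metadata["phi_target"] = float(target)
        out.append(model)
    return out


def _rotate_block(
    chain: ChainModel,
    scheme: SubdomainScheme,
    axis: np.ndarray,
    pivot: np.ndarray,
    angle_deg: float,
) -> ChainModel:
    block = scheme.residues("SD1") | scheme.residues("SD2")
    R = Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()
    residues = []
    for res in chain.residues:
        if res.author_number in block:
            atoms = [a.moved(R @ (a.coords - pivot) + pivot) for a in res.atoms]
        else:
            atoms = [a.moved(a.coords.copy()) for a in res.atoms]
        residues.append(ResidueRecord(res.author_number, res.name, atoms, res.insertion_code))
    return ChainModel(chain.chain_id, residues)


@dataclass(frozen=True)
class GateTrajectorySpec:
    """Recipe for a two-state gate trajectory."""

    p_open: float = 0.4
    n_frames: int = 1000
    d_closed: float = 3.5
    d_open: float = 10.0
    switching: str = "iid"          # iid | markov
    stay_probability: float = 0.95  # markov only
    seed: int = 0
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_open <= 1.0:
            raise SpecError("p_open must be in [0, 1]")
        if self.n_frames < 1:
            raise SpecError("n_frames must be >= 1")
        if self.d_open <= self.d_closed:
            raise SpecError("d_open must exceed d_closed")
        if self.switching not in ("iid", "markov"):
            raise SpecError(f"unknown switching {self.switching!r}")
        if not 0.0 <= self.stay_probability <= 1.0:
            raise SpecError("stay_probability must be in [0, 1]")


def _state_sequence(spec: GateTrajectorySpec, rng: np.random.Generator) -> np.ndarray:
    if spec.switching == "iid":
        return rng.random(spec.n_frames) < spec.p_open
    # markov: with stay_probability keep the state, else resample from
    # Bernoulli(p_open) -> stationary distribution is exactly p_open
    states = np.empty(spec.n_frames, dtype=bool)
    states[0] = rng.random() < spec.p_open
    stays = rng.random(spec.n_frames - 1) < spec.stay_probability
    fresh = rng.random(spec.n_frames - 1) < spec.p_open
    for i in range(1, spec.n_frames):
        states[i] = states[i - 1] if stays[i - 1] else fresh[i - 1]
    return states


def make_gate_trajectory(spec: GateTrajectorySpec) -> StructureModel:
    """Multi-frame structure whose Tyr143 OH sits at ``d_closed`` or
    ``d_open`` from Gly168 O according to the switching process.

    The true state sequence is kept in ``metadata["gate_states"]``.
    """
    rng = np.random.default_rng(spec.seed)
    states = _state_sequence(spec, rng)
    o168 = np.array([0.0, 0.0, 0.0])
    ca168 = np.array([-1.2, -0.4, 0.0])
    ca169 = np.array([2.1, 3.0, 0.5])
    u = np.array([0.0, 0.0, 1.0])      # gate opening direction
    frames = []
    for open_ in states:
        d = spec.d_open if open_ else spec.d_closed
        oh = o168 + d * u
        w = np.array([0.2, -0.5, 0.84])
        ca143 = ca169 + 11.2 * w / np.linalg.norm(w)
        chain = ChainModel(
            spec.chain_id,
            [
                ResidueRecord(143, "TYR", [AtomRecord("CA", "C", ca143), AtomRecord("OH", "O", oh)]),
                ResidueRecord(168, "GLY", [AtomRecord("CA", "C", ca168), AtomRecord("O", "O", o168)]),
                ResidueRecord(169, "TYR", [AtomRecord("CA", "C", ca169)]),
            ],
        )
        frames.append({spec.chain_id: chain})
    model = StructureModel("synthetic-gate-trajectory", frames)
    model.metadata["gate_states"] = states
    model.metadata["spec"] = spec
    return model


def rigid_transform(
    angle_deg: float = 0.0,
    axis=(0.0, 0.0, 1.0),
    pivot=(0.0, 0.0, 0.0),
    translation=(0.0, 0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """(R, t) rotating by ``angle_deg`` about ``axis`` through ``pivot``,
    then translating; apply as x -> R x + t."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    pivot = np.asarray(pivot, dtype=float)
    R = Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()
    t = pivot - R @ pivot + np.asarray(translation, dtype=float)
    return R, t


def make_trimer(
    subunit: StructureModel,
    placements: list[tuple[np.ndarray, np.ndarray]],
    chain_ids: str = "ABC",
) -> StructureModel:
    """Multi-chain structure with rigid copies of the first chain of
    ``subunit`` under each (R, t) placement (A2-lateral / A1-A3
    longitudinal topology is up to the caller's transforms).

    Inter-chain atom pairs closer than 1 A trigger a clash warning but not
    an error.
    """
    if len(placements) < 2:
        raise SpecError("need at least 2 placements")
    if len(placements) > len(chain_ids):
        raise SpecError("not enough chain ids for placements")
    base = next(iter(subunit.models[0].values()))
    chains: dict[str, ChainModel] = {}
    for cid, (R, t) in zip(chain_ids, placements):
        moved = base.transformed(np.asarray(R, dtype=float), np.asarray(t, dtype=float))
        chains[cid] = ChainModel(cid, moved.residues)
    ids = list(chains)
    for i in range(len(ids)):
        tree = cKDTree(chains[ids[i]].coords())
        for j in range(i + 1, len(ids)):
            d, _ = tree.query(chains[ids[j]].coords(), k=1)
            if np.min(d) < 1.0:
                warnings.warn(
                    f"chains {ids[i]}/{ids[j]}: inter-chain clash "
                    f"(min distance {np.min(d):.2f} A)",
                    stacklevel=2,
                )
    model = StructureModel("synthetic-trimer", [chains])
    model.metadata["roles"] = {f"A{k + 1}": cid for k, cid in enumerate(ids)}
    return model
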