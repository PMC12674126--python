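"""Conformational-state metrics for a single actin subunit.

The actin fold divides into four subdomains; the degree of flattening of a
subunit — the G-to-F transition — is quantified by the dihedral angle phi
through the four subdomain centers of mass (order SD2-SD1-SD3-SD4).
Twisted monomeric (G) actin sits near -24 deg, flattened filamentous (F)
actin near -6 deg. Complementary metrics:

* Delta SD1 / Delta SD2: offsets of the SD1/SD2 centers of mass relative
  to a reference conformer after superposing on the rigid SD3+SD4 core.
* W-loop gate: the Tyr143 OH to Gly168 O distance reports whether the
  gate over the Met44 binding pocket is shut (hydrogen-bonded, ~3-4 A) or
  open (8-12 A); Tyr143 CA to Tyr169 CA tracks the W-loop itself.
* Tilt/displacement: how far a subunit sits from its filament position
  after anchoring a neighbouring subunit, probed at a named atom
  (default Asp244 CA).
* Lateral helix engagement: Lys113 N to Glu195 O below 4 A marks an
  engaged (hydrogen-bonded) lateral helix pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_CONFIG, AnalysisConfig
from .errors import PartitionError
from .geometry import (
    SuperpositionResult,
    center_of_mass,
    kabsch,
    match_residues,
    torsion,
)
from .model import AtomRecord, ChainModel, StructureModel, gather_atoms, require_atom, select_chain

# canonical subdomain residue ranges (author numbering), chosen to be
# modeled in all commonly compared actin structures
_DEFAULT_RANGES: dict[str, tuple[tuple[int, int], ...]] = {
    "SD1": ((7, 31), (74, 136), (347, 364)),
    "SD2": ((34, 39), (53, 68)),
    "SD3": ((149, 179), (274, 331)),
    "SD4": ((185, 256),),
}


@dataclass(frozen=True)
class SubdomainScheme:
    """Residue ranges (inclusive) defining the four actin subdomains."""

    ranges: dict[str, tuple[tuple[int, int], ...]] = field(
        default_factory=lambda: dict(_DEFAULT_RANGES)
    )

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for sd, rngs in self.ranges.items():
            for lo, hi in rngs:
                if lo > hi:
                    raise ValueError(f"{sd}: bad range {lo}-{hi}")
                block = set(range(lo, hi + 1))
                if block & seen:
                    raise ValueError(f"{sd}: ranges overlap another subdomain")
                seen |= block

    @property
    def subdomains(self) -> tuple[str, ...]:
        return tuple(self.ranges)

    def residues(self, sd: str) -> set[int]:
        return {
            n for lo, hi in self.ranges[sd] for n in range(lo, hi + 1)
        }


DEFAULT_SCHEME = SubdomainScheme()


@dataclass
class SubdomainPartition:
    """Realization of a scheme on a concrete chain: scheme ∩ modeled residues."""

    scheme: SubdomainScheme
    realized: dict[str, set[int]]
    coverage: dict[str, float]

    def atoms(self, chain: ChainModel, sd: str) -> list[AtomRecord]:
        return gather_atoms(chain, self.realized[sd])


def assign_subdomains(
    chain: ChainModel,
    scheme: SubdomainScheme = DEFAULT_SCHEME,
    coverage_warning: float = DEFAULT_CONFIG.coverage_warning,
) -> SubdomainPartition:
    """Intersect the subdomain scheme with the chain's modeled residues.

    Raises :class:`PartitionError` if any subdomain is entirely unmodeled;
    warns when coverage of a subdomain falls below ``coverage_warning``
    (disordered loops bias a center of mass silently otherwise).
    """
    modeled = chain.residue_numbers()
    realized: dict[str, set[int]] = {}
    coverage: dict[str, float] = {}
    for sd in scheme.subdomains:
        wanted = scheme.residues(sd)
        got = wanted & modeled
        if not got:
            raise PartitionError(
                f"chain {chain.chain_id!r}: no modeled residues in {sd} "
                f"(ranges {scheme.ranges[sd]})"
            )
        realized[sd] = got
        coverage[sd] = len(got) / len(wanted)
        if coverage[sd] < coverage_warning:
            warnings.warn(
                f"chain {chain.chain_id!r}: {sd} coverage "
                f"{len(got)}/{len(wanted)} = {coverage[sd]:.2f}",
                stacklevel=2,
            )
    return SubdomainPartition(scheme, realized, coverage)


def _com_atoms(atoms: list[AtomRecord], weighting: str) -> np.ndarray:
    if weighting == "ca":
        ca = [a for a in atoms if a.atom_name == "CA"]
        if not ca:
            raise PartitionError("no CA atoms for ca-weighted center of mass")
        return center_of_mass(ca, weighting="geometric")
    return center_of_mass(atoms, weighting=weighting)


def subdomain_centers(
    partition: SubdomainPartition,
    chain: ChainModel,
    weighting: str = "mass",
) -> dict[str, np.ndarray]:
    """Center of mass of each realized subdomain."""
    return {
        sd: _com_atoms(partition.atoms(chain, sd), weighting)
        for sd in partition.scheme.subdomains
    }


def flattening_dihedral(
    partition: SubdomainPartition,
    chain: ChainModel,
    weighting: str = "mass",
    order: tuple[str, str, str, str] = DEFAULT_CONFIG.com_order,
) -> float:
    """The flattening dihedral phi (degrees) through the subdomain centers.

    Torsion over the centers of mass in the order SD2-SD1-SD3-SD4 by
    default; the rotation axis is then the SD1-SD3 line, about which the
    SD1/SD2 half of the molecule twists relative to SD3/SD4.
    """
    centers = subdomain_centers(partition, chain, weighting)
    pts = [centers[sd] for sd in order]
    return torsion(*pts)


def classify_conformer(
    phi: float, config: AnalysisConfig = DEFAULT_CONFIG
) -> str:
    """Classify a flattening dihedral as G_like, F_like or intermediate."""
    if not np.isfinite(phi):
        raise ValueError("phi must be finite")
    if phi >= config.phi_f_like_min:
        return "F_like"
    if phi <= config.phi_g_like_max:
        return "G_like"
    return "intermediate"


@dataclass(frozen=True)
class DeltaOffsets:
    """SD1/SD2 center-of-mass offsets of a query conformer vs a reference,
    measured after superposing the rigid SD3+SD4 core."""

    delta_sd1_deg: float
    delta_sd1_ang: float
    delta_sd2_ang: float
    n_fit: int


def delta_offsets(
    query: ChainModel,
    reference: ChainModel,
    scheme: SubdomainScheme = DEFAULT_SCHEME,
    weighting: str = "mass",
) -> DeltaOffsets:
    """Superpose query onto reference over SD3+SD4 C-alphas, then measure
    how far the query's SD1 and SD2 centers of mass sit from the
    reference's. Delta SD1 is reported both as a displacement (A) and as
    the angle (deg) subtended at the reference SD3 center of mass.
    """
    part_q = assign_subdomains(query, scheme)
    part_r = assign_subdomains(reference, scheme)
    core = scheme.residues("SD3") | scheme.residues("SD4")
    sub_q = ChainModel(query.chain_id, [r for r in query.residues if r.author_number in core])
    sub_r = ChainModel(
        reference.chain_id, [r for r in reference.residues if r.author_number in core]
    )
    P, Q, n = match_residues(sub_q, sub_r)
    fit = kabsch(P, Q)

    com_q = subdomain_centers(part_q, query, weighting)
    com_r = subdomain_centers(part_r, reference, weighting)
    sd1_q = fit.rotation @ com_q["SD1"] + fit.translation
    sd2_q = fit.rotation @ com_q["SD2"] + fit.translation

    d_sd1 = float(np.linalg.norm(sd1_q - com_r["SD1"]))
    d_sd2 = float(np.linalg.norm(sd2_q - com_r["SD2"]))
    v1 = sd1_q - com_r["SD3"]
    v2 = com_r["SD1"] - com_r["SD3"]
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return DeltaOffsets(delta_sd1_deg=ang, delta_sd1_ang=d_sd1, delta_sd2_ang=d_sd2, n_fit=n)


@dataclass(frozen=True)
class GateMetrics:
    """W-loop gate geometry of one subunit."""

    d_y143ca_y169ca: float
    d_y143oh_g168o: float
    gate_state: str


def wloop_gate(chain: ChainModel, config: AnalysisConfig = DEFAULT_CONFIG) -> GateMetrics:
    """Measure the W-loop gate: Tyr143 OH to Gly168 O (the gate hydrogen
    bond) and Tyr143 CA to Tyr169 CA (the pocket width).

    Gate state: closed if the OH-O distance <= ``gate_closed_max`` (5 A),
    open if >= ``gate_open_min`` (8 A), else intermediate.
    """
    y143_ca = require_atom(chain, 143, "CA", "Tyr143")
    y143_oh = require_atom(chain, 143, "OH", "Tyr143 hydroxyl")
    g168_o = require_atom(chain, 168, "O", "Gly168 carbonyl")
    y169_ca = require_atom(chain, 169, "CA", "Tyr169")
    d_ca = float(np.linalg.norm(y143_ca.coords - y169_ca.coords))
    d_gate = float(np.linalg.norm(y143_oh.coords - g168_o.coords))
    if d_gate <= config.gate_closed_max:
        state = "closed"
    elif d_gate >= config.gate_open_min:
        state = "open"
    else:
        state = "intermediate"
    return GateMetrics(d_y143ca_y169ca=d_ca, d_y143oh_g168o=d_gate, gate_state=state)


@dataclass(frozen=True)
class HelixEngagement:
    """Lateral SD1-helix to SD4-helix contact between two subunits."""

    d_k113n_e195o: float
    engaged: bool


def helix_engagement(
    chain_a: ChainModel,
    chain_b: ChainModel,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> HelixEngagement:
    """Distance from Lys113 main-chain N (chain_a) to Glu195 carbonyl O
    (chain_b); strictly below 4 A the helices are hydrogen-bond engaged."""
    n113 = require_atom(chain_a, 113, "N", "Lys113 main-chain N")
    o195 = require_atom(chain_b, 195, "O", "Glu195 carbonyl O")
    d = float(np.linalg.norm(n113.coords - o195.coords))
    return HelixEngagement(d_k113n_e195o=d, engaged=d < config.helix_engaged_max)


@dataclass(frozen=True)
class TiltResult:
    """Rigid-body deviation of a probe subunit from its reference position
    after anchoring a neighbouring subunit pair."""

    tilt_angle: float
    probe_displacement: float
    anchor: SuperpositionResult


def tilt_displacement(
    nucleus: StructureModel,
    filament: StructureModel,
    anchor_map: tuple[str, str],
    probe_map: tuple[str, str],
    probe: tuple[int, str] = (244, "CA"),
) -> TiltResult:
    """Anchor the nucleus onto the filament by superposing one subunit
    pair over all common C-alphas, then measure how the probe subunit
    deviates from its filament counterpart.

    ``probe_displacement`` is the distance (A) of the probe atom (default
    Asp244 CA) from its filament position after the anchor fit; ``tilt``
    is the rotation angle (deg) of the residual Kabsch fit between the two
    probe chains.
    """
    anchor_n = select_chain(nucleus, anchor_map[0])
    anchor_f = select_chain(filament, anchor_map[1])
    probe_n = select_chain(nucleus, probe_map[0])
    probe_f = select_chain(filament, probe_map[1])

    P, Q, _ = match_residues(anchor_n, anchor_f)
    anchor_fit = kabsch(P, Q)

    resnum, atom_name = probe
    probe_atom_n = require_atom(probe_n, resnum, atom_name, "probe")
    probe_atom_f = require_atom(probe_f, resnum, atom_name, "probe")
    moved = anchor_fit.rotation @ probe_atom_n.coords + anchor_fit.translation
    displacement = float(np.linalg.norm(moved - probe_atom_f.coords))

    probe_n_fitted = probe_n.transformed(anchor_fit.rotation, anchor_fit.translation)
    Pp, Qp, _ = match_residues(probe_n_fitted, probe_f)
    residual = kabsch(Pp, Qp)
    return TiltResult(
        tilt_angle=residual.rotation_angle_deg,
        probe_displacement=displacement,
        anchor=anchor_fit,
    )


@dataclass
class ConformerMetrics:
    """All single-subunit metrics for one chain, plus per-reference deltas."""

    chain_id: str
    phi_sd1_sd4: float
    conformer_class: str
    gate: GateMetrics
    delta_vs: dict[str, DeltaOffsets] = field(default_factory=dict)


def conformer_metrics(
    chain: ChainModel,
    references: dict[str, ChainModel] | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
    scheme: SubdomainScheme = DEFAULT_SCHEME,
) -> ConformerMetrics:
    """Compute phi, the G/F class, W-loop gate metrics, and (optionally)
    Delta SD1/SD2 offsets against named reference conformers."""
    partition = assign_subdomains(chain, scheme, config.coverage_warning)
    phi = flattening_dihedral(partition, chain, config.com_weighting, config.com_order)
    metrics = ConformerMetrics(
        chain_id=chain.chain_id,
        phi_sd1_sd4=phi,
        conformer_class=classify_conformer(phi, config),
        gate=wloop_gate(chain, config),
    )
    for name, ref in (references or {}).items():
        metrics.delta_vs[name] = delta_offsets(chain, ref, scheme, config.com_weighting)
    return metrics
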