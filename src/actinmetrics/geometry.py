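"""Geometry primitives: centers of mass, torsion angles, Kabsch
superposition, residue matching and RMSD.

Torsion sign convention is the right-handed IUPAC one: looking down the
p2->p3 bond, a positive angle is a clockwise rotation of the far bond.
With this convention the subdomain-center dihedral of twisted monomeric
actin comes out near -24 deg and flattened filamentous actin near -6 deg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateGeometryError, MatchingError
from .model import AtomRecord, ChainModel

_DEGENERACY_EPS = 1e-12


@dataclass(frozen=True)
class SuperpositionResult:
    """Proper rotation + translation minimizing the paired-point RMSD.

    Applying ``x -> rotation @ x + translation`` maps the mobile point set
    onto the reference. ``n_matched`` is the number of paired C-alpha atoms
    the fit used.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_matched: int

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    @property
    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees (0..180).

        atan2 form (stable near 0 and 180, unlike arccos of the trace)."""
        R = self.rotation
        s = 0.5 * np.linalg.norm(
            [R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]]
        )
        c = (np.trace(R) - 1.0) / 2.0
        return float(np.degrees(np.arctan2(s, c)))


def center_of_mass(
    atoms: Iterable[AtomRecord], weighting: str = "mass"
) -> np.ndarray:
    """Weighted mean position of a set of atoms, in Angstrom.

    ``mass`` uses atomic masses; ``geometric`` weights every atom equally.
    """
    atoms = list(atoms)
    if not atoms:
        raise DegenerateGeometryError("center of mass of an empty atom collection")
    if weighting == "mass":
        w = np.array([a.mass for a in atoms], dtype=float)
    elif weighting == "geometric":
        w = np.ones(len(atoms))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    X = np.vstack([a.coords for a in atoms])
    return (w[:, None] * X).sum(axis=0) / w.sum()


def torsion(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) of four points.

    Standard atan2 formulation: with bond vectors b1=p2-p1, b2=p3-p2,
    b3=p4-p3, the angle is atan2(|b2| b1.(b2 x b3), (b1 x b2).(b2 x b3)).
    Degenerate (collinear) configurations raise.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < _DEGENERACY_EPS:
        raise DegenerateGeometryError("torsion: central bond p2->p3 has zero length")
    if np.dot(n1, n1) < _DEGENERACY_EPS or np.dot(n2, n2) < _DEGENERACY_EPS:
        raise DegenerateGeometryError("torsion: collinear points, dihedral undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / b2n)
    angle = np.degrees(np.arctan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def kabsch(
    P: np.ndarray, Q: np.ndarray, weights: Sequence[float] | None = None
) -> SuperpositionResult:
    """Least-squares proper rigid fit of P onto Q (both N x 3, N >= 3).

    Reflections are suppressed: the determinant of the returned rotation is
    forced to +1 by flipping the smallest singular vector, so a mirror-image
    pair yields a proper rotation with nonzero residual RMSD.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching N x 3 arrays")
    n = P.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points to superpose, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
    w = w / w.sum()
    cP = (w[:, None] * P).sum(axis=0)
    cQ = (w[:, None] * Q).sum(axis=0)
    P0 = P - cP
    Q0 = Q - cQ
    H = (w[:, None] * P0).T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # rank < 2 leaves a rotation degree of freedom undetermined
    if S[1] < 1e-10 * max(S[0], 1.0):
        raise DegenerateGeometryError("rank-deficient point set: superposition degenerate")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cQ - R @ cP
    diff = (P0 @ R.T) - Q0
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_matched=n)


def match_residues(
    a: ChainModel,
    b: ChainModel,
    atom: str = "CA",
    trim: str = "none",
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pair atoms of one name across two chains by author residue number.

    Insertion codes must match. ``trim="iterative"`` runs up to 5 cycles
    removing pairs whose deviation (after a Kabsch fit) exceeds twice the
    current RMSD — a crude outlier rejection mirroring what superposition
    programs do. Returns (coords_a, coords_b, n_matched).
    """
    if trim not in ("none", "iterative"):
        raise ValueError(f"unknown trim mode {trim!r}")
    amap = {r.key: r for r in a.residues}
    bmap = {r.key: r for r in b.residues}
    pa, pb = [], []
    for key in sorted(set(amap) & set(bmap)):
        atom_a = amap[key].atom(atom)
        atom_b = bmap[key].atom(atom)
        if atom_a is not None and atom_b is not None:
            pa.append(atom_a.coords)
            pb.append(atom_b.coords)
    if len(pa) < 3:
        raise MatchingError(
            f"only {len(pa)} common {atom} positions between chains "
            f"{a.chain_id!r} and {b.chain_id!r} (need >= 3)"
        )
    P = np.vstack(pa)
    Q = np.vstack(pb)
    if trim == "iterative":
        keep = np.ones(len(P), dtype=bool)
        for _ in range(5):
            if keep.sum() < 3:
                break
            fit = kabsch(P[keep], Q[keep])
            dev = np.linalg.norm(fit.apply(P) - Q, axis=1)
            new_keep = dev <= max(2.0 * fit.rmsd, 1e-6)
            new_keep &= keep  # only ever remove
            if new_keep.sum() < 3 or np.array_equal(new_keep, keep):
                break
            keep = new_keep
        P, Q = P[keep], Q[keep]
    return P, Q, len(P)


def rmsd_after_superposition(
    a: ChainModel,
    b: ChainModel,
    fit_selection: Iterable[int] | None = None,
    report_selection: Iterable[int] | None = None,
    atom: str = "CA",
    trim: str = "none",
) -> SuperpositionResult:
    """Kabsch-fit chain a onto chain b over ``fit_selection`` residues and
    report the RMSD over ``report_selection`` (both default to all common
    residues, giving the global C-alpha RMSD).
    """
    fit_a, fit_b = a, b
    if fit_selection is not None:
        sel = set(fit_selection)
        fit_a = ChainModel(a.chain_id, [r for r in a.residues if r.author_number in sel])
        fit_b = ChainModel(b.chain_id, [r for r in b.residues if r.author_number in sel])
    P, Q, n = match_residues(fit_a, fit_b, atom=atom, trim=trim)
    fit = kabsch(P, Q)
    if report_selection is None and fit_selection is None:
        return fit
    rep_a, rep_b = a, b
    if report_selection is not None:
        sel = set(report_selection)
        rep_a = ChainModel(a.chain_id, [r for r in a.residues if r.author_number in sel])
        rep_b = ChainModel(b.chain_id, [r for r in b.residues if r.author_number in sel])
    Pr, Qr, nr = match_residues(rep_a, rep_b, atom=atom, trim="none")
    diff = fit.apply(Pr) - Qr
    rmsd = float(np.sqrt(np.mean(np.einsum("ij,ij->i", diff, diff))))
    return SuperpositionResult(
        rotation=fit.rotation, translation=fit.translation, rmsd=rmsd, n_matched=nr
    )
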