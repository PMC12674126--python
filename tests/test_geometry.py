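"""Geometry primitives: centers of mass, torsions, Kabsch fits, matching.

The torsion oracle here is an independent projection-based implementation
(project the outer bonds onto the plane normal to the central bond), plus
Bio.PDB's calc_dihedral to pin the sign convention.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from actinmetrics import (
    AtomRecord,
    center_of_mass,
    kabsch,
    match_residues,
    rmsd_after_superposition,
    torsion,
)
from actinmetrics.errors import DegenerateGeometryError, MatchingError
from conftest import make_ca_chain


def torsion_oracle(p1, p2, p3, p4) -> float:
    """Independent dihedral: project b1 and b3 onto the plane normal to b2,
    then take the signed angle between the projections."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b2 = p3 - p2
    u = b2 / np.linalg.norm(b2)
    v = (p1 - p2) - np.dot(p1 - p2, u) * u  # toward p1, i.e. -b1 projected
    w = (p4 - p3) - np.dot(p4 - p3, u) * u
    x = np.dot(v, w)
    y = np.dot(np.cross(u, v), w)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def random_rigid(rng) -> tuple[np.ndarray, np.ndarray]:
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.normal(scale=20.0, size=3)
    return R, t


class TestCenterOfMass:
    def test_equal_mass_midpoint(self):
        atoms = [AtomRecord("C1", "C", [0, 0, 0]), AtomRecord("C2", "C", [2, 0, 0])]
        assert np.allclose(center_of_mass(atoms), [1, 0, 0])

    def test_carbon_oxygen_weighted(self):
        # 15.999 / (12.011 + 15.999) = 0.57119...
        atoms = [AtomRecord("C", "C", [0, 0, 0]), AtomRecord("O", "O", [1, 0, 0])]
        com = center_of_mass(atoms)
        assert com[0] == pytest.approx(15.999 / 28.010, abs=1e-4)

    def test_geometric_ignores_mass(self):
        atoms = [AtomRecord("C", "C", [0, 0, 0]), AtomRecord("O", "O", [1, 0, 0])]
        assert np.allclose(center_of_mass(atoms, weighting="geometric"), [0.5, 0, 0])

    def test_empty_raises(self):
        with pytest.raises(DegenerateGeometryError):
            center_of_mass([])


class TestTorsion:
    @pytest.mark.parametrize(
        "p4,expected",
        [((1, 0, 1), 0.0), ((-1, 0, 1), 180.0)],
        ids=["cis", "trans"],
    )
    def test_planar(self, p4, expected):
        got = torsion((1, 0, 0), (0, 0, 0), (0, 0, 1), p4)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_perpendicular_sign_matches_biopython(self):
        from Bio.PDB.vectors import Vector, calc_dihedral

        pts = [(1, 0, 0), (0, 0, 0), (0, 0, 1), (0, 1, 1)]
        mine = torsion(*pts)
        bio = np.degrees(calc_dihedral(*[Vector(np.asarray(p, float)) for p in pts]))
        assert abs(mine) == pytest.approx(90.0, abs=1e-12)
        assert mine == pytest.approx(bio, abs=1e-9)

    def test_range_is_half_open(self):
        assert torsion((1, 0, 0), (0, 0, 0), (0, 0, 1), (-1, 0, 1)) == 180.0

    @pytest.mark.parametrize(
        "pts",
        [
            ((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0)),  # p1p2p3 collinear
            ((1, 1, 0), (0, 0, 0), (0, 0, 0), (1, 0, 1)),  # zero central bond
        ],
    )
    def test_degenerate_raises(self, pts):
        with pytest.raises(DegenerateGeometryError):
            torsion(*pts)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(scale=8.0, size=(4, 3))
        try:
            mine = torsion(*pts)
        except DegenerateGeometryError:
            return
        diff = (mine - torsion_oracle(*pts) + 180.0) % 360.0 - 180.0
        assert abs(diff) < 1e-9

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_reversal_invariance_and_mirror_antisymmetry(self, seed):
        """The IUPAC torsion reads the same from either end of the chain
        (reversal invariance); a mirror reflection negates it."""
        rng = np.random.default_rng(seed)
        p = rng.normal(scale=5.0, size=(4, 3))
        try:
            fwd = torsion(*p)
        except DegenerateGeometryError:
            return
        assert torsion(p[3], p[2], p[1], p[0]) == pytest.approx(fwd, abs=1e-9)
        mirrored = p * np.array([1.0, 1.0, -1.0])
        neg = torsion(*mirrored)
        if abs(abs(fwd) - 180.0) < 1e-9:  # +180 is its own mirror image
            assert abs(neg) == pytest.approx(180.0, abs=1e-9)
        else:
            assert neg == pytest.approx(-fwd, abs=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.normal(scale=5.0, size=(4, 3))
        try:
            before = torsion(*p)
        except DegenerateGeometryError:
            return
        R, t = random_rigid(rng)
        after = torsion(*(p @ R.T + t))
        assert after == pytest.approx(before, abs=1e-8)


class TestKabsch:
    def test_identity(self):
        P = np.random.default_rng(0).normal(size=(10, 3))
        fit = kabsch(P, P)
        assert np.allclose(fit.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(fit.translation, 0, atol=1e-12)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_constructed_transform(self):
        rng = np.random.default_rng(1)
        P = rng.normal(scale=5.0, size=(8, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        Q = P @ R.T + t
        fit = kabsch(P, Q)
        assert np.allclose(fit.rotation, R, atol=1e-10)
        assert np.allclose(fit.translation, t, atol=1e-10)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-10)
        assert fit.rotation_angle_deg == pytest.approx(90.0, abs=1e-9)

    def test_mirror_image_yields_proper_rotation(self):
        # chiral 4-point set; reflection is not reachable by det +1
        P = np.array([[0, 0, 0], [3, 0, 0], [0, 2, 0], [0, 0, 1.0]])
        Q = P * np.array([1, 1, -1.0])
        fit = kabsch(P, Q)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-12)
        assert fit.rmsd > 0.1

    def test_fitted_rmsd_never_exceeds_unfitted(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            P = rng.normal(scale=4.0, size=(6, 3))
            Q = rng.normal(scale=4.0, size=(6, 3))
            fit = kabsch(P, Q)
            raw = np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1)))
            assert fit.rmsd <= raw + 1e-9

    def test_weights_change_fit(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(5, 3))
        Q = rng.normal(size=(5, 3))
        w = np.array([10.0, 1, 1, 1, 1])
        fit_w = kabsch(P, Q, weights=w)
        dev = np.linalg.norm(fit_w.apply(P) - Q, axis=1)
        # the heavily weighted point should be fit tightest
        assert dev[0] <= dev.mean()

    def test_too_few_points(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_rank_deficient_collinear(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch(P, P.copy())

    def test_matches_scipy_align_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            P = rng.normal(scale=6.0, size=(12, 3))
            Q = rng.normal(scale=6.0, size=(12, 3))
            fit = kabsch(P, Q)
            rot, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
            assert fit.rmsd == pytest.approx(rssd / np.sqrt(len(P)), abs=1e-9)


class TestMatchResidues:
    def test_identical_chains(self):
        a = make_ca_chain(range(1, 101), seed=0)
        b = make_ca_chain(range(1, 101), "B", coords=a.coords())
        P, Q, n = match_residues(a, b)
        assert n == 100
        assert np.allclose(P, Q)

    def test_gap_reduces_count(self):
        full = make_ca_chain(range(1, 101), seed=1)
        gapped_nums = [n for n in range(1, 101) if not 41 <= n <= 50]
        gapped = make_ca_chain(gapped_nums, "B", seed=2)
        _, _, n = match_residues(full, gapped)
        assert n == 90

    def test_disjoint_numbering_raises(self):
        a = make_ca_chain(range(1, 10), seed=0)
        b = make_ca_chain(range(100, 110), "B", seed=1)
        with pytest.raises(MatchingError):
            match_residues(a, b)

    def test_iterative_trim_drops_outlier(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(scale=10.0, size=(30, 3))
        a = make_ca_chain(range(1, 31), coords=coords)
        moved = coords + rng.normal(scale=0.05, size=coords.shape)
        moved[7] += 25.0  # one wild outlier
        b = make_ca_chain(range(1, 31), "B", coords=moved)
        _, _, n_trim = match_residues(a, b, trim="iterative")
        assert n_trim == 29


class TestRmsdAfterSuperposition:
    def test_self_is_zero(self):
        a = make_ca_chain(range(1, 50), seed=6)
        fit = rmsd_after_superposition(a, a)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-12)
        assert fit.n_matched == 49

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        a = make_ca_chain(range(1, 60), seed=7)
        R, t = random_rigid(rng)
        b = a.transformed(R, t)
        fit = rmsd_after_superposition(a, b)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_in_arguments(self):
        a = make_ca_chain(range(1, 40), seed=8)
        b = make_ca_chain(range(1, 40), "B", seed=9)
        ab = rmsd_after_superposition(a, b).rmsd
        ba = rmsd_after_superposition(b, a).rmsd
        assert ab == pytest.approx(ba, abs=1e-6)

    def test_fit_and_report_selections_differ(self):
        rng = np.random.default_rng(10)
        coords = rng.normal(scale=10.0, size=(40, 3))
        a = make_ca_chain(range(1, 41), coords=coords)
        shifted = coords.copy()
        shifted[20:] += [5.0, 0, 0]  # second half displaced rigidly
        b = make_ca_chain(range(1, 41), "B", coords=shifted)
        fit_first = rmsd_after_superposition(
            a, b, fit_selection=range(1, 21), report_selection=range(21, 41)
        )
        assert fit_first.rmsd == pytest.approx(5.0, abs=1e-9)
        assert fit_first.n_matched == 20
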