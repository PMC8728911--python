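"""Torsion/planar angle arithmetic and backbone angle extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from ssangles.geometry import (
    AngleTable,
    BackboneChain,
    DegenerateGeometryError,
    compute_backbone_angles,
    dihedral,
    planar_angle,
    read_pdb,
    wrap_angle,
    write_pdb,
)


class TestWrapAngle:
    @pytest.mark.parametrize(
        "x,expected",
        [(190, -170), (-190, 170), (180, 180), (0, 0), (-180, 180), (540, 180), (361, 1)],
    )
    def test_examples(self, x, expected):
        assert wrap_angle(x) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False))
    def test_wrap_properties_hold_for_any_finite_angle(self, x):
        w = wrap_angle(x)
        assert -180 < w <= 180
        assert np.isclose(np.mod(w - x, 360.0), 0.0, atol=1e-6) or np.isclose(
            np.mod(w - x, 360.0), 360.0, atol=1e-6
        )
        assert wrap_angle(w) == w

    def test_idempotent_and_congruent(self, rng):
        x = rng.uniform(-2000, 2000, 500)
        w = wrap_angle(x)
        assert np.allclose(wrap_angle(w), w)
        assert np.allclose(np.mod(w - x, 360.0), 0.0, atol=1e-9)
        assert np.all((w > -180) & (w <= 180))


class TestDihedral:
    def test_cis_is_zero(self):
        assert dihedral((1, 1, 0), (0, 1, 0), (0, 0, 0), (1, 0, 0)) == pytest.approx(0.0)

    def test_trans_is_plus_180(self):
        # planarity forces +/-180; the half-open range picks +180
        assert dihedral((1, 1, 0), (0, 1, 0), (0, 0, 0), (-1, 0, 0)) == pytest.approx(180.0)

    def test_matches_rotation_construction_oracle(self, rng):
        # build quadruples with a known torsion via an explicit axis rotation
        for _ in range(50):
            b, c = rng.normal(size=3), rng.normal(size=3)
            axis = c - b
            axis /= np.linalg.norm(axis)
            v = rng.normal(size=3)
            v -= v.dot(axis) * axis
            v /= np.linalg.norm(v)
            t = rng.uniform(-179.9, 179.9)
            d = c + Rotation.from_rotvec(np.radians(t) * axis).apply(v)
            assert dihedral(b + v, b, c, d) == pytest.approx(t, abs=1e-9)

    def test_reversal_invariance_and_mirror_antisymmetry(self, rng):
        # chain reversal preserves a dihedral; mirror reflection negates it
        for _ in range(1000):
            p = rng.normal(size=(4, 3))
            try:
                fwd = dihedral(*p)
            except DegenerateGeometryError:
                continue
            rev = dihedral(*p[::-1])
            assert wrap_angle(fwd - rev) == pytest.approx(0.0, abs=1e-9) or (
                fwd == pytest.approx(180.0) and rev == pytest.approx(180.0)
            )
            mirror = p * np.array([1.0, 1.0, -1.0])
            refl = dihedral(*mirror)
            assert wrap_angle(fwd + refl) == pytest.approx(0.0, abs=1e-9) or (
                fwd == pytest.approx(180.0) and refl == pytest.approx(180.0)
            )

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateGeometryError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))  # collinear triple
        with pytest.raises(DegenerateGeometryError):
            dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))  # coincident


class TestPlanarAngle:
    def test_orthogonal_and_collinear(self):
        assert planar_angle((1, 0, 0), (0, 0, 0), (0, 1, 0)) == pytest.approx(90.0)
        assert planar_angle((1, 0, 0), (0, 0, 0), (-1, 0, 0)) == pytest.approx(180.0)

    def test_matches_arccos_oracle(self, rng):
        for _ in range(50):
            p1, p2, p3 = rng.normal(size=(3, 3))
            u, v = p1 - p2, p3 - p2
            expected = np.degrees(
                np.arccos(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
            )
            assert planar_angle(p1, p2, p3) == pytest.approx(expected, abs=1e-9)

    def test_coincident_raises(self):
        with pytest.raises(DegenerateGeometryError):
            planar_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))


def _random_chain(rng, L=5):
    # random but locally sane coordinates: consecutive atoms ~1.4 A apart
    pos = np.zeros(3)
    coords = {k: np.zeros((L, 3)) for k in ("N", "CA", "C")}
    for i in range(L):
        for name in ("N", "CA", "C"):
            step = rng.normal(size=3)
            pos = pos + 1.4 * step / np.linalg.norm(step)
            coords[name][i] = pos
    return BackboneChain("A" * L, coords)


class TestComputeBackboneAngles:
    def test_single_residue_all_undefined(self):
        chain = BackboneChain(
            "A", {k: np.array([[i, 0.0, 0.0]]) for i, k in enumerate(("N", "CA", "C"))}
        )
        t = compute_backbone_angles(chain)
        assert all(np.isnan(getattr(t, a)).all() for a in ("phi", "psi", "theta", "tau"))

    def test_compositional_oracle(self, rng):
        chain = _random_chain(rng, L=5)
        t = compute_backbone_angles(chain)
        N, CA, C = chain.coords["N"], chain.coords["CA"], chain.coords["C"]
        for i in range(1, 5):
            assert t.phi[i] == pytest.approx(dihedral(C[i - 1], N[i], CA[i], C[i]))
        for i in range(4):
            assert t.psi[i] == pytest.approx(dihedral(N[i], CA[i], C[i], N[i + 1]))
        for i in range(1, 4):
            assert t.theta[i] == pytest.approx(planar_angle(CA[i - 1], CA[i], CA[i + 1]))
        for i in range(1, 3):
            assert t.tau[i] == pytest.approx(
                dihedral(CA[i - 1], CA[i], CA[i + 1], CA[i + 2])
            )
        # terminus flags
        assert np.isnan(t.phi[0]) and np.isnan(t.psi[-1])
        assert np.isnan(t.theta[0]) and np.isnan(t.theta[-1])
        assert np.isnan(t.tau[0]) and np.isnan(t.tau[-1]) and np.isnan(t.tau[-2])

    def test_rigid_motion_invariance(self, rng):
        chain = _random_chain(rng, L=6)
        R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        moved = chain.transformed(R, rng.normal(size=3) * 10)
        t0, t1 = compute_backbone_angles(chain), compute_backbone_angles(moved)
        for a in ("phi", "psi", "theta", "tau"):
            assert np.allclose(
                getattr(t0, a), getattr(t1, a), atol=1e-6, equal_nan=True
            )

    def test_missing_atom_degrades_to_nan(self, rng):
        chain = _random_chain(rng, L=5)
        chain.coords["N"][2] = np.nan
        t = compute_backbone_angles(chain)
        assert np.isnan(t.phi[2]) and np.isnan(t.psi[1]) and np.isnan(t.psi[2])
        assert np.isfinite(t.theta[2])  # theta needs only CA atoms

    def test_empty_chain_raises(self):
        with pytest.raises(ValueError):
            compute_backbone_angles(
                BackboneChain("", {k: np.zeros((0, 3)) for k in ("N", "CA", "C")})
            )


class TestIO:
    def test_pdb_round_trip(self, tmp_path, rng):
        from ssangles.builder import build_backbone

        phi = rng.uniform(-170, 170, 8)
        psi = rng.uniform(-170, 170, 8)
        chain = build_backbone("ACDEFGHI", phi, psi)
        path = tmp_path / "m.pdb"
        write_pdb(chain, path)
        back = read_pdb(path)
        assert back.sequence == chain.sequence
        for name in ("N", "CA", "C"):
            assert np.allclose(back.coords[name], chain.coords[name], atol=1e-3)

    def test_angle_table_tsv_round_trip(self, tmp_path):
        t = AngleTable(
            phi=np.array([np.nan, 10.5]),
            psi=np.array([20.25, np.nan]),
            theta=np.array([np.nan, np.nan]),
            tau=np.array([np.nan, np.nan]),
            sequence="AG",
        )
        p = tmp_path / "a.tsv"
        t.to_tsv(p)
        back = AngleTable.from_tsv(p)
        assert np.isnan(back.phi[0]) and back.phi[1] == pytest.approx(10.5)
        assert back.psi[0] == pytest.approx(20.25) and np.isnan(back.psi[1])
        assert back.sequence == "AG"
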