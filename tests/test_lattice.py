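import numpy as np
import pytest

from kinetomt import (
    FlareProfile,
    LatticeParams,
    build_straight_mt,
    closure_count,
    estimate_lattice_params,
    flare_protofilaments,
    lattice_transform,
)
from kinetomt.errors import ConfigurationError, InsufficientDataError, InvalidArgumentError
from kinetomt.geometry import superpose
from kinetomt.lattice import _dimer_groups, _group_coords


def dimer_centroids(mt):
    return {site: _group_coords(chs).mean(axis=0) for site, chs in _dimer_groups(mt).items()}


class TestLatticeTransform:
    def test_origin_site_is_identity(self, params):
        assert lattice_transform(params, 0, 0).is_identity()

    def test_neighbor_protofilament_step(self, params):
        # adjacent protofilaments: 9.65 A rise, -27.6 deg rotation
        t = lattice_transform(params, 1, 0)
        assert t.apply([params.radius, 0.0, 0.0])[2] == pytest.approx(9.65)
        phi = np.rad2deg(np.arctan2(*t.apply([params.radius, 0.0, 0.0])[1::-1]))
        assert phi == pytest.approx(-27.6)

    def test_next_dimer_step(self, params):
        # consecutive dimers in one protofilament: 83.3 A rise, 0.43 deg twist
        t = lattice_transform(params, 0, 1)
        p = t.apply([params.radius, 0.0, 0.0])
        assert p[2] == pytest.approx(83.3)
        assert np.rad2deg(np.arctan2(p[1], p[0])) == pytest.approx(0.43)

    def test_homomorphism_in_dimer_index(self, params):
        t12 = lattice_transform(params, 0, 3)
        composed = lattice_transform(params, 0, 1).compose(lattice_transform(params, 0, 2))
        assert np.allclose(t12.rotation, composed.rotation, atol=1e-9)
        assert np.allclose(t12.translation, composed.translation, atol=1e-9)

    def test_out_of_range_protofilament_rejected(self, params):
        with pytest.raises(InvalidArgumentError):
            lattice_transform(params, 13, 0)


class TestBuildStraightMT:
    def test_single_site_reproduces_template_shape(self, tubulin):
        p = LatticeParams(n_pf=1, twist_pf=-27.6)
        mt = build_straight_mt(tubulin, p, 1)
        assert mt.n_atoms == tubulin.n_atoms
        # same internal geometry (placed rigidly at the lattice site)
        _, rmsd = superpose(mt.coords(), tubulin.coords())
        assert rmsd < 1e-9

    def test_13pf_2dimer_lattice_has_26_copies(self, tubulin, params):
        mt = build_straight_mt(tubulin, params, 2)
        assert len(_dimer_groups(mt)) == 26
        assert mt.n_atoms == 26 * tubulin.n_atoms

    def test_seam_axial_offset(self, tubulin, params):
        # pf 12 vs pf 0 at equal dimer index: 12 * 9.65 = 115.8 A along the axis
        mt = build_straight_mt(tubulin, params, 1)
        cen = dimer_centroids(mt)
        assert cen[(12, 0)][2] - cen[(0, 0)][2] == pytest.approx(115.8)

    def test_all_centroids_on_radius(self, params, straight_mt):
        # the template centroid is the frame origin, so every dimer centroid
        # lies exactly at the lattice radius from the tube axis
        for c in dimer_centroids(straight_mt).values():
            assert np.hypot(c[0], c[1]) == pytest.approx(params.radius, abs=1e-9)

    def test_missing_body_frame_rejected(self, tubulin, params):
        bare = tubulin.copy()
        bare.metadata.pop("body_frame")
        with pytest.raises(ConfigurationError):
            build_straight_mt(bare, params, 1)


class TestClosureCount:
    @pytest.mark.parametrize(
        "twist,expected",
        [(-27.6, 13), (-90.0, 4), (-360.0 / 17.0, 17), (27.6, 13)],
    )
    def test_closure(self, twist, expected):
        assert closure_count(twist) == expected

    def test_zero_twist_rejected(self):
        with pytest.raises(InvalidArgumentError):
            closure_count(0.0)

    def test_default_twist_closes_default_pf_count(self, params):
        assert closure_count(params.twist_pf) == params.n_pf


class TestEstimateLatticeParams:
    def test_noiseless_roundtrip_recovers_generating_values(self, straight_mt, params):
        est = estimate_lattice_params(straight_mt)
        assert est.rise_dimer == pytest.approx(params.rise_dimer, abs=1e-6)
        assert est.twist_dimer == pytest.approx(params.twist_dimer, abs=1e-6)
        assert est.rise_pf == pytest.approx(params.rise_pf, abs=1e-6)
        assert est.twist_pf == pytest.approx(params.twist_pf, abs=1e-6)
        assert est.n_pf == params.n_pf

    def test_single_protofilament_flags_pf_params_unavailable(self, tubulin):
        p = LatticeParams(n_pf=1)
        mt = build_straight_mt(tubulin, p, 3)
        with pytest.warns(UserWarning, match="inter-pf"):
            est = estimate_lattice_params(mt)
        assert np.isnan(est.rise_pf) and np.isnan(est.twist_pf)
        assert est.rise_dimer == pytest.approx(83.3, abs=1e-6)

    def test_jittered_coordinates_estimated_within_half_percent(self, tubulin, params):
        mt = build_straight_mt(tubulin, params, 3)
        rng = np.random.default_rng(777)
        mt.set_coords(mt.coords() + rng.normal(0.0, 0.1, size=(mt.n_atoms, 3)))
        est = estimate_lattice_params(mt)
        assert est.rise_dimer == pytest.approx(params.rise_dimer, rel=0.005)
        assert est.rise_pf == pytest.approx(params.rise_pf, rel=0.005)
        assert est.twist_pf == pytest.approx(params.twist_pf, rel=0.005)

    def test_too_few_dimers_rejected(self, tubulin, params):
        mt = build_straight_mt(tubulin, params, 1)
        with pytest.raises(InsufficientDataError):
            estimate_lattice_params(mt)


class TestFlare:
    def recover_transform(self, straight, flared, site):
        """Rigid motion applied to one dimer, recovered by superposition."""
        a = _group_coords(_dimer_groups(straight)[site])
        b = _group_coords(_dimer_groups(flared)[site])
        t, rmsd = superpose(a, b)
        assert rmsd < 1e-9  # dimers stay internally rigid
        return t

    def test_zero_bend_is_identity(self, straight_mt, params):
        out = flare_protofilaments(straight_mt, FlareProfile(1, 0.0), params)
        assert np.array_equal(out.coords(), straight_mt.coords())

    def test_dimers_before_flare_start_unchanged(self, straight_mt, params):
        out = flare_protofilaments(straight_mt, FlareProfile(2, 20.0), params)
        for site, chs in _dimer_groups(straight_mt).items():
            if site[1] < 2:
                assert np.array_equal(
                    _group_coords(chs), _group_coords(_dimer_groups(out)[site])
                )

    @pytest.mark.parametrize("n_flared,expected_terminal_angle", [(1, 20.0), (3, 60.0)])
    def test_cumulative_bend_angle(self, tubulin, params, n_flared, expected_terminal_angle):
        n_dimers = n_flared + 1
        mt = build_straight_mt(tubulin, params, n_dimers)
        out = flare_protofilaments(mt, FlareProfile(1, 20.0), params)
        t = self.recover_transform(mt, out, (0, n_dimers - 1))
        # rotation angle of the terminal dimer's recovered rigid motion
        angle = np.rad2deg(np.arccos(np.clip((np.trace(t.rotation) - 1) / 2, -1, 1)))
        assert angle == pytest.approx(expected_terminal_angle, abs=1e-6)

    def test_flare_bends_outward(self, tubulin, params):
        mt = build_straight_mt(tubulin, params, 2)
        out = flare_protofilaments(mt, FlareProfile(1, 20.0), params)
        for p in range(params.n_pf):
            c0 = dimer_centroids(mt)[(p, 1)]
            c1 = dimer_centroids(out)[(p, 1)]
            assert np.hypot(c1[0], c1[1]) > np.hypot(c0[0], c0[1])

    def test_intra_dimer_distances_exact_and_hinge_continuous(self, straight_mt, params):
        profile = FlareProfile(1, 22.0)
        out = flare_protofilaments(straight_mt, profile, params)
        groups_in = _dimer_groups(straight_mt)
        groups_out = _dimer_groups(out)
        half_rise = params.rise_dimer / 2.0
        for p in range(params.n_pf):
            transforms = {}
            for d in range(3):
                a = _group_coords(groups_in[(p, d)])
                b = _group_coords(groups_out[(p, d)])
                # intra-dimer geometry rigid
                da = np.linalg.norm(a[:, None] - a[None, :], axis=2)
                db = np.linalg.norm(b[:, None] - b[None, :], axis=2)
                assert np.allclose(da, db, atol=1e-9)
                t, _ = superpose(a, b)
                transforms[d] = t
            # hinge continuity: the junction point maps identically from
            # both flanking dimers' recovered transforms
            for d in range(2):
                junction = _group_coords(groups_in[(p, d)]).mean(axis=0) + [0, 0, half_rise]
                gap = np.linalg.norm(
                    transforms[d].apply(junction) - transforms[d + 1].apply(junction)
                )
                assert gap < 1e-6

    def test_flare_start_beyond_length_warns_noop(self, straight_mt, params):
        with pytest.warns(UserWarning, match="beyond"):
            out = flare_protofilaments(straight_mt, FlareProfile(10, 20.0), params)
        assert np.array_equal(out.coords(), straight_mt.coords())
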