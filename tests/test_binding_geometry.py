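import numpy as np
import pytest
from hypothesis import given, strategies as st

from nitrigeom.binding_geometry import (
    LigandFrame,
    analyze_site,
    build_ligand_frame,
    classify_mode,
    compute_phi,
    compute_psi,
    compute_theta,
)
from nitrigeom.structures_io import ActiveSite, HisNitrogen
from nitrigeom.synthetic_data import SiteSpec, make_site, random_site_specs

from conftest import planar_site
from oracles import cu_local_oracle, phi_oracle, psi_oracle, theta_oracle


def frame_at(cu_local):
    return LigandFrame(
        origin=np.zeros(3),
        x_axis=np.array([1.0, 0.0, 0.0]),
        y_axis=np.array([0.0, 1.0, 0.0]),
        z_axis=np.array([0.0, 0.0, 1.0]),
        cu_local=np.asarray(cu_local, dtype=float),
    )


class TestLigandFrame:
    def test_frame_invariants(self, canonical_site):
        frame = build_ligand_frame(canonical_site)
        R = frame.rotation
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        # Nitrite N lies on +X; both oxygens lie in the XY plane.
        n_local = R @ (canonical_site.nitrite_n - frame.origin)
        assert n_local[0] > 0
        assert abs(n_local[1]) < 1e-9 and abs(n_local[2]) < 1e-9
        for o in (canonical_site.nitrite_o1, canonical_site.nitrite_o2):
            assert abs((R @ (o - frame.origin))[2]) < 1e-9
        assert frame.cu_local[2] >= 0

    def test_cu_on_x_ray_gives_axis_aligned_local(self):
        site = planar_site()
        d = np.linalg.norm(site.cu - build_ligand_frame(site).origin)
        cu_local = build_ligand_frame(site).cu_local
        # Cu is at the origin and the nitrite points away along +x, so Cu
        # sits on the -X side... here Cu is *behind* the COM: check via theta.
        assert np.hypot(cu_local[1], cu_local[2]) < 1e-9
        assert abs(np.linalg.norm(cu_local) - d) < 1e-9

    def test_rigid_motion_leaves_cu_local_unchanged(self, canonical_site, rigid_motion):
        frame0 = build_ligand_frame(canonical_site)
        for _ in range(10):
            R, t = rigid_motion()
            moved = canonical_site.transformed(R, t)
            assert np.allclose(build_ligand_frame(moved).cu_local, frame0.cu_local, atol=1e-9)

    def test_collinear_nitrite_is_degenerate(self):
        site = planar_site()
        bad = ActiveSite(
            cu=site.cu,
            his_n=site.his_n,
            nitrite_n=np.array([2.0, 0.0, 0.0]),
            nitrite_o1=np.array([3.0, 0.0, 0.0]),
            nitrite_o2=np.array([4.0, 0.0, 0.0]),
        )
        with pytest.raises(ValueError, match="degenerate ligand plane"):
            build_ligand_frame(bad)

    def test_oracle_agreement_on_random_sites(self):
        for spec in random_site_specs(200, seed=11):
            frame = build_ligand_frame(make_site(spec))
            assert np.allclose(frame.cu_local, cu_local_oracle(make_site(spec)), atol=1e-6)


class TestAngles:
    @pytest.mark.parametrize(
        "cu_local, expected",
        [((2.0, 0.0, 0.0), 0.0), ((0.0, 0.3, 2.0), 90.0), ((-2.0, 0.1, 0.0), 180.0)],
    )
    def test_theta_poles(self, cu_local, expected):
        assert compute_theta(frame_at(cu_local)) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "cu_local, expected",
        [((2.0, 0.0, 0.1), 0.0), ((-2.0, 0.0, 0.1), 180.0), ((1.0, 1.0, 0.0), 45.0)],
    )
    def test_psi_poles(self, cu_local, expected):
        assert compute_psi(frame_at(cu_local)) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_projections_raise(self):
        with pytest.raises(ValueError, match="altitude undefined"):
            compute_theta(frame_at((0.0, 2.0, 0.0)))
        with pytest.raises(ValueError, match="azimuth undefined"):
            compute_psi(frame_at((0.0, 0.0, 2.0)))

    def test_angle_oracles_on_random_sites(self):
        for spec in random_site_specs(200, seed=12):
            site = make_site(spec)
            frame = build_ligand_frame(site)
            assert compute_theta(frame) == pytest.approx(theta_oracle(site), abs=1e-6)
            assert compute_psi(frame) == pytest.approx(psi_oracle(site), abs=1e-6)


class TestClassification:
    @pytest.mark.parametrize(
        "theta, psi, label",
        [
            # mean angle pairs of the four observed orientation clusters
            (175.8, 174.2, "bidentate top-hat"),
            (178.1, 175.0, "bidentate top-hat"),
            (177.7, 174.1, "bidentate top-hat"),
            (5.8, 1.0, "symmetrical N-bound"),
            (7.1, 3.3, "symmetrical N-bound"),
            (4.3, 2.4, "symmetrical N-bound"),
            (5.8, 12.6, "l-shaped N-bound"),
            (6.1, 12.2, "l-shaped N-bound"),
            (5.1, 15.8, "l-shaped N-bound"),
            (175.5, 156.7, "monodentate top-hat"),
            (174.5, 160.4, "monodentate top-hat"),
            (175.3, 158.8, "monodentate top-hat"),
            (88.0, 88.0, "side-on"),
            (153.2, 160.0, "borderline"),
            (145.0, 160.0, "borderline"),
        ],
    )
    def test_observed_cluster_labels(self, theta, psi, label):
        assert classify_mode(theta, psi).mode_label == label

    @pytest.mark.parametrize(
        "theta, psi, altitudinal, azimuthal",
        [
            (20.0, 5.0, "N-bound", "symmetrical"),  # closed upper theta bound
            (10.0, 10.0, "N-bound", "symmetrical"),  # shared psi boundary -> symmetrical
            (10.0, 30.0, "N-bound", "l-shaped"),
            (10.0, 45.2, "N-bound", "unclassified"),  # crystal-like azimuth
            (160.0, 170.0, "top-hat", "bidentate"),  # shared boundary -> bidentate
            (160.0, 140.0, "top-hat", "monodentate"),
            (165.0, 120.0, "top-hat", "unclassified"),
            (70.0, 10.0, "side-on", "n/a"),
            (110.0, 170.0, "side-on", "n/a"),
            (130.0, 100.0, "borderline", "n/a"),
        ],
    )
    def test_boundary_assignment(self, theta, psi, altitudinal, azimuthal):
        mode = classify_mode(theta, psi)
        assert mode.altitudinal_class == altitudinal
        assert mode.azimuthal_class == azimuthal

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError, match="out of range"):
            classify_mode(-1.0, 10.0)
        with pytest.raises(ValueError, match="out of range"):
            classify_mode(10.0, 181.0)

    @given(
        theta=st.floats(min_value=0.0, max_value=180.0),
        psi=st.floats(min_value=0.0, max_value=180.0),
    )
    def test_classes_consistent_with_windows(self, theta, psi):
        mode = classify_mode(theta, psi)
        if mode.altitudinal_class == "N-bound":
            assert 0 <= theta <= 20
        elif mode.altitudinal_class == "top-hat":
            assert 160 <= theta <= 180
        elif mode.altitudinal_class == "side-on":
            assert 70 <= theta <= 110
        else:
            assert 20 < theta < 70 or 110 < theta < 160
        if mode.azimuthal_class == "symmetrical":
            assert psi <= 10
        elif mode.azimuthal_class == "l-shaped":
            assert 10 < psi <= 30
        elif mode.azimuthal_class == "bidentate":
            assert psi >= 170
        elif mode.azimuthal_class == "monodentate":
            assert 140 <= psi < 170


class TestTwistAngle:
    def test_near_square_planar_is_tetragonal(self):
        # Nitrite and three His nitrogens coplanar with Cu: the two planes
        # coincide, so phi folds to 0/180 and the shape is tetragonal.
        geo = compute_phi(planar_site((170.0, 85.0, -85.0)))
        assert min(geo.phi, 180.0 - geo.phi) == pytest.approx(0.0, abs=1e-6)
        assert geo.shape_label == "tetragonal"
        assert geo.axial_his == "His99"

    def test_trigonal_c3v_site_gives_phi_90(self):
        # Equatorial pair symmetric about the axial azimuth: phi is forced
        # to 90 by symmetry.
        site = make_site(
            SiteSpec(10.0, 5.0, 2.0, phi_target=90.0, randomize_pose=False)
        )
        geo = compute_phi(site)
        assert geo.phi == pytest.approx(90.0, abs=1e-9)
        assert geo.shape_label == "trigonal"

    def test_axial_is_largest_angle(self):
        geo = compute_phi(planar_site((170.0, 85.0, -85.0)))
        assert geo.axial_his == "His99"
        geo = compute_phi(planar_site((85.0, 170.0, -85.0)))
        assert geo.axial_his == "His134"

    def test_six_angles_reported(self, canonical_site):
        geo = compute_phi(canonical_site)
        assert len(geo.angles) == 6
        assert all(0.0 <= a <= 180.0 for a in geo.angles.values())

    def test_axial_tie_warns_and_picks_lower_residue(self):
        site = planar_site((120.0, -120.0, 10.0))  # His99 and His134 tied
        with pytest.warns(UserWarning, match="ambiguous axial"):
            geo = compute_phi(site)
        assert geo.axial_his == "His99"

    def test_cu_o_asymmetry_flag(self):
        site = planar_site()
        geo = compute_phi(site)
        d1, d2 = geo.cu_o_distances
        assert geo.o_asymmetric == (abs(d1 - d2) > 0.3)
        # A strongly l-shaped site has clearly inequivalent oxygens.
        lshaped = make_site(SiteSpec(6.0, 25.0, 2.0, randomize_pose=False))
        assert compute_phi(lshaped).o_asymmetric

    def test_oracle_agreement_on_random_sites(self):
        for spec in random_site_specs(200, seed=13):
            site = make_site(spec)
            assert compute_phi(site).phi == pytest.approx(phi_oracle(site), abs=1e-6)


class TestAnalyzeSite:
    @pytest.mark.parametrize(
        "theta, psi, label",
        [
            (175.0, 174.0, "bidentate top-hat"),
            (5.0, 15.0, "l-shaped N-bound"),
            (90.0, 90.0, "side-on"),
        ],
    )
    def test_generator_round_trip_labels(self, theta, psi, label):
        site = make_site(SiteSpec(theta, psi, 2.2, phi_target=85.0, seed=5))
        assert analyze_site(site).mode.mode_label == label

    def test_rigid_motion_and_o_swap_invariance(self, rigid_motion):
        for spec in random_site_specs(20, seed=14):
            site = make_site(spec)
            ref = analyze_site(site)
            R, t = rigid_motion()
            for variant in (site.transformed(R, t), site.with_swapped_oxygens()):
                rep = analyze_site(variant)
                assert rep.mode.theta == pytest.approx(ref.mode.theta, abs=1e-6)
                assert rep.mode.psi == pytest.approx(ref.mode.psi, abs=1e-6)
                assert rep.coordination.phi == pytest.approx(ref.coordination.phi, abs=1e-6)
                assert rep.mode.mode_label == ref.mode.mode_label
                assert rep.coordination.o_asymmetric == ref.coordination.o_asymmetric

    def test_errors_tagged_with_chain_and_frame(self):
        site = planar_site()
        bad = ActiveSite(
            cu=site.cu,
            his_n=site.his_n,
            nitrite_n=np.array([2.0, 0.0, 0.0]),
            nitrite_o1=np.array([3.0, 0.0, 0.0]),
            nitrite_o2=np.array([4.0, 0.0, 0.0]),
            chain_id="B",
            frame_index=7,
        )
        with pytest.raises(ValueError, match="chain B, frame 7"):
            analyze_site(bad)
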