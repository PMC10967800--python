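"""Surface geometry: SASA, surface mask, SES, volume, roughness."""

import numpy as np
import pytest

from hacsurf.structure import ProteinStructure
from hacsurf.surface import (
    DEFAULT_FD_RADII,
    RoughnessProfile,
    classify_surface_residues,
    fractal_dimension,
    max_sas_reference,
    protein_volume,
    ses_area,
    shrake_rupley_sasa,
    sphere_points,
    surface_exposure_degree,
)
from hacsurf.synthetic import make_backbone_structure, make_sphere_cluster


def _rigid_copy(s, seed=0):
    rng = np.random.default_rng(seed)
    m = rng.standard_normal((3, 3))
    q, _ = np.linalg.qr(m)
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return s.transformed(q, rng.uniform(-20, 20, 3))


class TestShrakeRupley:
    def test_isolated_sphere_closed_form(self, single_sphere):
        area = shrake_rupley_sasa(single_sphere, probe_radius=1.4).total
        closed = 4.0 * np.pi * (1.7 + 1.4) ** 2
        assert area == pytest.approx(closed, rel=1e-6)  # lattice fractions are exact here

    def test_additivity_at_large_separation(self):
        s = make_sphere_cluster([[0, 0, 0], [100, 0, 0]], 1.7)
        area = shrake_rupley_sasa(s).total
        assert area == pytest.approx(2 * 4 * np.pi * 3.1**2, rel=1e-6)

    def test_overlapping_pair_against_mc_rejection_oracle(self):
        # Monte-Carlo oracle: uniform points on each expanded sphere,
        # rejected when inside the neighbour's expanded sphere.
        r, p, d = 1.7, 1.4, 2.0
        centers = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        s = make_sphere_cluster(centers, r)
        area = shrake_rupley_sasa(s).total
        rng = np.random.default_rng(2024)
        R = r + p
        mc = 0.0
        for k, c in enumerate(centers):
            pts = rng.standard_normal((100_000, 3))
            pts /= np.linalg.norm(pts, axis=1)[:, None]
            pts = c + R * pts
            other = centers[1 - k]
            keep = np.linalg.norm(pts - other, axis=1) >= R
            mc += 4 * np.pi * R**2 * keep.mean()
        assert area == pytest.approx(mc, rel=0.02)

    def test_rigid_motion_invariance(self, helix15):
        ref = shrake_rupley_sasa(helix15)
        moved = shrake_rupley_sasa(_rigid_copy(helix15, seed=5))
        np.testing.assert_allclose(
            moved.per_residue_area, ref.per_residue_area, rtol=1e-6, atol=1e-6
        )

    def test_lattice_convergence_to_closed_form(self, fused_pair):
        # analytic two-sphere SASA: each expanded sphere keeps the cap with
        # cos(theta) <= d / (2R)
        r, p, d = 1.7, 1.4, 2.5
        R = r + p
        closed = 2 * 2 * np.pi * R**2 * (1 + d / (2 * R))
        coarse = shrake_rupley_sasa(fused_pair, n_sphere_points=96).total
        fine = shrake_rupley_sasa(fused_pair, n_sphere_points=960).total
        assert abs(fine - closed) / closed < 0.01
        assert abs(fine - closed) <= abs(coarse - closed) + 1e-9

    def test_cross_check_against_biotite(self, helix15):
        # independent Shrake-Rupley implementation, same radii and probe
        import biotite.structure as struc

        atoms = helix15.atoms()
        arr = struc.AtomArray(len(atoms))
        arr.coord = np.array([a.coords for a in atoms], dtype=np.float32)
        arr.element = np.array([a.element.upper() for a in atoms])
        arr.atom_name = np.array([a.name for a in atoms])
        arr.res_id = np.concatenate(
            [[i + 1] * len(r.heavy_atoms()) for i, r in enumerate(helix15.residues)]
        )
        arr.res_name = np.array(
            [r.name for r in helix15.residues for _ in r.heavy_atoms()]
        )
        arr.chain_id = np.array(["A"] * len(atoms))
        radii = np.array([a.vdw_radius for a in atoms], dtype=np.float32)
        ref = struc.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii=radii).sum()
        ours = shrake_rupley_sasa(helix15).total
        assert ours == pytest.approx(ref, rel=0.01)

    def test_invalid_probe_raises(self, single_sphere):
        with pytest.raises(ValueError):
            shrake_rupley_sasa(single_sphere, probe_radius=0.0)

    def test_sphere_points_unit_norm(self):
        pts = sphere_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)


class TestMaxSasReference:
    def test_table_mode_values(self):
        assert max_sas_reference("GLY") == pytest.approx(104.0)
        assert max_sas_reference("TRP") == pytest.approx(285.0)

    def test_computed_mode_ala_agrees_with_table(self):
        computed = max_sas_reference("ALA", mode="computed")
        assert computed == pytest.approx(129.0, rel=0.15)

    def test_unknown_residue_raises(self):
        with pytest.raises(KeyError):
            max_sas_reference("XYZ")


class TestSurfaceMask:
    def test_threshold_boundary_inclusive(self, helix15):
        # a residue exactly at the threshold counts as surface (>=, not >);
        # threshold 0.25 makes the ratio binary-exact
        sasa = shrake_rupley_sasa(helix15)
        ref = max_sas_reference("ALA")
        sasa.per_residue_area[0] = 0.25 * ref
        sasa.per_residue_area[1] = 0.249 * ref
        mask = classify_surface_residues(helix15, sasa, threshold=0.25)
        assert mask.surface_flag[0]
        assert not mask.surface_flag[1]
        assert mask.rel_acc[0] == pytest.approx(0.25)

    def test_extended_tripeptide_centre_is_surface(self):
        tri = make_backbone_structure(["GLY", "ALA", "GLY"], phi=-139.0, psi=135.0)
        sasa = shrake_rupley_sasa(tri)
        mask = classify_surface_residues(tri, sasa)
        assert mask.surface_flag[1]
        assert mask.rel_acc[1] > 0.8

    def test_nonstandard_residues_buried_with_warning(self, fused_pair):
        sasa = shrake_rupley_sasa(fused_pair)
        with pytest.warns(UserWarning, match="nonstandard"):
            mask = classify_surface_residues(fused_pair, sasa)
        assert not mask.surface_flag.any()
        assert np.isnan(mask.rel_acc).all()


class TestSesArea:
    def test_single_sphere_is_its_vdw_sphere(self, single_sphere):
        vdw = 4 * np.pi * 1.7**2
        for probe in (1.0, 1.4, 3.0):
            est = ses_area(single_sphere, probe_radius=probe, voxel=0.25)
            assert est == pytest.approx(vdw, rel=0.02)

    def test_far_pair_additivity(self):
        s = make_sphere_cluster([[0, 0, 0], [50, 0, 0]], 1.7)
        est = ses_area(s, probe_radius=1.4, voxel=0.25)
        assert est == pytest.approx(2 * 4 * np.pi * 1.7**2, rel=0.02)

    def test_fused_pair_against_connolly_closed_form(self, fused_pair):
        # analytic SES of two equal fused spheres: two spherical caps plus
        # the toroidal reentrant seam swept by the rolling probe
        r, p, d = 1.7, 1.4, 2.5
        R = r + p
        a = np.sqrt(R**2 - (d / 2) ** 2)
        alpha = np.arcsin((d / 2) / R)
        analytic = 2 * 2 * np.pi * r**2 * (1 + d / (2 * R)) + 4 * np.pi * p * (
            a * alpha - p * np.sin(alpha)
        )
        est = ses_area(fused_pair, probe_radius=p, voxel=0.25)
        assert est == pytest.approx(analytic, rel=0.03)

    def test_voxel_larger_than_probe_raises(self, single_sphere):
        with pytest.raises(ValueError, match="voxel"):
            ses_area(single_sphere, probe_radius=1.0, voxel=1.2)


class TestFractalDimension:
    def test_smooth_sphere_has_fd_two(self, single_sphere):
        prof = fractal_dimension(single_sphere, voxel=0.5)
        assert prof.fd == pytest.approx(2.0, abs=0.02)
        np.testing.assert_allclose(prof.di, 2.0, atol=0.1)

    def test_default_sweep_has_13_pairs(self, single_sphere):
        prof = fractal_dimension(single_sphere, voxel=0.5)
        assert prof.n_pairs == 13
        assert len(DEFAULT_FD_RADII) == 14
        np.testing.assert_allclose(np.diff(DEFAULT_FD_RADII), 0.2)

    def test_power_law_areas_recover_exponent(self):
        # A(R) = c R^-k plugged into the finite differences gives FD = 2 + k
        radii = DEFAULT_FD_RADII
        for k in (0.15, 0.5):
            prof = RoughnessProfile(radii=radii, ses_areas=3000.0 * radii ** (-k))
            assert prof.fd == pytest.approx(2.0 + k, abs=1e-12)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            RoughnessProfile(radii=np.array([1.0, 1.2]), ses_areas=np.array([10.0, 0.0]))

    def test_fd_in_physical_range_on_fixtures(self, helix15, fused_pair):
        for s in (helix15, fused_pair):
            prof = fractal_dimension(s, voxel=0.5)
            assert 2.0 <= prof.fd <= 3.0


class TestVolumeAndExposure:
    def test_single_sphere_volume(self, single_sphere):
        est = protein_volume(single_sphere, voxel=0.2)
        assert est == pytest.approx(4 / 3 * np.pi * 1.7**3, rel=0.05)

    def test_grid_convergence_on_helix(self, helix15):
        v1 = protein_volume(helix15, voxel=0.5)
        v2 = protein_volume(helix15, voxel=0.25)
        assert v1 == pytest.approx(v2, rel=0.02)

    def test_exposure_degree_closed_form(self):
        sas = 4 * np.pi * 3.1**2
        vol = 4 / 3 * np.pi * 1.7**3
        assert surface_exposure_degree(sas, vol) == pytest.approx(5.868, abs=0.01)

    def test_exposure_scales_inversely_with_size(self, helix15):
        # doubling all lengths doubles area/volume ratio denominators: s_sf halves
        doubled = ProteinStructure(
            "double",
            [r for r in _scaled_copy(helix15, 2.0).residues],
        )
        v, v2 = protein_volume(helix15, 0.25), protein_volume(doubled, 0.5)
        s, s2 = (
            shrake_rupley_sasa(helix15, probe_radius=1.4).total,
            shrake_rupley_sasa(doubled, probe_radius=2.8).total,
        )
        ratio = surface_exposure_degree(s, v) / surface_exposure_degree(s2, v2)
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            surface_exposure_degree(100.0, 0.0)


def _scaled_copy(s, factor):
    from dataclasses import replace

    residues = []
    for r in s.residues:
        atoms = [
            replace(a, coords=np.asarray(a.coords) * factor, vdw_radius=a.vdw_radius * factor)
            for a in r.atoms
        ]
        residues.append(type(r)(r.name, r.seq_index, atoms))
    return ProteinStructure(s.id, residues)
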