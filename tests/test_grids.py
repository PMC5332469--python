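"""2D membrane property maps: thickness, APL, S_CD, radial profile, psi6."""

import numpy as np
import pytest

import lipidshell as ls
from lipidshell.core_io import Trajectory
from lipidshell.grids import (
    _bin_indices,
    _carbon_rows,
    _phosphate_rows,
    psi6,
    scd_samples,
    voronoi_areas_periodic,
)


class TestThickness:
    def test_flat_bilayer_exact(self, flat_bilayer):
        traj, topo, la_ = flat_bilayer
        la = ls.assign_leaflets(traj, topo)
        g = ls.thickness_map(traj, topo, la, "pp", 10, 10, radial_cutoff=None)
        assert np.allclose(g.values, 3.5, atol=1e-12)
        gh = ls.thickness_map(traj, topo, la, "hydrophobic", 10, 10, radial_cutoff=None)
        assert np.allclose(gh.values, 2.9, atol=1e-12)

    def test_noisy_recovery_within_se(self, noisy_bilayer):
        """sigma=0.05 nm noise, 200 frames: global mean within 0.005 nm and
        cells within 3 SE."""
        traj, topo, gt = noisy_bilayer
        la = ls.assign_leaflets(traj, topo)
        g = ls.thickness_map(traj, topo, la, "pp", 8, 8, radial_cutoff=None)
        assert np.nanmean(g.values) == pytest.approx(gt.thickness_pp, abs=0.005)
        # per-cell: ~ n samples per surface cell; thickness SE = sqrt(2) * sigma/sqrt(n)
        n_cell = g.counts / (2 * 64)  # counts pooled over leaflets and cells
        n_per = traj.n_frames * 64 / 64.0
        se = np.sqrt(2.0) * 0.05 / np.sqrt(n_per)
        assert np.abs(g.values - gt.thickness_pp).max() < 5 * se  # cells vary in n

    def test_rigid_z_translation_invariance(self, noisy_bilayer):
        traj, topo, _ = noisy_bilayer
        la = ls.assign_leaflets(traj, topo)
        g1 = ls.thickness_map(traj, topo, la, "pp", 6, 6, radial_cutoff=None)
        shifted = Trajectory(traj.coords + np.array([0, 0, 0.7]), traj.box)
        g2 = ls.thickness_map(shifted, topo, la, "pp", 6, 6, radial_cutoff=None)
        assert np.allclose(g1.values, g2.values, atol=1e-12)

    def test_z_flip_keeps_thickness(self, noisy_bilayer):
        traj, topo, _ = noisy_bilayer
        la = ls.assign_leaflets(traj, topo)
        g1 = ls.thickness_map(traj, topo, la, "pp", 6, 6, radial_cutoff=None)
        zc = traj.box[0][2]
        flipped = Trajectory(
            traj.coords * np.array([1, 1, -1.0]) + np.array([0, 0, zc]), traj.box
        )
        laf = ls.assign_leaflets(flipped, topo)
        g2 = ls.thickness_map(flipped, topo, laf, "pp", 6, 6, radial_cutoff=None)
        assert np.allclose(g1.values, g2.values, atol=1e-12)

    def test_brute_force_oracle_bitwise(self):
        """16 lipids, 4x4 grid: per-sample binning oracle matches bit for bit."""
        spec = ls.SyntheticBilayerSpec(
            n_lipids_per_leaflet=16, n_frames=3, seed=13,
            positional_noise_sigma=0.05, site_jitter_sigma=0.05,
        )
        traj, topo, _ = ls.generate_bilayer(spec)
        la = ls.assign_leaflets(traj, topo)
        g = ls.thickness_map(traj, topo, la, "pp", 4, 4, radial_cutoff=None)
        extent = tuple(traj.box.mean(axis=0)[:2])
        surf = {}
        for side in (1, -1):
            rids = la.residue_ids[la.leaflet == side]
            rows = _phosphate_rows(topo, rids)
            zsum = np.zeros((4, 4))
            cnt = np.zeros((4, 4))
            for f in range(traj.n_frames):
                for r in rows:
                    p = traj.coords[f, r]
                    ix, iy = _bin_indices(p[None, :2], extent, 4, 4)
                    zsum[ix[0], iy[0]] += p[2]
                    cnt[ix[0], iy[0]] += 1.0
            surf[side] = zsum / cnt
        assert np.array_equal(surf[1] - surf[-1], g.values)


class TestApl:
    def test_area_conservation(self):
        rng = np.random.default_rng(5)
        for n in (10, 50, 200):
            xy = rng.uniform(0, 7, (n, 2))
            areas = voronoi_areas_periodic(xy, (7.0, 7.0))
            assert abs(areas.sum() - 49.0) / 49.0 < 1e-9

    def test_square_lattice_exact(self, flat_bilayer):
        traj, topo, gt = flat_bilayer
        la = ls.assign_leaflets(traj, topo)
        g = ls.apl_map(traj, topo, la, "upper", 6, 6, radial_cutoff=None)
        assert np.allclose(g.values, gt.apl, rtol=1e-9)

    def test_jittered_lattice_mean_conserved(self, noisy_bilayer):
        traj, topo, gt = noisy_bilayer
        la = ls.assign_leaflets(traj, topo)
        one = Trajectory(traj.coords[:1], traj.box[:1])
        rids = la.residue_ids[la.leaflet == 1]
        prow = _phosphate_rows(topo, rids)
        xy = one.coords[0, prow, :2]
        areas = voronoi_areas_periodic(xy, gt.box_xy)
        assert areas.mean() == pytest.approx(
            gt.box_xy[0] * gt.box_xy[1] / len(rids), rel=1e-9
        )

    def test_collinear_degenerate_error(self):
        xy = np.column_stack([np.linspace(1, 4, 5), np.full(5, 2.0)])
        with pytest.raises(ValueError):
            voronoi_areas_periodic(xy[:2], (5.0, 5.0))

    def test_two_domain_recovery(self):
        """Gel-packed annulus (0.48 nm^2) in fluid bulk (0.60 nm^2), each
        recovered within 5% in seam-free measurement bands."""
        spec = ls.SyntheticBilayerSpec(
            n_lipids_per_leaflet=256, apl_target=0.60, n_frames=200, seed=21,
            positional_noise_sigma=0.02, site_jitter_sigma=0.02,
            inclusion=ls.InclusionSpec(
                radius=1.2, static=True, annulus_apl=0.48,
                annulus_domain_width=3.0,
            ),
        )
        traj, topo, gt = ls.generate_inclusion_system(spec)
        la = ls.assign_leaflets(traj, topo)
        g = ls.apl_map(traj, topo, la, "upper", 80, 80, radial_cutoff=None)
        xc, yc = g.cell_centers()
        cx, cy = gt.inclusion_center
        r = np.hypot(xc[:, None] - cx, yc[None, :] - cy)
        half = min(gt.box_xy) / 2
        ann = (r >= 2.6) & (r < 3.4)
        bulk = (r >= 5.6) & (r < half - 0.1)
        assert np.nanmean(g.values[ann]) == pytest.approx(0.48, rel=0.05)
        assert np.nanmean(g.values[bulk]) == pytest.approx(0.60, rel=0.05)

    def test_brute_force_oracle_bitwise(self):
        """16 lipids, 4x4 grid: explicit nearest-image ownership oracle."""
        spec = ls.SyntheticBilayerSpec(
            n_lipids_per_leaflet=16, n_frames=2, seed=13,
            positional_noise_sigma=0.05, site_jitter_sigma=0.05,
        )
        traj, topo, _ = ls.generate_bilayer(spec)
        la = ls.assign_leaflets(traj, topo)
        g = ls.apl_map(traj, topo, la, "upper", 4, 4, radial_cutoff=None)
        extent = tuple(traj.box.mean(axis=0)[:2])
        bx, by = extent
        rids = la.residue_ids[la.leaflet == 1]
        prow = _phosphate_rows(topo, rids)
        xc = (bx / 4) * (np.arange(4) + 0.5)
        yc = (by / 4) * (np.arange(4) + 0.5)
        vsum = np.zeros((4, 4))
        cnt = np.zeros((4, 4))
        for f in range(traj.n_frames):
            pos = traj.coords[f, prow, :]
            xy = np.column_stack([np.mod(pos[:, 0], bx), np.mod(pos[:, 1], by)])
            areas = voronoi_areas_periodic(xy, extent)
            for i in range(4):
                for j in range(4):
                    best, bd = -1, np.inf
                    for li in range(len(xy)):
                        for sx in (-1, 0, 1):
                            for sy in (-1, 0, 1):
                                d = np.hypot(xy[li, 0] + sx * bx - xc[i],
                                             xy[li, 1] + sy * by - yc[j])
                                if d < bd:
                                    bd, best = d, li
                    vsum[i, j] += areas[best]
                    cnt[i, j] += 1.0
        assert np.array_equal(vsum / cnt, g.values)


class TestScd:
    def test_all_trans_along_normal(self, flat_bilayer):
        """Chains exactly along z: reconstructed C-H perpendicular to z,
        S_CD = -0.5, reported 0.5 everywhere."""
        traj, topo, _ = flat_bilayer
        la = ls.assign_leaflets(traj, topo)
        for leaf in ("upper", "lower"):
            m = ls.scd_map(traj, topo, la, ls.ScdSpec(7, "both", leaf),
                           6, 6, radial_cutoff=None)
            vals = m.values[np.isfinite(m.values)]
            assert np.allclose(vals, 0.5, atol=1e-12)
        ms = ls.scd_map(traj, topo, la, ls.ScdSpec(7, "both", "upper"),
                        6, 6, radial_cutoff=None, signed=True)
        assert np.allclose(ms.values[np.isfinite(ms.values)], -0.5, atol=1e-12)

    def test_isotropic_null(self):
        """Isotropic axes: |S_CD| < 0.02 at 1e5 samples."""
        rng = np.random.default_rng(0)
        n = 100000
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        s, valid = scd_samples(np.zeros((n, 3)), v)
        assert valid.all()
        assert abs(np.mean(s)) < 0.02

    def test_axis_to_ch_factor_against_tetrahedral_geometry(self):
        """The orthonormal-pair reconstruction equals the azimuth-averaged
        ideal tetrahedral C-H pair: numerically validate the -1/2 factor."""
        rng = np.random.default_rng(1)
        n = 200000
        a = rng.normal(size=(n, 3))
        a /= np.linalg.norm(a, axis=1, keepdims=True)
        # explicit tetrahedral H pair: both perpendicular to the axis,
        # separated by the tetrahedral angle, random azimuth
        ref = np.where(np.abs(a[:, 2:3]) < 0.9, [[0, 0, 1.0]], [[1.0, 0, 0]])
        e1 = np.cross(a, ref)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(a, e1)
        phi = rng.uniform(0, 2 * np.pi, n)
        delta = np.arccos(-1.0 / 3.0)  # 109.47 deg between the two C-H bonds
        h1 = np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2
        h2 = np.cos(phi + delta)[:, None] * e1 + np.sin(phi + delta)[:, None] * e2
        p2 = lambda c: 0.5 * (3 * c**2 - 1)
        s_tetra = 0.5 * (p2(h1[:, 2]) + p2(h2[:, 2]))
        s_pair, _ = scd_samples(np.zeros((n, 3)), a)
        # identical in expectation; -1/2 relation holds per-sample for the pair
        assert np.allclose(s_pair, -0.5 * p2(a[:, 2]), atol=1e-12)
        se = np.std(s_tetra - s_pair) / np.sqrt(n)
        assert np.mean(s_tetra) == pytest.approx(np.mean(s_pair), abs=4 * se)

    def test_imposed_order_recovered(self):
        """Generator chain order S -> measured |S_CD| = S/2 within 3 SE."""
        spec = ls.SyntheticBilayerSpec(
            n_lipids_per_leaflet=64, n_frames=100, seed=9,
            positional_noise_sigma=0.0,
        )
        traj, topo, gt = ls.generate_bilayer(spec)
        la = ls.assign_leaflets(traj, topo)
        m = ls.scd_map(traj, topo, la, ls.ScdSpec(7, "both", "upper"),
                       1, 1, radial_cutoff=None)
        n = m.counts.sum()
        assert m.values[0, 0] == pytest.approx(gt.scd, abs=3 * np.sqrt(0.1 / n))

    def test_signed_values_bounded(self, noisy_bilayer):
        traj, topo, _ = noisy_bilayer
        la = ls.assign_leaflets(traj, topo)
        one = Trajectory(traj.coords[:5], traj.box[:5])
        m = ls.scd_map(one, topo, la, ls.ScdSpec(7, "both", "upper"),
                       8, 8, radial_cutoff=None, signed=True)
        v = m.values[np.isfinite(m.values)]
        assert v.min() >= -0.5 - 1e-12 and v.max() <= 1.0 + 1e-12

    def test_missing_neighbor_carbon_error(self, flat_bilayer):
        traj, topo, _ = flat_bilayer
        la = ls.assign_leaflets(traj, topo)
        L = 14
        with pytest.raises(ValueError, match="carbon"):
            ls.scd_map(traj, topo, la, ls.ScdSpec(L, "both", "upper"), 4, 4)

    def test_brute_force_oracle_bitwise(self):
        spec = ls.SyntheticBilayerSpec(
            n_lipids_per_leaflet=16, n_frames=3, seed=13,
            positional_noise_sigma=0.05, site_jitter_sigma=0.05,
        )
        traj, topo, _ = ls.generate_bilayer(spec)
        la = ls.assign_leaflets(traj, topo)
        m = ls.scd_map(traj, topo, la, ls.ScdSpec(7, "sn1", "upper"),
                       4, 4, radial_cutoff=None)
        extent = tuple(traj.box.mean(axis=0)[:2])
        rids = la.residue_ids[la.leaflet == 1]
        rm1 = _carbon_rows(topo, rids, 6, "sn1")
        r0 = _carbon_rows(topo, rids, 7, "sn1")
        rp1 = _carbon_rows(topo, rids, 8, "sn1")
        ssum = np.zeros((4, 4))
        cnt = np.zeros((4, 4))
        for f in range(traj.n_frames):
            s, valid = scd_samples(traj.coords[f, rm1], traj.coords[f, rp1],
                                   traj.box[f])
            for i in range(len(rids)):
                if not valid[i]:
                    continue
                ix, iy = _bin_indices(traj.coords[f, r0[i], :2][None, :],
                                      extent, 4, 4)
                ssum[ix[0], iy[0]] += s[i]
                cnt[ix[0], iy[0]] += 1.0
        assert np.array_equal(np.abs(ssum / cnt), m.values)


class TestRadialProfile:
    def test_uniform_map_constant(self):
        g = ls.PropertyGrid2D(np.full((20, 20), 2.5), np.ones((20, 20)),
                              (10.0, 10.0), "thickness_pp", "nm")
        r, prof = ls.radial_profile(g, dr=0.5)
        assert np.allclose(prof[np.isfinite(prof)], 2.5)

    def test_dr_larger_than_map_radius(self):
        g = ls.PropertyGrid2D(np.full((10, 10), 1.5), np.ones((10, 10)),
                              (5.0, 5.0), "apl", "nm^2")
        r, prof = ls.radial_profile(g, dr=100.0)
        assert len(prof) == 1
        assert prof[0] == pytest.approx(1.5)

    def test_bad_dr(self):
        g = ls.PropertyGrid2D(np.ones((4, 4)), np.ones((4, 4)), (2.0, 2.0), "apl", "nm^2")
        with pytest.raises(ValueError):
            ls.radial_profile(g, dr=0.0)

    def test_thicker_annulus_elevated(self):
        """Annulus with larger P-P separation shows up in the radial profile."""
        spec = ls.SyntheticBilayerSpec(
            n_lipids_per_leaflet=196, apl_target=0.60, n_frames=30, seed=23,
            positional_noise_sigma=0.02, site_jitter_sigma=0.02,
            inclusion=ls.InclusionSpec(
                radius=1.2, static=True, annulus_apl=0.48,
                annulus_domain_width=2.2, annulus_half_thickness_pp=1.95,
            ),
        )
        traj, topo, gt = ls.generate_inclusion_system(spec)
        la = ls.assign_leaflets(traj, topo)
        g = ls.thickness_map(traj, topo, la, "pp", 60, 60, radial_cutoff=None)
        r, prof = ls.radial_profile(g, gt.inclusion_center, dr=0.4)
        in_ann = (r > 1.8) & (r < 3.0)
        in_bulk = (r > 4.2) & (r < 5.2)
        assert np.nanmean(prof[in_ann]) == pytest.approx(
            gt.annulus["thickness_pp"], abs=0.05
        )
        assert np.nanmean(prof[in_bulk]) == pytest.approx(gt.thickness_pp, abs=0.05)


class TestHexatic:
    def test_perfect_hexagonal_lattice(self):
        from lipidshell.synthetic import _hex_lattice

        pts, bx, by, _ = _hex_lattice(64, 0.24)
        a = np.sqrt(2 * 0.24 / np.sqrt(3))
        v = psi6(pts, (bx, by), 1.2 * a)
        assert np.abs(v - 1.0).max() < 1e-12

    def test_square_lattice_low(self):
        n = 10
        a = 1.0
        ix, iy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        pts = np.column_stack([ix.ravel() + 0.5, iy.ravel() + 0.5])
        v = psi6(pts, (float(n), float(n)), 1.1)  # 4-neighbor cutoff
        assert np.nanmax(v) < 0.1

    def test_uniform_random_low(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 10, (200, 2))
        v = psi6(pts, (10.0, 10.0), 0.9)
        assert np.nanmean(v) < 0.45

    def test_needs_seven_sites(self):
        with pytest.raises(ValueError):
            psi6(np.zeros((4, 2)), (1.0, 1.0), 0.5)
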