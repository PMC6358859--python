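"""Generator tests: geometry, determinism, loading bookkeeping, renders, traces."""

import math

import numpy as np
import pytest

from poreloadkit import bulk, synthetic as syn


def voxelized_porosity(net, voxel_nm):
    """Independent oracle: count voxel centers falling inside any open body."""
    n = int(net.domain_size / voxel_nm)
    grid = np.zeros((n, n, n), dtype=bool)
    radii = net.open_diameters / 2.0
    radii[net.interparticle] = 0.0
    for c, r in zip(net.centers, radii):
        if r <= 0:
            continue
        lo = np.maximum(((c - r) / voxel_nm).astype(int), 0)
        hi = np.minimum(((c + r) / voxel_nm).astype(int) + 2, n)
        xs = (np.arange(lo[0], hi[0]) + 0.5) * voxel_nm - c[0]
        ys = (np.arange(lo[1], hi[1]) + 0.5) * voxel_nm - c[1]
        zs = (np.arange(lo[2], hi[2]) + 0.5) * voxel_nm - c[2]
        d2 = xs[:, None, None] ** 2 + ys[None, :, None] ** 2 + zs[None, None, :] ** 2
        grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 < r * r
    return grid.mean()


class TestGenerateNetwork:
    def test_porosity_hits_target_voxelized(self):
        """60% target porosity in a 5 µm domain, checked on a voxel grid."""
        net = syn.generate_network(
            syn.NetworkSpec(seed=3, domain_size=5000.0, target_porosity=0.60)
        )
        assert abs(voxelized_porosity(net, 20.0) - 0.60) < 0.02

    def test_analytic_porosity_exact(self, dense_network):
        assert abs(dense_network.porosity - 0.60) < 5e-3

    def test_deterministic_for_fixed_seed(self):
        spec = syn.NetworkSpec(seed=11)
        a, b = syn.generate_network(spec), syn.generate_network(spec)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.body_diameters, b.body_diameters)
        assert np.array_equal(a.throat_diameters, b.throat_diameters)

    def test_single_body_degenerate(self):
        net = syn.generate_network(syn.NetworkSpec(seed=0, n_bodies=1))
        assert net.n_bodies == 1
        assert np.any(net.throats[:, 1] == syn.EXTERIOR)

    def test_every_body_has_a_throat(self, dense_network):
        degree = np.zeros(dense_network.n_bodies, dtype=int)
        for i, j in dense_network.throats:
            degree[i] += 1
            if j != syn.EXTERIOR:
                degree[j] += 1
        assert (degree >= 1).all()

    def test_throat_never_wider_than_bodies(self, dense_network):
        t = dense_network.throats
        inner = t[:, 1] != syn.EXTERIOR
        d = dense_network.body_diameters
        lim = np.where(inner, np.minimum(d[t[:, 0]], d[np.where(inner, t[:, 1], 0)]), d[t[:, 0]])
        assert (dense_network.throat_diameters <= lim + 1e-9).all()

    def test_infeasible_porosity_raises(self):
        with pytest.raises(syn.InfeasiblePorosityError):
            syn.generate_network(
                syn.NetworkSpec(seed=0, target_porosity=0.72, min_wall=20.0)
            )

    def test_walls_respect_minimum(self, sparse_network):
        from scipy.spatial import cKDTree

        net = sparse_network
        tree = cKDTree(net.centers)
        pairs = np.asarray(sorted(tree.query_pairs(r=300.0)), dtype=int)
        dist = np.linalg.norm(net.centers[pairs[:, 0]] - net.centers[pairs[:, 1]], axis=1)
        gap = dist - (net.body_diameters[pairs[:, 0]] + net.body_diameters[pairs[:, 1]]) / 2
        assert gap.min() >= 12.0 - 1e-6


class TestApplyLoading:
    def test_zero_fill_is_identity(self, dense_network):
        out = syn.apply_loading(dense_network, syn.LoadingMode("pore_filling", 0.0))
        assert np.array_equal(out.deposit, dense_network.deposit)
        assert out.pore_volume == dense_network.pore_volume

    def test_full_fill_closes_everything(self, dense_network):
        out = syn.apply_loading(dense_network, syn.LoadingMode("pore_filling", 1.0))
        assert out.pore_volume == 0.0
        assert (out.open_diameters == 0.0).all()

    @pytest.mark.parametrize("fill", [0.1, 0.33, 0.5, 0.85])
    def test_volume_conservation(self, dense_network, fill):
        """Skeleton + deposit + remaining pore volume is invariant (to 1e-9)."""
        v0 = dense_network.pore_volume
        out = syn.apply_loading(dense_network, syn.LoadingMode("pore_filling", fill))
        assert abs(out.deposit_volume + out.pore_volume - v0) / v0 < 1e-9
        assert abs(out.deposit_volume / v0 - fill) < 1e-6

    def test_smallest_pores_close_first(self, dense_network):
        out = syn.apply_loading(dense_network, syn.LoadingMode("pore_filling", 0.5))
        closed = out.open_diameters == 0
        if closed.any() and (~closed).any():
            assert dense_network.body_diameters[closed].max() <= \
                dense_network.body_diameters[~closed].min() + 1e-9

    def test_surface_blocking_reachability_oracle(self, dense_network):
        """Blocked-off volume >= fill fraction, by an independent BFS."""
        out = syn.apply_loading(
            dense_network, syn.LoadingMode("surface_blocking", 0.5), seed=3
        )
        # brute-force reachability, written independently of the library BFS
        adj = {}
        exterior_open = []
        for (i, j), d, b in zip(out.throats, out.throat_diameters, out.blocked):
            if b:
                continue
            if j == syn.EXTERIOR:
                exterior_open.append(i)
            else:
                adj.setdefault(i, []).append(j)
                adj.setdefault(j, []).append(i)
        seen = set()
        stack = list(exterior_open)
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            stack.extend(adj.get(k, []))
        intra = ~out.interparticle
        vols = out.body_volumes
        reach_vol = sum(vols[k] for k in seen if intra[k])
        assert reach_vol <= 0.5 * dense_network.intraparticle_volume

    def test_surface_blocking_preserves_bodies_and_adds_voids(self, dense_network):
        out = syn.apply_loading(
            dense_network, syn.LoadingMode("surface_blocking", 0.5), seed=3
        )
        n0 = dense_network.n_bodies
        assert np.array_equal(out.body_diameters[:n0], dense_network.body_diameters)
        voids = out.body_diameters[out.interparticle]
        assert len(voids) > 0 and voids.min() > 500.0


class TestRenderCrossSection:
    def test_artifact_free_render_is_two_level(self, clean_render):
        img, _ = clean_render
        assert len(np.unique(img.pixels)) == 2

    def test_area_fraction_matches_analytic_slice_porosity(self, dense_network, clean_render):
        img, mask = clean_render
        analytic = syn.slice_porosity_analytic(dense_network, "z", 1500.0)
        assert abs(mask.porosity_2d - analytic) < 0.01

    def test_curtaining_adds_columnwise_energy(self, dense_network, clean_render, noisy_render):
        rs = syn.RenderSpec(
            pixel_size=dense_network.domain_size / 512, image_size=(512, 512),
            seed=5, curtain_amplitude=15.0,
        )
        img_s, _ = syn.render_cross_section(dense_network, "z", 1500.0, rs)
        img_c, _ = clean_render
        colvar = lambda a: np.var(a.mean(axis=0))
        assert colvar(img_s.pixels) > colvar(img_c.pixels)

    def test_stereology_many_slices(self, dense_network):
        """Mean 2D porosity over >= 50 random slices tracks 3D porosity (±3 pp)."""
        rng = np.random.default_rng(9)
        pors = [
            syn.slice_porosity_analytic(
                dense_network, "z", rng.uniform(0.1, 0.9) * dense_network.domain_size
            )
            for _ in range(60)
        ]
        assert abs(np.mean(pors) - dense_network.porosity) < 0.03

    def test_plane_outside_domain_raises(self, dense_network):
        rs = syn.RenderSpec(seed=0)
        with pytest.raises(ValueError):
            syn.render_cross_section(dense_network, "z", -5.0, rs)

    def test_render_deterministic(self, dense_network):
        rs = syn.RenderSpec(seed=12, noise_sd=8.0, curtain_amplitude=10.0)
        a, _ = syn.render_cross_section(dense_network, "z", 1200.0, rs)
        b, _ = syn.render_cross_section(dense_network, "z", 1200.0, rs)
        assert np.array_equal(a.pixels, b.pixels)


class TestTraces:
    def test_tga_flat_when_nothing_degrades(self):
        refs = syn.TGAReferenceSet(f_material=0.0, f_carrier=0.5)
        tr = syn.simulate_tga(50.0, 0.0, refs)
        assert np.allclose(tr.mass, tr.mass[0])

    def test_tga_pure_material_total_loss(self):
        refs = syn.TGAReferenceSet(f_material=0.8, f_carrier=0.03)
        tr = syn.simulate_tga(100.0, 0.0, refs)
        assert tr.window_loss() == pytest.approx(100.0 * 0.8, rel=1e-12)

    def test_tga_roundtrip_zero_noise(self):
        refs = syn.TGAReferenceSet(f_material=0.9, f_carrier=0.03)
        tr = syn.simulate_tga(25.0, 75.0, refs)
        res = bulk.tga_content_from_trace(tr, refs)
        assert res.DL_est == pytest.approx(0.25, abs=1e-10)

    def test_sorption_zero_duration_zero_mass(self):
        props = bulk.LiquidProps(999.1, 0.69, 50.8)
        tr = syn.simulate_sorption(props, 30.0, 1e-16, duration=0.0, n_points=1)
        assert tr.mass[0] == 0.0

    def test_sorption_perfect_wetting_slope(self):
        """cos(0) = 1: slope of m² vs t equals c·ρ²·σ/η in SI."""
        props = bulk.LiquidProps(654.8, 0.294, 17.9)
        c = 2.5e-16
        tr = syn.simulate_sorption(props, 0.0, c)
        m2 = (tr.mass * 1e-3) ** 2
        slope = np.polyfit(tr.time, m2, 1)[0]
        expected = c * props.density**2 * (props.surface_tension * 1e-3) / (props.viscosity * 1e-3)
        assert slope == pytest.approx(expected, rel=1e-9)

    def test_sorption_nonwetting_gives_zero_uptake(self):
        props = bulk.LiquidProps(1000.0, 1.0, 50.0)
        tr = syn.simulate_sorption(props, 95.0, 1e-16)
        assert (tr.mass == 0.0).all()

    def test_table1_bsa_low_roundtrip(self):
        """Water (BSA-low): ρ=999.1, η=0.69, σ=50.8 at θ=66.3° recovers 66.3°."""
        props, theta = bulk.TABLE1_LIQUIDS["BSA-low"]
        tr = syn.simulate_sorption(props, theta, 1e-16)
        rec = bulk.washburn_contact_angle(tr, props, 1e-16)
        assert rec == pytest.approx(66.3, abs=0.1)
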