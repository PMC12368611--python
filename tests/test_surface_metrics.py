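"""Surface sampling, radiality, thickness, filtering, and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortexdti.core import ScalarVolume
from cortexdti.phantom import make_shell_phantom, make_slab_phantom
from cortexdti.surface_metrics import (
    apply_vertex_filter,
    build_vertex_table,
    compute_radiality,
    compute_thickness,
    high_radiality_fraction,
    sample_to_vertices,
    summarize_regions,
    vertex_normals,
)


class TestVertexNormals:
    def test_flat_slab_normals_are_plus_z(self, slab):
        surfaces, _ = slab
        n = vertex_normals(surfaces.vertices_mid, surfaces.faces)
        assert np.allclose(n, [0.0, 0.0, 1.0], atol=1e-12)

    @pytest.mark.parametrize("subdivisions, max_deg", [(3, 1.0), (4, 0.5)])
    def test_icosphere_normals_are_nearly_radial(self, subdivisions,
                                                 max_deg):
        """Brute-force angle check over all vertices: area-weighted normals
        converge to the radial direction as the mesh is refined."""
        surfaces, _ = make_shell_phantom(subdivisions=subdivisions)
        v = surfaces.vertices_mid
        n = vertex_normals(v, surfaces.faces)
        radial = v / np.linalg.norm(v, axis=1, keepdims=True)
        angles = np.degrees(np.arccos(np.clip(
            np.einsum("ij,ij->i", n, radial), -1, 1)))
        assert angles.max() <= max_deg
        assert np.median(angles) <= max_deg / 3

    def test_reversed_faces_flip_normals_but_not_radiality(self, slab):
        surfaces, _ = slab
        flipped = surfaces.faces[:, ::-1]
        n1 = vertex_normals(surfaces.vertices_mid, surfaces.faces)
        n2 = vertex_normals(surfaces.vertices_mid, flipped)
        assert np.allclose(n1, -n2, atol=1e-12)
        e1 = np.tile([0.0, 0.0, 1.0], (len(n1), 1))
        assert np.allclose(compute_radiality(e1, n1),
                           compute_radiality(e1, n2))

    def test_isolated_vertex_gets_nan_normal(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 5, 5.0]])
        faces = np.array([[0, 1, 2]])
        n = vertex_normals(verts, faces)
        assert np.isnan(n[3]).all()
        assert np.allclose(n[0], [0, 0, 1])


class TestSampling:
    def test_vertex_at_voxel_center_gets_that_voxel(self):
        values = np.arange(27.0).reshape(3, 3, 3)
        vol = ScalarVolume(values=values, affine=np.eye(4),
                           mask=np.ones((3, 3, 3), bool))
        got, ok = sample_to_vertices(vol, np.array([[1.0, 2.0, 0.0]]))
        assert ok.all()
        assert got[0] == values[1, 2, 0]

    def test_uniform_volume_gives_constant(self, slab):
        surfaces, tv = slab
        vol = ScalarVolume(values=np.full(tv.shape, 7.5), affine=tv.affine,
                           mask=tv.mask)
        got, ok = sample_to_vertices(vol, surfaces.vertices_mid)
        assert np.all(got[ok] == 7.5)

    def test_outside_grid_vertices_are_excluded(self, slab):
        surfaces, tv = slab
        vol = ScalarVolume(values=np.ones(tv.shape), affine=tv.affine,
                           mask=tv.mask)
        far = np.array([[1e4, 1e4, 1e4]])
        got, ok = sample_to_vertices(vol, far)
        assert not ok[0]
        assert np.isnan(got[0])

    def test_matches_exhaustive_nearest_voxel_oracle(self, slab, rng):
        """Every sampled vertex value equals a brute-force nearest-centre
        search over all voxel centres (half-away-from-zero rounding)."""
        surfaces, tv = slab
        values = rng.normal(size=tv.shape)
        vol = ScalarVolume(values=values, affine=tv.affine, mask=tv.mask)
        got, ok = sample_to_vertices(vol, surfaces.vertices_mid)

        # oracle: enumerate voxel centres in world space; a vertex
        # equidistant from several centres may take any of them
        idx = np.indices(tv.shape).reshape(3, -1).T
        centers = idx * tv.affine[0, 0] + tv.affine[:3, 3]
        for v, g, o in zip(surfaces.vertices_mid, got, ok):
            d = np.linalg.norm(centers - v, axis=1)
            nearest = idx[d <= d.min() + 1e-9]
            masked = [tuple(b) for b in nearest if tv.mask[tuple(b)]]
            if len(masked) == len(nearest) and masked:
                assert o and any(g == values[b] for b in masked)

    def test_singular_affine_raises(self, slab):
        surfaces, tv = slab
        bad = np.zeros((4, 4))
        vol = ScalarVolume(values=np.ones(tv.shape), affine=bad, mask=tv.mask)
        with pytest.raises(ValueError, match="singular"):
            sample_to_vertices(vol, surfaces.vertices_mid)


class TestRadiality:
    @pytest.mark.parametrize("angle, expected",
                             [(0.0, 1.0), (60.0, 0.5), (90.0, 0.0)])
    def test_known_angles(self, angle, expected):
        a = np.deg2rad(angle)
        e1 = np.array([[np.sin(a), 0.0, np.cos(a)]])
        n = np.array([[0.0, 0.0, 1.0]])
        assert compute_radiality(e1, n)[0] == pytest.approx(expected,
                                                            abs=1e-12)

    def test_zero_vector_excluded(self):
        r = compute_radiality(np.zeros((1, 3)), np.array([[0, 0, 1.0]]))
        assert np.isnan(r[0])

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_sign_invariance(self, seed):
        rng = np.random.default_rng(seed)
        e1 = rng.normal(size=(5, 3))
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        n = rng.normal(size=(5, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        base = compute_radiality(e1, n)
        assert np.allclose(base, compute_radiality(-e1, n))
        assert np.allclose(base, compute_radiality(e1, -n))
        assert np.all((base >= 0) & (base <= 1))


class TestThickness:
    def test_known_distances(self):
        from cortexdti.core import CorticalSurfaceSet
        inner = np.array([[0, 0, 0], [1, 2, 3.0]])
        outer = np.array([[0, 0, 2.5], [2, 4, 5.0]])
        s = CorticalSurfaceSet(
            vertices_inner=inner, vertices_mid=(inner + outer) / 2,
            vertices_outer=outer, faces=np.empty((0, 3), int),
            hemisphere_label=np.array(["left", "right"]),
            lobe_label=np.array(["frontal", "frontal"]))
        assert np.allclose(compute_thickness(s), [2.5, 3.0])

    def test_concentric_spheres(self):
        surfaces, _ = make_shell_phantom(inner_radius_mm=40.0,
                                         thickness_mm=2.9, subdivisions=2)
        assert np.allclose(compute_thickness(surfaces), 2.9, atol=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_rigid_motion_invariance(self, seed):
        surfaces, _ = make_slab_phantom(extent_mm=6.0, voxel_mm=1.5)
        rng = np.random.default_rng(seed)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = rng.uniform(0, np.pi)
        k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        r = np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)
        shift = rng.normal(scale=10, size=3)
        from dataclasses import replace
        moved = replace(
            surfaces,
            vertices_inner=surfaces.vertices_inner @ r.T + shift,
            vertices_mid=surfaces.vertices_mid @ r.T + shift,
            vertices_outer=surfaces.vertices_outer @ r.T + shift)
        assert np.allclose(compute_thickness(moved),
                           compute_thickness(surfaces), atol=1e-9)


class TestVertexFilter:
    @pytest.mark.parametrize("md, fa, expect_included", [
        (1.6e-3, 0.10, False),      # MD above threshold
        (1.0e-3, 0.31, False),      # FA above threshold
        (1.5e-3, 0.30, True),       # exactly at both thresholds: kept
        (0.8e-3, 0.15, True),       # typical cortex
    ])
    def test_threshold_boundaries_are_strict(self, md, fa, expect_included):
        table = pd.DataFrame({
            "MD": [md], "FA": [fa], "AD": [md], "RD": [md],
            "radiality": [0.7], "thickness": [2.5],
            "hemisphere": ["left"], "lobe": ["frontal"],
            "included": [True]})
        out = apply_vertex_filter(table)
        assert bool(out["included"][0]) is expect_included

    def test_filter_never_reincludes(self):
        table = pd.DataFrame({
            "MD": [0.8e-3], "FA": [0.1], "AD": [0.9e-3], "RD": [0.7e-3],
            "radiality": [0.7], "thickness": [2.5],
            "hemisphere": ["left"], "lobe": ["frontal"],
            "included": [False]})
        assert not apply_vertex_filter(table)["included"].any()


def _toy_table():
    lobes = ["frontal"] * 4 + ["temporal"] * 4
    hemis = (["left", "right"] * 4)
    return pd.DataFrame({
        "thickness": [2.0, 2.2, 2.4, 2.6, 3.0, 3.2, 3.4, 3.6],
        "FA": [0.1] * 8, "MD": [0.8e-3] * 8,
        "AD": [0.9e-3] * 8, "RD": [0.7e-3] * 8,
        "radiality": [0.8, 0.6, 0.8, 0.6, 0.8, 0.6, 0.8, 0.6],
        "hemisphere": hemis, "lobe": lobes, "included": [True] * 8})


class TestRegionSummary:
    def test_uniform_metric_gives_uniform_means(self, slab_maps):
        surfaces, maps, eigen = slab_maps
        table = build_vertex_table(surfaces, maps, eigen)
        summary = summarize_regions(table)
        rad = summary[summary["metric"] == "radiality"]
        assert np.allclose(rad["value"], 1.0, atol=1e-9)

    def test_both_hemisphere_is_mean_of_left_and_right(self):
        summary = summarize_regions(_toy_table())
        rad = summary[(summary["metric"] == "radiality")
                      & (summary["region"] == "total")]
        left = rad.loc[rad["hemisphere"] == "left", "value"].item()
        right = rad.loc[rad["hemisphere"] == "right", "value"].item()
        both = rad.loc[rad["hemisphere"] == "both", "value"].item()
        assert left == pytest.approx(0.8)
        assert right == pytest.approx(0.6)
        assert both == pytest.approx(0.7)

    def test_total_is_vertex_weighted_combination_of_lobes(self):
        table = _toy_table()
        # unbalance inclusion so weighting matters
        table.loc[0, "included"] = False
        summary = summarize_regions(table)
        sel = summary[(summary["metric"] == "FA")
                      & (summary["hemisphere"] == "left")]
        lobes = sel[sel["region"] != "total"]
        total = sel[sel["region"] == "total"]
        weighted = (lobes["value"] * lobes["n_vertices"]).sum() \
            / lobes["n_vertices"].sum()
        assert total["value"].item() == pytest.approx(weighted, abs=1e-12)
        assert total["n_vertices"].item() == lobes["n_vertices"].sum()

    def test_thickness_ignores_dti_filter_by_default(self):
        table = _toy_table()
        table.loc[:, "included"] = False
        summary = summarize_regions(table)
        assert (summary["metric"] == "thickness").any()
        assert not (summary["metric"] == "FA").any()
        strict = summarize_regions(table, thickness_uses_filter=True)
        assert strict.empty

    def test_planted_lobe_values_recovered_on_shell(self):
        """Per-lobe FA values planted by sector are recovered by regional
        averaging within nearest-neighbour sampling error."""
        from cortexdti.phantom import shell_sector_labels

        surfaces, tv = make_shell_phantom(subdivisions=3)
        planted = {"frontal": 0.10, "parietal": 0.12, "insula": 0.14,
                   "temporal": 0.16, "occipital": 0.18}
        shape = tv.shape
        idx = np.indices(shape).reshape(3, -1).T
        centers = idx * tv.affine[0, 0] + tv.affine[:3, 3]
        vox_lobe = shell_sector_labels(centers)
        values = np.array([planted[l] for l in vox_lobe]).reshape(shape)
        vol = ScalarVolume(values=values, affine=tv.affine, mask=tv.mask)

        got, ok = sample_to_vertices(vol, surfaces.vertices_mid)
        for lobe, val in planted.items():
            sel = ok & (surfaces.lobe_label == lobe)
            # sector mismatch can only occur for vertices near band borders
            assert abs(np.median(got[sel]) - val) < 1e-12
            assert (got[sel] == val).mean() > 0.9


class TestHighRadialityFraction:
    def test_slab_extremes(self, slab_maps):
        surfaces, maps, eigen = slab_maps
        table = build_vertex_table(surfaces, maps, eigen)
        assert high_radiality_fraction(table) == 1.0

    def test_mixture_is_halfway(self):
        table = _toy_table()
        table["radiality"] = [1.0, 1.0, 1.0, 1.0, 0.5, 0.5, 0.5, 0.5]
        assert high_radiality_fraction(table, threshold=0.9) == 0.5
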