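"""Vertex-wise surface statistics: FDR, maps, geometry, rendering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from neurocohort.gam import GAMRegressor, LinearTerm, SmoothTerm
from neurocohort.models import ModelTerms
from neurocohort.surface import (
    ColormapSpec,
    FIGURE_COLLAGE_VIEWS,
    SurfaceMesh,
    VertexMeasureMatrix,
    apply_colormap,
    closest_region,
    deform_geometry,
    fdr_threshold,
    fit_per_vertex,
    neglog10_map,
    rate_of_change,
    read_ply,
    vertex_normals,
    write_ply,
)


def brute_force_bh(pvals, q):
    """Independent oracle: the textbook BH definition, scanned directly."""
    ps = sorted(pvals)
    m = len(ps)
    threshold = 0.0
    for i, p in enumerate(ps, start=1):
        if p <= q * i / m:
            threshold = p
    return threshold


@pytest.fixture(scope="module")
def lh(fixture_dir):
    mesh, _ = read_ply(fixture_dir.mesh_ply["lh"])
    return mesh


@pytest.fixture(scope="module")
def lh_maps(fixture_dir, view, lh):
    vmm = VertexMeasureMatrix.from_csv(fixture_dir.vertex_csv["lh"])
    mt = ModelTerms("__vertex__", (SmoothTerm("Age_At_IMGExam", role="independent"),))
    return fit_per_vertex(view, mt, vmm)


class TestFdrThreshold:
    def test_worked_example(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.27]
        assert fdr_threshold(p, 0.05) == pytest.approx(0.008)

    def test_all_ones_returns_no_rejection_sentinel(self):
        assert fdr_threshold(np.ones(50), 0.05) == 0.0

    def test_uniformly_extreme_passes_everything(self):
        assert fdr_threshold(np.full(100, 1e-9), 0.05) == pytest.approx(1e-9)

    def test_invalid_q_is_an_error(self):
        with pytest.raises(ValueError, match="q"):
            fdr_threshold([0.5], 1.5)

    def test_invalid_pvalues_are_errors(self):
        with pytest.raises(ValueError):
            fdr_threshold([0.0, 0.5], 0.05)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 500))
    def test_matches_brute_force_oracle(self, seed, m):
        rng = np.random.default_rng(seed)
        p = 1.0 - rng.random(m)
        q = rng.uniform(0.01, 0.2)
        assert fdr_threshold(p, q) == pytest.approx(brute_force_bh(p, q))

    def test_matches_statsmodels_rejection_set(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(99)
        for _ in range(20):
            p = 1.0 - rng.random(300)
            p[:20] = rng.uniform(0, 1e-3, 20)
            thr = fdr_threshold(p, 0.05)
            reject_ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(p <= thr if thr > 0 else np.zeros_like(p, bool),
                                  reject_ref)


class TestNegLog10:
    def test_closed_form_values(self):
        assert neglog10_map(0.05) == pytest.approx(1.3010, abs=1e-4)
        assert neglog10_map(1.0) == 0.0

    def test_vector_matches_scalar_elementwise(self):
        p = np.array([0.05, 1.0, 0.001])
        got = neglog10_map(p)
        assert np.allclose(got, [neglog10_map(x) for x in p])

    def test_nonpositive_p_is_an_error(self):
        with pytest.raises(ValueError):
            neglog10_map(np.array([0.5, 0.0]))


class TestApplyColormap:
    CMAP = ColormapSpec(stops=[(0.0, (0, 0, 255)), (2.0, (255, 255, 0)),
                               (4.0, (255, 0, 0))])

    def test_value_at_stop_gives_exact_stop_color(self):
        rgba = apply_colormap(np.array([2.0]), self.CMAP, np.array([True]))
        assert tuple(rgba[0]) == (255, 255, 0, 255)

    def test_midpoint_value_gives_channelwise_midpoint(self):
        rgba = apply_colormap(np.array([1.0]), self.CMAP, np.array([True]))
        assert tuple(rgba[0][:3]) == (127, 127, 127)

    def test_masked_vertex_is_gray_regardless_of_value(self):
        rgba = apply_colormap(np.array([4.0]), self.CMAP, np.array([False]))
        assert tuple(rgba[0]) == (128, 128, 128, 255)

    def test_values_clamped_at_ends(self):
        rgba = apply_colormap(np.array([-5.0, 99.0]), self.CMAP,
                              np.array([True, True]))
        assert tuple(rgba[0][:3]) == (0, 0, 255)
        assert tuple(rgba[1][:3]) == (255, 0, 0)

    def test_unsorted_stops_are_an_error(self):
        with pytest.raises(ValueError, match="increasing"):
            ColormapSpec(stops=[(2.0, (0, 0, 0)), (1.0, (1, 1, 1))])

    def test_monotone_in_value(self):
        vals = np.linspace(0, 4, 50)
        rgba = apply_colormap(vals, self.CMAP, np.ones(50, bool))
        red = rgba[:, 0].astype(int)
        assert (np.diff(red) >= 0).all()

    def test_remasking_is_idempotent(self):
        vals = np.linspace(0, 4, 20)
        mask = vals > 2
        once = apply_colormap(vals, self.CMAP, mask)
        twice = apply_colormap(vals, self.CMAP, mask)
        assert np.array_equal(once, twice)


class TestRateOfChange:
    def test_linear_frames_give_exact_constant_slope(self):
        grid = np.linspace(3, 21, 9)
        frames = np.outer(2.0 * grid, np.ones(5)) + 7.0
        d = rate_of_change(frames, grid)
        assert np.allclose(d, 2.0, atol=1e-12)

    def test_constant_frames_give_zero(self):
        grid = np.linspace(0, 1, 5)
        assert np.allclose(rate_of_change(np.ones((5, 3)), grid), 0.0)

    def test_too_few_frames_is_an_error(self):
        with pytest.raises(ValueError, match="3 frames"):
            rate_of_change(np.ones((2, 3)), np.array([0.0, 1.0]))

    def test_fixture_peak_produces_sign_flip_near_true_peak(
        self, lh_maps, lh, fixture_dir
    ):
        truth = fixture_dir.truth
        patch = lh.roi_labels == truth["effect_patch"]
        deriv = rate_of_change(lh_maps.predicted_frames, lh_maps.grid)
        step = lh_maps.grid[1] - lh_maps.grid[0]
        mids = []
        for v in np.nonzero(patch)[0]:
            flips = np.nonzero(np.diff(np.sign(deriv[:, v])) < 0)[0]
            if flips.size:
                mids.append((lh_maps.grid[flips[0]] + lh_maps.grid[flips[0] + 1]) / 2)
        assert len(mids) > 0.9 * patch.sum()
        assert abs(np.median(mids) - truth["peak_age_vertex"]) <= step


class TestFitPerVertex:
    def test_map_lengths_equal_vertex_count(self, lh_maps, lh):
        assert lh_maps.n_vertices == lh.n_vertices
        assert lh_maps.effect.shape == (lh.n_vertices,)
        assert lh_maps.predicted_frames.shape == (17, lh.n_vertices)

    def test_patch_strongly_significant_off_patch_not(self, lh_maps, lh, fixture_dir):
        patch = lh.roi_labels == fixture_dir.truth["effect_patch"]
        assert np.median(lh_maps.p_independent[patch]) < 1e-3
        assert np.median(lh_maps.p_independent[~patch]) > 0.2

    def test_constant_vertex_column_gets_p_one_zero_effect(self, view):
        df = view.data.dropna(subset=["Age_At_IMGExam"]).iloc[:100]
        vmm = VertexMeasureMatrix(pd.DataFrame(
            {"v0": np.full(100, 1.5),
             "v1": np.asarray(df["Age_At_IMGExam"], float) * 0.1},
            index=df.index,
        ))
        mt = ModelTerms("__v__", (LinearTerm("Age_At_IMGExam", role="independent"),))
        maps = fit_per_vertex(df, mt, vmm)
        assert maps.p_independent[0] == 1.0
        assert maps.effect[0] == 0.0
        assert maps.p_independent[1] < 1e-10

    def test_single_vertex_agrees_with_direct_fit(self, view):
        """Consistency oracle: a 1-column matrix equals a plain model fit."""
        df = view.data.dropna(subset=["Age_At_IMGExam"]).iloc[:150]
        rng = np.random.default_rng(3)
        y = 1.0 + 0.05 * np.asarray(df["Age_At_IMGExam"], float) \
            + rng.normal(0, 0.2, 150)
        vmm = VertexMeasureMatrix(pd.DataFrame({"v0": y}, index=df.index))
        terms = (SmoothTerm("Age_At_IMGExam", role="independent"),)
        maps = fit_per_vertex(df, ModelTerms("__v__", terms), vmm)
        est = GAMRegressor(terms=terms).fit(df, y)
        direct_p = est.term_summaries_[0]["p_value"]
        assert maps.p_independent[0] == pytest.approx(direct_p, rel=1e-8)

    def test_no_overlapping_sessions_is_an_error(self, view):
        other = pd.DataFrame(
            {"v0": [1.0]},
            index=pd.MultiIndex.from_tuples([("ZZZ", "V9")],
                                            names=["SubjID", "Visit"]),
        )
        mt = ModelTerms("__v__", (LinearTerm("Age_At_IMGExam", role="independent"),))
        with pytest.raises(ValueError, match="overlap"):
            fit_per_vertex(view, mt, VertexMeasureMatrix(other))

    def test_interaction_maps_present_when_requested(self, fixture_dir, view):
        from neurocohort.models import ModelSpec, build_terms

        vmm = VertexMeasureMatrix.from_csv(fixture_dir.vertex_csv["lh"])
        spec = ModelSpec("__v__", "Age_At_IMGExam", smooth=True,
                         interaction="Gender", use_device=False, use_ses=False,
                         use_ancestry=False)
        maps = fit_per_vertex(view, build_terms(spec), vmm)
        assert maps.p_interaction_main is not None
        assert maps.p_interaction is not None
        assert len(maps.p_interaction) == vmm.n_vertices


class TestGeometry:
    @pytest.fixture()
    def two_patch_mesh(self):
        import trimesh

        ico = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
        labels = np.where(np.asarray(ico.vertices)[:, 2] > 3.0,
                          "crown", "unknown").astype(object)
        labels[np.asarray(ico.vertices)[:, 2] < -3.0] = "base"
        return SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces),
                           "lh", labels)

    def test_vertex_inside_patch_returns_its_label(self, two_patch_mesh):
        v = int(np.argmax(two_patch_mesh.vertices[:, 2]))
        name, _ = closest_region(two_patch_mesh, v)
        assert name == "crown"

    def test_unlabeled_vertex_takes_nearest_labeled_label(self, two_patch_mesh):
        mesh = two_patch_mesh
        unlabeled = np.nonzero(mesh.roi_labels == "unknown")[0]
        v = int(unlabeled[np.argmax(mesh.vertices[unlabeled, 2])])
        # brute-force nearest-labeled scan oracle
        labeled = np.nonzero(mesh.roi_labels != "unknown")[0]
        d = np.linalg.norm(mesh.vertices[labeled] - mesh.vertices[v], axis=1)
        expected = mesh.roi_labels[labeled[np.argmin(d)]]
        assert closest_region(mesh, v)[0] == expected

    def test_single_label_mesh_has_empty_boundary(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        faces = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
        mesh = SurfaceMesh(verts, faces, "lh", np.array(["roi"] * 4, dtype=object))
        _, boundary = closest_region(mesh, 0)
        assert boundary.size == 0

    def test_out_of_range_index_is_an_error(self, two_patch_mesh):
        with pytest.raises(ValueError, match="range"):
            closest_region(two_patch_mesh, 10**6)

    def test_constant_map_leaves_mesh_unchanged(self, two_patch_mesh):
        out = deform_geometry(two_patch_mesh, np.full(two_patch_mesh.n_vertices, 3.3),
                              scale=5.0)
        assert np.allclose(out.vertices, two_patch_mesh.vertices)

    def test_doubling_scale_doubles_displacement(self, two_patch_mesh):
        pm = np.linspace(0, 1, two_patch_mesh.n_vertices)
        d1 = deform_geometry(two_patch_mesh, pm, 1.0).vertices - two_patch_mesh.vertices
        d2 = deform_geometry(two_patch_mesh, pm, 2.0).vertices - two_patch_mesh.vertices
        assert np.allclose(d2, 2 * d1)

    def test_positive_patch_moves_outward_on_sphere(self, two_patch_mesh):
        mesh = two_patch_mesh
        pm = np.where(mesh.roi_labels == "crown", 1.0, 0.0)
        out = deform_geometry(mesh, pm, scale=2.0)
        disp = out.vertices - mesh.vertices
        normals = vertex_normals(mesh)
        crown = mesh.roi_labels == "crown"
        assert (np.einsum("ij,ij->i", disp[crown], normals[crown]) > 0).all()
        # input untouched (pure function)
        assert mesh.vertices[0, 0] == two_patch_mesh.vertices[0, 0]

    def test_sphere_normals_point_outward(self, two_patch_mesh):
        centred = two_patch_mesh.vertices - two_patch_mesh.vertices.mean(axis=0)
        dots = np.einsum("ij,ij->i", vertex_normals(two_patch_mesh), centred)
        assert (dots > 0).all()


class TestPlyIO:
    def test_round_trip_preserves_geometry_labels_scalars(self, tmp_path, lh):
        scalars = {"stat": np.linspace(0, 1, lh.n_vertices)}
        path = tmp_path / "mesh.ply"
        write_ply(lh, path, scalars)
        back, got_scalars = read_ply(path)
        assert np.allclose(back.vertices, lh.vertices, atol=1e-5)
        assert np.array_equal(back.faces, lh.faces)
        assert list(back.roi_labels) == list(lh.roi_labels)
        assert np.allclose(got_scalars["stat"], scalars["stat"], atol=1e-7)
        assert back.hemisphere == lh.hemisphere

    def test_bad_face_index_is_an_error(self):
        with pytest.raises(ValueError, match="face"):
            SurfaceMesh(np.zeros((3, 3)), np.array([[0, 1, 5]]))


class TestExportImage:
    @pytest.fixture()
    def colored(self, lh, lh_maps):
        cmap = ColormapSpec(stops=[(0.0, (0, 0, 255)), (6.0, (255, 0, 0))])
        vals = neglog10_map(lh_maps.p_independent)
        return apply_colormap(vals, cmap, vals > 1.3)

    def test_export_is_byte_deterministic(self, lh, colored, tmp_path):
        from neurocohort.surface import export_map_image

        a = export_map_image(lh, colored, "lateral", tmp_path / "a.png")
        b = export_map_image(lh, colored, "lateral", tmp_path / "b.png")
        assert a.read_bytes() == b.read_bytes()

    def test_background_pixels_have_zero_alpha(self, lh, colored, tmp_path):
        from PIL import Image

        from neurocohort.surface import export_map_image

        path = export_map_image(lh, colored, "superior", tmp_path / "c.png")
        img = np.asarray(Image.open(path))
        assert img[0, 0, 3] == 0          # corner is background
        assert (img[..., 3] == 255).any()  # surface is opaque

    def test_collage_view_set_matches_publication_layout(self):
        assert len(FIGURE_COLLAGE_VIEWS) == 10
        assert FIGURE_COLLAGE_VIEWS[0][0] == "superior"
        assert FIGURE_COLLAGE_VIEWS[-1][0] == "inferior"
        laterals = [v for v, _ in FIGURE_COLLAGE_VIEWS if v == "lateral"]
        medials = [v for v, _ in FIGURE_COLLAGE_VIEWS if v == "medial"]
        assert len(laterals) == 4 and len(medials) == 4
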