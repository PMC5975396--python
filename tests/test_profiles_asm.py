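"""Gray-level profile models and Active Shape Model search."""

import numpy as np
import pytest

from shapeseg import ActiveShapeModelSegmenter, Volume, dice
from shapeseg.asm import ASMConfig, classic_asm_step, fit_asm, optimal_feature_asm_step
from shapeseg.errors import DegenerateInputError
from shapeseg.gpmm import _vertex_normals
from shapeseg.pdm import build_pdm, procrustes_align
from shapeseg.profiles import (
    build_optimal_feature_model,
    build_profile_model,
    point_features,
    sample_profile,
)


def _step_volume(edge_x=16.0, lo=0.0, hi=100.0, n=32, spacing=1.0):
    """Ideal step edge: intensity hi for x < edge_x, lo beyond."""
    x = np.arange(n) * spacing
    img = np.where(x[:, None, None] < edge_x, hi, lo) * np.ones((1, n, n))
    return Volume(img, (spacing,) * 3)


def test_constant_image_gives_zero_profile():
    vol = Volume(np.full((16, 16, 16), 42.0))
    g = sample_profile(vol, [[8, 8, 8]], [[1, 0, 0]], half_length=4)
    np.testing.assert_array_equal(g, 0.0)


def test_step_edge_profile_peak_at_center():
    vol = _step_volume(edge_x=16.0)
    g = sample_profile(vol, [[15.5, 16, 16]], [[1, 0, 0]], half_length=4)[0]
    k = len(g) // 2
    assert np.abs(g).argmax() == k  # peak at the landmark position
    assert g[k] < 0  # intensity decreases along +normal (inside -> outside)


def test_profile_normalization(rng):
    vol = Volume(rng.normal(50, 20, (20, 20, 20)))
    g = sample_profile(vol, rng.uniform(5, 15, (10, 3)), rng.normal(size=(10, 3)),
                       half_length=4)
    np.testing.assert_allclose(np.abs(g).sum(axis=1), 1.0, atol=1e-12)


def test_zero_normal_rejected():
    vol = Volume(np.zeros((8, 8, 8)))
    with pytest.raises(DegenerateInputError):
        sample_profile(vol, [[4, 4, 4]], [[0, 0, 0]])


def test_profile_model_identical_training_cases(small_cohort):
    case = small_cohort[0]
    pts = case.mesh.vertices
    nrm = case.mesh.vertex_normals()
    model = build_profile_model([case.image] * 3, [pts] * 3, [nrm] * 3,
                                half_length=4, resolutions=(1.0,))
    st = model.stats(1.0)
    np.testing.assert_allclose(st.cov, 0.0, atol=1e-20)
    single = sample_profile(case.image, pts, nrm, 4)
    np.testing.assert_allclose(st.mean, single, atol=1e-12)


def test_profile_model_matches_direct_loop(small_cohort):
    cases = small_cohort[:3]
    vols = [c.image for c in cases]
    pts = [c.mesh.vertices for c in cases]
    nrm = [c.mesh.vertex_normals() for c in cases]
    model = build_profile_model(vols, pts, nrm, half_length=3, resolutions=(1.0,))
    st = model.stats(1.0)
    # brute-force per-landmark loop over cases
    profs = np.stack([sample_profile(v, p, n, 3) for v, p, n in zip(vols, pts, nrm)])
    for lm in range(0, profs.shape[1], 97):
        mean = profs[:, lm].mean(0)
        dev = profs[:, lm] - mean
        cov = dev.T @ dev / len(cases)
        np.testing.assert_allclose(st.mean[lm], mean, atol=1e-12)
        np.testing.assert_allclose(st.cov[lm], cov, atol=1e-12)


def test_profile_length_follows_config(small_cohort):
    cases = small_cohort[:2]
    model = build_profile_model([c.image for c in cases],
                                [c.mesh.vertices for c in cases],
                                [c.mesh.vertex_normals() for c in cases],
                                half_length=4, resolutions=(1.0,))
    assert model.stats(1.0).mean.shape[1] == 2 * 4 + 1


def test_profile_model_requires_two_cases(small_cohort):
    c = small_cohort[0]
    with pytest.raises(DegenerateInputError):
        build_profile_model([c.image], [c.mesh.vertices], [c.mesh.vertex_normals()])


def test_mahalanobis_of_mean_is_zero(small_cohort):
    cases = small_cohort[:3]
    model = build_profile_model([c.image for c in cases],
                                [c.mesh.vertices for c in cases],
                                [c.mesh.vertex_normals() for c in cases],
                                half_length=4, resolutions=(1.0,))
    st = model.stats(1.0)
    d = model.mahalanobis(st.mean[:, None, :], level=1.0)
    np.testing.assert_allclose(d, 0.0, atol=1e-10)


# ---------------------------------------------------------------------------
# search steps
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def trained_asm(small_split):
    train, _ = small_split
    seg = ActiveShapeModelSegmenter(variant="classic").fit(
        [c.image for c in train], [c.mesh for c in train]
    )
    return seg, train


def test_classic_step_fixed_point_on_noiseless_truth(small_split):
    """With profiles trained on the test volume itself, a step from ground
    truth barely moves the landmarks (the truth is a fixed point)."""
    train, _ = small_split
    case = train[0]
    vols = [c.image for c in train]
    meshes = [c.mesh for c in train]
    seg = ActiveShapeModelSegmenter(variant="classic").fit(vols, meshes)
    cfg = ASMConfig(resolutions=(1.0,))
    moved = classic_asm_step(case.image, case.mesh.vertices, case.mesh.faces,
                             seg.pdm_, seg.appearance_, cfg, level=1.0)
    motion = np.linalg.norm(moved - case.mesh.vertices, axis=1)
    assert np.median(motion) <= min(case.image.spacing)


def test_candidate_count_respects_config(small_split, monkeypatch):
    train, _ = small_split
    case = train[0]
    seg, _ = ActiveShapeModelSegmenter(variant="classic").fit(
        [c.image for c in train], [c.mesh for c in train]), None
    seen = {}
    import shapeseg.asm as A

    orig = A._candidate_offsets

    def spy(n, step):
        seen["n"] = n
        return orig(n, step)

    monkeypatch.setattr(A, "_candidate_offsets", spy)
    cfg = ASMConfig(candidate_positions=6)
    classic_asm_step(case.image, case.mesh.vertices, case.mesh.faces,
                     seg.pdm_, seg.appearance_, cfg, level=1.0)
    assert seen["n"] == 6


def test_knn_classifier_separates_inside_outside(small_split):
    train, _ = small_split
    model = build_optimal_feature_model(
        [c.image for c in train],
        [c.mesh.vertices for c in train],
        [c.mesh.vertex_normals() for c in train],
        half_length=4, resolutions=(1.0,),
    )
    case = train[0]
    pts = case.mesh.vertices
    nrm = case.mesh.vertex_normals()
    step = float(min(case.image.spacing))
    inside_pts = pts - 3 * step * nrm
    outside_pts = pts + 3 * step * nrm
    fin = point_features(case.image, inside_pts, nrm, step)
    fout = point_features(case.image, outside_pts, nrm, step)
    p_in, p_out = [], []
    for i in range(0, len(pts), 23):
        p_in.append(model.inside_probability(1.0, i, fin[i : i + 1]))
        p_out.append(model.inside_probability(1.0, i, fout[i : i + 1]))
    assert np.mean(p_in) >= 0.9
    assert np.mean(p_out) <= 0.1


def test_one_nn_memorizes_training_labels(small_split):
    train, _ = small_split
    model = build_optimal_feature_model(
        [c.image for c in train[:2]],
        [c.mesh.vertices for c in train[:2]],
        [c.mesh.vertex_normals() for c in train[:2]],
        half_length=3, k_neighbors=1, resolutions=(1.0,),
    )
    clf = model.classifiers(1.0)[0]
    X = clf._fit_X if hasattr(clf, "_fit_X") else None
    pred = clf.predict(X)
    np.testing.assert_array_equal(pred, clf._y)


def test_knn_even_k_rejected(small_split):
    train, _ = small_split
    with pytest.raises(ValueError):
        build_optimal_feature_model(
            [c.image for c in train[:2]],
            [c.mesh.vertices for c in train[:2]],
            [c.mesh.vertex_normals() for c in train[:2]],
            k_neighbors=4,
        )


def test_boundary_scores_better_than_outward_offset(small_split):
    """On a clean phantom, the ideal boundary location outranks a position
    3 voxels outward under the kNN agreement score."""
    train, _ = small_split
    model = build_optimal_feature_model(
        [c.image for c in train],
        [c.mesh.vertices for c in train],
        [c.mesh.vertex_normals() for c in train],
        half_length=4, resolutions=(1.0,),
    )
    case = train[1]
    pts = case.mesh.vertices
    nrm = case.mesh.vertex_normals()
    step = float(min(case.image.spacing))
    k = 4
    pos_off = np.arange(-k, k + 1) * step
    ideal = np.where(pos_off < 0, 1.0, np.where(pos_off > 0, 0.0, 0.5))

    def score_at(center, i):
        pos = center + pos_off[:, None] * nrm[i]
        f = point_features(case.image, pos, np.tile(nrm[i], (len(pos), 1)), step)
        p = model.inside_probability(1.0, i, f)
        return np.abs(p - ideal).sum()

    wins = 0
    total = 0
    for i in range(0, len(pts), 29):
        s_true = score_at(pts[i], i)
        s_out = score_at(pts[i] + 3 * step * nrm[i], i)
        wins += s_true < s_out
        total += 1
    assert wins / total > 0.9


# ---------------------------------------------------------------------------
# full fit
# ---------------------------------------------------------------------------


def test_fit_asm_stays_at_optimum():
    """Noiseless phantom, model span covering the truth, init = ground truth:
    the multi-resolution search must stay at the optimum (DICE >= 99%)."""
    from shapeseg.phantom import PhantomSpec, generate_cohort

    spec = PhantomSpec(grid_shape=(32, 32, 32), spacing=(4.0, 4.0, 4.0),
                       n_vertices=400, noise_sd=0.0, seed=3)
    cohort = generate_cohort(spec, 8, seed=3)
    seg = ActiveShapeModelSegmenter(variant="classic").fit(
        [c.image for c in cohort], [c.mesh for c in cohort]
    )
    case = cohort[0]
    pts, mask = fit_asm(case.image, seg.pdm_, seg.appearance_, case.mesh.vertices,
                        case.mesh.faces, seg._config(), variant="classic")
    assert dice(mask, case.mask) >= 99.0


def test_fit_asm_improves_over_init(small_split):
    train, test = small_split
    case = test[0]
    seg = ActiveShapeModelSegmenter(variant="classic").fit(
        [c.image for c in train], [c.mesh for c in train]
    )
    init_pts = seg.initial_shape(case.image)
    from shapeseg.core import SurfaceMesh, surface_to_mask

    init_mask = surface_to_mask(SurfaceMesh(init_pts, seg.faces_), case.image.shape,
                                case.image.spacing, case.image.origin)
    final_mask = seg.predict(case.image)
    assert dice(final_mask, case.mask) > dice(init_mask, case.mask)


def test_emitted_shapes_respect_mode_clamp(small_split):
    """Every shape produced during fitting projects within 3 sqrt(lambda)."""
    train, test = small_split
    seg = ActiveShapeModelSegmenter(variant="classic").fit(
        [c.image for c in train], [c.mesh for c in train]
    )
    case = test[0]
    pts = seg.initial_shape(case.image)
    cfg = seg._config()
    from shapeseg.pdm import similarity_fit

    for level in cfg.resolutions:
        from shapeseg.registration import _downsample

        v = _downsample(case.image, level)
        for _ in range(cfg.iterations_per_level):
            pts = classic_asm_step(v, pts, seg.faces_, seg.pdm_, seg.appearance_,
                                   cfg, level)
            s, R, t = similarity_fit(seg.pdm_.mean_points(), pts)
            b = seg.pdm_.project((pts - t) @ R / s)
            lim = cfg.b_limit * np.sqrt(np.maximum(seg.pdm_.variances, 0)) + 1e-8
            assert np.all(np.abs(b) <= lim)


def test_fit_deterministic(small_split):
    train, test = small_split
    seg = ActiveShapeModelSegmenter(variant="classic").fit(
        [c.image for c in train], [c.mesh for c in train]
    )
    m1 = seg.predict(test[0].image)
    m2 = seg.predict(test[0].image)
    np.testing.assert_array_equal(m1.voxels, m2.voxels)


def test_knn_variant_runs_end_to_end(small_split):
    train, test = small_split
    seg = ActiveShapeModelSegmenter(variant="knn").fit(
        [c.image for c in train], [c.mesh for c in train]
    )
    mask = seg.predict(test[0].image)
    assert dice(mask, test[0].mask) > 80.0
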