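"""Gaussian Process Morphable Models: kernels, low-rank basis, Nystrom,
correspondence, empirical statistics and fitting."""

import numpy as np
import pytest

from shapeseg import (
    GaussianKernel,
    GPMMFitConfig,
    GPMMSegmenter,
    SurfaceMesh,
    build_empirical_gp,
    build_low_rank_gp,
    dice,
    establish_correspondence,
    fit_gpmm,
    sample_deformation,
)
from shapeseg.errors import DimensionError
from shapeseg.gpmm import empirical_kernel, empirical_mean
from shapeseg.phantom import make_reference_organ


@pytest.fixture(scope="module")
def sphere300():
    """~300-vertex organ surface for eigen-decomposition tests."""
    return make_reference_organ(300, diameter_mm=40.0, center_mm=(0, 0, 0))


def test_gaussian_kernel_closed_forms(rng):
    k = GaussianKernel(s=2.0, sigma=5.0)
    x = rng.normal(0, 3, 3)
    np.testing.assert_allclose(k.evaluate(x, x), 2.0 * np.eye(3), atol=1e-12)
    y = x + np.array([5.0, 0.0, 0.0])  # ||x-y|| = sigma
    np.testing.assert_allclose(k.evaluate(x, y), 2.0 * np.exp(-1) * np.eye(3), atol=1e-12)
    np.testing.assert_allclose(k.evaluate(x, y), k.evaluate(y, x).T, atol=1e-12)


def test_kernel_gram_psd(rng):
    k = GaussianKernel(s=1.5, sigma=8.0)
    pts = rng.uniform(-20, 20, (50, 3))
    w = np.linalg.eigvalsh(k.gram(pts))
    assert w.min() >= -1e-8


def test_kernel_combinators(rng):
    a = GaussianKernel(1.0, 5.0)
    b = GaussianKernel(0.5, 15.0)
    pts = rng.uniform(0, 10, (4, 3))
    np.testing.assert_allclose((a + b).scalar(pts, pts),
                               a.scalar(pts, pts) + b.scalar(pts, pts))
    np.testing.assert_allclose((2.0 * a).scalar(pts, pts), 2.0 * a.scalar(pts, pts))


def test_kernel_rejects_bad_parameters():
    with pytest.raises(ValueError):
        GaussianKernel(s=-1.0, sigma=1.0)
    with pytest.raises(ValueError):
        GaussianKernel(s=1.0, sigma=0.0)


def test_nystrom_full_sample_matches_dense(sphere300):
    """Nystrom with m = V equals the dense eigendecomposition."""
    kern = GaussianKernel(s=1.0, sigma=30.0)
    V = sphere300.n_vertices
    dense = build_low_rank_gp(kern, sphere300, r=10, dense_limit=10**9)
    nyst = build_low_rank_gp(kern, sphere300, r=10, m=V, dense_limit=0)
    np.testing.assert_allclose(nyst.variances, dense.variances, rtol=1e-8)
    # basis fields agree up to sign
    for i in range(10):
        dot = abs(nyst.basis[:, i] @ dense.basis[:, i])
        assert dot == pytest.approx(1.0, abs=1e-6)


def test_nystrom_half_sample_within_10pct(sphere300):
    """Leading eigenvalues from a 50% vertex subsample stay within 10%."""
    V = sphere300.n_vertices
    for kern in (GaussianKernel(1.0, 40.0),
                 GaussianKernel(0.7, 40.0) + GaussianKernel(0.3, 20.0)):
        dense = build_low_rank_gp(kern, sphere300, r=8, dense_limit=10**9)
        nyst = build_low_rank_gp(kern, sphere300, r=8, m=V // 2, seed=0, dense_limit=0)
        rel = np.abs(nyst.variances - dense.variances) / dense.variances
        assert rel.max() <= 0.10


def test_zero_kernel_limit(sphere300):
    gp = build_low_rank_gp(GaussianKernel(s=1e-30, sigma=30.0), sphere300, r=5)
    assert np.all(gp.variances <= 1e-20)


def test_basis_orthonormal(sphere300):
    gp = build_low_rank_gp(GaussianKernel(1.0, 30.0), sphere300, r=12)
    np.testing.assert_allclose(gp.basis.T @ gp.basis, np.eye(gp.rank), atol=1e-6)
    assert np.all(np.diff(gp.variances) <= 1e-9 * gp.variances[0])


def test_low_rank_gp_archive_roundtrip(tmp_path, sphere300, rng):
    gp = build_low_rank_gp(GaussianKernel(2.0, 35.0), sphere300, r=6)
    path = str(tmp_path / "gp.npz")
    gp.save(path)
    from shapeseg.gpmm import LowRankGP

    back = LowRankGP.load(path)
    np.testing.assert_array_equal(back.basis, gp.basis)
    np.testing.assert_array_equal(back.variances, gp.variances)
    a = rng.standard_normal(6)
    np.testing.assert_allclose(back.sample(a), gp.sample(a))
    pts = rng.uniform(-20, 20, (7, 3))
    np.testing.assert_allclose(back.basis_at(pts), gp.basis_at(pts), atol=1e-10)


def test_sample_deformation_mean_and_linearity(sphere300, rng):
    gp = build_low_rank_gp(GaussianKernel(1.0, 30.0), sphere300, r=6)
    np.testing.assert_allclose(sample_deformation(gp, np.zeros(6)), gp.mean_field)
    a, b = rng.standard_normal(6), rng.standard_normal(6)
    lhs = gp.sample(a + b) - gp.mean_field
    rhs = (gp.sample(a) - gp.mean_field) + (gp.sample(b) - gp.mean_field)
    np.testing.assert_allclose(lhs, rhs, atol=1e-10)
    with pytest.raises(DimensionError):
        gp.sample(np.zeros(7))


def test_monte_carlo_covariance_matches_analytic(rng):
    """Per-vertex sample covariance of 10,000 draws matches sum lambda phi phiT
    within 5% relative Frobenius error."""
    mesh = make_reference_organ(120, diameter_mm=30.0, center_mm=(0, 0, 0))
    gp = build_low_rank_gp(GaussianKernel(1.0, 25.0), mesh, r=5)
    alphas = rng.standard_normal((10000, gp.rank))
    fields = gp.sample_batch(alphas).reshape(10000, -1)
    emp = np.cov(fields.T, bias=False)
    analytic = (gp.basis * gp.variances) @ gp.basis.T
    rel = np.linalg.norm(emp - analytic) / np.linalg.norm(analytic)
    assert rel <= 0.05


# ---------------------------------------------------------------------------
# correspondence
# ---------------------------------------------------------------------------


def test_correspondence_identity_target(sphere300):
    prior = build_low_rank_gp(GaussianKernel(4.0, 30.0), sphere300, r=20)
    res = establish_correspondence(prior, sphere300)
    assert np.linalg.norm(res.field, axis=1).mean() <= 1e-6
    assert all(np.diff(res.objective_trace) <= 1e-12)


def test_correspondence_in_span_recovery(sphere300, rng):
    prior = build_low_rank_gp(GaussianKernel(4.0, 30.0), sphere300, r=10)
    alpha_true = rng.standard_normal(10) * 0.8
    target = SurfaceMesh(sphere300.vertices + prior.sample(alpha_true),
                         sphere300.faces)
    res = establish_correspondence(prior, target, max_iter=100, ridge=1e-6)
    # recovered field close to truth; residual below the mesh edge length
    edge = np.linalg.norm(
        sphere300.vertices[sphere300.faces[:, 0]]
        - sphere300.vertices[sphere300.faces[:, 1]], axis=1).mean()
    assert res.residual < edge
    true_field = prior.sample(alpha_true)
    rel = np.linalg.norm(res.field - true_field) / np.linalg.norm(true_field)
    assert rel <= 0.05
    assert all(np.diff(res.objective_trace) <= 1e-12)


# ---------------------------------------------------------------------------
# empirical GP
# ---------------------------------------------------------------------------


def test_empirical_mean_and_kernel_match_direct_formulas(sphere300, rng):
    N, V = 12, sphere300.n_vertices
    fields = rng.normal(0, 2, (N, V, 3))
    gp = build_empirical_gp(sphere300, fields)
    np.testing.assert_allclose(gp.mean_field, fields.mean(0), atol=1e-12)
    np.testing.assert_allclose(empirical_mean(fields), fields.mean(0), atol=1e-14)
    # low-rank factorization reproduces the direct 1/(N-1) covariance blocks
    analytic = (gp.basis * gp.variances) @ gp.basis.T
    idx = rng.choice(V, 10, replace=False)
    for i in idx:
        for j in idx[:3]:
            block = empirical_kernel(fields, i, j)
            np.testing.assert_allclose(
                analytic[3 * i : 3 * i + 3, 3 * j : 3 * j + 3], block, atol=1e-10
            )
    assert gp.rank <= N - 1


def test_empirical_gp_requires_two_fields(sphere300):
    with pytest.raises(Exception):
        build_empirical_gp(sphere300, np.zeros((1, sphere300.n_vertices, 3)))


def test_empirical_gp_recovers_known_variances(sphere300, rng):
    truth = build_low_rank_gp(GaussianKernel(9.0, 30.0), sphere300, r=3)
    fields = truth.sample_batch(rng.standard_normal((50, 3)))
    emp = build_empirical_gp(sphere300, fields)
    rel = np.abs(emp.variances[:3] - truth.variances) / truth.variances
    assert rel.max() <= 0.30


def test_empirical_gp_converges_with_sample_count(sphere300):
    """Median leading-eigenvalue error shrinks from N=10 to N=200 draws."""
    truth = build_low_rank_gp(GaussianKernel(9.0, 30.0), sphere300, r=3)
    errs = {10: [], 200: []}
    for rep in range(5):
        g = np.random.default_rng(100 + rep)
        for N in (10, 200):
            emp = build_empirical_gp(sphere300, truth.sample_batch(g.standard_normal((N, 3))))
            errs[N].append(abs(emp.variances[0] - truth.variances[0]) / truth.variances[0])
    assert np.median(errs[200]) < np.median(errs[10])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_fit_gpmm_zero_iterations_returns_initial_mean(small_split):
    train, test = small_split
    seg = GPMMSegmenter(seed=0).fit([c.image for c in train], [c.mesh for c in train])
    cfg = GPMMFitConfig(iterations=0, seed=0)
    mesh, alpha, _ = fit_gpmm(test[0].image, seg.model_, seg.profiles_, config=cfg)
    np.testing.assert_allclose(
        mesh.vertices, seg.model_.reference.vertices + seg.model_.mean_field
    )
    np.testing.assert_array_equal(alpha, 0.0)


def test_fit_gpmm_shapes_stay_in_model_span(small_split):
    train, test = small_split
    seg = GPMMSegmenter(seed=0, iterations=30).fit(
        [c.image for c in train], [c.mesh for c in train]
    )
    model = seg.model_
    mesh, alpha, _ = fit_gpmm(test[0].image, model, seg.profiles_,
                              config=GPMMFitConfig(iterations=30, seed=0))
    np.testing.assert_allclose(
        mesh.vertices, model.reference.vertices + model.sample(alpha), atol=1e-10
    )


def test_fit_gpmm_deterministic_and_seed_sensitive(small_split):
    train, test = small_split
    seg = GPMMSegmenter(seed=0, iterations=40).fit(
        [c.image for c in train], [c.mesh for c in train]
    )
    cfg = lambda s: GPMMFitConfig(iterations=40, seed=s)
    _, a1, t1 = fit_gpmm(test[0].image, seg.model_, seg.profiles_, config=cfg(5))
    _, a2, t2 = fit_gpmm(test[0].image, seg.model_, seg.profiles_, config=cfg(5))
    _, a3, _ = fit_gpmm(test[0].image, seg.model_, seg.profiles_, config=cfg(6))
    np.testing.assert_array_equal(a1, a2)
    assert t1 == t2
    assert not np.array_equal(a1, a3)


def test_fit_gpmm_score_trace_nonincreasing(small_split):
    train, test = small_split
    seg = GPMMSegmenter(seed=0, iterations=40).fit(
        [c.image for c in train], [c.mesh for c in train]
    )
    _, _, trace = fit_gpmm(test[0].image, seg.model_, seg.profiles_,
                           config=GPMMFitConfig(iterations=40, seed=0))
    assert all(np.diff(trace) <= 0)


def test_gpmm_self_consistent_recovery(small_spec, small_split):
    """A target drawn from the learned deformation model itself is recovered
    with DICE >= 95% under the standard 200 x 20 sampling budget."""
    from shapeseg.phantom import render_case

    train, _ = small_split
    seg = GPMMSegmenter(seed=0, iterations=200, candidates=20).fit(
        [c.image for c in train], [c.mesh for c in train]
    )
    rng = np.random.default_rng(99)
    alpha_true = rng.standard_normal(seg.model_.rank)
    case = render_case(small_spec, seg.model_, alpha_true, rng)
    mask = seg.predict(case.image)
    assert dice(mask, case.mask) >= 95.0
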