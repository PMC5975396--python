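"""Gaussian Process Morphable Models (GPMMs).

A shape is represented as a reference surface plus a deformation field,
``s = { x + u(x) | x in Gamma_R }``, where ``u`` is a Gaussian process with
mean ``mu`` and matrix-valued kernel ``k``.  The process is approximated by
its rank-r Karhunen-Loeve expansion

    u = mu + sum_{i=1..r} alpha_i sqrt(lambda_i) phi_i,

computed from the kernel's Gram matrix on the reference vertices — exactly
for small meshes, via the Nystrom method on a vertex subsample otherwise.
Empirical deformation statistics estimated from example shapes (mean field
and 1/(N-1)-normalized sample covariance) yield the same low-rank form, so
analytic and data-driven models share one representation.

Segmentation of a new image draws whole-shape candidates from the
deformation distribution and keeps the candidate whose boundary profiles
best match a trained appearance model (summed per-vertex Mahalanobis
distance), so accepted states always stay in the model span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import SurfaceMesh, Volume
from .errors import DegenerateInputError, DimensionError
from .profiles import GrayProfileModel, sample_profile

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# kernels (matrix-valued: scalar radial function times the 3x3 identity)
# ---------------------------------------------------------------------------


class Kernel:
    """Matrix-valued kernel k(x, y) = g(x, y) * I3 with scalar part g."""

    def scalar(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def evaluate(self, x, y) -> np.ndarray:
        """The 3x3 kernel matrix at a single pair of points."""
        g = self.scalar(np.atleast_2d(x), np.atleast_2d(y))[0, 0]
        return g * np.eye(3)

    def gram(self, X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
        """Full (3|X|, 3|Y|) Gram matrix (vertex-major ordering)."""
        Y = X if Y is None else Y
        return np.kron(self.scalar(np.asarray(X), np.asarray(Y)), np.eye(3))

    def __add__(self, other: "Kernel") -> "Kernel":
        return SumKernel(self, other)

    def __mul__(self, c: float) -> "Kernel":
        return ScaledKernel(self, float(c))

    __rmul__ = __mul__


@dataclass
class GaussianKernel(Kernel):
    """k(x, y) = s * exp(-||x-y||^2 / sigma^2) * I3 (sigma in mm)."""

    s: float = 1.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.s <= 0 or self.sigma <= 0:
            raise ValueError("kernel scale and bandwidth must be positive")

    def scalar(self, X, Y):
        X = np.asarray(X, float)
        Y = np.asarray(Y, float)
        d2 = ((X[:, None, :] - Y[None, :, :]) ** 2).sum(-1)
        return self.s * np.exp(-d2 / self.sigma**2)


@dataclass
class SumKernel(Kernel):
    a: Kernel
    b: Kernel

    def scalar(self, X, Y):
        return self.a.scalar(X, Y) + self.b.scalar(X, Y)


@dataclass
class ScaledKernel(Kernel):
    base: Kernel
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("kernel scale factor must be positive")

    def scalar(self, X, Y):
        return self.factor * self.base.scalar(X, Y)


# ---------------------------------------------------------------------------
# low-rank GP representation
# ---------------------------------------------------------------------------


@dataclass
class LowRankGP:
    """Rank-r Karhunen-Loeve representation of a GP on reference vertices.

    ``basis`` has orthonormal columns of length 3V (vertex-major x,y,z
    stacking); ``variances`` are the corresponding eigenvalues, descending.
    When built from an analytic kernel the Nystrom data needed to evaluate
    the basis at arbitrary points is retained.
    """

    reference: SurfaceMesh
    mean_field: np.ndarray  # (V, 3)
    basis: np.ndarray  # (3V, r)
    variances: np.ndarray  # (r,)
    kernel: Kernel | None = None
    sample_points: np.ndarray | None = None  # Nystrom anchor points (m, 3)
    extension: np.ndarray | None = None  # (3m, r): phi(x) = kron(g(x, anchors), I3) @ extension

    def __post_init__(self) -> None:
        V = self.reference.n_vertices
        self.mean_field = np.asarray(self.mean_field, float).reshape(V, 3)
        self.basis = np.asarray(self.basis, float)
        self.variances = np.asarray(self.variances, float)
        if self.basis.shape[0] != 3 * V:
            raise DimensionError("basis rows must equal 3 * vertex count")
        if self.basis.shape[1] != len(self.variances):
            raise DimensionError("one variance per basis field required")

    @property
    def rank(self) -> int:
        return self.basis.shape[1]

    def sample(self, alpha: np.ndarray) -> np.ndarray:
        """Deformation field mu + sum_i alpha_i sqrt(lambda_i) phi_i, (V, 3)."""
        alpha = np.asarray(alpha, float).ravel()
        if len(alpha) != self.rank:
            raise DimensionError(f"expected {self.rank} coefficients, got {len(alpha)}")
        coef = alpha * np.sqrt(np.maximum(self.variances, 0.0))
        return self.mean_field + (self.basis @ coef).reshape(-1, 3)

    def sample_batch(self, alphas: np.ndarray) -> np.ndarray:
        """Fields for a (B, r) batch of coefficients, shape (B, V, 3)."""
        coef = np.asarray(alphas, float) * np.sqrt(np.maximum(self.variances, 0.0))
        return self.mean_field[None] + (coef @ self.basis.T).reshape(len(coef), -1, 3)

    def deformed_vertices(self, alpha: np.ndarray) -> np.ndarray:
        return self.reference.vertices + self.sample(alpha)

    def basis_at(self, points: np.ndarray) -> np.ndarray:
        """Kernel (Nystrom) extension of the basis fields to arbitrary points,
        shape (3P, r).  Only available for kernel-built models."""
        if self.kernel is None or self.extension is None:
            raise DegenerateInputError("this GP has no kernel extension")
        g = self.kernel.scalar(np.asarray(points, float), self.sample_points)
        return np.kron(g, np.eye(3)) @ self.extension

    def mean_at(self, points: np.ndarray) -> np.ndarray:
        if np.allclose(self.mean_field, 0):
            return np.zeros((len(points), 3))
        raise DegenerateInputError("nonzero mean has no kernel extension")

    def random_coefficients(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        return rng.standard_normal((size, self.rank))

    def save(self, path: str) -> None:
        """Archive the model: reference mesh + mean/basis/variances + metadata
        (kernel spec when the model was kernel-built)."""
        import json as _json

        meta = {"rank": int(self.rank)}
        if isinstance(self.kernel, GaussianKernel):
            meta["kernel"] = {"type": "gauss", "s": self.kernel.s,
                              "sigma": self.kernel.sigma}
        arrays = {
            "vertices": self.reference.vertices,
            "faces": self.reference.faces,
            "mean_field": self.mean_field,
            "basis": self.basis,
            "variances": self.variances,
            "meta": _json.dumps(meta),
        }
        if self.sample_points is not None and self.extension is not None:
            arrays["sample_points"] = self.sample_points
            arrays["extension"] = self.extension
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "LowRankGP":
        import json as _json

        z = np.load(path, allow_pickle=False)
        meta = _json.loads(str(z["meta"]))
        kernel = None
        if "kernel" in meta and meta["kernel"]["type"] == "gauss":
            kernel = GaussianKernel(meta["kernel"]["s"], meta["kernel"]["sigma"])
        return cls(
            SurfaceMesh(z["vertices"], z["faces"]),
            z["mean_field"],
            z["basis"],
            z["variances"],
            kernel=kernel,
            sample_points=z["sample_points"] if "sample_points" in z else None,
            extension=z["extension"] if "extension" in z else None,
        )


def build_low_rank_gp(
    kernel: Kernel,
    reference: SurfaceMesh,
    r: int,
    m: int | None = None,
    seed: int = 0,
    dense_limit: int = 1000,
) -> LowRankGP:
    """Karhunen-Loeve basis of a kernel restricted to the reference vertices.

    Dense eigendecomposition when ``3 * V <= dense_limit`` (or ``m >= V``);
    otherwise the Nystrom approximation on ``m`` uniformly sampled vertices
    (seeded).  The returned basis is exactly orthonormal in both cases; if
    fewer than ``r`` positive eigenvalues exist the rank is truncated with a
    warning.
    """
    X = reference.vertices
    V = len(X)
    if r > 3 * V:
        raise DimensionError("rank cannot exceed 3 * vertex count")
    if m is None:
        m = V if 3 * V <= dense_limit else min(V, max(r * 4, 100))
    m = min(max(m, int(np.ceil(r / 3))), V)
    if m >= V:
        anchors = X
    else:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(V, size=m, replace=False))
        anchors = X[idx]
    C = kernel.gram(anchors)  # (3m, 3m)
    w, U = np.linalg.eigh(C)
    keep = w > max(w.max(), 0) * 1e-12
    C_inv_sqrt = U[:, keep] / np.sqrt(w[keep])  # (3m, p)
    B = kernel.gram(X, anchors) @ C_inv_sqrt  # (3V, p); K approx B Bᵀ
    Mmat = B.T @ B
    s, Q = np.linalg.eigh(Mmat)
    order = np.argsort(s)[::-1]
    s, Q = s[order], Q[:, order]
    pos = s > max(s[0], 0) * 1e-12
    s, Q = s[pos], Q[:, pos]
    if len(s) < r:
        log.warning("requested rank %d exceeds positive spectrum %d; truncating", r, len(s))
    r_eff = min(r, len(s))
    basis = B @ (Q[:, :r_eff] / np.sqrt(s[:r_eff]))
    extension = C_inv_sqrt @ (Q[:, :r_eff] / np.sqrt(s[:r_eff]))
    return LowRankGP(
        reference,
        np.zeros((V, 3)),
        basis,
        s[:r_eff],
        kernel=kernel,
        sample_points=anchors,
        extension=extension,
    )


def sample_deformation(gp: LowRankGP, alpha: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`LowRankGP.sample`."""
    return gp.sample(alpha)


# ---------------------------------------------------------------------------
# empirical GP from example deformation fields
# ---------------------------------------------------------------------------


def empirical_mean(fields: np.ndarray) -> np.ndarray:
    """Arithmetic mean deformation field, (V, 3)."""
    return np.asarray(fields, float).mean(0)


def empirical_kernel(fields: np.ndarray, x_idx, y_idx=None) -> np.ndarray:
    """Sample covariance k(X, Y) between reference vertices, 3x3 blocks with
    1/(N-1) normalization (direct evaluation, used as oracle and for tests)."""
    F = np.asarray(fields, float)
    N = len(F)
    if N < 2:
        raise DegenerateInputError("empirical kernel needs at least 2 fields")
    mu = F.mean(0)
    dev = F - mu
    y_idx = x_idx if y_idx is None else y_idx
    return np.einsum("ni,nj->ij", dev[:, x_idx, :], dev[:, y_idx, :]) / (N - 1)


def build_empirical_gp(reference: SurfaceMesh, fields: np.ndarray) -> LowRankGP:
    """Low-rank GP with the empirical mean (Eq. of the arithmetic average)
    and the 1/(N-1) sample covariance of the deformation fields, factorized
    through the N x N Gram matrix (rank <= N-1)."""
    F = np.asarray(fields, dtype=float)
    if F.ndim != 3 or F.shape[1] != reference.n_vertices or F.shape[2] != 3:
        raise DimensionError("fields must have shape (N, V, 3) on the reference vertices")
    N = F.shape[0]
    if N < 2:
        raise DegenerateInputError("need at least 2 deformation fields")
    mu = F.mean(0)
    dev = (F - mu).reshape(N, -1)  # (N, 3V)
    gram = dev @ dev.T / (N - 1)
    w, U = np.linalg.eigh(gram)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    keep = w > max(w[0], 0) * 1e-12
    w, U = w[keep], U[:, keep]
    basis = dev.T @ U / np.sqrt(w * (N - 1))
    return LowRankGP(reference, mu, basis, w)


# ---------------------------------------------------------------------------
# GP-regularized correspondence
# ---------------------------------------------------------------------------


@dataclass
class CorrespondenceResult:
    field: np.ndarray  # (V, 3) deformation of the reference
    alpha: np.ndarray
    residual: float  # symmetric mean closest-point distance (mm)
    objective_trace: list
    converged: bool


def establish_correspondence(
    prior: LowRankGP,
    target: SurfaceMesh,
    max_iter: int = 50,
    ridge: float = 1e-3,
    tol: float = 1e-6,
) -> CorrespondenceResult:
    """Register the GP model to a target surface, yielding a deformation
    field of the reference in the model span.

    Alternates closest-point correspondence with a ridge-regularized linear
    projection of the matched displacements onto the GP basis; a step is
    accepted only if the symmetric mean closest-point distance decreases
    (damping is shrunk otherwise), so the objective trace is non-increasing.
    """
    ref = prior.reference.vertices
    tree_t = cKDTree(target.vertices)
    sqrt_lam = np.sqrt(np.maximum(prior.variances, 1e-30))
    alpha = np.zeros(prior.rank)

    def objective(a):
        verts = ref + prior.sample(a)
        d1 = tree_t.query(verts, k=1)[0]
        d2 = cKDTree(verts).query(target.vertices, k=1)[0]
        return (d1.sum() + d2.sum()) / (len(d1) + len(d2))

    obj = objective(alpha)
    trace = [obj]
    damping = 1.0
    converged = False
    for _ in range(max_iter):
        verts = ref + prior.sample(alpha)
        _, nn = tree_t.query(verts, k=1)
        matched = target.vertices[nn]
        resid = (matched - ref - prior.mean_field).ravel()
        # exact ridge solution thanks to orthonormal basis columns
        proj = prior.basis.T @ resid
        alpha_star = proj * sqrt_lam / (sqrt_lam**2 + ridge)
        accepted = False
        d = damping
        for _ in range(8):
            cand = alpha + d * (alpha_star - alpha)
            val = objective(cand)
            if val < obj - 1e-12:
                alpha, obj = cand, val
                trace.append(obj)
                accepted = True
                damping = min(1.0, d * 2)
                break
            d *= 0.5
        if not accepted:
            converged = True
            break
        if abs(trace[-2] - trace[-1]) < tol * max(1.0, trace[-2]):
            converged = True
            break
    field = prior.sample(alpha)
    return CorrespondenceResult(field, alpha, obj, trace, converged)


# ---------------------------------------------------------------------------
# segmentation of a new case
# ---------------------------------------------------------------------------


@dataclass
class GPMMFitConfig:
    """Random-search fitting parameters."""

    iterations: int = 200
    candidates: int = 20
    sigma0: float = 1.0  # initial proposal std (units of sqrt(lambda))
    sigma_final: float = 0.1
    alpha_limit: float | None = None  # optional clamp on |alpha_i|
    profile_half_length: int = 4
    seed: int = 0


def _vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    fn = np.cross(
        vertices[faces[:, 1]] - vertices[faces[:, 0]],
        vertices[faces[:, 2]] - vertices[faces[:, 0]],
    )
    normals = np.zeros_like(vertices)
    for c in range(3):
        np.add.at(normals, faces[:, c], fn)
    nrm = np.linalg.norm(normals, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return normals / nrm


def profile_cost(
    vol: Volume,
    vertices: np.ndarray,
    faces: np.ndarray,
    profiles: GrayProfileModel,
    half_length: int,
) -> float:
    """Summed per-vertex Mahalanobis distance of image profiles to the model."""
    normals = _vertex_normals(vertices, faces)
    g = sample_profile(vol, vertices, normals, half_length)
    return float(profiles.mahalanobis(g[:, None, :], level=1.0)[:, 0].sum())


def _batch_vertex_normals(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted unit vertex normals for a (B, V, 3) batch of meshes."""
    B, V = verts.shape[:2]
    fn = np.cross(
        verts[:, faces[:, 1]] - verts[:, faces[:, 0]],
        verts[:, faces[:, 2]] - verts[:, faces[:, 0]],
    )  # (B, F, 3)
    normals = np.zeros((B * V, 3))
    base = (np.arange(B) * V)[:, None]
    for c in range(3):
        idx = (base + faces[None, :, c]).ravel()
        np.add.at(normals, idx, fn.reshape(-1, 3))
    normals = normals.reshape(B, V, 3)
    nrm = np.linalg.norm(normals, axis=-1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return normals / nrm


def _profile_cost_batch(
    vol: Volume,
    verts: np.ndarray,  # (B, V, 3)
    faces: np.ndarray,
    profiles: GrayProfileModel,
    half_length: int,
) -> np.ndarray:
    """Vectorized :func:`profile_cost` over a batch of candidate shapes."""
    from .profiles import _sample_intensities

    B, V = verts.shape[:2]
    normals = _batch_vertex_normals(verts, faces)
    step = float(min(vol.spacing))
    offsets = (np.arange(2 * half_length + 2) - (half_length + 0.5)) * step
    pos = verts[:, :, None, :] + offsets[None, None, :, None] * normals[:, :, None, :]
    samples = _sample_intensities(vol, pos)  # (B, V, 2k+2)
    deriv = np.diff(samples, axis=-1)
    denom = np.abs(deriv).sum(axis=-1, keepdims=True)
    g = deriv / np.where(denom < 1e-12, 1.0, denom)
    st = profiles.stats(1.0)
    dev = g - st.mean[None]
    return np.einsum("bvi,vij,bvj->b", dev, st.inv_cov, dev)


def fit_gpmm(
    vol: Volume,
    model: LowRankGP,
    profiles: GrayProfileModel,
    init=None,
    config: GPMMFitConfig | None = None,
) -> tuple[SurfaceMesh, np.ndarray, list]:
    """Fit a GP shape model to an image by candidate sampling.

    At every iteration ``candidates`` coefficient vectors are drawn around
    the current best from the (annealed) Gaussian proposal, each whole-shape
    candidate is scored by the summed per-vertex profile Mahalanobis
    distance, and the best is kept.  All accepted shapes lie exactly in the
    model span; the run is reproducible for a fixed seed.

    ``init`` is an optional pose callable/transform applied to model-space
    vertices (e.g. a SimilarityTransform from pose initialization).

    Returns the fitted surface, the coefficients, and the score trace.
    """
    config = config or GPMMFitConfig()
    faces = model.reference.faces
    rng = np.random.default_rng(config.seed)

    def to_world(v):
        if init is None:
            return v
        return init.apply(v) if hasattr(init, "apply") else init(v)

    verts0 = to_world(model.reference.vertices + model.sample(np.zeros(model.rank)))
    lo = vol.index_to_world(np.zeros(3))
    hi = vol.index_to_world(np.asarray(vol.shape) - 1)
    if np.any(verts0.min(0) > hi) or np.any(verts0.max(0) < lo):
        raise DegenerateInputError("initialized model lies outside the image volume")
    best_alpha = np.zeros(model.rank)
    best_cost = profile_cost(vol, verts0, faces, profiles, config.profile_half_length)
    trace = [best_cost]
    if config.iterations <= 0:
        return SurfaceMesh(verts0, faces.copy()), best_alpha, trace
    sigmas = np.geomspace(config.sigma0, config.sigma_final, config.iterations)
    for it in range(config.iterations):
        prop = best_alpha[None, :] + sigmas[it] * rng.standard_normal(
            (config.candidates, model.rank)
        )
        if config.alpha_limit is not None:
            np.clip(prop, -config.alpha_limit, config.alpha_limit, out=prop)
        fields = model.sample_batch(prop)
        verts = model.reference.vertices[None] + fields
        if init is not None:
            verts = np.stack([to_world(v) for v in verts])
        costs = _profile_cost_batch(vol, verts, faces, profiles,
                                    config.profile_half_length)
        c = int(costs.argmin())
        if costs[c] < best_cost:
            best_cost = float(costs[c])
            best_alpha = prop[c]
        trace.append(best_cost)
    verts = to_world(model.reference.vertices + model.sample(best_alpha))
    return SurfaceMesh(verts, faces.copy()), best_alpha, trace


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class GPMMSegmenter:
    """GPMM segmentation as a fit/predict estimator (sklearn conventions).

    fit(volumes, meshes) expects training surfaces whose vertices are in
    correspondence with a common reference (``correspondence='given'``: the
    first mesh — or an explicit ``reference`` — defines the vertex set and
    per-case deformation fields are vertex differences; ``'estimate'`` runs
    GP-regularized correspondence with an analytic Gaussian prior instead).
    predict(volume) samples shape candidates from the learned deformation
    distribution and keeps the best-scoring one, returning a binary mask.
    """

    def __init__(
        self,
        reference: SurfaceMesh | None = None,
        correspondence: str = "given",
        iterations: int = 200,
        candidates: int = 20,
        sigma0: float = 1.0,
        sigma_final: float = 0.1,
        alpha_limit: float | None = None,
        profile_half_length: int = 4,
        prior_rank: int = 100,
        seed: int = 0,
        init: str = "none",
    ):
        self.reference = reference
        self.correspondence = correspondence
        self.iterations = iterations
        self.candidates = candidates
        self.sigma0 = sigma0
        self.sigma_final = sigma_final
        self.alpha_limit = alpha_limit
        self.profile_half_length = profile_half_length
        self.prior_rank = prior_rank
        self.seed = seed
        self.init = init

    # minimal get/set_params so the estimator composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "reference correspondence iterations candidates sigma0 sigma_final "
                "alpha_limit profile_half_length prior_rank seed init".split()
            )
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _fit_config(self) -> GPMMFitConfig:
        return GPMMFitConfig(
            iterations=self.iterations,
            candidates=self.candidates,
            sigma0=self.sigma0,
            sigma_final=self.sigma_final,
            alpha_limit=self.alpha_limit,
            profile_half_length=self.profile_half_length,
            seed=self.seed,
        )

    def fit(self, volumes: list[Volume], meshes: list[SurfaceMesh],
            fields: np.ndarray | None = None):
        from .profiles import build_profile_model

        ref = self.reference if self.reference is not None else meshes[0]
        if fields is not None:
            F = np.asarray(fields, float)
        elif self.correspondence == "given":
            F = np.stack([m.vertices - ref.vertices for m in meshes])
        elif self.correspondence == "estimate":
            diag = ref.bounding_box_diagonal()
            kern = GaussianKernel(s=(0.05 * diag) ** 2, sigma=0.3 * diag)
            prior = build_low_rank_gp(kern, ref, r=self.prior_rank, seed=self.seed)
            F = np.stack(
                [establish_correspondence(prior, m).field for m in meshes]
            )
        else:
            raise ValueError(f"unknown correspondence mode {self.correspondence!r}")
        self.model_ = build_empirical_gp(ref, F)
        verts_sets = [ref.vertices + f for f in F]
        normal_sets = [
            _vertex_normals(v, ref.faces) for v in verts_sets
        ]
        self.profiles_ = build_profile_model(
            volumes, verts_sets, normal_sets,
            half_length=self.profile_half_length, resolutions=(1.0,),
        )
        return self

    def predict(self, vol: Volume) -> "LabelMask":
        from .core import surface_to_mask
        from .registration import moments_pose

        pose = None
        if self.init == "moments":
            mean_pts = self.model_.reference.vertices + self.model_.mean_field
            pose = moments_pose(vol, mean_pts, with_scale=False)
        mesh, alpha, trace = fit_gpmm(
            vol, self.model_, self.profiles_, init=pose, config=self._fit_config()
        )
        self.last_alpha_ = alpha
        self.last_trace_ = trace
        self.last_mesh_ = mesh
        return surface_to_mask(mesh, vol.shape, vol.spacing, vol.origin)
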