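"""Similarity and B-spline free-form deformation (FFD) registration.

The non-rigid transform is a cubic B-spline FFD: a coarse control-point
lattice is superimposed on the fixed image and the dense displacement at a
point is the tensor-product spline interpolation of the 4x4x4 surrounding
control displacements,

    u(x) = sum_{l,m,n=0..3} B_l(mu_x) B_m(mu_y) B_n(mu_z) d_{i+l, j+m, k+n}

with the standard uniform cubic basis B_0..B_3.  Registration minimizes a
similarity cost (mean squared difference, or negated mutual information from
the joint histogram) over the transform parameters; the similarity stage
uses a derivative-free Powell search, the FFD stage a gradient descent with
analytic cost gradients scattered onto the lattice and step halving.

Both optimizers run coarse-to-fine over an image pyramid and are fully
deterministic for fixed inputs and configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .core import LabelMask, Volume
from .errors import ConvergenceError, DegenerateInputError, DimensionError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cubic B-spline basis
# ---------------------------------------------------------------------------


def bspline_basis(mu: np.ndarray) -> np.ndarray:
    """The four uniform cubic B-spline basis functions at ``mu`` in [0, 1).

    Returns an array of shape ``mu.shape + (4,)``; the four weights sum to 1
    (partition of unity).
    """
    mu = np.asarray(mu, dtype=float)
    m2 = mu * mu
    m3 = m2 * mu
    out = np.empty(mu.shape + (4,))
    out[..., 0] = (1 - mu) ** 3 / 6.0
    out[..., 1] = (3 * m3 - 6 * m2 + 4) / 6.0
    out[..., 2] = (-3 * m3 + 3 * m2 + 3 * mu + 1) / 6.0
    out[..., 3] = m3 / 6.0
    return out


@dataclass
class BSplineGrid:
    """Control-point lattice of an FFD transform (world mm)."""

    dims: tuple[int, int, int]
    grid_spacing: tuple[float, float, float]
    grid_origin: tuple[float, float, float]
    displacements: np.ndarray = None  # (Kx, Ky, Kz, 3) mm

    def __post_init__(self) -> None:
        self.dims = tuple(int(k) for k in self.dims)
        if min(self.dims) < 4:
            raise DimensionError("cubic FFD needs at least 4 control points per axis")
        self.grid_spacing = tuple(float(s) for s in self.grid_spacing)
        self.grid_origin = tuple(float(o) for o in self.grid_origin)
        if self.displacements is None:
            self.displacements = np.zeros(self.dims + (3,))
        self.displacements = np.asarray(self.displacements, dtype=float).reshape(
            self.dims + (3,)
        )
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("control displacements must be finite")

    # -- evaluation ---------------------------------------------------------

    def _cells(self, points: np.ndarray):
        t = (np.asarray(points, float) - self.grid_origin) / self.grid_spacing
        base = np.floor(t).astype(int) - 1  # first of the 4 support control points
        mu = t - np.floor(t)
        return base, mu

    def support_mask(self, points: np.ndarray) -> np.ndarray:
        base, _ = self._cells(points)
        dims = np.asarray(self.dims)
        return ((base >= 0) & (base + 3 <= dims - 1)).all(axis=-1)

    def displacement(self, points: np.ndarray, outside: str = "error") -> np.ndarray:
        """Displacement (mm) at world points, shape (N, 3).

        ``outside``: 'error' raises for points without full 4x4x4 lattice
        support, 'zero' returns a zero displacement there.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        base, mu = self._cells(pts)
        ok = self.support_mask(pts)
        if not ok.all():
            if outside == "error":
                raise DegenerateInputError(
                    f"{(~ok).sum()} point(s) outside the control-lattice support"
                )
            base = np.where(ok[:, None], base, 0)
        w = bspline_basis(mu)  # (N, 3, 4)
        out = np.zeros((len(pts), 3))
        D = self.displacements
        for chunk in np.array_split(np.arange(len(pts)), max(1, len(pts) // 65536)):
            b = base[chunk]
            idx = (
                b[:, 0, None, None, None] + np.arange(4)[None, :, None, None],
                b[:, 1, None, None, None] + np.arange(4)[None, None, :, None],
                b[:, 2, None, None, None] + np.arange(4)[None, None, None, :],
            )
            gath = D[idx]  # (n, 4, 4, 4, 3)
            wc = (
                w[chunk][:, 0, :, None, None]
                * w[chunk][:, 1, None, :, None]
                * w[chunk][:, 2, None, None, :]
            )
            out[chunk] = np.einsum("nlmk,nlmkd->nd", wc, gath)
        if not ok.all():
            out[~ok] = 0.0
        return out if np.asarray(points).ndim > 1 else out[0]

    # -- separable dense evaluation on a regular grid -----------------------

    def _axis_weights(self, n: int, spacing: float, origin: float, axis: int) -> np.ndarray:
        """Dense (n, K) B-spline weight matrix for one image axis."""
        x = origin + spacing * np.arange(n)
        t = (x - self.grid_origin[axis]) / self.grid_spacing[axis]
        base = np.floor(t).astype(int) - 1
        if base.min() < 0 or base.max() + 3 > self.dims[axis] - 1:
            raise DegenerateInputError("image grid extends beyond lattice support")
        w = bspline_basis(t - np.floor(t))  # (n, 4)
        W = np.zeros((n, self.dims[axis]))
        rows = np.repeat(np.arange(n), 4)
        cols = (base[:, None] + np.arange(4)[None, :]).ravel()
        W[rows, cols] = w.ravel()
        return W

    def dense_field(self, shape, spacing, origin) -> np.ndarray:
        """Displacement field (mm) on every voxel center of a regular grid."""
        Wx = self._axis_weights(shape[0], spacing[0], origin[0], 0)
        Wy = self._axis_weights(shape[1], spacing[1], origin[1], 1)
        Wz = self._axis_weights(shape[2], spacing[2], origin[2], 2)
        t = np.einsum("xa,abcd->xbcd", Wx, self.displacements)
        t = np.einsum("yb,xbcd->xycd", Wy, t)
        return np.einsum("zc,xycd->xyzd", Wz, t)

    def scatter_adjoint(self, forces: np.ndarray, shape, spacing, origin) -> np.ndarray:
        """Adjoint of :meth:`dense_field`: scatter per-voxel 3-vector forces
        back to the control points (the chain-rule factor of the cost
        gradient)."""
        Wx = self._axis_weights(shape[0], spacing[0], origin[0], 0)
        Wy = self._axis_weights(shape[1], spacing[1], origin[1], 1)
        Wz = self._axis_weights(shape[2], spacing[2], origin[2], 2)
        t = np.einsum("xa,xyzd->ayzd", Wx, forces)
        t = np.einsum("yb,ayzd->abzd", Wy, t)
        return np.einsum("zc,abzd->abcd", Wz, t)

    def to_json(self) -> str:
        return json.dumps(
            {
                "type": "bspline",
                "dims": list(self.dims),
                "grid_spacing": list(self.grid_spacing),
                "grid_origin": list(self.grid_origin),
                "displacements": self.displacements.ravel().tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "BSplineGrid":
        d = json.loads(s)
        return cls(
            tuple(d["dims"]),
            tuple(d["grid_spacing"]),
            tuple(d["grid_origin"]),
            np.asarray(d["displacements"]),
        )


def bspline_grid_for_volume(vol: Volume, grid_spacing_mm: float) -> BSplineGrid:
    """Lattice covering a volume with one extra control point beyond each side
    so every voxel center has full cubic support."""
    gs = np.full(3, float(grid_spacing_mm))
    extent = (np.asarray(vol.shape) - 1) * np.asarray(vol.spacing)
    ncells = np.maximum(1, np.ceil(extent / gs).astype(int))
    dims = tuple(int(n) + 4 for n in ncells)
    origin = tuple(np.asarray(vol.origin) - gs)
    return BSplineGrid(dims, tuple(gs), origin)


# ---------------------------------------------------------------------------
# similarity transform
# ---------------------------------------------------------------------------


@dataclass
class SimilarityTransform:
    """7-parameter transform: isotropic scale, rotation, translation (mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.scale = float(self.scale)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-10):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return (
            self.scale * (p - self.center) @ self.rotation.T + self.center + self.translation
        )

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()

    @classmethod
    def from_params(cls, params: np.ndarray, center=(0, 0, 0), with_scale=True):
        params = np.asarray(params, dtype=float)
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        scale = float(np.exp(params[6])) if with_scale and len(params) > 6 else 1.0
        return cls(rot, params[3:6], scale, np.asarray(center, float))

    def to_params(self, with_scale=True) -> np.ndarray:
        rv = Rotation.from_matrix(self.rotation).as_rotvec()
        p = np.concatenate([rv, self.translation])
        if with_scale:
            p = np.concatenate([p, [np.log(self.scale)]])
        return p

    def to_json(self) -> str:
        return json.dumps(
            {
                "type": "similarity",
                "rotation": self.rotation.ravel().tolist(),
                "translation": self.translation.tolist(),
                "scale": self.scale,
                "center": self.center.tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "SimilarityTransform":
        d = json.loads(s)
        return cls(
            np.asarray(d["rotation"]).reshape(3, 3),
            d["translation"],
            d["scale"],
            d.get("center", (0, 0, 0)),
        )


@dataclass
class CompositeTransform:
    """Similarity pose followed by an additive FFD displacement:
    ``T(x) = S(x) + u(x)`` with ``u`` defined over the fixed domain."""

    similarity: SimilarityTransform
    ffd: BSplineGrid | None = None

    def apply(self, points: np.ndarray) -> np.ndarray:
        out = self.similarity.apply(points)
        if self.ffd is not None:
            out = out + self.ffd.displacement(points, outside="zero")
        return out


def transform_points(transform, points: np.ndarray) -> np.ndarray:
    """Map fixed-domain world points through any supported transform."""
    if transform is None:
        return np.asarray(points, dtype=float)
    if isinstance(transform, BSplineGrid):
        return np.asarray(points, float) + transform.displacement(points, outside="zero")
    return transform.apply(points)


# ---------------------------------------------------------------------------
# sampling and costs
# ---------------------------------------------------------------------------


def _fixed_grid_points(fixed: Volume) -> np.ndarray:
    idx = np.stack(
        np.meshgrid(*(np.arange(n) for n in fixed.shape), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    return fixed.index_to_world(idx)


def _sample(moving: Volume, world_pts: np.ndarray, order: int = 1):
    """Interpolate a moving volume at world points; returns (values, valid)."""
    ci = moving.world_to_index(world_pts).T  # (3, N)
    valid = np.all(
        (ci >= 0) & (ci <= (np.asarray(moving.shape) - 1)[:, None]), axis=0
    )
    vals = ndimage.map_coordinates(
        moving.voxels.astype(float), ci, order=order, mode="nearest", prefilter=False
    )
    return vals, valid


def warp_volume(moving: Volume, transform, fixed_like: Volume, order: int = 1,
                background: float = 0.0) -> Volume:
    """Resample ``moving`` onto the grid of ``fixed_like`` through ``transform``."""
    pts = _fixed_grid_points(fixed_like)
    warped = transform_points(transform, pts)
    vals, valid = _sample(moving, warped, order=order)
    vals[~valid] = background
    return Volume(vals.reshape(fixed_like.shape), fixed_like.spacing, fixed_like.origin)


def warp_mask(mask: LabelMask, transform, fixed_like: Volume | None = None) -> LabelMask:
    """Propagate a binary mask through a transform with nearest-neighbor
    resampling onto the target grid (atlas-propagation step)."""
    target = fixed_like if fixed_like is not None else mask
    pts = _fixed_grid_points(target)
    warped = transform_points(transform, pts)
    vals, valid = _sample(
        Volume(mask.voxels.astype(float), mask.spacing, mask.origin), warped, order=0
    )
    vals[~valid] = 0
    out = (vals > 0.5).astype(np.uint8).reshape(target.shape)
    return LabelMask(out, target.spacing, target.origin)


_MIN_OVERLAP = 0.10


def _overlap_values(fixed: Volume, moving: Volume, transform):
    pts = _fixed_grid_points(fixed)
    warped = transform_points(transform, pts)
    mvals, valid = _sample(moving, warped)
    if valid.mean() < _MIN_OVERLAP:
        raise DegenerateInputError(
            f"transform leaves only {100 * valid.mean():.1f}% overlap (<10%)"
        )
    return fixed.voxels.ravel()[valid].astype(float), mvals[valid]


def ssd_cost(fixed: Volume, moving: Volume, transform=None) -> float:
    """Mean squared intensity difference over the overlap region."""
    f, m = _overlap_values(fixed, moving, transform)
    return float(np.mean((f - m) ** 2))


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _hist_range(vol: Volume) -> tuple[float, float]:
    lo, hi = np.percentile(vol.voxels, [1, 99])
    if hi <= lo:
        hi = lo + 1.0
    return float(lo), float(hi)


def mutual_information(f: np.ndarray, m: np.ndarray, bins: int = 32,
                       f_range=None, m_range=None) -> float:
    """MI = H(F) + H(M) - H(F, M) from a joint histogram (natural logs)."""
    if f_range is None:
        f_range = (f.min(), f.max())
    if m_range is None:
        m_range = (m.min(), m.max())
    if f_range[1] <= f_range[0] or m_range[1] <= m_range[0]:
        log.warning("constant image in overlap: MI degenerates to 0")
        return 0.0
    joint, _, _ = np.histogram2d(
        np.clip(f, *f_range), np.clip(m, *m_range), bins=bins, range=[f_range, m_range]
    )
    p = joint / joint.sum()
    return _entropy(p.sum(1)) + _entropy(p.sum(0)) - _entropy(p.ravel())


def mi_cost(fixed: Volume, moving: Volume, transform=None, bins: int = 32) -> float:
    """Negated mutual information (to be *minimized*)."""
    f, m = _overlap_values(fixed, moving, transform)
    return -mutual_information(f, m, bins=bins, f_range=_hist_range(fixed),
                               m_range=_hist_range(moving))


# ---------------------------------------------------------------------------
# registration result & config
# ---------------------------------------------------------------------------


@dataclass
class RegistrationResult:
    """Optimized transform plus per-iteration cost bookkeeping.

    ``cost_trace`` concatenates all accepted costs; ``level_traces`` holds
    one list per pyramid level (costs at different resolutions are not
    comparable across levels, but are non-increasing within one)."""

    parameters: object
    cost_trace: list
    converged: bool
    level_traces: list = field(default_factory=list)


@dataclass
class RegistrationConfig:
    """Knobs of both registration stages (all deterministic)."""

    metric: str = "mi"  # {'ssd', 'mi'}
    bins: int = 32
    levels: tuple[float, ...] = (0.25, 0.5, 1.0)
    max_iter: int = 100
    grid_spacing_mm: float = 16.0
    with_scale: bool = True
    background: float = 0.0
    ffd_tol: float = 1e-7
    seed: int = 0


_MIN_LEVEL_DIM = 12


def _downsample(vol: Volume, factor: float) -> Volume:
    # never shrink below a usable histogram/gradient size
    factor = min(1.0, max(factor, _MIN_LEVEL_DIM / min(vol.shape)))
    if factor >= 1.0:
        return vol
    sigma = 0.5 / factor
    sm = ndimage.gaussian_filter(vol.voxels.astype(float), sigma)
    data = ndimage.zoom(sm, factor, order=1, mode="nearest")
    new_spacing = tuple(np.asarray(vol.spacing) / factor)
    return Volume(data, new_spacing, vol.origin)


def moments_pose(vol: Volume, model_pts: np.ndarray, with_scale: bool = True
                 ) -> SimilarityTransform:
    """Translation(+scale) pose placing a model at the image foreground.

    The foreground is estimated with an Otsu threshold; the model centroid is
    moved to the foreground centroid and (optionally) scaled so the bounding
    volumes match.  A cheap, deterministic initializer for model fitting."""
    from skimage.filters import threshold_otsu

    data = vol.voxels.astype(float)
    thr = threshold_otsu(data)
    fg = data > thr
    if not fg.any():
        raise DegenerateInputError("no foreground found for pose initialization")
    idx = np.argwhere(fg)
    com = vol.index_to_world(idx.mean(0))
    model_pts = np.asarray(model_pts, float)
    centered = model_pts - model_pts.mean(0)
    scale = 1.0
    if with_scale and np.abs(centered).max() > 0:
        ext = (idx.max(0) - idx.min(0) + 1) * np.asarray(vol.spacing)
        model_ext = centered.max(0) - centered.min(0)
        scale = float(np.cbrt(np.prod(ext) / max(np.prod(model_ext), 1e-12)))
    translation = com - scale * model_pts.mean(0)
    return SimilarityTransform(np.eye(3), translation, scale)


def _cost_fn(metric: str, bins: int):
    if metric == "ssd":
        return lambda F, M, T: ssd_cost(F, M, T)
    if metric == "mi":
        return lambda F, M, T: mi_cost(F, M, T, bins=bins)
    raise ValueError(f"unknown metric {metric!r}")


_MAX_COST_POINTS = 32768


def _adaptive_bins(bins: int, n_samples: int) -> int:
    """Cap the histogram bin count so sparse overlaps keep usable statistics."""
    return int(np.clip(round(np.sqrt(n_samples / 32.0)), 8, bins))


def _strided_points(fixed: Volume, max_points: int = _MAX_COST_POINTS):
    """Fixed-grid voxel centers subsampled to a budget (with their values)."""
    n = int(np.prod(fixed.shape))
    stride = max(1, int(np.ceil((n / max_points) ** (1 / 3))))
    sl = (slice(None, None, stride),) * 3
    idx = np.stack(
        np.meshgrid(*(np.arange(0, fixed.shape[a], stride) for a in range(3)),
                    indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    return fixed.index_to_world(idx), fixed.voxels[sl].ravel().astype(float)


def _point_cost(metric, bins, fvals, pts, M, f_range, m_range):
    """Cost on precomputed fixed points (fast inner loop of the optimizers)."""

    def cost(transform) -> float:
        warped = transform_points(transform, pts)
        mvals, valid = _sample(M, warped)
        if valid.mean() < _MIN_OVERLAP:
            return 1e30
        f, m = fvals[valid], mvals[valid]
        if metric == "ssd":
            return float(np.mean((f - m) ** 2))
        return -mutual_information(f, m, bins=_adaptive_bins(bins, len(f)),
                                   f_range=f_range, m_range=m_range)

    return cost


def register_similarity(
    fixed: Volume, moving: Volume, config: RegistrationConfig | None = None
) -> tuple[SimilarityTransform, RegistrationResult]:
    """Multi-resolution similarity (rotation+translation+scale) registration.

    Optimizes the chosen cost (negated MI by default) with a Powell search
    at each pyramid level, coarse to fine, on a subsampled set of fixed-grid
    voxel centers.
    """
    config = config or RegistrationConfig()
    if np.ptp(fixed.voxels) == 0 or np.ptp(moving.voxels) == 0:
        raise DegenerateInputError("cannot register constant volumes")
    center = np.asarray(fixed.origin) + 0.5 * (np.asarray(fixed.shape) - 1) * np.asarray(
        fixed.spacing
    )
    f_range, m_range = _hist_range(fixed), _hist_range(moving)
    nparams = 7 if config.with_scale else 6
    params = np.zeros(nparams)
    level_traces: list[list[float]] = []
    for factor in config.levels:
        F = _downsample(fixed, factor)
        M = _downsample(moving, factor)
        pts, fvals = _strided_points(F)
        pcost = _point_cost(config.metric, config.bins, fvals, pts, M, f_range, m_range)

        def f(p):
            return pcost(SimilarityTransform.from_params(p, center, config.with_scale))

        best_at_level = [f(params)]

        def cb(p):
            best_at_level.append(f(p))

        res = optimize.minimize(
            f,
            params,
            method="Powell",
            callback=cb,
            options={"maxiter": 6, "maxfev": 30 * nparams, "xtol": 1e-4, "ftol": 1e-9},
        )
        params = res.x
        level_traces.append(np.minimum.accumulate(best_at_level).tolist())
    transform = SimilarityTransform.from_params(params, center, config.with_scale)
    trace = [c for lv in level_traces for c in lv]
    return transform, RegistrationResult(transform, trace, True, level_traces)


def _ffd_cost_and_force(pre: dict, field: np.ndarray, metric: str, bins: int, ranges):
    """Cost and per-voxel force dCost/d(displacement) on the fixed grid.

    ``pre`` carries level-constant data: warped-pose fixed points, fixed
    values, the moving volume and its precomputed spatial gradient."""
    warped = pre["posed"] + field.reshape(-1, 3)
    M = pre["moving"]
    mvals, valid = _sample(M, warped)
    fvals = pre["fvals"]
    n = valid.sum()
    if n < _MIN_OVERLAP * len(fvals):
        raise DegenerateInputError("degenerate overlap during FFD registration")
    # moving-image spatial gradient at the warped positions (mm^-1)
    ci = M.world_to_index(warped).T
    grad = np.empty((len(fvals), 3))
    for ax in range(3):
        grad[:, ax] = ndimage.map_coordinates(pre["mgrad"][ax], ci, order=1,
                                              mode="nearest", prefilter=False)
    grad[~valid] = 0.0
    if metric == "ssd":
        diff = np.where(valid, mvals - fvals, 0.0)
        cost = float((diff[valid] ** 2).sum() / n)
        dm = 2.0 * diff / n  # dCost/dm per voxel
    else:
        fr, mr = ranges
        fv = fvals[valid]
        mv = mvals[valid]
        nb = _adaptive_bins(bins, int(n))
        fb = np.clip(((fv - fr[0]) / (fr[1] - fr[0]) * nb).astype(int), 0, nb - 1)
        mpos = np.clip((mv - mr[0]) / (mr[1] - mr[0]) * nb - 0.5, 0, nb - 1 - 1e-9)
        mb = mpos.astype(int)
        frac = mpos - mb
        joint = np.zeros((nb, nb))
        np.add.at(joint, (fb, mb), 1 - frac)
        np.add.at(joint, (fb, np.minimum(mb + 1, nb - 1)), frac)
        p = joint / n
        pf = p.sum(1, keepdims=True)
        pm = p.sum(0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            L = np.where(p > 0, np.log(p / (pf * pm + 1e-300) + 1e-300), 0.0)
        mi = float((p * L).sum())
        cost = -mi
        dmi = (L[fb, np.minimum(mb + 1, nb - 1)] - L[fb, mb]) / (
            n * (mr[1] - mr[0]) / nb
        )
        dm = np.zeros(len(fvals))
        dm[valid] = -dmi  # d(-MI)/dm
    force = dm[:, None] * grad
    return cost, force.reshape(pre["shape"] + (3,))


def register_ffd(
    fixed: Volume,
    moving: Volume,
    init: SimilarityTransform | None = None,
    config: RegistrationConfig | None = None,
) -> tuple[BSplineGrid, RegistrationResult]:
    """Coarse-to-fine FFD registration on top of an initial similarity pose.

    Control displacements are optimized by gradient descent with analytic
    gradients (per-voxel force scattered through the B-spline weights) and
    step halving; accepted steps never increase the cost.
    """
    config = config or RegistrationConfig()
    init = init or SimilarityTransform.identity()
    grid = bspline_grid_for_volume(fixed, config.grid_spacing_mm)
    ranges = (_hist_range(fixed), _hist_range(moving))
    level_traces: list[list[float]] = []
    for factor in config.levels:
        F = _downsample(fixed, factor)
        M = _downsample(moving, factor)
        # keep the cost-evaluation grid regular but within the point budget
        stride = max(1, int(np.ceil((np.prod(F.shape) / _MAX_COST_POINTS) ** (1 / 3))))
        if stride > 1:
            F = Volume(
                F.voxels[::stride, ::stride, ::stride],
                tuple(np.asarray(F.spacing) * stride),
                F.origin,
            )
        pts = _fixed_grid_points(F)
        pre = {
            "posed": init.apply(pts),
            "fvals": F.voxels.ravel().astype(float),
            "moving": M,
            "mgrad": np.gradient(M.voxels.astype(float), *M.spacing),
            "shape": F.shape,
        }
        field = grid.dense_field(F.shape, F.spacing, F.origin)
        cost, force = _ffd_cost_and_force(pre, field, config.metric,
                                          config.bins, ranges)
        trace: list[float] = [cost]
        level_traces.append(trace)
        g = grid.scatter_adjoint(force, F.shape, F.spacing, F.origin)
        gmax = np.abs(g).max()
        if gmax == 0:
            continue
        step = 0.5 * min(F.spacing) / gmax  # first trial moves <= half a voxel
        for _ in range(config.max_iter):
            trial = grid.displacements - step * g
            trial_grid = replace(grid, displacements=trial)
            field = trial_grid.dense_field(F.shape, F.spacing, F.origin)
            new_cost, new_force = _ffd_cost_and_force(
                pre, field, config.metric, config.bins, ranges
            )
            if new_cost < cost - config.ffd_tol * max(1.0, abs(cost)):
                grid = trial_grid
                cost, force = new_cost, new_force
                trace.append(cost)
                g = grid.scatter_adjoint(force, F.shape, F.spacing, F.origin)
                gmax = np.abs(g).max()
                if gmax == 0:
                    break
                step = min(step * 2.0, 2.0 * min(F.spacing) / gmax)
            else:
                step *= 0.5
                if step * gmax < 1e-4 * min(F.spacing):
                    break
    flat = [c for lv in level_traces for c in lv]
    return grid, RegistrationResult(grid, flat, True, level_traces)
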