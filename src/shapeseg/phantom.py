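"""Seeded liver-like phantoms with known ground truth.

Each case is a smooth asymmetric organ (a lobed ellipsoid) deformed by a
known Gaussian-process deformation model, voxelized to a binary mask and
rendered as a CT-like volume: distinct interior/exterior mean intensities,
partial-volume smoothing, additive Gaussian noise.  Because every case is a
deformation of one reference surface, vertex-wise correspondence and the
generating coefficients are available by construction, which lets
experiments separate correspondence error from model error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .core import LabelMask, SurfaceMesh, Volume, surface_to_mask
from .errors import DegenerateInputError, DimensionError
from .gpmm import GaussianKernel, LowRankGP, build_low_rank_gp

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# reference organ
# ---------------------------------------------------------------------------


def _uv_sphere(n_lat: int, n_lon: int) -> tuple[np.ndarray, np.ndarray]:
    """Closed unit sphere with n_lat interior rings of n_lon vertices + 2 poles."""
    theta = np.pi * (np.arange(1, n_lat + 1)) / (n_lat + 1)
    phi = 2 * np.pi * np.arange(n_lon) / n_lon
    T, P = np.meshgrid(theta, phi, indexing="ij")
    ring = np.stack(
        [np.sin(T) * np.cos(P), np.sin(T) * np.sin(P), np.cos(T)], axis=-1
    ).reshape(-1, 3)
    verts = np.vstack([[[0, 0, 1.0]], ring, [[0, 0, -1.0]]])
    faces = []
    top, bottom = 0, len(verts) - 1

    def vid(i, j):
        return 1 + i * n_lon + (j % n_lon)

    for j in range(n_lon):  # pole caps
        faces.append([top, vid(0, j), vid(0, j + 1)])
        faces.append([bottom, vid(n_lat - 1, j + 1), vid(n_lat - 1, j)])
    for i in range(n_lat - 1):  # quad strips
        for j in range(n_lon):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i + 1, j), vid(i + 1, j + 1)
            faces.append([a, c, b])
            faces.append([b, c, d])
    return verts, np.asarray(faces, dtype=np.int64)


_LOBES = (  # direction (unit), relative amplitude, angular width
    (np.array([0.80, 0.50, 0.33]), 0.28, 0.55),
    (np.array([-0.55, 0.70, -0.45]), 0.18, 0.45),
)
_SEMI_AXES = np.array([1.0, 0.78, 0.60])


def make_reference_organ(
    n_vertices: int = 1000,
    diameter_mm: float = 70.0,
    center_mm=(64.0, 64.0, 64.0),
) -> SurfaceMesh:
    """Deterministic smooth asymmetric closed organ surface (genus 0).

    An anisotropic ellipsoid with two Gaussian lobe bulges; the actual vertex
    count is the closest UV-sphere tessellation to ``n_vertices``.
    """
    if n_vertices < 100:
        raise DimensionError("need at least 100 vertices")
    n_lat = max(3, int(round(np.sqrt(n_vertices / 2.0))))
    n_lon = max(6, int(round((n_vertices - 2) / n_lat)))
    d, faces = _uv_sphere(n_lat, n_lon)
    r_ell = 1.0 / np.sqrt(((d / _SEMI_AXES) ** 2).sum(axis=1))
    bump = np.zeros(len(d))
    for direction, amp, width in _LOBES:
        u = direction / np.linalg.norm(direction)
        ang2 = ((d - u) ** 2).sum(axis=1)
        bump += amp * np.exp(-ang2 / width**2)
    radius = 0.5 * diameter_mm * r_ell * (1.0 + bump)
    verts = np.asarray(center_mm, float) + radius[:, None] * d
    return SurfaceMesh(verts, faces)


# ---------------------------------------------------------------------------
# phantom spec / case
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Study conditions of the synthetic cohort (all units mm / HU-like)."""

    n_vertices: int = 1000
    deformation_rank: int = 5
    amplitude: float = 0.06  # RMS vertex displacement as fraction of diameter
    kernel_sigma_factor: float = 0.30  # bandwidth as fraction of diameter
    diameter_mm: float = 70.0
    intensity_in: float = 100.0
    intensity_out: float = 0.0
    noise_sd: float = 15.0
    smooth_voxels: float = 1.0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    nystrom_samples: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intensity_in == self.intensity_out:
            raise ValueError("interior and exterior intensities must differ")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")

    def center(self) -> np.ndarray:
        return np.asarray(self.origin) + 0.5 * (
            np.asarray(self.grid_shape) - 1
        ) * np.asarray(self.spacing)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhantomCase:
    image: Volume
    mask: LabelMask
    mesh: SurfaceMesh
    true_alpha: np.ndarray
    true_field: np.ndarray  # (V, 3) deformation of the reference vertices
    case_id: str = ""


def true_deformation_gp(spec: PhantomSpec) -> LowRankGP:
    """The known generating GP on the reference organ, scaled so the expected
    RMS vertex displacement is ``amplitude * diameter``."""
    ref = make_reference_organ(spec.n_vertices, spec.diameter_mm, spec.center())
    kern = GaussianKernel(s=1.0, sigma=spec.kernel_sigma_factor * spec.diameter_mm)
    gp = build_low_rank_gp(
        kern, ref, r=spec.deformation_rank, m=min(spec.nystrom_samples, ref.n_vertices),
        seed=spec.seed,
    )
    if spec.amplitude == 0:
        gp.variances = np.zeros_like(gp.variances)
        return gp
    # E ||u||^2 summed over vertices = sum_i lambda_i; rescale to the target RMS
    target = (spec.amplitude * spec.diameter_mm) ** 2 * ref.n_vertices
    gp.variances = gp.variances * (target / gp.variances.sum())
    return gp


def render_case(
    spec: PhantomSpec, gp: LowRankGP, alpha: np.ndarray, rng: np.random.Generator,
    case_id: str = "",
) -> PhantomCase:
    field = gp.sample(alpha)
    mesh = SurfaceMesh(gp.reference.vertices + field, gp.reference.faces.copy())
    mask = surface_to_mask(mesh, spec.grid_shape, spec.spacing, spec.origin)
    if mask.voxels.sum() == 0:
        raise DegenerateInputError("deformed organ missed the voxel grid")
    img = spec.intensity_out + (spec.intensity_in - spec.intensity_out) * mask.voxels.astype(
        float
    )
    if spec.smooth_voxels > 0:
        img = ndimage.gaussian_filter(img, spec.smooth_voxels)
    img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    vol = Volume(img, spec.spacing, spec.origin)
    return PhantomCase(vol, mask, mesh, np.asarray(alpha, float), field, case_id)


def generate_cohort(spec: PhantomSpec, n_cases: int, seed: int | None = None
                    ) -> list[PhantomCase]:
    """Seeded phantom cohort; byte-identical for identical spec and seed."""
    seed = spec.seed if seed is None else seed
    gp = true_deformation_gp(spec)
    ss = np.random.SeedSequence(seed)
    cases: list[PhantomCase] = []
    sub = iter(ss.spawn(4 * max(1, n_cases)))
    while len(cases) < n_cases:
        rng = np.random.default_rng(next(sub))
        alpha = rng.standard_normal(gp.rank)
        try:
            case = render_case(spec, gp, alpha, rng, case_id=f"case{len(cases):03d}")
        except DegenerateInputError:
            log.warning("degenerate phantom draw; regenerating with next substream")
            continue
        tm = case.mesh.to_trimesh()
        if not tm.is_watertight or tm.volume <= 0:
            log.warning("self-intersecting phantom mesh; regenerating")
            continue
        cases.append(case)
    return cases


def split_train_test(cohort: list, n_train: int, seed: int = 0) -> tuple[list, list]:
    """Seeded shuffle then disjoint split."""
    if not 0 < n_train < len(cohort):
        raise ValueError("n_train must be in (0, len(cohort))")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort))
    train = [cohort[i] for i in order[:n_train]]
    test = [cohort[i] for i in order[n_train:]]
    return train, test


def fields_on_mesh(gp: LowRankGP, mesh: SurfaceMesh, alphas: np.ndarray) -> np.ndarray:
    """Ground-truth deformation fields of the generating GP evaluated on an
    arbitrary resolution of the reference organ (kernel extension), shape
    (N, V, 3)."""
    basis = gp.basis_at(mesh.vertices)  # (3V, r)
    coef = np.asarray(alphas, float) * np.sqrt(np.maximum(gp.variances, 0.0))
    return (coef @ basis.T).reshape(len(coef), -1, 3)


def cohort_manifest(spec: PhantomSpec, cases: list[PhantomCase]) -> str:
    return json.dumps(
        {
            "spec": spec.to_dict(),
            "cases": [
                {"case_id": c.case_id, "true_alpha": c.true_alpha.tolist()} for c in cases
            ],
        },
        indent=2,
    )
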