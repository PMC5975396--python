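"""Active Shape Model search: classic Mahalanobis and optimal-feature variants.

Fitting iterates, at three image resolutions (0.25/0.5/1, five iterations
each by default): propose a new position for every landmark along its
surface normal — either the candidate minimizing the Mahalanobis distance of
its derivative profile to the trained mean (classic), or the candidate whose
kNN inside/outside classifications best match the ideal half-inside /
half-outside pattern (optimal features) — then regularize the proposal by a
similarity pose fit plus projection onto the point-distribution model with
mode weights clamped to ±3 standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .core import LabelMask, SurfaceMesh, Volume, surface_to_mask
from .errors import DegenerateInputError
from .gpmm import _vertex_normals
from .pdm import (
    PointDistributionModel,
    apply_similarity,
    build_pdm,
    procrustes_align,
    similarity_fit,
)
from .profiles import (
    GrayProfileModel,
    OptimalFeatureModel,
    build_optimal_feature_model,
    build_profile_model,
    point_features,
    sample_profile,
)
from .registration import _downsample, moments_pose

log = logging.getLogger(__name__)


@dataclass
class ASMConfig:
    """Search parameters (defaults follow the standard three-level protocol)."""

    resolutions: tuple[float, ...] = (0.25, 0.5, 1.0)
    iterations_per_level: int = 5
    profile_half_length: int = 4  # profile length 8 pixels -> k=4 per side
    candidate_positions: int = 6
    candidate_step_voxels: float = 0.5  # sub-voxel pitch between candidates
    b_limit: float = 3.0
    k_neighbors: int = 5

    def __post_init__(self) -> None:
        if any(not 0 < r <= 1 for r in self.resolutions) or list(
            self.resolutions
        ) != sorted(self.resolutions):
            raise ValueError("resolutions must be ascending within (0, 1]")
        if min(self.iterations_per_level, self.profile_half_length,
               self.candidate_positions) <= 0:
            raise ValueError("iteration/profile/candidate counts must be positive")


def _candidate_offsets(n: int, step: float) -> np.ndarray:
    """n near-symmetric offsets along the normal, always including 0 so a
    perfectly placed landmark can stay put (for even n the extra position
    goes inward)."""
    return (np.arange(n) - n // 2) * step


def _regularize(pdm: PointDistributionModel, proposed: np.ndarray, b_limit: float):
    """Similarity pose fit + clamped projection onto the PDM."""
    s, R, t = similarity_fit(pdm.mean_points(), proposed)
    in_model = (proposed - t) @ R / s  # inverse similarity
    b = pdm.clamp(pdm.project(in_model), b_limit)
    return apply_similarity(pdm.synthesize(b), s, R, t), b


def classic_asm_step(
    vol: Volume,
    shape_pts: np.ndarray,
    faces: np.ndarray,
    pdm: PointDistributionModel,
    profiles: GrayProfileModel,
    config: ASMConfig,
    level: float = 1.0,
) -> np.ndarray:
    """One classic ASM update on the image at the given resolution level."""
    step = float(min(vol.spacing))
    normals = _vertex_normals(shape_pts, faces)
    offsets = _candidate_offsets(config.candidate_positions,
                                 step * config.candidate_step_voxels)
    cand = shape_pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    V, C = cand.shape[:2]
    prof = sample_profile(
        vol,
        cand.reshape(-1, 3),
        np.repeat(normals, C, axis=0),
        config.profile_half_length,
        step,
    ).reshape(V, C, -1)
    scores = profiles.mahalanobis(prof, level=level)  # (V, C)
    best = scores.argmin(axis=1)
    proposed = cand[np.arange(V), best]
    new_pts, _ = _regularize(pdm, proposed, config.b_limit)
    return new_pts


def optimal_feature_asm_step(
    vol: Volume,
    shape_pts: np.ndarray,
    faces: np.ndarray,
    pdm: PointDistributionModel,
    feature_model: OptimalFeatureModel,
    config: ASMConfig,
    level: float = 1.0,
) -> np.ndarray:
    """One optimal-feature (kNN) ASM update."""
    step = float(min(vol.spacing))
    normals = _vertex_normals(shape_pts, faces)
    offsets = _candidate_offsets(config.candidate_positions,
                                 step * config.candidate_step_voxels)
    k = feature_model.half_length
    pos_off = (np.arange(-k, k + 1)) * step
    ideal = np.where(pos_off < 0, 1.0, np.where(pos_off > 0, 0.0, 0.5))
    # positions: (V, C, P, 3)
    cand = shape_pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    pos = cand[:, :, None, :] + pos_off[None, None, :, None] * normals[:, None, None, :]
    feats = point_features(
        vol, pos, np.broadcast_to(normals[:, None, None, :], pos.shape), step
    )
    V, C, P = feats.shape[:3]
    # kNN probabilities are quantized (multiples of 1/k), so ties between
    # candidate offsets are common; break them toward the smallest move
    tie_break = 1e-6 * np.abs(offsets) / max(step, 1e-12)
    proposed = np.empty_like(shape_pts)
    for i in range(V):
        p_in = feature_model.inside_probability(level, i, feats[i].reshape(C * P, -1))
        score = np.abs(p_in.reshape(C, P) - ideal[None, :]).sum(axis=1) + tie_break
        proposed[i] = cand[i, int(score.argmin())]
    new_pts, _ = _regularize(pdm, proposed, config.b_limit)
    return new_pts


def fit_asm(
    vol: Volume,
    pdm: PointDistributionModel,
    appearance,
    init_pts: np.ndarray,
    faces: np.ndarray,
    config: ASMConfig | None = None,
    variant: str = "classic",
) -> tuple[np.ndarray, LabelMask]:
    """Multi-resolution ASM fitting; returns final landmarks and their mask."""
    config = config or ASMConfig()
    lo = vol.index_to_world(np.zeros(3))
    hi = vol.index_to_world(np.asarray(vol.shape) - 1)
    if np.any(init_pts.max(0) < lo) or np.any(init_pts.min(0) > hi):
        raise DegenerateInputError("initial shape lies outside the image volume")
    pts = np.asarray(init_pts, dtype=float).copy()
    for level in config.resolutions:
        v = _downsample(vol, level)
        for _ in range(config.iterations_per_level):
            if variant == "classic":
                pts = classic_asm_step(v, pts, faces, pdm, appearance, config, level)
            elif variant == "knn":
                pts = optimal_feature_asm_step(v, pts, faces, pdm, appearance, config, level)
            else:
                raise ValueError(f"unknown ASM variant {variant!r}")
    mask = surface_to_mask(SurfaceMesh(pts, faces), vol.shape, vol.spacing, vol.origin)
    return pts, mask


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class ActiveShapeModelSegmenter(BaseEstimator):
    """ASM segmentation as a fit/predict estimator.

    fit(volumes, meshes) takes training images and corresponding surfaces
    (identical vertex ordering across cases); predict(volume) returns a
    binary mask.  ``variant`` selects the classic Mahalanobis profile search
    or the optimal-feature kNN search.
    """

    def __init__(
        self,
        variant: str = "classic",
        resolutions: tuple[float, ...] = (0.25, 0.5, 1.0),
        iterations_per_level: int = 5,
        profile_half_length: int = 4,
        candidate_positions: int = 6,
        candidate_step_voxels: float = 0.5,
        b_limit: float = 3.0,
        k_neighbors: int = 5,
        mode_rule=None,
        init: str = "mean",
    ):
        self.variant = variant
        self.resolutions = resolutions
        self.iterations_per_level = iterations_per_level
        self.profile_half_length = profile_half_length
        self.candidate_positions = candidate_positions
        self.candidate_step_voxels = candidate_step_voxels
        self.b_limit = b_limit
        self.k_neighbors = k_neighbors
        self.mode_rule = mode_rule
        self.init = init

    def _config(self) -> ASMConfig:
        return ASMConfig(
            resolutions=tuple(self.resolutions),
            iterations_per_level=self.iterations_per_level,
            profile_half_length=self.profile_half_length,
            candidate_positions=self.candidate_positions,
            candidate_step_voxels=self.candidate_step_voxels,
            b_limit=self.b_limit,
            k_neighbors=self.k_neighbors,
        )

    def fit(self, volumes: list[Volume], meshes: list[SurfaceMesh]):
        if len(volumes) != len(meshes) or len(volumes) < 2:
            raise DegenerateInputError("need >= 2 paired training volumes and meshes")
        cfg = self._config()
        shapes = np.stack([m.vertices for m in meshes])
        aligned, _ = procrustes_align(shapes)
        self.pdm_ = build_pdm(aligned, self.mode_rule)
        self.faces_ = meshes[0].faces.copy()
        landmark_sets = [m.vertices for m in meshes]
        normal_sets = [m.vertex_normals() for m in meshes]
        if self.variant == "classic":
            self.appearance_ = build_profile_model(
                volumes, landmark_sets, normal_sets,
                half_length=cfg.profile_half_length, resolutions=cfg.resolutions,
            )
        elif self.variant == "knn":
            self.appearance_ = build_optimal_feature_model(
                volumes, landmark_sets, normal_sets,
                half_length=cfg.profile_half_length, k_neighbors=cfg.k_neighbors,
                resolutions=cfg.resolutions,
            )
        else:
            raise ValueError(f"unknown ASM variant {self.variant!r}")
        self.mean_world_ = shapes.mean(0)
        return self

    def initial_shape(self, vol: Volume) -> np.ndarray:
        if self.init == "moments":
            pose = moments_pose(vol, self.mean_world_)
            return pose.apply(self.mean_world_)
        return self.mean_world_.copy()

    def predict(self, vol: Volume) -> LabelMask:
        pts, mask = fit_asm(
            vol,
            self.pdm_,
            self.appearance_,
            self.initial_shape(vol),
            self.faces_,
            self._config(),
            variant=self.variant,
        )
        self.last_landmarks_ = pts
        return mask
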