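"""Gray-level appearance models along landmark normals.

The classic appearance model stores, per landmark, the mean and covariance
of normalized first-derivative intensity profiles sampled perpendicular to
the object boundary; candidate boundary positions are scored by the
Mahalanobis distance to the mean profile.  The optimal-feature alternative
replaces this with a per-landmark k-nearest-neighbor classifier estimating,
for each position along the profile, the probability of being inside the
object; a candidate is scored by its disagreement with the ideal
half-inside / half-outside pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.neighbors import KNeighborsClassifier

from .core import Volume
from .errors import DegenerateInputError, DimensionError


def _sample_intensities(vol: Volume, points: np.ndarray) -> np.ndarray:
    """Trilinear samples at world points of any leading shape (..., 3)."""
    pts = np.asarray(points, dtype=float)
    ci = vol.world_to_index(pts.reshape(-1, 3)).T
    vals = ndimage.map_coordinates(
        vol.voxels.astype(float), ci, order=1, mode="nearest", prefilter=False
    )
    return vals.reshape(pts.shape[:-1])


def profile_sample_points(
    points: np.ndarray, normals: np.ndarray, half_length: int, step_mm: float
) -> np.ndarray:
    """The 2k+2 intensity sampling positions per landmark, shape (N, 2k+2, 3).

    Successive differences of the 2k+2 samples give a derivative profile of
    length 2k+1 whose center element sits on the landmark.
    """
    normals = np.asarray(normals, dtype=float)
    norms = np.linalg.norm(normals, axis=-1, keepdims=True)
    if np.any(norms < 1e-12):
        raise DegenerateInputError("zero-length profile normal")
    normals = normals / norms
    offsets = (np.arange(2 * half_length + 2) - (half_length + 0.5)) * step_mm
    return (
        np.asarray(points, float)[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    )


def sample_profile(
    vol: Volume,
    points: np.ndarray,
    normals: np.ndarray,
    half_length: int = 4,
    step_mm: float | None = None,
) -> np.ndarray:
    """Normalized first-derivative profiles, shape (N, 2k+1).

    Intensities are sampled at 1-voxel steps along +/- the unit normal,
    differenced, and each profile divided by the sum of absolute differences
    (zero-safe): a constant image yields an all-zero profile.
    """
    if step_mm is None:
        step_mm = float(min(vol.spacing))
    pts = np.atleast_2d(np.asarray(points, float))
    nrm = np.atleast_2d(np.asarray(normals, float))
    samples = _sample_intensities(vol, profile_sample_points(pts, nrm, half_length, step_mm))
    deriv = np.diff(samples, axis=-1)
    denom = np.abs(deriv).sum(axis=-1, keepdims=True)
    return deriv / np.where(denom < 1e-12, 1.0, denom)


def raw_profile(vol: Volume, points, normals, half_length=4, step_mm=None) -> np.ndarray:
    """Unnormalized intensity samples at offsets -k..k (length 2k+1)."""
    if step_mm is None:
        step_mm = float(min(vol.spacing))
    pts = np.atleast_2d(np.asarray(points, float))
    nrm = np.atleast_2d(np.asarray(normals, float))
    norms = np.linalg.norm(nrm, axis=-1, keepdims=True)
    if np.any(norms < 1e-12):
        raise DegenerateInputError("zero-length profile normal")
    nrm = nrm / norms
    offsets = (np.arange(2 * half_length + 1) - half_length) * step_mm
    pos = pts[:, None, :] + offsets[None, :, None] * nrm[:, None, :]
    return _sample_intensities(vol, pos)


# ---------------------------------------------------------------------------
# classic (Mahalanobis) profile model
# ---------------------------------------------------------------------------


@dataclass
class ProfileStats:
    mean: np.ndarray  # (V, L)
    cov: np.ndarray  # (V, L, L)
    inv_cov: np.ndarray  # (V, L, L)


@dataclass
class GrayProfileModel:
    """Per-landmark profile statistics, one set per resolution level."""

    half_length: int
    levels: dict = field(default_factory=dict)  # level -> ProfileStats

    def stats(self, level: float) -> ProfileStats:
        key = min(self.levels, key=lambda lv: abs(lv - level))
        return self.levels[key]

    def mahalanobis(self, profiles: np.ndarray, level: float = 1.0) -> np.ndarray:
        """(g - ḡ)ᵀ S⁻¹ (g - ḡ) per landmark; ``profiles`` is (V, ..., L)."""
        st = self.stats(level)
        dev = profiles - st.mean.reshape(
            (st.mean.shape[0],) + (1,) * (profiles.ndim - 2) + (st.mean.shape[1],)
        )
        return np.einsum("v...i,vij,v...j->v...", dev, st.inv_cov, dev)


#: default shrinkage toward the scaled identity for profile covariances;
#: with ~10 training cases a raw L x L sample covariance is near-singular and
#: its smallest eigen-directions are pure noise, so substantial shrinkage is
#: required for a meaningful Mahalanobis distance.
PROFILE_COV_SHRINKAGE = 0.1


def _regularized_inverse(cov: np.ndarray, shrinkage: float | None = None) -> np.ndarray:
    gamma = PROFILE_COV_SHRINKAGE if shrinkage is None else shrinkage
    L = cov.shape[-1]
    eps = gamma * np.trace(cov, axis1=-2, axis2=-1) / L
    eps = np.maximum(eps, 1e-12)
    reg = cov + eps[:, None, None] * np.eye(L)
    return np.linalg.inv(reg)


def build_profile_model(
    volumes: list[Volume],
    landmark_sets: list[np.ndarray],
    normal_sets: list[np.ndarray],
    half_length: int = 4,
    resolutions: tuple[float, ...] = (0.25, 0.5, 1.0),
    downsampler=None,
    shrinkage: float | None = None,
) -> GrayProfileModel:
    """Mean/covariance of derivative profiles per landmark and resolution.

    Landmarks and normals are given in world mm (one array per training
    case, in correspondence).  At a resolution level the profile step is one
    voxel of the downsampled image.  The covariance is shrunk toward the
    scaled identity (``+ gamma * (trace/L) * I``) before inversion.
    """
    if len(volumes) < 2:
        raise DegenerateInputError("need at least 2 training cases")
    if len(volumes) != len(landmark_sets) or len(volumes) != len(normal_sets):
        raise DimensionError("one landmark/normal set per volume required")
    from .registration import _downsample

    downsampler = downsampler or _downsample
    model = GrayProfileModel(half_length=half_length)
    for level in resolutions:
        profs = []
        for vol, pts, nrm in zip(volumes, landmark_sets, normal_sets):
            v = downsampler(vol, level)
            profs.append(sample_profile(v, pts, nrm, half_length))
        P = np.stack(profs)  # (N, V, L)
        mean = P.mean(0)
        dev = P - mean
        cov = np.einsum("nvl,nvm->vlm", dev, dev) / len(volumes)
        model.levels[level] = ProfileStats(mean, cov, _regularized_inverse(cov, shrinkage))
    return model


# ---------------------------------------------------------------------------
# optimal-feature (kNN) model
# ---------------------------------------------------------------------------


def point_features(vol: Volume, points, normals, step_mm: float) -> np.ndarray:
    """Feature vector per query point: raw intensities in a 3-sample window
    along the normal plus their first differences, shape (..., 5)."""
    win = raw_profile(vol, points.reshape(-1, 3), normals.reshape(-1, 3), 1, step_mm)
    feats = np.concatenate([win, np.diff(win, axis=-1)], axis=-1)
    return feats.reshape(points.shape[:-1] + (5,))


@dataclass
class OptimalFeatureModel:
    """One kNN inside/outside classifier per landmark and resolution level."""

    half_length: int
    k_neighbors: int = 5
    levels: dict = field(default_factory=dict)  # level -> list of fitted kNN

    def classifiers(self, level: float):
        key = min(self.levels, key=lambda lv: abs(lv - level))
        return self.levels[key]

    def inside_probability(self, level: float, landmark: int, feats: np.ndarray):
        clf = self.classifiers(level)[landmark]
        proba = clf.predict_proba(feats)
        # column of the 'inside' class (label 1)
        col = int(np.where(clf.classes_ == 1)[0][0]) if 1 in clf.classes_ else None
        if col is None:
            return np.zeros(len(feats))
        return proba[:, col]


def build_optimal_feature_model(
    volumes: list[Volume],
    landmark_sets: list[np.ndarray],
    normal_sets: list[np.ndarray],
    half_length: int = 4,
    k_neighbors: int = 5,
    resolutions: tuple[float, ...] = (0.25, 0.5, 1.0),
    downsampler=None,
) -> OptimalFeatureModel:
    """Train per-landmark kNN classifiers labelling profile positions as
    inside (negative offsets along the outward normal) or outside."""
    if len(volumes) < 2:
        raise DegenerateInputError("need at least 2 training cases")
    if k_neighbors % 2 == 0:
        raise ValueError("k_neighbors must be odd")
    from .registration import _downsample

    downsampler = downsampler or _downsample
    model = OptimalFeatureModel(half_length=half_length, k_neighbors=k_neighbors)
    offsets = np.arange(-half_length, half_length + 1)
    labels = np.where(offsets < 0, 1, 0)  # inward = inside the object
    keep = offsets != 0
    for level in resolutions:
        feats_per_lm = None
        for vol, pts, nrm in zip(volumes, landmark_sets, normal_sets):
            v = downsampler(vol, level)
            step = float(min(v.spacing))
            n_unit = nrm / np.linalg.norm(nrm, axis=-1, keepdims=True)
            # positions (V, 2k+1, 3) along the normal around ground truth
            pos = pts[:, None, :] + (offsets[None, :, None] * step) * n_unit[:, None, :]
            f = point_features(v, pos, np.broadcast_to(n_unit[:, None, :], pos.shape), step)
            f = f[:, keep, :]
            if feats_per_lm is None:
                feats_per_lm = [[] for _ in range(len(pts))]
            for i in range(len(pts)):
                feats_per_lm[i].append(f[i])
        y = np.tile(labels[keep], len(volumes))
        clfs = []
        for i, chunks in enumerate(feats_per_lm):
            X = np.concatenate(chunks, axis=0)
            k = min(k_neighbors, len(X))
            clf = KNeighborsClassifier(n_neighbors=k, algorithm="brute")
            clf.fit(X, y)
            clfs.append(clf)
        model.levels[level] = clfs
    return model
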