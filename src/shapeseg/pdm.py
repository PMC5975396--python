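"""Point distribution models: Procrustes alignment and PCA shape statistics.

A shape is an ordered set of n corresponding landmarks in d dimensions.  The
training set is brought into a common frame by generalized Procrustes
analysis (least-squares similarity alignment to an iteratively re-estimated
mean), then the mean shape, the covariance of the deviations (1/N
normalization) and its leading eigenvectors ("modes of variation") are
computed.  New shapes are synthesized as  x = x̄ + P b  with mode weights b,
optionally clamped to ±3 standard deviations per mode.

For large landmark counts the eigendecomposition uses the N x N Gram matrix
of the centered data instead of the (n·d) x (n·d) covariance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, DimensionError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# similarity (Umeyama) fit between corresponding point sets
# ---------------------------------------------------------------------------


def similarity_fit(src: np.ndarray, dst: np.ndarray, with_scale: bool = True):
    """Least-squares similarity transform mapping ``src`` onto ``dst``.

    Returns ``(scale, R, t)`` with a proper rotation (reflections excluded),
    minimizing ``sum ||dst_i - (s R src_i + t)||^2``.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    mu_s, mu_d = src.mean(0), dst.mean(0)
    sc, dc = src - mu_s, dst - mu_d
    var_s = (sc**2).sum() / len(src)
    if var_s < 1e-30:
        raise DegenerateInputError("degenerate shape: all points coincide")
    cov = dc.T @ sc / len(src)
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0] * (src.shape[1] - 1) + [d])
    R = U @ D @ Vt
    s = float(np.trace(np.diag(S) @ D) / var_s) if with_scale else 1.0
    if s <= 0:
        s = 1e-12
    t = mu_d - s * R @ mu_s
    return s, R, t


def apply_similarity(points: np.ndarray, s: float, R: np.ndarray, t: np.ndarray):
    return s * np.asarray(points, float) @ np.asarray(R).T + np.asarray(t)


# ---------------------------------------------------------------------------
# generalized Procrustes alignment
# ---------------------------------------------------------------------------


def procrustes_align(
    shapes: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Align a stack of corresponding shapes (N, n, d) by similarity transforms.

    Iterates: align every shape to the current mean, re-estimate the mean,
    normalize the mean to zero centroid and unit centroid size.  Returns the
    aligned stack and the final mean shape (n, d).
    """
    shapes = np.asarray(shapes, dtype=float)
    if shapes.ndim != 3:
        raise DimensionError("expected shapes of shape (N, n, d)")
    N, n, d = shapes.shape
    if N < 2:
        raise DegenerateInputError("need at least 2 shapes")
    if n < 3:
        raise DimensionError("need at least 3 landmarks per shape")
    aligned = shapes.copy()
    mean = _normalize_shape(aligned[0])
    for _ in range(max_iter):
        for i in range(N):
            s, R, t = similarity_fit(aligned[i], mean)
            aligned[i] = apply_similarity(aligned[i], s, R, t)
        new_mean = _normalize_shape(aligned.mean(0))
        change = np.linalg.norm(new_mean - mean) / max(np.linalg.norm(mean), 1e-30)
        mean = new_mean
        if change < tol:
            break
    return aligned, mean


def _normalize_shape(shape: np.ndarray) -> np.ndarray:
    centered = shape - shape.mean(0)
    size = np.linalg.norm(centered)
    if size < 1e-30:
        raise DegenerateInputError("degenerate mean shape")
    return centered / size


def procrustes_sum_of_squares(aligned: np.ndarray) -> float:
    mean = aligned.mean(0)
    return float(((aligned - mean) ** 2).sum())


# ---------------------------------------------------------------------------
# the PDM proper
# ---------------------------------------------------------------------------


@dataclass
class PointDistributionModel:
    """Mean shape, orthonormal modes of variation and their variances."""

    mean_shape: np.ndarray  # flattened, length n*d
    modes: np.ndarray  # (n*d, t), orthonormal columns
    variances: np.ndarray  # (t,), descending
    n_points: int
    n_dim: int = 3

    def __post_init__(self) -> None:
        self.mean_shape = np.asarray(self.mean_shape, float).ravel()
        self.modes = np.asarray(self.modes, float)
        self.variances = np.asarray(self.variances, float)
        if self.modes.shape[0] != self.mean_shape.size:
            raise DimensionError("modes and mean shape disagree in length")
        if len(self.variances) != self.modes.shape[1]:
            raise DimensionError("one variance per mode required")
        if np.any(np.diff(self.variances) > 1e-12):
            raise ValueError("variances must be sorted descending")

    @property
    def t(self) -> int:
        return self.modes.shape[1]

    def mean_points(self) -> np.ndarray:
        return self.mean_shape.reshape(self.n_points, self.n_dim)

    def synthesize(self, b: np.ndarray, clamp: bool = False, b_limit: float = 3.0):
        """Shape x̄ + P b as (n, d) landmarks; optionally clamp |b_i| to
        ``b_limit``·sqrt(λ_i) first."""
        b = np.asarray(b, float).ravel()
        if len(b) != self.t:
            raise DimensionError(f"expected {self.t} mode weights, got {len(b)}")
        if clamp:
            b = self.clamp(b, b_limit)
        return (self.mean_shape + self.modes @ b).reshape(self.n_points, self.n_dim)

    def clamp(self, b: np.ndarray, b_limit: float = 3.0) -> np.ndarray:
        lim = b_limit * np.sqrt(np.maximum(self.variances, 0.0))
        return np.clip(b, -lim, lim)

    def project(self, shape: np.ndarray) -> np.ndarray:
        """Mode weights b = Pᵀ (x − x̄) of a landmark shape (n, d)."""
        flat = np.asarray(shape, float).ravel()
        if flat.size != self.mean_shape.size:
            raise DimensionError("shape does not match the model dimensions")
        return self.modes.T @ (flat - self.mean_shape)

    def save(self, path: str) -> None:
        np.savez(
            path,
            mean_shape=self.mean_shape,
            modes=self.modes,
            variances=self.variances,
            meta=json.dumps({"n_points": self.n_points, "n_dim": self.n_dim}),
        )

    @classmethod
    def load(cls, path: str) -> "PointDistributionModel":
        z = np.load(path, allow_pickle=False)
        meta = json.loads(str(z["meta"]))
        return cls(z["mean_shape"], z["modes"], z["variances"], **meta)


def _fix_sign(modes: np.ndarray) -> np.ndarray:
    """Flip each mode so its largest-magnitude component is positive
    (reproducible across LAPACK backends)."""
    idx = np.abs(modes).argmax(axis=0)
    signs = np.sign(modes[idx, np.arange(modes.shape[1])])
    signs[signs == 0] = 1.0
    return modes * signs


def build_pdm(
    aligned: np.ndarray,
    mode_rule: int | float | None = None,
) -> PointDistributionModel:
    """PCA shape model from aligned shapes (N, n, d).

    The covariance uses the 1/N normalization of the deviations from the
    mean.  ``mode_rule``: an int keeps that many modes; a float in (0, 1)
    keeps the smallest t explaining that variance fraction; None keeps every
    positive mode (at most N-1).
    """
    aligned = np.asarray(aligned, dtype=float)
    N, n, d = aligned.shape
    flat = aligned.reshape(N, n * d)
    mean = flat.mean(0)
    dev = flat - mean
    if N == 1:
        log.warning("single training shape: covariance is identically zero")
        return PointDistributionModel(mean, np.zeros((n * d, 0)), np.zeros(0), n, d)
    if n * d <= N:
        cov = dev.T @ dev / N
        lam, vec = np.linalg.eigh(cov)
        lam, vec = lam[::-1], vec[:, ::-1]
    else:  # Gram trick: eigenvectors of (1/N) dev devᵀ map to mode space
        gram = dev @ dev.T / N
        glam, gvec = np.linalg.eigh(gram)
        glam, gvec = glam[::-1], gvec[:, ::-1]
        keep = glam > max(glam[0], 0) * 1e-12
        lam = glam[keep]
        vec = dev.T @ gvec[:, keep] / np.sqrt(np.maximum(lam, 1e-300) * N)
    lam = np.maximum(lam, 0.0)
    pos = lam > (lam[0] if len(lam) else 0) * 1e-12
    lam, vec = lam[pos], vec[:, pos]
    if isinstance(mode_rule, int):
        t = min(mode_rule, len(lam))
    elif isinstance(mode_rule, float):
        if not 0 < mode_rule <= 1:
            raise ValueError("variance fraction must lie in (0, 1]")
        cum = np.cumsum(lam) / lam.sum()
        t = int(np.searchsorted(cum, mode_rule) + 1)
    else:
        t = len(lam)
    return PointDistributionModel(mean, _fix_sign(vec[:, :t]), lam[:t], n, d)


def read_landmarks(path: str) -> np.ndarray:
    """Landmark coordinates from CSV (id,x,y,z header) or JSON (list of
    [x, y, z]); rows ordered by id for CSV."""
    import json as _json

    p = str(path)
    if p.lower().endswith(".json"):
        with open(p) as fh:
            return np.asarray(_json.load(fh), dtype=float).reshape(-1, 3)
    import pandas as pd

    df = pd.read_csv(p)
    df = df.sort_values("id")
    return df[["x", "y", "z"]].to_numpy(dtype=float)


def write_landmarks(points: np.ndarray, path: str) -> None:
    import json as _json

    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    p = str(path)
    if p.lower().endswith(".json"):
        with open(p, "w") as fh:
            _json.dump(pts.tolist(), fh)
        return
    import pandas as pd

    pd.DataFrame(
        {"id": np.arange(len(pts)), "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2]}
    ).to_csv(p, index=False)


def covariance_matrix(aligned: np.ndarray) -> np.ndarray:
    """Explicit (n·d)x(n·d) covariance with 1/N normalization (small sets only)."""
    aligned = np.asarray(aligned, dtype=float)
    N = aligned.shape[0]
    flat = aligned.reshape(N, -1)
    dev = flat - flat.mean(0)
    return dev.T @ dev / N
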