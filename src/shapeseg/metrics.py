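"""Segmentation-quality measures: DICE overlap, mean surface distance, Hausdorff.

DICE is reported in percent.  Surface distances are symmetric: every surface
element of each input is matched to its closest point on the other surface,
and the mean (MSD) or the maximum of the two directed suprema (Hausdorff) is
returned in mm.  Masks are reduced to their boundary voxels — foreground
voxels with at least one background 6-neighbor — placed at voxel centers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import LabelMask, SurfaceMesh
from .errors import DegenerateInputError, DimensionError

log = logging.getLogger(__name__)

_CROSS = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def dice(a: LabelMask, b: LabelMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|), in percent."""
    if a.shape != b.shape or not np.allclose(a.spacing, b.spacing) or not np.allclose(
        a.origin, b.origin
    ):
        raise DimensionError("dice requires masks on an identical grid")
    av = a.voxels.astype(bool)
    bv = b.voxels.astype(bool)
    denom = int(av.sum()) + int(bv.sum())
    if denom == 0:
        log.warning("dice of two empty masks: returning 100%% by the 0/0 convention")
        return 100.0
    return 200.0 * int((av & bv).sum()) / denom


def boundary_points(mask: LabelMask) -> np.ndarray:
    """World-mm coordinates of boundary voxels (foreground with a background 6-neighbor)."""
    fg = mask.voxels.astype(bool)
    if not fg.any():
        raise DegenerateInputError("mask has no foreground; no surface exists")
    interior = ndimage.binary_erosion(fg, structure=_CROSS, border_value=0)
    idx = np.argwhere(fg & ~interior)
    return mask.index_to_world(idx)


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, LabelMask):
        return boundary_points(obj)
    if isinstance(obj, SurfaceMesh):
        if obj.n_vertices == 0:
            raise DegenerateInputError("empty mesh")
        return obj.vertices
    pts = np.asarray(obj, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise DegenerateInputError("empty point set")
    return pts


def _directed_distances(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    return cKDTree(dst).query(src, k=1)[0]


def mean_surface_distance(a, b) -> float:
    """Symmetric mean of closest surface distances, in mm.

    ``(Σ_i d_i + Σ_j d_j) / (n_X + n_Y)`` over both directed distance sets.
    """
    pa, pb = _as_points(a), _as_points(b)
    d_ab = _directed_distances(pa, pb)
    d_ba = _directed_distances(pb, pa)
    return float((d_ab.sum() + d_ba.sum()) / (len(pa) + len(pb)))


def hausdorff(a, b) -> float:
    """Hausdorff distance: max of the two directed sup-inf distances, in mm."""
    pa, pb = _as_points(a), _as_points(b)
    return float(max(_directed_distances(pa, pb).max(), _directed_distances(pb, pa).max()))


@dataclass
class MetricsReport:
    """DICE/MSD/Hausdorff for one segmented case."""

    case_id: str
    dice_percent: float
    msd_mm: float
    hausdorff_mm: float

    def to_row(self) -> dict:
        return asdict(self)


def evaluate_case(predicted: LabelMask, reference: LabelMask, case_id: str = "") -> MetricsReport:
    """Compute all three measures for a predicted mask against its reference."""
    return MetricsReport(
        case_id=case_id,
        dice_percent=dice(predicted, reference),
        msd_mm=mean_surface_distance(predicted, reference),
        hausdorff_mm=hausdorff(predicted, reference),
    )
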