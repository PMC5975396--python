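"""Single-atlas segmentation: register an atlas image to the target and
propagate the atlas mask through the recovered transform.

The transform is a similarity alignment (driven by mutual information)
refined by a B-spline free-form deformation optimizing SSD or MI; the binary
mask is propagated by nearest-neighbor resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator

from .core import LabelMask, Volume
from .errors import DegenerateInputError, DimensionError
from .registration import (
    CompositeTransform,
    RegistrationConfig,
    RegistrationResult,
    register_ffd,
    register_similarity,
    warp_mask,
)

log = logging.getLogger(__name__)


@dataclass
class AtlasCase:
    """A reference image with its expert segmentation on the same grid."""

    image: Volume
    mask: LabelMask
    case_id: str = ""

    def __post_init__(self) -> None:
        if not self.image.same_grid(self.mask):
            raise DimensionError("atlas image and mask must share grid metadata")
        if self.mask.voxels.sum() == 0:
            raise DegenerateInputError("atlas mask is empty")


def segment_single_atlas(
    atlas: AtlasCase,
    target: Volume,
    metric: str = "mi",
    config: RegistrationConfig | None = None,
) -> tuple[LabelMask, RegistrationResult]:
    """Similarity + FFD registration of the atlas image to the target,
    then propagation of the atlas mask onto the target grid."""
    config = config or RegistrationConfig()
    config = replace(config, metric=metric)
    # similarity alignment always uses MI (robust to intensity differences)
    sim, _ = register_similarity(target, atlas.image, replace(config, metric="mi"))
    ffd, result = register_ffd(target, atlas.image, init=sim, config=config)
    out = warp_mask(atlas.mask, CompositeTransform(sim, ffd), fixed_like=target)
    if out.voxels.sum() == 0:
        log.warning("propagated atlas mask is empty")
    return out, result


class SingleAtlasSegmenter(BaseEstimator):
    """Atlas propagation as a fit/predict estimator.

    fit(volumes, masks) keeps the first training case (sorted by id when ids
    are provided) as the atlas; predict(volume) registers it to the target
    and propagates its mask.
    """

    def __init__(self, metric: str = "mi", grid_spacing_mm: float = 16.0,
                 levels: tuple[float, ...] = (0.25, 0.5, 1.0), max_iter: int = 100,
                 bins: int = 32):
        self.metric = metric
        self.grid_spacing_mm = grid_spacing_mm
        self.levels = levels
        self.max_iter = max_iter
        self.bins = bins

    def fit(self, volumes: list[Volume], masks: list[LabelMask], ids=None):
        if len(volumes) == 0 or len(volumes) != len(masks):
            raise DegenerateInputError("need paired training volumes and masks")
        order = np.argsort(ids) if ids is not None else [0]
        first = int(order[0])
        self.atlas_ = AtlasCase(volumes[first], masks[first],
                                str(ids[first]) if ids is not None else "0")
        return self

    def _config(self) -> RegistrationConfig:
        return RegistrationConfig(
            metric=self.metric, bins=self.bins, levels=tuple(self.levels),
            max_iter=self.max_iter, grid_spacing_mm=self.grid_spacing_mm,
        )

    def predict(self, vol: Volume) -> LabelMask:
        mask, result = segment_single_atlas(self.atlas_, vol, self.metric, self._config())
        self.last_result_ = result
        return mask
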