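"""Consume multi-channel images plus external label masks.

Segmentation itself (e.g. StarDist) and illumination correction (e.g. BaSiC)
are upstream of this package: here we take an integer label mask produced by
an external segmenter, cut out one record per labeled nucleus, and apply the
size filter that removes objects smaller than a minimum equivalent radius
(default 4 um, configurable within the field-typical 3-7 um range).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)


@dataclass
class NucleusRecord:
    """One segmented nucleus: local mask + per-channel intensity crops."""

    label: int
    channels: tuple[str, ...]
    local_mask: np.ndarray            # bool, cropped to the bounding box
    channel_stack: np.ndarray         # (n_channels, *local_mask.shape)
    offset: tuple[int, ...]           # bbox origin in the source image
    centroid: tuple[float, ...]
    area: int                         # pixels (2D) or voxels (3D)
    source: str = ""

    def channel_image(self, name: str) -> np.ndarray:
        try:
            i = self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in record (has {self.channels})")
        return self.channel_stack[i]

    def masked_sum(self, name: str) -> float:
        return float(self.channel_image(name)[self.local_mask].sum())

    @property
    def pixel_coords(self) -> np.ndarray:
        """Coordinates of the nucleus pixels in source-image frame."""
        local = np.argwhere(self.local_mask)
        return local + np.asarray(self.offset)


@dataclass(frozen=True)
class SizeFilterSpec:
    """Remove objects whose area/volume implies a radius below ``min_radius_um``."""

    min_radius_um: float = 4.0
    pixel_size_um: float = 1.0
    dimensionality: int = 2

    def __post_init__(self):
        if self.min_radius_um < 0 or self.pixel_size_um <= 0:
            raise ValueError("radius must be >= 0 and pixel size > 0")
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")

    @property
    def min_size(self) -> float:
        """Minimum area (px) or volume (voxels) to keep, assuming a sphere."""
        r = self.min_radius_um / self.pixel_size_um
        if self.dimensionality == 2:
            return math.pi * r**2
        return 4.0 / 3.0 * math.pi * r**3


def _read_array(source) -> np.ndarray:
    if isinstance(source, np.ndarray):
        return source
    import tifffile

    return tifffile.imread(str(source))


def load_labeled_image(
    image,
    mask,
    channel_names: Sequence[str],
    *,
    max_project: bool = False,
    source: str = "",
    illumination_corrected: bool | None = None,
) -> list[NucleusRecord]:
    """Build one :class:`NucleusRecord` per nonzero label.

    Parameters
    ----------
    image
        Array or TIFF path, shape ``(C, Y, X)`` or ``(C, Z, Y, X)``.
    mask
        Integer label array or TIFF path, shape ``(Y, X)`` or ``(Z, Y, X)``.
    max_project
        If the image has a z axis, take the per-channel maximum projection
        (and the mask's any-z projection) before extraction — the default
        analysis mode for widefield stacks.
    illumination_corrected
        Purely informational hook: records whether flat-field correction was
        declared upstream.  ``None`` logs nothing.
    """
    img = np.asarray(_read_array(image))
    lab = np.asarray(_read_array(mask))
    if not np.issubdtype(lab.dtype, np.integer):
        if np.allclose(lab, np.round(lab)):
            lab = np.round(lab).astype(np.int64)
        else:
            raise ValueError("mask must be integer-valued")
    if img.ndim != lab.ndim + 1:
        raise ValueError(f"image ndim {img.ndim} must be mask ndim {lab.ndim} + 1 (channel axis)")
    if img.shape[1:] != lab.shape:
        raise ValueError(f"spatial shape mismatch: image {img.shape[1:]} vs mask {lab.shape}")
    if img.shape[0] != len(channel_names):
        raise ValueError(f"{img.shape[0]} channels in image but {len(channel_names)} names")
    if illumination_corrected is not None:
        logger.info("illumination correction declared upstream: %s", illumination_corrected)

    if max_project and lab.ndim == 3:
        img = img.max(axis=1)
        lab_2d = np.zeros(lab.shape[1:], dtype=lab.dtype)
        # keep each label's most frequent z-column value (labels are solid)
        for z in range(lab.shape[0]):
            sel = lab[z] != 0
            lab_2d[sel] = lab[z][sel]
        lab = lab_2d

    channels = tuple(channel_names)
    records: list[NucleusRecord] = []
    objects = ndimage.find_objects(lab)
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        local = lab[sl] == idx
        stack = np.stack([img[c][sl] for c in range(img.shape[0])])
        coords = np.argwhere(local)
        centroid = tuple((coords.mean(axis=0) + [s.start for s in sl]).tolist())
        records.append(NucleusRecord(
            label=idx, channels=channels, local_mask=local, channel_stack=stack,
            offset=tuple(s.start for s in sl), centroid=centroid,
            area=int(local.sum()), source=source,
        ))
    return records


def filter_small_objects(records: Sequence[NucleusRecord], spec: SizeFilterSpec) -> list[NucleusRecord]:
    """Keep records with area/volume >= the spherical-equivalent threshold.

    Objects strictly smaller than the threshold are removed; order is
    preserved and the operation is idempotent.
    """
    thr = spec.min_size
    kept = [r for r in records if r.area >= thr]
    if len(kept) < len(records):
        logger.info("size filter removed %d/%d objects (threshold %.2f)",
                    len(records) - len(kept), len(records), thr)
    return kept
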