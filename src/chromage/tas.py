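"""Threshold adjacency statistics (TAS) on band-pass binarized nuclei.

Each nucleus/channel is binarized at 28 intensity intervals defined relative
to its own mean masked intensity ``v_m``: one static interval ``(v_m, inf)``
and three families (lower-bounded, upper-bounded, band) over nine width
factors ``p = 0.1 .. 0.9``.  For every binarization the TAS statistic is the
distribution, over foreground pixels, of the number of foreground neighbors
(8-connectivity in 2D, 26-connectivity in 3D), giving 9 or 27 values per
binarization and hence 252 (2D) or 756 (3D) features per channel.

Because the intervals scale with ``v_m``, the features are invariant under
global rescaling of a nucleus' intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

BAND_FACTORS: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))
FAMILIES: tuple[str, ...] = ("static", "lower", "upper", "band")
N_INTERVALS = 1 + 3 * len(BAND_FACTORS)  # 28


@dataclass(frozen=True)
class ThresholdSpec:
    """One binarization interval: ``lo < v <= hi`` relative to ``v_m``."""

    family: str
    p: float | None
    lo: float
    hi: float


def band_intervals(v_m: float) -> list[ThresholdSpec]:
    """Return the 28 band-pass intervals for mean masked intensity ``v_m``.

    Order is frozen: static, then lower family (p ascending), upper family,
    band family.  Open upper ends are ``inf``; membership is ``lo < v <= hi``.
    """
    if v_m < 0:
        raise ValueError("v_m must be non-negative")
    out = [ThresholdSpec("static", None, v_m, np.inf)]
    for p in BAND_FACTORS:
        out.append(ThresholdSpec("lower", p, v_m - v_m * p, np.inf))
    for p in BAND_FACTORS:
        out.append(ThresholdSpec("upper", p, v_m + v_m * p, np.inf))
    for p in BAND_FACTORS:
        out.append(ThresholdSpec("band", p, v_m - v_m * p, v_m + v_m * p))
    assert len(out) == N_INTERVALS
    return out


def binarize(intensities: np.ndarray, mask: np.ndarray, interval: ThresholdSpec) -> np.ndarray:
    """Binary foreground array: inside ``mask`` and ``lo < v <= hi``."""
    v = np.asarray(intensities, dtype=float)
    fg = (v > interval.lo) & (v <= interval.hi)
    return fg & np.asarray(mask, dtype=bool)


def _neighbor_kernel(ndim: int) -> np.ndarray:
    k = np.ones((3,) * ndim, dtype=np.uint8)
    k[(1,) * ndim] = 0
    return k


def tas_statistics(binary: np.ndarray) -> np.ndarray:
    """Neighbor-count distribution over foreground pixels.

    Entry ``k`` is the fraction of foreground pixels having exactly ``k``
    foreground neighbors under full (8/26) connectivity; neighbors outside
    the array count as background.  All-zero vector when there is no
    foreground.
    """
    b = np.asarray(binary, dtype=bool)
    if b.ndim not in (2, 3):
        raise ValueError("binary mask must be 2D or 3D")
    n_bins = 3**b.ndim  # 9 or 27
    n_fg = int(b.sum())
    if n_fg == 0:
        return np.zeros(n_bins)
    counts = ndimage.convolve(b.astype(np.uint8), _neighbor_kernel(b.ndim),
                              mode="constant", cval=0)
    hist = np.bincount(counts[b], minlength=n_bins).astype(float)
    return hist / n_fg


def channel_features(intensities: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """252 (2D) or 756 (3D) TAS features for one nucleus/channel.

    ``v_m`` is the mean intensity over masked pixels only.  Feature order:
    family -> p ascending -> neighbor count k ascending.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty nucleus mask")
    v_m = float(np.asarray(intensities, dtype=float)[mask].mean())
    blocks = [tas_statistics(binarize(intensities, mask, iv))
              for iv in band_intervals(v_m)]
    return np.concatenate(blocks)


def feature_names(channels: Sequence[str], ndim: int = 2) -> list[str]:
    """Frozen feature naming: ``{channel}|{family}|p{p}|k{k}``."""
    n_k = 3**ndim
    names = []
    for ch in channels:
        for iv in band_intervals(1.0):
            ptag = "static" if iv.p is None else f"p{iv.p:.1f}"
            for k in range(n_k):
                names.append(f"{ch}|{iv.family}|{ptag}|k{k}")
    return names


def nucleus_features(record, channels: Sequence[str], ndim: int | None = None) -> np.ndarray:
    """Concatenated per-channel TAS vector for a :class:`NucleusRecord`.

    ``record`` must expose ``channel_image(name)`` and ``local_mask``
    (see :mod:`chromage.segio`).  Concatenation order follows ``channels``.
    """
    mask = record.local_mask
    if ndim is not None and mask.ndim != ndim:
        raise ValueError(f"record is {mask.ndim}D, requested {ndim}D")
    parts = []
    for ch in channels:
        parts.append(channel_features(record.channel_image(ch), mask))
    return np.concatenate(parts)
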