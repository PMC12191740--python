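"""Single-cell crop extraction from cartridge channel images.

Given three fluorescence channels (DAPI, CK, CD45) and an integer instance
mask from an upstream segmentation, each labeled instance is cut out as a
fixed-size three-channel window centered on its mask centroid, zero-padded
at image borders, and min-max normalized per channel to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

CROP_SIZE = 48
CHANNEL_ORDER = ("dapi", "ck", "cd45")


@dataclass(frozen=True)
class ChannelStack:
    """The three stain channels of one cartridge tile, identical shape."""

    dapi: np.ndarray
    ck: np.ndarray
    cd45: np.ndarray

    def __post_init__(self) -> None:
        if not (self.dapi.shape == self.ck.shape == self.cd45.shape):
            raise ValueError("channel shapes must be identical")
        for name in CHANNEL_ORDER:
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} channel contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"{name} channel contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dapi.shape

    def as_array(self) -> np.ndarray:
        """Stack channels along the last axis in (DAPI, CK, CD45) order."""
        return np.stack(
            [np.asarray(getattr(self, n), dtype=float) for n in CHANNEL_ORDER],
            axis=-1,
        )


@dataclass(frozen=True)
class LabelMask:
    """Integer instance mask: 0 = background, k > 0 = instance k."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if not np.issubdtype(mask.dtype, np.integer):
            raise ValueError("mask must be an integer array")
        if mask.min(initial=0) < 0:
            raise ValueError("mask labels must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def instances(self) -> np.ndarray:
        labels = np.unique(self.mask)
        return labels[labels > 0]


@dataclass(frozen=True)
class CellCrop:
    """Normalized 48x48x3 single-cell image with its source location."""

    pixels: np.ndarray           # (size, size, 3) in [0, 1]
    source_instance: int
    centroid: tuple[int, int]    # (row, col), 0-based image coordinates

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be (size, size, 3)")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")


def normalize_crop(raw: np.ndarray) -> np.ndarray:
    """Min-max normalize each channel independently to [0, 1].

    A constant channel (max == min) maps to all zeros: no dynamic range is
    read as no signal.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("crop contains NaN or infinite values")
    out = np.zeros_like(raw)
    for ch in range(raw.shape[-1]):
        channel = raw[..., ch]
        lo, hi = channel.min(), channel.max()
        if hi > lo:
            out[..., ch] = (channel - lo) / (hi - lo)
    return out


def _centroid(mask: np.ndarray, label: int) -> tuple[int, int]:
    # unweighted mean of instance pixel coordinates, rounded toward zero
    coords = np.argwhere(mask == label)
    mean = coords.mean(axis=0)
    return int(mean[0]), int(mean[1])


def extract_crops(
    stack: ChannelStack, mask: LabelMask, size: int = CROP_SIZE
) -> list[CellCrop]:
    """Cut one normalized crop per mask instance, ordered by instance label.

    The window is centered on the instance centroid (size//2 pixels before,
    size - size//2 after); regions outside the image are zero-padded so
    every crop has the exact requested shape.
    """
    if stack.shape != mask.shape:
        raise ValueError(
            f"stack shape {stack.shape} != mask shape {mask.shape}"
        )
    if size <= 0 or size % 2 != 0:
        raise ValueError("size must be a positive even integer")

    image = stack.as_array()
    h, w, _ = image.shape
    half = size // 2
    crops = []
    for label in mask.instances():
        cr, cc = _centroid(mask.mask, int(label))
        window = np.zeros((size, size, 3), dtype=float)
        r0, r1 = cr - half, cr + half
        c0, c1 = cc - half, cc + half
        sr0, sr1 = max(r0, 0), min(r1, h)
        sc0, sc1 = max(c0, 0), min(c1, w)
        window[sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0] = image[
            sr0:sr1, sc0:sc1
        ]
        crops.append(
            CellCrop(
                pixels=normalize_crop(window),
                source_instance=int(label),
                centroid=(cr, cc),
            )
        )
    return crops


def read_channel_stack(dapi_path, ck_path, cd45_path) -> ChannelStack:
    return ChannelStack(
        dapi=tifffile.imread(dapi_path),
        ck=tifffile.imread(ck_path),
        cd45=tifffile.imread(cd45_path),
    )


def read_label_mask(path) -> LabelMask:
    return LabelMask(mask=tifffile.imread(path).astype(np.int32))


def write_crops(crops: list[CellCrop], out_dir) -> pd.DataFrame:
    """Write crops as one multi-page TIFF plus a CSV manifest; return the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiff_path = out_dir / "crops.tiff"
    if crops:
        stack = np.stack([c.pixels.astype(np.float32) for c in crops])
        tifffile.imwrite(tiff_path, stack)
    manifest = pd.DataFrame(
        {
            "id": [f"crop_{c.source_instance:05d}" for c in crops],
            "instance": [c.source_instance for c in crops],
            "centroid_row": [c.centroid[0] for c in crops],
            "centroid_col": [c.centroid[1] for c in crops],
            "path": [f"crops.tiff#{k}" for k in range(len(crops))],
        }
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
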