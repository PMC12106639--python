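"""Tiling, background filtering, normalization, and patch encoding.

Rasters are tessellated into non-overlapping patches; partial edge tiles
are dropped.  Coordinates are 0-based grid indices in the downsampled
frame with x = column, y = row, and z the slide index within a patient.
Background patches are removed by a luminance threshold combined with a
Canny edge-density test.  Features are produced by a pluggable patch
encoder and stored with their coordinates in an HDF5 container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import h5py
import numpy as np
from skimage.color import rgb2gray
from skimage.feature import canny
from skimage.transform import resize

__all__ = [
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "PatchSet",
    "EmptySlideError",
    "tile_image",
    "filter_background",
    "normalize_patches",
    "encode_patches",
    "PatchEncoder",
    "ToyPatchEncoder",
    "concat_patchsets",
    "save_features",
    "load_features",
]

#: per-channel normalization defaults of the upstream pre-trained encoders
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


class EmptySlideError(RuntimeError):
    """Every patch of a slide was filtered out as background."""


@dataclass
class PatchSet:
    """Per-patient patch collection before or after encoding.

    Exactly one of ``patches`` (raw n×h×w×3) / ``features`` (n×d) is the
    payload at any pipeline stage; ``coords`` rows are (x, y, z) grid
    indices aligned 1:1 with payload rows.
    """

    coords: np.ndarray
    patient_id: str = "patient"
    patch_size_px: int = 256
    downsample: int = 1
    patches: np.ndarray | None = None
    features: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int32)
        n = len(self)
        if n < 1:
            raise ValueError("PatchSet must contain at least one patch")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords must be ({n}, 3), got {self.coords.shape}")
        if len(np.unique(self.coords, axis=0)) != n:
            raise ValueError("coords must be unique per (x, y, z)")
        if self.features is not None and not np.isfinite(self.features).all():
            raise ValueError("features must be finite")

    def __len__(self) -> int:
        payload = self.features if self.features is not None else self.patches
        if payload is None:
            raise ValueError("PatchSet has neither patches nor features")
        return payload.shape[0]

    @property
    def n(self) -> int:
        return len(self)

    @property
    def dim(self) -> int:
        if self.features is None:
            raise ValueError("PatchSet has no features yet")
        return self.features.shape[1]


def tile_image(
    image: np.ndarray,
    patch_size: int = 256,
    downsample: int = 1,
    resize_to: int | None = 224,
    z: int = 0,
    patient_id: str = "patient",
) -> PatchSet:
    """Tessellate a raster into non-overlapping ``patch_size`` tiles.

    The raster is first downsampled by an integer factor (stride
    sampling), partial edge tiles are dropped, and each tile is resized
    to ``resize_to`` (None keeps the native tile size).
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H×W×3 RGB raster")
    if downsample < 1:
        raise ValueError("downsample must be a positive integer factor")
    small = image[::downsample, ::downsample]
    h, w = small.shape[:2]
    ny, nx = h // patch_size, w // patch_size
    if ny == 0 or nx == 0:
        raise ValueError(
            f"image ({h}×{w} after downsampling) smaller than one "
            f"{patch_size}px patch"
        )
    tiles, coords = [], []
    for gy in range(ny):
        for gx in range(nx):
            tile = small[
                gy * patch_size : (gy + 1) * patch_size,
                gx * patch_size : (gx + 1) * patch_size,
            ]
            if resize_to is not None and resize_to != patch_size:
                tile = resize(
                    tile.astype(np.float64),
                    (resize_to, resize_to, 3),
                    order=1,
                    preserve_range=True,
                    anti_aliasing=False,
                )
            tiles.append(np.asarray(tile, dtype=np.float64))
            coords.append((gx, gy, z))
    return PatchSet(
        coords=np.array(coords, dtype=np.int32),
        patient_id=patient_id,
        patch_size_px=patch_size,
        downsample=downsample,
        patches=np.stack(tiles),
    )


def _patch_stats(patch: np.ndarray) -> tuple[float, float]:
    """(mean luminance in [0,1], Canny edge-pixel fraction) of one patch."""
    gray = rgb2gray(np.clip(patch, 0, 255) / 255.0)
    edges = canny(gray, sigma=1.0)
    return float(gray.mean()), float(edges.mean())


def filter_background(
    patches: PatchSet,
    white_threshold: float = 0.90,
    edge_fraction_threshold: float = 0.02,
) -> PatchSet:
    """Drop background tiles; keep survivor order.

    A patch is excluded iff its mean luminance exceeds ``white_threshold``
    (fraction of maximum) OR its Canny edge-pixel fraction falls below
    ``edge_fraction_threshold``.
    """
    if not (0 < white_threshold <= 1) or not (0 <= edge_fraction_threshold <= 1):
        raise ValueError("thresholds out of range")
    if patches.patches is None:
        raise ValueError("filter_background requires raw patches")
    keep = []
    for i in range(len(patches)):
        lum, edge_frac = _patch_stats(patches.patches[i])
        if lum > white_threshold or edge_frac < edge_fraction_threshold:
            continue
        keep.append(i)
    if not keep:
        raise EmptySlideError(
            f"all {len(patches)} patches of {patches.patient_id!r} were "
            "filtered as background"
        )
    keep = np.array(keep)
    return PatchSet(
        coords=patches.coords[keep],
        patient_id=patches.patient_id,
        patch_size_px=patches.patch_size_px,
        downsample=patches.downsample,
        patches=patches.patches[keep],
        meta=dict(patches.meta),
    )


def normalize_patches(
    patches: PatchSet,
    mean: tuple[float, float, float] = IMAGENET_MEAN,
    std: tuple[float, float, float] = IMAGENET_STD,
) -> PatchSet:
    """Map 0-255 channel values to ``(v/255 - mean_c) / std_c``."""
    mean_arr = np.asarray(mean, dtype=np.float64)
    std_arr = np.asarray(std, dtype=np.float64)
    if (std_arr <= 0).any():
        raise ValueError("std must be positive per channel")
    if patches.patches is None:
        raise ValueError("normalize_patches requires raw patches")
    data = (patches.patches / 255.0 - mean_arr) / std_arr
    return PatchSet(
        coords=patches.coords.copy(),
        patient_id=patches.patient_id,
        patch_size_px=patches.patch_size_px,
        downsample=patches.downsample,
        patches=data,
        meta=dict(patches.meta),
    )


@runtime_checkable
class PatchEncoder(Protocol):
    """Pluggable frozen patch encoder: tiles in, fixed-dim features out."""

    dim: int
    name: str

    def __call__(self, patches: np.ndarray) -> np.ndarray: ...


class ToyPatchEncoder:
    """Deterministic handcrafted encoder for desk-scale experiments.

    Summarises each tile by per-channel mean/std and a coarse 4×4 gray
    thumbnail, then applies a fixed seeded random projection to ``dim``.
    Color statistics make the synthetic classes linearly separable.
    """

    def __init__(self, dim: int = 64, seed: int = 0):
        self.dim = dim
        self.name = f"toy-{dim}"
        self._rng_seed = seed

    def _descriptor(self, patch: np.ndarray) -> np.ndarray:
        p = np.asarray(patch, dtype=np.float64)
        if p.max() > 1.5:  # raw 0-255 scale
            p = p / 255.0
        chan = p.reshape(-1, 3)
        gray = p.mean(axis=2)
        h, w = gray.shape
        th = np.array(
            [
                gray[i * h // 4 : (i + 1) * h // 4, j * w // 4 : (j + 1) * w // 4].mean()
                for i in range(4)
                for j in range(4)
            ]
        )
        return np.concatenate([chan.mean(axis=0), chan.std(axis=0), th])

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        desc = np.stack([self._descriptor(p) for p in patches])
        rng = np.random.default_rng(self._rng_seed)
        proj = rng.normal(0, 1.0 / np.sqrt(desc.shape[1]), size=(desc.shape[1], self.dim))
        return desc @ proj


def encode_patches(
    patches: PatchSet,
    encoder: PatchEncoder,
    expected_dim: int | None = None,
) -> PatchSet:
    """Run the patch encoder; coordinates are carried through unchanged."""
    if patches.patches is None:
        raise ValueError("encode_patches requires raw patches")
    if expected_dim is not None and encoder.dim != expected_dim:
        raise ValueError(
            f"encoder declares dim {encoder.dim}, configuration expects {expected_dim}"
        )
    feats = np.asarray(encoder(patches.patches), dtype=np.float64)
    if feats.shape != (len(patches), encoder.dim):
        raise ValueError(
            f"encoder emitted shape {feats.shape}, declared dim is {encoder.dim}"
        )
    return PatchSet(
        coords=patches.coords.copy(),
        patient_id=patches.patient_id,
        patch_size_px=patches.patch_size_px,
        downsample=patches.downsample,
        features=feats,
        meta={**patches.meta, "encoder": encoder.name},
    )


def concat_patchsets(sets: list[PatchSet]) -> PatchSet:
    """Stack per-slide PatchSets of one patient along the patch axis.

    z coordinates must already distinguish the slides.
    """
    if not sets:
        raise ValueError("no PatchSets to concatenate")
    first = sets[0]
    if first.features is not None:
        payload = {"features": np.concatenate([s.features for s in sets])}
    else:
        payload = {"patches": np.concatenate([s.patches for s in sets])}
    return PatchSet(
        coords=np.concatenate([s.coords for s in sets]),
        patient_id=first.patient_id,
        patch_size_px=first.patch_size_px,
        downsample=first.downsample,
        meta=dict(first.meta),
        **payload,
    )


# ---------------------------------------------------------------------------
# feature container I/O
# ---------------------------------------------------------------------------

def save_features(path: str | Path, patchsets: list[PatchSet]) -> None:
    """Write encoded PatchSets to one HDF5 container.

    Layout: ``features`` (n×d float32), ``coords`` (n×3 int32),
    ``slide_ids`` (n strings = patient ids), plus metadata attributes.
    """
    feats = np.concatenate([np.asarray(p.features, dtype=np.float32) for p in patchsets])
    coords = np.concatenate([p.coords for p in patchsets])
    ids = np.concatenate(
        [np.full(len(p), p.patient_id, dtype=object) for p in patchsets]
    )
    first = patchsets[0]
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=feats)
        f.create_dataset("coords", data=coords.astype(np.int32))
        f.create_dataset(
            "slide_ids", data=ids.astype("S"), dtype=h5py.string_dtype("ascii")
        )
        f.attrs["patch_size_px"] = first.patch_size_px
        f.attrs["downsample"] = first.downsample
        f.attrs["encoder"] = first.meta.get("encoder", "unknown")


def load_features(path: str | Path) -> list[PatchSet]:
    """Read a feature container back into per-patient PatchSets."""
    with h5py.File(path, "r") as f:
        feats = f["features"][:].astype(np.float64)
        coords = f["coords"][:]
        ids = np.array([s.decode() if isinstance(s, bytes) else s for s in f["slide_ids"][:]])
        patch_size = int(f.attrs["patch_size_px"])
        downsample = int(f.attrs["downsample"])
        encoder = str(f.attrs["encoder"])
    out = []
    for pid in dict.fromkeys(ids):  # preserve order
        sel = ids == pid
        out.append(
            PatchSet(
                coords=coords[sel],
                patient_id=str(pid),
                patch_size_px=patch_size,
                downsample=downsample,
                features=feats[sel],
                meta={"encoder": encoder},
            )
        )
    return out
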