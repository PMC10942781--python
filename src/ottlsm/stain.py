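"""Patch preparation for style-transfer training, and virtual H&E rendering.

The network that learns fluorescence-to-H&E style transfer trains on
512 x 512 patches cropped from large reconstructed images and augmented
six-fold: identity, rotations by 90/180/270 degrees, and vertical and
horizontal flips (2,387 source crops become 14,322 training patches).
That patch pipeline is implemented here in full.  The adversarial training
itself is a GPU-scale hand-off and is deliberately not part of this
package; in its place a deterministic Beer-Lambert absorption model renders
an H&E-like image so the end-to-end pipeline still produces pathology-style
output: per RGB band b,

    T_b = white_b * exp(-(c_nuc * OD_H[b] + c_str * OD_E[b])),

with the standard color-deconvolution optical-density vectors for
hematoxylin (applied to the nuclear fluorescence channel) and eosin
(applied to the SHG/stromal channel).  Zero input renders white; increasing
either concentration monotonically darkens every band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PatchSet", "StainConfig", "extract_patches", "augment",
           "virtual_he", "AUGMENTATIONS"]

#: fixed augmentation order, so dataset manifests are reproducible
AUGMENTATIONS = ("identity", "rot90", "rot180", "rot270", "flip_v", "flip_h")


def _apply_augmentation(patch: np.ndarray, tag: str) -> np.ndarray:
    if tag == "identity":
        return patch.copy()
    if tag == "rot90":
        return np.rot90(patch, 1).copy()
    if tag == "rot180":
        return np.rot90(patch, 2).copy()
    if tag == "rot270":
        return np.rot90(patch, 3).copy()
    if tag == "flip_v":
        return np.flipud(patch).copy()
    if tag == "flip_h":
        return np.fliplr(patch).copy()
    raise ValueError(f"unknown augmentation {tag!r}")


@dataclass
class PatchSet:
    """Patches plus the bookkeeping that traces each back to its crop."""

    patches: list                      # list of 2D arrays (size x size)
    source_ids: list                   # source image id per patch
    origins: list                      # (row, col) crop origin per patch
    tags: list                         # augmentation tag per patch
    size: int = 512
    dropped_tiles: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patches)

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame({
            "source": self.source_ids,
            "origin_row": [o[0] for o in self.origins],
            "origin_col": [o[1] for o in self.origins],
            "augmentation": self.tags,
        })


def extract_patches(image: np.ndarray, size: int = 512,
                    stride: int | None = None,
                    source_id: str = "image0") -> PatchSet:
    """Row-major tiling of an image into size x size crops.

    Partial edge tiles are dropped and recorded in ``dropped_tiles``.
    Images smaller than one patch raise.
    """
    if stride is None:
        stride = size
    if stride <= 0 or size <= 0:
        raise ValueError("size and stride must be positive")
    h, w = image.shape[:2]
    if h < size or w < size:
        raise ValueError(f"image {h}x{w} smaller than patch size {size}")
    patches, origins, dropped = [], [], []
    for r in range(0, h - size + 1, stride):
        for c in range(0, w - size + 1, stride):
            patches.append(np.asarray(image[r:r + size, c:c + size]).copy())
            origins.append((r, c))
    # record the partial tiles the stride grid would have produced
    rows = list(range(0, h, stride))
    cols = list(range(0, w, stride))
    for r in rows:
        for c in cols:
            if r + size > h or c + size > w:
                dropped.append((r, c))
    return PatchSet(patches=patches, source_ids=[source_id] * len(patches),
                    origins=origins, tags=["identity"] * len(patches),
                    size=size, dropped_tiles=dropped)


def augment(patchset: PatchSet) -> PatchSet:
    """Six-fold augmentation: identity, three rotations, two flips.

    Output count is exactly 6x the input count, in the fixed order of
    ``AUGMENTATIONS`` per source patch, and every augmented patch keeps its
    source id and crop origin.
    """
    patches, ids, origins, tags = [], [], [], []
    for patch, sid, org in zip(patchset.patches, patchset.source_ids,
                               patchset.origins):
        for tag in AUGMENTATIONS:
            patches.append(_apply_augmentation(patch, tag))
            ids.append(sid)
            origins.append(org)
            tags.append(tag)
    return PatchSet(patches=patches, source_ids=ids, origins=origins,
                    tags=tags, size=patchset.size,
                    dropped_tiles=list(patchset.dropped_tiles))


@dataclass(frozen=True)
class StainConfig:
    """Beer-Lambert virtual-stain parameters.

    OD vectors are the standard H&E color-deconvolution pair; hematoxylin
    darkens the nuclear channel toward purple-blue, eosin the stromal
    channel toward pink.  Concentration scalings map channel intensities
    (normalized to [0, 1]) to optical densities.
    """

    hematoxylin_od: tuple = (0.65, 0.70, 0.29)
    eosin_od: tuple = (0.07, 0.99, 0.11)
    nuclear_scale: float = 1.2
    stromal_scale: float = 0.8
    white_level: tuple = (1.0, 1.0, 1.0)
    normalize_od: bool = False

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.hematoxylin_od + self.eosin_od):
            raise ValueError("OD vectors must be non-negative")

    def od_vectors(self) -> tuple:
        h = np.asarray(self.hematoxylin_od, dtype=float)
        e = np.asarray(self.eosin_od, dtype=float)
        if self.normalize_od:
            h = h / np.linalg.norm(h)
            e = e / np.linalg.norm(e)
        return h, e


def virtual_he(fluor: np.ndarray, shg: np.ndarray,
               cfg: StainConfig | None = None) -> np.ndarray:
    """Deterministic two-channel to RGB virtual-H&E transform.

    Channels must be co-registered and equal in shape; they are normalized
    by their own maxima (all-zero channels stay zero), converted to stain
    concentrations, and absorbed per Beer-Lambert.  Output is float RGB in
    [0, 1]; zero input is white paper.
    """
    cfg = cfg or StainConfig()
    fluor = np.asarray(fluor, dtype=float)
    shg = np.asarray(shg, dtype=float)
    if fluor.shape != shg.shape:
        raise ValueError("channels must share one shape")
    h_od, e_od = cfg.od_vectors()

    def norm(a):
        m = np.nanmax(a)
        return np.nan_to_num(a / m) if m > 0 else np.zeros_like(a)

    c_nuc = cfg.nuclear_scale * norm(fluor)
    c_str = cfg.stromal_scale * norm(shg)
    od = (c_nuc[..., None] * h_od[None, None, :]
          + c_str[..., None] * e_od[None, None, :])
    rgb = np.asarray(cfg.white_level)[None, None, :] * np.exp(-od)
    return np.clip(rgb, 0.0, 1.0)
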