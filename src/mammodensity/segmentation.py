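"""Breast-envelope (region of interest) segmentation for MLO views.

Pipeline: background removal (Otsu), pectoral-muscle removal (corner
region growing guided by laterality), overlay-text removal (bright
components confined to the background), and a subcutaneous-fat peel
(inward erosion of the skin line, chest-wall edge untouched).

All internal processing happens in a normalized orientation with the
chest wall on the LEFT; images with laterality R are mirrored on entry
and the masks mirrored back on exit, which removes laterality branches
from the core logic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from .dicom_io import MammogramImage
from .errors import DegenerateMaskError, EmptyImageError, UnsupportedViewError


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters for envelope construction.

    The published pipeline names the removed structures but none of the
    method parameters; everything here is a configuration decision.
    """

    fat_peel_margin: int = 4
    min_text_component_area: int = 20
    pectoral_method: str = "corner_region_growing"
    background_method: str = "otsu"
    fixed_background_level: int = 0
    # region growing accepts pixels no darker than seed mean minus this
    # multiple of the seed standard deviation (floored at 5% of range)
    pectoral_tolerance_sigmas: float = 6.0

    def __post_init__(self) -> None:
        if self.fat_peel_margin < 0:
            raise ValueError("fat_peel_margin must be >= 0")
        if self.min_text_component_area < 0:
            raise ValueError("min_text_component_area must be >= 0")


@dataclass
class SegmentationMasks:
    """Disjoint masks that tile the image.

    ``envelope_mask`` is the analysis ROI; ``background_mask`` is defined
    as the complement of the other three, so the partition property holds
    by construction and is asserted in :meth:`validate`.
    """

    envelope_mask: np.ndarray
    pectoral_mask: np.ndarray
    text_mask: np.ndarray
    background_mask: np.ndarray
    provenance: dict | None = None

    def validate(self) -> None:
        total = (self.envelope_mask.astype(int) + self.pectoral_mask
                 + self.text_mask + self.background_mask)
        assert np.all(total == 1), "masks must tile the image exactly once"


def _chest_left(pixels: np.ndarray, laterality: str) -> np.ndarray:
    """Mirror so the chest wall is on the left."""
    return pixels[:, ::-1] if laterality == "R" else pixels


def _background_threshold(pixels: np.ndarray, config: SegmentationConfig) -> float:
    if config.background_method == "fixed":
        return float(config.fixed_background_level)
    try:
        return float(threshold_otsu(pixels))
    except ValueError as exc:  # constant image
        raise EmptyImageError("image is single-valued; no foreground") from exc


def _background_and_candidate(pixels: np.ndarray, config: SegmentationConfig):
    """Background mask (dark components touching non-chest-wall borders)
    and the breast candidate (largest remaining component).

    Assumes chest wall on the left.
    """
    thr = _background_threshold(pixels, config)
    below = pixels <= thr
    labels = label(below, connectivity=2)
    border_labels = set(np.unique(labels[0, :])) | set(np.unique(labels[-1, :])) \
        | set(np.unique(labels[:, -1]))
    border_labels.discard(0)
    background = np.isin(labels, sorted(border_labels))

    fg_labels = label(~background, connectivity=2)
    if fg_labels.max() == 0:
        raise EmptyImageError("no foreground component above background level")
    sizes = np.bincount(fg_labels.ravel())
    sizes[0] = 0
    candidate = fg_labels == int(np.argmax(sizes))
    return background, candidate, thr


def segment_background(image: MammogramImage,
                       config: SegmentationConfig | None = None) -> np.ndarray:
    """Mask of dark pixels connected to the non-chest-wall borders."""
    config = config or SegmentationConfig()
    pixels = _chest_left(image.pixels, image.laterality)
    background, _, _ = _background_and_candidate(pixels, config)
    return _chest_left(background, image.laterality)


def remove_pectoral(image: MammogramImage, breast_candidate: np.ndarray,
                    laterality: str | None = None,
                    config: SegmentationConfig | None = None) -> np.ndarray:
    """Pectoral mask grown from the chest-wall top corner.

    The muscle is assumed to be the brightest, roughly homogeneous
    structure adjacent to the chest-wall top corner; growth is confined
    to the chest-side half of the image and never reaches the nipple-side
    half.  An empty result is legal (pectoral not found).
    """
    config = config or SegmentationConfig()
    laterality = laterality or image.laterality
    pixels = _chest_left(image.pixels, laterality)
    candidate = _chest_left(np.asarray(breast_candidate, dtype=bool), laterality)
    mask = _grow_pectoral(pixels, candidate, config)
    return _chest_left(mask, laterality)


def _grow_pectoral(pixels: np.ndarray, candidate: np.ndarray,
                   config: SegmentationConfig) -> np.ndarray:
    h, w = pixels.shape
    seed = np.zeros_like(candidate)
    seed[:3, :3] = True
    seed &= candidate
    if not np.any(seed):
        return np.zeros_like(candidate)
    seed_vals = pixels[seed].astype(float)
    seed_mean = seed_vals.mean()
    seed_sd = seed_vals.std()
    span = float(pixels.max()) - float(pixels.min())
    tol = max(config.pectoral_tolerance_sigmas * seed_sd, 0.05 * span)

    constraint = np.zeros_like(candidate)
    constraint[: int(0.75 * h), : w // 2] = True
    bright = pixels >= seed_mean - tol
    region = candidate & bright & constraint
    labels = label(region, connectivity=2)
    keep = np.unique(labels[seed])
    keep = keep[keep > 0]
    if keep.size == 0:
        return np.zeros_like(candidate)
    mask = np.isin(labels, keep)
    # close pinholes left by noise without extending the boundary outwards
    mask = ndimage.binary_fill_holes(mask)
    return mask & candidate


def remove_text_overlay(image: MammogramImage, background_mask: np.ndarray,
                        config: SegmentationConfig | None = None) -> np.ndarray:
    """Bright components fully surrounded by background, large enough to be
    overlay text."""
    config = config or SegmentationConfig()
    background = np.asarray(background_mask, dtype=bool)
    foreground = ~background
    labels = label(foreground, connectivity=2)
    if labels.max() == 0:
        return np.zeros_like(background)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    main = int(np.argmax(sizes))
    text = np.zeros_like(background)
    structure = np.ones((3, 3), dtype=bool)
    for lbl in range(1, labels.max() + 1):
        if lbl == main or sizes[lbl] < config.min_text_component_area:
            continue
        comp = labels == lbl
        halo = ndimage.binary_dilation(comp, structure) & ~comp
        if np.all(background[halo]):
            text |= comp
    return text


def peel_subcutaneous_fat(breast_mask: np.ndarray, margin: int) -> np.ndarray:
    """Erode the skin-line boundary inward by ``margin`` pixels.

    The chest-wall edge (left image border in the normalized orientation)
    is protected by replicate padding, so erosion only eats the outer
    (skin) boundary.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    mask = np.asarray(breast_mask, dtype=bool)
    if margin == 0:
        return mask.copy()
    padded = np.pad(mask, ((margin, margin), (0, margin)), constant_values=False)
    padded = np.pad(padded, ((0, 0), (margin, 0)), mode="edge")
    dist = ndimage.distance_transform_edt(padded)
    peeled = dist[margin:-margin, margin:-margin] > margin
    if not np.any(peeled):
        raise DegenerateMaskError(
            f"fat peel margin {margin} erased the entire breast mask")
    return peeled


def build_envelope(image: MammogramImage,
                   config: SegmentationConfig | None = None) -> SegmentationMasks:
    """Compose background, pectoral, text and fat-peel stages into the
    final disjoint mask set (original image orientation)."""
    config = config or SegmentationConfig()
    if image.view_position.upper() != "MLO":
        raise UnsupportedViewError(
            f"segmentation supports MLO views only, got "
            f"{image.view_position!r}")
    pixels = _chest_left(image.pixels, image.laterality)

    try:
        background, candidate, bg_thr = _background_and_candidate(pixels, config)
    except EmptyImageError as exc:
        raise EmptyImageError(f"background stage: {exc}") from exc

    pectoral = _grow_pectoral(pixels, candidate, config)

    norm_image = MammogramImage(
        pixels=pixels.copy(), laterality="L", view_position="MLO",
        bits_stored=image.bits_stored, source_id=image.source_id)
    text = remove_text_overlay(norm_image, background, config)

    envelope = candidate & ~pectoral & ~text
    try:
        envelope = peel_subcutaneous_fat(envelope, config.fat_peel_margin)
    except DegenerateMaskError as exc:
        raise DegenerateMaskError(f"fat peel stage: {exc}") from exc

    # keep the largest connected piece so the envelope is a single
    # component attached to the chest wall
    labels = label(envelope, connectivity=2)
    if labels.max() == 0:
        raise DegenerateMaskError("envelope stage: empty envelope")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    envelope = labels == int(np.argmax(sizes))

    provenance = {
        "background_threshold": float(bg_thr),
        "pectoral_found": bool(pectoral.any()),
        "fat_peel_margin": config.fat_peel_margin,
        "envelope_touches_chest_wall": bool(envelope[:, 0].any()),
    }

    flip = lambda m: _chest_left(m, image.laterality).copy()
    envelope, pectoral, text = flip(envelope), flip(pectoral), flip(text)
    masks = SegmentationMasks(
        envelope_mask=envelope,
        pectoral_mask=pectoral & ~envelope,
        text_mask=text & ~envelope,
        background_mask=~(envelope | pectoral | text),
        provenance=provenance,
    )
    masks.validate()
    return masks
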