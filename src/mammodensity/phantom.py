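"""Synthetic MLO-like mammogram phantoms with exact ground truth.

The phantom uses a four-intensity-class model: dark background, a fatty
half-elliptical breast envelope attached to the chest-wall edge, bright
fibroglandular (dense) blobs inside the envelope, and a brighter pectoral
wedge in the chest-wall upper corner — the simplest geometry under which
background removal, pectoral removal, text removal and histogram
thresholding are all exercised meaningfully.  Dense blobs are painted
(random ellipses, trimmed on the last blob) until the dense/envelope
pixel ratio hits the requested density exactly.

A companion rater-panel simulator emits visual percent-density readings
on the 21-point grid {0, 5, ..., 100}.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .dicom_io import MammogramImage
from .errors import InfeasiblePhantomError


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters describing one synthetic mammogram."""

    image_height: int = 256
    image_width: int = 208
    laterality: str = "L"
    true_density: float = 0.25
    pectoral_fraction: float = 0.08
    n_dense_blobs: int = 12
    fat_intensity: int = 500
    dense_intensity: int = 700
    pectoral_intensity: int = 800
    background_intensity: int = 40
    noise_sd: float = 10.0
    with_text_overlay: bool = False
    seed: int = 0
    max_gray: int = 4095

    def validate(self) -> None:
        if self.image_height < 128 or self.image_width < 128:
            raise InfeasiblePhantomError("phantom must be at least 128x128")
        if self.laterality not in ("L", "R"):
            raise InfeasiblePhantomError(
                f"laterality must be L or R, got {self.laterality!r}")
        if not 0.0 <= self.true_density <= 1.0:
            raise InfeasiblePhantomError(
                f"true_density {self.true_density} outside [0, 1]")
        if not 0.0 <= self.pectoral_fraction <= 0.3:
            raise InfeasiblePhantomError(
                f"pectoral_fraction {self.pectoral_fraction} outside [0, 0.3]")
        if self.n_dense_blobs < 1:
            raise InfeasiblePhantomError("n_dense_blobs must be positive")
        if not (0 <= self.background_intensity < self.fat_intensity
                < self.dense_intensity <= self.pectoral_intensity
                <= self.max_gray):
            raise InfeasiblePhantomError(
                "intensities must satisfy background < fat < dense <= "
                "pectoral <= max_gray")
        if self.noise_sd < 0:
            raise InfeasiblePhantomError("noise_sd must be >= 0")


@dataclass
class PhantomTruth:
    """Ground-truth masks for a generated phantom (original orientation)."""

    envelope_mask: np.ndarray
    pectoral_mask: np.ndarray
    dense_mask: np.ndarray
    text_mask: np.ndarray
    true_density: float

    def validate(self) -> None:
        assert not np.any(self.dense_mask & ~self.envelope_mask), \
            "dense mask must lie inside the envelope"
        assert not np.any(self.pectoral_mask & self.envelope_mask), \
            "pectoral and envelope masks must be disjoint"
        assert not np.any(self.text_mask & self.envelope_mask), \
            "text and envelope masks must be disjoint"
        n_env = int(self.envelope_mask.sum())
        assert n_env > 0
        assert self.true_density == self.dense_mask.sum() / n_env


@dataclass(frozen=True)
class RaterModel:
    """Generative model for a panel of visual density readers."""

    n_raters: int = 5
    rater_biases: tuple[float, ...] | None = None
    noise_sd: float = 5.0
    seed: int = 0

    def biases(self) -> np.ndarray:
        if self.rater_biases is None:
            return np.zeros(self.n_raters)
        if len(self.rater_biases) != self.n_raters:
            raise ValueError("rater_biases length must equal n_raters")
        return np.asarray(self.rater_biases, dtype=float)


def _half_ellipse(h: int, w: int) -> np.ndarray:
    """Breast outline: half ellipse attached to the left (chest-wall) edge."""
    rows, cols = np.mgrid[0:h, 0:w]
    a = 0.42 * h  # vertical semi-axis
    b = 0.62 * w  # horizontal semi-axis
    return (cols / b) ** 2 + ((rows - h / 2) / a) ** 2 <= 1.0


def _pectoral_wedge(h: int, w: int, fraction: float) -> np.ndarray:
    """Triangular wedge anchored at the top-left (chest-wall upper) corner."""
    wedge = np.zeros((h, w), dtype=bool)
    area = fraction * h * w
    if area < 1.0:
        return wedge
    # aspect ratio 1.8 (taller than wide), capped to stay out of the
    # nipple-side half and the lower part of the image
    h_t = np.sqrt(2.0 * area * 1.8)
    w_t = h_t / 1.8
    if w_t > 0.45 * w:
        w_t = 0.45 * w
        h_t = 2.0 * area / w_t
    h_t = min(h_t, 0.85 * h)
    rows, cols = np.mgrid[0:h, 0:w]
    wedge = cols / w_t + rows / h_t <= 1.0
    return wedge


def _paint_dense(envelope: np.ndarray, target: int, n_blobs: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Paint random elliptical blobs inside ``envelope`` until exactly
    ``target`` pixels are dense (the final blob is trimmed by distance
    from its center)."""
    dense = np.zeros_like(envelope)
    n_env = int(envelope.sum())
    if target <= 0:
        return dense
    if target >= n_env:
        return envelope.copy()
    h, w = envelope.shape
    env_rows, env_cols = np.nonzero(envelope)
    typical_r = max(2.0, np.sqrt((target / n_blobs) / np.pi))
    painted = 0
    while painted < target:
        free = envelope & ~dense
        free_idx = np.flatnonzero(free)
        # a free pixel always exists because painted < target < n_env
        pick = free_idx[rng.integers(free_idx.size)]
        cr, cc = divmod(pick, w)
        r1 = typical_r * rng.uniform(0.6, 1.4)
        r2 = typical_r * rng.uniform(0.6, 1.4)
        theta = rng.uniform(0, np.pi)
        r0 = int(np.ceil(max(r1, r2))) + 1
        rlo, rhi = max(0, cr - r0), min(h, cr + r0 + 1)
        clo, chi = max(0, cc - r0), min(w, cc + r0 + 1)
        rows, cols = np.mgrid[rlo:rhi, clo:chi]
        dr, dc = rows - cr, cols - cc
        u = dr * np.cos(theta) + dc * np.sin(theta)
        v = -dr * np.sin(theta) + dc * np.cos(theta)
        blob = (u / r1) ** 2 + (v / r2) ** 2 <= 1.0
        blob &= free[rlo:rhi, clo:chi]
        new = int(blob.sum())
        if new == 0:
            continue
        if painted + new > target:
            # trim the final blob: keep the pixels closest to its center
            need = target - painted
            rr, cc2 = np.nonzero(blob)
            d2 = (rr + rlo - cr) ** 2 + (cc2 + clo - cc) ** 2
            order = np.lexsort((cc2, rr, d2))[:need]
            keep = np.zeros_like(blob)
            keep[rr[order], cc2[order]] = True
            blob = keep
            new = need
        patch = dense[rlo:rhi, clo:chi]
        patch |= blob
        dense[rlo:rhi, clo:chi] = patch
        painted += new
    return dense


def _text_blocks(h: int, w: int, foreground: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Bright glyph-like rectangles in background corners, away from the
    breast (chest wall is on the left in generation orientation)."""
    text = np.zeros((h, w), dtype=bool)
    glyph_h, glyph_w, gap = 10, 8, 4
    for corner_row in (int(0.04 * h), int(0.92 * h)):
        col = w - 5 * (glyph_w + gap)
        for _ in range(4):
            block = np.zeros((h, w), dtype=bool)
            block[corner_row:corner_row + glyph_h, col:col + glyph_w] = True
            if not np.any(block & foreground):
                text |= block
            col += glyph_w + gap
    return text


def generate_phantom(spec: PhantomSpec) -> tuple[MammogramImage, PhantomTruth]:
    """Generate a synthetic MLO mammogram and its exact ground truth.

    Deterministic for a fixed ``spec.seed``.  The dense/envelope pixel
    ratio equals ``spec.true_density`` to within half a pixel (the blob
    painter hits ``round(true_density * |envelope|)`` exactly).
    """
    spec.validate()
    h, w = spec.image_height, spec.image_width
    rng = np.random.default_rng(spec.seed)

    breast = _half_ellipse(h, w)
    pectoral = _pectoral_wedge(h, w, spec.pectoral_fraction)
    envelope = breast & ~pectoral
    n_env = int(envelope.sum())
    if n_env == 0:
        raise InfeasiblePhantomError("pectoral wedge swallowed the envelope")

    target = int(round(spec.true_density * n_env))
    dense = _paint_dense(envelope, target, spec.n_dense_blobs, rng)

    image = np.full((h, w), float(spec.background_intensity))
    image[envelope] = spec.fat_intensity
    image[dense] = spec.dense_intensity
    image[pectoral] = spec.pectoral_intensity

    text = np.zeros((h, w), dtype=bool)
    if spec.with_text_overlay:
        text = _text_blocks(h, w, breast | pectoral, rng)
        image[text] = spec.pectoral_intensity

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, spec.max_gray).astype(np.uint16)

    if spec.laterality == "R":
        image = image[:, ::-1].copy()
        envelope = envelope[:, ::-1].copy()
        pectoral = pectoral[:, ::-1].copy()
        dense = dense[:, ::-1].copy()
        text = text[:, ::-1].copy()

    mammogram = MammogramImage(
        pixels=image,
        laterality=spec.laterality,
        view_position="MLO",
        photometric_interpretation="MONOCHROME2",
        bits_stored=12,
        source_id=f"phantom-s{spec.seed}",
    )
    truth = PhantomTruth(
        envelope_mask=envelope,
        pectoral_mask=pectoral,
        dense_mask=dense,
        text_mask=text,
        true_density=target / n_env,
    )
    truth.validate()
    return mammogram, truth


# ---------------------------------------------------------------------------
# rater panel simulation
# ---------------------------------------------------------------------------

def snap_to_grid(values: np.ndarray) -> np.ndarray:
    """Round to the nearest multiple of 5, ties away from zero.

    Inputs are clipped percentages (nonnegative), so ties-away-from-zero
    is simply floor(x/5 + 0.5) * 5.
    """
    return 5.0 * np.floor(np.asarray(values, dtype=float) / 5.0 + 0.5)


def simulate_rater_panel(true_densities, model: RaterModel):
    """Simulate visual assessments on the 21-point percent grid.

    rating(i, r) = snap5(clip(100 * truth_i + bias_r + eps, 0, 100)),
    eps ~ Normal(0, noise_sd), deterministic per ``model.seed``.
    """
    from .agreement import RaterPanel  # local import avoids a cycle

    truths = np.asarray(true_densities, dtype=float)
    if truths.size == 0:
        raise ValueError("true_densities must be non-empty")
    if np.any((truths < 0) | (truths > 1)):
        raise ValueError("true densities must lie in [0, 1]")
    rng = np.random.default_rng(model.seed)
    biases = model.biases()
    eps = rng.normal(0.0, model.noise_sd, size=(truths.size, model.n_raters)) \
        if model.noise_sd > 0 else np.zeros((truths.size, model.n_raters))
    raw = 100.0 * truths[:, None] + biases[None, :] + eps
    ratings = snap_to_grid(np.clip(raw, 0.0, 100.0))
    return RaterPanel(
        ratings=ratings,
        subject_ids=[f"subject-{i}" for i in range(truths.size)],
        rater_ids=[f"rater-{r}" for r in range(model.n_raters)],
    )


# ---------------------------------------------------------------------------
# text-only persistence (16-bit PNG + JSON sidecar with RLE masks)
# ---------------------------------------------------------------------------

def rle_encode(mask: np.ndarray) -> list[int]:
    """Run lengths of the row-major flattened mask, starting with a run of
    False (possibly length 0)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return []
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    runs = np.diff(bounds).tolist()
    if flat[0]:
        runs = [0] + runs
    return [int(r) for r in runs]


def rle_decode(runs: list[int], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, value = 0, False
    for run in runs:
        if value:
            flat[pos:pos + run] = True
        pos += run
        value = not value
    return flat.reshape(shape)


def save_phantom(image: MammogramImage, truth: PhantomTruth, spec: PhantomSpec,
                 directory: str | Path, fmt: str = "dicom") -> dict[str, Path]:
    """Write a phantom as DICOM or 16-bit PNG, plus a JSON sidecar holding
    the generating :class:`PhantomSpec` and run-length-encoded truth
    masks."""
    import imageio.v3 as iio

    from .dicom_io import write_mammogram

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = image.source_id or "phantom"
    if fmt == "dicom":
        image_path = directory / f"{stem}.dcm"
        write_mammogram(image, image_path)
    elif fmt == "png":
        image_path = directory / f"{stem}.png"
        iio.imwrite(image_path, image.pixels.astype(np.uint16))
    else:
        raise ValueError(f"unsupported phantom format {fmt!r}")
    sidecar = {
        "spec": asdict(spec),
        "true_density": truth.true_density,
        "shape": list(image.shape),
        "laterality": image.laterality,
        "view_position": image.view_position,
        "masks_rle": {
            "envelope": rle_encode(truth.envelope_mask),
            "pectoral": rle_encode(truth.pectoral_mask),
            "dense": rle_encode(truth.dense_mask),
            "text": rle_encode(truth.text_mask),
        },
    }
    sidecar_path = directory / f"{stem}.json"
    sidecar_path.write_text(json.dumps(sidecar))
    return {"image": image_path, "sidecar": sidecar_path}


def load_phantom_truth(sidecar_path: str | Path) -> PhantomTruth:
    """Reconstruct :class:`PhantomTruth` from a JSON sidecar."""
    data = json.loads(Path(sidecar_path).read_text())
    shape = tuple(data["shape"])
    masks = data["masks_rle"]
    return PhantomTruth(
        envelope_mask=rle_decode(masks["envelope"], shape),
        pectoral_mask=rle_decode(masks["pectoral"], shape),
        dense_mask=rle_decode(masks["dense"], shape),
        text_mask=rle_decode(masks["text"], shape),
        true_density=data["true_density"],
    )
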