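"""Reading and writing of single-frame grayscale mammograms.

Only the small DICOM subset the density pipeline depends on is supported:
single-frame, uncompressed, little-endian (explicit or implicit VR)
grayscale images with the View Position (0018,5101) and Image Laterality
(0020,0062) header elements.  The codec is self-contained so the package
has no runtime DICOM dependency.

Intensity convention: every ingested image is normalized so that larger
pixel values mean brighter (denser) tissue.  MONOCHROME1 images are
inverted exactly once, at ingestion; all downstream code may assume
bright = dense.
"""

from __future__ import annotations

import csv
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError, MetadataError, UnsupportedViewError

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
IMPLICIT_VR_LE = "1.2.840.10008.1.2"

_TAG_TRANSFER_SYNTAX = (0x0002, 0x0010)
_TAG_VIEW_POSITION = (0x0018, 0x5101)
_TAG_LATERALITY = (0x0020, 0x0062)
_TAG_SAMPLES = (0x0028, 0x0002)
_TAG_PHOTOMETRIC = (0x0028, 0x0004)
_TAG_ROWS = (0x0028, 0x0010)
_TAG_COLS = (0x0028, 0x0011)
_TAG_BITS_ALLOCATED = (0x0028, 0x0100)
_TAG_BITS_STORED = (0x0028, 0x0101)
_TAG_HIGH_BIT = (0x0028, 0x0102)
_TAG_PIXEL_REPR = (0x0028, 0x0103)
_TAG_PIXEL_DATA = (0x7FE0, 0x0010)

# VRs that use the 12-byte (reserved + 32-bit length) explicit header form.
_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}


@dataclass
class MammogramImage:
    """A 2-D grayscale mammogram plus the header fields the pipeline uses.

    ``pixels`` follow the bright = dense convention (MONOCHROME1 sources
    are inverted at read time).  ``bits_stored`` records the native bit
    depth; thresholding operates on the native histogram, never on a
    rescaled 8-bit copy.
    """

    pixels: np.ndarray
    laterality: str
    view_position: str = "MLO"
    photometric_interpretation: str = "MONOCHROME2"
    bits_stored: int = 12
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise FormatError("pixel array must be 2-D and non-empty")
        if np.issubdtype(self.pixels.dtype, np.integer) and self.pixels.min() < 0:
            raise FormatError("pixel values must be nonnegative")
        if self.laterality not in ("L", "R"):
            raise MetadataError(
                f"laterality must be 'L' or 'R', got {self.laterality!r}"
            )

    @property
    def max_gray(self) -> int:
        return (1 << self.bits_stored) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def _normalize_laterality(raw: str) -> str:
    value = raw.strip().upper()
    if value and value[0] in ("L", "R"):
        return value[0]
    raise MetadataError(
        f"Image Laterality (0020,0062) value {raw!r} is not recognizably L or R"
    )


# ---------------------------------------------------------------------------
# low-level element codec
# ---------------------------------------------------------------------------

def _encode_element(tag: tuple[int, int], vr: bytes, value: bytes,
                    explicit: bool) -> bytes:
    if len(value) % 2:
        pad = b"\x00" if vr in _LONG_VRS else b" "
        value += pad
    head = struct.pack("<HH", tag[0], tag[1])
    if explicit:
        if vr in _LONG_VRS:
            return head + vr + b"\x00\x00" + struct.pack("<I", len(value)) + value
        return head + vr + struct.pack("<H", len(value)) + value
    return head + struct.pack("<I", len(value)) + value


def _cs(text: str) -> bytes:
    return text.encode("ascii")


def _us(number: int) -> bytes:
    return struct.pack("<H", number)


def _parse_one(buf: bytes, offset: int, explicit: bool):
    """Decode one element; return (tag, value_bytes, next_offset)."""
    group, elem = struct.unpack_from("<HH", buf, offset)
    offset += 4
    if explicit:
        vr = buf[offset:offset + 2]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", buf, offset + 4)
            offset += 8
        else:
            (length,) = struct.unpack_from("<H", buf, offset + 2)
            offset += 4
    else:
        (length,) = struct.unpack_from("<I", buf, offset)
        offset += 4
    if length == 0xFFFFFFFF or offset + length > len(buf):
        raise FormatError("truncated or undefined-length DICOM element")
    return (group, elem), buf[offset:offset + length], offset + length


def _iter_elements(buf: bytes, offset: int, explicit: bool):
    """Yield (tag, value_bytes) until the buffer is exhausted."""
    while offset + 8 <= len(buf):
        tag, value, offset = _parse_one(buf, offset, explicit)
        yield tag, value


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def write_mammogram(image: MammogramImage, path: str | Path,
                    transfer_syntax: str = EXPLICIT_VR_LE) -> Path:
    """Serialize ``image`` as a minimal part-10 DICOM file.

    MONOCHROME1 images are stored inverted (``max_gray - p``) so that a
    subsequent :func:`read_mammogram` round-trips the in-memory pixels
    bit-exactly.
    """
    if transfer_syntax not in (EXPLICIT_VR_LE, IMPLICIT_VR_LE):
        raise FormatError(f"unsupported transfer syntax {transfer_syntax!r}")
    path = Path(path)
    pixels = np.ascontiguousarray(image.pixels, dtype="<u2")
    if image.photometric_interpretation == "MONOCHROME1":
        pixels = (image.max_gray - pixels).astype("<u2")
    elif image.photometric_interpretation != "MONOCHROME2":
        raise FormatError(
            f"unsupported photometric interpretation "
            f"{image.photometric_interpretation!r}"
        )
    rows, cols = pixels.shape

    meta = b"".join([
        _encode_element((0x0002, 0x0001), b"OB", b"\x00\x01", True),
        _encode_element((0x0002, 0x0002), b"UI",
                        _cs("1.2.840.10008.5.1.4.1.1.1.2"), True),
        _encode_element((0x0002, 0x0003), b"UI",
                        _cs("2.25." + str(abs(hash(image.source_id)) % 10**12)),
                        True),
        _encode_element(_TAG_TRANSFER_SYNTAX, b"UI", _cs(transfer_syntax), True),
    ])
    explicit = transfer_syntax == EXPLICIT_VR_LE
    body = b"".join([
        _encode_element((0x0008, 0x0060), b"CS", _cs("MG"), explicit),
        _encode_element(_TAG_VIEW_POSITION, b"CS", _cs(image.view_position),
                        explicit),
        _encode_element(_TAG_LATERALITY, b"CS", _cs(image.laterality), explicit),
        _encode_element(_TAG_SAMPLES, b"US", _us(1), explicit),
        _encode_element(_TAG_PHOTOMETRIC, b"CS",
                        _cs(image.photometric_interpretation), explicit),
        _encode_element(_TAG_ROWS, b"US", _us(rows), explicit),
        _encode_element(_TAG_COLS, b"US", _us(cols), explicit),
        _encode_element(_TAG_BITS_ALLOCATED, b"US", _us(16), explicit),
        _encode_element(_TAG_BITS_STORED, b"US", _us(image.bits_stored), explicit),
        _encode_element(_TAG_HIGH_BIT, b"US", _us(image.bits_stored - 1),
                        explicit),
        _encode_element(_TAG_PIXEL_REPR, b"US", _us(0), explicit),
        _encode_element(_TAG_PIXEL_DATA, b"OW", pixels.tobytes(), explicit),
    ])
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128)
        fh.write(b"DICM")
        fh.write(_encode_element((0x0002, 0x0000), b"UL",
                                 struct.pack("<I", len(meta)), True))
        fh.write(meta)
        fh.write(body)
    return path


def _read_elements(buf: bytes) -> dict[tuple[int, int], bytes]:
    if len(buf) > 132 and buf[128:132] == b"DICM":
        # file meta group is always explicit VR little endian
        offset = 132
        elements: dict[tuple[int, int], bytes] = {}
        while offset + 8 <= len(buf):
            tag, value, nxt = _parse_one(buf, offset, explicit=True)
            if tag[0] != 0x0002:
                break
            elements[tag] = value
            offset = nxt
        transfer_syntax = EXPLICIT_VR_LE
        if _TAG_TRANSFER_SYNTAX in elements:
            transfer_syntax = elements[_TAG_TRANSFER_SYNTAX].decode(
                "ascii").strip("\x00 ")
        explicit = transfer_syntax != IMPLICIT_VR_LE
        dataset = dict(_iter_elements(buf, offset, explicit=explicit))
        dataset.update(elements)
        return dataset
    # headerless stream: sniff explicit vs implicit from the first VR bytes
    if len(buf) < 8:
        raise FormatError("file too short to be a DICOM stream")
    vr = buf[4:6]
    explicit = vr.isalpha() and vr.isupper()
    return dict(_iter_elements(buf, 0, explicit=explicit))


def read_mammogram(path: str | Path) -> MammogramImage:
    """Read a single-frame MLO mammogram from a DICOM file.

    Raises :class:`MetadataError` when (0018,5101) or (0020,0062) is
    absent, :class:`UnsupportedViewError` for non-MLO views, and
    :class:`FormatError` when no pixel data can be decoded.
    """
    path = Path(path)
    buf = path.read_bytes()
    try:
        elements = _read_elements(buf)
    except (struct.error, ValueError) as exc:
        raise FormatError(f"{path.name}: not parseable as DICOM: {exc}") from exc

    if _TAG_VIEW_POSITION not in elements:
        raise MetadataError(
            f"{path.name}: missing View Position element (0018,5101)")
    if _TAG_LATERALITY not in elements:
        raise MetadataError(
            f"{path.name}: missing Image Laterality element (0020,0062)")
    view = elements[_TAG_VIEW_POSITION].decode("ascii").strip("\x00 ")
    if view.upper() != "MLO":
        raise UnsupportedViewError(
            f"{path.name}: view position {view!r} is not supported; only MLO "
            f"views are analyzed (craniocaudal support is future work)")
    laterality = _normalize_laterality(
        elements[_TAG_LATERALITY].decode("ascii").strip("\x00 "))

    if _TAG_PIXEL_DATA not in elements:
        raise FormatError(f"{path.name}: missing PixelData (7FE0,0010)")
    try:
        rows = struct.unpack("<H", elements[_TAG_ROWS][:2])[0]
        cols = struct.unpack("<H", elements[_TAG_COLS][:2])[0]
        bits_alloc = struct.unpack("<H", elements[_TAG_BITS_ALLOCATED][:2])[0]
    except (KeyError, struct.error) as exc:
        raise FormatError(f"{path.name}: missing image geometry tags") from exc
    bits_stored = bits_alloc
    if _TAG_BITS_STORED in elements:
        bits_stored = struct.unpack("<H", elements[_TAG_BITS_STORED][:2])[0]
    dtype = {8: np.uint8, 16: np.dtype("<u2")}.get(bits_alloc)
    if dtype is None:
        raise FormatError(f"{path.name}: unsupported bit depth {bits_alloc}")
    raw = elements[_TAG_PIXEL_DATA]
    expected = rows * cols * np.dtype(dtype).itemsize
    if len(raw) < expected:
        raise FormatError(f"{path.name}: pixel data shorter than Rows×Columns")
    pixels = np.frombuffer(raw[:expected], dtype=dtype).reshape(rows, cols)

    photometric = "MONOCHROME2"
    if _TAG_PHOTOMETRIC in elements:
        photometric = elements[_TAG_PHOTOMETRIC].decode("ascii").strip("\x00 ")
    max_gray = (1 << bits_stored) - 1
    if photometric == "MONOCHROME1":
        pixels = (max_gray - pixels.astype(np.int64)).astype(dtype)

    return MammogramImage(
        pixels=pixels,
        laterality=laterality,
        view_position="MLO",
        photometric_interpretation=photometric,
        bits_stored=bits_stored,
        source_id=path.stem,
    )


# ---------------------------------------------------------------------------
# result reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = (
    "source_id",
    "threshold_maxentropy",
    "threshold_moments",
    "threshold_final",
    "dense_pixels",
    "roi_pixels",
    "percent_density",
    "birads_category",
)


def write_density_report(results: Sequence, path: str | Path) -> Path:
    """Write per-image density results as a deterministic CSV.

    One row per image, fixed column order, percent density printed with
    two decimal places.
    """
    if not results:
        raise ValueError("results must be non-empty")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(REPORT_COLUMNS)
        for res in results:
            writer.writerow([
                res.source_id,
                res.threshold_maxentropy,
                res.threshold_moments,
                res.threshold_final,
                res.dense_pixels,
                res.roi_pixels,
                f"{res.percent_density:.2f}",
                res.birads_category,
            ])
    return path


def read_density_report(path: str | Path) -> list[dict]:
    """Parse a CSV written by :func:`write_density_report`."""
    rows = []
    with open(path, newline="") as fh:
        for record in csv.DictReader(fh):
            rows.append({
                "source_id": record["source_id"],
                "threshold_maxentropy": float(record["threshold_maxentropy"]),
                "threshold_moments": float(record["threshold_moments"]),
                "threshold_final": float(record["threshold_final"]),
                "dense_pixels": int(record["dense_pixels"]),
                "roi_pixels": int(record["roi_pixels"]),
                "percent_density": float(record["percent_density"]),
                "birads_category": int(record["birads_category"]),
            })
    return rows
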