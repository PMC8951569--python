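"""Minimal DICOM codec for uncompressed grayscale cine acquisitions.

Supports reading Explicit and Implicit VR Little Endian datasets
(single- or multi-frame, MONOCHROME1/MONOCHROME2, 8/16-bit unsigned or
signed pixel data) and writing Explicit VR Little Endian multi-frame
secondary-capture objects.  Compressed transfer syntaxes, sequences with
pixel data inside them, and color images are out of scope.
"""

from __future__ import annotations

import os
import struct
from typing import Any

import numpy as np

from .errors import FormatError

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
IMPLICIT_VR_LE = "1.2.840.10008.1.2"
_SC_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.7"  # secondary capture
_UID_ROOT = "1.2.826.0.1.3680043.10.1462"

# tags we care about, by (group, element)
TAG_TRANSFER_SYNTAX = (0x0002, 0x0010)
TAG_PHOTOMETRIC = (0x0028, 0x0004)
TAG_SAMPLES_PER_PIXEL = (0x0028, 0x0002)
TAG_NUM_FRAMES = (0x0028, 0x0008)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLS = (0x0028, 0x0011)
TAG_BITS_ALLOCATED = (0x0028, 0x0100)
TAG_PIXEL_REPRESENTATION = (0x0028, 0x0103)
TAG_PIXEL_DATA = (0x7FE0, 0x0010)
TAG_INSTANCE_NUMBER = (0x0020, 0x0013)
TAG_CINE_RATE = (0x0018, 0x0040)
TAG_FRAME_TIME = (0x0018, 0x1063)
TAG_IMAGER_PIXEL_SPACING = (0x0018, 0x1164)
TAG_PIXEL_SPACING = (0x0028, 0x0030)

_LONG_VRS = {b"OB", b"OW", b"OF", b"OD", b"OL", b"SQ", b"UC", b"UR", b"UT", b"UN"}
_KNOWN_VRS = _LONG_VRS | {
    b"AE", b"AS", b"AT", b"CS", b"DA", b"DS", b"DT", b"FL", b"FD", b"IS",
    b"LO", b"LT", b"PN", b"SH", b"SL", b"SS", b"ST", b"TM", b"UI", b"UL", b"US",
}


# VRs of the tags we consume, for implicit-VR streams
_TAG_VRS = {
    TAG_SAMPLES_PER_PIXEL: b"US",
    TAG_ROWS: b"US",
    TAG_COLS: b"US",
    TAG_BITS_ALLOCATED: b"US",
    TAG_PIXEL_REPRESENTATION: b"US",
    TAG_NUM_FRAMES: b"IS",
    TAG_INSTANCE_NUMBER: b"IS",
    TAG_CINE_RATE: b"IS",
    TAG_FRAME_TIME: b"DS",
    TAG_PHOTOMETRIC: b"CS",
}


def _parse_elements(
    buf: bytes, offset: int, explicit: bool
) -> dict[tuple[int, int], tuple[bytes, bytes]]:
    """Walk a little-endian dataset, returning (VR, value bytes) per tag."""
    out: dict[tuple[int, int], tuple[bytes, bytes]] = {}
    n = len(buf)
    pos = offset
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", buf, pos)
        pos += 4
        if explicit and group != 0xFFFE:
            vr = buf[pos : pos + 2]
            if vr in _LONG_VRS:
                (length,) = struct.unpack_from("<I", buf, pos + 4)
                pos += 8
            elif vr in _KNOWN_VRS:
                (length,) = struct.unpack_from("<H", buf, pos + 2)
                pos += 4
            else:  # stream is not actually explicit VR
                raise FormatError(f"unknown VR {vr!r} at offset {pos}")
        else:
            vr = b""
            (length,) = struct.unpack_from("<I", buf, pos)
            pos += 4
        if length == 0xFFFFFFFF:
            if (group, elem) == TAG_PIXEL_DATA:
                raise FormatError("encapsulated (compressed) pixel data is not supported")
            # undefined-length sequence: skip to its delimiter
            pos = _skip_undefined(buf, pos)
            continue
        if pos + length > n:
            raise FormatError("truncated DICOM element")
        if not vr:
            vr = _TAG_VRS.get((group, elem), b"")
        out[(group, elem)] = (vr, buf[pos : pos + length])
        pos += length
    return out


def _skip_undefined(buf: bytes, pos: int) -> int:
    depth = 1
    n = len(buf)
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", buf, pos)
        (length,) = struct.unpack_from("<I", buf, pos + 4)
        pos += 8
        if (group, elem) == (0xFFFE, 0xE0DD):
            depth -= 1
            if depth == 0:
                return pos
        elif length == 0xFFFFFFFF:
            depth += 1
        elif (group, elem) != (0xFFFE, 0xE00D):
            pos += length
    raise FormatError("unterminated undefined-length sequence")


def _decode_str(item: tuple[bytes, bytes] | None) -> str | None:
    if item is None:
        return None
    return item[1].decode("ascii", errors="replace").strip("\x00 ").strip()


def _decode_int(item: tuple[bytes, bytes] | None) -> int | None:
    if item is None:
        return None
    vr, raw = item
    if vr in (b"US", b"SS") and len(raw) == 2:
        return struct.unpack("<H" if vr == b"US" else "<h", raw)[0]
    if vr in (b"UL", b"SL") and len(raw) == 4:
        return struct.unpack("<I" if vr == b"UL" else "<i", raw)[0]
    # IS (or unknown VR holding ASCII digits)
    try:
        return int(item[1].decode("ascii").strip("\x00 ") or "")
    except (UnicodeDecodeError, ValueError):
        if len(raw) == 2:
            return struct.unpack("<H", raw)[0]
        if len(raw) == 4:
            return struct.unpack("<I", raw)[0]
        raise FormatError(f"cannot decode integer value {raw!r}") from None


def _decode_floats(item: tuple[bytes, bytes] | None) -> list[float] | None:
    s = _decode_str(item)
    if not s:
        return None
    try:
        return [float(x) for x in s.split("\\")]
    except ValueError:
        return None


class DicomFrameSet:
    """Pixel array plus the handful of attributes the pipeline consumes."""

    def __init__(
        self,
        pixels: np.ndarray,
        photometric: str,
        frame_rate: float | None,
        pixel_spacing: tuple[float, float] | None,
        instance_number: int | None,
    ):
        self.pixels = pixels  # (frames, rows, cols)
        self.photometric = photometric
        self.frame_rate = frame_rate
        self.pixel_spacing = pixel_spacing
        self.instance_number = instance_number


def read_dicom_file(path: str | os.PathLike) -> DicomFrameSet:
    """Parse one DICOM file into a frame stack (frames, rows, cols)."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 8:
        raise FormatError(f"{path}: file too small to be DICOM")

    if len(buf) > 132 and buf[128:132] == b"DICM":
        # file meta group is always explicit VR LE; read it to find syntax
        meta_end, meta = _read_meta(buf, 132)
        syntax = _decode_str(meta.get(TAG_TRANSFER_SYNTAX)) or EXPLICIT_VR_LE
        if syntax == EXPLICIT_VR_LE:
            explicit = True
        elif syntax == IMPLICIT_VR_LE:
            explicit = False
        else:
            raise FormatError(f"{path}: unsupported transfer syntax {syntax}")
        elements = _parse_elements(buf, meta_end, explicit)
    else:
        # raw dataset without preamble; sniff VR style
        try:
            elements = _parse_elements(buf, 0, explicit=True)
        except FormatError:
            elements = _parse_elements(buf, 0, explicit=False)

    samples = _decode_int(elements.get(TAG_SAMPLES_PER_PIXEL)) or 1
    if samples != 1:
        raise FormatError(f"{path}: color/multi-sample images are not supported")
    photometric = _decode_str(elements.get(TAG_PHOTOMETRIC)) or "MONOCHROME2"
    if photometric not in ("MONOCHROME1", "MONOCHROME2"):
        raise FormatError(f"{path}: unsupported photometric interpretation {photometric}")

    rows = _decode_int(elements.get(TAG_ROWS))
    cols = _decode_int(elements.get(TAG_COLS))
    if not rows or not cols:
        raise FormatError(f"{path}: missing Rows/Columns")
    n_frames = _decode_int(elements.get(TAG_NUM_FRAMES)) or 1
    bits = _decode_int(elements.get(TAG_BITS_ALLOCATED)) or 16
    signed = bool(_decode_int(elements.get(TAG_PIXEL_REPRESENTATION)) or 0)
    pix = elements.get(TAG_PIXEL_DATA)
    if pix is None:
        raise FormatError(f"{path}: no PixelData")
    raw = pix[1]
    if bits == 8:
        dtype = np.int8 if signed else np.uint8
    elif bits == 16:
        dtype = np.dtype("<i2") if signed else np.dtype("<u2")
    else:
        raise FormatError(f"{path}: unsupported BitsAllocated {bits}")
    expected = n_frames * rows * cols * (bits // 8)
    if len(raw) < expected:
        raise FormatError(f"{path}: PixelData shorter than expected")
    pixels = np.frombuffer(raw[:expected], dtype=dtype).reshape(n_frames, rows, cols)

    frame_rate = None
    cine_rate = _decode_floats(elements.get(TAG_CINE_RATE))
    frame_time = _decode_floats(elements.get(TAG_FRAME_TIME))
    if cine_rate and cine_rate[0] > 0:
        frame_rate = float(cine_rate[0])
    elif frame_time and frame_time[0] > 0:
        frame_rate = 1000.0 / frame_time[0]

    spacing = None
    for tag in (TAG_IMAGER_PIXEL_SPACING, TAG_PIXEL_SPACING):
        vals = _decode_floats(elements.get(tag))
        if vals and len(vals) == 2:
            spacing = (vals[0], vals[1])
            break

    return DicomFrameSet(
        pixels=pixels,
        photometric=photometric,
        frame_rate=frame_rate,
        pixel_spacing=spacing,
        instance_number=_decode_int(elements.get(TAG_INSTANCE_NUMBER)),
    )


def _read_meta(
    buf: bytes, offset: int
) -> tuple[int, dict[tuple[int, int], tuple[bytes, bytes]]]:
    """Read the group-0002 file meta elements; return (dataset offset, meta)."""
    meta: dict[tuple[int, int], tuple[bytes, bytes]] = {}
    pos = offset
    while pos + 8 <= len(buf):
        group, elem = struct.unpack_from("<HH", buf, pos)
        if group != 0x0002:
            break
        vr = buf[pos + 4 : pos + 6]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", buf, pos + 8)
            value_off = pos + 12
        else:
            (length,) = struct.unpack_from("<H", buf, pos + 6)
            value_off = pos + 8
        meta[(group, elem)] = (vr, buf[value_off : value_off + length])
        pos = value_off + length
    return pos, meta


# ---------------------------------------------------------------------------
# writing


def _elem_short(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr in (b"UI", b"OB") else b" "
    return struct.pack("<HH2sH", group, elem, vr, len(value)) + value


def _elem_long(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00"
    return struct.pack("<HH2sHI", group, elem, vr, 0, len(value)) + value


def write_dicom(
    path: str | os.PathLike,
    pixels: np.ndarray,
    frame_rate: float | None = None,
    pixel_spacing: tuple[float, float] | None = None,
    instance_number: int | None = None,
    photometric: str = "MONOCHROME2",
    series_uid: str | None = None,
) -> None:
    """Write a (frames, rows, cols) or (rows, cols) uint8/uint16 stack.

    Output is a part-10 Explicit VR Little Endian secondary-capture object.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim == 2:
        pixels = pixels[None]
    if pixels.ndim != 3:
        raise ValueError("pixels must be 2-D or 3-D")
    if pixels.dtype == np.uint8:
        bits = 8
    elif pixels.dtype == np.uint16:
        bits = 16
        pixels = pixels.astype("<u2")
    else:
        raise ValueError(f"unsupported dtype {pixels.dtype}; use uint8 or uint16")
    n_frames, rows, cols = pixels.shape

    sop_uid = f"{_UID_ROOT}.{abs(hash((rows, cols, n_frames, instance_number))) % 10**10}"
    series_uid = series_uid or f"{_UID_ROOT}.1"

    def s(v: Any) -> bytes:
        return str(v).encode("ascii")

    meta_body = b"".join(
        [
            _elem_long(0x0002, 0x0001, b"OB", b"\x00\x01"),
            _elem_short(0x0002, 0x0002, b"UI", s(_SC_SOP_CLASS)),
            _elem_short(0x0002, 0x0003, b"UI", s(sop_uid)),
            _elem_short(0x0002, 0x0010, b"UI", s(EXPLICIT_VR_LE)),
            _elem_short(0x0002, 0x0012, b"UI", s(_UID_ROOT + ".0.1")),
        ]
    )
    meta = _elem_short(0x0002, 0x0000, b"UL", struct.pack("<I", len(meta_body))) + meta_body

    ds = [
        _elem_short(0x0008, 0x0016, b"UI", s(_SC_SOP_CLASS)),
        _elem_short(0x0008, 0x0018, b"UI", s(sop_uid)),
        _elem_short(0x0008, 0x0060, b"CS", b"XA"),
        _elem_short(0x0020, 0x000E, b"UI", s(series_uid)),
    ]
    if instance_number is not None:
        ds.append(_elem_short(0x0020, 0x0013, b"IS", s(instance_number)))
    if frame_rate is not None:
        ds.append(_elem_short(0x0018, 0x0040, b"IS", s(int(round(frame_rate)))))
        ds.append(_elem_short(0x0018, 0x1063, b"DS", s(round(1000.0 / frame_rate, 4))))
    if pixel_spacing is not None:
        ds.append(
            _elem_short(0x0018, 0x1164, b"DS", s(pixel_spacing[0]) + b"\\" + s(pixel_spacing[1]))
        )
    ds += [
        _elem_short(0x0028, 0x0002, b"US", struct.pack("<H", 1)),
        _elem_short(0x0028, 0x0004, b"CS", s(photometric)),
        _elem_short(0x0028, 0x0008, b"IS", s(n_frames)),
        _elem_short(0x0028, 0x0010, b"US", struct.pack("<H", rows)),
        _elem_short(0x0028, 0x0011, b"US", struct.pack("<H", cols)),
        _elem_short(0x0028, 0x0100, b"US", struct.pack("<H", bits)),
        _elem_short(0x0028, 0x0101, b"US", struct.pack("<H", bits)),
        _elem_short(0x0028, 0x0102, b"US", struct.pack("<H", bits - 1)),
        _elem_short(0x0028, 0x0103, b"US", struct.pack("<H", 0)),
        _elem_long(0x7FE0, 0x0010, b"OB" if bits == 8 else b"OW", pixels.tobytes()),
    ]

    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM")
        fh.write(meta)
        fh.write(b"".join(ds))
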