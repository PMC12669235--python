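"""Minimal DICOM codec for uncompressed single-frame CT images.

Supports exactly the subset this package needs: Part-10 files with a
128-byte preamble, Explicit VR Little Endian written by :func:`write_file`,
and reading of both Explicit and Implicit VR Little Endian transfer
syntaxes. Sequences, undefined lengths and compressed pixel data are
rejected rather than half-parsed.

The full DICOM standard is deliberately out of scope; a purpose-built codec
keeps the package free of runtime dependencies that are not available in
minimal deployments.
"""

from __future__ import annotations

import struct
import uuid
from typing import Any, BinaryIO

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
IMPLICIT_VR_LE = "1.2.840.10008.1.2"
CT_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.2"

# 4-byte-length VRs in explicit encoding (reserved 2 bytes + uint32 length)
_LONG_VRS = {"OB", "OW", "OF", "OD", "OL", "SQ", "UC", "UR", "UT", "UN"}

# Tag -> (VR, keyword) for everything we read or write.  Used as the VR
# dictionary when decoding Implicit VR Little Endian.
_DICT: dict[tuple[int, int], tuple[str, str]] = {
    (0x0008, 0x0016): ("UI", "SOPClassUID"),
    (0x0008, 0x0018): ("UI", "SOPInstanceUID"),
    (0x0008, 0x0060): ("CS", "Modality"),
    (0x0018, 0x0050): ("DS", "SliceThickness"),
    (0x0018, 0x0060): ("DS", "KVP"),
    (0x0018, 0x1152): ("IS", "Exposure"),
    (0x0018, 0x9332): ("FD", "ExposureInmAs"),
    (0x0020, 0x000D): ("UI", "StudyInstanceUID"),
    (0x0020, 0x000E): ("UI", "SeriesInstanceUID"),
    (0x0020, 0x0013): ("IS", "InstanceNumber"),
    (0x0020, 0x0032): ("DS", "ImagePositionPatient"),
    (0x0020, 0x0037): ("DS", "ImageOrientationPatient"),
    (0x0028, 0x0002): ("US", "SamplesPerPixel"),
    (0x0028, 0x0004): ("CS", "PhotometricInterpretation"),
    (0x0028, 0x0010): ("US", "Rows"),
    (0x0028, 0x0011): ("US", "Columns"),
    (0x0028, 0x0030): ("DS", "PixelSpacing"),
    (0x0028, 0x0100): ("US", "BitsAllocated"),
    (0x0028, 0x0101): ("US", "BitsStored"),
    (0x0028, 0x0102): ("US", "HighBit"),
    (0x0028, 0x0103): ("US", "PixelRepresentation"),
    (0x0028, 0x1052): ("DS", "RescaleIntercept"),
    (0x0028, 0x1053): ("DS", "RescaleSlope"),
    (0x7FE0, 0x0010): ("OW", "PixelData"),
}
_KEYWORD_TO_TAG = {kw: tag for tag, (_, kw) in _DICT.items()}


class DicomError(ValueError):
    """Malformed or unsupported DICOM content."""


def generate_uid() -> str:
    """Random UID under the UUID-derived '2.25' root."""
    return f"2.25.{uuid.uuid4().int}"


# ---------------------------------------------------------------------------
# encoding


def _encode_value(vr: str, value: Any) -> bytes:
    if vr == "US":
        return struct.pack("<H", int(value))
    if vr == "FD":
        if isinstance(value, (list, tuple)):
            return b"".join(struct.pack("<d", float(v)) for v in value)
        return struct.pack("<d", float(value))
    if vr in ("OB", "OW"):
        return bytes(value)
    # string VRs; multi-valued joined by backslash
    if isinstance(value, (list, tuple)):
        text = "\\".join(_format_number(v) if vr in ("DS", "IS") else str(v)
                         for v in value)
    elif vr in ("DS", "IS"):
        text = _format_number(value)
    else:
        text = str(value)
    raw = text.encode("ascii")
    if len(raw) % 2:
        raw += b"\x00" if vr == "UI" else b" "
    return raw


def _format_number(value: Any) -> str:
    if isinstance(value, int):
        return str(value)
    # DS is limited to 16 bytes
    text = repr(float(value))
    if len(text) > 16:
        text = f"{float(value):.10g}"
    return text


def _encode_element(group: int, elem: int, vr: str, value: Any) -> bytes:
    payload = _encode_value(vr, value)
    head = struct.pack("<HH", group, elem) + vr.encode("ascii")
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(payload)) + payload
    if len(payload) > 0xFFFF:
        raise DicomError(f"value too long for short-form VR {vr}")
    return head + struct.pack("<H", len(payload)) + payload


def write_file(path: str, elements: dict[str, Any], pixel_data: bytes) -> None:
    """Write a Part-10 Explicit-VR-LE file.

    ``elements`` maps keywords from the internal dictionary to values;
    ``pixel_data`` is the raw little-endian pixel buffer (OW).
    """
    sop_instance = elements.get("SOPInstanceUID") or generate_uid()
    elements = dict(elements, SOPInstanceUID=sop_instance)
    elements.setdefault("SOPClassUID", CT_IMAGE_STORAGE)

    meta = b"".join(
        _encode_element(0x0002, el, vr, val)
        for el, vr, val in [
            (0x0001, "OB", b"\x00\x01"),
            (0x0002, "UI", elements["SOPClassUID"]),
            (0x0003, "UI", sop_instance),
            (0x0010, "UI", EXPLICIT_VR_LE),
            (0x0012, "UI", "2.25.0.1"),
        ]
    )
    # UL is a short-form VR; encode the group length manually
    group_len = (struct.pack("<HH", 0x0002, 0x0000) + b"UL"
                 + struct.pack("<H", 4) + struct.pack("<I", len(meta)))

    body = []
    for keyword in sorted(elements, key=lambda k: _KEYWORD_TO_TAG[k]):
        (group, elem) = _KEYWORD_TO_TAG[keyword]
        vr = _DICT[(group, elem)][0]
        body.append(_encode_element(group, elem, vr, elements[keyword]))
    body.append(_encode_element(0x7FE0, 0x0010, "OW", pixel_data))

    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128)
        fh.write(b"DICM")
        fh.write(group_len)
        fh.write(meta)
        fh.write(b"".join(body))


# ---------------------------------------------------------------------------
# decoding


def _read_exact(fh: BinaryIO, n: int) -> bytes:
    raw = fh.read(n)
    if len(raw) != n:
        raise DicomError("truncated DICOM stream")
    return raw


def _decode_value(vr: str, raw: bytes) -> Any:
    if vr == "US":
        count = len(raw) // 2
        vals = struct.unpack(f"<{count}H", raw)
        return vals[0] if count == 1 else list(vals)
    if vr == "UL":
        return struct.unpack("<I", raw[:4])[0]
    if vr == "FD":
        count = len(raw) // 8
        vals = struct.unpack(f"<{count}d", raw)
        return vals[0] if count == 1 else list(vals)
    if vr in ("OB", "OW", "UN"):
        return raw
    text = raw.decode("ascii", errors="replace").rstrip(" \x00")
    if vr == "DS":
        parts = [float(p) for p in text.split("\\") if p.strip()]
        return parts[0] if len(parts) == 1 else parts
    if vr == "IS":
        parts = [int(float(p)) for p in text.split("\\") if p.strip()]
        return parts[0] if len(parts) == 1 else parts
    if "\\" in text:
        return text.split("\\")
    return text


def _parse_elements(fh: BinaryIO, explicit: bool, stop_at_group: int | None = None,
                    limit: int | None = None) -> dict[str, Any]:
    out: dict[str, Any] = {}
    start = fh.tell()
    while True:
        if limit is not None and fh.tell() - start >= limit:
            break
        head = fh.read(4)
        if len(head) == 0:
            break
        if len(head) != 4:
            raise DicomError("truncated element header")
        group, elem = struct.unpack("<HH", head)
        if stop_at_group is not None and group != stop_at_group:
            fh.seek(-4, 1)
            break
        if explicit:
            vr = _read_exact(fh, 2).decode("ascii")
            if vr in _LONG_VRS:
                _read_exact(fh, 2)
                length = struct.unpack("<I", _read_exact(fh, 4))[0]
            else:
                length = struct.unpack("<H", _read_exact(fh, 2))[0]
        else:
            vr = _DICT.get((group, elem), ("UN", ""))[0]
            length = struct.unpack("<I", _read_exact(fh, 4))[0]
        if length == 0xFFFFFFFF:
            raise DicomError(
                f"undefined-length element ({group:04X},{elem:04X}) unsupported")
        raw = _read_exact(fh, length)
        entry = _DICT.get((group, elem))
        if entry is None:
            continue  # unrecognised element: skipped
        decoded_vr, keyword = entry
        out[keyword] = _decode_value(decoded_vr if not explicit else vr, raw)
    return out


def read_file(path: str) -> dict[str, Any]:
    """Read a Part-10 file into a keyword->value dict (known tags only)."""
    with open(path, "rb") as fh:
        preamble = fh.read(132)
        if len(preamble) != 132 or preamble[128:132] != b"DICM":
            raise DicomError(f"{path}: not a Part-10 DICOM file")
        # file meta group is always explicit VR LE; first element is the
        # group length, which bounds the remaining meta elements
        head = _read_exact(fh, 8)
        group, elem, vr, length = struct.unpack("<HH2sH", head)
        if (group, elem) != (0x0002, 0x0000) or vr != b"UL":
            raise DicomError(f"{path}: missing file meta group length")
        meta_len = struct.unpack("<I", _read_exact(fh, 4))[0]
        meta = _parse_meta(fh, meta_len)
        ts = meta.get("TransferSyntaxUID", EXPLICIT_VR_LE)
        if ts == EXPLICIT_VR_LE:
            explicit = True
        elif ts == IMPLICIT_VR_LE:
            explicit = False
        else:
            raise DicomError(f"{path}: unsupported transfer syntax {ts}")
        return _parse_elements(fh, explicit=explicit)


def _parse_meta(fh: BinaryIO, meta_len: int) -> dict[str, Any]:
    out: dict[str, Any] = {}
    end = fh.tell() + meta_len
    while fh.tell() < end:
        group, elem = struct.unpack("<HH", _read_exact(fh, 4))
        vr = _read_exact(fh, 2).decode("ascii")
        if vr in _LONG_VRS:
            _read_exact(fh, 2)
            length = struct.unpack("<I", _read_exact(fh, 4))[0]
        else:
            length = struct.unpack("<H", _read_exact(fh, 2))[0]
        raw = _read_exact(fh, length)
        if (group, elem) == (0x0002, 0x0010):
            out["TransferSyntaxUID"] = _decode_value("UI", raw)
    return out
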