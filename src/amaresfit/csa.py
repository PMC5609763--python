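"""Siemens CSA private-header binary codec.

Siemens MR systems store acquisition parameters in a proprietary binary
block inside private DICOM elements (group ``0x0029``, private creator
``SIEMENS CSA HEADER``).  Two dialects exist: CSA2 blocks start with the
magic ``SV10``; anything else is treated as the older CSA1 layout, which
differs only in how item lengths are encoded.  Both store a flat list of
named tags, each with a value-representation code and a list of
null-terminated ASCII items.

:func:`parse_csa` decodes either dialect into ``{name: [values]}`` with
numeric VRs converted; :func:`build_csa2` produces a CSA2 block (used by
the synthetic fixture DICOM writer).  Malformed input raises
:class:`~amaresfit.errors.CsaParseError` carrying the byte offset of the
failure.
"""

from __future__ import annotations

import struct

from .errors import CsaParseError

__all__ = ["parse_csa", "build_csa2", "build_csa1", "csa_scalar"]

_NUMERIC_VR = {
    "FL": float, "FD": float, "DS": float,
    "SS": int, "US": int, "SL": int, "UL": int, "IS": int,
}

_MAX_TAGS = 1000


def _nt_str(raw: bytes) -> str:
    end = raw.find(b"\x00")
    if end != -1:
        raw = raw[:end]
    return raw.decode("latin-1")


def parse_csa(blob: bytes) -> dict[str, list]:
    """Decode a CSA1 or CSA2 block into ``{tag_name: [values]}``.

    The dialect is auto-detected from the ``SV10`` magic.  Values with a
    numeric VR are converted to int/float; everything else stays a string.
    """
    if len(blob) < 8:
        raise CsaParseError("CSA block shorter than its fixed header", offset=0)
    is_csa2 = blob[:4] == b"SV10"
    pos = 8 if is_csa2 else 0

    try:
        n_tags, check = struct.unpack_from("<2I", blob, pos)
    except struct.error:
        raise CsaParseError("truncated CSA tag-count header", offset=pos)
    pos += 8
    if not 0 < n_tags <= _MAX_TAGS:
        raise CsaParseError(f"implausible CSA tag count {n_tags}", offset=pos - 8)

    tags: dict[str, list] = {}
    csa1_len_bias = 0  # CSA1 encodes item lengths biased by tag #1's n_items
    for tag_no in range(n_tags):
        if pos + 84 > len(blob):
            raise CsaParseError(
                f"truncated tag record {tag_no}/{n_tags}", offset=pos)
        name_raw, vm, vr_raw, _syngodt, n_items, _last3 = struct.unpack_from(
            "<64si4s3i", blob, pos)
        pos += 84
        name = _nt_str(name_raw)
        vr = _nt_str(vr_raw).strip()
        if n_items > _MAX_TAGS:
            raise CsaParseError(
                f"implausible item count {n_items} in tag {name!r}",
                offset=pos - 84)
        if tag_no == 1:
            csa1_len_bias = n_items
        converter = _NUMERIC_VR.get(vr)
        n_values = vm if vm != 0 else n_items
        items: list = []
        for item_no in range(n_items):
            if pos + 16 > len(blob):
                raise CsaParseError(
                    f"truncated item header in tag {name!r}", offset=pos)
            x = struct.unpack_from("<4i", blob, pos)
            pos += 16
            item_len = (x[0] - csa1_len_bias) if not is_csa2 else x[1]
            if item_len < 0 or pos + item_len > len(blob):
                raise CsaParseError(
                    f"item {item_no} of tag {name!r} overruns the block "
                    f"(claimed {item_len} bytes)", offset=pos - 16)
            raw = blob[pos:pos + item_len]
            pos += item_len
            pos += (4 - item_len % 4) % 4  # 4-byte alignment
            if item_no >= n_values:
                continue
            text = _nt_str(raw)
            if converter is not None:
                if not text.strip():
                    continue
                try:
                    items.append(converter(text.strip()))
                except ValueError:
                    raise CsaParseError(
                        f"item {item_no} of tag {name!r} is not a valid "
                        f"{vr} value: {text!r}", offset=pos - item_len)
            else:
                items.append(text)
        tags[name] = items
    return tags


def _encode_items(values, vr: str, csa2: bool, len_bias: int = 0) -> tuple[bytes, int]:
    out = b""
    for v in values:
        if isinstance(v, float):
            text = repr(float(v))
        else:
            text = str(v)
        raw = text.encode("latin-1") + b"\x00"
        n = len(raw)
        if csa2:
            head = struct.pack("<4i", n, n, 77, n)
        else:
            head = struct.pack("<4i", n + len_bias, n, 77, n)
        out += head + raw + b"\x00" * ((4 - n % 4) % 4)
    return out, len(values)


def _build(tags: dict[str, tuple[str, list]], csa2: bool) -> bytes:
    names = list(tags)
    # CSA1 item lengths are biased by the n_items of tag index 1
    len_bias = 0
    if not csa2 and len(names) > 1:
        len_bias = len(tags[names[1]][1])
    body = b""
    for tag_no, (name, (vr, values)) in enumerate(tags.items()):
        # the length bias only applies from tag 1 onwards in CSA1 readers
        bias = len_bias if (not csa2 and tag_no >= 1) else 0
        items, n_items = _encode_items(values, vr, csa2, bias)
        body += struct.pack(
            "<64si4s3i", name.encode("latin-1")[:64].ljust(64, b"\x00"),
            len(values), vr.encode("latin-1")[:4].ljust(4, b"\x00"),
            0, n_items, 77)
        body += items
    head = struct.pack("<2I", len(tags), 77)
    if csa2:
        return b"SV10" + b"\x04\x03\x02\x01" + head + body
    return head + body


def build_csa2(tags: dict[str, tuple[str, list]]) -> bytes:
    """Encode ``{name: (vr, [values])}`` as a CSA2 block."""
    return _build(tags, csa2=True)


def build_csa1(tags: dict[str, tuple[str, list]]) -> bytes:
    """Encode ``{name: (vr, [values])}`` as a CSA1 block (for dialect tests)."""
    return _build(tags, csa2=False)


def csa_scalar(tags: dict[str, list], name: str, default=None):
    """First value of a CSA tag, or ``default`` when absent/empty."""
    items = tags.get(name)
    if not items:
        return default
    return items[0]
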