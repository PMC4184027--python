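"""Versioned single-file array container.

Layout: 8-byte magic ``QGMAPC01``, 8-byte little-endian header length, a JSON
header, then the raw little-endian array blobs back to back. The header
records per-array name, dtype, shape, byte count and CRC32, plus free-form
metadata, so loads can verify integrity and version before touching data.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np

MAGIC = b"QGMAPC01"
FORMAT_VERSION = 1


class ContainerError(IOError):
    """Corrupt, truncated or version-incompatible container file."""


def save_container(path: str | Path, kind: str, meta: dict, arrays: dict[str, np.ndarray]) -> None:
    entries = []
    blobs = []
    for name, arr in arrays.items():
        arr = np.ascontiguousarray(arr)
        if arr.dtype.byteorder == ">":
            arr = arr.astype(arr.dtype.newbyteorder("<"))
        blob = arr.tobytes()
        entries.append({
            "name": name,
            "dtype": arr.dtype.str.lstrip("<=|"),
            "shape": list(arr.shape),
            "nbytes": len(blob),
            "crc32": zlib.crc32(blob),
        })
        blobs.append(blob)
    header = json.dumps({
        "format": kind,
        "version": FORMAT_VERSION,
        "meta": meta,
        "arrays": entries,
    }).encode()
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(len(header).to_bytes(8, "little"))
        fh.write(header)
        for blob in blobs:
            fh.write(blob)


def load_container(path: str | Path, kind: str) -> tuple[dict, dict[str, np.ndarray]]:
    with open(path, "rb") as fh:
        magic = fh.read(8)
        if magic != MAGIC:
            raise ContainerError(f"{path}: not a qgmap container (bad magic)")
        hlen = int.from_bytes(fh.read(8), "little")
        try:
            header = json.loads(fh.read(hlen))
        except (ValueError, UnicodeDecodeError) as exc:
            raise ContainerError(f"{path}: corrupt header") from exc
        if header.get("version") != FORMAT_VERSION:
            raise ContainerError(
                f"{path}: container version {header.get('version')} "
                f"not supported (expected {FORMAT_VERSION})"
            )
        if header.get("format") != kind:
            raise ContainerError(
                f"{path}: container holds {header.get('format')!r}, expected {kind!r}"
            )
        arrays: dict[str, np.ndarray] = {}
        for entry in header["arrays"]:
            blob = fh.read(entry["nbytes"])
            if len(blob) != entry["nbytes"]:
                raise ContainerError(f"{path}: truncated file at array {entry['name']!r}")
            if zlib.crc32(blob) != entry["crc32"]:
                raise ContainerError(f"{path}: checksum mismatch for array {entry['name']!r}")
            arr = np.frombuffer(blob, dtype=np.dtype(entry["dtype"]).newbyteorder("<"))
            arrays[entry["name"]] = arr.reshape(entry["shape"]).copy()
    return header["meta"], arrays
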