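"""Minimal NRRD (Nearly Raw Raster Data) reader/writer.

Covers the subset of NRRD used for atlas annotation volumes: attached
headers, ``raw``/``ascii``/``gzip`` encodings, scalar integer or float
types, and per-axis voxel size given either as ``spacings`` or as
diagonal ``space directions``.  Data are stored fastest-axis-first, so
arrays are (de)serialized in Fortran order, matching the convention of
the reference NRRD tooling.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np

_TYPE_MAP = {
    "signed char": np.int8, "int8": np.int8, "int8_t": np.int8,
    "uchar": np.uint8, "unsigned char": np.uint8, "uint8": np.uint8,
    "short": np.int16, "int16": np.int16, "signed short": np.int16,
    "ushort": np.uint16, "uint16": np.uint16, "unsigned short": np.uint16,
    "int": np.int32, "int32": np.int32, "signed int": np.int32,
    "uint": np.uint32, "uint32": np.uint32, "unsigned int": np.uint32,
    "long long": np.int64, "int64": np.int64,
    "unsigned long long": np.uint64, "uint64": np.uint64,
    "float": np.float32, "double": np.float64,
}


def _parse_vector(text: str) -> list[float]:
    return [float(t) for t in text.strip().lstrip("(").rstrip(")").split(",")]


def read(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an NRRD file; return ``(array, header)``.

    The header dict keeps raw field strings plus a parsed
    ``"spacings"`` entry (list of per-axis voxel sizes) when the file
    declares either ``spacings`` or ``space directions``.
    """
    path = Path(path)
    raw = path.read_bytes()
    magic_end = raw.index(b"\n")
    magic = raw[:magic_end].decode("ascii", "replace").strip()
    if not magic.startswith("NRRD"):
        raise ValueError(f"{path}: not an NRRD file (magic {magic!r})")

    header: dict = {}
    pos = magic_end + 1
    while True:
        eol = raw.index(b"\n", pos)
        line = raw[pos:eol].decode("ascii", "replace").rstrip("\r")
        pos = eol + 1
        if line == "":
            break
        if line.startswith("#"):
            continue
        if ":=" in line:
            key, _, val = line.partition(":=")
        else:
            key, _, val = line.partition(":")
        header[key.strip().lower()] = val.strip()

    dim = int(header["dimension"])
    sizes = [int(s) for s in header["sizes"].split()]
    if len(sizes) != dim:
        raise ValueError(f"{path}: sizes {sizes} inconsistent with dimension {dim}")
    dtype = np.dtype(_TYPE_MAP[header["type"]])
    endian = header.get("endian", "little")
    if dtype.itemsize > 1:
        dtype = dtype.newbyteorder("<" if endian == "little" else ">")

    if "spacings" in header:
        header["spacings"] = [float(s) for s in header["spacings"].split()]
    elif "space directions" in header:
        dirs = [_parse_vector(v) for v in header["space directions"].split()
                if v.lower() != "none"]
        header["spacings"] = [float(np.linalg.norm(d)) for d in dirs]

    encoding = header.get("encoding", "raw").lower()
    payload = raw[pos:]
    n = int(np.prod(sizes))
    if encoding == "raw":
        data = np.frombuffer(payload, dtype=dtype, count=n)
    elif encoding in ("gzip", "gz"):
        data = np.frombuffer(gzip.decompress(payload), dtype=dtype, count=n)
    elif encoding in ("ascii", "text", "txt"):
        data = np.array(payload.split(), dtype=dtype)
    else:
        raise ValueError(f"{path}: unsupported NRRD encoding {encoding!r}")
    if data.size != n:
        raise ValueError(f"{path}: expected {n} samples, found {data.size}")
    return data.reshape(sizes, order="F"), header


def write(path: str | Path, array: np.ndarray,
          spacings: list[float] | tuple[float, ...] | None = None,
          encoding: str = "raw") -> None:
    """Write ``array`` as an attached-header NRRD file."""
    array = np.asarray(array)
    inv = {np.dtype(v): k for k, v in reversed(list(_TYPE_MAP.items()))}
    type_name = inv[array.dtype.newbyteorder("=")]
    lines = [
        "NRRD0004",
        f"type: {type_name}",
        f"dimension: {array.ndim}",
        "sizes: " + " ".join(str(s) for s in array.shape),
        f"encoding: {encoding}",
    ]
    if array.dtype.itemsize > 1:
        lines.append("endian: little")
    if spacings is not None:
        lines.append("spacings: " + " ".join(repr(float(s)) for s in spacings))
    header = ("\n".join(lines) + "\n\n").encode("ascii")

    body = array.astype(array.dtype.newbyteorder("<"), copy=False)
    if encoding == "raw":
        payload = body.tobytes(order="F")
    elif encoding in ("gzip", "gz"):
        payload = gzip.compress(body.tobytes(order="F"), mtime=0)
    elif encoding in ("ascii", "text", "txt"):
        payload = " ".join(str(v) for v in body.flatten(order="F")).encode("ascii")
    else:
        raise ValueError(f"unsupported NRRD encoding {encoding!r}")
    Path(path).write_bytes(header + payload)
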