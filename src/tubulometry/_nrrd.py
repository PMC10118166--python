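"""Minimal NRRD (Nearly Raw Raster Data) reader/writer.

Supports the subset of NRRD0004 this package emits and consumes:
3D arrays, `raw` / `gzip` / `ascii` encodings, little/big endian,
spacing carried in `spacings` or diagonal `space directions`.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np

_NRRD_TO_DTYPE = {
    "signed char": "i1", "int8": "i1", "int8_t": "i1",
    "uchar": "u1", "unsigned char": "u1", "uint8": "u1", "uint8_t": "u1",
    "short": "i2", "signed short": "i2", "int16": "i2", "int16_t": "i2",
    "ushort": "u2", "unsigned short": "u2", "uint16": "u2", "uint16_t": "u2",
    "int": "i4", "signed int": "i4", "int32": "i4", "int32_t": "i4",
    "uint": "u4", "unsigned int": "u4", "uint32": "u4", "uint32_t": "u4",
    "longlong": "i8", "int64": "i8", "int64_t": "i8",
    "ulonglong": "u8", "uint64": "u8", "uint64_t": "u8",
    "float": "f4", "double": "f8",
}

_DTYPE_TO_NRRD = {
    "int8": "int8", "uint8": "uint8",
    "int16": "int16", "uint16": "uint16",
    "int32": "int32", "uint32": "uint32",
    "int64": "int64", "uint64": "uint64",
    "float32": "float", "float64": "double",
}


def _parse_vector(text: str) -> list[float]:
    return [float(t) for t in text.strip("() ").replace(",", " ").split()]


def read(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an NRRD file; returns (array, header dict).

    The array is indexed in C order matching the reversed `sizes` field
    (NRRD lists sizes fastest-axis first).
    """
    path = Path(path)
    raw = path.read_bytes()
    end = raw.find(b"\n\n")
    if end < 0:
        raise ValueError(f"{path}: no NRRD header terminator (blank line) found")
    header_text = raw[: end + 1].decode("ascii", errors="replace")
    body = raw[end + 2:]

    lines = header_text.splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise ValueError(f"{path}: not an NRRD file (bad magic {lines[:1]})")
    fields: dict[str, str] = {}
    for line in lines[1:]:
        if not line or line.startswith("#"):
            continue
        if ":=" in line:  # key-value pairs: keep verbatim
            k, v = line.split(":=", 1)
            fields[k.strip().lower()] = v.strip()
            continue
        k, v = line.split(":", 1)
        fields[k.strip().lower()] = v.strip()

    dim = int(fields["dimension"])
    sizes = [int(t) for t in fields["sizes"].split()]
    if len(sizes) != dim:
        raise ValueError(f"{path}: sizes/dimension mismatch")
    kind = fields["type"].lower()
    if kind not in _NRRD_TO_DTYPE:
        raise ValueError(f"{path}: unsupported NRRD type {kind!r}")
    code = _NRRD_TO_DTYPE[kind]
    endian = fields.get("endian", "little")
    dtype = np.dtype(("<" if endian == "little" else ">") + code)

    encoding = fields.get("encoding", "raw").lower()
    count = int(np.prod(sizes))
    if encoding == "raw":
        data = np.frombuffer(body[: count * dtype.itemsize], dtype=dtype)
    elif encoding in ("gzip", "gz"):
        data = np.frombuffer(gzip.decompress(body), dtype=dtype)[:count]
    elif encoding in ("ascii", "text", "txt"):
        data = np.array(body.split(), dtype=dtype.base)[:count]
    else:
        raise ValueError(f"{path}: unsupported NRRD encoding {encoding!r}")
    if data.size != count:
        raise ValueError(f"{path}: truncated data ({data.size} of {count} samples)")
    # NRRD stores fastest axis first; numpy C order is slowest first.
    arr = data.reshape(sizes[::-1])

    header: dict = {"sizes": sizes, "type": kind, "encoding": encoding}
    if "spacings" in fields:
        header["spacings"] = _parse_vector(fields["spacings"])
    if "space directions" in fields:
        vecs = [
            _parse_vector(v)
            for v in fields["space directions"].split(") (")
            if "none" not in v
        ]
        header["spacings"] = [float(np.linalg.norm(v)) for v in vecs]
    if "space origin" in fields:
        header["space origin"] = _parse_vector(fields["space origin"])
    return arr, header


def write(
    path: str | Path,
    array: np.ndarray,
    spacings: "list[float] | None" = None,
    origin: "list[float] | None" = None,
    encoding: str = "gzip",
) -> None:
    """Write a C-ordered array as NRRD; `spacings` in slowest-axis-first order."""
    path = Path(path)
    arr = np.ascontiguousarray(array)
    name = _DTYPE_TO_NRRD.get(arr.dtype.name)
    if name is None:
        raise ValueError(f"cannot write dtype {arr.dtype} as NRRD")
    lines = [
        "NRRD0004",
        "# written by tubulometry",
        f"type: {name}",
        f"dimension: {arr.ndim}",
        f"sizes: {' '.join(str(s) for s in arr.shape[::-1])}",
        f"encoding: {encoding}",
    ]
    if arr.dtype.itemsize > 1:
        lines.append("endian: little")
    if spacings is not None:
        lines.append(f"spacings: {' '.join(repr(float(s)) for s in spacings[::-1])}")
    if origin is not None:
        lines.append(
            "space origin: (" + ",".join(repr(float(o)) for o in origin[::-1]) + ")"
        )
    header = ("\n".join(lines) + "\n\n").encode("ascii")

    le = arr.astype(arr.dtype.newbyteorder("<"), copy=False)
    if encoding == "raw":
        body = le.tobytes()
    elif encoding == "gzip":
        body = gzip.compress(le.tobytes(), compresslevel=1)
    elif encoding == "ascii":
        body = " ".join(str(v) for v in arr.ravel()).encode("ascii")
    else:
        raise ValueError(f"unsupported encoding {encoding!r}")
    path.write_bytes(header + body)
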