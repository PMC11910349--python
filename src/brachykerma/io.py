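"""File formats: raw volumes with sidecar headers, structure sets, doses.

Volumes are stored as little-endian raw binary next to a plain-text
``.hdr`` sidecar carrying ``key value`` lines (shape, voxel size mm,
origin mm, dtype, optional extras).  Masks use the same format with uint8
voxels.  Structure sets use a per-slice polygon text dialect::

    structure <name>
    slice <z_mm>
    x,y
    x,y
    ...

Binary mask export of structures is also supported (one volume per
structure) but the polygon dialect is the interchange format.
"""

from __future__ import annotations

import gzip
import pathlib

import numpy as np

from .dvh import StructureMask
from .errors import InvalidInputError

__all__ = ["write_volume", "read_volume", "write_dose", "read_dose",
           "write_structures", "read_structures"]

_DTYPES = {"float64": np.float64, "float32": np.float32,
           "int16": np.int16, "uint8": np.uint8}


def _hdr_path(path: pathlib.Path) -> pathlib.Path:
    name = path.name
    for suffix in (".raw.gz", ".raw"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".hdr")
    return path.with_suffix(".hdr")


def write_volume(path, volume: np.ndarray, voxel_size, origin,
                 extra: dict | None = None) -> None:
    """Write a 3-D volume as raw binary plus text sidecar header."""
    path = pathlib.Path(path)
    volume = np.ascontiguousarray(volume)
    if volume.ndim != 3:
        raise InvalidInputError("volume must be 3-D")
    dtype = volume.dtype.name
    if dtype not in _DTYPES:
        raise InvalidInputError(f"unsupported dtype {dtype}")
    data = volume.astype("<" + volume.dtype.str[1:]).tobytes()
    if path.name.endswith(".gz"):
        with gzip.open(path, "wb") as fh:
            fh.write(data)
    else:
        path.write_bytes(data)
    lines = [
        f"shape {volume.shape[0]} {volume.shape[1]} {volume.shape[2]}",
        "voxel_size_mm " + " ".join(repr(float(v)) for v in
                                    np.asarray(voxel_size, float)),
        "origin_mm " + " ".join(repr(float(v)) for v in
                                np.asarray(origin, float)),
        f"dtype {dtype}",
        "order C",
    ]
    for k, v in (extra or {}).items():
        lines.append(f"{k} {v}")
    _hdr_path(path).write_text("\n".join(lines) + "\n")


def read_volume(path):
    """Read a raw volume; returns (array, meta dict)."""
    path = pathlib.Path(path)
    hdr = _hdr_path(path)
    meta: dict = {}
    for raw in hdr.read_text().splitlines():
        parts = raw.split()
        if not parts:
            continue
        meta[parts[0]] = parts[1:]
    shape = tuple(int(v) for v in meta.pop("shape"))
    dtype = _DTYPES[meta.pop("dtype")[0]]
    meta.pop("order", None)
    out = {
        "voxel_size": np.array([float(v) for v in
                                meta.pop("voxel_size_mm")]),
        "origin": np.array([float(v) for v in meta.pop("origin_mm")]),
    }
    out.update({k: " ".join(v) for k, v in meta.items()})
    if path.name.endswith(".gz"):
        with gzip.open(path, "rb") as fh:
            data = fh.read()
    else:
        data = path.read_bytes()
    arr = np.frombuffer(data, dtype=np.dtype(dtype).newbyteorder("<"))
    return arr.reshape(shape).astype(dtype), out


def write_dose(path, grid) -> None:
    """Serialize a DoseGrid (dose volume + metadata sidecar)."""
    write_volume(path, grid.dose, grid.voxel_size, grid.origin, extra={
        "scheme": grid.scheme_label,
        "n_histories": grid.n_histories,
        "n_batches": grid.n_batches,
        "seed": grid.seed,
    })


def read_dose(path):
    """Read a serialized dose volume; returns (dose array, meta)."""
    return read_volume(path)


def write_structures(path, structures: dict[str, StructureMask],
                     voxel_size, origin) -> None:
    """Write structures as per-slice polygons (rectangular hull per
    connected row-run would lose shape, so each slice is written as the
    marching-square-free outline of its voxel rows: one rectangle per
    contiguous row run, combined under the even-odd rule at read time)."""
    voxel_size = np.asarray(voxel_size, float)
    origin = np.asarray(origin, float)
    dx, dy, _ = voxel_size
    lines: list[str] = []
    for key, s in structures.items():
        lines.append(f"structure {s.name}")
        mask = s.mask
        for k in range(mask.shape[2]):
            sl = mask[:, :, k]
            if not sl.any():
                continue
            z = origin[2] + k * voxel_size[2]
            for i in range(sl.shape[0]):
                row = sl[i]
                if not row.any():
                    continue
                # contiguous runs of voxels along y -> one thin rectangle
                edges = np.diff(np.concatenate(([0], row.view(np.int8),
                                                [0])))
                starts = np.nonzero(edges == 1)[0]
                stops = np.nonzero(edges == -1)[0]
                x0 = origin[0] + i * dx - 0.49 * dx
                x1 = origin[0] + i * dx + 0.49 * dx
                for j0, j1 in zip(starts, stops):
                    y0 = float(origin[1] + j0 * dy - 0.49 * dy)
                    y1 = float(origin[1] + (j1 - 1) * dy + 0.49 * dy)
                    lines.append(f"slice {float(z)!r}")
                    lines.append(f"{float(x0)!r},{y0!r}")
                    lines.append(f"{float(x1)!r},{y0!r}")
                    lines.append(f"{float(x1)!r},{y1!r}")
                    lines.append(f"{float(x0)!r},{y1!r}")
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


def read_structures(path) -> dict[str, list[tuple[float, np.ndarray]]]:
    """Read a structure set; returns name -> list of (z, polygon)."""
    out: dict[str, list[tuple[float, np.ndarray]]] = {}
    name = None
    z = None
    poly: list[list[float]] = []

    def flush():
        nonlocal poly
        if name is not None and z is not None and len(poly) >= 3:
            out.setdefault(name, []).append((z, np.array(poly)))
        poly = []

    for raw in pathlib.Path(path).read_text().splitlines():
        s = raw.strip()
        if not s:
            continue
        if s.startswith("structure "):
            flush()
            name = s.split(None, 1)[1]
            z = None
        elif s.startswith("slice "):
            flush()
            z = float(s.split()[1])
        else:
            x, y = s.split(",")
            poly.append([float(x), float(y)])
    flush()
    return out
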