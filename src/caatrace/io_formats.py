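"""Volume and SWC input/output.

Coordinate contract used throughout the package:

* In-memory volumes are numpy arrays indexed ``(z, y, x)`` (plane, row,
  column), 0-based.
* SWC files store 0-based voxel-unit coordinates in the order ``x y z``
  (x is the fastest-varying axis of the array).  Multiplying by the voxel
  spacing happens only on an explicit export flag.
"""

from __future__ import annotations

import gzip
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

__all__ = [
    "Volume",
    "SwcRecord",
    "VolumeFormatError",
    "SwcParseError",
    "read_volume",
    "write_volume",
    "read_swc",
    "write_swc",
]

VOLUME_KINDS = ("intensity", "probability", "mask", "labels")


class VolumeFormatError(ValueError):
    """Raised when a volume file cannot be read or violates its kind contract."""


class SwcParseError(ValueError):
    """Raised on malformed SWC input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class Volume:
    """A 3D image block.

    Parameters
    ----------
    values
        Array of shape ``(Z, Y, X)``.
    spacing
        Per-axis voxel size in micrometres, ``(z, y, x)`` order.
    kind
        One of ``intensity``, ``probability``, ``mask``, ``labels``.
        Probability volumes must lie in ``[0, 1]``; label volumes hold
        non-negative integers with 0 meaning background.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    kind: str = "intensity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise VolumeFormatError(
                f"volume must be 3-D with every dimension >= 1, got shape {self.values.shape}"
            )
        if self.kind not in VOLUME_KINDS:
            raise VolumeFormatError(f"unknown volume kind {self.kind!r}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if self.kind == "probability":
            lo, hi = float(self.values.min()), float(self.values.max())
            if lo < 0.0 or hi > 1.0:
                raise VolumeFormatError(
                    f"probability volume out of [0, 1]: range [{lo}, {hi}]"
                )
        if self.kind in ("mask", "labels"):
            if not np.issubdtype(self.values.dtype, np.integer) and not np.issubdtype(
                self.values.dtype, np.bool_
            ):
                raise VolumeFormatError(f"{self.kind} volume must be integer-typed")
            if self.kind == "labels" and self.values.size and self.values.min() < 0:
                raise VolumeFormatError("labels volume must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def astype_kind(self, kind: str) -> "Volume":
        return replace(self, kind=kind)


@dataclass(frozen=True)
class SwcRecord:
    """One line of an SWC morphology file.

    ``x, y, z`` are voxel-unit coordinates (x fastest axis); ``parent_id``
    is -1 for a root and must reference an earlier record otherwise.
    """

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    def __post_init__(self) -> None:
        if self.id < 1:
            raise SwcParseError(f"node id must be positive, got {self.id}")
        if self.radius <= 0:
            raise SwcParseError(f"radius must be positive, got {self.radius}")


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def _kind_from_array(arr: np.ndarray, kind: str | None) -> str:
    if kind is not None:
        return kind
    if arr.dtype == np.bool_:
        return "mask"
    if np.issubdtype(arr.dtype, np.integer):
        return "labels"
    if arr.size and 0.0 <= float(arr.min()) and float(arr.max()) <= 1.0:
        return "probability"
    return "intensity"


def read_volume(path: str | Path, kind: str | None = None) -> Volume:
    """Read a multi-page TIFF or NRRD stack into a ``Volume``.

    A single-page (2-D) image is promoted to shape ``(1, H, W)``.  Values are
    returned untouched — no normalisation.  ``kind`` overrides the dtype-based
    guess.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such volume file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
        spacing = (1.0, 1.0, 1.0)
    elif suffix == ".nrrd":
        arr, spacing = _read_nrrd(path)
    else:
        raise VolumeFormatError(f"unrecognised volume format: {path}")
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[np.newaxis, ...]
    if arr.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 2-D or 3-D stack, got ndim={arr.ndim}")
    if arr.size == 0:
        raise VolumeFormatError(f"{path}: empty stack")
    return Volume(arr, spacing=spacing, kind=_kind_from_array(arr, kind))


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume to multi-page TIFF or NRRD (chosen by suffix).

    Masks and labels are written losslessly as integers (labels as uint32 or
    wider, never truncated to 16 bits); probability and intensity volumes are
    written as 32-bit floats.
    """
    path = Path(path)
    arr = vol.values
    if vol.kind == "mask":
        arr = arr.astype(np.uint8)
    elif vol.kind == "labels":
        arr = arr.astype(np.uint32 if arr.size == 0 or arr.max() < 2**32 else np.uint64)
    else:
        arr = arr.astype(np.float32)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(str(path), arr, photometric="minisblack")
    elif suffix == ".nrrd":
        _write_nrrd(path, arr, vol.spacing)
    else:
        raise VolumeFormatError(f"unrecognised volume format: {path}")


# -- minimal NRRD support (text header + raw/gzip payload) -------------------

_NRRD_TYPES = {
    "uchar": np.uint8, "unsigned char": np.uint8, "uint8": np.uint8,
    "short": np.int16, "int16": np.int16,
    "ushort": np.uint16, "uint16": np.uint16,
    "int": np.int32, "int32": np.int32,
    "uint": np.uint32, "uint32": np.uint32,
    "longlong": np.int64, "int64": np.int64,
    "ulonglong": np.uint64, "uint64": np.uint64,
    "float": np.float32, "double": np.float64,
}


def _read_nrrd(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise VolumeFormatError(f"{path}: not an NRRD file")
        fields: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii", "replace").strip()
            if text.startswith("#") or ":" not in text:
                continue
            key, _, value = text.partition(":")
            fields[key.strip().lower()] = value.lstrip("=").strip()
        payload = fh.read()

    try:
        dtype = np.dtype(_NRRD_TYPES[fields["type"]])
        sizes = [int(s) for s in fields["sizes"].split()]
        encoding = fields.get("encoding", "raw").lower()
        endian = fields.get("endian", "little")
    except KeyError as exc:
        raise VolumeFormatError(f"{path}: missing NRRD header field {exc}") from exc
    if encoding in ("gzip", "gz"):
        payload = gzip.decompress(payload)
    elif encoding == "zlib":
        payload = zlib.decompress(payload)
    elif encoding != "raw":
        raise VolumeFormatError(f"{path}: unsupported NRRD encoding {encoding!r}")
    if endian == "big":
        dtype = dtype.newbyteorder(">")
    arr = np.frombuffer(payload, dtype=dtype)
    expected = int(np.prod(sizes))
    if arr.size != expected:
        raise VolumeFormatError(
            f"{path}: payload has {arr.size} samples, header promises {expected}"
        )
    # NRRD sizes are fastest axis first (x, y, z); our memory order is (z, y, x).
    arr = arr.reshape(sizes[::-1])
    spacing = (1.0, 1.0, 1.0)
    if "spacings" in fields:
        sp = [float(s) for s in fields["spacings"].split()]
        if len(sp) == 3:
            spacing = (sp[2], sp[1], sp[0])
    return np.ascontiguousarray(arr), spacing


def _write_nrrd(path: Path, arr: np.ndarray, spacing: Sequence[float]) -> None:
    dtype_name = {
        np.dtype(np.uint8): "uint8", np.dtype(np.uint16): "uint16",
        np.dtype(np.uint32): "uint32", np.dtype(np.uint64): "uint64",
        np.dtype(np.int16): "int16", np.dtype(np.int32): "int32",
        np.dtype(np.int64): "int64",
        np.dtype(np.float32): "float", np.dtype(np.float64): "double",
    }[arr.dtype]
    sz, sy, sx = arr.shape
    sp = list(spacing)
    header = (
        "NRRD0004\n"
        "# caatrace volume\n"
        f"type: {dtype_name}\n"
        "dimension: 3\n"
        f"sizes: {sx} {sy} {sz}\n"
        f"spacings: {sp[2]} {sp[1]} {sp[0]}\n"
        "encoding: gzip\n"
        "endian: little\n"
        "\n"
    )
    payload = gzip.compress(np.ascontiguousarray(arr).tobytes(), mtime=0)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(payload)


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def read_swc(path: str | Path) -> list[list[SwcRecord]]:
    """Read an SWC file, validating ids, and return one record list per tree.

    Ids must be unique and strictly increasing; a parent must appear before
    its children (forward references are a parse error).  Records are grouped
    into trees by following parent links to each root.
    """
    path = Path(path)
    records: list[SwcRecord] = []
    seen: dict[int, SwcRecord] = {}
    last_id = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split()
            if len(parts) != 7:
                raise SwcParseError(f"expected 7 fields, got {len(parts)}", lineno)
            try:
                nid = int(parts[0])
                tcode = int(parts[1])
                x, y, z, radius = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SwcParseError(f"non-numeric field: {exc}", lineno) from exc
            if nid in seen:
                raise SwcParseError(f"duplicate node id {nid}", lineno)
            if nid <= last_id:
                raise SwcParseError(f"ids must be strictly increasing, got {nid}", lineno)
            if parent != -1 and parent not in seen:
                raise SwcParseError(
                    f"node {nid} references parent {parent} not defined earlier", lineno
                )
            rec = SwcRecord(nid, tcode, x, y, z, radius, parent)
            seen[nid] = rec
            records.append(rec)
            last_id = nid

    # group into trees by root ancestry
    root_of: dict[int, int] = {}
    for rec in records:
        root_of[rec.id] = rec.id if rec.parent_id == -1 else root_of[rec.parent_id]
    trees: dict[int, list[SwcRecord]] = {}
    for rec in records:
        trees.setdefault(root_of[rec.id], []).append(rec)
    return [trees[root] for root in sorted(trees)]


def write_swc(
    trees: Iterable[Sequence[SwcRecord]],
    path: str | Path,
    header: str | None = None,
    spacing: tuple[float, float, float] | None = None,
) -> None:
    """Write trees to SWC, renumbering ids 1..N in depth-first order per tree.

    ``spacing`` (z, y, x voxel size) scales coordinates to physical units on
    request; by default coordinates stay in voxel units.
    """
    lines = ["# SWC written by caatrace"]
    if header:
        for h in header.splitlines():
            lines.append(f"# {h}")
    if spacing is not None:
        lines.append(f"# coordinates scaled by spacing (z,y,x)={spacing}")
    next_id = 1
    for tree in trees:
        by_id = {rec.id: rec for rec in tree}
        children: dict[int, list[int]] = {rec.id: [] for rec in tree}
        roots = []
        for rec in tree:
            if rec.parent_id == -1 or rec.parent_id not in by_id:
                roots.append(rec.id)
            else:
                children[rec.parent_id].append(rec.id)
        if len(roots) != 1:
            raise SwcParseError(f"tree must have exactly one root, found {len(roots)}")
        new_ids: dict[int, int] = {}
        stack = [roots[0]]
        visited: set[int] = set()
        order: list[int] = []
        while stack:
            nid = stack.pop()
            if nid in visited:
                raise SwcParseError("cycle detected in SWC tree")
            visited.add(nid)
            order.append(nid)
            for child in reversed(children[nid]):
                stack.append(child)
        if len(order) != len(tree):
            raise SwcParseError("tree contains nodes unreachable from its root (cycle?)")
        for nid in order:
            new_ids[nid] = next_id
            next_id += 1
        sx, sy, sz = (1.0, 1.0, 1.0)
        if spacing is not None:
            sz, sy, sx = spacing
        for nid in order:
            rec = by_id[nid]
            parent = -1 if rec.parent_id == -1 or rec.parent_id not in by_id else new_ids[rec.parent_id]
            lines.append(
                f"{new_ids[nid]} {rec.type_code} {rec.x * sx:.4f} {rec.y * sy:.4f} "
                f"{rec.z * sz:.4f} {rec.radius:.4f} {parent}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
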