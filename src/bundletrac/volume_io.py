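"""Density-volume and filament-model I/O, and the coordinate convention.

Everything downstream works on a :class:`DensityVolume` whose grid is indexed
``(x, y, z)`` with the bundle axis along ``+y`` and cross-sections in the
``x-z`` plane.  Voxel coordinates are 0-based and continuous: voxel centers
sit at integer coordinates, so a marker at ``x = 3.5`` lies halfway between
the centers of voxels 3 and 4 (sub-voxel tracing accuracy requires this).

Volumes are stored on disk as MRC2014 (the de-facto standard for tomograms);
filament models as CSV (``filament_id,x,y,z`` in voxel units) or as Chimera
CMM marker-set XML, one marker set per filament with consecutive markers
linked.  Densities are oriented so that *higher value = more filament mass*;
maps with dark filaments can be negated on read (``invert=True``).
"""

from __future__ import annotations

import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = [
    "DensityVolume",
    "FilamentTrace",
    "BundleModel",
    "read_volume",
    "write_volume",
    "read_model",
    "write_model",
]

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DensityVolume:
    """A 3D scalar density grid.

    Parameters
    ----------
    data:
        3D array indexed ``(x, y, z)``; the bundle axis is approximately
        the ``+y`` index direction.
    voxel_size_nm:
        Isotropic voxel edge length in nanometres.
    origin_nm:
        Physical position of voxel ``(0, 0, 0)`` in nanometres.
    """

    data: np.ndarray
    voxel_size_nm: float = 1.0
    origin_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"volume must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValidationError(f"all dimensions must be >= 1, got {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float32)
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume contains non-finite values")
        self.voxel_size_nm = float(self.voxel_size_nm)
        if not (self.voxel_size_nm > 0 and np.isfinite(self.voxel_size_nm)):
            raise ValidationError(f"voxel_size_nm must be > 0, got {self.voxel_size_nm}")
        self.origin_nm = np.asarray(self.origin_nm, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class FilamentTrace:
    """Ordered 3D markers of one filament (the balls of a ball-and-stick model).

    Markers are continuous voxel coordinates; their y components must be
    strictly increasing because traces advance along the bundle axis.
    """

    markers: np.ndarray
    id: str

    def __post_init__(self) -> None:
        self.markers = np.asarray(self.markers, dtype=float)
        if self.markers.ndim != 2 or self.markers.shape[1] != 3:
            raise ValidationError(
                f"filament {self.id!r}: markers must be (n, 3), got {self.markers.shape}"
            )
        if len(self.markers) < 2:
            raise ValidationError(f"filament {self.id!r}: needs >= 2 markers")
        dy = np.diff(self.markers[:, 1])
        if not np.all(dy > 0):
            raise ValidationError(
                f"filament {self.id!r}: marker y-coordinates must be strictly increasing"
            )
        self.id = str(self.id)

    def __len__(self) -> int:
        return len(self.markers)


@dataclass
class BundleModel:
    """A set of filament traces plus free-text provenance metadata."""

    traces: list[FilamentTrace]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.id for t in self.traces]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate trace ids: {dupes}")

    def __len__(self) -> int:
        return len(self.traces)

    def ids(self) -> list[str]:
        return [t.id for t in self.traces]

    def get(self, trace_id: str) -> FilamentTrace:
        for t in self.traces:
            if t.id == trace_id:
                return t
        raise KeyError(trace_id)


# ---------------------------------------------------------------------------
# MRC2014 volumes
#
# Layout: 1024-byte header, optional extended header (nsymbt bytes), then the
# data with the mapc axis fastest.  Only the fields the format requires are
# interpreted; everything else is preserved as zeros on write.
# ---------------------------------------------------------------------------

_MRC_MODE_DTYPES = {
    0: np.dtype("<i1"),
    1: np.dtype("<i2"),
    2: np.dtype("<f4"),
    6: np.dtype("<u2"),
}


def read_volume(path: str | Path, invert: bool = False) -> DensityVolume:
    """Read an MRC2014 volume, mapping index order to the (x, y, z) convention.

    The on-disk axis ordering (``mapc``, ``mapr``, ``maps``) is undone so that
    internal axis 1 is the header's Y axis.  ``invert=True`` negates the
    density for maps where filaments are dark.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 1024:
        raise FormatError(f"{path}: file shorter than the 1024-byte MRC header")

    ints = struct.unpack("<10i", raw[0:40])
    nc, nr, ns, mode = ints[0], ints[1], ints[2], ints[3]
    mx, my, mz = struct.unpack("<3i", raw[28:40])
    cella = struct.unpack("<3f", raw[40:52])
    mapc, mapr, maps_ = struct.unpack("<3i", raw[64:76])
    nsymbt = struct.unpack("<i", raw[92:96])[0]
    origin = struct.unpack("<3f", raw[196:208])
    map_tag = raw[208:212]

    if map_tag not in (b"MAP ", b"MAP\x00"):
        raise FormatError(f"{path}: MAP identifier field is {map_tag!r}, not 'MAP '")
    if mode not in _MRC_MODE_DTYPES:
        raise FormatError(f"{path}: unsupported MODE field {mode}")
    if min(nc, nr, ns) < 1:
        raise FormatError(f"{path}: non-positive dimension field NX/NY/NZ = {(nc, nr, ns)}")
    if sorted((mapc, mapr, maps_)) != [1, 2, 3]:
        raise FormatError(
            f"{path}: MAPC/MAPR/MAPS = {(mapc, mapr, maps_)} is not a permutation of 1,2,3"
        )

    dtype = _MRC_MODE_DTYPES[mode]
    n_vox = nc * nr * ns
    need = 1024 + nsymbt + n_vox * dtype.itemsize
    if len(raw) < need:
        raise FormatError(
            f"{path}: truncated data section ({len(raw)} bytes, header implies {need})"
        )
    flat = np.frombuffer(raw, dtype=dtype, count=n_vox, offset=1024 + nsymbt)
    grid = flat.reshape(ns, nr, nc)  # slow-to-fast: maps, mapr, mapc

    # disk axes (0,1,2) carry crystallographic axes (maps_, mapr, mapc);
    # transpose so result axis i holds crystallographic axis i+1 (= x, y, z)
    disk_axis_of = {maps_: 0, mapr: 1, mapc: 2}
    grid = np.transpose(grid, axes=(disk_axis_of[1], disk_axis_of[2], disk_axis_of[3]))
    data = np.ascontiguousarray(grid).astype(np.float32, copy=False)
    if invert:
        data = -data

    m = {1: mx, 2: my, 3: mz}
    sizes = []
    for ax in (1, 2, 3):
        if m[ax] <= 0:
            raise FormatError(f"{path}: non-positive MX/MY/MZ field for axis {ax}")
        sizes.append(cella[ax - 1] / m[ax] / 10.0)  # angstrom -> nm
    if max(sizes) > 0 and (max(sizes) - min(sizes)) > 1e-3 * max(sizes):
        raise FormatError(f"{path}: anisotropic voxel size {sizes} nm not supported")
    voxel = float(np.mean(sizes)) if max(sizes) > 0 else 1.0

    return DensityVolume(
        data=data,
        voxel_size_nm=voxel,
        origin_nm=np.asarray(origin, dtype=float) / 10.0,
    )


def write_volume(vol: DensityVolume, path: str | Path) -> None:
    """Write ``vol`` as MRC2014 mode 2 (float32), axes in x-fastest order."""
    path = Path(path)
    data = np.ascontiguousarray(vol.data.astype(np.float32))
    nx, ny, nz = data.shape
    cella = tuple(float(n * vol.voxel_size_nm * 10.0) for n in (nx, ny, nz))
    dmin, dmax, dmean = float(data.min()), float(data.max()), float(data.mean())
    rms = float(data.std())

    header = bytearray(1024)
    struct.pack_into("<3i", header, 0, nx, ny, nz)  # NX NY NZ (columns=x fastest)
    struct.pack_into("<i", header, 12, 2)  # MODE 2 = float32
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # NXSTART..
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # MX MY MZ
    struct.pack_into("<3f", header, 40, *cella)  # CELLA (angstrom)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # MAPC MAPR MAPS
    struct.pack_into("<3f", header, 76, dmin, dmax, dmean)
    struct.pack_into("<i", header, 88, 1)  # ISPG = 1 (volume)
    struct.pack_into("<i", header, 92, 0)  # NSYMBT
    struct.pack_into("<3f", header, 196, *(float(o * 10.0) for o in vol.origin_nm))
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, rms)
    struct.pack_into("<i", header, 220, 0)  # NLABL

    try:
        with open(path, "wb") as fh:
            fh.write(bytes(header))
            # disk order slow-to-fast = (z, y, x)
            fh.write(np.transpose(data, (2, 1, 0)).tobytes())
    except OSError as exc:
        raise FormatError(f"cannot write volume to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# filament models: CSV and Chimera CMM
# ---------------------------------------------------------------------------


def _model_from_rows(rows: Iterable[tuple[str, float, float, float]], source: str) -> BundleModel:
    by_id: dict[str, list[tuple[float, float, float]]] = {}
    for fid, x, y, z in rows:
        by_id.setdefault(str(fid), []).append((float(x), float(y), float(z)))
    traces = []
    for fid, pts in by_id.items():
        arr = np.asarray(pts, dtype=float)
        dy = np.diff(arr[:, 1])
        if len(arr) < 2 or not np.all(dy > 0):
            raise ValidationError(
                f"{source}: filament {fid!r} has non-monotonic or too few marker "
                "y-coordinates (markers must advance strictly along y)"
            )
        traces.append(FilamentTrace(markers=arr, id=fid))
    return BundleModel(traces=traces, provenance={"source": source})


def read_model(path: str | Path) -> BundleModel:
    """Read a filament model; dialect chosen by extension (.cmm = XML, else CSV)."""
    path = Path(path)
    if path.suffix.lower() == ".cmm":
        return _read_cmm(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error wording varies
        raise FormatError(f"{path}: cannot parse CSV model: {exc}") from exc
    required = {"filament_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: CSV model must have columns {sorted(required)}")
    rows = zip(df["filament_id"].astype(str), df["x"], df["y"], df["z"])
    return _model_from_rows(rows, str(path))


def _read_cmm(path: Path) -> BundleModel:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"{path}: malformed CMM XML: {exc}") from exc
    sets = [root] if root.tag == "marker_set" else list(root.iter("marker_set"))
    if not sets:
        raise FormatError(f"{path}: no <marker_set> elements found")
    rows: list[tuple[str, float, float, float]] = []
    for ms in sets:
        fid = ms.get("name", f"set{len(rows)}")
        for mk in ms.iter("marker"):
            try:
                rows.append((fid, float(mk.get("x")), float(mk.get("y")), float(mk.get("z"))))
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}: marker in set {fid!r} lacks numeric x/y/z") from exc
    return _model_from_rows(rows, str(path))


def write_model(model: BundleModel, path: str | Path) -> None:
    """Write a model as CSV or Chimera CMM depending on the file extension.

    Marker coordinates are voxels (the package-wide convention); CSV carries
    them to full float precision, CMM to 6 significant digits.
    """
    path = Path(path)
    if path.suffix.lower() == ".cmm":
        _write_cmm(model, path)
        return
    recs = []
    for t in model.traces:
        for x, y, z in t.markers:
            recs.append((t.id, x, y, z))
    df = pd.DataFrame(recs, columns=["filament_id", "x", "y", "z"])
    try:
        df.to_csv(path, index=False, float_format="%.9g")
    except OSError as exc:
        raise FormatError(f"cannot write model to {path}: {exc}") from exc


def _write_cmm(model: BundleModel, path: Path) -> None:
    root = ET.Element("marker_sets")
    for t in model.traces:
        ms = ET.SubElement(root, "marker_set", name=t.id)
        for i, (x, y, z) in enumerate(t.markers, start=1):
            ET.SubElement(
                ms, "marker", id=str(i),
                x=f"{x:.6g}", y=f"{y:.6g}", z=f"{z:.6g}", radius="1",
            )
        for i in range(1, len(t.markers)):
            ET.SubElement(ms, "link", id1=str(i), id2=str(i + 1))
    try:
        ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)
    except OSError as exc:
        raise FormatError(f"cannot write model to {path}: {exc}") from exc
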