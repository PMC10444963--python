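"""Minimal MRC/CCP4-2014 volume reader and writer.

Only volume data (3-D scalar grids) are supported.  Data are exchanged as
``numpy`` arrays in ``(z, y, x)`` axis order regardless of the axis
permutation recorded in the file header (``mapc``/``mapr``/``maps``).
Physical metadata (voxel size, origin) use ``(x, y, z)`` component order.

Modes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16) are read; mode 2 is
always written.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

HEADER_SIZE = 1024

_MODE_DTYPES = {
    0: np.dtype("i1"),
    1: np.dtype("<i2"),
    2: np.dtype("<f4"),
    6: np.dtype("<u2"),
}


class MrcFormatError(ValueError):
    """Raised when a file violates the supported subset of the MRC format."""


@dataclass
class MrcVolume:
    data: np.ndarray  # (z, y, x), float32
    voxel_size: np.ndarray  # (x, y, z) in Angstrom
    origin: np.ndarray  # (x, y, z) in Angstrom
    label: str = ""


def _axis_permutation(mapc: int, mapr: int, maps: int) -> tuple[int, int, int]:
    """Return the transpose axes that bring file order (s, r, c) to (z, y, x)."""
    file_axes = (maps, mapr, mapc)  # crystal axis (1=x,2=y,3=z) per array dim
    if sorted(file_axes) != [1, 2, 3]:
        raise MrcFormatError(
            f"invalid axis order fields mapc/mapr/maps = {mapc}/{mapr}/{maps}"
        )
    # target array dims are (z, y, x) == crystal axes (3, 2, 1)
    return tuple(file_axes.index(a) for a in (3, 2, 1))


def read_mrc(path) -> MrcVolume:
    with open(path, "rb") as fh:
        header = fh.read(HEADER_SIZE)
        if len(header) < HEADER_SIZE:
            raise MrcFormatError(f"truncated header in {path!r}")
        (nc, nr, ns, mode) = struct.unpack("<4i", header[0:16])
        (ncstart, nrstart, nsstart) = struct.unpack("<3i", header[16:28])
        (mx, my, mz) = struct.unpack("<3i", header[28:40])
        cella = struct.unpack("<3f", header[40:52])
        (mapc, mapr, maps_) = struct.unpack("<3i", header[64:76])
        nsymbt = struct.unpack("<i", header[92:96])[0]
        origin_field = struct.unpack("<3f", header[196:208])
        nlabl = struct.unpack("<i", header[220:224])[0]
        label = b""
        if 0 < nlabl <= 10:
            label = header[224 : 224 + 80].rstrip(b"\x00 ")

        if mode not in _MODE_DTYPES:
            raise MrcFormatError(f"unsupported MRC mode={mode} in {path!r}")
        if min(nc, nr, ns) <= 0 or min(mx, my, mz) <= 0:
            raise MrcFormatError(
                f"non-positive grid dimensions nc/nr/ns={nc}/{nr}/{ns} in {path!r}"
            )

        fh.seek(HEADER_SIZE + max(nsymbt, 0))
        dtype = _MODE_DTYPES[mode]
        count = nc * nr * ns
        raw = np.fromfile(fh, dtype=dtype, count=count)
        if raw.size != count:
            raise MrcFormatError(f"truncated data block in {path!r}")

    arr = raw.reshape(ns, nr, nc)  # sections, rows, columns
    perm = _axis_permutation(mapc, mapr, maps_)
    data = np.ascontiguousarray(np.transpose(arr, perm)).astype(np.float32)

    voxel = np.array(
        [cella[0] / mx, cella[1] / my, cella[2] / mz], dtype=np.float64
    )
    if np.any(voxel <= 0):
        raise MrcFormatError(f"non-positive voxel size derived from cella in {path!r}")

    if any(abs(v) > 1e-12 for v in origin_field):
        origin = np.array(origin_field, dtype=np.float64)
    else:
        # fall back to the start indices; they count grid steps along the
        # crystal axis mapped to each array dimension
        starts = {mapc: ncstart, mapr: nrstart, maps_: nsstart}
        origin = np.array(
            [starts[1] * voxel[0], starts[2] * voxel[1], starts[3] * voxel[2]],
            dtype=np.float64,
        )

    return MrcVolume(
        data=data,
        voxel_size=voxel,
        origin=origin,
        label=label.decode("ascii", "replace"),
    )


def write_mrc(path, volume: MrcVolume, axis_order: tuple[int, int, int] = (1, 2, 3)) -> None:
    """Write a volume as MRC mode 2.

    ``axis_order`` is the (mapc, mapr, maps) triple to record; the data are
    permuted accordingly so every choice describes the same physical volume.
    """
    data = np.asarray(volume.data, dtype=np.float32)
    if data.ndim != 3:
        raise MrcFormatError(f"expected 3-D data, got shape {data.shape}")
    mapc, mapr, maps_ = axis_order
    if sorted(axis_order) != [1, 2, 3]:
        raise MrcFormatError(f"invalid axis_order {axis_order}")

    # data is (z, y, x) == crystal axes (3, 2, 1); file layout is (s, r, c)
    zyx_pos = {3: 0, 2: 1, 1: 2}  # crystal axis -> dim index in `data`
    perm = (zyx_pos[maps_], zyx_pos[mapr], zyx_pos[mapc])
    file_arr = np.ascontiguousarray(np.transpose(data, perm))

    nz, ny, nx = data.shape
    dims = {1: nx, 2: ny, 3: nz}  # crystal axis -> grid length
    nc, nr, ns = dims[mapc], dims[mapr], dims[maps_]
    vx, vy, vz = (float(v) for v in volume.voxel_size)
    cella = (nx * vx, ny * vy, nz * vz)

    finite = data[np.isfinite(data)]
    dmin = float(finite.min()) if finite.size else 0.0
    dmax = float(finite.max()) if finite.size else 0.0
    dmean = float(finite.mean()) if finite.size else 0.0
    rms = float(finite.std()) if finite.size else 0.0

    header = bytearray(HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nc, nr, ns, 2)
    struct.pack_into("<3i", header, 16, 0, 0, 0)
    struct.pack_into("<3i", header, 28, nx, ny, nz)
    struct.pack_into("<3f", header, 40, *cella)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, mapc, mapr, maps_)
    struct.pack_into("<3f", header, 76, dmin, dmax, dmean)
    struct.pack_into("<2i", header, 88, 1, 0)  # ispg=1 (volume), nsymbt=0
    struct.pack_into("<3f", header, 196, *(float(o) for o in volume.origin))
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian machine stamp
    struct.pack_into("<f", header, 216, rms)
    label = volume.label.encode("ascii", "replace")[:80]
    struct.pack_into("<i", header, 220, 1 if label else 0)
    header[224 : 224 + len(label)] = label

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        file_arr.astype("<f4").tofile(fh)
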