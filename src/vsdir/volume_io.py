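"""Volume I/O: NIfTI / MetaImage / DICOM-series reading, writing, and grid resampling.

All geometry is axis-aligned: a voxel index ``v = (i, j, k)`` maps to the
physical point ``origin + v * spacing`` in millimetres. Oblique orientation
matrices are rejected rather than silently resampled.
"""

from __future__ import annotations

import logging
import os
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import nibabel as nib
from scipy.ndimage import map_coordinates

log = logging.getLogger(__name__)

__all__ = [
    "Volume3D",
    "PointMM",
    "FormatError",
    "read_volume",
    "write_volume",
    "resample_to_grid",
    "physical_to_voxel",
    "voxel_to_physical",
    "read_deformation_field",
    "write_deformation_field",
]


class FormatError(ValueError):
    """Raised when a file does not parse under the named standard."""


@dataclass
class Volume3D:
    """A 3D scalar grid with per-axis spacing and origin in millimetres.

    ``data`` is indexed ``(i, j, k)``; physical coordinates are
    ``origin + index * spacing`` (axis aligned, no oblique orientation).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        if self.spacing.shape != (3,) or not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.origin.shape != (3,) or not np.all(np.isfinite(self.origin)):
            raise ValueError(f"origin must be 3 finite values, got {self.origin}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "Volume3D", atol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def copy_with(self, data: np.ndarray) -> "Volume3D":
        return Volume3D(data=data, spacing=self.spacing.copy(), origin=self.origin.copy())


#: A physical point in mm. Plain ndarray of shape (3,) keeps the arithmetic light.
PointMM = np.ndarray


def as_point(p: Sequence[float]) -> PointMM:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,) or not np.all(np.isfinite(a)):
        raise ValueError(f"point must be 3 finite mm coordinates, got {p!r}")
    return a


def physical_to_voxel(vol: Volume3D, p: PointMM) -> np.ndarray:
    """Continuous voxel index of physical point ``p`` (mm). Inverse of voxel_to_physical."""
    return (np.asarray(p, dtype=float) - vol.origin) / vol.spacing


def voxel_to_physical(vol: Volume3D, v: Sequence[float]) -> PointMM:
    """Physical position (mm) of continuous voxel index ``v``."""
    return vol.origin + np.asarray(v, dtype=float) * vol.spacing


# ---------------------------------------------------------------------------
# NIfTI


def _check_axis_aligned(rot: np.ndarray, what: str) -> None:
    off = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off)) > 1e-3 * max(1.0, np.max(np.abs(rot))):
        raise FormatError(
            f"{what}: oblique orientation matrix not supported (off-diagonal terms {off.max():.3g})"
        )


def _read_nifti(path: Path) -> Volume3D:
    img = nib.load(str(path))
    affine = img.affine
    _check_axis_aligned(affine[:3, :3], f"{path} affine")
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D image, got shape {data.shape}")
    spacing = np.abs(np.diag(affine[:3, :3]))
    if not np.all(spacing > 0):
        raise FormatError(f"{path}: non-positive pixdim {spacing}")
    origin = affine[:3, 3].astype(float)
    # Flip axes stored with negative direction so spacing stays positive.
    for ax in range(3):
        if affine[ax, ax] < 0:
            data = np.flip(data, axis=ax)
            origin[ax] = affine[ax, ax] * (data.shape[ax] - 1) + origin[ax]
    return Volume3D(data=np.ascontiguousarray(data), spacing=spacing, origin=origin)


def _write_nifti(vol: Volume3D, path: Path) -> None:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vol.spacing)
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.data), affine)
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# MetaImage (.mhd + .raw)

_MHD_TYPES = {
    "MET_UCHAR": np.uint8,
    "MET_CHAR": np.int8,
    "MET_USHORT": np.uint16,
    "MET_SHORT": np.int16,
    "MET_UINT": np.uint32,
    "MET_INT": np.int32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_MHD_NAMES = {np.dtype(v): k for k, v in _MHD_TYPES.items()}


def _read_metaimage(path: Path) -> Volume3D:
    header: dict[str, str] = {}
    with open(path, "r") as fh:
        for line in fh:
            if "=" not in line:
                continue
            key, _, value = line.partition("=")
            header[key.strip()] = value.strip()
    for req in ("NDims", "DimSize", "ElementType", "ElementDataFile"):
        if req not in header:
            raise FormatError(f"{path}: missing MetaImage field {req}")
    if header["NDims"] != "3":
        raise FormatError(f"{path}: NDims={header['NDims']}, only 3 supported")
    if header.get("CompressedData", "False").lower() == "true":
        raise FormatError(f"{path}: compressed MetaImage not supported")
    dims = tuple(int(x) for x in header["DimSize"].split())
    etype = header["ElementType"]
    if etype not in _MHD_TYPES:
        raise FormatError(f"{path}: unsupported ElementType {etype}")
    spacing = np.array(
        [float(x) for x in header.get("ElementSpacing", "1 1 1").split()], dtype=float
    )
    origin = np.array([float(x) for x in header.get("Offset", "0 0 0").split()], dtype=float)
    if "TransformMatrix" in header:
        mat = np.array([float(x) for x in header["TransformMatrix"].split()]).reshape(3, 3)
        _check_axis_aligned(mat, f"{path} TransformMatrix")
    raw_path = path.parent / header["ElementDataFile"]
    expected = int(np.prod(dims)) * np.dtype(_MHD_TYPES[etype]).itemsize
    raw = np.fromfile(raw_path, dtype=_MHD_TYPES[etype])
    if raw.nbytes != expected:
        raise FormatError(
            f"{raw_path}: raw size {raw.nbytes} bytes does not match DimSize ({expected} expected)"
        )
    byte_order_msb = header.get("BinaryDataByteOrderMSB", "False").lower() == "true"
    if byte_order_msb:
        raw = raw.byteswap()
    # MetaImage stores x fastest; our (i, j, k) = (x, y, z) index order needs Fortran layout.
    data = raw.reshape(dims[::-1]).transpose(2, 1, 0)
    return Volume3D(data=np.ascontiguousarray(data), spacing=spacing, origin=origin)


def _write_metaimage(vol: Volume3D, path: Path) -> None:
    dtype = np.dtype(vol.data.dtype)
    if dtype not in _MHD_NAMES:
        raise FormatError(f"cannot write dtype {dtype} as MetaImage")
    raw_name = path.with_suffix(".raw").name
    lines = [
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        "CompressedData = False",
        "TransformMatrix = 1 0 0 0 1 0 0 0 1",
        f"Offset = {vol.origin[0]:.10g} {vol.origin[1]:.10g} {vol.origin[2]:.10g}",
        f"ElementSpacing = {vol.spacing[0]:.10g} {vol.spacing[1]:.10g} {vol.spacing[2]:.10g}",
        f"DimSize = {vol.dims[0]} {vol.dims[1]} {vol.dims[2]}",
        f"ElementType = {_MHD_NAMES[dtype]}",
        f"ElementDataFile = {raw_name}",
    ]
    tmp_hdr = path.with_suffix(path.suffix + ".tmp")
    tmp_raw = (path.parent / raw_name).with_suffix(".raw.tmp")
    try:
        with open(tmp_raw, "wb") as fh:
            vol.data.transpose(2, 1, 0).astype(dtype).tofile(fh)
        with open(tmp_hdr, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        os.replace(tmp_raw, path.parent / raw_name)
        os.replace(tmp_hdr, path)
    finally:
        for tmp in (tmp_hdr, tmp_raw):
            if tmp.exists():
                tmp.unlink()


# ---------------------------------------------------------------------------
# DICOM series (read only).
#
# Minimal explicit-VR little-endian parser: no general-purpose DICOM library is
# available in this environment, and only uncompressed axial CT/CBCT exports
# need to be read. Anything else is rejected with a FormatError.

_EXPLICIT_LE = "1.2.840.10008.1.2.1"
_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}

_TAG_ROWS = (0x0028, 0x0010)
_TAG_COLS = (0x0028, 0x0011)
_TAG_BITS_ALLOC = (0x0028, 0x0100)
_TAG_PIXEL_REP = (0x0028, 0x0103)
_TAG_SPACING = (0x0028, 0x0030)
_TAG_POSITION = (0x0020, 0x0032)
_TAG_ORIENTATION = (0x0020, 0x0037)
_TAG_SLOPE = (0x0028, 0x1053)
_TAG_INTERCEPT = (0x0028, 0x1052)
_TAG_PIXELDATA = (0x7FE0, 0x0010)


def _parse_dicom_file(path: Path) -> dict:
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 132 or blob[128:132] != b"DICM":
        raise FormatError(f"{path}: missing DICM magic")
    pos = 132
    elements: dict[tuple[int, int], bytes] = {}
    transfer_syntax = None
    n = len(blob)
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", blob, pos)
        vr = blob[pos + 4 : pos + 6]
        if vr.isalpha() and vr.isupper():
            if vr in _LONG_VRS:
                (length,) = struct.unpack_from("<I", blob, pos + 8)
                value_at = pos + 12
            else:
                (length,) = struct.unpack_from("<H", blob, pos + 6)
                value_at = pos + 8
        else:  # implicit VR inside the dataset is rejected below via transfer syntax
            (length,) = struct.unpack_from("<I", blob, pos + 4)
            value_at = pos + 8
            vr = b"UN"
        if length == 0xFFFFFFFF:
            raise FormatError(f"{path}: undefined-length element {group:04x},{elem:04x}")
        value = blob[value_at : value_at + length]
        tag = (group, elem)
        elements[tag] = value
        if tag == (0x0002, 0x0010):
            transfer_syntax = value.decode("ascii").strip("\x00 ")
        pos = value_at + length
    if transfer_syntax is not None and transfer_syntax != _EXPLICIT_LE:
        raise FormatError(f"{path}: transfer syntax {transfer_syntax} not supported")
    return elements


def _ds_floats(elements: dict, tag: tuple[int, int], default=None) -> np.ndarray | None:
    if tag not in elements:
        return default
    text = elements[tag].decode("ascii").strip("\x00 ")
    return np.array([float(x) for x in text.split("\\")])


def _ds_int(elements: dict, tag: tuple[int, int]) -> int:
    raw = elements[tag]
    return int.from_bytes(raw[:2], "little")


def _read_dicom_series(directory: Path) -> Volume3D:
    files = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix.lower() != ".txt")
    if not files:
        raise FormatError(f"{directory}: no files in DICOM series directory")
    slices = []
    for f in files:
        el = _parse_dicom_file(f)
        for tag, name in [
            (_TAG_ROWS, "Rows"),
            (_TAG_COLS, "Columns"),
            (_TAG_POSITION, "ImagePositionPatient"),
            (_TAG_SPACING, "PixelSpacing"),
            (_TAG_PIXELDATA, "PixelData"),
        ]:
            if tag not in el:
                raise FormatError(f"{f}: missing required DICOM field {name}")
        orient = _ds_floats(el, _TAG_ORIENTATION, np.array([1, 0, 0, 0, 1, 0], float))
        if not np.allclose(orient, [1, 0, 0, 0, 1, 0], atol=1e-3):
            raise FormatError(f"{f}: oblique ImageOrientationPatient {orient} not supported")
        rows = _ds_int(el, _TAG_ROWS)
        cols = _ds_int(el, _TAG_COLS)
        bits = _ds_int(el, _TAG_BITS_ALLOC) if _TAG_BITS_ALLOC in el else 16
        signed = (_ds_int(el, _TAG_PIXEL_REP) if _TAG_PIXEL_REP in el else 0) == 1
        if bits != 16:
            raise FormatError(f"{f}: BitsAllocated={bits} not supported")
        dtype = np.int16 if signed else np.uint16
        pix = np.frombuffer(el[_TAG_PIXELDATA], dtype=dtype)
        if pix.size != rows * cols:
            raise FormatError(f"{f}: PixelData size mismatch ({pix.size} vs {rows * cols})")
        # DICOM rows advance along y, columns along x.
        plane = pix.reshape(rows, cols).T.astype(np.float64)
        slope = _ds_floats(el, _TAG_SLOPE, np.array([1.0]))[0]
        intercept = _ds_floats(el, _TAG_INTERCEPT, np.array([0.0]))[0]
        plane = plane * slope + intercept
        position = _ds_floats(el, _TAG_POSITION)
        spacing_rc = _ds_floats(el, _TAG_SPACING)  # row spacing (y), column spacing (x)
        slices.append(
            {"z": position[2], "pos": position, "plane": plane, "spacing_xy": spacing_rc[::-1]}
        )
    slices.sort(key=lambda s: s["z"])
    xy = slices[0]["spacing_xy"]
    for s in slices[1:]:
        if not np.allclose(s["spacing_xy"], xy, atol=1e-6):
            raise FormatError(f"{directory}: mixed in-plane PixelSpacing across series")
    if len(slices) > 1:
        dz = np.diff([s["z"] for s in slices])
        if dz.min() <= 0 or not np.allclose(dz, dz[0], atol=1e-3):
            raise FormatError(f"{directory}: non-uniform slice positions {dz}")
        z_spacing = float(dz[0])
    else:
        z_spacing = 1.0
    data = np.stack([s["plane"] for s in slices], axis=2)
    if np.allclose(data, np.round(data)):
        data = data.astype(np.int32)
    spacing = np.array([xy[0], xy[1], z_spacing], dtype=float)
    origin = np.array(slices[0]["pos"], dtype=float)
    return Volume3D(data=np.ascontiguousarray(data), spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------


def _guess_format(path: Path) -> str:
    name = str(path)
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".mhd"):
        return "metaimage"
    if path.is_dir():
        return "dicom_series"
    raise FormatError(f"cannot infer format of {path}; pass format explicitly")


def read_volume(path: str | Path, format: str | None = None) -> Volume3D:
    """Read a 3D volume from NIfTI, MetaImage, or a DICOM series directory."""
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "nifti":
        vol = _read_nifti(path)
    elif fmt == "metaimage":
        vol = _read_metaimage(path)
    elif fmt == "dicom_series":
        vol = _read_dicom_series(path)
    else:
        raise FormatError(f"unsupported read format {fmt!r}")
    log.info("read %s [%s]: dims=%s spacing=%s", path, fmt, vol.dims, vol.spacing)
    return vol


def write_volume(vol: Volume3D, path: str | Path, format: str | None = None) -> None:
    """Write a volume as NIfTI or MetaImage (DICOM writing is not supported)."""
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "nifti":
        _write_nifti(vol, path)
    elif fmt == "metaimage":
        _write_metaimage(vol, path)
    else:
        raise FormatError(f"unsupported write format {fmt!r}")
    log.info("wrote %s [%s]: dims=%s spacing=%s", path, fmt, vol.dims, vol.spacing)


def resample_to_grid(
    moving: Volume3D, target: Volume3D, fill: float = 0.0, origin_offset: Sequence[float] | None = None
) -> Volume3D:
    """Trilinearly resample ``moving`` onto ``target``'s grid; outside voxels get ``fill``.

    ``origin_offset`` (mm) shifts the moving volume before resampling, for data
    sources whose frame alignment is not encoded in the headers.
    """
    if moving.same_grid(target) and origin_offset is None:
        return moving.copy_with(moving.data.copy())
    idx = np.indices(target.dims, dtype=float)
    phys = target.origin[:, None, None, None] + idx * target.spacing[:, None, None, None]
    if origin_offset is not None:
        phys = phys - np.asarray(origin_offset, dtype=float)[:, None, None, None]
    vox = (phys - moving.origin[:, None, None, None]) / moving.spacing[:, None, None, None]
    out = map_coordinates(
        moving.data.astype(float), vox, order=1, mode="constant", cval=fill, prefilter=False
    )
    return Volume3D(data=out, spacing=target.spacing.copy(), origin=target.origin.copy())


# ---------------------------------------------------------------------------
# Deformation fields as 3-component vector NIfTI on the reference grid.


def write_deformation_field(displacement: np.ndarray, grid: Volume3D, path: str | Path) -> None:
    """Store per-voxel mm displacement vectors (shape dims + (3,)) as vector NIfTI."""
    if displacement.shape != grid.dims + (3,):
        raise ValueError(
            f"displacement shape {displacement.shape} does not match grid {grid.dims}"
        )
    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = grid.origin
    nib.save(nib.Nifti1Image(displacement.astype(np.float64), affine), str(path))


def read_deformation_field(path: str | Path) -> tuple[np.ndarray, Volume3D]:
    img = nib.load(str(path))
    _check_axis_aligned(img.affine[:3, :3], f"{path} affine")
    disp = np.asanyarray(img.dataobj).astype(np.float64)
    if disp.ndim != 4 or disp.shape[3] != 3:
        raise FormatError(f"{path}: expected 3-vector field, got shape {disp.shape}")
    spacing = np.abs(np.diag(img.affine[:3, :3]))
    grid = Volume3D(
        data=np.zeros(disp.shape[:3], dtype=np.uint8),
        spacing=spacing,
        origin=img.affine[:3, 3].astype(float),
    )
    return disp, grid
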