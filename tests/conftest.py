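import struct

import numpy as np
import pytest

from vsdir.phantom import PhantomSpec, make_pair
from vsdir.subdivision import ParameterSet
from vsdir.volume_io import Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_volume(rng):
    data = rng.normal(100.0, 30.0, size=(16, 12, 10))
    return Volume3D(data=data, spacing=np.array([1.0, 1.5, 2.0]), origin=np.array([-5.0, 3.0, 0.0]))


def small_params() -> ParameterSet:
    """Coarse settings for fast tests on small phantoms."""
    return ParameterSet(
        min_subvolume_size=(8, 8, 4),
        simplex_max_iterations=60,
        name="small",
    )


@pytest.fixture(scope="session")
def small_pair():
    spec = PhantomSpec(
        dims=(32, 32, 16), spacing=(2.0, 2.0, 3.0), seed=3,
        deform_amplitude=3.0, rigid_translation=(2.0, -1.0, 0.0), n_structures=6,
    )
    return make_pair(spec)


# ---------------------------------------------------------------------------
# Minimal explicit-VR little-endian DICOM slice writer (test fixtures only).


def _dcm_element(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b" " if vr in (b"DS", b"UI", b"CS", b"LO") else b"\x00"
    if vr in (b"OB", b"OW"):
        return struct.pack("<HH2sHI", group, elem, vr, 0, len(value)) + value
    return struct.pack("<HH2sH", group, elem, vr, len(value)) + value


def write_dicom_slice(
    path,
    pixels: np.ndarray,
    position=(0.0, 0.0, 0.0),
    pixel_spacing=(1.0, 1.0),
    slope: float = 1.0,
    intercept: float = 0.0,
) -> None:
    """pixels indexed (x, y); stored per DICOM as rows (y) x columns (x), int16."""
    pixels = np.asarray(pixels)
    cols, rows = pixels.shape
    body = b""
    body += _dcm_element(0x0002, 0x0010, b"UI", b"1.2.840.10008.1.2.1")
    pos = "\\".join(f"{v:g}" for v in position).encode()
    body += _dcm_element(0x0020, 0x0032, b"DS", pos)
    body += _dcm_element(0x0020, 0x0037, b"DS", b"1\\0\\0\\0\\1\\0")
    body += _dcm_element(0x0028, 0x0010, b"US", struct.pack("<H", rows))
    body += _dcm_element(0x0028, 0x0011, b"US", struct.pack("<H", cols))
    spacing = f"{pixel_spacing[1]:g}\\{pixel_spacing[0]:g}".encode()  # row\col
    body += _dcm_element(0x0028, 0x0030, b"DS", spacing)
    body += _dcm_element(0x0028, 0x0100, b"US", struct.pack("<H", 16))
    body += _dcm_element(0x0028, 0x0103, b"US", struct.pack("<H", 1))
    body += _dcm_element(0x0028, 0x1052, b"DS", f"{intercept:g}".encode())
    body += _dcm_element(0x0028, 0x1053, b"DS", f"{slope:g}".encode())
    body += _dcm_element(0x7FE0, 0x0010, b"OW", pixels.T.astype("<i2").tobytes())
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM" + body)
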