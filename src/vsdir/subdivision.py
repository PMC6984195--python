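"""Hierarchical octree volume subdivision with per-subvolume rigid refinement.

The reference volume is split level by level (8 children per node, or 4 while
the z-subdivision rate defers splitting along z). Each new leaf refines its
parent's rigid transform by MI-driven registration, under a displacement cap
that grows with subvolume size and the flexibility parameter so image folding
cannot occur. The finest level yields a regular grid of rigid transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable

import numpy as np

from . import similarity
from .preprocess import WindowLevel
from .rigid import (
    RegistrationResult,
    RigidTransform,
    SimplexSettings,
    apply_transform,
    identity_transform,
    region_center,
    rigid_register,
)
from .volume_io import Volume3D

__all__ = [
    "SubvolumeNode",
    "ParameterSet",
    "LeafTransformGrid",
    "subdivide",
    "max_displacement_bound",
    "hierarchical_register",
]

#: Fraction of the smallest subvolume extent allowed as displacement at
#: flexibility 1.0; encodes the topology-preservation cap.
DISP_FRACTION = 0.4


@dataclass
class SubvolumeNode:
    """Octree node over the reference voxel grid.

    ``bounds`` are half-open index ranges per axis; ``transform`` is the node's
    cumulative rigid transform in physical mm; ``grid_index`` locates the node
    in the regular grid of its level.
    """

    level: int
    bounds: tuple[slice, slice, slice]
    transform: RigidTransform
    grid_index: tuple[int, int, int] = (0, 0, 0)
    children: list["SubvolumeNode"] = field(default_factory=list)
    result: RegistrationResult | None = None

    @property
    def extents(self) -> np.ndarray:
        return np.array([s.stop - s.start for s in self.bounds], dtype=int)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> Iterable["SubvolumeNode"]:
        if self.is_leaf():
            yield self
        else:
            for c in self.children:
                yield from c.leaves()


@dataclass
class ParameterSet:
    """The four tunables (window/level, minimum subvolume size, flexibility,
    z-subdivision rate) plus solver settings; the unit of the parameter sweep."""

    ref_window: WindowLevel = field(default_factory=lambda: WindowLevel(0.0, 1000.0))
    flt_window: WindowLevel = field(default_factory=lambda: WindowLevel(-1000.0, 1000.0))
    min_subvolume_size: tuple[int, int, int] = (16, 16, 8)
    flexibility: float = 1.0
    z_rate: int = 0
    smoothing: bool = True
    n_bins_global: int = similarity.N_BINS_GLOBAL
    n_bins_subvolume: int = similarity.N_BINS_SUBVOLUME
    simplex_tolerance: float = 1e-4
    simplex_max_iterations: int = 150
    initial_step_mm: float = 2.0
    initial_step_deg: float = 2.0
    global_max_disp: float = 50.0
    stride: int = 1
    name: str = "default"

    def __post_init__(self) -> None:
        if self.flexibility <= 0:
            raise ValueError("flexibility must be positive")
        if self.z_rate < 0:
            raise ValueError("z_rate must be >= 0")
        if any(m < 2 for m in self.min_subvolume_size):
            raise ValueError("min_subvolume_size must be >= 2 per axis")

    # flat key=value config round-trip -------------------------------------

    def to_config(self, path: str | Path) -> None:
        kv = {
            "name": self.name,
            "ref_window_min": self.ref_window.wmin,
            "ref_window_max": self.ref_window.wmax,
            "flt_window_min": self.flt_window.wmin,
            "flt_window_max": self.flt_window.wmax,
            "min_subvolume_x": self.min_subvolume_size[0],
            "min_subvolume_y": self.min_subvolume_size[1],
            "min_subvolume_z": self.min_subvolume_size[2],
            "flexibility": self.flexibility,
            "z_rate": self.z_rate,
            "smoothing": int(self.smoothing),
            "n_bins_global": self.n_bins_global,
            "n_bins_subvolume": self.n_bins_subvolume,
            "simplex_tolerance": self.simplex_tolerance,
            "simplex_max_iterations": self.simplex_max_iterations,
            "initial_step_mm": self.initial_step_mm,
            "initial_step_deg": self.initial_step_deg,
            "global_max_disp": self.global_max_disp,
            "stride": self.stride,
        }
        Path(path).write_text("".join(f"{k} = {v}\n" for k, v in kv.items()))

    @classmethod
    def from_config(cls, path: str | Path) -> "ParameterSet":
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        return cls(
            name=kv.get("name", "config"),
            ref_window=WindowLevel(float(kv["ref_window_min"]), float(kv["ref_window_max"])),
            flt_window=WindowLevel(float(kv["flt_window_min"]), float(kv["flt_window_max"])),
            min_subvolume_size=(
                int(kv["min_subvolume_x"]),
                int(kv["min_subvolume_y"]),
                int(kv["min_subvolume_z"]),
            ),
            flexibility=float(kv["flexibility"]),
            z_rate=int(kv["z_rate"]),
            smoothing=bool(int(kv.get("smoothing", "1"))),
            n_bins_global=int(kv.get("n_bins_global", similarity.N_BINS_GLOBAL)),
            n_bins_subvolume=int(kv.get("n_bins_subvolume", similarity.N_BINS_SUBVOLUME)),
            simplex_tolerance=float(kv.get("simplex_tolerance", "1e-4")),
            simplex_max_iterations=int(kv.get("simplex_max_iterations", "150")),
            initial_step_mm=float(kv.get("initial_step_mm", "2.0")),
            initial_step_deg=float(kv.get("initial_step_deg", "2.0")),
            global_max_disp=float(kv.get("global_max_disp", "50.0")),
            stride=int(kv.get("stride", "1")),
        )


def _split_axis(s: slice) -> tuple[slice, slice]:
    mid = s.start + (s.stop - s.start) // 2
    return slice(s.start, mid), slice(mid, s.stop)


def can_subdivide(node: SubvolumeNode, params: ParameterSet) -> bool:
    split_z = node.level >= params.z_rate
    for axis in range(3):
        if axis == 2 and not split_z:
            continue
        lo, _ = _split_axis(node.bounds[axis])
        hi_len = (node.bounds[axis].stop - node.bounds[axis].start) - (lo.stop - lo.start)
        if min(lo.stop - lo.start, hi_len) < params.min_subvolume_size[axis]:
            return False
    return True


def subdivide(node: SubvolumeNode, params: ParameterSet) -> list[SubvolumeNode]:
    """Split a leaf into 8 children (4 while level < z_rate: no z split).

    Odd extents split at the floor midpoint. Children inherit the parent's
    transform. Returns an empty list if any child would fall below the minimum
    subvolume size on any axis.
    """
    if not node.is_leaf():
        raise ValueError("subdivide called on a non-leaf node")
    if not can_subdivide(node, params):
        return []
    split_z = node.level >= params.z_rate
    halves = [_split_axis(node.bounds[0]), _split_axis(node.bounds[1])]
    halves.append(_split_axis(node.bounds[2]) if split_z else (node.bounds[2],))
    gx, gy, gz = node.grid_index
    children = []
    for iz, sz in enumerate(halves[2]):
        for iy, sy in enumerate(halves[1]):
            for ix, sx in enumerate(halves[0]):
                children.append(
                    SubvolumeNode(
                        level=node.level + 1,
                        bounds=(sx, sy, sz),
                        transform=node.transform,
                        grid_index=(
                            2 * gx + ix,
                            2 * gy + iy,
                            2 * gz + iz if split_z else gz,
                        ),
                    )
                )
    node.children = children
    return children


def max_displacement_bound(node: SubvolumeNode, flexibility: float, spacing: np.ndarray) -> float:
    """Displacement cap in mm: flexibility x DISP_FRACTION x smallest physical extent."""
    if flexibility <= 0:
        raise ValueError("flexibility must be positive")
    physical = node.extents * np.asarray(spacing, dtype=float)
    return float(flexibility * DISP_FRACTION * physical.min())


@dataclass
class LeafTransformGrid:
    """Regular 3D grid of finest-level rigid transforms with their region centers."""

    centers: np.ndarray  # (nx, ny, nz, 3) physical mm
    transforms: np.ndarray  # (nx, ny, nz) object array of RigidTransform
    shape: tuple[int, int, int]


def _collect_leaf_grid(root: SubvolumeNode, ref: Volume3D) -> LeafTransformGrid:
    leaves = list(root.leaves())
    idx = np.array([lf.grid_index for lf in leaves], dtype=int)
    shape = tuple(idx.max(axis=0) + 1)
    if len(leaves) != int(np.prod(shape)):
        raise ValueError(f"leaf grid incomplete: {len(leaves)} leaves for shape {shape}")
    centers = np.zeros(shape + (3,))
    transforms = np.empty(shape, dtype=object)
    for lf in leaves:
        centers[lf.grid_index] = region_center(ref, lf.bounds)
        transforms[lf.grid_index] = lf.transform
    return LeafTransformGrid(centers=centers, transforms=transforms, shape=shape)


def hierarchical_register(
    ref: Volume3D,
    flt: Volume3D,
    params: ParameterSet,
    map_fn: Callable = map,
    skip_global: bool = False,
) -> tuple[SubvolumeNode, LeafTransformGrid]:
    """Global rigid stage followed by level-by-level subdivision and refinement.

    Inputs must be preprocessed (windowed to [0, 255], smoothed) and share a
    grid. At each level every current leaf is split and each child refined by
    rigid registration initialized from its parent, with the displacement of
    its center capped by ``max_displacement_bound``. Subdivision stops when any
    leaf can no longer split (keeping the finest level a complete regular
    grid). Leaves within a level are independent: ``map_fn`` may evaluate them
    concurrently with identical results.
    """
    if ref.dims != flt.dims:
        raise ValueError(f"reference and floating grids differ: {ref.dims} vs {flt.dims}")
    whole = tuple(slice(0, d) for d in ref.dims)
    root = SubvolumeNode(level=0, bounds=whole, transform=identity_transform())

    settings = SimplexSettings(
        tolerance=params.simplex_tolerance, max_iterations=params.simplex_max_iterations
    )
    if not skip_global:
        res = rigid_register(
            ref,
            flt,
            whole,
            init=root.transform,
            max_disp=params.global_max_disp,
            settings=replace(
                settings,
                initial_step=np.array([params.initial_step_mm] * 3 + [params.initial_step_deg] * 3),
            ),
            n_bins=params.n_bins_global,
            stride=params.stride,
        )
        root.transform, root.result = res.transform, res

    frontier = [root]
    while all(can_subdivide(n, params) for n in frontier):
        children: list[SubvolumeNode] = []
        for node in frontier:
            children.extend(subdivide(node, params))
        level = children[0].level
        step_scale = 0.5**level
        child_settings = replace(
            settings,
            initial_step=np.array(
                [params.initial_step_mm * step_scale] * 3
                + [params.initial_step_deg * step_scale] * 3
            ),
        )

        def refine(node: SubvolumeNode) -> RegistrationResult:
            cap = max_displacement_bound(node, params.flexibility, ref.spacing)
            return rigid_register(
                ref,
                flt,
                node.bounds,
                init=node.transform,
                max_disp=cap,
                settings=child_settings,
                n_bins=None,
                stride=params.stride,
                max_rotation_deg=20.0 * step_scale,
            )

        for node, res in zip(children, map_fn(refine, children)):
            node.transform, node.result = res.transform, res
        frontier = children

    return root, _collect_leaf_grid(root, ref)


def check_displacement_constraints(root: SubvolumeNode, ref: Volume3D, params: ParameterSet) -> float:
    """Largest violation (mm, negative if all satisfied) of the per-leaf cap on
    center displacement relative to the parent's prediction."""
    worst = -np.inf

    def visit(node: SubvolumeNode) -> None:
        nonlocal worst
        for child in node.children:
            c = region_center(ref, child.bounds)
            moved = apply_transform(child.transform, c)
            predicted = apply_transform(node.transform, c)
            cap = max_displacement_bound(child, params.flexibility, ref.spacing)
            worst = max(worst, float(np.linalg.norm(moved - predicted)) - cap)
            visit(child)

    visit(root)
    return worst
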