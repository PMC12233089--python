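"""Voxel-lattice geometry.

The lattice is described by :class:`GridSpec`: a *central* region of
``dims`` voxels per axis at a fixed ``resolution`` (Å per voxel), plus a
symmetric *buffer* of ``buffer_voxels`` padding voxels per side per axis.
Feature kernels have finite reach (a Gaussian truncation cutoff or an
observer's receptive-field radius); computing on the enlarged, buffered
lattice and returning only the central crop guarantees the returned values
are free of edge-truncation artifacts.

Conventions (fixed and relied upon throughout the package):

* grid points are voxel **centers**: the center of central-region voxel
  ``(i, j, k)`` is ``origin + (index + 0.5) * resolution``;
* indices are 0-based, axis order is ``(x, y, z)``;
* ``origin`` is the lower corner of the central region, in Å.

The same formula applied on the padded lattice after shifting indices by
``buffer_voxels`` yields identical center coordinates, so padded and
central evaluations agree exactly on the overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["GridSpec", "VoxelGrid", "build_grid", "crop_center"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a buffered voxel lattice.

    Parameters
    ----------
    dims
        Voxels per axis of the central region, ``(nx, ny, nz)``; each >= 1.
        Non-cubic lattices are allowed.
    resolution
        Edge length of one voxel in Å; > 0.
    origin
        Lower corner of the central region in Å.
    buffer_voxels
        Padding voxels added per side per axis; >= 0.
    """

    dims: tuple[int, int, int]
    resolution: float
    origin: tuple[float, float, float]
    buffer_voxels: int = 0

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise InvalidArgumentError(f"dims must be three integers >= 1, got {self.dims}")
        if not (self.resolution > 0):
            raise InvalidArgumentError(f"resolution must be > 0, got {self.resolution}")
        if int(self.buffer_voxels) < 0:
            raise InvalidArgumentError(f"buffer_voxels must be >= 0, got {self.buffer_voxels}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "resolution", float(self.resolution))
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "buffer_voxels", int(self.buffer_voxels))

    @property
    def padded_dims(self) -> tuple[int, int, int]:
        b = 2 * self.buffer_voxels
        return (self.dims[0] + b, self.dims[1] + b, self.dims[2] + b)

    @property
    def padded_origin(self) -> tuple[float, float, float]:
        shift = self.buffer_voxels * self.resolution
        return tuple(o - shift for o in self.origin)

    @property
    def pad_distance(self) -> float:
        """Physical width of the buffer in Å (reach the buffer covers)."""
        return self.buffer_voxels * self.resolution

    def box_bounds(self, padded: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """``(lower, upper)`` corners of the central (or padded) box in Å."""
        origin = np.asarray(self.padded_origin if padded else self.origin, dtype=float)
        dims = np.asarray(self.padded_dims if padded else self.dims, dtype=float)
        return origin, origin + dims * self.resolution

    def centers(self, padded: bool = False) -> np.ndarray:
        """Voxel-center coordinates, shape ``dims + (3,)`` (C order, xyz)."""
        dims = self.padded_dims if padded else self.dims
        origin = np.asarray(self.padded_origin if padded else self.origin, dtype=float)
        axes = [origin[a] + (np.arange(dims[a]) + 0.5) * self.resolution for a in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)


@dataclass
class VoxelGrid:
    """One 3D property lattice over the central region (buffer cropped).

    ``values`` has shape ``spec.dims`` exactly and must be finite
    everywhere; ``channel_tag`` names the property/feature it holds.
    """

    spec: GridSpec
    values: np.ndarray
    channel_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.dims:
            raise InvalidArgumentError(
                f"values shape {self.values.shape} != central dims {self.spec.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("VoxelGrid values must be finite")


def build_grid(
    center: tuple[float, float, float],
    dims: tuple[int, int, int],
    resolution: float,
    pad_distance: float = 0.0,
) -> GridSpec:
    """Build a buffered :class:`GridSpec` centered at ``center``.

    The buffer is sized as ``ceil(pad_distance / resolution)`` voxels per
    side, the smallest padding whose physical width covers ``pad_distance``
    (typically the kernel cutoff or receptive-field radius), so the padded
    lattice fully contains the central box plus ``pad_distance`` on every
    side.
    """
    if pad_distance < 0:
        raise InvalidArgumentError(f"pad_distance must be >= 0, got {pad_distance}")
    if not (resolution > 0):
        raise InvalidArgumentError(f"resolution must be > 0, got {resolution}")
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or any(d < 1 for d in dims):
        raise InvalidArgumentError(f"dims must be three integers >= 1, got {dims}")
    center = np.asarray(center, dtype=float)
    origin = center - np.asarray(dims, dtype=float) * resolution / 2.0
    buffer_voxels = int(math.ceil(pad_distance / resolution - 1e-12)) if pad_distance > 0 else 0
    # guard against float fuzz making the buffer one voxel short
    while buffer_voxels * resolution < pad_distance - 1e-12:
        buffer_voxels += 1
    return GridSpec(
        dims=dims,
        resolution=float(resolution),
        origin=tuple(origin),
        buffer_voxels=buffer_voxels,
    )


def crop_center(padded_values: np.ndarray, spec: GridSpec, channel_tag: str = "") -> VoxelGrid:
    """Extract the central ``spec.dims`` block from a padded-lattice array.

    Pure index arithmetic — no value is recomputed.
    """
    padded_values = np.asarray(padded_values)
    if padded_values.shape != spec.padded_dims:
        raise InvalidArgumentError(
            f"padded array shape {padded_values.shape} != padded dims {spec.padded_dims}"
        )
    b = spec.buffer_voxels
    if b == 0:
        central = padded_values
    else:
        central = padded_values[b:-b, b:-b, b:-b]
    return VoxelGrid(spec=spec, values=np.array(central, dtype=float), channel_tag=channel_tag)
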