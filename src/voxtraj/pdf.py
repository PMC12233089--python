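"""Property-density flow (PDF) dynamic features.

Each frame of a slice is voxelized onto the *same* lattice (the grid is
anchored once per slice), so every voxel carries a time series of length
W of a rasterized property.  An aggregation function reduces each voxel's
series to a scalar, yielding one 3D grid per slice — floor(T/W) grids per
trajectory of length T.

Built-in aggregators: ``mean``, ``std`` (sample standard deviation,
denominator W-1; 0 for W=1), ``sum``, ``min``, ``max``, ``median``, and
``slope`` (least-squares slope of value against frame index; 0 for W=1).
User aggregators register through :func:`register_aggregator`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import InvalidArgumentError
from .grid import GridSpec, VoxelGrid
from .properties import AtomPropertyTable, cache_properties
from .trajectory import FrameSlice
from .voxelize import VoxelizeParams, voxelize_frame

__all__ = [
    "VoxelSeries",
    "Aggregator",
    "register_aggregator",
    "aggregator_names",
    "voxelize_slice",
    "aggregate_series",
    "pdf_feature",
]


@dataclass
class VoxelSeries:
    """Per-voxel time series over a frame slice.

    ``values`` is indexed ``(t, i, j, k)`` with ``t`` running over the W
    frames of the slice; each time-slab is a valid central-region grid.
    """

    spec: GridSpec
    values: np.ndarray
    channel_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4 or self.values.shape[1:] != self.spec.dims:
            raise InvalidArgumentError(
                f"series shape {self.values.shape} incompatible with dims {self.spec.dims}"
            )
        if self.values.shape[0] < 1:
            raise InvalidArgumentError("series must contain at least one time slab")

    @property
    def window(self) -> int:
        return self.values.shape[0]


def _std(values: np.ndarray) -> np.ndarray:
    if values.shape[0] == 1:
        return np.zeros(values.shape[1:], dtype=float)
    out = np.std(values, axis=0, ddof=1)
    # a constant series has exactly zero variance; mask rounding residue
    constant = values.max(axis=0) == values.min(axis=0)
    out[constant] = 0.0
    return out


def _slope(values: np.ndarray) -> np.ndarray:
    """Least-squares slope of each voxel's series against frame index."""
    w = values.shape[0]
    if w == 1:
        return np.zeros(values.shape[1:], dtype=float)
    t = np.arange(w, dtype=float)
    t_centered = t - t.mean()
    denom = np.sum(t_centered**2)
    v_centered = values - values.mean(axis=0, keepdims=True)
    return np.tensordot(t_centered, v_centered, axes=(0, 0)) / denom


_AGGREGATORS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "mean": lambda v: np.mean(v, axis=0),
    "std": _std,
    "sum": lambda v: np.sum(v, axis=0),
    "min": lambda v: np.min(v, axis=0),
    "max": lambda v: np.max(v, axis=0),
    "median": lambda v: np.median(v, axis=0),
    "slope": _slope,
}


def register_aggregator(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register a reduction ``fn(values with time on axis 0) -> grid``."""
    _AGGREGATORS[name] = fn


def aggregator_names() -> list[str]:
    return sorted(_AGGREGATORS)


@dataclass(frozen=True)
class Aggregator:
    """A named time-window reduction.

    Every built-in aggregator is defined for a length-1 series
    (``std`` and ``slope`` return 0 by convention).
    """

    name: str

    def __post_init__(self) -> None:
        if self.name not in _AGGREGATORS:
            raise InvalidArgumentError(
                f"unknown aggregator {self.name!r}; valid: {aggregator_names()}"
            )

    def reduce(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(_AGGREGATORS[self.name](values), dtype=float)


def _as_aggregator(agg: "Aggregator | str") -> Aggregator:
    return agg if isinstance(agg, Aggregator) else Aggregator(str(agg))


def voxelize_slice(
    slice_: FrameSlice,
    channel_name: str,
    spec: GridSpec,
    params: VoxelizeParams = VoxelizeParams(),
    *,
    table: "AtomPropertyTable | None" = None,
    require_buffer: bool = True,
) -> VoxelSeries:
    """Voxelize every frame of a slice onto the shared lattice.

    Time-slab ``t`` equals a static voxelization of frame ``t`` with
    identical spec/params; the property table is cached once from the
    slice topology.
    """
    if table is None:
        table = cache_properties(slice_.topology)
    weights = table.channel(channel_name)
    slabs = [
        voxelize_frame(f, weights, spec, params, require_buffer=require_buffer).values
        for f in slice_.frames
    ]
    return VoxelSeries(spec=spec, values=np.stack(slabs, axis=0), channel_tag=channel_name)


def aggregate_series(series, agg: "Aggregator | str") -> VoxelGrid:
    """Reduce a per-voxel time series elementwise along t.

    Accepts a :class:`VoxelSeries` (or any object with ``spec``,
    ``values`` 4D, ``channel_tag``).  The output's ``channel_tag`` is
    ``"<input tag>.<aggregator>"``.
    """
    agg = _as_aggregator(agg)
    reduced = agg.reduce(series.values)
    tag = f"{series.channel_tag}.{agg.name}" if series.channel_tag else agg.name
    return VoxelGrid(spec=series.spec, values=reduced, channel_tag=tag)


def pdf_feature(
    slice_: FrameSlice,
    channel_name: str,
    spec: GridSpec,
    params: VoxelizeParams = VoxelizeParams(),
    agg: "Aggregator | str" = "mean",
    *,
    table: "AtomPropertyTable | None" = None,
    require_buffer: bool = True,
) -> VoxelGrid:
    """Property-density flow: voxelize each frame, then aggregate over time."""
    series = voxelize_slice(
        slice_, channel_name, spec, params, table=table, require_buffer=require_buffer
    )
    return aggregate_series(series, agg)
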