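"""Marching-observer (OBS) dynamic features.

Every grid point acts as an *observer*: each frame it perceives the atoms
inside its receptive field (a sphere of given ``radius``) and computes an
observable from their positions and weights — with no adjustment for
molecular topology, so outputs depend only on positions and weights.
Perception uses a hard distance cutoff, so observables jump discretely
when an atom crosses the field boundary.  Per-frame observations are then
aggregated over the slice's time window exactly as for property-density
flow.

Built-in observables, over the in-field atom set A(g) of observer g:

``existence``           1 if any atom with nonzero weight is in field
``direct_count``        number of in-field atoms with nonzero weight
                        (index/annotation channels thereby act as masks;
                        the ``uniform`` channel counts all atoms)
``distinct_count``      number of distinct nonzero weight values in field
                        (meant for index-like integer channels; not
                        meaningful for continuous channels)
``mean_distance``       sum_a w_a d_a / sum_a w_a over A (0 if sum w = 0)
``radius_of_gyration``  sqrt(sum_a w_a ||p_a - pbar||^2 / sum_a w_a) with
                        pbar the w-weighted centroid of A (0 if sum w = 0)

The zero-weight-sum guard returns 0 rather than propagating a non-finite
value.  Custom observables register with :func:`register_observable`.

The grid buffer must cover the receptive-field radius; observations are
computed on the padded lattice and cropped, like static voxelization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ConfigurationError, InvalidArgumentError
from .grid import GridSpec, VoxelGrid, crop_center
from .pdf import Aggregator, aggregate_series
from .properties import AtomPropertyTable, cache_properties
from .trajectory import Frame, FrameSlice

__all__ = [
    "ObserverParams",
    "ObservationSeries",
    "observe_frame",
    "obs_feature",
    "register_observable",
    "observable_names",
]

_CHUNK = 2048


# -- vectorized built-in observables ---------------------------------------
# Each receives, for a chunk of observers: dist (chunk x atoms), in-field
# mask (chunk x atoms, bool), weights (atoms,), positions (atoms, 3) and
# returns (chunk,) values.


def _obs_existence(dist, mask, weights, positions):
    nz = mask & (weights != 0.0)
    return nz.any(axis=1).astype(float)


def _obs_direct_count(dist, mask, weights, positions):
    nz = mask & (weights != 0.0)
    return nz.sum(axis=1).astype(float)


def _obs_distinct_count(dist, mask, weights, positions):
    nz = mask & (weights != 0.0)
    out = np.zeros(mask.shape[0], dtype=float)
    for i in np.flatnonzero(nz.any(axis=1)):
        out[i] = float(np.unique(weights[nz[i]]).size)
    return out


def _obs_mean_distance(dist, mask, weights, positions):
    wmask = np.where(mask, weights[None, :], 0.0)
    wsum = wmask.sum(axis=1)
    num = (wmask * dist).sum(axis=1)
    return np.divide(num, wsum, out=np.zeros_like(num), where=wsum != 0.0)


def _obs_radius_of_gyration(dist, mask, weights, positions):
    # centered second moment: rg^2 = sum_a w_a ||p_a - pbar||^2 / sum_a w_a;
    # computed from explicit deviations (not a difference of raw moments,
    # which loses precision for tight clusters far from the origin)
    wmask = np.where(mask, weights[None, :], 0.0)
    wsum = wmask.sum(axis=1)
    safe = np.where(wsum != 0.0, wsum, 1.0)
    centroid = (wmask @ positions) / safe[:, None]
    deviations = positions[None, :, :] - centroid[:, None, :]
    rg2 = np.einsum("ca,cad->c", wmask, deviations**2) / safe
    rg2 = np.where(wsum != 0.0, np.maximum(rg2, 0.0), 0.0)
    return np.sqrt(rg2)


_VECTOR_OBSERVABLES: dict[str, Callable] = {
    "existence": _obs_existence,
    "direct_count": _obs_direct_count,
    "distinct_count": _obs_distinct_count,
    "mean_distance": _obs_mean_distance,
    "radius_of_gyration": _obs_radius_of_gyration,
}
#: user-registered scalar observables: fn(positions_in_field, weights_in_field,
#: observer_point) -> float
_SCALAR_OBSERVABLES: dict[str, Callable] = {}


def register_observable(
    name: str, fn: Callable[[np.ndarray, np.ndarray, np.ndarray], float]
) -> None:
    """Register a custom observable.

    ``fn(positions, weights, observer_point)`` receives only the in-field
    atoms' positions/weights plus the observer coordinates and returns a
    scalar; it is evaluated observer by observer.
    """
    _SCALAR_OBSERVABLES[name] = fn


def observable_names() -> list[str]:
    return sorted(set(_VECTOR_OBSERVABLES) | set(_SCALAR_OBSERVABLES))


@dataclass(frozen=True)
class ObserverParams:
    """Receptive-field cutoff, observable, and the weight channel it reads.

    The default radius of 2.5 Å matches the default voxelization cutoff.
    """

    radius: float = 2.5
    observable: str = "direct_count"
    weight_channel: str = "uniform"

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise InvalidArgumentError(f"radius must be > 0, got {self.radius}")
        if self.observable not in _VECTOR_OBSERVABLES and self.observable not in _SCALAR_OBSERVABLES:
            raise InvalidArgumentError(
                f"unknown observable {self.observable!r}; valid: {observable_names()}"
            )


@dataclass
class ObservationSeries:
    """Per-observer, per-frame observation values, indexed ``(t, i, j, k)``."""

    spec: GridSpec
    values: np.ndarray
    channel_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4 or self.values.shape[1:] != self.spec.dims:
            raise InvalidArgumentError(
                f"series shape {self.values.shape} incompatible with dims {self.spec.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("observations must be finite")

    @property
    def window(self) -> int:
        return self.values.shape[0]


def observe_frame(
    frame: "Frame | np.ndarray",
    weights: np.ndarray,
    spec: GridSpec,
    obs: ObserverParams = ObserverParams(),
    *,
    require_buffer: bool = True,
) -> np.ndarray:
    """One frame of observations; returns the central-region 3D array.

    Computed for every padded-lattice observer, then cropped, so central
    observers never sit against a truncated neighborhood.
    """
    coords = frame.coordinates if isinstance(frame, Frame) else np.asarray(frame, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (coords.shape[0],):
        raise InvalidArgumentError(
            f"weights length {weights.shape} != atom count {coords.shape[0]}"
        )
    if require_buffer and spec.pad_distance < obs.radius - 1e-9:
        raise ConfigurationError(
            f"grid buffer ({spec.pad_distance:g} Å) is smaller than the receptive-field "
            f"radius ({obs.radius:g} Å); enlarge pad_distance or set require_buffer=False."
        )

    from .voxelize import _cull_to_reach

    coords, weights = _cull_to_reach(coords, weights, spec, obs.radius)
    pdims = spec.padded_dims
    n_voxels = pdims[0] * pdims[1] * pdims[2]
    out = np.zeros(n_voxels, dtype=float)
    if coords.shape[0] > 0:
        centers = spec.centers(padded=True).reshape(-1, 3)
        vector_fn = _VECTOR_OBSERVABLES.get(obs.observable)
        for start in range(0, n_voxels, _CHUNK):
            block = centers[start : start + _CHUNK]
            diff = block[:, None, :] - coords[None, :, :]
            dist = np.sqrt(np.einsum("van,van->va", diff, diff))
            mask = dist <= obs.radius
            if vector_fn is not None:
                out[start : start + block.shape[0]] = vector_fn(dist, mask, weights, coords)
            else:
                fn = _SCALAR_OBSERVABLES[obs.observable]
                for i in range(block.shape[0]):
                    sel = mask[i]
                    out[start + i] = float(fn(coords[sel], weights[sel], block[i]))
    return crop_center(out.reshape(pdims), spec).values


def obs_feature(
    slice_: FrameSlice,
    obs: ObserverParams,
    spec: GridSpec,
    agg: "Aggregator | str" = "mean",
    *,
    table: "AtomPropertyTable | None" = None,
    require_buffer: bool = True,
) -> VoxelGrid:
    """Marching-observer feature: observe every frame, aggregate over time.

    The output ``channel_tag`` is
    ``"<weight channel>.<observable>.<aggregator>"``.
    """
    if table is None:
        table = cache_properties(slice_.topology)
    weights = table.channel(obs.weight_channel)
    slabs = [
        observe_frame(f, weights, spec, obs, require_buffer=require_buffer)
        for f in slice_.frames
    ]
    series = ObservationSeries(
        spec=spec,
        values=np.stack(slabs, axis=0),
        channel_tag=f"{obs.weight_channel}.{obs.observable}",
    )
    return aggregate_series(series, agg)
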