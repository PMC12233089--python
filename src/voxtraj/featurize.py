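"""Run orchestration: feature registration, the per-slice pipeline, and
HDF output.

A run is described by a :class:`RunManifest` — ordered trajectories, a
focus expression, the lattice geometry, the registered
:class:`FeatureRequest` list, labels, and the output path.  Re-running an
identical manifest reproduces identical dataset contents.

The lifecycle per feature mirrors hook/cache/query/run/dump:

1. **hook** — every request is validated and bound to the run up front;
   the single lattice buffer is sized to the maximum reach (cutoff or
   receptive-field radius) over *all* registered features;
2. **cache** — property channels are computed once per queried topology;
3. **query** — each slice is reduced to the focus atoms plus anything
   inside the padded box;
4. **run** — the feature implementations produce one grid (or scalar)
   per slice;
5. **dump** — records append to the per-tag HDF datasets in canonical
   ``(trajectory order, slice order)`` order.

Grid anchoring: per slice, the lattice center is the geometric centroid
of the focus atoms in the slice's *first* frame, then held fixed for all
W frames (dynamic features need one lattice per slice for per-voxel time
series to be comparable).  A fixed manifest center overrides this.

Static features inside a dynamic run are evaluated once per slice on its
anchor (first) frame so every tag aligns 1:1 per slice record.

Failures are isolated per slice: a failing slice is logged, recorded in
the ``skipped`` dataset, and does not abort the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np

from .errors import (
    ConfigurationError,
    InvalidArgumentError,
    RegistrationError,
)
from .grid import build_grid
from .observer import ObserverParams, obs_feature, observable_names
from .pdf import Aggregator, aggregator_names, pdf_feature
from .properties import cache_properties, channel_names, load_charge_file
from .selection import select_focus
from .store import FeatureStore
from .trajectory import load_trajectory, query_subsystem, slice_frames
from .voxelize import VoxelizeParams, voxelize_channel

__all__ = ["FeatureRequest", "TrajectorySource", "RunManifest", "Featurizer", "run_manifest"]

logger = logging.getLogger(__name__)

_KINDS = ("static", "pdf", "obs", "label")


@dataclass
class FeatureRequest:
    """One registered output: a (kind, channel, observable, aggregator,
    window, kernel-parameter) bundle with a unique output ``tag``."""

    kind: str
    tag: str
    channel: str = "uniform"
    aggregator: str = "mean"
    window: int = 1
    sigma: float = 1.0
    cutoff: float = 2.5
    radius: float = 2.5
    observable: str = "direct_count"
    normalize: bool = True

    def validate(self) -> None:
        if self.kind not in _KINDS:
            raise RegistrationError(f"unknown feature kind {self.kind!r}; valid: {_KINDS}")
        if not self.tag:
            raise RegistrationError("feature tag must be non-empty")
        if self.window < 1:
            raise RegistrationError(f"window must be >= 1, got {self.window}")
        if self.kind in ("pdf", "obs") and self.aggregator not in aggregator_names():
            raise RegistrationError(
                f"unknown aggregator {self.aggregator!r}; valid: {aggregator_names()}"
            )
        if self.kind in ("static", "pdf", "obs") and self.channel not in channel_names():
            raise RegistrationError(
                f"unknown channel {self.channel!r}; valid: {channel_names()}"
            )
        if self.kind == "obs" and self.observable not in observable_names():
            raise RegistrationError(
                f"unknown observable {self.observable!r}; valid: {observable_names()}"
            )
        if self.kind in ("static", "pdf") and not (self.sigma > 0 and self.cutoff > 0):
            raise RegistrationError("sigma and cutoff must be > 0")
        if self.kind == "obs" and not (self.radius > 0):
            raise RegistrationError("radius must be > 0")

    @property
    def reach(self) -> float:
        """Distance the feature perceives beyond a grid point: the kernel
        cutoff for static/PDF, the receptive-field radius for OBS."""
        if self.kind in ("static", "pdf"):
            return self.cutoff
        if self.kind == "obs":
            return self.radius
        return 0.0


@dataclass
class TrajectorySource:
    """One input trajectory: file paths, format tag, and optional charges."""

    traj_id: str
    topology: "str | None" = None
    coordinates: "str | None" = None
    format: str = "pdb"
    charges: "str | None" = None


@dataclass
class RunManifest:
    """Full, serializable description of one featurization run."""

    trajectories: list[TrajectorySource]
    features: list[FeatureRequest]
    output: str
    focus: str = "all"
    grid_dims: tuple[int, int, int] = (16, 16, 16)
    resolution: float = 1.0
    grid_center: Any = "auto"  # "auto" or an (x, y, z) triple in Å
    environment: float = 0.0
    labels: dict[str, float] = field(default_factory=dict)
    label_mode: str = "lenient"  # lenient: skip unlabeled; strict: error
    seed: int = 0
    allow_edge_artifacts: bool = False  # zero-buffer benchmark mode

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_dims"] = list(self.grid_dims)
        if not isinstance(self.grid_center, str):
            d["grid_center"] = [float(x) for x in self.grid_center]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunManifest":
        data = dict(data)
        grid = data.pop("grid", None)
        if grid is not None:
            data.setdefault("grid_dims", grid.get("dims", (16, 16, 16)))
            data.setdefault("resolution", grid.get("resolution", 1.0))
            data.setdefault("grid_center", grid.get("center", "auto"))
        trajs = [
            t if isinstance(t, TrajectorySource) else TrajectorySource(
                traj_id=str(t.get("id", t.get("traj_id", f"traj{i}"))),
                topology=t.get("topology"),
                coordinates=t.get("coordinates"),
                format=t.get("format", "pdb"),
                charges=t.get("charges"),
            )
            for i, t in enumerate(data.pop("trajectories", []))
        ]
        feats = [
            f if isinstance(f, FeatureRequest) else FeatureRequest(**f)
            for f in data.pop("features", [])
        ]
        known = {
            "output", "focus", "grid_dims", "resolution", "grid_center",
            "environment", "labels", "label_mode", "seed", "allow_edge_artifacts",
        }
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown manifest keys: {sorted(unknown)}")
        if "output" not in data:
            raise ConfigurationError("manifest must name an output path")
        data["grid_dims"] = tuple(int(x) for x in data.get("grid_dims", (16, 16, 16)))
        return cls(trajectories=trajs, features=feats, **data)

    def canonical_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


class Featurizer:
    """Validates feature registrations and executes a manifest."""

    def __init__(self, manifest: RunManifest):
        self.manifest = manifest
        self.requests: dict[str, FeatureRequest] = {}
        for request in manifest.features:
            self.hook(request)

    # -- hook --------------------------------------------------------------
    def hook(self, request: FeatureRequest) -> None:
        """Validate and bind one feature request to the run."""
        request.validate()
        if request.tag in self.requests:
            raise RegistrationError(f"duplicate feature tag {request.tag!r}")
        self.requests[request.tag] = request

    @property
    def pad_distance(self) -> float:
        """Shared lattice buffer width: max reach over registered features."""
        if self.manifest.allow_edge_artifacts:
            return 0.0
        return max((r.reach for r in self.requests.values()), default=0.0)

    # -- run ---------------------------------------------------------------
    def run(self) -> str:
        """Execute the manifest; returns the output HDF path."""
        manifest = self.manifest
        if not self.requests:
            raise RegistrationError("empty run: no features registered")
        grid_requests = [r for r in self.requests.values() if r.kind != "label"]
        if not grid_requests:
            raise RegistrationError("empty run: no grid features registered")

        windows = sorted({r.window for r in self.requests.values()})
        by_window = {
            w: [r for r in self.requests.values() if r.window == w] for w in windows
        }
        require_buffer = not manifest.allow_edge_artifacts

        with FeatureStore(manifest.output, "w") as store:
            store.attrs["resolution"] = manifest.resolution
            store.attrs["dims"] = np.asarray(manifest.grid_dims, dtype=np.int64)
            store.attrs["buffer_voxels"] = int(
                build_grid((0, 0, 0), manifest.grid_dims, manifest.resolution,
                           self.pad_distance).buffer_voxels
            )
            store.attrs["manifest_hash"] = manifest.canonical_hash()
            store.attrs["seed"] = int(manifest.seed)
            tag_attrs = {
                r.tag: {
                    "kind": r.kind, "channel": r.channel, "aggregator": r.aggregator,
                    "window": r.window, "sigma": r.sigma, "cutoff": r.cutoff,
                    "radius": r.radius, "observable": r.observable,
                }
                for r in self.requests.values()
            }

            for traj_idx, source in enumerate(manifest.trajectories):
                self._run_trajectory(
                    store, traj_idx, source, by_window, require_buffer, tag_attrs
                )
        return manifest.output

    def _run_trajectory(self, store, traj_idx, source, by_window, require_buffer, tag_attrs):
        manifest = self.manifest
        topology, frame_iter = load_trajectory(
            source.topology, source.coordinates, source.format
        )
        frames = list(frame_iter)
        charges = (
            load_charge_file(source.charges, topology.n_atoms)
            if source.charges
            else None
        )
        logger.info(
            "trajectory %s: %d atoms, %d frames", source.traj_id, topology.n_atoms, len(frames)
        )
        focus_full = select_focus(manifest.focus, topology)

        for window, requests in by_window.items():
            slices = slice_frames(frames, window, topology)
            logger.info(
                "trajectory %s: window %d -> %d slice(s)", source.traj_id, window, len(slices)
            )
            for slc in slices:
                try:
                    self._run_slice(
                        store, traj_idx, source, slc, requests, focus_full,
                        charges, require_buffer, tag_attrs,
                    )
                except Exception:
                    logger.exception(
                        "slice %d of trajectory %s failed; skipping",
                        slc.slice_index, source.traj_id,
                    )
                    store.dump_rows(
                        np.array([[traj_idx, window, slc.slice_index]]), "skipped"
                    )

    def _run_slice(
        self, store, traj_idx, source, slc, requests, focus_full, charges,
        require_buffer, tag_attrs,
    ):
        manifest = self.manifest
        # anchor the lattice: focus centroid of the slice's first frame
        if isinstance(manifest.grid_center, str) and manifest.grid_center == "auto":
            idx = focus_full.resolved_indices
            anchor = slc.frames[0].coordinates
            if len(idx) == 0:
                logger.warning("focus empty; anchoring grid at the all-atom centroid")
                center = anchor.mean(axis=0) if anchor.shape[0] else np.zeros(3)
            else:
                center = anchor[idx].mean(axis=0)
        else:
            center = np.asarray(manifest.grid_center, dtype=float)
        spec = build_grid(center, manifest.grid_dims, manifest.resolution, self.pad_distance)

        qslice = query_subsystem(slc, manifest.focus, spec, manifest.environment)
        q_charges = (
            charges[qslice.source_indices] if charges is not None else None
        )
        table = cache_properties(qslice.topology, q_charges)

        # labels first: a strict-mode miss aborts the slice before any grid
        # record is appended, keeping per-slice failures atomic
        ordered = sorted(requests, key=lambda r: r.kind != "label")
        for request in ordered:
            if request.kind == "label":
                self._dump_label(store, traj_idx, source, slc, request)
                continue
            if request.kind == "static":
                params = VoxelizeParams(request.sigma, request.cutoff, request.normalize)
                grid = voxelize_channel(
                    qslice, request.channel, spec, params,
                    table=table, frame_index=0, require_buffer=require_buffer,
                )
            elif request.kind == "pdf":
                params = VoxelizeParams(request.sigma, request.cutoff, request.normalize)
                grid = pdf_feature(
                    qslice, request.channel, spec, params, Aggregator(request.aggregator),
                    table=table, require_buffer=require_buffer,
                )
            else:  # obs
                obs = ObserverParams(
                    radius=request.radius,
                    observable=request.observable,
                    weight_channel=request.channel,
                )
                grid = obs_feature(
                    qslice, obs, spec, Aggregator(request.aggregator),
                    table=table, require_buffer=require_buffer,
                )
            store.dump(grid, request.tag, attrs=tag_attrs[request.tag])

    def _dump_label(self, store, traj_idx, source, slc, request):
        manifest = self.manifest
        if source.traj_id not in manifest.labels:
            if manifest.label_mode == "strict":
                raise ConfigurationError(
                    f"no label for trajectory {source.traj_id!r} (strict mode)"
                )
            logger.warning(
                "no label for trajectory %s; slice %d skipped for tag %s",
                source.traj_id, slc.slice_index, request.tag,
            )
            return
        value = float(manifest.labels[source.traj_id])
        store.dump(np.float32(value), request.tag)
        store.dump_rows(np.array([[traj_idx, slc.slice_index]]), f"{request.tag}_index")


def run_manifest(manifest: "RunManifest | dict") -> str:
    """Execute a manifest (object or plain dict) and return the HDF path."""
    if isinstance(manifest, dict):
        manifest = RunManifest.from_dict(manifest)
    return Featurizer(manifest).run()
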