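"""HDF5 feature store.

One file per featurization run.  Schema:

* one dataset per feature tag — shape ``(n_records, Dx, Dy, Dz)`` float32
  for grid features, ``(n_records,)`` float32 for labels — chunked one
  record per chunk and gzip-compressed, appendable along axis 0;
* labels are *orthogonal* datasets: separate from, but record-aligned
  with, the grid datasets in the same file;
* a ``skipped`` integer dataset records (trajectory, window, slice)
  triples of slices whose computation failed;
* file attributes hold the lattice geometry (``resolution``, ``dims``,
  ``buffer_voxels``), the manifest hash and seed; per-dataset attributes
  hold the feature parameters (sigma/cutoff/radius/...).

Features are computed in float64 and stored as float32 (the ML-standard
precision); read-back equals what was written bitwise at float32.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import h5py
import numpy as np

from .errors import SchemaError
from .grid import VoxelGrid

__all__ = ["FeatureStore", "dump", "read_batch"]

_GRID_DTYPE = np.float32


class FeatureStore:
    """Thin append/read wrapper around one HDF5 file."""

    def __init__(self, path: str, mode: str = "r"):
        self.path = str(path)
        try:
            self._file = h5py.File(self.path, mode)
        except OSError as exc:
            raise OSError(f"cannot open HDF store {path!r}: {exc}") from exc

    # -- lifecycle ---------------------------------------------------------
    def close(self) -> None:
        self._file.close()

    def __enter__(self) -> "FeatureStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @property
    def attrs(self):
        return self._file.attrs

    # -- writing -----------------------------------------------------------
    def dump(self, record, tag: str, attrs: "dict | None" = None) -> int:
        """Append one record (a :class:`VoxelGrid`, array, or scalar) to the
        dataset ``tag``; returns the index it was written at.

        The first dump of a tag creates the dataset with unlimited first
        axis, one-record chunks and gzip compression; later dumps must
        match its record shape.
        """
        if isinstance(record, VoxelGrid):
            data = record.values
        else:
            data = np.asarray(record)
        data = np.asarray(data, dtype=_GRID_DTYPE)
        record_shape = data.shape

        if tag not in self._file:
            ds = self._file.create_dataset(
                tag,
                shape=(0,) + record_shape,
                maxshape=(None,) + record_shape,
                dtype=_GRID_DTYPE,
                chunks=(1,) + record_shape if record_shape else (256,),
                compression="gzip",
                compression_opts=4,
            )
            if attrs:
                for k, v in attrs.items():
                    ds.attrs[k] = v
        else:
            ds = self._file[tag]
            if ds.shape[1:] != record_shape:
                raise SchemaError(
                    f"record shape {record_shape} != dataset {tag!r} record shape {ds.shape[1:]}"
                )
        n = ds.shape[0]
        ds.resize(n + 1, axis=0)
        ds[n] = data
        return n

    def dump_rows(self, rows: np.ndarray, tag: str) -> None:
        """Append integer rows (e.g. skipped-slice or alignment records)."""
        rows = np.atleast_2d(np.asarray(rows, dtype=np.int64))
        if tag not in self._file:
            ds = self._file.create_dataset(
                tag,
                shape=(0, rows.shape[1]),
                maxshape=(None, rows.shape[1]),
                dtype=np.int64,
            )
        else:
            ds = self._file[tag]
        n = ds.shape[0]
        ds.resize(n + rows.shape[0], axis=0)
        ds[n:] = rows

    # -- reading -----------------------------------------------------------
    def tags(self) -> list[str]:
        return sorted(self._file.keys())

    def n_records(self, tag: str) -> int:
        if tag not in self._file:
            raise KeyError(f"unknown dataset tag {tag!r}")
        return self._file[tag].shape[0]

    def read(self, tag: str, index: int) -> np.ndarray:
        if tag not in self._file:
            raise KeyError(f"unknown dataset tag {tag!r}")
        return np.asarray(self._file[tag][index])

    def read_batch(
        self,
        tags: Sequence[str],
        indices: Iterable[int],
        strict: bool = True,
    ) -> dict[str, np.ndarray]:
        """Read records ``indices`` from each tag, aligned by record index.

        In strict mode all requested datasets must share one record count
        (the alignment contract for training data vs labels).
        """
        idx = np.asarray(list(indices), dtype=int)
        lengths = {tag: self.n_records(tag) for tag in tags}
        if strict and len(set(lengths.values())) > 1:
            raise SchemaError(f"ragged record counts across tags: {lengths}")
        out: dict[str, np.ndarray] = {}
        for tag in tags:
            ds = self._file[tag]
            if idx.size and (idx.min() < 0 or idx.max() >= ds.shape[0]):
                raise IndexError(f"indices out of range for tag {tag!r} (n={ds.shape[0]})")
            if idx.size == 0:
                out[tag] = np.empty((0,) + ds.shape[1:], dtype=ds.dtype)
            else:
                # h5py fancy indexing needs strictly increasing indices;
                # gather the unique set, then scatter back into request order
                uniq, inverse = np.unique(idx, return_inverse=True)
                gathered = np.asarray(ds[uniq.tolist()])
                out[tag] = gathered[inverse]
        return out

    def summary(self) -> dict:
        """Machine-readable schema summary (tags, shapes, attributes)."""
        datasets = {}
        for tag in self.tags():
            ds = self._file[tag]
            datasets[tag] = {
                "shape": list(ds.shape),
                "dtype": str(ds.dtype),
                "n_records": int(ds.shape[0]),
                "attrs": {k: _jsonable(v) for k, v in ds.attrs.items()},
            }
        return {
            "path": self.path,
            "n_tags": len(datasets),
            "datasets": datasets,
            "attrs": {k: _jsonable(v) for k, v in self._file.attrs.items()},
        }


def _jsonable(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, bytes):
        return value.decode("utf-8", "replace")
    return value


def dump(record, tag: str, store: FeatureStore) -> int:
    """Module-level convenience: append ``record`` to ``tag`` in ``store``."""
    return store.dump(record, tag)


def read_batch(store: FeatureStore, tags: Sequence[str], indices: Iterable[int], strict: bool = True):
    return store.read_batch(tags, indices, strict=strict)
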