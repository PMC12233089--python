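"""Independent reference implementations used only by the tests.

These deliberately share no code with the package: plain per-voxel /
per-atom loops (or a single dense matrix, where noted) evaluating the
definitions directly, against which the chunked production kernels are
compared.
"""

from __future__ import annotations

import math

import numpy as np


def loop_voxelize(coords, weights, centers, sigma, cutoff, normalize=True):
    """Pure-Python triple loop over voxels, inner loop over atoms."""
    nx, ny, nz, _ = centers.shape
    out = np.zeros((nx, ny, nz))
    pref = (sigma * math.sqrt(2.0 * math.pi)) ** -3 if normalize else 1.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c = centers[i, j, k]
                acc = 0.0
                for a in range(len(weights)):
                    d = math.dist(c, coords[a])
                    if d <= cutoff:
                        acc += weights[a] * math.exp(-(d * d) / (2.0 * sigma * sigma))
                out[i, j, k] = pref * acc
    return out


def dense_voxelize(coords, weights, centers, sigma, cutoff, normalize=True):
    """Brute force over all (voxel, atom) pairs in one dense matrix —
    no chunking or neighbor shortcuts; atoms beyond the cutoff zeroed."""
    flat = centers.reshape(-1, 3)
    if len(weights) == 0:
        return np.zeros(centers.shape[:3])
    diff = flat[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    kernel = np.exp(-(dist**2) / (2.0 * sigma**2))
    kernel[dist > cutoff] = 0.0
    pref = (sigma * math.sqrt(2.0 * math.pi)) ** -3 if normalize else 1.0
    return (pref * (kernel @ weights)).reshape(centers.shape[:3])


def loop_observe(coords, weights, centers, radius, observable):
    """Pure-Python per-gridpoint, per-atom scan for every observable."""
    nx, ny, nz, _ = centers.shape
    out = np.zeros((nx, ny, nz))
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c = centers[i, j, k]
                in_field = [
                    a for a in range(len(weights)) if math.dist(c, coords[a]) <= radius
                ]
                out[i, j, k] = _observe_point(coords, weights, c, in_field, observable)
    return out


def _observe_point(coords, weights, point, in_field, observable):
    nonzero = [a for a in in_field if weights[a] != 0.0]
    if observable == "existence":
        return 1.0 if nonzero else 0.0
    if observable == "direct_count":
        return float(len(nonzero))
    if observable == "distinct_count":
        return float(len({weights[a] for a in nonzero}))
    wsum = sum(weights[a] for a in in_field)
    if wsum == 0.0:
        return 0.0
    if observable == "mean_distance":
        return sum(weights[a] * math.dist(point, coords[a]) for a in in_field) / wsum
    if observable == "radius_of_gyration":
        centroid = [
            sum(weights[a] * coords[a][d] for a in in_field) / wsum for d in range(3)
        ]
        rg2 = sum(
            weights[a] * math.dist(centroid, coords[a]) ** 2 for a in in_field
        ) / wsum
        return math.sqrt(max(rg2, 0.0))
    raise ValueError(observable)


def loop_reduce(values, name):
    """Per-voxel scalar reduction: loop over voxels, reduce each series."""
    w = values.shape[0]
    out = np.zeros(values.shape[1:])
    for idx in np.ndindex(values.shape[1:]):
        series = values[(slice(None),) + idx]
        if name == "mean":
            out[idx] = float(np.mean(series))
        elif name == "std":
            out[idx] = 0.0 if w == 1 else float(np.std(series, ddof=1))
        elif name == "sum":
            out[idx] = float(np.sum(series))
        elif name == "min":
            out[idx] = float(np.min(series))
        elif name == "max":
            out[idx] = float(np.max(series))
        elif name == "median":
            out[idx] = float(np.median(series))
        elif name == "slope":
            out[idx] = 0.0 if w == 1 else float(np.polyfit(np.arange(w), series, 1)[0])
        else:
            raise ValueError(name)
    return out
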