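"""Seeded synthetic trajectories of dummy atoms.

The generator emulates the benchmark input used to exercise the
featurization engine: point atoms (no bonds) placed uniformly in a box
centered at the origin and displaced frame-to-frame by a simple motion
model.  The default shape — 300 atoms, 50-frame slices, 1 Å resolution
grids with a 2.5 Å cutoff — is the benchmark configuration.

Motion models
-------------
``frozen``
    all frames identical (degenerate baseline);
``brownian``
    independent per-atom, per-axis Gaussian steps of standard deviation
    ``step_sigma`` Å/frame, accumulated over frames;
``harmonic``
    each atom oscillates along a fixed random unit direction:
    ``p(t) = p0 + amplitude * sin(2*pi*t/period) * u``.

The seed fully determines the output; identical specs regenerate
bitwise-identical trajectories.

Output formats: the topology as a minimal PDB (ligand atoms get residue
``LIG``, the rest ``DUM``, which round-trips the part annotation through
the PDB loader) and the frames as plain-text XYZ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidArgumentError
from .trajectory import Frame, Topology

__all__ = ["SyntheticSpec", "generate", "write_trajectory", "benchmark_suite"]

_ELEMENT_CYCLE = ("C", "N", "O", "S", "H")


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of one synthetic trajectory.

    Defaults are the benchmark shape: 300 dummy atoms, 50 frames,
    Brownian motion with 0.1 Å/frame steps, a 24 Å box, 10% of atoms
    tagged as ligand.
    """

    n_atoms: int = 300
    n_frames: int = 50
    motion: str = "brownian"  # frozen | brownian | harmonic
    step_sigma: float = 0.1  # Å/frame, brownian
    amplitude: float = 2.0  # Å, harmonic
    period: float = 10.0  # frames, harmonic
    box: tuple[float, float, float] = (24.0, 24.0, 24.0)
    ligand_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atoms < 1 or self.n_frames < 1:
            raise InvalidArgumentError("n_atoms and n_frames must be >= 1")
        if self.motion not in ("frozen", "brownian", "harmonic"):
            raise InvalidArgumentError(f"unknown motion model {self.motion!r}")
        if not (0.0 <= self.ligand_fraction <= 1.0):
            raise InvalidArgumentError("ligand_fraction must be in [0, 1]")


def generate(spec: SyntheticSpec) -> tuple[Topology, list[Frame]]:
    """Generate the topology and frame sequence for ``spec``.

    Atoms are uniform in the box (centered at the origin) at frame 0;
    the first ``ceil(ligand_fraction * n_atoms)`` atoms carry the ligand
    part annotation (residue ``LIG``); elements cycle through C,N,O,S,H.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    n = spec.n_atoms
    p0 = (rng.random((n, 3)) - 0.5) * box[None, :]

    if spec.motion == "frozen":
        coords = np.repeat(p0[None, :, :], spec.n_frames, axis=0)
    elif spec.motion == "brownian":
        steps = rng.normal(0.0, spec.step_sigma, size=(spec.n_frames - 1, n, 3))
        coords = np.concatenate([p0[None], p0[None] + np.cumsum(steps, axis=0)])
    else:  # harmonic
        directions = rng.normal(size=(n, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        t = np.arange(spec.n_frames, dtype=float)
        phase = np.sin(2.0 * np.pi * t / spec.period)
        coords = p0[None, :, :] + spec.amplitude * phase[:, None, None] * directions[None, :, :]

    n_ligand = math.ceil(spec.ligand_fraction * n)
    part = np.zeros(n, dtype=int)
    part[:n_ligand] = 1
    resname = np.array(["LIG" if p == 1 else "DUM" for p in part], dtype=object)
    elements = np.array([_ELEMENT_CYCLE[i % len(_ELEMENT_CYCLE)] for i in range(n)], dtype=object)
    topology = Topology(
        element=elements,
        atom_name=elements.copy(),
        residue_name=resname,
        residue_index=np.where(part == 1, 1, 2),
        part_annotation=part,
    )
    frames = [Frame(coordinates=coords[t], time_index=t) for t in range(spec.n_frames)]
    return topology, frames


def write_trajectory(
    topology: Topology, frames: list[Frame], out_dir: str
) -> tuple[str, str]:
    """Write ``topology.pdb`` and ``frames.xyz`` under ``out_dir``.

    Returns ``(pdb_path, xyz_path)``.  The PDB holds frame 0's
    coordinates; the XYZ file concatenates all frames.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pdb_path = out / "topology.pdb"
    xyz_path = out / "frames.xyz"

    coords0 = frames[0].coordinates
    with open(pdb_path, "w") as fh:
        for i in range(topology.n_atoms):
            x, y, z = coords0[i]
            fh.write(
                "HETATM{serial:>5d} {name:<4s}{resname:>4s} A{resid:>4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {elem:>2s}\n".format(
                    serial=(i + 1) % 100000,
                    name=str(topology.atom_name[i])[:4],
                    resname=str(topology.residue_name[i])[:3],
                    resid=int(topology.residue_index[i]) % 10000,
                    x=x, y=y, z=z,
                    elem=str(topology.element[i])[:2].upper(),
                )
            )
        fh.write("END\n")

    with open(xyz_path, "w") as fh:
        for t, frame in enumerate(frames):
            fh.write(f"{topology.n_atoms}\n")
            fh.write(f"frame {t}\n")
            for i in range(topology.n_atoms):
                x, y, z = frame.coordinates[i]
                fh.write(f"{topology.element[i]} {x:.8f} {y:.8f} {z:.8f}\n")
    return str(pdb_path), str(xyz_path)


def benchmark_suite(grid_sizes: list[int], seed: int = 0) -> list[dict]:
    """Benchmark-shaped manifests: one per grid edge length.

    Each manifest describes a run over a 300-atom, 50-frame synthetic
    trajectory at 1 Å resolution with a 2.5 Å cutoff and *zero-buffer
    compatibility mode* (``allow_edge_artifacts``), so the nominal grid
    size is the actual computed size.  Zero-buffer mode exists only for
    benchmark replication; default runs always buffer.
    """
    manifests = []
    for g in grid_sizes:
        g = int(g)
        manifests.append(
            {
                "synthetic": SyntheticSpec(n_atoms=300, n_frames=50, seed=seed),
                "grid": {"dims": (g, g, g), "resolution": 1.0, "center": (0.0, 0.0, 0.0)},
                "focus": "all",
                "window": 50,
                "sigma": 1.0,
                "cutoff": 2.5,
                "radius": 2.5,
                "allow_edge_artifacts": True,
                "seed": seed,
            }
        )
    return manifests
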