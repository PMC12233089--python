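# voxtraj

Voxel-grid featurization of molecular dynamics (MD) trajectories for
3D-CNN-style machine learning: static Gaussian density voxelization of
per-atom property channels, plus two families of **dynamic** features —
**property-density flow (PDF)** and **marching observers (OBS)** — with
results persisted in HDF5 alongside record-aligned label datasets.

The package is for computational biologists, structural bioinformaticians,
and ML engineers who have ensembles of MD trajectories (or single
structures, which are simply one-frame trajectories) and want 3D-grid
features that reflect not just a snapshot's geometry but its local
dynamics over configurable time windows.

## The model

**Static voxelization.** A substructure of interest (e.g. a ligand
binding site) is enclosed in a regular lattice of voxel centers
c<sub>ijk</sub> at a fixed resolution, and an atomic property channel
w<sub>a</sub> (mass, partial charge, element one-hots, part annotation,
hydropathy, ...) is interpolated onto it with a truncated Gaussian
kernel:

```
w_ijk = (σ√(2π))⁻³ · Σ_a  w_a · exp( −‖c_ijk − p_a‖² / 2σ² ),   ‖c_ijk − p_a‖ ≤ cutoff
```

Atoms beyond the cutoff contribute exactly zero. Because a hard bounding
box would truncate the kernel at the grid edge, the lattice is computed
**buffered** — enlarged on every side by enough voxels to cover the
kernel reach — and only the artifact-free central region is returned.

**Property-density flow (PDF).** Over a *frame slice* (W consecutive
frames sharing one topology and one grid anchor), each voxel carries a
time series of the rasterized property. An aggregation function (mean,
sample standard deviation, sum, min, max, median, least-squares slope)
reduces each voxel's series to a scalar — yielding ⌊T/W⌋ feature grids
for a trajectory of T frames.

**Marching observers (OBS).** Every grid point is an observer that
perceives, each frame, the atoms inside its receptive field (a sphere of
given radius, with hard-cutoff, discrete-jump semantics) and evaluates an
observable on their positions and weights: existence, direct count,
distinct count (for index-like channels), weighted mean distance to the
observer, or weighted radius of gyration. Per-frame observations are
aggregated over the window like PDF. For example, ligand-annotation
weights + `direct_count` + `mean` gives the time-averaged count of ligand
atoms near each observer; mass weights + `mean_distance` + `std` gives
the temporal variability of the mass-weighted distance of atoms to each
observer.

Channels, aggregators, and observables are open registries — new ones
plug in without touching the core.

## Worked example

```python
import voxtraj as vt

# a seeded synthetic trajectory: 300 dummy atoms, 50 frames, 10% ligand-tagged
topology, frames = vt.generate(vt.SyntheticSpec(n_atoms=300, n_frames=50, seed=42))
pdb, xyz = vt.write_trajectory(topology, frames, "example")

manifest = vt.RunManifest(
    trajectories=[vt.TrajectorySource("t0", pdb, xyz, "xyz")],
    features=[
        vt.FeatureRequest(kind="static", tag="static_mass", channel="mass", window=10),
        vt.FeatureRequest(kind="pdf", tag="pdf_mass_std", channel="mass",
                          aggregator="std", window=10),
        vt.FeatureRequest(kind="obs", tag="obs_ligand_count", channel="part_annotation",
                          observable="direct_count", aggregator="mean", window=10),
        vt.FeatureRequest(kind="label", tag="affinity", window=10),
    ],
    output="example/features.h5",
    focus="part:1",              # anchor the grid on the ligand atoms
    grid_dims=(16, 16, 16),      # 16³ central voxels at 1 Å
    labels={"t0": 7.2},
)
path = vt.run_manifest(manifest)

with vt.FeatureStore(path) as store:
    print("tags:", store.tags())
    for tag in ("static_mass", "pdf_mass_std", "obs_ligand_count"):
        data = store.read_batch([tag], range(store.n_records(tag)))[tag]
        print(f"{tag}: shape {data.shape}, record-0 max {data[0].max():.4f}")
    print("affinity labels:", store.read_batch(["affinity"], range(5))["affinity"])
```

prints

```
tags: ['affinity', 'affinity_index', 'obs_ligand_count', 'pdf_mass_std', 'static_mass']
static_mass: shape (5, 16, 16, 16), record-0 max 2.7536
pdf_mass_std: shape (5, 16, 16, 16), record-0 max 0.3992
obs_ligand_count: shape (5, 16, 16, 16), record-0 max 2.3000
affinity labels: [7.2 7.2 7.2 7.2 7.2]
```

The 50 frames split into 5 nonoverlapping 10-frame slices, so every tag
holds 5 records. `static_mass` is the mass density of each slice's
anchor frame (peak ≈ 2.75 Da/Å³ where atoms overlap); `pdf_mass_std` is
each voxel's temporal standard deviation of that density; and
`obs_ligand_count` peaks at ≈ 2.3, i.e. on average a bit over two
ligand atoms within 2.5 Å of the busiest observer. The label 7.2 is
broadcast to all 5 record-aligned rows of the orthogonal `affinity`
dataset.

The same run works from the shell:

```sh
voxtraj synth --spec spec.yaml --out example/
voxtraj featurize --manifest manifest.yaml --set features.0.window=10 -v
voxtraj inspect example/features.h5 --json
```

## HDF schema

One dataset per feature tag, shape `(n_records, Dx, Dy, Dz)` float32
(labels: `(n_records,)`), chunked one record per chunk and
gzip-compressed. File attributes: `resolution`, `dims`, `buffer_voxels`,
`manifest_hash`, `seed`; per-dataset attributes hold the feature's
parameters (`kind`, `channel`, `aggregator`, `window`, `sigma`,
`cutoff`, `radius`, `observable`). A `skipped` dataset records
`(trajectory, window, slice)` triples of failed slices; `<tag>_index`
datasets align label records when some trajectories are unlabeled.

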