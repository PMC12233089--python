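# Methods

This note documents the models and procedures voxtraj implements, the
parameters that matter, the numerical choices, what the synthetic-data
generator does and does not emulate, and known limitations. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Lattice geometry and buffering

A grid is a *central* region of `dims` voxels per axis at `resolution` Å
per voxel plus a symmetric buffer of `buffer_voxels` padding voxels per
side. Grid points are voxel **centers**: the center of central voxel
(i, j, k) is `origin + (index + 0.5)·resolution`, 0-based indices, axis
order (x, y, z). The center convention (rather than corners) was a
genuinely open choice; it is fixed here because it round-trips
unambiguously between the central and padded lattices after an index
shift of `buffer_voxels`. Non-cubic `dims` are allowed.

Every feature kernel has a finite reach — the Gaussian truncation
`cutoff` for densities, the receptive-field `radius` for observers. All
values are computed on the padded lattice and cropped to the central
region, so central values are identical to what an unbounded lattice
would produce there ("edge-artifact freedom"). `build_grid` sizes the
buffer as `ceil(pad_distance / resolution)`, the smallest padding whose
physical width covers the reach; when several features share a run, the
buffer covers the maximum reach over all of them. A zero-buffer
compatibility switch (`allow_edge_artifacts` / `require_buffer=False`)
exists solely to replicate unbuffered benchmark layouts where the
nominal grid size must be the computed one; default runs always buffer.

## Static voxelization

The density at grid point c is
`w(c) = (σ√2π)⁻³ Σ_a w_a exp(−‖c − p_a‖²/2σ²)` over atoms with
`‖c − p_a‖ ≤ cutoff`. The truncation is a hard distance cutoff with no
boundary smoothing — values jump discretely when an atom crosses it,
consistent with the observer semantics below.

Parameters and defaults:

* `sigma` = 1.0 Å — one voxel at the reference resolution of 1 Å. The
  kernel width is a free modeling choice; it is global with per-feature
  override.
* `cutoff` = 2.5 Å — the reference benchmark cutoff. At 2.5σ the
  truncated tail carries ≈ 1.2% of the kernel mass, so truncation is a
  visible (intentional) approximation at the default; mass-conservation
  guarantees are stated for cutoff ≥ 6σ, where the discarded tail and
  lattice-quadrature error together stay under 1%.
* `normalize` = on — applies the (σ√2π)⁻³ prefactor so the grid
  integrates to Σw. For categorical/one-hot channels the absolute scale
  is arbitrary and the prefactor can be switched off.

The reference implementation is CPU-only and processes voxel-space
chunks against all atoms: a dense, grid-parallel layout whose per-frame
cost grows with (grid points × atoms) — i.e. cubically in the grid edge
at fixed atom count, which the acceptance script measures as a log-log
slope. Two numerical choices matter: squared distances come from
explicit coordinate differences (the expanded inner-product form loses
~3 digits near the cutoff, where kernel values are smallest), and the
exponential is evaluated only inside the truncation sphere (outside it
the result is exactly zero, and deeply-underflowing `exp` calls hit
slow FPU paths). Atoms farther than the reach from the *padded* box are
culled before any arithmetic: they cannot touch any voxel, and removing
them first makes them bitwise-invisible rather than merely
numerically-invisible (floating-point summation is not invariant to
appended zero terms). Accelerated backends may replace this kernel only
if results are identical.

## Property channels

Channels are computed once per topology (never from coordinates) and
cached. Built-ins: `mass`, `partial_charge` (user-supplied, else zero —
no charge model is computed), eight element one-hot flags
(C/N/O/S/P/H/halogen/other, exactly one fires per atom),
`residue_index`, `atom_index`, `part_annotation` (0 receptor, 1 ligand,
2 solvent), `hydropathy` (Kyte–Doolittle residue scale),
`aromatic_flag`, `donor_flag`, `acceptor_flag`, and `uniform` (all
ones). Chemical perception is deliberately template-driven
(residue/atom-name lookup over the canonical amino acids, common
nucleotides, and water) rather than toolkit-perceived: templates are
transparent and reproducible, at the price of returning zeros (with a
one-time warning) for non-template residues. Unknown elements fall back
to the `other` flag and a documented default mass of 12.011 Da. The
channel set is a registry: `register_channel` adds user channels
without core changes.

## Frame slices, grid anchoring, and querying

A trajectory of T frames splits into ⌊T/W⌋ nonoverlapping slices of
length W; trailing `T mod W` frames are dropped and logged. Dynamic
features need one lattice per slice so per-voxel time series are
comparable across frames; the lattice center is anchored at the
geometric centroid of the focus atoms in the slice's **first** frame and
held fixed for all W frames (a fixed manifest center overrides this).
Static features inside a dynamic run are likewise evaluated once per
slice on that anchor frame, so all tags align 1:1 per record.

The focus is a small bespoke selection language (`resname:`, `resid:`,
`atomid:`, `part:`, `all`, combined with and/or/not and parentheses) —
dependency-neutral by design rather than borrowing an existing mask
dialect. Querying reduces each slice to the focus atoms plus any atom
inside the padded box in at least one frame (plus an optional
`environment` margin); because the padded box already extends beyond the
central region by the full feature reach, the default margin of 0 is
lossless for central-region outputs. The reduced atom set is fixed
across the slice so all frames share one topology, and the operation is
idempotent.

Periodic boundary conditions are **not** handled and no superposition or
alignment is performed; trajectories are assumed imaged, whole, and
consistently oriented — a preprocessing responsibility.

## Aggregators

`mean`, `std`, `sum`, `min`, `max`, `median`, `slope`, applied per voxel
along the window. `std` is the sample standard deviation (denominator
W−1) and returns exactly 0 both for W = 1 and for bitwise-constant
series (the rounding residue of the two-pass formula is masked so a
frozen trajectory yields exact zeros). `slope` is the least-squares
slope of value against frame index, 0 for W = 1. Time-reversing a series
leaves all aggregators invariant except `slope`, which negates. The set
is a registry open to user reductions.

## Marching observers

Each grid point observes the atoms within its receptive field each
frame; observables depend only on positions and weights (no topology
adjustment), so atom order is irrelevant. Count-type observables
(`existence`, `direct_count`, `distinct_count`) are evaluated over
in-field atoms with **nonzero weight**: annotation/index channels
thereby act as masks, and the `uniform` channel counts all atoms. (The
stated invariants `existence ≤ direct_count` and
`distinct_count ≤ direct_count` force this reading — counting zero-weight
atoms in `existence` would violate them.) `distinct_count` compares
weight values exactly and is meant for integer-valued channels; it is
not meaningful on continuous channels. `mean_distance` and
`radius_of_gyration` are weight-averaged; a zero weight-sum returns 0
rather than propagating NaN (flagged here: with signed weights a
near-zero weight-sum makes these observables ill-conditioned, which is
the user's modeling choice). The radius of gyration uses the explicitly
centered second moment — not the difference of raw moments, which loses
precision for tight clusters far from the origin. Default radius 2.5 Å,
mirroring the voxelization cutoff. Custom observables register as
scalar functions of (in-field positions, weights, observer point).

## Run orchestration and storage

A run manifest (YAML/JSON or the `RunManifest` dataclass) lists ordered
trajectories, the focus, the grid geometry, the feature requests, labels
and the output path, and is fully serializable; its SHA-256 hash is
stored in the output. Requests are validated at registration (hook)
time, not mid-run. Failures are isolated per slice: a failing slice is
logged, recorded in the `skipped` dataset, and aborts nothing else;
label requests are processed first within a slice so a strict-mode
missing label skips the slice before any grid record is appended.
Records append in canonical (trajectory, slice) order regardless of
internal execution order, and re-running an identical manifest
reproduces the dataset contents byte for byte.

Features are computed in float64 and stored as float32 (the ML-standard
precision boundary), one gzip-compressed chunk per record for
record-random training access, one file per run. Labels are orthogonal,
record-aligned datasets in the same file.

Trajectory input: PDB (single- and multi-MODEL, via mdtraj) and a
plain-text XYZ-per-frame dialect (count line, comment line, `element x
y z` rows, frames concatenated); other dialects (NetCDF/XTC/DCD, ...)
enter through the reader-plugin contract — a callable returning a
topology and a lazy frame iterator. A single static structure is a
one-frame trajectory. Part annotation on load is residue-name driven
(water names → solvent; a documented small-molecule name set, e.g.
`LIG`, → ligand; otherwise receptor).

## Synthetic data

The generator emulates the benchmark input: point atoms without bonds,
uniformly placed in a box centered at the origin, moved by one of three
models — `frozen` (baseline), `brownian` (i.i.d. Gaussian steps of
`step_sigma` Å/frame per axis, default 0.1), or `harmonic` (fixed random
direction, closed-form sinusoid). Defaults are the benchmark shape: 300
atoms, 50 frames, 1 Å grids with 2.5 Å cutoff downstream; the 24 Å
default box gives a sparse, binding-site-like atom density of
~0.02 atoms/Å³. The seed fully determines the output.

What this does **not** emulate: bonded structure and excluded volume,
solvent shells, force-field correlations between atoms, or heterogeneous
time steps. Tests passing on synthetic data therefore validate the
featurization machinery — geometry, accounting, determinism, kernel
correctness — not the biological informativeness of any feature on real
trajectories.

`benchmark_suite` produces benchmark-shaped manifests (grid edges
16–128, zero-buffer mode) for cost studies; problem sizes used in the
automated checks are scaled to small desk-run sizes (grids up to 32³ for
correctness oracles, edges 16–64 for the scaling fit, one 50-frame slice
at 32³ for the end-to-end run), chosen so the whole suite runs in
minutes on one CPU.

## Known limitations

* No PBC awareness; atoms imaged far from the focus are simply absent.
* Template chemistry ignores non-canonical residues and protonation
  states; partial charges must be supplied externally.
* `distinct_count` on continuous channels, and weight-averaged
  observables with signed weights summing near zero, are documented
  sharp edges rather than guarded errors.
* One HDF file per run; concatenating multi-run datasets is a
  reader-side concern.
* The CPU kernels favor clarity and exact reproducibility over raw
  throughput; the results contract (bitwise-identical output) is the
  interface any accelerated backend must honor.
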