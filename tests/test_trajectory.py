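import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_slice, make_topology
from voxtraj import (
    CorruptInputError,
    Frame,
    InvalidArgumentError,
    UnsupportedFormatError,
    build_grid,
    generate,
    load_trajectory,
    query_subsystem,
    select_focus,
    slice_frames,
    write_trajectory,
)
from voxtraj.synthetic import SyntheticSpec


@pytest.fixture(scope="module")
def synthetic_files(tmp_path_factory):
    spec = SyntheticSpec(n_atoms=30, n_frames=6, seed=7, ligand_fraction=0.2)
    topology, frames = generate(spec)
    out = tmp_path_factory.mktemp("traj")
    pdb, xyz = write_trajectory(topology, frames, str(out))
    return topology, frames, pdb, xyz


def test_single_model_pdb_is_one_frame_trajectory(synthetic_files):
    topology, frames, pdb, _ = synthetic_files
    top, frame_iter = load_trajectory(pdb, format_tag="pdb")
    loaded = list(frame_iter)
    assert len(loaded) == 1  # a static structure is a one-frame trajectory
    assert top.n_atoms == topology.n_atoms
    assert list(top.residue_name[:3]) == ["LIG"] * 3
    np.testing.assert_allclose(loaded[0].coordinates, frames[0].coordinates, atol=2e-3)


def test_xyz_round_trip_preserves_frames_and_parts(synthetic_files):
    topology, frames, pdb, xyz = synthetic_files
    top, frame_iter = load_trajectory(pdb, xyz, "xyz")
    loaded = list(frame_iter)
    assert len(loaded) == len(frames)
    assert np.array_equal(top.part_annotation, topology.part_annotation)
    for orig, back in zip(frames, loaded):
        np.testing.assert_allclose(back.coordinates, orig.coordinates, atol=1e-7)


def test_benchmark_shaped_input_loads_300_atoms_50_frames(tmp_path):
    topology, frames = generate(SyntheticSpec(n_atoms=300, n_frames=50, seed=42))
    pdb, xyz = write_trajectory(topology, frames, str(tmp_path))
    top, frame_iter = load_trajectory(pdb, xyz, "xyz")
    loaded = list(frame_iter)
    assert top.n_atoms == 300 and len(loaded) == 50


def test_atom_count_mismatch_is_corrupt_input(synthetic_files, tmp_path):
    _, frames, pdb, _ = synthetic_files
    bad = tmp_path / "bad.xyz"
    lines = ["29", "truncated frame"]
    lines += [f"C {x:.3f} {y:.3f} {z:.3f}" for x, y, z in frames[0].coordinates[:29]]
    bad.write_text("\n".join(lines) + "\n")
    _, frame_iter = load_trajectory(pdb, str(bad), "xyz")
    with pytest.raises(CorruptInputError):
        list(frame_iter)


def test_unknown_format_tag(synthetic_files):
    _, _, pdb, _ = synthetic_files
    with pytest.raises(UnsupportedFormatError):
        load_trajectory(pdb, format_tag="netcdf4-custom")


@pytest.mark.parametrize(
    "total,window,expected_slices,dropped",
    [(50, 10, 5, 0), (7, 3, 2, 1), (1, 1, 1, 0), (101, 10, 10, 1)],
)
def test_slice_accounting(total, window, expected_slices, dropped):
    topology = make_topology(2)
    frames = [Frame(coordinates=np.zeros((2, 3)), time_index=t) for t in range(total)]
    slices = slice_frames(frames, window, topology)
    assert len(slices) == expected_slices
    assert all(s.window == window for s in slices)
    covered = sum(s.window for s in slices)
    assert total - covered == dropped


def test_slice_window_below_one_rejected():
    with pytest.raises(InvalidArgumentError):
        slice_frames([], 0, make_topology(1))


@settings(derandomize=True, max_examples=40, deadline=None)
@given(total=st.integers(1, 60), window=st.integers(1, 12))
def test_slicing_then_concatenating_reproduces_prefix(total, window):
    topology = make_topology(1)
    frames = [Frame(coordinates=np.array([[t, 0.0, 0.0]]), time_index=t) for t in range(total)]
    slices = slice_frames(frames, window, topology)
    assert len(slices) == total // window
    flattened = [f for s in slices for f in s.frames]
    for got, expected in zip(flattened, frames[: (total // window) * window]):
        assert got.time_index == expected.time_index
        assert np.array_equal(got.coordinates, expected.coordinates)


# -- query_subsystem --------------------------------------------------------


def test_query_identity_when_everything_is_in_reach(rng):
    coords = rng.uniform(-4, 4, size=(3, 20, 3))
    slc = make_slice(coords)
    spec = build_grid((0, 0, 0), (10, 10, 10), 1.0, 2.5)
    out = query_subsystem(slc, "all", spec, include_environment=100.0)
    assert out.n_atoms == 20
    for a, b in zip(out.frames, slc.frames):
        assert np.array_equal(a.coordinates, b.coordinates)


def test_query_excludes_far_atom_and_features_see_zero_weight_set():
    coords = np.zeros((2, 3, 3))
    coords[:, 0] = [0.0, 0.0, 0.0]
    coords[:, 1] = [1.0, 1.0, 1.0]
    coords[:, 2] = [50.0, 0.0, 0.0]  # far beyond pad + environment in every frame
    topology = make_topology(3, parts=[1, 1, 0])
    slc = make_slice(coords, topology)
    spec = build_grid((0, 0, 0), (8, 8, 8), 1.0, 2.5)
    out = query_subsystem(slc, "part:1", spec, include_environment=1.0)
    assert out.n_atoms == 2
    assert np.array_equal(out.source_indices, [0, 1])


def test_query_membership_matches_brute_force_box_test(rng):
    coords = rng.uniform(-12, 12, size=(4, 50, 3))
    topology = make_topology(50, parts=[1] * 5 + [0] * 45)
    slc = make_slice(coords, topology)
    spec = build_grid((0, 0, 0), (8, 8, 8), 1.0, 2.5)
    env = 2.0
    out = query_subsystem(slc, "part:1", spec, include_environment=env)

    lower, upper = spec.box_bounds(padded=True)
    expected = set(range(5))  # focus atoms
    for a in range(50):
        for t in range(4):
            clamped = np.clip(coords[t, a], lower, upper)
            if np.linalg.norm(coords[t, a] - clamped) <= env:
                expected.add(a)
                break
    assert set(out.source_indices.tolist()) == expected
    # ordering preserved
    assert np.array_equal(out.source_indices, np.sort(out.source_indices))


def test_query_is_idempotent(rng):
    coords = rng.uniform(-10, 10, size=(3, 40, 3))
    topology = make_topology(40, parts=[1] * 4 + [0] * 36)
    slc = make_slice(coords, topology)
    spec = build_grid((0, 0, 0), (8, 8, 8), 1.0, 2.5)
    once = query_subsystem(slc, "part:1", spec, include_environment=1.5)
    twice = query_subsystem(once, "part:1", spec, include_environment=1.5)
    assert twice.n_atoms == once.n_atoms
    assert np.array_equal(twice.source_indices, once.source_indices)
    for a, b in zip(twice.frames, once.frames):
        assert np.array_equal(a.coordinates, b.coordinates)
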