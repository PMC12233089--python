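import numpy as np
import pytest

from voxtraj import (
    ConfigurationError,
    FeatureRequest,
    FeatureStore,
    Featurizer,
    RegistrationError,
    RunManifest,
    SyntheticSpec,
    TrajectorySource,
    generate,
    run_manifest,
    write_trajectory,
)


@pytest.fixture(scope="module")
def traj_files(tmp_path_factory):
    out = tmp_path_factory.mktemp("traj")
    spec = SyntheticSpec(n_atoms=60, n_frames=20, seed=21, ligand_fraction=0.2, box=(12, 12, 12))
    pdb, xyz = write_trajectory(*generate(spec), str(out))
    return pdb, xyz


def base_features(window=5):
    return [
        FeatureRequest(kind="static", tag="static_mass", channel="mass", window=window),
        FeatureRequest(kind="pdf", tag="pdf_u_std", channel="uniform", aggregator="std", window=window),
        FeatureRequest(
            kind="obs", tag="obs_lig_mean", channel="part_annotation",
            observable="direct_count", aggregator="mean", window=window,
        ),
    ]


def make_manifest(traj_files, out_path, features=None, n_traj=1, labels=None, **kwargs):
    pdb, xyz = traj_files
    return RunManifest(
        trajectories=[
            TrajectorySource(f"t{i}", pdb, xyz, "xyz") for i in range(n_traj)
        ],
        features=features if features is not None else base_features(),
        output=str(out_path),
        focus="part:1",
        grid_dims=(8, 8, 8),
        labels=labels or {},
        **kwargs,
    )


def test_buffer_covers_the_largest_feature_reach(traj_files, tmp_path):
    features = base_features()
    features[2].radius = 4.0
    manifest = make_manifest(traj_files, tmp_path / "o.h5", features)
    assert Featurizer(manifest).pad_distance == 4.0


def test_duplicate_tag_is_a_registration_error(traj_files, tmp_path):
    features = base_features() + [FeatureRequest(kind="static", tag="static_mass")]
    with pytest.raises(RegistrationError):
        Featurizer(make_manifest(traj_files, tmp_path / "o.h5", features))


def test_empty_run_is_an_error(traj_files, tmp_path):
    with pytest.raises(RegistrationError):
        Featurizer(make_manifest(traj_files, tmp_path / "o.h5", features=[])).run()


def test_record_counts_are_floor_t_over_w_per_tag(traj_files, tmp_path):
    # T = 20, W = 5 -> 4 records for each registered feature
    path = run_manifest(make_manifest(traj_files, tmp_path / "o.h5"))
    with FeatureStore(path) as store:
        for tag in ("static_mass", "pdf_u_std", "obs_lig_mean"):
            assert store.n_records(tag) == 4
            assert store._file[tag].shape[1:] == (8, 8, 8)


def test_two_identical_trajectories_double_the_records(traj_files, tmp_path):
    path = run_manifest(make_manifest(traj_files, tmp_path / "o.h5", n_traj=2))
    with FeatureStore(path) as store:
        for tag in ("static_mass", "pdf_u_std", "obs_lig_mean"):
            data = np.asarray(store._file[tag][...])
            assert data.shape[0] == 8
            assert np.array_equal(data[:4], data[4:])  # determinism across copies


def test_rerunning_a_manifest_is_byte_identical(traj_files, tmp_path):
    path_a = run_manifest(make_manifest(traj_files, tmp_path / "a.h5"))
    path_b = run_manifest(make_manifest(traj_files, tmp_path / "b.h5"))
    with FeatureStore(path_a) as sa, FeatureStore(path_b) as sb:
        assert sa.tags() == sb.tags()
        for tag in sa.tags():
            assert np.array_equal(sa._file[tag][...], sb._file[tag][...])


def test_feature_independence(traj_files, tmp_path):
    """Removing one request leaves every other tag's output unchanged."""
    full = run_manifest(make_manifest(traj_files, tmp_path / "full.h5"))
    reduced = run_manifest(
        make_manifest(traj_files, tmp_path / "reduced.h5", features=base_features()[:2])
    )
    with FeatureStore(full) as sf, FeatureStore(reduced) as sr:
        for tag in ("static_mass", "pdf_u_std"):
            assert np.array_equal(sf._file[tag][...], sr._file[tag][...])


def test_mixed_windows_account_separately(traj_files, tmp_path):
    features = [
        FeatureRequest(kind="static", tag="s1", channel="uniform", window=1),
        FeatureRequest(kind="pdf", tag="p7", channel="uniform", aggregator="mean", window=7),
    ]
    path = run_manifest(make_manifest(traj_files, tmp_path / "o.h5", features))
    with FeatureStore(path) as store:
        assert store.n_records("s1") == 20  # T=20, W=1
        assert store.n_records("p7") == 2  # floor(20/7)


def test_label_broadcast_to_every_slice(traj_files, tmp_path):
    features = base_features() + [FeatureRequest(kind="label", tag="affinity", window=5)]
    manifest = make_manifest(
        traj_files, tmp_path / "o.h5", features, labels={"t0": 7.2}
    )
    path = run_manifest(manifest)
    with FeatureStore(path) as store:
        labels = np.asarray(store._file["affinity"][...])
        assert np.array_equal(labels, np.full(4, np.float32(7.2)))


def test_missing_label_strict_mode_skips_slice_with_record(traj_files, tmp_path):
    features = base_features() + [FeatureRequest(kind="label", tag="affinity", window=5)]
    manifest = make_manifest(
        traj_files, tmp_path / "o.h5", features, n_traj=2,
        labels={"t0": 1.5}, label_mode="strict",
    )
    path = run_manifest(manifest)
    with FeatureStore(path) as store:
        # strict mode raises inside the per-slice isolation: t1 slices are
        # recorded as skipped rather than silently dropped
        assert store.n_records("affinity") == 4
        skipped = np.asarray(store._file["skipped"][...])
        assert skipped.shape[0] == 4 and set(skipped[:, 0]) == {1}
        # the failed slices contributed no grid records either
        assert store.n_records("static_mass") == 4


def test_missing_label_lenient_mode_records_alignment(traj_files, tmp_path):
    features = base_features() + [FeatureRequest(kind="label", tag="affinity", window=5)]
    manifest = make_manifest(
        traj_files, tmp_path / "o.h5", features, n_traj=2, labels={"t1": 3.0}
    )
    path = run_manifest(manifest)
    with FeatureStore(path) as store:
        assert store.n_records("affinity") == 4  # only the labeled trajectory
        align = np.asarray(store._file["affinity_index"][...])
        assert np.array_equal(align[:, 0], [1, 1, 1, 1])
        assert np.array_equal(align[:, 1], [0, 1, 2, 3])
        # grid features are unaffected by the missing label
        assert store.n_records("static_mass") == 8


def test_fixed_grid_center_and_geometry_attrs(traj_files, tmp_path):
    manifest = make_manifest(traj_files, tmp_path / "o.h5", grid_center=(0.0, 0.0, 0.0))
    path = run_manifest(manifest)
    with FeatureStore(path) as store:
        assert store.attrs["resolution"] == 1.0
        assert list(store.attrs["dims"]) == [8, 8, 8]
        assert store.attrs["buffer_voxels"] == 3  # ceil(2.5 / 1.0)
        assert store._file["static_mass"].attrs["cutoff"] == 2.5


def test_manifest_dict_round_trip(traj_files, tmp_path):
    pdb, xyz = traj_files
    config = {
        "trajectories": [{"id": "t0", "topology": pdb, "coordinates": xyz, "format": "xyz"}],
        "focus": "part:1",
        "grid": {"dims": [8, 8, 8], "resolution": 1.0, "center": "auto"},
        "features": [
            {"kind": "static", "tag": "s", "channel": "mass", "window": 5},
        ],
        "output": str(tmp_path / "o.h5"),
        "seed": 3,
    }
    manifest = RunManifest.from_dict(config)
    assert manifest.grid_dims == (8, 8, 8)
    assert manifest.canonical_hash() == RunManifest.from_dict(config).canonical_hash()
    path = run_manifest(manifest)
    with FeatureStore(path) as store:
        assert store.n_records("s") == 4

    with pytest.raises(ConfigurationError):
        RunManifest.from_dict({"output": "x.h5", "bogus_key": 1})


def test_unknown_channel_rejected_at_hook_time(traj_files, tmp_path):
    features = [FeatureRequest(kind="static", tag="s", channel="bogus")]
    with pytest.raises(RegistrationError):
        Featurizer(make_manifest(traj_files, tmp_path / "o.h5", features))
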