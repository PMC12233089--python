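import numpy as np
import pytest

from conftest import make_slice, make_topology
from oracles import loop_observe
from voxtraj import (
    ConfigurationError,
    InvalidArgumentError,
    ObserverParams,
    build_grid,
    obs_feature,
    observe_frame,
    register_observable,
)

OBSERVABLES = ("existence", "direct_count", "distinct_count", "mean_distance", "radius_of_gyration")
SPEC = build_grid((0, 0, 0), (6, 6, 6), 1.0, 2.5)


def observer_centered_spec():
    # odd grid centered at the origin: the (2, 2, 2) voxel center is (0, 0, 0)
    return build_grid((0.0, 0.0, 0.0), (5, 5, 5), 1.0, 2.5)


@pytest.mark.parametrize("observable", OBSERVABLES)
def test_empty_field_guard_values(observable):
    obs = ObserverParams(radius=2.0, observable=observable)
    out = observe_frame(np.empty((0, 3)), np.empty(0), SPEC, obs)
    assert np.all(out == 0.0)


def test_single_atom_closed_forms():
    spec = observer_centered_spec()
    coords = np.array([[1.5, 0.0, 0.0]])  # 1.5 Å from the origin observer
    w = np.ones(1)
    center_idx = (2, 2, 2)  # observer at (0, 0, 0)
    md = observe_frame(coords, w, spec, ObserverParams(2.5, "mean_distance"))
    rg = observe_frame(coords, w, spec, ObserverParams(2.5, "radius_of_gyration"))
    ct = observe_frame(coords, w, spec, ObserverParams(2.5, "direct_count"))
    ex = observe_frame(coords, w, spec, ObserverParams(2.5, "existence"))
    assert md[center_idx] == pytest.approx(1.5, rel=1e-12)
    assert rg[center_idx] == pytest.approx(0.0, abs=1e-9)
    assert ct[center_idx] == 1.0
    assert ex[center_idx] == 1.0


def test_two_unit_atoms_two_angstroms_apart_have_rg_one():
    spec = observer_centered_spec()
    coords = np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
    rg = observe_frame(coords, np.ones(2), spec, ObserverParams(2.5, "radius_of_gyration"))
    assert rg[2, 2, 2] == pytest.approx(1.0, rel=1e-12)


@pytest.mark.parametrize("observable", OBSERVABLES)
def test_matches_naive_per_gridpoint_scan(observable, rng):
    params = ObserverParams(radius=1.8, observable=observable, weight_channel="uniform")
    spec = build_grid((0.3, -0.2, 0.1), (5, 4, 6), 0.9, params.radius)
    coords = rng.uniform(-3, 3, size=(40, 3))
    # integer-like weights incl. zeros so masks and distinct values are exercised
    weights = rng.integers(0, 4, size=40).astype(float)
    got = observe_frame(coords, weights, spec, params)
    expected = loop_observe(coords, weights, spec.centers(), params.radius, observable)
    if observable in ("existence", "direct_count", "distinct_count"):
        assert np.array_equal(got, expected)
    else:
        np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-12)


def test_count_observables_are_nonnegative_integers(rng):
    coords = rng.uniform(-3, 3, size=(60, 3))
    weights = rng.integers(0, 3, size=60).astype(float)
    for observable in ("existence", "direct_count", "distinct_count"):
        out = observe_frame(coords, weights, SPEC, ObserverParams(2.0, observable))
        assert np.all(out >= 0) and np.array_equal(out, np.round(out))


def test_count_bounds_pointwise(rng):
    coords = rng.uniform(-3, 3, size=(50, 3))
    weights = rng.integers(0, 5, size=50).astype(float)
    ex = observe_frame(coords, weights, SPEC, ObserverParams(2.0, "existence"))
    ct = observe_frame(coords, weights, SPEC, ObserverParams(2.0, "direct_count"))
    dc = observe_frame(coords, weights, SPEC, ObserverParams(2.0, "distinct_count"))
    assert np.all(ex <= ct)
    assert np.all(dc <= ct)


def test_discrete_jump_when_an_atom_crosses_the_cutoff():
    spec = observer_centered_spec()
    radius = 2.0
    eps = 1e-3
    before = observe_frame(
        np.array([[radius - eps, 0.0, 0.0]]), np.ones(1), spec, ObserverParams(radius, "direct_count")
    )
    after = observe_frame(
        np.array([[radius + eps, 0.0, 0.0]]), np.ones(1), spec, ObserverParams(radius, "direct_count")
    )
    diff = before - after
    assert set(np.unique(diff)) <= {0.0, 1.0, -1.0}
    # only observers within radius of the atom's path may change
    centers = spec.centers()
    d_path = np.minimum(
        np.linalg.norm(centers - [radius - eps, 0, 0], axis=-1),
        np.linalg.norm(centers - [radius + eps, 0, 0], axis=-1),
    )
    assert np.all(diff[d_path > radius] == 0.0)
    assert diff[2, 2, 2] == 1.0  # the origin observer loses exactly one atom


def test_atom_permutation_invariance(rng):
    coords = rng.uniform(-3, 3, size=(30, 3))
    weights = rng.uniform(0.1, 2.0, size=30)
    perm = rng.permutation(30)
    for observable in OBSERVABLES:
        obs = ObserverParams(2.2, observable)
        a = observe_frame(coords, weights, SPEC, obs)
        b = observe_frame(coords[perm], weights[perm], SPEC, obs)
        np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-12)


def test_zero_weight_atoms_act_as_mask_for_counts():
    spec = observer_centered_spec()
    coords = np.array([[0.5, 0.0, 0.0], [-0.5, 0.0, 0.0]])
    masked = observe_frame(coords, np.array([1.0, 0.0]), spec, ObserverParams(2.0, "direct_count"))
    assert masked[2, 2, 2] == 1.0
    uniform = observe_frame(coords, np.ones(2), spec, ObserverParams(2.0, "direct_count"))
    assert uniform[2, 2, 2] == 2.0


def test_radius_exceeding_buffer_is_a_configuration_error(rng):
    spec = build_grid((0, 0, 0), (6, 6, 6), 1.0, 1.0)
    with pytest.raises(ConfigurationError):
        observe_frame(rng.uniform(-2, 2, (5, 3)), np.ones(5), spec, ObserverParams(3.0))


def test_unknown_observable_rejected():
    with pytest.raises(InvalidArgumentError):
        ObserverParams(observable="velocity_flux")


# -- slice-level features ---------------------------------------------------


def test_frozen_trajectory_observation_std_is_zero(rng):
    coords = np.repeat(rng.uniform(-2, 2, size=(1, 10, 3)), 5, axis=0)
    slc = make_slice(coords)
    grid = obs_feature(slc, ObserverParams(2.0, "direct_count"), SPEC, agg="std")
    assert np.all(grid.values == 0.0)


def test_mean_ligand_count_matches_oracle_chain(rng):
    """Ligand-annotation weights + direct_count + mean = the average count
    of ligand particles near each observer."""
    coords = rng.uniform(-2.5, 2.5, size=(4, 12, 3))
    topology = make_topology(12, parts=[1] * 5 + [0] * 7)
    slc = make_slice(coords, topology)
    obs = ObserverParams(2.0, "direct_count", weight_channel="part_annotation")
    got = obs_feature(slc, obs, SPEC, agg="mean")
    per_frame = [
        loop_observe(coords[t], topology.part_annotation.astype(float), SPEC.centers(), 2.0, "direct_count")
        for t in range(4)
    ]
    np.testing.assert_allclose(got.values, np.mean(per_frame, axis=0), rtol=1e-12, atol=1e-12)
    assert got.channel_tag == "part_annotation.direct_count.mean"


def test_mass_weighted_distance_variability_matches_oracle_chain(rng):
    """Mass weights + mean_distance + std = variability of the mass-weighted
    distance of particles to each observer."""
    from voxtraj import cache_properties

    coords = rng.uniform(-2.5, 2.5, size=(5, 10, 3))
    slc = make_slice(coords)
    masses = cache_properties(slc.topology).channel("mass")
    got = obs_feature(slc, ObserverParams(2.2, "mean_distance", "mass"), SPEC, agg="std")
    per_frame = np.stack(
        [loop_observe(coords[t], masses, SPEC.centers(), 2.2, "mean_distance") for t in range(5)]
    )
    np.testing.assert_allclose(got.values, np.std(per_frame, axis=0, ddof=1), rtol=1e-10, atol=1e-12)


def test_custom_observable_registration(rng):
    register_observable("max_weight", lambda pos, w, point: float(w.max()) if len(w) else 0.0)
    coords = rng.uniform(-2, 2, size=(8, 3))
    weights = rng.uniform(0.5, 3.0, size=8)
    out = observe_frame(coords, weights, SPEC, ObserverParams(2.0, "max_weight"))
    expected = loop_observe(coords, weights, SPEC.centers(), 2.0, "direct_count")
    assert np.all((out > 0) == (expected >= 1))
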