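"""RDFs, N-H distributions, rocking modes and Pearson correlations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import shblab as sl
from shblab.shb_model import IDX_N

CELL = sl.SimulationCell(12.0, 12.0, 12.0)


def test_rdf_ideal_gas_is_flat():
    """g(r) of uniform random points around one center is 1 within 5%
    (statistics pooled over frames so every shell is well populated)."""
    rng = np.random.default_rng(20)
    n_pts, n_frames = 10_000, 100
    species = ["O"] + ["Ar"] * n_pts
    pos = np.concatenate(
        [np.full((n_frames, 1, 3), 6.0), rng.uniform(0, 12, (n_frames, n_pts, 3))],
        axis=1,
    )
    traj = sl.Trajectory(species, pos, CELL)
    g = sl.rdf(traj, centers=[0], others=list(range(1, n_pts + 1)), r_max=5.5, dr_bin=0.25)
    mask = g.r_centers > 1.0
    assert np.max(np.abs(g.g_values[mask] - 1.0)) < 0.05


def test_rdf_single_pair_single_bin():
    traj = sl.Trajectory(
        ["O", "N"], np.array([[[3.0, 3, 3], [3.0, 3, 5.5]]]), CELL
    )
    g = sl.rdf(traj, [0], [1], r_max=5.0, dr_bin=0.1)
    nz = np.nonzero(g.g_values)[0]
    assert len(nz) == 1
    assert g.r_centers[nz[0]] == pytest.approx(2.55, abs=0.051)


def test_rdf_r_max_validation():
    traj = sl.Trajectory(["O", "N"], np.zeros((1, 2, 3)), CELL)
    with pytest.raises(ValueError):
        sl.rdf(traj, [0], [1], r_max=7.0)


def test_rdf_normalization_matches_neighbor_count():
    """integral of g * rho * 4 pi r^2 dr over r < r_max equals the mean
    neighbor count within r_max."""
    rng = np.random.default_rng(21)
    n_pts = 3000
    species = ["N"] + ["O"] * n_pts
    pos = np.concatenate(
        [np.full((1, 1, 3), 6.0), rng.uniform(0, 12, (1, n_pts, 3))], axis=1
    )
    traj = sl.Trajectory(species, pos, CELL)
    r_max = 4.0
    g = sl.rdf(traj, [0], list(range(1, n_pts + 1)), r_max=r_max, dr_bin=0.1)
    density = n_pts / CELL.volume
    integral = np.sum(g.g_values * density * 4 * np.pi * g.r_centers**2 * g.dr_bin)
    count = sl.neighbor_count(traj[0], 0, "O", r_max)
    assert integral == pytest.approx(count, rel=1e-9)


def test_rdf_peak_asymmetry_classical(classical_run, classical_shb):
    """The ammonium sits nearer the donor oxygen, so the donor-N RDF peaks
    at shorter distance than the acceptor-N RDF."""
    n_index = classical_run.species.index("N")
    g_don = sl.rdf(classical_run, [classical_shb.donor_O], [n_index], r_max=5.0)
    g_acc = sl.rdf(classical_run, [classical_shb.acceptor_O], [n_index], r_max=5.0)
    assert g_don.first_peak() < g_acc.first_peak()


def test_nh_rest_fixture_is_delta(params, pyro_fixture):
    from shblab.shb_model import ModelState

    rest = sl.state_to_frame(ModelState.rest(params), params, pyro_fixture)
    traj = sl.Trajectory(rest.species, rest.positions[None], rest.cell)
    lengths = sl.nh_bond_lengths(traj)
    assert len(lengths) == 4
    np.testing.assert_allclose(lengths, params.r_NH0_A, atol=1e-9)


def test_nh_mean_near_rest_both_ensembles(classical_run, quantum_run, params):
    for traj in (classical_run, quantum_run):
        lengths = sl.nh_bond_lengths(traj)
        assert np.mean(lengths) == pytest.approx(params.r_NH0_A, abs=0.01)


def test_nh_quantum_broader_than_classical(classical_run, quantum_run):
    assert sl.nh_bond_lengths(quantum_run).std() > sl.nh_bond_lengths(classical_run).std()


def test_nh_malformed_frame_raises(pyro_fixture):
    pos = pyro_fixture.positions.copy()
    pos[6] += 5.0  # displace one ammonium hydrogen far away
    traj = sl.Trajectory(pyro_fixture.species, pos[None], pyro_fixture.cell)
    with pytest.raises(ValueError, match="frame 0"):
        sl.nh_bond_lengths(traj)


def test_rocking_modes_static_antisymmetric(pyro_fixture, tracked_sites):
    traj = sl.Trajectory(
        pyro_fixture.species, np.repeat(pyro_fixture.positions[None], 5, axis=0),
        pyro_fixture.cell,
    )
    rock = sl.rocking_modes(traj, IDX_N, tracked_sites)
    assert rock.n_sites == 12
    assert len(rock.pairs()) == 66
    for (i, j) in rock.pairs()[:10]:
        np.testing.assert_allclose(rock.pair_series(i, j), -rock.pair_series(j, i))
    # static fixture -> constant series
    assert np.all(rock.d.std(axis=1) < 1e-12)


def test_rocking_modes_need_two_sites(classical_run):
    with pytest.raises(ValueError):
        sl.rocking_modes(classical_run, IDX_N, [0])


def test_pearson_examples():
    rng = np.random.default_rng(22)
    a = rng.normal(size=1000)
    assert sl.pearson(a, a) == pytest.approx(1.0)
    assert sl.pearson(a, -2 * a + 3) == pytest.approx(-1.0)
    x = rng.normal(size=100_000)
    y = rng.normal(size=100_000)
    assert abs(sl.pearson(x, y)) < 0.01
    with pytest.raises(ValueError):
        sl.pearson(a, np.full(1000, 2.0))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    alpha=st.floats(-3, 3).filter(lambda a: abs(a) > 1e-3),
    beta=st.floats(-5, 5),
)
def test_pearson_affine_invariance(alpha, beta):
    rng = np.random.default_rng(23)
    a = rng.normal(size=500)
    b = rng.normal(size=500) + 0.5 * a
    rho = sl.pearson(a, b)
    rho2 = sl.pearson(alpha * a + beta, b)
    assert rho2 == pytest.approx(np.sign(alpha) * rho, abs=1e-9)


def test_correlation_matrix_agrees_with_direct_pearson(
    classical_run, classical_shb, tracked_sites
):
    """The covariance-algebra shortcut equals pairwise pearson calls."""
    dr = sl.delta_r_series(classical_run, classical_shb)[:20_000]
    rock = sl.rocking_modes(classical_run, IDX_N, tracked_sites)
    sub = sl.RockingModes(rock.d[:, :20_000], rock.site_labels, rock.atom_indices)
    corr = sl.correlation_matrix(dr, sub)
    for k in (0, 7, 33, 65):
        i, j = corr.pair_labels[k]
        ii, jj = i - 1, j - 1
        direct = sl.pearson(dr, sub.pair_series(ii, jj))
        assert corr.rho[k] == pytest.approx(direct, abs=1e-9)


def test_correlation_shuffled_dr_vanishes(classical_run, classical_shb, tracked_sites):
    rng = np.random.default_rng(24)
    dr = sl.delta_r_series(classical_run, classical_shb)
    rock = sl.rocking_modes(classical_run, IDX_N, tracked_sites)
    corr = sl.correlation_matrix(rng.permutation(dr), rock)
    assert corr.max_abs_rho < 0.01


def test_shb_aligned_pairs_include_shb_axis_pair(pyro_fixture, tracked_sites, classical_run):
    rock = sl.rocking_modes(classical_run, IDX_N, tracked_sites)
    aligned = sl.shb_aligned_pairs(pyro_fixture, rock)
    donor_label = tracked_sites.index(0) + 1
    acceptor_label = tracked_sites.index(1) + 1
    assert tuple(sorted((donor_label, acceptor_label))) in {
        tuple(sorted(p)) for p in aligned
    }


def test_neighbor_count_cases(pyro_fixture):
    assert sl.neighbor_count(pyro_fixture, IDX_N, "O", 5.0) == 12
    assert sl.neighbor_count(pyro_fixture, IDX_N, "O", 0.1) == 0
    assert sl.neighbor_count(pyro_fixture, IDX_N, "Zn", 5.0) == 0
    with pytest.raises(ValueError):
        sl.neighbor_count(pyro_fixture, IDX_N, "O", 8.0)
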