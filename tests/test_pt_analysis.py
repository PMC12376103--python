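"""SHB detection, the PT coordinate, Boltzmann inversion and block errors."""

import numpy as np
import pytest

import shblab as sl
from shblab.units import kT

CELL = sl.SimulationCell(20.0, 20.0, 20.0)
KT300_MEV = kT(300.0) * 1000.0


def _frame(species, pos):
    return sl.Frame(species, np.asarray(pos, dtype=float), CELL)


def test_detect_shb_tie_break_lower_index():
    f = _frame(["O", "O", "H"], [[0, 0, 0], [2.5, 0, 0], [1.25, 0, 0]])
    (t,) = sl.detect_shb(f)
    assert t.donor_O == 0 and t.acceptor_O == 1


def test_detect_shb_no_triple_beyond_cutoffs():
    f = _frame(["O", "O", "H"], [[0, 0, 0], [2.8, 0, 0], [1.0, 0, 0]])
    assert sl.detect_shb(f) == []


def test_delta_r_arithmetic_and_antisymmetry():
    f = _frame(["O", "O", "H"], [[0, 0, 0], [2.5, 0, 0], [1.0, 0, 0]])
    shb = sl.SHBTriple(0, 1, 2)
    assert sl.delta_r(f, shb) == pytest.approx(-0.5)
    swapped = sl.SHBTriple(1, 0, 2)
    assert sl.delta_r(f, swapped) == pytest.approx(+0.5)
    f_mid = _frame(["O", "O", "H"], [[0, 0, 0], [2.5, 0, 0], [1.25, 0, 0]])
    assert sl.delta_r(f_mid, shb) == pytest.approx(0.0)


def test_free_energy_two_state_closed_form():
    """Populations (p, 1-p) produce Delta F = kBT ln(p/(1-p)) exactly."""
    p = 0.731
    n = 100_000
    series = np.concatenate([
        np.full(int(n * p), -0.3), np.full(n - int(n * p), +0.3)
    ])
    prof = sl.free_energy_profile(series, 300.0)
    finite = np.isfinite(prof.F_meV)
    assert finite.sum() == 2
    dF = abs(np.diff(prof.F_meV[finite])[0])
    expected = KT300_MEV * np.log(int(n * p) / (n - int(n * p)))
    assert dF == pytest.approx(expected, abs=1e-9)
    assert expected == pytest.approx(25.9, abs=0.15)
    # equal populations -> zero free-energy difference
    series = np.concatenate([np.full(500, -0.3), np.full(500, 0.3)])
    prof = sl.free_energy_profile(series, 300.0)
    assert abs(np.diff(prof.F_meV[np.isfinite(prof.F_meV)])[0]) == 0.0


def test_free_energy_flat_for_equal_counts():
    centers = np.linspace(-0.79, 0.79, 81) + 1e-4  # one value per bin
    series = np.tile(centers, 100)
    prof = sl.free_energy_profile(series, 300.0)
    assert np.nanmax(np.abs(prof.F_meV)) == 0.0


def test_free_energy_empty_series_and_gauge():
    with pytest.raises(ValueError):
        sl.free_energy_profile(np.array([]), 300.0)
    rng = np.random.default_rng(0)
    prof = sl.free_energy_profile(rng.normal(0, 0.2, 10_000), 300.0)
    assert np.nanmin(prof.F_meV) == 0.0  # gauge fixed
    assert np.isnan(prof.F_meV[0])  # empty tail bins undefined, not zero


def test_block_errors_constant_series():
    err = sl.block_errors(np.full(10_000, 0.1), dt_fs=0.5, T_K=300.0)
    finite = err[np.isfinite(err)]
    assert len(finite) == 1 and finite[0] == 0.0


def test_block_errors_iid_matches_multinomial():
    """For i.i.d. samples, block errors agree with the analytic multinomial
    standard error within 20% in well-populated bins."""
    rng = np.random.default_rng(12)
    n = 200_000
    series = rng.normal(0.0, 0.2, n)
    err = sl.block_errors(series, dt_fs=0.5, T_K=300.0)
    counts, edges = np.histogram(series, bins=81, range=(-0.8, 0.8))
    p = counts / n
    ok = p > 0.005
    naive = KT300_MEV / 1000 * 1000 * np.sqrt((1 - p[ok]) / (n * p[ok]))
    ratio = err[ok] / naive
    assert np.median(ratio) == pytest.approx(1.0, abs=0.2)


def test_block_errors_autocorrelated_exceed_naive():
    """An AR(1) series with phi = 0.99 has block errors well above the
    naive i.i.d. estimate."""
    rng = np.random.default_rng(13)
    n = 100_000
    phi = 0.99
    eps = rng.normal(0, 0.2 * np.sqrt(1 - phi**2), n)
    x = np.empty(n)
    x[0] = 0.0
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    err = sl.block_errors(x, dt_fs=0.5, T_K=300.0)
    counts, _ = np.histogram(x, bins=81, range=(-0.8, 0.8))
    p = counts / n
    ok = p > 0.01
    naive = KT300_MEV * np.sqrt((1 - p[ok]) / (n * p[ok]))
    assert np.median(err[ok] / naive) > 1.5


def test_block_errors_requires_two_blocks():
    with pytest.raises(ValueError):
        sl.block_errors(np.zeros(50), dt_fs=0.5, T_K=300.0, block_fs=50.0)


def test_barrier_synthetic_double_well():
    centers = np.linspace(-0.8, 0.8, 81)
    F = np.where(np.abs(centers) < 0.6, 30.0 * ((centers / 0.4) ** 2 - 1) ** 2, np.nan)
    prof = sl.FreeEnergyProfile(centers, F, None, 300.0, 1000)
    barrier, asym, n_min = sl.barrier_and_asymmetry(prof)
    assert n_min == 2
    assert barrier == pytest.approx(30.0, abs=1.5)  # median smoothing flattens the peak
    assert asym == pytest.approx(0.0, abs=1e-9)


def test_barrier_single_parabola():
    centers = np.linspace(-0.8, 0.8, 81)
    prof = sl.FreeEnergyProfile(centers, 100 * centers**2, None, 300.0, 1000)
    assert sl.barrier_and_asymmetry(prof) == (0.0, 0.0, 1)


def test_joint_independent_series_uncorrelated():
    rng = np.random.default_rng(14)
    n = 100_000
    joint = sl.joint_dr_R(rng.normal(0, 0.2, n), rng.normal(2.5, 0.05, n))
    assert abs(joint.rho_abs_dr_R) < 0.05
    assert joint.counts.sum() <= n


def test_joint_length_mismatch():
    with pytest.raises(ValueError):
        sl.joint_dr_R(np.zeros(10), np.zeros(11))


def test_classical_transfer_coincides_with_compression(classical_run, classical_shb):
    """Classically |delta_r| and R rise and fall together (the transition
    state is compressed and the wells widen with R), so rho(|dr|, R) > 0;
    quantum delocalization weakens the coupling."""
    dr = sl.delta_r_series(classical_run, classical_shb)
    R = sl.R_series(classical_run, classical_shb)
    joint = sl.joint_dr_R(dr, R)
    assert joint.rho_abs_dr_R > 0.1


def test_quantum_weakens_compression_coupling(
    classical_run, classical_shb, quantum_run, quantum_shb
):
    j_cl = sl.joint_dr_R(
        sl.delta_r_series(classical_run, classical_shb),
        sl.R_series(classical_run, classical_shb),
    )
    j_q = sl.joint_dr_R(
        sl.delta_r_series(quantum_run, quantum_shb),
        sl.R_series(quantum_run, quantum_shb),
    )
    assert abs(j_q.rho_abs_dr_R) < abs(j_cl.rho_abs_dr_R)


def test_bead_pooling_equals_average_of_bead_histograms(quantum_run, quantum_shb):
    """Pooling all bead series and histogramming equals averaging the
    per-bead histograms (exact identity for equal-length beads)."""
    dr = sl.delta_r_series(quantum_run, quantum_shb)
    pooled, edges = np.histogram(dr, bins=81, range=(-0.8, 0.8))
    per_bead = []
    for k in range(quantum_run.n_beads):
        drk = sl.delta_r_series(quantum_run.bead(k), quantum_shb)
        per_bead.append(np.histogram(drk, bins=81, range=(-0.8, 0.8))[0])
    np.testing.assert_array_equal(pooled, np.sum(per_bead, axis=0))


def test_profile_recovers_known_potential():
    """Boltzmann inversion of rejection-sampled draws from a known 1D
    potential recovers that potential within twice the block error in every
    bin holding at least 100 counts."""
    rng = np.random.default_rng(15)
    beta = 1.0 / kT(300.0)

    def v(x):  # quartic double well, eV
        return 0.030 * ((x / 0.3) ** 2 - 1) ** 2

    lo, hi = -0.75, 0.75
    vmax = np.exp(-beta * 0.0)
    samples = []
    while sum(len(s) for s in samples) < 400_000:
        x = rng.uniform(lo, hi, 100_000)
        keep = rng.uniform(0, vmax, 100_000) < np.exp(-beta * v(x))
        samples.append(x[keep])
    x = np.concatenate(samples)
    prof = sl.free_energy_profile(x, 300.0)
    err = sl.block_errors(x, dt_fs=0.5, T_K=300.0)
    counts, edges = np.histogram(x, bins=81, range=(-0.8, 0.8))
    ok = counts >= 100
    # oracle: bin-integrated Boltzmann weight (what a histogram estimates)
    grid = np.linspace(-0.8, 0.8, 81 * 50 + 1)
    w = np.exp(-v(grid) / kT(300.0))
    f_bin = np.array([
        -KT300_MEV * np.log(np.trapezoid(w[(grid >= lo) & (grid <= hi)],
                                         grid[(grid >= lo) & (grid <= hi)]))
        for lo, hi in zip(edges[:-1], edges[1:])
    ])
    f_bin -= f_bin[ok & np.isfinite(prof.F_meV)].min()
    diff = np.abs(prof.F_meV[ok] - f_bin[ok])
    # 2-sigma nominal coverage (~95%) up to finite-bin fluctuation; 3-sigma envelope strict
    assert np.mean(diff <= 2.0 * err[ok] + 0.5) >= 0.93
    assert np.all(diff <= 3.0 * err[ok] + 0.5)
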