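"""Sampler correctness: equipartition, finite-P oracles, detailed balance,
determinism, and Wannier emission."""

import numpy as np
import pytest
from scipy import stats as sps

import shblab as sl
from shblab.shb_model import IDX_H_SHB, ModelState
from shblab.units import HBAR_EV_FS, AMU_TO_EV_FS2_PER_A2, kT

T = 300.0
M_H = 1.008


def test_classical_equipartition_harmonic():
    """P=1 sampling of a harmonic well reproduces <x^2> = kBT/(m w^2)
    within 2%."""
    w = 0.3
    rec = sl.sample_pimc_harmonic(1, T, M_H, w, n_sweeps=2_000_000, seed=2)
    expected = kT(T) / (M_H * AMU_TO_EV_FS2_PER_A2 * w * w)
    assert np.mean(rec**2) == pytest.approx(expected, rel=0.02)


def test_harmonic_oracle_limits():
    w = 0.5
    # classical limit
    assert sl.harmonic_pimc_oracle(1, T, M_H, w) == pytest.approx(
        kT(T) / (M_H * AMU_TO_EV_FS2_PER_A2 * w * w), rel=1e-12
    )
    # quantum limit at beta*hbar*w = 5: P=64 within 2% of the coth form
    w5 = 5.0 * kT(T) / HBAR_EV_FS
    m = M_H * AMU_TO_EV_FS2_PER_A2
    exact = HBAR_EV_FS / (2 * m * w5) / np.tanh(5.0 / 2)
    assert sl.harmonic_pimc_oracle(64, T, M_H, w5) == pytest.approx(exact, rel=0.02)


def test_harmonic_oracle_monotone_in_P():
    w5 = 5.0 * kT(T) / HBAR_EV_FS
    vals = [sl.harmonic_pimc_oracle(P, T, M_H, w5) for P in (1, 2, 4, 8, 16)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))


@pytest.mark.parametrize("P", [1, 2, 6, 8])
def test_pimc_matches_gaussian_oracle(P):
    """Bead-averaged <x^2> of the sampled harmonic ring polymer agrees with
    the exact finite-P precision-matrix value within 1%."""
    w = 0.5
    rec = sl.sample_pimc_harmonic(P, T, M_H, w, n_sweeps=3_000_000, seed=4)
    oracle = sl.harmonic_pimc_oracle(P, T, M_H, w)
    assert np.mean(rec**2) == pytest.approx(oracle, rel=0.01)


def test_ring_spring_energy_cyclic_invariance():
    rng = np.random.default_rng(5)
    beads = rng.normal(size=(6, 3))
    e0 = sl.ring_spring_energy(beads, M_H, T)
    for shift in range(1, 6):
        assert sl.ring_spring_energy(np.roll(beads, shift, axis=0), M_H, T) == pytest.approx(e0)
    assert sl.ring_spring_energy(beads[:1], M_H, T) == 0.0


def test_ring_polymer_chain_centroid():
    chain = sl.RingPolymerChain(np.arange(12.0).reshape(6, 2))
    assert chain.P == 6
    np.testing.assert_allclose(chain.centroid, np.arange(12.0).reshape(6, 2).mean(axis=0))


def test_seeded_determinism_classical_and_pimc(params):
    for cfg in (
        sl.SamplerConfig(n_sweeps=5000, seed=11),
        sl.SamplerConfig(n_sweeps=3000, seed=11, P=3),
    ):
        run = sl.sample_classical if cfg.P == 1 else sl.sample_pimc
        a = run(params, cfg)
        b = run(params, cfg)
        np.testing.assert_array_equal(a.positions, b.positions)


def test_different_seeds_differ(params):
    a = sl.sample_classical(params, sl.SamplerConfig(n_sweeps=5000, seed=1))
    b = sl.sample_classical(params, sl.SamplerConfig(n_sweeps=5000, seed=2))
    assert not np.array_equal(a.positions, b.positions)


def test_frozen_environment_marginal_matches_quadrature(params):
    """Chi-square test at alpha = 0.01 of the sampled proton x-marginal
    (environment frozen) against direct numerical quadrature of
    exp(-V_1D/kBT)."""
    cfg = sl.SamplerConfig(n_sweeps=400_000, seed=9, record_every=20, freeze_environment=True)
    traj = sl.sample_classical(params, cfg)
    mid = traj.meta["fixture_meta"]["mid"]
    x = traj.positions[:, IDX_H_SHB, 0] - mid[0]
    # frozen uN = 0 leaves the bare well plus the harmonic counter-term
    grid = np.linspace(-0.7, 0.7, 4001)
    v = sl.effective_1d_potential(grid, params) + params.c_eVA2**2 * grid**2 / (
        2 * params.kN_eVA2
    )
    pdf = np.exp(-v / kT(params.T_K))
    edges = np.linspace(-0.5, 0.5, 21)
    probs = np.array([
        np.trapezoid(pdf[(grid >= lo) & (grid < hi)], grid[(grid >= lo) & (grid < hi)])
        for lo, hi in zip(edges[:-1], edges[1:])
    ])
    probs /= probs.sum()
    obs = np.histogram(x, bins=edges)[0]
    keep = probs * x.size > 10
    expected = probs[keep] / probs[keep].sum() * obs[keep].sum()
    _, pval = sps.chisquare(obs[keep], expected)
    assert pval > 0.01


def test_classical_delta_r_is_bimodal(classical_run, classical_shb):
    prof = sl.free_energy_profile(sl.delta_r_series(classical_run, classical_shb), T)
    _, _, n_min = sl.barrier_and_asymmetry(prof)
    assert n_min == 2


def test_quantum_delta_r_is_unimodal(quantum_run, quantum_shb):
    prof = sl.free_energy_profile(sl.delta_r_series(quantum_run, quantum_shb), T)
    _, _, n_min = sl.barrier_and_asymmetry(prof)
    assert n_min == 1


def test_quantum_compresses_mean_OO(classical_run, classical_shb, quantum_run, quantum_shb):
    """Emergent nuclear quantum effect: the average O-O distance shrinks."""
    r_cl = sl.R_series(classical_run, classical_shb).mean()
    r_q = sl.R_series(quantum_run, quantum_shb).mean()
    assert r_q <= r_cl


def test_sampler_config_validation():
    with pytest.raises(ValueError):
        sl.SamplerConfig(n_sweeps=0)
    with pytest.raises(ValueError):
        sl.SamplerConfig(burn_in_fraction=1.0)
    with pytest.raises(ValueError):
        sl.sample_classical(sl.SHBModelParams(), sl.SamplerConfig(P=2))
    with pytest.raises(ValueError):
        sl.sample_pimc(sl.SHBModelParams(), sl.SamplerConfig(P=1))


# -- Wannier emission -----------------------------------------------------


def _zero_sigma_params():
    wc = sl.WannierEmissionParams(
        d_OH_sigma_A=0.0, d_LP_sigma_A=0.0, d_CO_sigma_A=0.0, d_OH_quantum_sigma_A=1e-12
    )
    return sl.SHBModelParams(wc=wc)


def test_emit_wannier_noise_free_rest_geometry(pyro_fixture):
    p = _zero_sigma_params()
    rest = sl.state_to_frame(ModelState.rest(p), p, pyro_fixture)
    out = sl.emit_wannier(rest, p, quantum=False, rng=np.random.default_rng(0))
    x_idx = out.indices_of("X")
    assert len(x_idx) == 8  # four per SHB oxygen
    # at rest |delta_r| = 2*x00, so the O-H center sits exactly at its mean
    shb = sl.detect_shb(rest)[0]
    d_oh = [
        np.linalg.norm(out.positions[i] - out.positions[shb.donor_O]) for i in x_idx
    ]
    assert min(abs(d - p.wc.d_OH_mean_A) for d in d_oh) < 1e-9


def test_emit_wannier_missing_carbon_raises(pyro_fixture, params):
    rest = sl.state_to_frame(ModelState.rest(params), params, pyro_fixture)
    keep = [i for i, s in enumerate(rest.species) if s != "C"]
    stripped = sl.Frame([rest.species[i] for i in keep], rest.positions[keep], rest.cell)
    with pytest.raises(ValueError, match="[Cc]arbon"):
        sl.emit_wannier(stripped, params, rng=np.random.default_rng(0))


def test_add_wannier_deterministic(params):
    cfg = sl.SamplerConfig(n_sweeps=3000, seed=21, record_every=10)
    traj = sl.sample_classical(params, cfg)
    a = sl.add_wannier(traj, params, quantum=False, seed=5)
    b = sl.add_wannier(traj, params, quantum=False, seed=5)
    np.testing.assert_array_equal(a.positions, b.positions)
    assert a.species.count("X") == 8


def test_wannier_quantum_shifts_outward(classical_wannier_run, quantum_wannier_run):
    d_cl = sl.wc_distances_by_label(classical_wannier_run)[sl.OH_BOND]
    d_q = sl.wc_distances_by_label(quantum_wannier_run)[sl.OH_BOND]
    assert d_q.mean() > d_cl.mean()
    assert d_q.std() > d_cl.std()
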