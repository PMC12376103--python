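"""Classical and path-integral Monte Carlo sampling of the SHB model.

These samplers stand in for the study's molecular-dynamics stages: a plain
Metropolis walk over the model coordinates generates the classical ensemble,
and a primitive-action path-integral Monte Carlo (PIMC) walk over P bead
replicas of the quantized coordinates (the SHB proton and the four N-H
stretches; the heavy-atom coordinates R and uN stay classical and are
shared across beads) generates the quantum ensemble.  Only static ensemble
averages are claimed; no dynamics.

The discretized action is the standard primitive form

    U = sum_k sum_q m_q P / (2 beta^2 hbar^2) |r_{q,k} - r_{q,k+1}|^2
        + (1/P) sum_k V(config_k)

with cyclic bead index k.  The move mix combines single-bead displacements,
whole-chain translations (which keep the centroid mobile), classical-
coordinate displacements, and a proton mirror move (x_k -> -x_k for all
beads together with uN_x -> -uN_x) that accelerates hopping between the
two wells; all moves are accepted by the Metropolis rule on U, so detailed
balance holds for each.  Step sizes are auto-tuned toward 40% acceptance
during burn-in and then frozen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numba import njit

from .shb_model import (
    IDX_H_N,
    IDX_H_SHB,
    IDX_N,
    IDX_O_ACCEPTOR,
    IDX_O_DONOR,
    SHBModelParams,
    WannierEmissionParams,
    build_pyro_fixture,
    _NH_DIRS,
)
from .trajectory_io import Frame, Trajectory, mic_displacement
from .units import AMU_TO_EV_FS2_PER_A2, HBAR_EV_FS, kT

__all__ = [
    "RingPolymerChain",
    "SamplerConfig",
    "sample_classical",
    "sample_pimc",
    "sample_pimc_harmonic",
    "harmonic_pimc_oracle",
    "ring_spring_energy",
    "emit_wannier",
    "add_wannier",
]


@dataclass
class RingPolymerChain:
    """P bead replicas of one quantized coordinate set.

    ``beads`` has shape (P, n_coords); the centroid is the arithmetic bead
    mean.
    """

    beads: np.ndarray

    def __post_init__(self):
        self.beads = np.atleast_2d(np.asarray(self.beads, dtype=float))

    @property
    def P(self) -> int:
        return self.beads.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.beads.mean(axis=0)


def ring_spring_energy(beads: np.ndarray, m_amu: float, T_K: float) -> float:
    """Harmonic ring-polymer spring energy of a bead chain, in eV.

    Invariant under cyclic relabeling of the beads.  For P = 1 the energy
    is zero.
    """
    beads = np.atleast_2d(np.asarray(beads, dtype=float))
    P = beads.shape[0]
    if P == 1:
        return 0.0
    beta = 1.0 / kT(T_K)
    ks = m_amu * AMU_TO_EV_FS2_PER_A2 * P / (beta**2 * HBAR_EV_FS**2)
    diffs = beads - np.roll(beads, -1, axis=0)
    return float(0.5 * ks * np.sum(diffs**2))


@dataclass
class SamplerConfig:
    """Monte-Carlo run configuration.

    ``P = 1`` selects the classical sampler.  The burn-in fraction mirrors
    the discarded equilibration period of the reference simulations;
    ``record_every`` thins the stored frames.  ``freeze_environment`` pins
    R, uN and the N-H stretches at their rest values (used for validating
    the proton marginal against quadrature).
    """

    n_sweeps: int = 100_000
    burn_in_fraction: float = 0.1
    seed: int = 0
    P: int = 1
    record_every: int = 1
    emit_wannier: bool = False
    freeze_environment: bool = False
    step_proton_A: float = 0.18
    step_stretch_A: float = 0.08
    step_chain_A: float = 0.10
    step_R_A: float = 0.10
    step_uN_A: float = 0.18
    tune: bool = True

    def __post_init__(self):
        if self.n_sweeps <= 0:
            raise ValueError("n_sweeps must be > 0")
        if not (0 <= self.burn_in_fraction < 1):
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        if self.P < 1:
            raise ValueError("P must be >= 1")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")

    def with_(self, **kw) -> "SamplerConfig":
        return replace(self, **kw)


# -- numba kernels --------------------------------------------------------

# parameter vector layout for the njit kernel
_P_D, _P_R0, _P_X00, _P_KAPPA, _P_KR, _P_KPERP, _P_EPS, _P_C, _P_KN, _P_KNH, \
    _P_KT, _P_KSPR = range(12)


@njit(cache=True)
def _v_bead(xk, sk, R, u, par):
    """Model potential of one bead configuration (classical terms included)."""
    x0 = par[_P_X00] + par[_P_KAPPA] * (R - par[_P_R0])
    if x0 <= 0.05:
        return 1.0e12
    x = xk[0]
    q = x * x - x0 * x0
    v = par[_P_D] * q * q / par[_P_X00] ** 4
    v += par[_P_EPS] * x / par[_P_X00]
    v += 0.5 * par[_P_KR] * (R - par[_P_R0]) ** 2
    v += 0.5 * par[_P_KPERP] * (xk[1] * xk[1] + xk[2] * xk[2])
    v += 0.5 * par[_P_KN] * (u[0] * u[0] + u[1] * u[1] + u[2] * u[2])
    v += par[_P_C] * u[0] * x + par[_P_C] ** 2 * x * x / (2.0 * par[_P_KN])
    v += 0.5 * par[_P_KNH] * (sk[0] ** 2 + sk[1] ** 2 + sk[2] ** 2 + sk[3] ** 2)
    return v


@njit(cache=True)
def _spring_delta(arr, k, new, P, ks):
    """Change in ring spring energy when bead k of a (P, d) chain moves."""
    if P == 1:
        return 0.0
    km = (k - 1) % P
    kp = (k + 1) % P
    e_old = 0.0
    e_new = 0.0
    for d in range(arr.shape[1]):
        e_old += (arr[k, d] - arr[km, d]) ** 2 + (arr[k, d] - arr[kp, d]) ** 2
        e_new += (new[d] - arr[km, d]) ** 2 + (new[d] - arr[kp, d]) ** 2
    return 0.5 * ks * (e_new - e_old)


@njit(cache=True)
def _run_shb_kernel(par, P, n_sweeps, burn_sweeps, record_every, steps, seed,
                    freeze_env, tune, x_init):
    np.random.seed(seed)
    x = np.zeros((P, 3))
    for k in range(P):
        x[k, 0] = x_init
    s = np.zeros((P, 4))
    R = par[_P_R0]
    u = np.zeros(3)
    kTe = par[_P_KT]
    ks = par[_P_KSPR]

    n_rec = (n_sweeps - burn_sweeps + record_every - 1) // record_every
    rec_x = np.empty((n_rec, P, 3))
    rec_s = np.empty((n_rec, P, 4))
    rec_R = np.empty(n_rec)
    rec_u = np.empty((n_rec, 3))

    acc = np.zeros(6)
    att = np.zeros(6)
    acc_w = np.zeros(6)
    att_w = np.zeros(6)

    xn = np.empty(3)
    sn = np.empty(4)
    irec = 0
    for sweep in range(n_sweeps):
        in_burn = sweep < burn_sweeps
        # single-bead proton displacements
        for k in range(P):
            for d in range(3):
                xn[d] = x[k, d] + (np.random.random() * 2.0 - 1.0) * steps[0]
            dU = (_v_bead(xn, s[k], R, u, par) - _v_bead(x[k], s[k], R, u, par)) / P
            dU += _spring_delta(x, k, xn, P, ks)
            att_w[0] += 1.0
            if dU <= 0.0 or np.random.random() < np.exp(-dU / kTe):
                for d in range(3):
                    x[k, d] = xn[d]
                acc_w[0] += 1.0
        # single-bead stretch displacements
        if not freeze_env:
            for k in range(P):
                for a in range(4):
                    sn[a] = s[k, a] + (np.random.random() * 2.0 - 1.0) * steps[1]
                dU = (_v_bead(x[k], sn, R, u, par) - _v_bead(x[k], s[k], R, u, par)) / P
                dU += _spring_delta(s, k, sn, P, ks)
                att_w[1] += 1.0
                if dU <= 0.0 or np.random.random() < np.exp(-dU / kTe):
                    for a in range(4):
                        s[k, a] = sn[a]
                    acc_w[1] += 1.0
        # whole-chain proton translation
        dx0 = (np.random.random() * 2.0 - 1.0) * steps[2]
        dx1 = (np.random.random() * 2.0 - 1.0) * steps[2]
        dx2 = (np.random.random() * 2.0 - 1.0) * steps[2]
        dU = 0.0
        for k in range(P):
            xn[0] = x[k, 0] + dx0
            xn[1] = x[k, 1] + dx1
            xn[2] = x[k, 2] + dx2
            dU += (_v_bead(xn, s[k], R, u, par) - _v_bead(x[k], s[k], R, u, par)) / P
        att_w[2] += 1.0
        if dU <= 0.0 or np.random.random() < np.exp(-dU / kTe):
            for k in range(P):
                x[k, 0] += dx0
                x[k, 1] += dx1
                x[k, 2] += dx2
            acc_w[2] += 1.0
        if not freeze_env:
            # whole-chain stretch translation
            ds0 = (np.random.random() * 2.0 - 1.0) * steps[3]
            ds1 = (np.random.random() * 2.0 - 1.0) * steps[3]
            ds2 = (np.random.random() * 2.0 - 1.0) * steps[3]
            ds3 = (np.random.random() * 2.0 - 1.0) * steps[3]
            dU = 0.0
            for k in range(P):
                sn[0] = s[k, 0] + ds0
                sn[1] = s[k, 1] + ds1
                sn[2] = s[k, 2] + ds2
                sn[3] = s[k, 3] + ds3
                dU += (_v_bead(x[k], sn, R, u, par) - _v_bead(x[k], s[k], R, u, par)) / P
            att_w[3] += 1.0
            if dU <= 0.0 or np.random.random() < np.exp(-dU / kTe):
                for k in range(P):
                    s[k, 0] += ds0
                    s[k, 1] += ds1
                    s[k, 2] += ds2
                    s[k, 3] += ds3
                acc_w[3] += 1.0
            # R move
            Rn = R + (np.random.random() * 2.0 - 1.0) * steps[4]
            if Rn > 1.5:
                dU = 0.0
                for k in range(P):
                    dU += (_v_bead(x[k], s[k], Rn, u, par) - _v_bead(x[k], s[k], R, u, par)) / P
                att_w[4] += 1.0
                if dU <= 0.0 or np.random.random() < np.exp(-dU / kTe):
                    R = Rn
                    acc_w[4] += 1.0
            # uN move
            un = np.empty(3)
            for d in range(3):
                un[d] = u[d] + (np.random.random() * 2.0 - 1.0) * steps[5]
            dU = 0.0
            for k in range(P):
                dU += (_v_bead(x[k], s[k], R, un, par) - _v_bead(x[k], s[k], R, u, par)) / P
            att_w[5] += 1.0
            if dU <= 0.0 or np.random.random() < np.exp(-dU / kTe):
                for d in range(3):
                    u[d] = un[d]
                acc_w[5] += 1.0
        # proton mirror move: x_k -> -x_k for all beads, uN_x -> -uN_x;
        # only the static tilt term changes
        xbar = 0.0
        for k in range(P):
            xbar += x[k, 0]
        xbar /= P
        dU = -2.0 * par[_P_EPS] * xbar / par[_P_X00]
        if dU <= 0.0 or np.random.random() < np.exp(-dU / kTe):
            for k in range(P):
                x[k, 0] = -x[k, 0]
            u[0] = -u[0]

        # step-size tuning toward 40% acceptance during burn-in
        if in_burn and tune and (sweep + 1) % 100 == 0:
            for c in range(6):
                if att_w[c] > 0:
                    rate = acc_w[c] / att_w[c]
                    if rate > 0.45:
                        steps[c] *= 1.2
                    elif rate < 0.35:
                        steps[c] *= 0.8
                    if steps[c] < 1e-4:
                        steps[c] = 1e-4
                    if steps[c] > 2.0:
                        steps[c] = 2.0
                acc_w[c] = 0.0
                att_w[c] = 0.0
        if not in_burn:
            # accumulate production acceptance statistics
            for c in range(6):
                acc[c] += acc_w[c]
                att[c] += att_w[c]
                acc_w[c] = 0.0
                att_w[c] = 0.0
            if (sweep - burn_sweeps) % record_every == 0:
                for k in range(P):
                    for d in range(3):
                        rec_x[irec, k, d] = x[k, d]
                    for a in range(4):
                        rec_s[irec, k, a] = s[k, a]
                rec_R[irec] = R
                for d in range(3):
                    rec_u[irec, d] = u[d]
                irec += 1
    return rec_x[:irec], rec_s[:irec], rec_R[:irec], rec_u[:irec], acc, att, steps


@njit(cache=True)
def _run_harmonic_kernel(P, ks, apot, kTe, n_sweeps, burn_sweeps, record_every,
                         step_bead, step_chain, seed):
    """Primitive PIMC for a 1D harmonic potential apot*x^2 (apot = m w^2 / 2)."""
    np.random.seed(seed)
    x = np.zeros((P, 1))
    n_rec = (n_sweeps - burn_sweeps + record_every - 1) // record_every
    rec = np.empty((n_rec, P))
    new = np.empty(1)
    sb = step_bead
    sc = step_chain
    acc_b = 0.0
    att_b = 0.0
    irec = 0
    for sweep in range(n_sweeps):
        in_burn = sweep < burn_sweeps
        for k in range(P):
            new[0] = x[k, 0] + (np.random.random() * 2.0 - 1.0) * sb
            dU = apot * (new[0] ** 2 - x[k, 0] ** 2) / P
            dU += _spring_delta(x, k, new, P, ks)
            att_b += 1.0
            if dU <= 0.0 or np.random.random() < np.exp(-dU / kTe):
                x[k, 0] = new[0]
                acc_b += 1.0
        dxc = (np.random.random() * 2.0 - 1.0) * sc
        dU = 0.0
        for k in range(P):
            dU += apot * ((x[k, 0] + dxc) ** 2 - x[k, 0] ** 2) / P
        if dU <= 0.0 or np.random.random() < np.exp(-dU / kTe):
            for k in range(P):
                x[k, 0] += dxc
        if in_burn and (sweep + 1) % 100 == 0:
            rate = acc_b / att_b if att_b > 0 else 0.4
            if rate > 0.45:
                sb *= 1.2
            elif rate < 0.35:
                sb *= 0.8
            acc_b = 0.0
            att_b = 0.0
        if not in_burn and (sweep - burn_sweeps) % record_every == 0:
            for k in range(P):
                rec[irec, k] = x[k, 0]
            irec += 1
    return rec[:irec]


# -- public sampling API --------------------------------------------------

_MOVE_CLASSES = ("proton_bead", "stretch_bead", "proton_chain", "stretch_chain", "R", "uN")


def _param_vector(params: SHBModelParams, P: int) -> np.ndarray:
    beta = 1.0 / kT(params.T_K)
    kspr = params.m_H_amu * AMU_TO_EV_FS2_PER_A2 * P / (beta**2 * HBAR_EV_FS**2)
    return np.array([
        params.barrier_eV, params.R0_A, params.x00_A, params.kappa,
        params.kR_eVA2, params.kperp_eVA2, params.asym_eV, params.c_eVA2,
        params.kN_eVA2, params.k_NH_eVA2, kT(params.T_K), kspr,
    ])


def _embed_trajectory(params: SHBModelParams, cfg: SamplerConfig,
                      rec_x, rec_s, rec_R, rec_u) -> Trajectory:
    fixture = build_pyro_fixture(params)
    mid = fixture.meta["mid"]
    n_site = fixture.meta["n_site"]
    n_rec, P = rec_x.shape[0], rec_x.shape[1]
    n_frames = n_rec * P
    n_atoms = fixture.n_atoms
    pos = np.broadcast_to(fixture.positions, (n_frames, n_atoms, 3)).copy()
    R_rep = np.repeat(rec_R, P)
    u_rep = np.repeat(rec_u, P, axis=0)
    xq = rec_x.reshape(n_frames, 3)
    sq = rec_s.reshape(n_frames, 4)
    ex = np.array([1.0, 0.0, 0.0])
    pos[:, IDX_O_DONOR] = mid - (R_rep / 2)[:, None] * ex
    pos[:, IDX_O_ACCEPTOR] = mid + (R_rep / 2)[:, None] * ex
    pos[:, IDX_H_SHB] = mid + xq
    pos[:, IDX_N] = n_site + u_rep
    for a, idx in enumerate(IDX_H_N):
        pos[:, idx] = pos[:, IDX_N] + (params.r_NH0_A + sq[:, a])[:, None] * _NH_DIRS[a]
    dt_fs = 0.5 * cfg.record_every
    return Trajectory(
        species=fixture.species,
        positions=pos,
        cell=fixture.cell,
        frame_index=np.repeat(np.arange(n_rec), P),
        bead_index=np.tile(np.arange(P), n_rec) if P > 1 else None,
        time_fs=np.repeat(np.arange(n_rec) * dt_fs, P),
        n_beads=P,
        dt_fs=dt_fs,
        temperature_K=params.T_K,
        meta={"fixture_meta": fixture.meta},
    )


def _sample(params: SHBModelParams, cfg: SamplerConfig) -> Trajectory:
    par = _param_vector(params, cfg.P)
    burn = int(round(cfg.burn_in_fraction * cfg.n_sweeps))
    steps = np.array([
        cfg.step_proton_A, cfg.step_stretch_A, cfg.step_chain_A,
        cfg.step_chain_A, cfg.step_R_A, cfg.step_uN_A,
    ])
    rec_x, rec_s, rec_R, rec_u, acc, att, steps_out = _run_shb_kernel(
        par, cfg.P, cfg.n_sweeps, burn, cfg.record_every, steps,
        cfg.seed, cfg.freeze_environment, cfg.tune, -params.x00_A,
    )
    rates = {}
    for c, name in enumerate(_MOVE_CLASSES):
        if att[c] > 0:
            rates[name] = float(acc[c] / att[c])
            if not 0.05 <= rates[name] <= 0.95:
                warnings.warn(
                    f"acceptance rate for {name} moves is {rates[name]:.2f}, "
                    "outside [0.05, 0.95] after auto-tuning"
                )
    traj = _embed_trajectory(params, cfg, rec_x, rec_s, rec_R, rec_u)
    traj.meta["acceptance"] = rates
    traj.meta["steps_A"] = {n: float(steps_out[c]) for c, n in enumerate(_MOVE_CLASSES)}
    traj.meta["seed"] = cfg.seed
    if cfg.emit_wannier:
        traj = add_wannier(traj, params, quantum=cfg.P > 1, seed=cfg.seed + 7777)
    return traj


def sample_classical(params: SHBModelParams, cfg: SamplerConfig) -> Trajectory:
    """Metropolis sampling of exp(-V/kBT) over all model coordinates (P=1)."""
    if cfg.P != 1:
        raise ValueError("sample_classical requires cfg.P == 1")
    return _sample(params, cfg)


def sample_pimc(params: SHBModelParams, cfg: SamplerConfig) -> Trajectory:
    """Primitive-action PIMC with quantized proton and N-H stretches (P>=2)."""
    if cfg.P < 2:
        raise ValueError("sample_pimc requires cfg.P >= 2")
    return _sample(params, cfg)


def sample_pimc_harmonic(
    P: int,
    T_K: float,
    m_amu: float,
    omega_per_fs: float,
    n_sweeps: int,
    seed: int = 0,
    burn_in_fraction: float = 0.1,
    record_every: int = 1,
) -> np.ndarray:
    """Sample a 1D harmonic oscillator ring polymer; returns bead positions
    with shape (n_recorded, P).  Validation workhorse for the PIMC action."""
    beta = 1.0 / kT(T_K)
    m = m_amu * AMU_TO_EV_FS2_PER_A2
    ks = m * P / (beta**2 * HBAR_EV_FS**2)
    apot = 0.5 * m * omega_per_fs**2
    burn = int(round(burn_in_fraction * n_sweeps))
    # sensible starting steps: thermal width of one bead
    step0 = max(0.02, 1.0 / np.sqrt(beta * (2 * ks + apot)))
    return _run_harmonic_kernel(
        P, ks, apot, kT(T_K), n_sweeps, burn, record_every, step0, step0, seed
    )


def harmonic_pimc_oracle(P: int, T_K: float, m_amu: float, omega_per_fs: float) -> float:
    """Exact finite-P bead-averaged <x^2> of the harmonic ring polymer, A^2.

    Built by assembling the (P x P) precision matrix of the discretized
    Gaussian action and inverting it; <x_k^2> = (A^-1)_kk, identical for all
    beads.  P=1 gives the classical kBT/(m w^2); P -> infinity approaches
    (hbar / 2 m w) coth(beta hbar w / 2).
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    beta = 1.0 / kT(T_K)
    m = m_amu * AMU_TO_EV_FS2_PER_A2
    if P == 1:
        return 1.0 / (beta * m * omega_per_fs**2)
    ks = m * P / (beta**2 * HBAR_EV_FS**2)
    L = 2 * np.eye(P) - np.roll(np.eye(P), 1, axis=1) - np.roll(np.eye(P), -1, axis=1)
    A = beta * (ks * L + (m * omega_per_fs**2 / P) * np.eye(P))
    cov = np.linalg.inv(A)
    return float(np.trace(cov) / P)


# -- Wannier-center emission ----------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


def emit_wannier(
    frame: Frame,
    params: SHBModelParams,
    quantum: bool = False,
    rng: Optional[np.random.Generator] = None,
    shb=None,
) -> Frame:
    """Append four Wannier-center ("X") records per SHB oxygen to a frame.

    Generative stand-in for an electronic-structure calculation: the C-O
    bond center lies along O->C, the O-H bond center (donor side, i.e. the
    oxygen currently nearer the proton) along O->H at a distance that
    elongates as the proton approaches the midpoint, and lone pairs along
    the remaining tetrahedral directions; the acceptor oxygen receives a
    third lone pair along its O->H direction in place of a bond center.
    """
    from .pt_analysis import delta_r, detect_shb  # analysis-side geometry

    rng = rng or np.random.default_rng(0)
    wc = params.wc
    if shb is not None:
        triples = [shb]
    else:
        triples = detect_shb(frame)
        if not triples:
            raise ValueError("no SHB found in frame; cannot emit Wannier centers")
    dr_rest = 2.0 * params.x00_A
    new_species = list(frame.species)
    new_pos = [frame.positions]
    c_idx = frame.indices_of("C")
    if len(c_idx) == 0:
        raise ValueError("frame has no carbon atoms; cannot orient C-O Wannier centers")
    for shb in triples:
        dr = delta_r(frame, shb)
        # the oxygen currently nearer the proton carries the O-H bond center
        donor_side = shb.donor_O if dr <= 0 else shb.acceptor_O
        for o_i in (shb.donor_O, shb.acceptor_O):
            is_donor = o_i == donor_side
            r_o = frame.positions[o_i]
            dc = [np.linalg.norm(mic_displacement(r_o, frame.positions[c], frame.cell)) for c in c_idx]
            j = int(np.argmin(dc))
            if dc[j] > 1.45:
                raise ValueError(f"oxygen {o_i} has no carbon partner within 1.45 A")
            e_c = _unit(mic_displacement(r_o, frame.positions[c_idx[j]], frame.cell))
            e_h = _unit(mic_displacement(r_o, frame.positions[shb.H], frame.cell))
            bis = -(e_c + e_h)
            perp = np.cross(e_c, e_h)
            if np.linalg.norm(perp) < 1e-9 or np.linalg.norm(bis) < 1e-9:
                raise ValueError("degenerate O-C / O-H geometry for lone-pair frame")
            bis = _unit(bis)
            perp = _unit(perp)
            lp_dirs = [_unit(bis + perp), _unit(bis - perp)]
            centers = []
            centers.append((e_c, wc.d_CO_mean_A + wc.d_CO_sigma_A * rng.standard_normal()))
            if is_donor:
                d_eff = wc.d_OH_mean_A + wc.slope_vs_dr * (dr_rest - abs(dr)) / 2.0
                sigma = wc.d_OH_sigma_A
                if quantum:
                    d_eff += wc.d_OH_quantum_shift_A
                    sigma = wc.d_OH_quantum_sigma_A
                centers.append((e_h, d_eff + sigma * rng.standard_normal()))
            else:
                centers.append((e_h, wc.d_LP_mean_A + wc.d_LP_sigma_A * rng.standard_normal()))
            for lp in lp_dirs:
                centers.append((lp, wc.d_LP_mean_A + wc.d_LP_sigma_A * rng.standard_normal()))
            for direction, dist in centers:
                new_species.append("X")
                new_pos.append((r_o + dist * direction)[None, :])
    return Frame(
        species=new_species,
        positions=np.vstack(new_pos),
        cell=frame.cell,
        frame_index=frame.frame_index,
        bead_index=frame.bead_index,
        time_fs=frame.time_fs,
        meta=dict(frame.meta),
    )


def add_wannier(traj: Trajectory, params: SHBModelParams, quantum: bool, seed: int) -> Trajectory:
    """Emit Wannier centers for every frame of a trajectory (deterministic
    given the seed).  The SHB triple is detected once on the time-averaged
    structure so thermally stretched frames are never dropped."""
    from .pt_analysis import detect_shb_tracked

    triples = detect_shb_tracked(traj)
    if not triples:
        raise ValueError("no SHB found in the time-averaged structure")
    rng = np.random.default_rng(seed)
    frames = [
        emit_wannier(traj[i], params, quantum=quantum, rng=rng, shb=triples[0])
        for i in range(len(traj))
    ]
    out = Trajectory.from_frames(
        frames,
        n_beads=traj.n_beads,
        dt_fs=traj.dt_fs,
        temperature_K=traj.temperature_K,
        meta=traj.meta,
    )
    out.frame_index = traj.frame_index.copy()
    out.bead_index = None if traj.bead_index is None else traj.bead_index.copy()
    return out
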