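"""Model Hamiltonian and crystal-like fixtures for a short hydrogen bond.

The degrees of freedom are the SHB proton (longitudinal displacement ``x``
from the O-O midpoint plus a transverse 2-vector), the heavy-atom
compression coordinate ``R`` (the O-O distance), the displacement ``uN`` of
an adjacent ammonium nitrogen from its lattice site, and four N-H stretch
displacements.  The proton moves in a compressible quartic double well

    V_dw = barrier_eV * (x^2 - x0(R)^2)^2 / x00^4

whose well separation narrows under compression,
``x0(R) = x00 + kappa*(R - R0)``.  Normalizing by the fixed rest
separation ``x00^4`` (rather than by ``x0(R)^4``) makes the barrier at
``x = 0`` scale as ``x0(R)^4``: compressing the O-O distance genuinely
lowers the transfer barrier, so the transition state compresses
classically, and a quantum-delocalized proton sitting near the midpoint
pulls the average O-O distance slightly inward - both signatures of real
short hydrogen bonds.  A small static tilt ``asym_eV`` biases one well,
standing in for the asymmetric electrostatic environment of the crystal.

The proton-ammonium ("presolvation") coupling is written in displaced-
equilibrium form::

    (1/2) kN |uN + (c/kN) x e_shb|^2

whose expansion contains the bilinear term ``c (uN . e_shb) x`` plus the
harmonic counter-term ``c^2 x^2 / (2 kN)``.  With this form, integrating
the environment out of the Boltzmann distribution leaves the proton's
potential of mean force exactly equal to the bare tilted double well, so
the barrier parameter ``barrier_eV`` is also the free-energy barrier a long
classical run recovers by Boltzmann inversion.  The bilinear strength ``c``
alone controls the proton-rocking correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

from .trajectory_io import Frame, SimulationCell
from .units import kT

__all__ = [
    "WannierEmissionParams",
    "SHBModelParams",
    "ModelState",
    "potential_energy",
    "effective_1d_potential",
    "analytic_barrier",
    "build_pyro_fixture",
    "build_control_fixture",
    "state_to_frame",
    "frame_to_state",
    "tracked_oxygen_sites",
    "IDX_O_DONOR",
    "IDX_O_ACCEPTOR",
    "IDX_H_SHB",
    "IDX_N",
]

# atom layout of the pyro-like fixture (fixed, documented)
IDX_O_DONOR = 0
IDX_O_ACCEPTOR = 1
IDX_H_SHB = 2
IDX_C_DONOR = 3
IDX_C_ACCEPTOR = 4
IDX_N = 5
IDX_H_N = (6, 7, 8, 9)
IDX_SPECTATOR_O = tuple(range(10, 20))
IDX_FAR_O = (20, 21)

_E_SHB = np.array([1.0, 0.0, 0.0])

# tetrahedral N-H directions (unit vectors)
_NH_DIRS = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)

# icosahedral directions for the spectator oxygens around the ammonium ion;
# the two vertices pointing at the SHB oxygens are omitted, and the shell is
# tilted about the lateral (y) axis so that most spectator pair separations
# mix axial and transverse character (part of the geometric calibration of
# the rocking-mode correlation spectrum)
_PHI = (1.0 + np.sqrt(5.0)) / 2.0
_ICO = np.array(
    [
        [0, 1, _PHI], [0, 1, -_PHI], [0, -1, _PHI], [0, -1, -_PHI],
        [1, _PHI, 0], [-1, _PHI, 0],
        [_PHI, 0, 1], [_PHI, 0, -1], [-_PHI, 0, 1], [-_PHI, 0, -1],
    ],
    dtype=float,
)
_ICO /= np.linalg.norm(_ICO, axis=1)[:, None]
_SPECTATOR_TILT_RAD = np.deg2rad(28.0)
_ROT_Y = np.array(
    [
        [np.cos(_SPECTATOR_TILT_RAD), 0.0, np.sin(_SPECTATOR_TILT_RAD)],
        [0.0, 1.0, 0.0],
        [-np.sin(_SPECTATOR_TILT_RAD), 0.0, np.cos(_SPECTATOR_TILT_RAD)],
    ]
)
_ICO = _ICO @ _ROT_Y.T
_SPECTATOR_RADII = np.array([2.85, 3.05, 3.25, 3.45, 3.65, 3.85, 4.05, 4.25, 4.45, 3.55])


@dataclass(frozen=True)
class WannierEmissionParams:
    """Distributional rules for emitting Wannier-center pseudo-atoms.

    Each SHB oxygen hosts four Wannier centers: one on the C-O bond, one on
    the O-H bond (donor side only) and two lone pairs; the acceptor oxygen
    carries a third lone pair in place of the O-H center.  Means and widths
    are in angstrom.  ``slope_vs_dr`` elongates the O-H center as the proton
    approaches the midpoint (|delta_r| -> 0), and the quantum flags shift and
    broaden the O-H center, mimicking the outward shift seen when nuclear
    quantum effects delocalize the proton.
    """

    d_OH_mean_A: float = 0.40
    d_OH_sigma_A: float = 0.02
    d_OH_quantum_shift_A: float = 0.05
    d_OH_quantum_sigma_A: float = 0.04
    d_LP_mean_A: float = 0.30
    d_LP_sigma_A: float = 0.015
    d_CO_mean_A: float = 0.55
    d_CO_sigma_A: float = 0.02
    slope_vs_dr: float = 0.05

    def __post_init__(self):
        for name in ("d_OH_mean_A", "d_LP_mean_A", "d_CO_mean_A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "d_OH_sigma_A", "d_OH_quantum_sigma_A", "d_LP_sigma_A", "d_CO_sigma_A",
        ):
            # zero widths are allowed: the noise-free limit is part of the contract
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SHBModelParams:
    """Constants of the SHB model Hamiltonian (eV, angstrom, amu, K).

    ``c_eVA2`` is the bilinear proton-rocking coupling strength; its default
    was calibrated (scripts/calibrate_coupling.py) so that the default
    classical ensemble shows a maximum |Pearson rho| of ~0.68 between the
    proton-transfer coordinate and the SHB-aligned ammonium rocking modes,
    while the default quantum (P=6) ensemble suppresses the median |rho|
    below 0.35.  ``asym_eV`` and the well half-separation ``x00_A`` are
    likewise calibration choices: together they fix the well asymmetry and
    keep the Boltzmann-inverted classical barrier at ~30 meV while letting
    six-bead path-integral sampling symmetrize the proton into a single
    well.
    """

    barrier_eV: float = 0.030
    R0_A: float = 2.50
    x00_A: float = 0.20
    kappa: float = 0.5
    kR_eVA2: float = 10.0
    kperp_eVA2: float = 8.0
    asym_eV: float = 0.003
    c_eVA2: float = 1.41
    kN_eVA2: float = 3.0
    r_NH0_A: float = 1.05
    k_NH_eVA2: float = 30.0
    m_H_amu: float = 1.008
    m_N_amu: float = 14.007
    m_O_amu: float = 15.999
    T_K: float = 300.0
    wc: WannierEmissionParams = field(default_factory=WannierEmissionParams)

    def __post_init__(self):
        if self.barrier_eV <= 0:
            raise ValueError("barrier_eV must be > 0")
        if self.x00_A <= 0:
            raise ValueError("x00_A must be > 0")
        for name in ("kR_eVA2", "kperp_eVA2", "kN_eVA2", "k_NH_eVA2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def x0_of(self, R: float) -> float:
        """Well half-separation at O-O distance R: x0(R) = x00 + kappa*(R-R0)."""
        return self.x00_A + self.kappa * (R - self.R0_A)

    def with_(self, **kw) -> "SHBModelParams":
        return replace(self, **kw)


@dataclass
class ModelState:
    """Dynamical coordinates of the model (angstrom).

    ``x``: proton displacement from the O-O midpoint along the SHB axis;
    ``yz``: transverse proton displacement; ``R``: O-O distance; ``uN``:
    ammonium-nitrogen displacement from its lattice site; ``s``: the four
    N-H stretch displacements.
    """

    x: float = 0.0
    yz: np.ndarray = field(default_factory=lambda: np.zeros(2))
    R: float = 2.50
    uN: np.ndarray = field(default_factory=lambda: np.zeros(3))
    s: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def __post_init__(self):
        self.yz = np.asarray(self.yz, dtype=float)
        self.uN = np.asarray(self.uN, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.R <= 1.5:
            raise ValueError("R must exceed 1.5 A")

    @classmethod
    def rest(cls, params: SHBModelParams) -> "ModelState":
        """Donor-side rest state: proton at -x00, everything else relaxed."""
        return cls(x=-params.x00_A, R=params.R0_A)


_X0_MIN = 0.05


def potential_energy(state: ModelState, params: SHBModelParams) -> float:
    """Total model potential energy in eV.

    Raises a domain error when the compression-narrowed well separation
    x0(R) falls below 0.05 A (pathological compression).
    """
    p = params
    x0 = p.x0_of(state.R)
    if x0 <= _X0_MIN:
        raise ValueError(f"x0(R) = {x0:.4f} A <= {_X0_MIN} A: pathological compression")
    x = state.x
    v = p.barrier_eV * (x * x - x0 * x0) ** 2 / p.x00_A**4
    v += p.asym_eV * x / p.x00_A
    v += 0.5 * p.kR_eVA2 * (state.R - p.R0_A) ** 2
    v += 0.5 * p.kperp_eVA2 * float(np.dot(state.yz, state.yz))
    # displaced-equilibrium ammonium coupling: bilinear + harmonic counter-term
    ux = float(np.dot(state.uN, _E_SHB))
    v += 0.5 * p.kN_eVA2 * float(np.dot(state.uN, state.uN))
    v += p.c_eVA2 * ux * x + p.c_eVA2**2 * x * x / (2.0 * p.kN_eVA2)
    v += 0.5 * p.k_NH_eVA2 * float(np.dot(state.s, state.s))
    return float(v)


def effective_1d_potential(x: np.ndarray, params: SHBModelParams, R: Optional[float] = None) -> np.ndarray:
    """Proton potential along x with all other coordinates relaxed, in eV.

    Relaxing uN cancels the coupling exactly, so this is the bare tilted
    double well at fixed R (default R0).
    """
    p = params
    x = np.asarray(x, dtype=float)
    x0 = p.x0_of(p.R0_A if R is None else R)
    if x0 <= _X0_MIN:
        raise ValueError("x0(R) below the supported range")
    return p.barrier_eV * (x * x - x0 * x0) ** 2 / p.x00_A**4 + p.asym_eV * x / p.x00_A


def analytic_barrier(params: SHBModelParams, grid_step_A: float = 1e-4) -> float:
    """Barrier of the tilted 1D double well at R=R0, in eV.

    Found by dense grid search: the two side minima of the relaxed 1D
    potential, the saddle between them, and the barrier measured from the
    global minimum (the convention of the sampled free-energy observable).
    Equals ``barrier_eV`` exactly when ``asym_eV = 0``.
    """
    x = np.arange(-0.6, 0.6 + grid_step_A / 2, grid_step_A)
    v = effective_1d_potential(x, params)
    left = x < 0
    right = x > 0
    i_l = np.argmin(np.where(left, v, np.inf))
    i_r = np.argmin(np.where(right, v, np.inf))
    lo, hi = sorted((i_l, i_r))
    saddle = float(v[lo:hi + 1].max())
    return saddle - float(min(v[i_l], v[i_r]))


# -- fixtures -------------------------------------------------------------


def build_pyro_fixture(params: Optional[SHBModelParams] = None, cell_A: float = 14.0) -> Frame:
    """Deterministic l-pyro-amm-like geometry hosting one SHB.

    The SHB oxygen pair sits on the x axis at separation R0 with the proton
    in the donor-side well; an ammonium ion (N + four H) is offset 3.0 A
    laterally from the SHB midpoint with a small 0.18 A axial bias toward
    the donor oxygen (the geometric origin of the environmental asymmetry);
    ten spectator oxygens on icosahedral directions complete the twelve
    oxygens within 5 A of the nitrogen, two further oxygens lie beyond 5 A,
    and one carbon is bonded 1.25 A from each SHB oxygen for C-O
    Wannier-center classification.  The cell is a cube large enough that
    minimum image is inert.
    """
    p = params or SHBModelParams()
    mid = np.full(3, cell_A / 2.0)
    pos = []
    species = []

    def add(sym, r):
        species.append(sym)
        pos.append(np.asarray(r, dtype=float))

    add("O", mid + [-p.R0_A / 2, 0, 0])            # donor
    add("O", mid + [+p.R0_A / 2, 0, 0])            # acceptor
    add("H", mid + [-p.x00_A, 0, 0])               # SHB proton, donor-side well
    add("C", mid + [-p.R0_A / 2 - 1.25 * 0.5, -1.25 * np.sqrt(3) / 2, 0])
    add("C", mid + [+p.R0_A / 2 + 1.25 * 0.5, -1.25 * np.sqrt(3) / 2, 0])
    n_site = mid + np.array([-0.18, 3.0, 0.0])
    add("N", n_site)
    for t in _NH_DIRS:
        add("H", n_site + p.r_NH0_A * t)
    for v, r in zip(_ICO, _SPECTATOR_RADII):
        add("O", n_site + r * v)
    add("O", n_site + 6.2 * np.array([0.0, 0.6, 0.8]))
    add("O", n_site + 6.2 * np.array([0.0, 0.0, -1.0]))

    frame = Frame(
        species=species,
        positions=np.array(pos),
        cell=SimulationCell(cell_A, cell_A, cell_A),
        meta={
            "mid": mid,
            "n_site": n_site,
            "e_shb": _E_SHB.copy(),
            "donor": IDX_O_DONOR,
            "acceptor": IDX_O_ACCEPTOR,
            "h_shb": IDX_H_SHB,
            "n": IDX_N,
        },
    )
    return frame


def build_control_fixture(cell_A: float = 14.0) -> Frame:
    """Normal-hydrogen-bond control: one donor N, five acceptor O.

    Donor-acceptor distances are evenly spaced over [2.70, 2.90] A, the
    conventional N-H...O range; four N-H hydrogens at 1.0 A point toward
    the first four acceptors.  No short hydrogen bond exists here.
    """
    mid = np.full(3, cell_A / 2.0)
    dirs = _ICO[:5]
    dists = np.linspace(2.70, 2.90, 5)
    species = ["N"]
    pos = [mid.copy()]
    for v, d in zip(dirs, dists):
        species.append("O")
        pos.append(mid + d * v)
    for v in dirs[:4]:
        species.append("H")
        pos.append(mid + 1.0 * v)
    return Frame(
        species=species,
        positions=np.array(pos),
        cell=SimulationCell(cell_A, cell_A, cell_A),
        meta={"n": 0, "acceptors": list(range(1, 6))},
    )


def tracked_oxygen_sites(fixture: Frame, radius_A: float = 5.0) -> np.ndarray:
    """Atom indices of the oxygens within ``radius_A`` of the ammonium N,
    sorted by rest-geometry distance from N (the site-label order 1..12)."""
    n_idx = fixture.meta.get("n", IDX_N)
    rn = fixture.positions[n_idx]
    o_idx = fixture.indices_of("O")
    d = np.linalg.norm(fixture.positions[o_idx] - rn, axis=1)
    sel = o_idx[d < radius_A]
    return sel[np.argsort(d[d < radius_A], kind="stable")]


# -- state embedding ------------------------------------------------------


def state_to_frame(state: ModelState, params: SHBModelParams, fixture: Frame) -> Frame:
    """Embed the dynamical coordinates into the fixture geometry.

    O and O' sit at midpoint +- R/2 along the SHB axis, the proton at
    midpoint + x*e_shb + transverse yz, the nitrogen at its site + uN with
    the four N-H hydrogens riding along at lengths r_NH0 + s_a.
    """
    p = params
    mid = fixture.meta["mid"]
    n_site = fixture.meta["n_site"]
    pos = fixture.positions.copy()
    pos[IDX_O_DONOR] = mid - (state.R / 2) * _E_SHB
    pos[IDX_O_ACCEPTOR] = mid + (state.R / 2) * _E_SHB
    pos[IDX_H_SHB] = mid + state.x * _E_SHB + [0.0, state.yz[0], state.yz[1]]
    pos[IDX_N] = n_site + state.uN
    for a, (idx, t) in enumerate(zip(IDX_H_N, _NH_DIRS)):
        pos[idx] = pos[IDX_N] + (p.r_NH0_A + state.s[a]) * t
    return Frame(
        species=fixture.species,
        positions=pos,
        cell=fixture.cell,
        frame_index=fixture.frame_index,
        meta=dict(fixture.meta),
    )


def frame_to_state(frame: Frame, params: SHBModelParams, fixture: Frame) -> ModelState:
    """Inverse of :func:`state_to_frame` (exact for embedded frames)."""
    mid = fixture.meta["mid"]
    n_site = fixture.meta["n_site"]
    pos = frame.positions
    R = float(np.linalg.norm(pos[IDX_O_ACCEPTOR] - pos[IDX_O_DONOR]))
    h_rel = pos[IDX_H_SHB] - mid
    x = float(np.dot(h_rel, _E_SHB))
    yz = np.array([h_rel[1], h_rel[2]])
    uN = pos[IDX_N] - n_site
    s = np.array(
        [
            np.linalg.norm(pos[idx] - pos[IDX_N]) - params.r_NH0_A
            for idx in IDX_H_N
        ]
    )
    return ModelState(x=x, yz=yz, R=R, uN=uN, s=s)
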