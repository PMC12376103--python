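"""Short-hydrogen-bond detection and proton-transfer observables.

The proton-transfer (PT) coordinate is delta_r = d(O,H) - d(H,O') for an
SHB triple (donor oxygen O, proton H, acceptor oxygen O'); negative values
mean the proton sits on the donor, zero a perfectly shared proton.  The
heavy-atom compression coordinate R is the donor-acceptor O-O distance.
One-dimensional free-energy profiles are obtained by Boltzmann inversion
F = -kBT ln P(delta_r) with per-bin standard errors from block analysis
(50 fs blocks by default), and the barrier/asymmetry of the profile is read
off its smoothed local minima.  For quantum (multi-bead) trajectories the
bead-resolved delta_r series is pooled, which is the proton's quantum
distribution; a centroid-based reduction is available where a single value
per frame set is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .trajectory_io import Frame, Trajectory, distance, mic_displacement
from .units import kT

__all__ = [
    "SHBTriple",
    "FreeEnergyProfile",
    "JointDistribution",
    "detect_shb",
    "detect_shb_tracked",
    "delta_r",
    "delta_r_series",
    "delta_r_bead_mean",
    "R_series",
    "free_energy_profile",
    "block_errors",
    "barrier_and_asymmetry",
    "joint_dr_R",
]

DR_BINS_DEFAULT = 81
DR_RANGE_DEFAULT = (-0.8, 0.8)
R_BINS_DEFAULT = 60
R_RANGE_DEFAULT = (2.3, 2.8)


@dataclass(frozen=True)
class SHBTriple:
    """Donor oxygen, acceptor oxygen and bridging proton (atom indices).

    The donor is the oxygen nearer the proton in the detection frame; ties
    resolve to the lower atom index.
    """

    donor_O: int
    acceptor_O: int
    H: int


@dataclass
class FreeEnergyProfile:
    """Binned free energy along delta_r, gauge-fixed to min F = 0.

    ``F_meV`` is NaN in empty bins (undefined, not zero); ``err_meV`` holds
    per-bin block standard errors when attached.
    """

    bin_centers: np.ndarray
    F_meV: np.ndarray
    err_meV: Optional[np.ndarray]
    T_K: float
    n_samples: int


@dataclass
class JointDistribution:
    """2D histogram of (delta_r, R) with F = -kBT ln P where counts > 0.

    ``rho_abs_dr_R`` is the Pearson correlation between |delta_r| and R,
    the compression-transfer coupling scalar.
    """

    dr_edges: np.ndarray
    R_edges: np.ndarray
    counts: np.ndarray
    F_meV: np.ndarray
    rho_abs_dr_R: float


# -- detection ------------------------------------------------------------


def detect_shb(frame: Frame, oo_cutoff_A: float = 2.60, oh_cutoff_A: float = 1.80) -> List[SHBTriple]:
    """All SHB triples of a frame: O-O pairs under the cutoff bridged by a
    hydrogen within ``oh_cutoff_A`` of both oxygens.

    The cutoff (2.60 A) sits above the nominal 2.5 A SHB ceiling so that
    thermally stretched SHB frames are not dropped.  Wannier records are
    ignored.  The returned list is ordered by (donor, acceptor) index.
    """
    o_idx = frame.indices_of("O")
    h_idx = frame.indices_of("H")
    if len(o_idx) < 2 or len(h_idx) < 1:
        return []
    L = frame.cell.lengths
    pos_o = frame.positions[o_idx]
    pos_h = frame.positions[h_idx]
    triples: List[SHBTriple] = []
    for a in range(len(o_idx)):
        for b in range(a + 1, len(o_idx)):
            d = pos_o[b] - pos_o[a]
            d = d - L * np.floor(d / L + 0.5)
            if np.linalg.norm(d) >= oo_cutoff_A:
                continue
            for hi, rh in zip(h_idx, pos_h):
                da = rh - pos_o[a]
                da = np.linalg.norm(da - L * np.floor(da / L + 0.5))
                db = rh - pos_o[b]
                db = np.linalg.norm(db - L * np.floor(db / L + 0.5))
                if da < oh_cutoff_A and db < oh_cutoff_A:
                    if da <= db:  # tie -> lower atom index is the donor
                        triples.append(SHBTriple(int(o_idx[a]), int(o_idx[b]), int(hi)))
                    else:
                        triples.append(SHBTriple(int(o_idx[b]), int(o_idx[a]), int(hi)))
    triples.sort(key=lambda t: (t.donor_O, t.acceptor_O))
    return triples


def detect_shb_tracked(traj: Trajectory, **kw) -> List[SHBTriple]:
    """Detect SHBs once on the time-averaged structure (beads included).

    Tracking a triple fixed by the averaged geometry keeps the delta_r sign
    convention tied to one donor even when the instantaneous nearer oxygen
    flips during proton transfer.
    """
    mean_frame = Frame(
        species=traj.species,
        positions=traj.positions.mean(axis=0),
        cell=traj.cell,
    )
    return detect_shb(mean_frame, **kw)


# -- PT coordinate --------------------------------------------------------


def delta_r(frame: Frame, shb: SHBTriple) -> float:
    """PT coordinate d(donor,H) - d(H,acceptor) in angstrom (minimum image)."""
    return distance(frame, shb.donor_O, shb.H) - distance(frame, shb.H, shb.acceptor_O)


def delta_r_series(traj: Trajectory, shb: SHBTriple) -> np.ndarray:
    """delta_r for every frame (bead frames included, i.e. bead-pooled)."""
    return traj.distances(shb.donor_O, shb.H) - traj.distances(shb.H, shb.acceptor_O)


def delta_r_bead_mean(traj: Trajectory, shb: SHBTriple) -> np.ndarray:
    """One delta_r value per frame set: the per-frame bead (centroid-like)
    mean of the bead-resolved series.  For classical input this is the plain
    series."""
    dr = delta_r_series(traj, shb)
    if traj.n_beads == 1:
        return dr
    order = traj.frame_index
    sets, inv = np.unique(order, return_inverse=True)
    sums = np.zeros(len(sets))
    counts = np.zeros(len(sets))
    np.add.at(sums, inv, dr)
    np.add.at(counts, inv, 1)
    return sums / counts


def R_series(traj: Trajectory, shb: SHBTriple, per_frame_set: bool = False) -> np.ndarray:
    """Donor-acceptor O-O distance per frame (or once per bead set)."""
    R = traj.distances(shb.donor_O, shb.acceptor_O)
    if per_frame_set and traj.n_beads > 1:
        mask = traj.bead_index == 0
        return R[mask]
    return R


# -- free energy ----------------------------------------------------------


def free_energy_profile(
    dr_series: np.ndarray,
    T_K: float,
    bins: int = DR_BINS_DEFAULT,
    range: Tuple[float, float] = DR_RANGE_DEFAULT,
) -> FreeEnergyProfile:
    """Boltzmann inversion F = -kBT ln P(delta_r), gauge-fixed to min 0.

    Empty bins are NaN.  Quantum input should be the pooled bead-resolved
    series.
    """
    dr = np.asarray(dr_series, dtype=float)
    if dr.size == 0:
        raise ValueError("empty delta_r series")
    counts, edges = np.histogram(dr, bins=bins, range=range)
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore"):
        F = -kT(T_K) * 1000.0 * np.log(counts / dr.size)
    F[counts == 0] = np.nan
    F = F - np.nanmin(F)
    return FreeEnergyProfile(
        bin_centers=centers, F_meV=F, err_meV=None, T_K=T_K, n_samples=int(dr.size)
    )


def block_errors(
    dr_series: np.ndarray,
    dt_fs: float,
    T_K: float,
    block_fs: float = 50.0,
    bins: int = DR_BINS_DEFAULT,
    range: Tuple[float, float] = DR_RANGE_DEFAULT,
) -> np.ndarray:
    """Per-bin standard errors of F from block analysis, in meV.

    The series is cut into contiguous blocks of ``block_fs`` (in frames:
    round(block_fs/dt_fs), at least 1); per-block bin probabilities give the
    between-block spread, propagated to F by the delta method
    sigma_F = kBT * sigma_p / (p * sqrt(Nb)).  NaN where p = 0.
    """
    dr = np.asarray(dr_series, dtype=float)
    Lb = max(1, int(round(block_fs / dt_fs)))
    Nb = dr.size // Lb
    if Nb < 2:
        raise ValueError(
            f"need at least 2 blocks of {Lb} frames, have {dr.size} frames"
        )
    trimmed = dr[: Nb * Lb].reshape(Nb, Lb)
    edges = np.linspace(range[0], range[1], bins + 1)
    probs = np.stack([np.histogram(b, bins=edges)[0] / Lb for b in trimmed])
    p_mean = probs.mean(axis=0)
    sigma_p = probs.std(axis=0, ddof=1)
    err = np.full(bins, np.nan)
    ok = p_mean > 0
    err[ok] = kT(T_K) * 1000.0 * sigma_p[ok] / (p_mean[ok] * np.sqrt(Nb))
    return err


def barrier_and_asymmetry(
    profile: FreeEnergyProfile, min_prominence_meV: float = 1.0
) -> Tuple[float, float, int]:
    """(barrier_meV, asymmetry_meV, n_minima) of a 1D profile.

    Minima are strict local minima of the 3-bin median-smoothed profile with
    a small prominence floor (keeps sparse tail bins from registering).  The
    barrier is the profile maximum between the two deepest minima measured
    from the global minimum; the asymmetry is the depth difference of those
    two minima.  A single-minimum profile returns (0, 0, 1).
    """
    F = profile.F_meV
    finite = np.isfinite(F)
    if not finite.any():
        raise ValueError("profile has no defined bins")
    idx = np.nonzero(finite)[0]
    # largest contiguous run of defined bins
    splits = np.nonzero(np.diff(idx) > 1)[0]
    runs = np.split(idx, splits + 1)
    seg = max(runs, key=len)
    Fs = median_filter(F[seg], size=3, mode="nearest")
    minima, _ = find_peaks(-Fs, prominence=min_prominence_meV)
    n_minima = max(1, len(minima))
    if len(minima) < 2:
        return 0.0, 0.0, n_minima
    deepest = minima[np.argsort(Fs[minima])[:2]]
    lo, hi = sorted(deepest)
    saddle = float(Fs[lo:hi + 1].max())
    global_min = float(Fs[deepest].min())
    barrier = saddle - global_min
    asymmetry = float(abs(Fs[deepest[0]] - Fs[deepest[1]]))
    return barrier, asymmetry, n_minima


def joint_dr_R(
    dr_series: np.ndarray,
    R_series: np.ndarray,
    T_K: float = 300.0,
    bins: Tuple[int, int] = (DR_BINS_DEFAULT, R_BINS_DEFAULT),
    ranges: Tuple[Tuple[float, float], Tuple[float, float]] = (DR_RANGE_DEFAULT, R_RANGE_DEFAULT),
) -> JointDistribution:
    """Joint (delta_r, R) histogram, F surface, and rho(|delta_r|, R)."""
    dr = np.asarray(dr_series, dtype=float)
    R = np.asarray(R_series, dtype=float)
    if dr.shape != R.shape:
        raise ValueError(f"series length mismatch: {dr.shape} vs {R.shape}")
    counts, dr_edges, R_edges = np.histogram2d(dr, R, bins=bins, range=ranges)
    with np.errstate(divide="ignore"):
        F = -kT(T_K) * 1000.0 * np.log(counts / dr.size)
    F[counts == 0] = np.nan
    F = F - np.nanmin(F)
    a = np.abs(dr) - np.abs(dr).mean()
    b = R - R.mean()
    rho = float(np.mean(a * b) / (np.sqrt(np.mean(a * a)) * np.sqrt(np.mean(b * b))))
    return JointDistribution(
        dr_edges=dr_edges, R_edges=R_edges, counts=counts, F_meV=F, rho_abs_dr_R=rho
    )
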