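"""Coupling of the SHB to the ammonium environment.

Radial distribution functions of the SHB oxygens against nitrogen, N-H
bond-length distributions of the ammonium ion, rocking-mode coordinates
d_i,j = d_i - d_j (differences of nitrogen-oxygen distances, which capture
directional displacement of the ion relative to the SHB), and the Pearson
correlation matrix between the PT coordinate and every rocking mode.

Conventions: population (1/n) covariance; signed rho is stored, absolute
values are used for the summary statistics (max|rho|, median|rho|).  For
quantum trajectories the environment coordinates are classical and shared
across beads, so they are taken once per frame set; the PT coordinate is
reduced to its per-frame bead mean before correlating (the bead-pooled
alternative simply repeats the environment series per bead).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .trajectory_io import Frame, Trajectory, mic_displacement

__all__ = [
    "RDFResult",
    "RockingModes",
    "CorrelationMatrix",
    "rdf",
    "nh_bond_lengths",
    "nh_bond_distribution",
    "rocking_modes",
    "pearson",
    "correlation_matrix",
    "shb_aligned_pairs",
    "neighbor_count",
]


@dataclass
class RDFResult:
    """g(r) on bin centers, with the bin width and frame count used."""

    r_centers: np.ndarray
    g_values: np.ndarray
    dr_bin: float
    n_frames: int

    def first_peak(self) -> float:
        """Position of the maximum of g(r)."""
        return float(self.r_centers[np.argmax(self.g_values)])


@dataclass
class RockingModes:
    """Nitrogen-oxygen distance series for the tracked oxygen sites.

    ``d`` has shape (n_sites, n_frame_sets); ``site_labels`` are 1-based
    labels in order of rest-geometry distance from N.  Pair series
    d_i,j = d_i - d_j are generated on demand (antisymmetric by
    construction).
    """

    d: np.ndarray
    site_labels: Sequence[int]
    atom_indices: Sequence[int]

    @property
    def n_sites(self) -> int:
        return self.d.shape[0]

    def pairs(self) -> List[Tuple[int, int]]:
        n = self.n_sites
        return [(i, j) for i in range(n) for j in range(i + 1, n)]

    def pair_series(self, i: int, j: int) -> np.ndarray:
        return self.d[i] - self.d[j]


@dataclass
class CorrelationMatrix:
    """Pearson rho between delta_r and every rocking mode d_i,j.

    ``pair_labels`` uses the 1-based site labels; rho for (j,i) is the
    negative of rho for (i,j) and only i<j pairs are stored.
    """

    pair_labels: List[Tuple[int, int]]
    rho: np.ndarray
    n_samples: int

    @property
    def max_abs_rho(self) -> float:
        return float(np.max(np.abs(self.rho)))

    @property
    def median_abs_rho(self) -> float:
        return float(np.median(np.abs(self.rho)))

    def max_abs_rho_over(self, pairs: Sequence[Tuple[int, int]]) -> float:
        wanted = {tuple(sorted(p)) for p in pairs}
        sel = [k for k, lab in enumerate(self.pair_labels) if tuple(sorted(lab)) in wanted]
        if not sel:
            raise ValueError("none of the requested pairs are present")
        return float(np.max(np.abs(self.rho[sel])))


def rdf(
    traj: Trajectory,
    centers: Sequence[int],
    others: Sequence[int],
    r_max: float,
    dr_bin: float = 0.02,
) -> RDFResult:
    """Radial distribution function of `others` around `centers`.

    Minimum-image histogram normalized by the shell volume 4 pi r^2 dr and
    by the others' number density in the cell; bead frames pool naturally.
    ``r_max`` must not exceed half the shortest cell edge.
    """
    L = traj.cell.lengths
    if r_max > L.min() / 2:
        raise ValueError(f"r_max {r_max} exceeds half the shortest cell edge {L.min() / 2}")
    centers = np.asarray(centers, dtype=int)
    others = np.asarray(others, dtype=int)
    nbin = int(np.ceil(r_max / dr_bin))
    edges = np.arange(nbin + 1) * dr_bin
    counts = np.zeros(nbin)
    n_frames = len(traj)
    chunk = max(1, int(2e7 // max(1, len(centers) * len(others))))
    for start in range(0, n_frames, chunk):
        pos = traj.positions[start:start + chunk]
        d = pos[:, others, None, :] - pos[:, None, centers, :]
        d = d - L * np.floor(d / L + 0.5)
        r = np.linalg.norm(d, axis=-1)
        # discard self pairs if index sets overlap
        same = others[:, None] == centers[None, :]
        r = r[:, ~same] if same.any() else r.reshape(r.shape[0], -1)
        counts += np.histogram(r, bins=edges)[0]
    shell = 4.0 * np.pi * (0.5 * (edges[:-1] + edges[1:])) ** 2 * dr_bin
    density = len(others) / traj.cell.volume
    norm = n_frames * len(centers) * shell * density
    return RDFResult(
        r_centers=0.5 * (edges[:-1] + edges[1:]),
        g_values=counts / norm,
        dr_bin=dr_bin,
        n_frames=n_frames,
    )


def nh_bond_lengths(traj: Trajectory, n_index: int = None, h_cutoff_A: float = 1.6) -> np.ndarray:
    """Pooled N-H bond lengths of the ammonium ion over all frames and beads.

    The four bonded hydrogens are the four nearest to the nitrogen in each
    frame; the fourth-nearest must fall within ``h_cutoff_A`` (generous
    enough for quantum stretch excursions) and the fifth-nearest, if any,
    must fall outside it, otherwise the frame is flagged as malformed.
    """
    if n_index is None:
        n_all = [i for i, s in enumerate(traj.species) if s == "N"]
        if len(n_all) != 1:
            raise ValueError(f"expected exactly one N, found {len(n_all)}; pass n_index")
        n_index = n_all[0]
    h_idx = np.array([i for i, s in enumerate(traj.species) if s == "H"], dtype=int)
    if len(h_idx) < 4:
        raise ValueError(f"only {len(h_idx)} hydrogens present; ammonium needs 4")
    L = traj.cell.lengths
    d = traj.positions[:, h_idx, :] - traj.positions[:, [n_index], :]
    d = d - L * np.floor(d / L + 0.5)
    r = np.sort(np.linalg.norm(d, axis=-1), axis=1)
    bad = np.nonzero(r[:, 3] >= h_cutoff_A)[0]
    if bad.size:
        raise ValueError(
            f"frame {bad[0]}: fourth-nearest hydrogen at {r[bad[0], 3]:.2f} A "
            f"from N (cutoff {h_cutoff_A} A); not an intact ammonium ion"
        )
    if r.shape[1] > 4:
        bad = np.nonzero(r[:, 4] < h_cutoff_A)[0]
        if bad.size:
            raise ValueError(
                f"frame {bad[0]}: {int((r[bad[0]] < h_cutoff_A).sum())} hydrogens "
                f"within {h_cutoff_A} A of N (need exactly 4)"
            )
    return r[:, :4].ravel()


def nh_bond_distribution(
    traj: Trajectory,
    bins: int = 60,
    range: Tuple[float, float] = (0.85, 1.25),
    n_index: int = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram (counts, edges) of the pooled N-H bond lengths."""
    lengths = nh_bond_lengths(traj, n_index=n_index)
    return np.histogram(lengths, bins=bins, range=range)


def rocking_modes(traj: Trajectory, N_index: int, O_indices: Sequence[int]) -> RockingModes:
    """N-O distance series for the tracked oxygen sites, once per frame set.

    ``O_indices`` should already be in site-label order (sorted by rest
    distance from N); labels are assigned 1..n in that order.
    """
    O_indices = list(O_indices)
    if len(O_indices) < 2:
        raise ValueError("need at least two tracked oxygens")
    if traj.n_beads > 1:
        mask = traj.bead_index == 0
    else:
        mask = slice(None)
    pos = traj.positions[mask]
    L = traj.cell.lengths
    d = pos[:, O_indices, :] - pos[:, [N_index], :]
    d = d - L * np.floor(d / L + 0.5)
    dist = np.linalg.norm(d, axis=-1).T  # (n_sites, n_frames)
    return RockingModes(d=dist, site_labels=list(range(1, len(O_indices) + 1)),
                        atom_indices=O_indices)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation Cov(a,b)/(sigma_a sigma_b), population convention."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("series must have equal length >= 2")
    da = a - a.mean()
    db = b - b.mean()
    va = np.mean(da * da)
    vb = np.mean(db * db)
    if va == 0 or vb == 0:
        raise ValueError("undefined correlation: a series has zero variance")
    return float(np.clip(np.mean(da * db) / np.sqrt(va * vb), -1.0, 1.0))


def correlation_matrix(dr_series: np.ndarray, rocking: RockingModes) -> CorrelationMatrix:
    """rho(delta_r, d_i,j) for every ordered site pair i<j.

    Uses the covariance algebra Cov(x, d_i - d_j) = Cov(x,d_i) - Cov(x,d_j)
    so the 66 pair series are never materialized.  The delta_r input must be
    aligned with the once-per-frame-set environment series (bead-mean
    reduced for quantum trajectories).
    """
    x = np.asarray(dr_series, dtype=float)
    d = rocking.d
    if x.shape[0] != d.shape[1]:
        raise ValueError(
            f"delta_r length {x.shape[0]} does not match {d.shape[1]} frame sets"
        )
    xc = x - x.mean()
    dc = d - d.mean(axis=1, keepdims=True)
    cov_xd = dc @ xc / x.size          # (n_sites,)
    cov_dd = dc @ dc.T / x.size        # (n_sites, n_sites)
    var_x = float(np.mean(xc * xc))
    if var_x == 0:
        raise ValueError("undefined correlation: delta_r has zero variance")
    labels = []
    rhos = []
    n = rocking.n_sites
    for i in range(n):
        for j in range(i + 1, n):
            var_ij = cov_dd[i, i] + cov_dd[j, j] - 2 * cov_dd[i, j]
            if var_ij <= 0:
                raise ValueError(
                    f"undefined correlation: pair ({rocking.site_labels[i]}, "
                    f"{rocking.site_labels[j]}) has zero variance"
                )
            rho = (cov_xd[i] - cov_xd[j]) / np.sqrt(var_x * var_ij)
            labels.append((rocking.site_labels[i], rocking.site_labels[j]))
            rhos.append(rho)
    return CorrelationMatrix(
        pair_labels=labels, rho=np.clip(np.array(rhos), -1.0, 1.0), n_samples=int(x.size)
    )


def shb_aligned_pairs(
    fixture: Frame,
    rocking: RockingModes,
    e_shb: np.ndarray = None,
    cos_min: float = 0.8,
) -> List[Tuple[int, int]]:
    """Site-label pairs whose separation vector aligns with the SHB axis.

    A pair (i, j) counts as SHB-aligned when the unit vector between the two
    oxygen sites (rest geometry) has |cos| > ``cos_min`` with the SHB axis.
    """
    if e_shb is None:
        e_shb = fixture.meta.get("e_shb")
    e = np.asarray(e_shb, dtype=float)
    e = e / np.linalg.norm(e)
    pos = fixture.positions
    out = []
    for (i, j) in rocking.pairs():
        v = mic_displacement(
            pos[rocking.atom_indices[i]], pos[rocking.atom_indices[j]], fixture.cell
        )
        cosang = abs(np.dot(v, e)) / np.linalg.norm(v)
        if cosang > cos_min:
            out.append((rocking.site_labels[i], rocking.site_labels[j]))
    return out


def neighbor_count(frame: Frame, center: int, species: str, radius_A: float) -> int:
    """Number of minimum-image neighbors of a species strictly within a radius."""
    L = frame.cell.lengths
    if radius_A > L.min() / 2:
        raise ValueError(f"radius {radius_A} exceeds half the shortest cell edge")
    idx = [i for i in frame.indices_of(species) if i != center]
    if not idx:
        return 0
    d = frame.positions[idx] - frame.positions[center]
    d = d - L * np.floor(d / L + 0.5)
    return int(np.sum(np.linalg.norm(d, axis=1) < radius_A))
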