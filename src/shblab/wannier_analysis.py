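"""Assignment and classification of Wannier-center records.

Wannier centers (maximally localized electron pairs, stored as "X"
pseudo-atoms) are assigned to their nearest oxygen within a cutoff and
classified against the oxygen's covalent partners by direction cosine:
the center best aligned with O->C is the C-O bond pair, the best remaining
alignment with O->H (when a hydrogen partner exists) is the O-H bond pair,
and everything else is a lone pair.  Direction-based classification is
robust to the outward shift of O-H bond centers under quantum sampling,
which moves their distances into the lone-pair range and breaks
distance-threshold rules.

For a proton shared near the SHB midpoint both oxygens fall within the
hydrogen-partner cutoff, so both may carry an O-H label - the operational
reading of the partial covalency of a symmetrized SHB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .trajectory_io import Frame, Trajectory, mic_displacement

__all__ = [
    "CO_BOND",
    "OH_BOND",
    "LONE_PAIR",
    "WannierAssignment",
    "Histogram1D",
    "assign_wcs",
    "classify_wcs",
    "wc_distances_by_label",
    "wc_distance_distributions",
    "peak_location",
]

CO_BOND = "CO_BOND"
OH_BOND = "OH_BOND"
LONE_PAIR = "LONE_PAIR"


@dataclass
class WannierAssignment:
    """One Wannier center attached to its host oxygen."""

    wc_index: int
    host_O: int
    distance_A: float
    label: Optional[str] = None


@dataclass
class Histogram1D:
    """Plain 1D histogram with bin centers; used for WC distance spectra."""

    counts: np.ndarray
    edges: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def assign_wcs(
    frame: Frame,
    cutoff_A: float = 0.8,
    require_four_for: Optional[Sequence[int]] = None,
) -> Dict[int, List[WannierAssignment]]:
    """Assign each Wannier center to its nearest oxygen within the cutoff.

    Returns assignments grouped by host oxygen index.  Unassigned centers
    are reported under key -1, never silently dropped.  Equidistant ties go
    to the lower oxygen index with a warning.  When ``require_four_for``
    lists oxygens of interest, each must receive exactly four centers.
    """
    wc_idx = frame.indices_of("X")
    if len(wc_idx) == 0:
        raise ValueError("frame contains no Wannier-center (X) records")
    o_idx = frame.indices_of("O")
    if len(o_idx) == 0:
        raise ValueError("frame contains no oxygen atoms")
    L = frame.cell.lengths
    d = frame.positions[wc_idx][:, None, :] - frame.positions[o_idx][None, :, :]
    d = d - L * np.floor(d / L + 0.5)
    dist = np.linalg.norm(d, axis=-1)  # (n_wc, n_O)
    groups: Dict[int, List[WannierAssignment]] = {}
    for w in range(len(wc_idx)):
        order = np.argsort(dist[w], kind="stable")  # stable -> lower index on ties
        best = order[0]
        if len(order) > 1 and dist[w, order[1]] == dist[w, best]:
            warnings.warn(
                f"Wannier center {wc_idx[w]} equidistant from oxygens "
                f"{o_idx[best]} and {o_idx[order[1]]}; assigning to the lower index"
            )
        if dist[w, best] <= cutoff_A:
            host = int(o_idx[best])
        else:
            host = -1
        groups.setdefault(host, []).append(
            WannierAssignment(
                wc_index=int(wc_idx[w]), host_O=host, distance_A=float(dist[w, best])
            )
        )
    if require_four_for is not None:
        bad = {o: len(groups.get(o, [])) for o in require_four_for if len(groups.get(o, [])) != 4}
        if bad:
            raise ValueError(
                "oxygens with a Wannier-center count other than 4: "
                + ", ".join(f"atom {o}: {n}" for o, n in bad.items())
            )
    return groups


def classify_wcs(
    frame: Frame,
    assignment: Dict[int, List[WannierAssignment]],
    c_cutoff_A: float = 1.45,
    h_cutoff_A: float = 1.3,
    extra_h: Optional[Sequence[int]] = None,
) -> Dict[int, List[WannierAssignment]]:
    """Label assigned centers as CO_BOND / OH_BOND / LONE_PAIR in place.

    For each host oxygen the center with maximal direction cosine to O->C
    (carbon partner within ``c_cutoff_A``; required) becomes CO_BOND; among
    the rest, the maximal cosine to O->H becomes OH_BOND if a hydrogen
    partner exists within ``h_cutoff_A`` (``extra_h`` can force candidate
    hydrogens, e.g. the tracked SHB proton); the remainder are LONE_PAIR.
    Labels are independent of the order of the WC records.
    """
    c_idx = frame.indices_of("C")
    h_idx = list(frame.indices_of("H"))
    if extra_h:
        h_idx = sorted(set(h_idx) | set(int(i) for i in extra_h))
    for host, wcs in assignment.items():
        if host < 0:
            continue
        r_o = frame.positions[host]
        if len(c_idx) == 0:
            raise ValueError(f"oxygen {host}: no carbon atoms present for classification")
        dc = np.array([
            np.linalg.norm(mic_displacement(r_o, frame.positions[c], frame.cell))
            for c in c_idx
        ])
        if dc.min() > c_cutoff_A:
            raise ValueError(
                f"oxygen {host}: no carbon partner within {c_cutoff_A} A "
                f"(nearest at {dc.min():.2f} A)"
            )
        e_c = mic_displacement(r_o, frame.positions[c_idx[int(np.argmin(dc))]], frame.cell)
        e_c = e_c / np.linalg.norm(e_c)
        e_h = None
        if h_idx:
            dh = np.array([
                np.linalg.norm(mic_displacement(r_o, frame.positions[h], frame.cell))
                for h in h_idx
            ])
            if dh.min() <= h_cutoff_A:
                e_h = mic_displacement(
                    r_o, frame.positions[h_idx[int(np.argmin(dh))]], frame.cell
                )
                e_h = e_h / np.linalg.norm(e_h)
        dirs = np.stack([
            mic_displacement(r_o, frame.positions[a.wc_index], frame.cell) for a in wcs
        ])
        dirs = dirs / np.linalg.norm(dirs, axis=1)[:, None]
        cos_c = dirs @ e_c
        i_co = int(np.argmax(cos_c))
        for a in wcs:
            a.label = LONE_PAIR
        wcs[i_co].label = CO_BOND
        if e_h is not None:
            cos_h = dirs @ e_h
            cos_h[i_co] = -np.inf
            wcs[int(np.argmax(cos_h))].label = OH_BOND
    return assignment


def wc_distances_by_label(
    traj: Trajectory,
    oxygens: Optional[Sequence[int]] = None,
    cutoff_A: float = 0.8,
) -> Dict[str, np.ndarray]:
    """Pooled WC-oxygen distances per label over all frames and beads.

    ``oxygens`` restricts the analysis to the oxygens of interest (default:
    every oxygen that receives a full complement of four centers in the
    first frame).  Bead frames pool, which is identical to averaging the
    per-bead histograms.
    """
    if oxygens is None:
        first = assign_wcs(traj[0], cutoff_A=cutoff_A)
        oxygens = sorted(o for o, wcs in first.items() if o >= 0 and len(wcs) == 4)
        if not oxygens:
            raise ValueError("no oxygen receives four Wannier centers in the first frame")
    out: Dict[str, List[float]] = {CO_BOND: [], OH_BOND: [], LONE_PAIR: []}
    for i in range(len(traj)):
        frame = traj[i]
        groups = assign_wcs(frame, cutoff_A=cutoff_A, require_four_for=oxygens)
        classify_wcs(frame, groups)
        for o in oxygens:
            for a in groups[o]:
                out[a.label].append(a.distance_A)
    return {k: np.array(v) for k, v in out.items()}


def wc_distance_distributions(
    traj: Trajectory,
    label: str,
    bin_A: float = 0.01,
    range_A: Tuple[float, float] = (0.0, 0.8),
    oxygens: Optional[Sequence[int]] = None,
    cutoff_A: float = 0.8,
) -> Histogram1D:
    """Bead-averaged histogram of WC-oxygen distances for one label."""
    dists = wc_distances_by_label(traj, oxygens=oxygens, cutoff_A=cutoff_A)[label]
    nbin = int(round((range_A[1] - range_A[0]) / bin_A))
    counts, edges = np.histogram(dists, bins=nbin, range=range_A)
    return Histogram1D(counts=counts, edges=edges)


def peak_location(histogram: Histogram1D) -> float:
    """Mode of a histogram: center of the maximal bin after 3-bin mean
    smoothing.  Ties on the smoothed value resolve to the larger raw count
    (so a delta-like spike keeps its own bin), then to the lower center."""
    c = np.asarray(histogram.counts, dtype=float)
    if c.sum() == 0:
        raise ValueError("empty histogram")
    smooth = np.convolve(c, np.ones(3) / 3.0, mode="same")
    best = np.nonzero(smooth >= smooth.max() - 1e-12 * max(1.0, smooth.max()))[0]
    i = best[np.argmax(c[best])]
    return float(histogram.centers[int(i)])
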