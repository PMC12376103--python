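"""Run configuration and the one-shot analysis report.

``RunConfig`` mirrors a flat TOML file with ``[model]``, ``[wannier]``,
``[sampling]``, ``[analysis]`` and ``[paths]`` tables; unknown keys are
rejected so that typos never silently fall back to defaults.  Every output
file embeds the sha256 hash of the canonical configuration, and re-running
with the stored configuration reproduces all numbers exactly.

``run_report`` wires the full analysis chain - PT free-energy profiles with
block errors, joint (delta_r, R) distributions, RDFs, N-H distributions,
rocking-mode correlation matrices and Wannier-center spectra - over a
classical and an optional quantum trajectory, writing TSV tables plus one
JSON summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tomllib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import env_analysis as env
from . import pt_analysis as pt
from . import wannier_analysis as wan
from .shb_model import SHBModelParams, WannierEmissionParams, build_pyro_fixture, tracked_oxygen_sites
from .samplers import SamplerConfig
from .trajectory_io import Trajectory

__all__ = ["AnalysisConfig", "RunConfig", "run_report"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Histogram and cutoff settings shared by the analysis stages."""

    dr_bins: int = 81
    dr_min: float = -0.8
    dr_max: float = 0.8
    R_bins: int = 60
    R_min: float = 2.3
    R_max: float = 2.8
    block_fs: float = 50.0
    oo_cutoff_A: float = 2.60
    oh_cutoff_A: float = 1.80
    rdf_r_max_A: float = 5.0
    rdf_dr_bin_A: float = 0.02
    wc_bin_A: float = 0.01
    wc_cutoff_A: float = 0.8
    aligned_cos_min: float = 0.8


@dataclass
class RunConfig:
    """Validated run configuration (model + sampling + analysis + paths)."""

    model: SHBModelParams = field(default_factory=SHBModelParams)
    sampling: SamplerConfig = field(default_factory=SamplerConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {"model", "wannier", "sampling", "analysis", "paths"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config tables: {sorted(unknown)}")

        def build(dc, table, name):
            fields = {f.name for f in dataclasses.fields(dc)} - {"wc"}
            bad = set(table) - fields
            if bad:
                raise ValueError(f"unknown keys in [{name}]: {sorted(bad)}")
            return table

        model_kw = build(SHBModelParams, data.get("model", {}), "model")
        wc_kw = build(WannierEmissionParams, data.get("wannier", {}), "wannier")
        sampling_kw = build(SamplerConfig, data.get("sampling", {}), "sampling")
        analysis_kw = build(AnalysisConfig, data.get("analysis", {}), "analysis")
        return cls(
            model=SHBModelParams(**model_kw, wc=WannierEmissionParams(**wc_kw)),
            sampling=SamplerConfig(**sampling_kw),
            analysis=AnalysisConfig(**analysis_kw),
            paths=dict(data.get("paths", {})),
        )

    @classmethod
    def from_toml(cls, path: str) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_dict(self) -> dict:
        model = dataclasses.asdict(self.model)
        wannier = model.pop("wc")
        return {
            "model": model,
            "wannier": wannier,
            "sampling": dataclasses.asdict(self.sampling),
            "analysis": dataclasses.asdict(self.analysis),
            "paths": dict(self.paths),
        }

    def to_toml(self) -> str:
        lines = []
        for table, entries in self.to_dict().items():
            lines.append(f"[{table}]")
            for k, v in entries.items():
                if isinstance(v, bool):
                    lines.append(f"{k} = {'true' if v else 'false'}")
                elif isinstance(v, (int, float)):
                    lines.append(f"{k} = {v!r}")
                else:
                    lines.append(f'{k} = "{v}"')
            lines.append("")
        return "\n".join(lines)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(path: str, header: str, columns, confhash: str) -> None:
    arr = np.column_stack(columns)
    np.savetxt(path, arr, delimiter="\t", header=f"config={confhash}\n{header}", fmt="%.8g")


def _profile_block(traj: Trajectory, shb, cfg: AnalysisConfig):
    a = cfg
    dr = pt.delta_r_series(traj, shb)
    prof = pt.free_energy_profile(
        dr, traj.temperature_K, bins=a.dr_bins, range=(a.dr_min, a.dr_max)
    )
    prof.err_meV = pt.block_errors(
        dr, traj.dt_fs, traj.temperature_K, block_fs=a.block_fs,
        bins=a.dr_bins, range=(a.dr_min, a.dr_max),
    )
    barrier, asym, n_min = pt.barrier_and_asymmetry(prof)
    R = pt.R_series(traj, shb)
    joint = pt.joint_dr_R(
        dr, R, traj.temperature_K, bins=(a.dr_bins, a.R_bins),
        ranges=((a.dr_min, a.dr_max), (a.R_min, a.R_max)),
    )
    return dr, prof, (barrier, asym, n_min), joint, R


def run_report(
    classical_traj: Trajectory,
    quantum_traj: Optional[Trajectory],
    config: RunConfig,
    outdir: str,
) -> dict:
    """Produce the full TSV + JSON report bundle for a run pair.

    The quantum trajectory may be None, in which case the corresponding
    summary entries are explicit nulls.  Any stage failure aborts with the
    stage name prefixed to the error.
    """
    os.makedirs(outdir, exist_ok=True)
    a = config.analysis
    chash = config.config_hash()
    summary: dict = {"config_hash": chash, "parameters": config.to_dict()}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"report stage '{name}' failed: {exc}") from exc

    fixture = build_pyro_fixture(config.model)
    sites = tracked_oxygen_sites(fixture)

    def do_pt(traj, tag):
        triples = pt.detect_shb_tracked(traj, oo_cutoff_A=a.oo_cutoff_A, oh_cutoff_A=a.oh_cutoff_A)
        if not triples:
            raise ValueError(f"no SHB detected in {tag} trajectory")
        shb = triples[0]
        dr, prof, (barrier, asym, n_min), joint, R = _profile_block(traj, shb, a)
        _write_tsv(
            os.path.join(outdir, f"profile_{tag}.tsv"),
            "bin_center_A\tF_meV\terr_meV",
            (prof.bin_centers, prof.F_meV, prof.err_meV),
            chash,
        )
        np.savetxt(
            os.path.join(outdir, f"joint_dr_R_{tag}.tsv"),
            joint.F_meV,
            delimiter="\t",
            header=f"config={chash}\nF(delta_r, R) in meV; rows delta_r bins, cols R bins",
            fmt="%.6g",
        )
        summary[f"{tag}_barrier_meV"] = barrier
        summary[f"{tag}_asymmetry_meV"] = asym
        summary[f"{tag}_n_minima"] = n_min
        summary[f"{tag}_rho_absdr_R"] = joint.rho_abs_dr_R
        summary[f"{tag}_mean_R_A"] = float(np.mean(R))
        return shb

    shb_cl = stage("pt_classical", lambda: do_pt(classical_traj, "classical"))

    def do_env(traj, shb, tag, reduce_beads):
        n_index = int(traj.species.index("N"))
        rock = env.rocking_modes(traj, n_index, list(sites))
        if reduce_beads:
            dr = pt.delta_r_bead_mean(traj, shb)
        else:
            dr = pt.delta_r_series(traj, shb)
        corr = env.correlation_matrix(dr, rock)
        aligned = env.shb_aligned_pairs(fixture, rock, cos_min=a.aligned_cos_min)
        _write_tsv(
            os.path.join(outdir, f"correlation_{tag}.tsv"),
            "site_i\tsite_j\trho",
            (
                np.array([p[0] for p in corr.pair_labels]),
                np.array([p[1] for p in corr.pair_labels]),
                corr.rho,
            ),
            chash,
        )
        for o_tag, o_idx in (("donor", shb.donor_O), ("acceptor", shb.acceptor_O)):
            g = env.rdf(traj, [o_idx], [n_index], r_max=a.rdf_r_max_A, dr_bin=a.rdf_dr_bin_A)
            _write_tsv(
                os.path.join(outdir, f"rdf_{o_tag}_N_{tag}.tsv"),
                "r_A\tg",
                (g.r_centers, g.g_values),
                chash,
            )
            summary[f"{tag}_rdf_peak_{o_tag}_N_A"] = g.first_peak()
        lengths = env.nh_bond_lengths(traj, n_index=n_index)
        counts, edges = np.histogram(lengths, bins=60, range=(0.85, 1.25))
        _write_tsv(
            os.path.join(outdir, f"nh_lengths_{tag}.tsv"),
            "r_center_A\tcount",
            (0.5 * (edges[:-1] + edges[1:]), counts),
            chash,
        )
        summary[f"{tag}_max_abs_rho"] = corr.max_abs_rho
        summary[f"{tag}_max_abs_rho_shb_aligned"] = corr.max_abs_rho_over(aligned)
        summary[f"{tag}_median_abs_rho"] = corr.median_abs_rho
        summary[f"{tag}_nh_std_A"] = float(np.std(lengths))
        summary["shb_aligned_pairs"] = [list(p) for p in aligned]

    stage("env_classical", lambda: do_env(classical_traj, shb_cl, "classical", False))

    def do_wannier(traj, tag):
        if "X" not in traj.species:
            summary[f"{tag}_wc"] = None
            return
        out = {}
        by_label = wan.wc_distances_by_label(traj, cutoff_A=a.wc_cutoff_A)
        nbin = int(round(0.8 / a.wc_bin_A))
        for label in (wan.CO_BOND, wan.OH_BOND, wan.LONE_PAIR):
            dists = by_label[label]
            counts, edges = np.histogram(dists, bins=nbin, range=(0.0, 0.8))
            hist = wan.Histogram1D(counts=counts, edges=edges)
            _write_tsv(
                os.path.join(outdir, f"wc_{label.lower()}_{tag}.tsv"),
                "r_center_A\tcount",
                (hist.centers, hist.counts),
                chash,
            )
            out[label] = {
                "mode_A": wan.peak_location(hist),
                "mean_A": float(np.mean(dists)),
                "std_A": float(np.std(dists)),
            }
        summary[f"{tag}_wc"] = out

    stage("wannier_classical", lambda: do_wannier(classical_traj, "classical"))

    if quantum_traj is not None:
        shb_q = stage("pt_quantum", lambda: do_pt(quantum_traj, "quantum"))
        stage("env_quantum", lambda: do_env(quantum_traj, shb_q, "quantum", True))
        stage("wannier_quantum", lambda: do_wannier(quantum_traj, "quantum"))
    else:
        for key in (
            "quantum_barrier_meV", "quantum_asymmetry_meV", "quantum_n_minima",
            "quantum_rho_absdr_R", "quantum_mean_R_A", "quantum_max_abs_rho",
            "quantum_max_abs_rho_shb_aligned", "quantum_median_abs_rho",
            "quantum_nh_std_A", "quantum_wc",
        ):
            summary[key] = None

    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
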