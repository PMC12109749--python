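"""Config-driven orchestration: generate, analyze, and report stages.

A run takes a YAML config plus a seed, writes every artifact into the output
directory, and records a manifest (parameters, seed, package version, and a
SHA-256 checksum per output) so any number in a report is traceable to a
stage output.  Runs are deterministic given config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .builder import DuplexBuildSpec
from .core import DnabowError, Selection, Trajectory, trailing_window
from .alignment import rmsd_series, rmsf_two_pass
from .basepairs import (
    DEFAULT_WINDOW_FRACTION,
    delta_c6,
    delta_wc,
    molecule_mean,
    residue_profile,
    spring_pair_distance,
)
from .fret import EmissionSpectrum, dose_response, relative_change
from .hbonds import (
    HBondCriteria,
    all_pair_hbond_counts,
    hbond_distribution,
    mean_hbonds_per_bp,
    smooth_series,
)
from .ions import mg_p_pairs, residence_analysis, shell_series
from .melting import MeltingCurve, tm_vs_condition
from .io import ground_truth_frames, read_trajectory, write_pdb, write_xyz
from .synthetic import (
    IonSpec,
    MeltingSimSpec,
    SpectrumSimSpec,
    SpringSpec,
    TrajectorySimSpec,
    simulate_melting_curve,
    simulate_spectrum,
    simulate_trajectory,
)

__all__ = ["PipelineConfig", "PipelineStageError", "run", "compare_conditions"]

log = logging.getLogger("dnabow")

MODES = ("generate", "analyze-traj", "melt", "fret", "report")


class PipelineStageError(DnabowError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """One pipeline invocation.

    ``params`` carries the mode-specific section of the YAML file verbatim;
    analysis defaults mirror the standard criteria (3.0 A / 20 deg hydrogen
    bonds, 5 A ion shell, 101-frame smoothing, trailing 100/260 window).
    """

    mode: str
    out_dir: str = "dnabow_out"
    seed: int = 0
    log_level: str = "INFO"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    @classmethod
    def from_yaml(cls, path, mode=None, out_dir=None, seed=None, log_level=None):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        m = mode or raw.get("mode")
        return cls(
            mode=m,
            out_dir=out_dir or raw.get("out_dir", "dnabow_out"),
            seed=seed if seed is not None else int(raw.get("seed", 0)),
            log_level=log_level or raw.get("log_level", "INFO"),
            params=raw.get(m.replace("-", "_"), raw.get("params", raw)),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _build_traj_spec(params: dict, seed: int) -> TrajectorySimSpec:
    p = dict(params)
    build = DuplexBuildSpec(**p.pop("build", {}))
    ions = tuple(IonSpec(**d) for d in p.pop("ions", []))
    spring = p.pop("spring_pair", None)
    kwargs = {}
    for key in ("n_frames", "dt_ns", "open_displacement", "mean_open_dwell_ns", "box"):
        if key in p:
            kwargs[key] = p[key]
    for key in ("sigma_per_residue", "open_prob_per_residue"):
        if key in p:
            kwargs[key] = np.asarray(p[key], dtype=float)
    return TrajectorySimSpec(
        build=build,
        ions=ions,
        spring_pair=None if spring is None else SpringSpec(**spring),
        seed=seed,
        **kwargs,
    )


def _stage_generate(cfg: PipelineConfig, out: Path) -> list[Path]:
    written = []
    p = cfg.params
    if "trajectory" in p:
        spec = _build_traj_spec(p["trajectory"], cfg.seed)
        traj, truth = simulate_trajectory(spec)
        write_pdb(out / "topology.pdb", traj.topology, traj.coords[0])
        write_xyz(out / "trajectory.xyz", traj)
        gt_pairs, gt_ions = ground_truth_frames(truth)
        gt_pairs.to_csv(out / "ground_truth_pairs.csv", index=False)
        gt_ions.to_csv(out / "ground_truth_ions.csv", index=False)
        (out / "trajectory_meta.json").write_text(
            json.dumps({"dt_ns": spec.dt_ns, "n_frames": spec.n_frames,
                        "box": list(spec.box), "seed": cfg.seed})
        )
        written += [
            out / "topology.pdb", out / "trajectory.xyz",
            out / "ground_truth_pairs.csv", out / "ground_truth_ions.csv",
            out / "trajectory_meta.json",
        ]
    for i, mdict in enumerate(p.get("melting", [])):
        spec = MeltingSimSpec(**{**mdict, "seed": cfg.seed + i})
        curve = simulate_melting_curve(spec)
        path = out / f"melting_{i:02d}.csv"
        with open(path, "w") as fh:
            fh.write(f"# condition: {spec.label}\n# tm_true: {spec.tm_true}\n")
            pd.DataFrame(
                {"temperature_C": curve.temperatures, "absorbance": curve.absorbance}
            ).to_csv(fh, index=False)
        written.append(path)
    for i, sdict in enumerate(p.get("spectra", [])):
        spec = SpectrumSimSpec(**{**sdict, "seed": cfg.seed + 1000 + i})
        spectrum = simulate_spectrum(spec)
        path = out / f"spectrum_{i:02d}.csv"
        with open(path, "w") as fh:
            fh.write(
                f"# construct: {spec.construct}\n# concentration_uM: {spec.label}\n"
                f"# epr_true: {spec.epr_true}\n"
            )
            pd.DataFrame(
                {"wavelength_nm": spectrum.wavelengths, "intensity": spectrum.intensities}
            ).to_csv(fh, index=False)
        written.append(path)
    return written


def _read_header_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
    return meta


def _stage_analyze(cfg: PipelineConfig, out: Path) -> list[Path]:
    p = cfg.params
    traj = read_trajectory(p["pdb"], p["trajectory"], float(p.get("dt_ns", 0.1)),
                           box=p.get("box"))
    wf = float(p.get("window_fraction", DEFAULT_WINDOW_FRACTION))
    criteria = HBondCriteria(
        d_cut=float(p.get("hbond_distance_cutoff", 3.0)),
        angle_cut=float(p.get("hbond_angle_cutoff", 20.0)),
    )
    smooth_win = int(p.get("smoothing_window", 101))
    shell_cutoff = float(p.get("shell_cutoff", 5.0))
    written = []

    t = traj.times_ns
    rmsd = rmsd_series(traj)
    pd.DataFrame({"time_ns": t, "rmsd_A": rmsd}).to_csv(out / "rmsd.csv", index=False)
    written.append(out / "rmsd.csv")
    for name in ("C6", "P"):
        prof = rmsf_two_pass(traj, Selection.of(names={name}, chains={"B", "C"}))
        topo = traj.topology
        pd.DataFrame(
            {
                "atom_serial": topo.serial[prof.atom_indices],
                "atom_name": topo.name[prof.atom_indices],
                "res_id": topo.res_id[prof.atom_indices],
                "rmsf_A": prof.rmsf,
            }
        ).to_csv(out / f"rmsf_{name}.csv", index=False)
        written.append(out / f"rmsf_{name}.csv")

    rows = []
    series_c6, series_wc = [], []
    for pair in traj.topology.pairs:
        s_c6 = delta_c6(traj, pair)
        s_wc = delta_wc(traj, pair)
        series_c6.append(s_c6)
        series_wc.append(s_wc)
        for metric, s in (("dC6", s_c6), ("dWC", s_wc)):
            rows.append(
                pd.DataFrame(
                    {
                        "frame": np.arange(traj.n_frames),
                        "time_ns": t,
                        "pair_res_b": pair.res_b,
                        "metric": metric,
                        "value_A": s.values,
                    }
                )
            )
    pd.concat(rows).to_csv(out / "basepair_series.csv", index=False)
    written.append(out / "basepair_series.csv")
    prof_c6 = residue_profile(series_c6, wf)
    prof_wc = residue_profile(series_wc, wf)
    prof_c6.to_frame().to_csv(out / "profile_dC6.csv", index=False)
    prof_wc.to_frame().to_csv(out / "profile_dWC.csv", index=False)
    written += [out / "profile_dC6.csv", out / "profile_dWC.csv"]
    pd.DataFrame({"time_ns": t, "dC6_2_29_A": spring_pair_distance(traj)}).to_csv(
        out / "spring_distance.csv", index=False
    )
    written.append(out / "spring_distance.csv")

    counts = all_pair_hbond_counts(traj, criteria)
    hb_rows = []
    for k, pair in enumerate(traj.topology.pairs):
        hb_rows.append(
            pd.DataFrame(
                {
                    "frame": np.arange(traj.n_frames),
                    "pair_res_b": pair.res_b,
                    "n_hbonds": counts[:, k],
                    "n_hbonds_smoothed": smooth_series(counts[:, k], smooth_win),
                }
            )
        )
    pd.concat(hb_rows).to_csv(out / "hbond_counts.csv", index=False)
    written.append(out / "hbond_counts.csv")
    nhb_series, nhb_scalar = mean_hbonds_per_bp(traj, criteria, wf, pair_counts=counts)
    pd.DataFrame({"time_ns": t, "mean_nhb": nhb_series}).to_csv(
        out / "nhb_mean.csv", index=False
    )
    written.append(out / "nhb_mean.csv")
    win = trailing_window(traj.n_frames, wf)
    per_pair_trailing = counts[win].mean(axis=0)
    hist, edges = hbond_distribution(per_pair_trailing)
    pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": hist}
    ).to_csv(out / "nhb_distribution.csv", index=False)
    written.append(out / "nhb_distribution.csv")

    summary = {
        "rmsd_trailing_mean_A": float(rmsd[win].mean()),
        "dC6_molecule_mean_A": molecule_mean(prof_c6),
        "dWC_molecule_mean_A": molecule_mean(prof_wc),
        "nhb_trailing_mean": nhb_scalar,
        "window_fraction": wf,
    }
    if traj.topology.ion_mask.any():
        ss = shell_series(traj, shell_cutoff)
        ss.to_frame(traj.dt_ns).to_csv(out / "ion_shell.csv", index=False)
        written.append(out / "ion_shell.csv")
        res_rows = []
        for sp in ("MG", "NA", "CL"):
            for r in residence_analysis(traj, sp, shell_cutoff):
                res_rows.append(
                    {"ion_serial": r.serial, "species": r.species,
                     "t_total_ns": r.total_ns, "n_intervals": len(r.intervals_ns)}
                )
        pd.DataFrame(res_rows).to_csv(out / "ion_residence.csv", index=False)
        written.append(out / "ion_residence.csv")
        mgp = mg_p_pairs(traj, window_fraction=wf)
        mgp_rows = []
        for pairser in mgp:
            mgp_rows.append(
                pd.DataFrame(
                    {
                        "frame": np.arange(traj.n_frames),
                        "mg_serial": pairser.mg_serial,
                        "p_serial": pairser.p_serial,
                        "dist_A": pairser.distances,
                    }
                )
            )
        (pd.concat(mgp_rows) if mgp_rows else pd.DataFrame(
            columns=["frame", "mg_serial", "p_serial", "dist_A"]
        )).to_csv(out / "mg_p_pairs.csv", index=False)
        written.append(out / "mg_p_pairs.csv")
        summary.update(ss.trailing_means(wf))
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    written.append(out / "summary.json")
    return written


def _stage_melt(cfg: PipelineConfig, out: Path) -> list[Path]:
    curves = []
    for entry in cfg.params["files"]:
        path = entry["path"] if isinstance(entry, dict) else entry
        meta = _read_header_meta(path)
        label = (
            entry.get("condition") if isinstance(entry, dict) else None
        ) or meta.get("condition", str(path))
        df = pd.read_csv(path, comment="#")
        curves.append(
            MeltingCurve(df["temperature_C"].to_numpy(), df["absorbance"].to_numpy(), label)
        )
    table = tm_vs_condition(curves)
    table.to_csv(out / "tm_table.csv", index=False)
    return [out / "tm_table.csv"]


def _stage_fret(cfg: PipelineConfig, out: Path) -> list[Path]:
    spectra = []
    for entry in cfg.params["files"]:
        path = entry["path"] if isinstance(entry, dict) else entry
        meta = _read_header_meta(path)
        df = pd.read_csv(path, comment="#")
        spectra.append(
            EmissionSpectrum(
                df["wavelength_nm"].to_numpy(),
                df["intensity"].to_numpy(),
                label=float(meta.get("concentration_uM", 0) or 0),
                construct=meta.get("construct", "PI"),
            )
        )
    table = dose_response(spectra)
    table.to_csv(out / "dose_response.csv", index=False)
    written = [out / "dose_response.csv"]
    deltas = []
    for construct, grp in table.groupby("construct"):
        q = dict(zip(grp["concentration_uM"], grp["e_pr"]))
        if 0 in q or 0.0 in q:
            d = relative_change(q)
            d.insert(0, "construct", construct)
            deltas.append(d)
    if deltas:
        pd.concat(deltas).to_csv(out / "relative_change.csv", index=False)
        written.append(out / "relative_change.csv")
    return written


def compare_conditions(summary_paths: list) -> pd.DataFrame:
    """Join per-condition analyze summaries into one comparison table."""
    rows = []
    for entry in summary_paths:
        if isinstance(entry, dict):
            path, cond = entry["path"], entry.get("condition")
        else:
            path, cond = entry, None
        s = json.loads(Path(path).read_text())
        s["condition"] = cond if cond is not None else str(Path(path).parent.name)
        rows.append(s)
    df = pd.DataFrame(rows)
    front = ["condition"]
    return df[front + [c for c in df.columns if c not in front]].sort_values(
        "condition", kind="stable"
    ).reset_index(drop=True)


def _stage_report(cfg: PipelineConfig, out: Path) -> list[Path]:
    table = compare_conditions(cfg.params["summaries"])
    table.to_csv(out / "condition_comparison.csv", index=False)
    return [out / "condition_comparison.csv"]


_STAGES = {
    "generate": _stage_generate,
    "analyze-traj": _stage_analyze,
    "melt": _stage_melt,
    "fret": _stage_fret,
    "report": _stage_report,
}


def run(config: PipelineConfig) -> dict:
    """Execute one pipeline stage; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    try:
        log.info("stage %s -> %s (seed %d)", config.mode, out, config.seed)
        try:
            written = _STAGES[config.mode](config, out)
        except Exception as exc:
            (out / "FAILED").write_text(f"{config.mode}: {exc}\n")
            log.error("stage %s failed: %s", config.mode, exc)
            raise PipelineStageError(config.mode, exc) from exc
        manifest = {
            "mode": config.mode,
            "seed": config.seed,
            "package_version": __version__,
            "parameters": config.params,
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in written},
            "status": "ok",
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return manifest
    finally:
        log.removeHandler(fh)
        fh.close()
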