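"""Full per-system analysis: replicate runs in, tables and plots out.

Orchestrates, in order: RMSD series (core, entire) per run → knob
offsets per run → motion summary; TAF profile over the stalk plus the two
knob residues adjacent to each stalk strand → hinge flags; knob-LC and
knob-HC-core vdW energy series per run → energy summary → local minima →
contact reports and snapshot structures at the minima.

Per-frame CSVs are written at full precision; summary tables at two
decimals. Every summary number is recomputable from the retained
per-frame CSVs (audited in the test suite), and reruns with identical
inputs produce byte-identical CSVs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .domain_model import DomainPartition, parse_domain_config, select_atoms
from .domain_motion import (
    MotionSummary,
    OffsetSeries,
    RmsdSeries,
    compute_knob_offsets,
    compute_rmsd_series,
    summarize_motion,
)
from .errors import AggregationError, StageError
from .interaction_energy import (
    ContactReport,
    EnergySeries,
    assign_lj_parameters,
    bonded_exclusion_pairs,
    classify_contacts,
    energy_series,
    find_local_minima,
    infer_bonds,
    load_lj_table,
    summarize_energy,
)
from .structure_io import (
    Trajectory,
    read_multimodel_pdb,
    read_pdb,
    write_pdb,
    write_series_table,
)
from .torsion_analysis import (
    TAFProfile,
    compute_backbone_torsions,
    compute_taf,
    flag_hinge_residues,
)

__all__ = ["AnalysisConfig", "SystemReport", "run_full_analysis", "aggregate_runs"]

logger = logging.getLogger("knobdyn")


@dataclass
class AnalysisConfig:
    """Resolved inputs and parameters for one system's analysis.

    ``runs`` maps run labels (conventionally A/B/C) to trajectories —
    either paths to multi-model PDB files or in-memory
    :class:`~knobdyn.structure_io.Trajectory` objects. ``reference`` is
    the simulation starting structure (crystal/model): a PDB path or a
    coordinate array matching the trajectory topology.
    """

    runs: dict
    reference: object  # path or (n_atoms, 3) array
    domains: object  # mapping or YAML path
    outdir: Path
    system_name: str = "system"
    frame_time_step: float = 1.0  # ns, used only when reading PDB trajectories
    fit_subset: str = "backbone"
    taf_threshold: float = 0.6
    knob_flank: int = 1  # knob residues per stalk junction in the TAF scope
    lj_cutoff: float = 12.0
    contact_cutoff: float = 4.5
    polar_cutoff: float = 3.5
    smooth_window: int = 11
    min_separation: int = 50
    lj_params: str = "ff14sb_lj"
    seed: int = 0
    make_plots: bool = True
    max_snapshots_per_run: int = 3

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        base = path.parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        kwargs = dict(doc.get("parameters", {}))
        return cls(
            runs={k: resolve(v) for k, v in doc["runs"].items()},
            reference=resolve(doc["reference"]),
            domains=doc["domains"] if isinstance(doc["domains"], dict) else resolve(doc["domains"]),
            outdir=resolve(doc.get("outdir", "knobdyn_out")),
            system_name=doc.get("system_name", "system"),
            **kwargs,
        )


@dataclass
class SystemReport:
    """All per-system results, internally consistent in frames/times."""

    system_name: str
    run_labels: list[str]
    motion: MotionSummary
    taf_profile: TAFProfile
    hinge_residues: list
    rmsd_series: dict  # run -> {"core": RmsdSeries, "entire": RmsdSeries}
    offset_series: dict  # run -> OffsetSeries
    energy_series: dict  # pair label -> {run -> EnergySeries}
    energy_summaries: dict  # pair label -> {run -> mean, "Average": mean}
    minima: dict  # run -> list of frame indices (knob-LC energy)
    contact_reports: dict  # (run, frame) -> ContactReport


def _stage(name: str):
    """Decorator-free stage wrapper: logs wall time, renames failures."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                logger.info("stage %s: done in %.2f s", name, dt)
                return False
            logger.error("stage %s: FAILED after %.2f s: %s", name, dt, exc)
            if not isinstance(exc, StageError):
                raise StageError(name, str(exc)) from exc
            return False

    return _Ctx()


def _load_trajectory(obj, frame_time_step: float) -> Trajectory:
    if isinstance(obj, Trajectory):
        return obj
    return read_multimodel_pdb(obj, frame_time_step=frame_time_step)


def _load_reference(obj, traj: Trajectory) -> np.ndarray:
    if isinstance(obj, (str, Path)):
        _, coords = read_pdb(obj)
        return coords
    return np.asarray(obj, dtype=float)


def run_full_analysis(config: AnalysisConfig) -> SystemReport:
    """Execute the complete analysis and write all artifacts to ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "log.txt", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()


def _run(config: AnalysisConfig, outdir: Path) -> SystemReport:
    logger.info("knobdyn %s analysing system '%s'", __version__, config.system_name)
    logger.info(
        "parameters: taf_threshold=%s lj_cutoff=%s contact_cutoff=%s polar_cutoff=%s "
        "smooth_window=%s min_separation=%s fit_subset=%s seed=%s",
        config.taf_threshold, config.lj_cutoff, config.contact_cutoff,
        config.polar_cutoff, config.smooth_window, config.min_separation,
        config.fit_subset, config.seed,
    )

    with _stage("load"):
        trajs = {
            run: _load_trajectory(obj, config.frame_time_step)
            for run, obj in config.runs.items()
        }
        run_labels = list(trajs)
        first = trajs[run_labels[0]]
        for run, t in trajs.items():
            if t.topology != first.topology:
                raise AggregationError(
                    f"run '{run}' topology differs from run '{run_labels[0]}'"
                )
        reference = _load_reference(config.reference, first)

    with _stage("partition"):
        partition = parse_domain_config(config.domains, first.topology)
        topo = first.topology
        sub = config.fit_subset
        core_fit = select_atoms(topo, partition, "core", sub)
        entire_sel = select_atoms(topo, partition, "entire", sub)
        knob_fit = select_atoms(topo, partition, "knob", sub)
        knob_heavy = select_atoms(topo, partition, "knob", "heavy")
        lc_heavy = select_atoms(topo, partition, "core_light", "heavy")
        hc_heavy = select_atoms(topo, partition, "core_heavy", "heavy")

    with _stage("motion"):
        rmsd_series: dict[str, dict[str, RmsdSeries]] = {}
        offset_series: dict[str, OffsetSeries] = {}
        for run, traj in trajs.items():
            core = compute_rmsd_series(traj, reference, core_fit, core_fit, "core")
            entire = compute_rmsd_series(traj, reference, entire_sel, core_fit, "entire")
            offs = compute_knob_offsets(traj, reference, core_fit, knob_fit)
            rmsd_series[run] = {"core": core, "entire": entire}
            offset_series[run] = offs
            write_series_table(
                pd.DataFrame(
                    {
                        "time_ns": traj.times,
                        "core_rmsd_A": core.values,
                        "entire_rmsd_A": entire.values,
                    }
                ),
                outdir / f"rmsd_{run}.csv",
            )
            write_series_table(
                pd.DataFrame(
                    {
                        "time_ns": traj.times,
                        "trans_A": offs.translational,
                        "rot_deg": offs.rotational,
                    }
                ),
                outdir / f"offsets_{run}.csv",
            )
        motion = summarize_motion(
            {
                run: {**rmsd_series[run], "offsets": offset_series[run]}
                for run in run_labels
            }
        )
        write_series_table(motion.to_frame(), outdir / "motion_summary.csv", decimals=2)

    with _stage("taf"):
        flank = config.knob_flank
        scope = (
            list(partition.stalk_n)
            + list(partition.knob[:flank])
            + list(partition.knob[-flank:] if len(partition.knob) > flank else ())
            + list(partition.stalk_c)
        )
        # pool frames across runs for the dispersion statistic
        pooled = Trajectory(
            topology=topo,
            frames=np.concatenate([trajs[r].frames for r in run_labels]),
            times=np.arange(sum(trajs[r].n_frames for r in run_labels), dtype=float),
        )
        entries = []
        for series in compute_backbone_torsions(pooled, scope):
            entry = compute_taf(series)
            if entry is not None:
                entries.append(entry)
        profile = TAFProfile(entries=entries, threshold=config.taf_threshold)
        hinge = flag_hinge_residues(profile)
        taf_df = pd.DataFrame(
            [
                {
                    "chain": e.residue[0],
                    "residue": e.residue[1],
                    "taf_phi": e.taf_phi if e.taf_phi is not None else np.nan,
                    "taf_psi": e.taf_psi if e.taf_psi is not None else np.nan,
                    "hinge_flag": e.residue in hinge,
                }
                for e in profile.entries
            ]
        )
        write_series_table(taf_df, outdir / "taf.csv")
        _write_hinge_map(outdir / "hinge_map.txt", profile, hinge, topo)

    with _stage("energy"):
        params = load_lj_table(config.lj_params)
        rmin_half, eps = assign_lj_parameters(topo, params)
        # knob vs heavy-chain core shares a chain: exclude through-bond pairs
        bonds = infer_bonds(reference, topo)
        exclusions = bonded_exclusion_pairs(bonds, max_separation=3)
        e_series: dict[str, dict[str, EnergySeries]] = {"knob-LC": {}, "knob-HC": {}}
        for run, traj in trajs.items():
            e_series["knob-LC"][run] = energy_series(
                traj, knob_heavy, lc_heavy, rmin_half, eps,
                cutoff=config.lj_cutoff, label="knob-LC",
            )
            e_series["knob-HC"][run] = energy_series(
                traj, knob_heavy, hc_heavy, rmin_half, eps,
                cutoff=config.lj_cutoff, exclusions=exclusions, label="knob-HC",
            )
            write_series_table(
                pd.DataFrame(
                    {
                        "time_ns": traj.times,
                        "e_vdw_knob_lc_kcal": e_series["knob-LC"][run].e_vdw,
                        "e_vdw_knob_hc_kcal": e_series["knob-HC"][run].e_vdw,
                    }
                ),
                outdir / f"energy_{run}.csv",
            )
        summaries = {pair: summarize_energy(d) for pair, d in e_series.items()}
        rows = [
            {"pair": pair, **{k: v for k, v in summ.items()}}
            for pair, summ in summaries.items()
        ]
        write_series_table(
            pd.DataFrame(rows, columns=["pair", *run_labels, "Average"]),
            outdir / "energy_summary.csv",
            decimals=2,
        )

    with _stage("minima"):
        minima: dict[str, list[int]] = {}
        minima_rows = []
        for run in run_labels:
            series = e_series["knob-LC"][run]
            frames = find_local_minima(
                series,
                smooth_window=config.smooth_window,
                min_separation=config.min_separation,
            )
            minima[run] = frames
            for f in frames:
                minima_rows.append(
                    {
                        "run": run,
                        "frame": f,
                        "time_ns": series.times[f],
                        "e_vdw_kcal": series.e_vdw[f],
                    }
                )
        write_series_table(
            minima_rows, outdir / "minima.csv",
            columns=["run", "frame", "time_ns", "e_vdw_kcal"],
        )

    with _stage("contacts"):
        contact_reports: dict[tuple[str, int], ContactReport] = {}
        contact_frames = []
        for run in run_labels:
            for f in minima[run][: config.max_snapshots_per_run]:
                report = classify_contacts(
                    trajs[run].frames[f],
                    topo,
                    knob_heavy,
                    lc_heavy,
                    contact_cutoff=config.contact_cutoff,
                    polar_cutoff=config.polar_cutoff,
                    frame_index=f,
                    time_ns=float(trajs[run].times[f]),
                )
                contact_reports[(run, f)] = report
                df = report.to_frame()
                df.insert(0, "run", run)
                contact_frames.append(df)
                write_pdb(
                    topo,
                    trajs[run].frames[f],
                    outdir / f"snapshot_{run}_f{f:05d}.pdb",
                )
        if contact_frames:
            contacts_df = pd.concat(contact_frames, ignore_index=True)
        else:
            contacts_df = pd.DataFrame(
                columns=["run", "frame", "time_ns", "knob_chain", "knob_residue",
                         "partner_chain", "partner_residue", "contact_class",
                         "min_distance_A"]
            )
        write_series_table(contacts_df, outdir / "contacts.csv")

    if config.make_plots:
        with _stage("plots"):
            _make_plots(outdir, run_labels, rmsd_series, offset_series, e_series, minima)

    return SystemReport(
        system_name=config.system_name,
        run_labels=run_labels,
        motion=motion,
        taf_profile=profile,
        hinge_residues=hinge,
        rmsd_series=rmsd_series,
        offset_series=offset_series,
        energy_series=e_series,
        energy_summaries=summaries,
        minima=minima,
        contact_reports=contact_reports,
    )


def _write_hinge_map(path: Path, profile: TAFProfile, hinge, topo) -> None:
    """Alignment-style text: one-letter-ish row with flagged residues marked."""
    lines = ["residue  ", "flagged  "]
    for e in profile.entries:
        tag = f"{e.residue[1]:>5s}"
        lines[0] += tag
        lines[1] += f"{'*' if e.residue in hinge else '.':>5s}"
    lines.append("")
    lines.append("* = phi- or psi-TAF > %.2f" % profile.threshold)
    path.write_text("\n".join(lines) + "\n")


def _make_plots(outdir, run_labels, rmsd_series, offset_series, e_series, minima):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {r: c for r, c in zip(run_labels, ["red", "green", "blue", "orange", "purple"])}

    fig, axes = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    for run in run_labels:
        axes[0].plot(rmsd_series[run]["core"].times, rmsd_series[run]["core"].values,
                     color=colors.get(run), lw=0.7, label=f"run{run}")
        axes[1].plot(rmsd_series[run]["entire"].times, rmsd_series[run]["entire"].values,
                     color=colors.get(run), lw=0.7)
    axes[0].set_ylabel("core RMSD (Å)")
    axes[1].set_ylabel("entire RMSD (Å)")
    axes[1].set_xlabel("time (ns)")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "rmsd.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    for run in run_labels:
        offs = offset_series[run]
        ax.scatter(offs.translational, offs.rotational, s=3,
                   color=colors.get(run), alpha=0.4, label=f"run{run}")
    ax.set_xlabel("translational offset (Å)")
    ax.set_ylabel("rotational offset (deg)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "tra_rot.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 3.5))
    for run in run_labels:
        s = e_series["knob-LC"][run]
        ax.plot(s.times, s.e_vdw, color=colors.get(run), lw=0.7, label=f"run{run}")
        for f in minima[run][:3]:
            ax.plot(s.times[f], s.e_vdw[f], "o", color=colors.get(run), ms=5)
    ax.set_xlabel("time (ns)")
    ax.set_ylabel("knob-LC E_vdW (kcal/mol)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "energy.png", dpi=120)
    plt.close(fig)


def aggregate_runs(reports: list[SystemReport]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-system tables: one motion row and one energy row per system.

    All systems must share the same run labels; single-run systems pass
    through (their cross-run mean is their own time mean).
    """
    if not reports:
        raise AggregationError("no reports to aggregate")
    labels = reports[0].run_labels
    for r in reports[1:]:
        if r.run_labels != labels:
            raise AggregationError(
                f"system '{r.system_name}' run labels {r.run_labels} differ "
                f"from {labels}"
            )
    motion_rows = [
        {"system": r.system_name, **{c: r.motion.overall[c] for c in MotionSummary.COLUMNS}}
        for r in reports
    ]
    energy_rows = [
        {
            "system": r.system_name,
            **{run: r.energy_summaries["knob-LC"][run] for run in labels},
            "Average": r.energy_summaries["knob-LC"]["Average"],
        }
        for r in reports
    ]
    return (
        pd.DataFrame(motion_rows, columns=["system", *MotionSummary.COLUMNS]),
        pd.DataFrame(energy_rows, columns=["system", *labels, "Average"]),
    )
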