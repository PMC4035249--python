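"""End-to-end analysis pipeline driven by a single YAML config.

For the apo and holo systems the pipeline computes windowed S² (iRED),
windowed local flexibility and the per-residue water MRT profile; scores
every window against the experimental S² (max r²) and heteronuclear NOE
(max anticorrelation) profiles; forms the consensus window ranking; runs the
ligand distance-distribution analysis on the top-ranked holo window; and
writes the holo/apo MRT ratio. Outputs are plain CSV tables plus one
machine-readable JSON summary; identical config + seed reproduces the JSON
byte for byte (wall-clock timings go only to the log).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import flexibility, hydration, ligand_ensemble, order_parameters
from . import substate_selection as sel
from .trajectory_io import (ResidueProfile, Trajectory, read_profile,
                            read_structure, read_trajectory, write_profile)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every problem found."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""


@dataclass
class SystemInputs:
    topology: str
    trajectory: str
    frame_spacing: float = 10.0


@dataclass
class RunConfig:
    apo: SystemInputs
    holo: SystemInputs
    experimental_s2: str
    experimental_noe: str
    experimental_hydration_ratio: str | None
    output_dir: str
    window_ns: float = 1.0
    sigmoid_d0: float = 7.0
    sigmoid_k: float = 2.0
    water_cutoff: float = 3.5
    contact_cutoff: float = 6.5
    residue_range: tuple[int, int] | None = None
    seed: int = 0
    ligand_resnames: tuple = ("LIG",)
    water_resnames: tuple = ("WAT", "HOH", "SOL", "TIP3")
    s2_small_sample_correction: bool = True
    mrt_mode: str = "survival"
    mrt_assignment: str = "terminal_nearest"

    def window_frames(self, frame_spacing: float) -> int:
        return int(round(self.window_ns * 1000.0 / frame_spacing))

    def canonical_dict(self) -> dict:
        d = asdict(self)
        d["residue_range"] = list(self.residue_range) if self.residue_range else None
        d["ligand_resnames"] = sorted(self.ligand_resnames)
        d["water_resnames"] = sorted(self.water_resnames)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML config, reporting every error at once."""
    path = Path(path)
    errors: list[str] = []
    try:
        raw = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError([f"cannot read config {path}: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError([f"config {path} is not a mapping"])

    base = path.parent

    def resolve(p: str) -> str:
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    def need_file(key: str, p) -> str | None:
        if not isinstance(p, str):
            errors.append(f"{key}: expected a path, got {p!r}")
            return None
        rp = resolve(p)
        if not Path(rp).exists():
            errors.append(f"{key}: file not found: {rp}")
        return rp

    systems = {}
    for tag in ("apo", "holo"):
        block = raw.get(tag)
        if not isinstance(block, dict):
            errors.append(f"missing or invalid section {tag!r}")
            continue
        top = need_file(f"{tag}.topology", block.get("topology"))
        trj = need_file(f"{tag}.trajectory", block.get("trajectory"))
        spacing = float(block.get("frame_spacing_ps",
                                  raw.get("frame_spacing_ps", 10.0)))
        if spacing <= 0:
            errors.append(f"{tag}.frame_spacing_ps must be > 0")
        systems[tag] = SystemInputs(top or "", trj or "", spacing)

    exp = raw.get("experimental") or {}
    if not isinstance(exp, dict):
        errors.append("'experimental' must be a mapping")
        exp = {}
    exp_s2 = need_file("experimental.s2", exp.get("s2")) if "s2" in exp else None
    if "s2" not in exp:
        errors.append("experimental.s2 table is required")
    exp_noe = need_file("experimental.noe", exp.get("noe")) if "noe" in exp else None
    if "noe" not in exp:
        errors.append("experimental.noe table is required")
    exp_hyd = (need_file("experimental.hydration_ratio",
                         exp.get("hydration_ratio"))
               if exp.get("hydration_ratio") else None)

    window_ns = float(raw.get("window_ns", 1.0))
    sig = raw.get("sigmoid") or {}
    cut = raw.get("cutoffs") or {}
    rr = raw.get("residue_range")
    residue_range = None
    if rr is not None:
        try:
            first, last = int(rr[0]), int(rr[1])
            if first > last:
                raise ValueError
            residue_range = (first, last)
        except (TypeError, ValueError, IndexError):
            errors.append(f"residue_range must be [first, last], got {rr!r}")
    out_dir = raw.get("output_dir")
    if not isinstance(out_dir, str):
        errors.append("output_dir is required")

    cfg = RunConfig(
        apo=systems.get("apo", SystemInputs("", "")),
        holo=systems.get("holo", SystemInputs("", "")),
        experimental_s2=exp_s2 or "",
        experimental_noe=exp_noe or "",
        experimental_hydration_ratio=exp_hyd,
        output_dir=resolve(out_dir) if isinstance(out_dir, str) else "",
        window_ns=window_ns,
        sigmoid_d0=float(sig.get("d0", 7.0)),
        sigmoid_k=float(sig.get("k", 2.0)),
        water_cutoff=float(cut.get("water", 3.5)),
        contact_cutoff=float(cut.get("contact", 6.5)),
        residue_range=residue_range,
        seed=int(raw.get("seed", 0)),
        ligand_resnames=tuple(raw.get("ligand_resnames", ["LIG"])),
        water_resnames=tuple(raw.get("water_resnames",
                                     ["WAT", "HOH", "SOL", "TIP3"])),
        s2_small_sample_correction=bool(raw.get("s2_small_sample_correction",
                                                True)),
        mrt_mode=str(raw.get("mrt_mode", "survival")),
        mrt_assignment=str(raw.get("mrt_assignment", "terminal_nearest")),
    )
    for tag in ("apo", "holo"):
        sysin = getattr(cfg, tag)
        if sysin.frame_spacing > 0 and cfg.window_frames(sysin.frame_spacing) < 2:
            errors.append(f"window_ns={window_ns} is shorter than 2 frames at "
                          f"{sysin.frame_spacing} ps spacing")
    if errors:
        raise ConfigError(errors)
    return cfg


def _ranking_rows(ranking: list[sel.WindowResult]) -> list[dict]:
    rows = []
    for rank, res in enumerate(ranking, start=1):
        rows.append({
            "rank": rank,
            "window_label": res.window_label,
            "first_frame": int(res.frame_range[0]),
            "last_frame": int(res.frame_range[1]),
            "pearson_r": None if np.isnan(res.pearson_r) else round(res.pearson_r, 6),
            "r_squared": None if np.isnan(res.r_squared) else round(res.r_squared, 6),
            "n_shared_residues": res.n_shared_residues,
            "error": res.error,
        })
    return rows


def _write_ranking_csv(ranking: list[sel.WindowResult], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank,window_label,first_frame,last_frame,r,r2,n_shared,error\n")
        for rank, res in enumerate(ranking, start=1):
            fh.write(f"{rank},{res.window_label},{res.frame_range[0]},"
                     f"{res.frame_range[1]},{res.pearson_r:.6f},"
                     f"{res.r_squared:.6f},{res.n_shared_residues},"
                     f"{res.error or ''}\n")


def _analyse_system(tag: str, cfg: RunConfig, outdir: Path, log) -> dict:
    sysin: SystemInputs = getattr(cfg, tag)
    stage = f"{tag}:load"
    try:
        top, _ = read_structure(sysin.topology,
                                ligand_resnames=set(cfg.ligand_resnames),
                                water_resnames=set(cfg.water_resnames))
        traj = read_trajectory(top, sysin.trajectory, sysin.frame_spacing)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc
    log(f"{tag}: {traj.n_frames} frames, {top.n_protein_residues} protein "
        f"residues, {top.n_atoms} atoms")

    n_res = top.n_protein_residues
    wf = cfg.window_frames(sysin.frame_spacing)
    exp_s2 = read_profile(cfg.experimental_s2, n_residues=n_res, label="S2")
    exp_noe = read_profile(cfg.experimental_noe, n_residues=n_res,
                           label="hetNOE")

    stage = f"{tag}:flexibility"
    try:
        filt = flexibility.SigmoidFilter(cfg.sigmoid_d0, cfg.sigmoid_k)
        t0 = time.perf_counter()
        flex_windows = flexibility.windowed_local_flexibility(traj, wf, filt)
        A_full = flexibility.distance_fluctuation_matrix(traj)
        flex_full = flexibility.local_flexibility(A_full, filt)
        log(f"{tag}: flexibility on {len(flex_windows)} windows "
            f"[{time.perf_counter() - t0:.1f}s]")
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    stage = f"{tag}:s2"
    try:
        t0 = time.perf_counter()
        vectors = order_parameters.extract_nh_vectors(traj)
        s2_windows = order_parameters.windowed_s2(
            vectors, wf, method="ired",
            small_sample_correction=cfg.s2_small_sample_correction)
        s2_full = order_parameters.ired_s2(
            vectors, small_sample_correction=cfg.s2_small_sample_correction)
        log(f"{tag}: iRED S2 on {len(s2_windows)} windows "
            f"[{time.perf_counter() - t0:.1f}s]")
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    stage = f"{tag}:hydration"
    mrt = None
    try:
        if (traj.topology.components == "water").any():
            t0 = time.perf_counter()
            mrt = hydration.mrt_profile(traj, cutoff=cfg.water_cutoff,
                                        mode=cfg.mrt_mode,
                                        assignment=cfg.mrt_assignment)
            log(f"{tag}: MRT profile over {mrt.n_valid} residues "
                f"[{time.perf_counter() - t0:.1f}s]")
        else:
            log(f"{tag}: no waters in topology; skipping MRT")
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    stage = f"{tag}:selection"
    try:
        s2_rank = sel.select_best_window(s2_windows, exp_s2,
                                         criterion="max_r2",
                                         residue_range=cfg.residue_range,
                                         frame_spacing=sysin.frame_spacing)
        flex_rank = sel.select_best_window(flex_windows, exp_noe,
                                           criterion="max_anticorr",
                                           residue_range=cfg.residue_range,
                                           frame_spacing=sysin.frame_spacing)
        consensus = sel.consensus_windows([s2_rank, flex_rank])
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    sysdir = outdir / tag
    sysdir.mkdir(parents=True, exist_ok=True)
    write_profile(flex_full, sysdir / "local_flexibility_full.csv")
    write_profile(s2_full, sysdir / "s2_full.csv")
    for rng, prof in flex_windows:
        write_profile(prof, sysdir / f"local_flexibility_w{rng[0]}_{rng[1]}.csv")
    for rng, prof in s2_windows:
        write_profile(prof, sysdir / f"s2_w{rng[0]}_{rng[1]}.csv")
    if mrt is not None:
        write_profile(mrt, sysdir / "mrt.csv")
    _write_ranking_csv(s2_rank, sysdir / "ranking_s2.csv")
    _write_ranking_csv(flex_rank, sysdir / "ranking_flexibility.csv")

    return {
        "trajectory": {"n_frames": traj.n_frames,
                       "frame_spacing_ps": sysin.frame_spacing,
                       "window_frames": wf, "n_windows": len(s2_windows)},
        "s2_ranking": _ranking_rows(s2_rank),
        "flexibility_ranking": _ranking_rows(flex_rank),
        "consensus": [
            {"rank": k + 1, "window_label": res.window_label,
             "first_frame": int(res.frame_range[0]),
             "last_frame": int(res.frame_range[1])}
            for k, res in enumerate(consensus)],
        "top_window": {
            "window_label": consensus[0].window_label,
            "first_frame": int(consensus[0].frame_range[0]),
            "last_frame": int(consensus[0].frame_range[1])},
        "_traj": traj, "_mrt": mrt, "_flex_full": flex_full,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the JSON-serializable summary."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    log(f"config hash {config.config_hash()} seed {config.seed}")
    summary: dict = {"config": config.canonical_dict(),
                     "config_hash": config.config_hash(),
                     "seed": config.seed, "systems": {}}
    try:
        results = {}
        for tag in ("apo", "holo"):
            results[tag] = _analyse_system(tag, config, outdir, log)
            summary["systems"][tag] = {
                k: v for k, v in results[tag].items() if not k.startswith("_")}

        # ligand ensemble on the top-ranked holo window
        stage = "ligand_ensemble"
        holo_traj: Trajectory = results["holo"]["_traj"]
        top_win = summary["systems"]["holo"]["top_window"]
        if (holo_traj.topology.components == "ligand").any():
            try:
                contacts = ligand_ensemble.contact_residues(
                    holo_traj, cutoff=config.contact_cutoff)
                rows = []
                if contacts:
                    dists = ligand_ensemble.com_distance_series(
                        holo_traj, contacts,
                        frame_range=(top_win["first_frame"],
                                     top_win["last_frame"]))
                    table = ligand_ensemble.summarize_ensemble(dists)
                    table.to_csv(outdir / "ligand_distance_summary.csv",
                                 index=False)
                    for d in dists:
                        np.savetxt(
                            outdir / f"ligand_distances_res{d.residue_index}.csv",
                            d.samples, header="distance_A", comments="# ")
                    rows = [
                        {k: (round(v, 6) if isinstance(v, float) else int(v))
                         for k, v in row.items()}
                        for row in table.to_dict(orient="records")]
                    log(f"ligand ensemble over {len(contacts)} contact residues")
                else:
                    log(f"no residues within {config.contact_cutoff} A of the "
                        f"ligand in the starting structure; nothing to "
                        f"summarize")
                summary["ligand_ensemble"] = {
                    "window": top_win,
                    "contact_residues": [int(r) for r in contacts],
                    "summary": rows,
                }
            except Exception as exc:
                raise PipelineError(f"stage {stage}: {exc}") from exc
        else:
            log("holo topology has no ligand; skipping ensemble analysis")

        # holo - apo local-flexibility difference (ligand-induced modulation)
        stage = "flexibility_difference"
        try:
            diff = flexibility.difference_profile(results["holo"]["_flex_full"],
                                                  results["apo"]["_flex_full"])
            write_profile(diff, outdir / "local_flexibility_difference.csv")
            log(f"flexibility difference over {diff.n_valid} residues")
        except ValueError as exc:
            log(f"stage {stage} skipped: {exc}")

        # holo/apo MRT ratio
        stage = "mrt_ratio"
        if results["apo"]["_mrt"] is not None and results["holo"]["_mrt"] is not None:
            try:
                ratio = hydration.mrt_ratio(results["holo"]["_mrt"],
                                            results["apo"]["_mrt"])
                write_profile(ratio, outdir / "mrt_ratio.csv")
                vals = [
                    {"residue": int(ratio.residue_index[i]),
                     "ratio": round(float(ratio.values[i]), 6)}
                    for i in range(len(ratio.values)) if ratio.mask[i]]
                summary["mrt_ratio"] = vals
                log(f"MRT ratio over {len(vals)} residues")
            except Exception as exc:
                raise PipelineError(f"stage {stage}: {exc}") from exc
    finally:
        log_path.write_text("\n".join(log_lines) + "\n")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
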