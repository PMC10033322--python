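"""End-to-end orchestration: load trajectories, run every analysis stage, and
write a deterministic TSV report bundle plus a machine-readable run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .builder import OligomerModel, read_model_sidecar
from .config import AnalysisConfig
from .contacts import contact_frequency, partner_selections
from .defects import build_slice_grid, compute_defect_series, xi_distribution, xi_free_energy
from .density import partial_density
from .ions import coordination_profile, crossing_events, permeation_free_energy
from .metrics import mainchain_cb_mask, pool_by_rmsd, superpose_rmsd
from .roles import Role, Subrole
from .trajectory import RoleSelection, TrajectorySet, read_trajectory, select_atoms

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def _write_tsv(path: Path, df: pd.DataFrame, config_hash: str, units: str) -> None:
    with path.open("w") as fh:
        fh.write(f"# edgepore {__version__} config={config_hash} units={units}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


DENSITY_GROUPS = {
    "water": RoleSelection(role=Role.WATER, subrole=Subrole.WATER_O),
    "polar_lipid": RoleSelection(role=Role.LIPID, elements=frozenset({"O", "P", "N"})),
    "phosphate": RoleSelection(role=Role.LIPID, subrole=Subrole.PHOSPHATE),
    "K": RoleSelection(role=Role.ION, subrole=Subrole.K),
    "Cl": RoleSelection(role=Role.ION, subrole=Subrole.CL),
}


def run_pipeline(
    config: AnalysisConfig,
    traj_paths: list[str | Path],
    out_dir: str | Path,
    sidecar_path: str | Path | None = None,
    residue_range: tuple[int, int] = (9, 21),
) -> dict:
    """Run every analysis stage on the given replicate trajectories.

    Identical inputs and config produce byte-identical outputs.  Any stage
    error aborts the run, removes partial outputs, and names the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    chash = config.hash()
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": chash,
        "inputs": {str(p): _file_hash(p) for p in traj_paths},
        "outputs": {},
        "timings_s": {},
    }

    def stage(name):
        def wrap(fn):
            t0 = _time.perf_counter()
            try:
                fn()
            except Exception as exc:
                for p in written:
                    p.unlink(missing_ok=True)
                raise PipelineError(name, str(exc)) from exc
            manifest["timings_s"][name] = round(_time.perf_counter() - t0, 3)
            logger.info("stage %s done in %.2fs", name, manifest["timings_s"][name])

        return wrap

    state: dict = {}

    @stage("load")
    def _load() -> None:
        state["traj"] = read_trajectory(
            traj_paths, stride=config.stride, discard=config.discard
        )
        if sidecar_path is not None:
            state["model"] = read_model_sidecar(sidecar_path, state["traj"].topology)
        else:
            state["model"] = None

    @stage("defect")
    def _defect() -> None:
        traj: TrajectorySet = state["traj"]
        model: OligomerModel | None = state["model"]
        grid = build_slice_grid(config.slab_thickness, config.slice_increment)
        edges = [e.definition for e in model.edges] if model else []
        series = compute_defect_series(
            traj, grid, edges, center_mode=config.center_mode, temperature=config.temperature
        )
        state["series"] = series
        rows = []
        for ri in range(series.n_replicates):
            for fi, t in enumerate(series.times[ri]):
                row = {"replicate": ri, "frame_time_ps": t, "xi": series.xi[ri][fi]}
                for label, reps in series.per_edge_xi.items():
                    row[label] = reps[ri][fi]
                rows.append(row)
        p = out / "defect.tsv"
        _write_tsv(p, pd.DataFrame(rows), chash, "xi dimensionless, time ps")
        written.append(p)

        dist = xi_distribution(series.xi, grid.n_slices)
        dg, _ = xi_free_energy(dist.p, config.temperature)
        p2 = out / "distribution.tsv"
        _write_tsv(
            p2,
            pd.DataFrame(
                {"xi_bin": dist.bins, "p": dist.p, "sem": dist.sem, "dG_kJmol": dg}
            ),
            chash,
            "p dimensionless, dG kJ/mol",
        )
        written.append(p2)

    @stage("density")
    def _density() -> None:
        traj = state["traj"]
        ddir = out / "density"
        ddir.mkdir(exist_ok=True)
        for name, sel in DENSITY_GROUPS.items():
            prof = partial_density(
                traj, sel, bin_width=config.density_bin, center_mode=config.center_mode
            )
            p = ddir / f"{name}.tsv"
            _write_tsv(
                p,
                pd.DataFrame(
                    {"z_nm": prof.bin_centers, "value": prof.values, "sem": prof.sem}
                ),
                chash,
                "z nm, value atoms/nm^3",
            )
            written.append(p)
            if name == "K":
                state["k_profile"] = prof

    @stage("contacts")
    def _contacts() -> None:
        traj = state["traj"]
        rows = []
        for cat, sel in partner_selections().items():
            cm = contact_frequency(
                traj,
                residue_range[0],
                residue_range[1],
                sel,
                cutoff=config.contact_cutoff,
                partner_category=cat,
            )
            for rn, name, f, s in zip(
                cm.residue_numbers, cm.residue_names, cm.frequency, cm.sem
            ):
                rows.append(
                    {
                        "residue_number": rn,
                        "residue_name": name,
                        "partner_category": cat,
                        "frequency": f,
                        "sem": s,
                    }
                )
        p = out / "contacts.tsv"
        _write_tsv(p, pd.DataFrame(rows), chash, "frequency dimensionless")
        written.append(p)

    @stage("ions")
    def _ions() -> None:
        traj = state["traj"]
        ions = select_atoms(traj.topology, RoleSelection(role=Role.ION, subrole=Subrole.K))
        rows = []
        if ions.size:
            profiles = coordination_profile(
                traj,
                ions,
                bin_width=config.density_bin,
                cutoff=config.shell_cutoff,
                center_mode=config.center_mode,
            )
            for cat, prof in profiles.items():
                for z, v, s in zip(prof.bin_centers, prof.values, prof.sem):
                    if np.isnan(v):
                        continue
                    rows.append(
                        {"z_nm": z, "category": cat, "mean_coordination": v, "sem": s}
                    )
        p = out / "coordination.tsv"
        _write_tsv(p, pd.DataFrame(rows, columns=["z_nm", "category", "mean_coordination", "sem"]), chash, "z nm")
        written.append(p)

        events = crossing_events(
            traj,
            ions if ions.size else None,
            slab_halfwidth=config.crossing_slab_halfwidth,
            bulk_margin=config.crossing_bulk_margin,
            center_mode=config.center_mode,
        ) if ions.size else []
        p2 = out / "crossings.tsv"
        _write_tsv(
            p2,
            pd.DataFrame(
                [
                    {
                        "ion": e.ion_index,
                        "replicate": e.replicate,
                        "entry_ps": e.entry_time,
                        "exit_ps": e.exit_time,
                        "direction": e.direction,
                    }
                    for e in events
                ],
                columns=["ion", "replicate", "entry_ps", "exit_ps", "direction"],
            ),
            chash,
            "times ps",
        )
        written.append(p2)

        kprof = state.get("k_profile")
        if kprof is not None and np.any(kprof.values > 0):
            try:
                pmf = permeation_free_energy(
                    kprof, bulk_window=config.bulk_window, temperature=config.temperature
                )
                p3 = out / "permeation_dG.tsv"
                _write_tsv(
                    p3,
                    pd.DataFrame({"z_nm": pmf.bin_centers, "dG_kJmol": pmf.values}),
                    chash,
                    "dG kJ/mol",
                )
                written.append(p3)
            except ValueError:
                logger.warning("no bulk ion density; skipping permeation profile")

    @stage("rmsd")
    def _rmsd() -> None:
        traj = state["traj"]
        prot = select_atoms(traj.topology, RoleSelection(role=Role.PROTEIN))
        rows = []
        means = []
        if prot.size:
            mask = mainchain_cb_mask(traj.topology, residue_range[0], residue_range[1])
            ref = traj.replicates[0][0].coordinates
            for ri, rep in enumerate(traj.replicates):
                vals = []
                for frame in rep:
                    r = superpose_rmsd(frame.coordinates, ref, mask)
                    rows.append(
                        {"replicate": ri, "frame_time_ps": frame.time, "rmsd_nm": r}
                    )
                    vals.append(r)
                means.append(float(np.mean(vals)))
        p = out / "rmsd.tsv"
        _write_tsv(p, pd.DataFrame(rows, columns=["replicate", "frame_time_ps", "rmsd_nm"]), chash, "rmsd nm")
        written.append(p)
        pools = pool_by_rmsd(means, config.pool_thresholds) if means else None
        p2 = out / "pools.tsv"
        _write_tsv(
            p2,
            pd.DataFrame(
                [
                    {"replicate": i, "mean_rmsd_nm": m, "pool": lab}
                    for i, (m, lab) in enumerate(zip(means, pools.labels if pools else []))
                ],
                columns=["replicate", "mean_rmsd_nm", "pool"],
            ),
            chash,
            "rmsd nm",
        )
        written.append(p2)

    manifest["outputs"] = {str(p.relative_to(out)): _file_hash(p) for p in written}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
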