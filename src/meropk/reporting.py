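"""Workflow entry points: full-factorial PTA runs, breakpoint tables,
regimen recommendation, and the end-to-end demonstration pipeline.

Every artifact embeds the package version, a hash of the run configuration
and the seed(s) in '#' comment header lines (CSV) or top-level fields
(JSON), and existing files are never overwritten unless ``force`` is set.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__, estimation
from .params import PopulationSpec, ValidationError
from .pkpd import MIC_GRID, pkpd_breakpoint, pta_grid
from .study import StudyDesign, generate_study, write_dataset

__all__ = [
    "DEFAULT_REGIMENS",
    "DEFAULT_INFUSIONS",
    "DEFAULT_DRAINAGES",
    "config_hash",
    "run_simulate_pta",
    "recommend_regimen",
    "run_end_to_end_demo",
    "plot_pta_grid",
    "plot_vpc",
]

log = logging.getLogger("meropk")

DEFAULT_REGIMENS: tuple[tuple[str, float, float], ...] = (
    ("1g q8h", 1000.0, 8.0),
    ("1g q6h", 1000.0, 6.0),
    ("2g q8h", 2000.0, 8.0),
)
DEFAULT_INFUSIONS: tuple[float | str, ...] = (0.5, 1, 2, 3, 4, "CI")
DEFAULT_DRAINAGES: tuple[float, ...] = (0.0, 50.0, 150.0, 250.0)


def config_hash(config: Mapping[str, Any]) -> str:
    """Short stable hash of a run configuration."""
    text = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _check_overwrite(paths: Sequence[Path], force: bool) -> None:
    existing = [str(p) for p in paths if p.exists()]
    if existing and not force:
        raise ValidationError(
            f"refusing to overwrite existing output files {existing}; "
            f"pass force=True / --force to allow")


def _header(seed: int, cfg_hash: str) -> list[str]:
    return [f"meropk {__version__}", f"seed={seed}", f"config={cfg_hash}"]


def _write_csv(df: pd.DataFrame, path: Path, header: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=float) + "\n")


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage %s: done in %.1f s", name, dt)
            else:
                log.error("stage %s: FAILED after %.1f s: %s", name, dt, exc)
            return False
    return _Timer()


# ---------------------------------------------------------------------------
# PTA workflow
# ---------------------------------------------------------------------------

def recommend_regimen(breakpoints: pd.DataFrame,
                      max_drainage_ml_day: float = 150.0,
                      pta_floor: float = 0.90) -> dict[str, Any]:
    """Pick the best non-continuous regimen at limited drainage.

    Among finite-infusion scenarios with drainage at or below
    ``max_drainage_ml_day``, choose the scenario maximizing (in order) the
    CSF 50% fT>MIC breakpoint, the CSF 100% breakpoint and the plasma
    breakpoint at the given PTA floor; the longest infusion wins remaining
    ties (prolonged infusion never lowers PTA for the same daily dose).
    Drainage ties resolve toward the *higher* drainage, i.e. the least
    restrictive clinical constraint delivering the same breakpoints.
    """
    bp = breakpoints[(breakpoints["pta_floor"] == pta_floor)
                     & (breakpoints["infusion"] != "CI")
                     & (breakpoints["drainage_ml_day"] <= max_drainage_ml_day)]
    if bp.empty:
        raise ValidationError("no scenarios available for recommendation")
    wide = bp.pivot_table(
        index=["regimen", "infusion", "infusion_h", "drainage_ml_day"],
        columns=["matrix", "target_fraction"],
        values="breakpoint_mic_mg_l").reset_index()
    wide.columns = ["regimen", "infusion", "infusion_h", "drainage_ml_day"] + [
        f"bp_{m}_{int(f * 100)}" for m, f in wide.columns[4:]]
    for col in wide.columns[4:]:
        wide[col] = wide[col].fillna(0.0)
    key_cols = [c for c in ("bp_csf_50", "bp_csf_100", "bp_plasma_40")
                if c in wide.columns]
    wide = wide.sort_values(key_cols + ["infusion_h", "drainage_ml_day"],
                            ascending=False, kind="mergesort")
    best = wide.iloc[0]
    return {
        "regimen": best["regimen"],
        "infusion_h": float(best["infusion_h"]),
        "drainage_ml_day_at_most": float(best["drainage_ml_day"]),
        "pta_floor": pta_floor,
        **{c: float(best[c]) for c in key_cols},
    }


def run_simulate_pta(outdir: str | Path,
                     spec: PopulationSpec | None = None,
                     regimens: Sequence[tuple[str, float, float]] = DEFAULT_REGIMENS,
                     infusion_hours: Sequence[float | str] = DEFAULT_INFUSIONS,
                     drainage_ml_day: Sequence[float] = DEFAULT_DRAINAGES,
                     mics: Sequence[float] = MIC_GRID,
                     n: int = 1000, seed: int = 0, force: bool = False,
                     make_plot: bool = True) -> dict[str, Path]:
    """Full factorial PTA evaluation + breakpoint tables + recommendation.

    Writes ``pta_grid.csv``, ``breakpoints.csv`` (floors 0.90 and 0.80),
    ``recommendation.json`` and optionally a PTA-versus-MIC figure.
    """
    spec = spec or PopulationSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = {"regimens": regimens, "infusions": infusion_hours,
           "drainage": drainage_ml_day, "mics": list(mics), "n": n,
           "seed": seed, "spec": spec.to_dict()}
    h = config_hash(cfg)
    paths = {
        "pta_grid": outdir / "pta_grid.csv",
        "breakpoints": outdir / "breakpoints.csv",
        "recommendation": outdir / "recommendation.json",
    }
    if make_plot:
        paths["plot"] = outdir / "pta_plot.png"
    _check_overwrite(list(paths.values()), force)

    with _stage("simulate-pta"):
        grid = pta_grid(spec, regimens=regimens, infusion_hours=infusion_hours,
                        drainage_ml_day=drainage_ml_day, mics=mics, n=n,
                        seed=seed)
        bps = pd.concat([pkpd_breakpoint(grid, floor)
                         for floor in (0.90, 0.80)], ignore_index=True)
        rec = recommend_regimen(bps)
        _write_csv(grid, paths["pta_grid"], _header(seed, h))
        _write_csv(bps, paths["breakpoints"], _header(seed, h))
        _write_json({"meropk_version": __version__, "seed": seed,
                     "config": h, "recommendation": rec},
                    paths["recommendation"])
        if make_plot:
            plot_pta_grid(grid, paths["plot"])
    return paths


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------

def plot_pta_grid(grid: pd.DataFrame, path: str | Path,
                  regimen: str | None = None) -> None:
    """PTA vs MIC, one panel per (matrix, target), curves per infusion x
    drainage.  Defaults to the highest-dose regimen in the grid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if regimen is None:
        regimen = sorted(grid["regimen"].unique())[-1]
    sub = grid[grid["regimen"] == regimen]
    panels = sub.groupby(["matrix", "target_fraction"], sort=True)
    fig, axes = plt.subplots(1, panels.ngroups, figsize=(4.2 * panels.ngroups,
                                                         3.6), squeeze=False)
    for ax, ((matrix, frac), part) in zip(axes[0], panels):
        for (inf, drain), curve in part.groupby(["infusion",
                                                 "drainage_ml_day"]):
            curve = curve.sort_values("mic_mg_l")
            ax.plot(curve["mic_mg_l"], 100 * curve["pta"],
                    label=f"{inf} h / {drain:g} ml", lw=1)
        ax.axhline(90, color="grey", ls="--", lw=0.8)
        ax.set_xscale("log", base=2)
        ax.set_xlabel("MIC (mg/liter)")
        ax.set_ylabel("PTA (%)")
        ax.set_title(f"{regimen}: {matrix} {frac:.0%} fT>MIC")
    axes[0][0].legend(fontsize=5, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_vpc(vpc_table: pd.DataFrame, path: str | Path) -> None:
    """Observed percentiles over simulated percentile bands, per matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matrices = sorted(vpc_table["matrix"].unique())
    fig, axes = plt.subplots(1, len(matrices), figsize=(4.5 * len(matrices),
                                                        3.6), squeeze=False)
    for ax, matrix in zip(axes[0], matrices):
        sub = vpc_table[vpc_table["matrix"] == matrix]
        for p, color in ((5.0, "tab:blue"), (50.0, "tab:red"),
                         (95.0, "tab:blue")):
            band = sub[sub["percentile"] == p].sort_values("time_h")
            ax.fill_between(band["time_h"], band["sim_lo"], band["sim_hi"],
                            alpha=0.3, color=color)
            ax.plot(band["time_h"], band["observed"], color=color, marker="o",
                    ms=3, lw=1)
        ax.set_yscale("log")
        ax.set_xlabel("time after sampled dose (h)")
        ax.set_ylabel("concentration (mg/liter)")
        ax.set_title(matrix)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# End-to-end demo
# ---------------------------------------------------------------------------

def run_end_to_end_demo(outdir: str | Path, seed: int = 0,
                        n_pta: int = 200, n_boot: int = 50,
                        n_sim_vpc: int = 200, force: bool = False,
                        make_plots: bool = False) -> dict[str, Path]:
    """Generate a study, fit it, run a VPC and a PTA sweep, at desk scale.

    Exercises every module; each stage logs start/stop and any failure
    aborts with a stage-tagged error.  Outputs are byte-reproducible for a
    fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = PopulationSpec()
    design = StudyDesign()
    cfg = {"seed": seed, "n_pta": n_pta, "n_boot": n_boot,
           "n_sim_vpc": n_sim_vpc}
    h = config_hash(cfg)
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(4)]

    paths = {
        "dataset": outdir / "dataset.csv",
        "subjects": outdir / "subjects.csv",
        "fit": outdir / "fit.json",
        "vpc": outdir / "vpc.csv",
    }
    _check_overwrite(list(paths.values()), force)

    with _stage("generate"):
        dataset = generate_study(design, spec, seed=seeds[0])
        write_dataset(dataset, paths["dataset"], paths["subjects"],
                      header_lines=_header(seeds[0], h))

    with _stage("fit"):
        fit = estimation.fit_pooled(dataset, n_starts=1)
        if not fit.converged:
            raise estimation.NumericalError("demo fit did not converge")
        boot = estimation.bootstrap_ci(dataset, fit, n_boot=n_boot,
                                       seed=seeds[1])
        fit.to_json(paths["fit"], meropk_version=__version__, seed=seeds[0],
                    config=h,
                    bootstrap={
                        "n_boot": boot.n_boot, "n_failed": boot.n_failed,
                        "seed": boot.seed,
                        "intervals": boot.intervals.to_dict("records")})

    with _stage("vpc"):
        vpc_table = estimation.vpc(dataset, spec, n_sim=n_sim_vpc,
                                   seed=seeds[2])
        _write_csv(vpc_table, paths["vpc"], _header(seeds[2], h))
        if make_plots:
            paths["vpc_plot"] = outdir / "vpc_plot.png"
            plot_vpc(vpc_table, paths["vpc_plot"])

    with _stage("simulate-pta"):
        pta_paths = run_simulate_pta(outdir, spec=spec, n=n_pta,
                                     seed=seeds[3], force=force,
                                     make_plot=make_plots)
        paths.update(pta_paths)

    with _stage("invariant-check"):
        grid = pd.read_csv(paths["pta_grid"], comment="#")
        keys = ["regimen", "infusion", "drainage_ml_day", "matrix",
                "target_fraction"]
        for _, sub in grid.groupby(keys):
            pta_sorted = sub.sort_values("mic_mg_l")["pta"].to_numpy()
            if np.any(np.diff(pta_sorted) > 1e-12):
                raise estimation.NumericalError(
                    "PTA is not non-increasing in MIC in demo output")
    return paths
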