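"""Configuration handling, the parameter-sweep runner, and tabular outputs.

A sweep fixes a grid of (alpha, BVF, rb/L) combinations, runs one
simulation per combination in deterministic lexicographic order, and
produces a summary table (death time and long-term regime per run)
together with the per-run f(t) series.  The whole pipeline is
deterministic: identical configuration yields byte-identical numeric
output.
"""

from __future__ import annotations

import itertools
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import DEFAULT_DT, DEFAULT_T_END, simulate
from .grid import DEFAULT_N_R, build_grid
from .observables import (
    DEFAULT_EXTINCTION_THRESHOLD,
    SimulationResult,
    classify_long_term,
    death_time,
)
from .parameters import DimensionalParams, ModelParams, nondimensionalize

__all__ = ["Numerics", "SweepSpec", "run_sweep", "emit_outputs", "load_config", "params_from_config"]

logger = logging.getLogger("kroghsim")

#: 17 significant digits round-trip IEEE doubles exactly.
FLOAT_FMT = "%.17g"

DIMENSIONLESS_KEYS = {"alpha", "rb_over_L", "bvf"}
DIMENSIONAL_KEYS = {"D", "lambda_u", "lambda_k", "sigma0", "phi0", "alpha_dim", "rb"}


@dataclass(frozen=True)
class Numerics:
    """Discretization settings shared by every run of a sweep."""

    n_r: int = DEFAULT_N_R
    dt: float = DEFAULT_DT
    t_end: float = DEFAULT_T_END
    threshold: float = DEFAULT_EXTINCTION_THRESHOLD
    record_every: Optional[int] = None
    snapshot_times: tuple[float, ...] = ()


@dataclass(frozen=True)
class SweepSpec:
    """Cartesian grid of dimensionless parameters to simulate."""

    alphas: tuple[float, ...]
    bvfs: tuple[float, ...]
    rb_over_Ls: tuple[float, ...]
    numerics: Numerics = field(default_factory=Numerics)

    def __post_init__(self) -> None:
        if not (self.alphas and self.bvfs and self.rb_over_Ls):
            raise ValueError("sweep lists must be non-empty")
        for alpha, bvf, rb in self.combinations():
            ModelParams(alpha=alpha, rb_over_L=rb, bvf=bvf)  # validates

    def combinations(self):
        """Lexicographic (alpha, bvf, rb_over_L) ordering; fixes run order."""
        return itertools.product(self.alphas, self.bvfs, self.rb_over_Ls)


def run_sweep(spec: SweepSpec) -> tuple[pd.DataFrame, dict[tuple, SimulationResult]]:
    """Run one simulation per parameter combination.

    Returns the summary table (one row per run: parameters, death time,
    long-term regime, status) and a dict of the full results keyed by
    (alpha, bvf, rb_over_L).  A failing run is logged and marked
    ``failed`` in the summary without aborting the rest of the sweep.
    """
    num = spec.numerics
    rows = []
    results: dict[tuple, SimulationResult] = {}
    for alpha, bvf, rb in spec.combinations():
        key = (alpha, bvf, rb)
        logger.info(
            "run start: alpha=%g bvf=%g rb_over_L=%g (n_r=%d dt=%g t_end=%g)",
            alpha, bvf, rb, num.n_r, num.dt, num.t_end,
        )
        row = {
            "alpha": alpha,
            "bvf": bvf,
            "rb_over_L": rb,
            "death_time": np.nan,
            "regime": "",
            "threshold": num.threshold,
            "status": "ok",
        }
        try:
            mp = ModelParams(alpha=alpha, rb_over_L=rb, bvf=bvf)
            grid = build_grid(mp, num.n_r)
            result = simulate(
                mp,
                grid,
                t_end=num.t_end,
                dt=num.dt,
                record_every=num.record_every,
                snapshot_times=num.snapshot_times,
            )
            td = death_time(result, num.threshold)
            # The outermost node sees the least drug, so its saturated
            # uptake is the binding constraint on long-term survival.
            mu_outer = float(result.U_series[-1, -1])
            row["death_time"] = td if td is not None else np.nan
            row["regime"] = classify_long_term(alpha, mu_outer).label
            results[key] = result
            logger.info("run done: alpha=%g bvf=%g rb_over_L=%g death_time=%s",
                        alpha, bvf, rb, td)
        except Exception:
            logger.exception("run failed: alpha=%g bvf=%g rb_over_L=%g", alpha, bvf, rb)
            row["status"] = "failed"
        rows.append(row)
    return pd.DataFrame(rows), results


def _run_stem(alpha: float, bvf: float, rb: float) -> str:
    return f"run_alpha{alpha:g}_bvf{bvf:g}_rb{rb:g}"


def emit_outputs(
    summary: pd.DataFrame,
    results: dict[tuple, SimulationResult],
    outdir: Path | str,
    *,
    numerics: Optional[Numerics] = None,
    plots: bool = False,
) -> list[Path]:
    """Write summary CSV, per-run f(t) series, metadata JSON, optional plots.

    All floats are written with 17 significant digits so that re-running
    an identical configuration reproduces the files byte for byte.
    """
    if len(results) == 0:
        raise ValueError("no completed runs to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    try:
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise ValueError(f"output directory {outdir} is not writable") from exc

    written: list[Path] = []
    summary_path = outdir / "summary.csv"
    summary.to_csv(summary_path, index=False, float_format=FLOAT_FMT)
    written.append(summary_path)

    for (alpha, bvf, rb), result in results.items():
        stem = _run_stem(alpha, bvf, rb)
        series_path = outdir / f"{stem}.csv"
        pd.DataFrame({"t": result.times, "f": result.f}).to_csv(
            series_path, index=False, float_format=FLOAT_FMT
        )
        written.append(series_path)
        for snap in result.snapshots:
            snap_path = outdir / f"{stem}_snapshot_t{snap.t:g}.csv"
            pd.DataFrame({"r": snap.r, "phi": snap.phi, "sigma": snap.sigma}).to_csv(
                snap_path, index=False, float_format=FLOAT_FMT
            )
            written.append(snap_path)

    meta = {
        "version": __version__,
        "runs": [
            {"alpha": a, "bvf": b, "rb_over_L": r, "series_file": _run_stem(a, b, r) + ".csv"}
            for (a, b, r) in results
        ],
    }
    if numerics is not None:
        meta["numerics"] = {
            "n_r": numerics.n_r,
            "dt": numerics.dt,
            "t_end": numerics.t_end,
            "threshold": numerics.threshold,
            "record_every": numerics.record_every,
            "snapshot_times": list(numerics.snapshot_times),
        }
    meta_path = outdir / "metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    written.append(meta_path)

    if plots:
        written.extend(_emit_plots(results, outdir))
    return written


def _emit_plots(results: dict[tuple, SimulationResult], outdir: Path) -> list[Path]:
    """One f-vs-t panel per (bvf, rb_over_L), curves keyed by alpha."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels: dict[tuple, list[tuple]] = {}
    for (alpha, bvf, rb), result in results.items():
        panels.setdefault((bvf, rb), []).append((alpha, result))

    written = []
    for (bvf, rb), runs in panels.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        for alpha, result in sorted(runs, key=lambda kv: kv[0]):
            ax.plot(result.times, result.f, label=f"$\\alpha$ = {alpha:g}")
        ax.set_xlabel("t (apoptotic cycles)")
        ax.set_ylabel("viable-mass ratio f")
        ax.set_title(f"BVF = {bvf:g}, $r_b/L$ = {rb:g}")
        ax.legend()
        fig.tight_layout()
        path = outdir / f"panel_bvf{bvf:g}_rb{rb:g}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written


def load_config(path: Path | str) -> dict:
    """Read a YAML (or plain key: value) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg


def params_from_config(cfg: dict) -> tuple[ModelParams, Optional[float], Optional[float]]:
    """Build ModelParams from a config in dimensionless or dimensional mode.

    Dimensionless mode uses keys ``alpha, rb_over_L, bvf``; dimensional
    mode uses ``D, lambda_u, lambda_k, sigma0, phi0, alpha_dim, rb`` plus
    ``bvf``.  The two modes are mutually exclusive.  Returns the model
    parameters and, in dimensional mode, the derived scales (T, L).
    """
    present_dimless = DIMENSIONLESS_KEYS & cfg.keys()
    present_dim = DIMENSIONAL_KEYS & cfg.keys()
    if present_dim and (present_dimless - {"bvf"}):
        raise ValueError(
            "config mixes dimensionless and dimensional parameter keys: "
            f"{sorted(present_dimless - {'bvf'})} vs {sorted(present_dim)}"
        )
    if present_dim:
        missing = DIMENSIONAL_KEYS - cfg.keys()
        if missing:
            raise ValueError(f"dimensional mode missing keys: {sorted(missing)}")
        if "bvf" not in cfg:
            raise ValueError("dimensional mode also requires bvf")
        p = DimensionalParams(
            D=cfg["D"],
            lambda_u=cfg["lambda_u"],
            lambda_k=cfg["lambda_k"],
            sigma0=cfg["sigma0"],
            phi0=cfg["phi0"],
            alpha=cfg["alpha_dim"],
            rb=cfg["rb"],
        )
        mp, T, L = nondimensionalize(p, cfg["bvf"])
        return mp, T, L
    missing = DIMENSIONLESS_KEYS - cfg.keys()
    if missing:
        raise ValueError(f"dimensionless mode missing keys: {sorted(missing)}")
    return ModelParams(alpha=cfg["alpha"], rb_over_L=cfg["rb_over_L"], bvf=cfg["bvf"]), None, None


def numerics_from_config(cfg: dict) -> Numerics:
    return Numerics(
        n_r=int(cfg.get("n_r", DEFAULT_N_R)),
        dt=float(cfg.get("dt", DEFAULT_DT)),
        t_end=float(cfg.get("t_end", DEFAULT_T_END)),
        threshold=float(cfg.get("threshold", DEFAULT_EXTINCTION_THRESHOLD)),
        record_every=cfg.get("record_every"),
        snapshot_times=tuple(cfg.get("snapshot_times", ())),
    )


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
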