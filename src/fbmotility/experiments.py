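"""Ensemble experiment grids: presets, the grid runner, and summaries.

The "main" preset crosses the control row (``alpha = 0``) and three levels
of translational correlation (``H`` in {0.5, 0.75, 0.99}) with four angular
diffusion coefficients (``Dr`` in {0, 0.1, 1, 10}) — 16 parameter cells at
200 replicates each of 1000 steps (``dt = 0.1``).  The "taxis" preset runs
the same 16 cells under each guidance strength ``f_tax`` in {0.01, 0.1, 1}
at 100 replicates, with the organizing center 100 length units from the
origin.

Replicate seeds derive deterministically from ``(base_seed, cell_index,
replicate)``, so results are independent of execution order and a rerun with
the same base seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import MotilityParams, run_simulation
from .metrics import (ensemble_msd, summary_frame, trajectory_stats,
                      write_msd_csv)
from .taxis import DEFAULT_X_ORG, TaxisParams, run_taxis_simulation

__all__ = ["ExperimentGrid", "EnsembleResult", "main_grid", "taxis_grid",
           "run_grid", "run_cell", "summarize"]

MAIN_H_VALUES = (0.5, 0.75, 0.99)
MAIN_DR_VALUES = (0.0, 0.1, 1.0, 10.0)
TAXIS_FTAX_VALUES = (0.01, 0.1, 1.0)


@dataclass(frozen=True)
class ExperimentGrid:
    """A full-factorial ensemble design.

    ``f_tax_values`` empty means unguided.  The ``alpha = 0`` control row is
    included alongside the ``H`` rows when ``include_control`` is set.
    """

    H_values: tuple = MAIN_H_VALUES
    Dr_values: tuple = MAIN_DR_VALUES
    alpha: float = 0.25
    f_tax_values: tuple = ()
    n_replicates: int = 200
    base_seed: int = 0
    n_steps: int = 1000
    dt: float = 0.1
    include_control: bool = True
    x_org: tuple = DEFAULT_X_ORG

    def cells(self) -> list[dict]:
        """Enumerate parameter cells in a fixed, seed-stable order."""
        out = []
        for f_tax in (self.f_tax_values or (None,)):
            rows = ([{"alpha": 0.0, "H": 0.5}] if self.include_control
                    else [])
            rows += [{"alpha": self.alpha, "H": H} for H in self.H_values]
            for row in rows:
                for Dr in self.Dr_values:
                    cell = dict(row, Dr=Dr)
                    if f_tax is not None:
                        cell["f_tax"] = f_tax
                    out.append(cell)
        return out


def main_grid(n_replicates: int = 200, n_steps: int = 1000,
              base_seed: int = 0) -> ExperimentGrid:
    """The unguided study design (16 cells x 200 replicates by default)."""
    return ExperimentGrid(n_replicates=n_replicates, n_steps=n_steps,
                          base_seed=base_seed)


def taxis_grid(n_replicates: int = 100, n_steps: int = 1000,
               base_seed: int = 0, x_org=DEFAULT_X_ORG) -> ExperimentGrid:
    """The guided study design (48 cells x 100 replicates by default)."""
    return ExperimentGrid(f_tax_values=TAXIS_FTAX_VALUES,
                          n_replicates=n_replicates, n_steps=n_steps,
                          base_seed=base_seed, x_org=tuple(x_org))


def cell_id(cell: dict) -> str:
    """Stable human-readable identifier, e.g. ``H0.75_Dr10`` or
    ``alpha0_Dr0.1_ftax0.01``."""
    head = "alpha0" if cell["alpha"] == 0 else f"H{cell['H']:g}"
    name = f"{head}_Dr{cell['Dr']:g}"
    if "f_tax" in cell:
        name += f"_ftax{cell['f_tax']:g}"
    return name


def replicate_seed(base_seed: int, cell_index: int, replicate: int) -> int:
    """Deterministic per-replicate seed, independent of scheduling order."""
    ss = np.random.SeedSequence((base_seed, cell_index, replicate))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class EnsembleResult:
    """Summary of one parameter cell."""

    cell: dict
    cell_index: int
    stats: pd.DataFrame = field(repr=False)
    msd: "object" = field(repr=False)  # MSDCurve
    trajectories: list | None = field(default=None, repr=False)


def run_cell(grid: ExperimentGrid, cell_index: int,
             keep_trajectories: bool = False) -> EnsembleResult:
    """Run all replicates of one parameter cell."""
    cell = grid.cells()[cell_index]
    params = MotilityParams(alpha=cell["alpha"], Dr=cell["Dr"], H=cell["H"],
                            dt=grid.dt, n_steps=grid.n_steps)
    taxis = None
    if "f_tax" in cell:
        taxis = TaxisParams(f_tax=cell["f_tax"],
                            x_org=np.asarray(grid.x_org, float))
    trajectories = []
    for r in range(grid.n_replicates):
        seed = replicate_seed(grid.base_seed, cell_index, r)
        if taxis is not None:
            traj = run_taxis_simulation(params, taxis, seed, replicate_id=r)
        else:
            traj = run_simulation(params, seed, replicate_id=r)
        trajectories.append(traj)
    stats = summary_frame(
        [trajectory_stats(t) for t in trajectories],
        x_org=None if taxis is None else taxis.x_org)
    msd = ensemble_msd(trajectories)
    return EnsembleResult(cell=cell, cell_index=cell_index, stats=stats,
                          msd=msd,
                          trajectories=trajectories if keep_trajectories
                          else None)


def run_grid(grid: ExperimentGrid, output_dir, overwrite: bool = False,
             progress=None) -> dict[str, EnsembleResult]:
    """Run every cell of the grid, writing one summary CSV and one MSD CSV
    per cell plus a manifest JSON.

    Existing outputs are refused unless ``overwrite`` is set.  ``progress``
    may be a callable ``(cell_id, i, total)`` for logging.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = output_dir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} exists; pass overwrite=True to replace")

    cells = grid.cells()
    results: dict[str, EnsembleResult] = {}
    for i, cell in enumerate(cells):
        cid = cell_id(cell)
        if progress is not None:
            progress(cid, i, len(cells))
        res = run_cell(grid, i)
        res.stats.to_csv(output_dir / f"summary_{cid}.csv", index=False,
                         float_format="%.17g")
        write_msd_csv(res.msd, output_dir / f"msd_{cid}.csv")
        results[cid] = res

    manifest = {
        "version": __version__,
        "grid": asdict(grid),
        "cells": [dict(c, cell_id=cell_id(c), cell_index=i)
                  for i, c in enumerate(cells)],
        "seed_rule": "SeedSequence((base_seed, cell_index, replicate))",
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return results


def summarize(results_dir) -> pd.DataFrame:
    """Per-cell means, variances and quartiles of the headline statistics.

    Reads the ``summary_*.csv`` files produced by :func:`run_grid`;
    malformed files are reported per file.
    """
    results_dir = Path(results_dir)
    files = sorted(results_dir.glob("summary_*.csv"))
    if not files:
        raise FileNotFoundError(f"no summary_*.csv under {results_dir}")
    quantities = ["pf", "total_distance", "displacement", "mean_increment",
                  "mean_rel_angle", "final_distance_to_target"]
    required = {"pf", "total_distance", "displacement"}
    rows, errors = [], []
    for f in files:
        try:
            df = pd.read_csv(f)
            missing = required - set(df.columns)
            if missing:
                raise ValueError(f"missing columns {sorted(missing)}")
            row = {"cell": f.stem.removeprefix("summary_"),
                   "n_replicates": len(df)}
            for q in quantities:
                if q not in df.columns:
                    continue
                col = df[q]
                row[f"{q}_mean"] = col.mean()
                row[f"{q}_var"] = col.var()
                row[f"{q}_q25"] = col.quantile(0.25)
                row[f"{q}_median"] = col.median()
                row[f"{q}_q75"] = col.quantile(0.75)
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 - reported per file
            errors.append(f"{f.name}: {exc}")
    if errors:
        raise ValueError("malformed summary files:\n" + "\n".join(errors))
    return pd.DataFrame(rows).set_index("cell")
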