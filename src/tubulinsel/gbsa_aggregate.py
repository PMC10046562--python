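"""MM/GBSA snapshot assembly and replicate aggregation.

Per species and snapshot the free energy is assembled as

    G = E_elec + E_vdw + E_internal + E_gb + E_sasa − T·S_solute,

and the per-snapshot binding energy as

    ΔG_bind = G_complex − (G_receptor + G_ligand)

under the single-trajectory convention (all three species extracted from the
same complex snapshot). Aggregation keeps the last nanosecond of each
replicate run, averages ΔG within runs, and reports the mean of run means
± the sample SD (n−1) across run means — the replicate-level uncertainty of
a five-runs-with-different-initial-conditions design. The ``ts_solute``
column already carries the T·S product in kcal/mol; the default of 0 omits
the entropy term, which end-point protocols rarely pin down reliably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import AssemblyError, WindowError
from .io_formats import ENERGY_COMPONENT_COLUMNS, validate_energy_table

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_PS = 1000.0


@dataclass
class SnapshotG:
    """Assembled per-species free energies for one snapshot."""

    complex_id: str
    run: int
    time_ps: float
    g_complex: float
    g_receptor: float
    g_ligand: float


@dataclass
class BindingEnergyEstimate:
    """Per-complex ΔG_bind mean ± SD over replicate runs (kcal/mol)."""

    complex_id: str
    dg_mean: float
    dg_sd: float
    n_runs: int
    n_snapshots_used: int
    degenerate: bool = False  # single run: SD undefined, reported as 0
    ligand: str = ""
    target: str = ""
    isotype: str = ""
    site: str = ""


def assemble_snapshot_g(
    components: Mapping[str, float], temperature: float = 298.0
) -> float:
    """Sum one species' energy components into its snapshot free energy.

    ``ts_solute`` must already be the T·S product in kcal/mol, so
    ``temperature`` is accepted for interface symmetry only and does not
    enter the sum. A missing component raises :class:`AssemblyError`;
    ``ts_solute`` alone defaults to 0.
    """
    total = 0.0
    for name in ENERGY_COMPONENT_COLUMNS:
        if name == "ts_solute":
            value = components.get("ts_solute", 0.0)
            total -= float(value)
            continue
        if name not in components or components[name] is None:
            raise AssemblyError(f"missing energy component '{name}'")
        total += float(components[name])
    return total


def binding_energy_per_snapshot(g: SnapshotG) -> float:
    """ΔG_bind = G_complex − (G_receptor + G_ligand) for one snapshot."""
    return g.g_complex - (g.g_receptor + g.g_ligand)


def select_last_window(
    table: pd.DataFrame, window_ps: float = DEFAULT_WINDOW_PS
) -> pd.DataFrame:
    """Keep, per run, snapshots within the trailing ``window_ps`` window.

    Retains rows with time_ps > (max time_ps of that run − window_ps); a
    window exceeding the run span keeps every snapshot (clamped, with a
    warning rather than an error, so short fixture runs pass through).
    """
    if window_ps <= 0:
        raise WindowError(f"window_ps must be positive, got {window_ps}")
    kept = []
    for (cid, run), grp in table.groupby(["complex_id", "run"], sort=False):
        tmax = grp["time_ps"].max()
        span = tmax - grp["time_ps"].min()
        if window_ps > span and span > 0:
            logger.warning(
                "window %.6g ps exceeds run span %.6g ps for %r run %s; "
                "keeping all snapshots", window_ps, span, cid, run,
            )
        sel = grp[grp["time_ps"] > tmax - window_ps]
        if sel.empty:
            raise WindowError(f"no snapshots in window for {cid!r} run {run}")
        kept.append(sel)
    if not kept:
        raise WindowError("table has no runs to select from")
    return pd.concat(kept, axis=0)


def assemble_table(table: pd.DataFrame) -> pd.DataFrame:
    """Assemble species rows into one row per snapshot with g_complex/receptor/ligand.

    Carries the (ligand, target, isotype, site) annotation of each complex.
    """
    table = validate_energy_table(table)
    g = table[list(ENERGY_COMPONENT_COLUMNS)].copy()
    total = (
        g["e_elec"] + g["e_vdw"] + g["e_internal"] + g["e_gb"] + g["e_sasa"]
        - g["ts_solute"]
    )
    assembled = table[["complex_id", "ligand", "target", "isotype", "site",
                       "run", "time_ps", "species"]].copy()
    assembled["g"] = total
    # "g_" prefix avoids the species value "ligand" colliding with the
    # ligand annotation column on reset_index
    assembled["species"] = "g_" + assembled["species"]
    wide = assembled.pivot_table(
        index=["complex_id", "ligand", "target", "isotype", "site", "run", "time_ps"],
        columns="species", values="g", aggfunc="first",
    ).reset_index()
    wide.columns.name = None
    wide["dg_bind"] = wide["g_complex"] - (wide["g_receptor"] + wide["g_ligand"])
    return wide


def estimate_binding_energy(
    table: pd.DataFrame, window_ps: float = DEFAULT_WINDOW_PS
) -> list[BindingEnergyEstimate]:
    """Aggregate an energy table into one ΔG_bind estimate per complex.

    Pipeline: trailing-window selection → per-snapshot assembly and binding
    energy → per-run mean → mean and sample SD (ddof=1) across run means.
    A single-run complex is flagged degenerate with SD 0.
    """
    windowed = select_last_window(table, window_ps)
    snap = assemble_table(windowed)
    estimates = []
    for cid, grp in snap.groupby("complex_id", sort=False):
        run_means = grp.groupby("run")["dg_bind"].mean()
        n_runs = len(run_means)
        dg_mean = float(run_means.mean())
        if n_runs > 1:
            dg_sd = float(run_means.std(ddof=1))
            degenerate = False
        else:
            dg_sd, degenerate = 0.0, True
        first = grp.iloc[0]
        estimates.append(BindingEnergyEstimate(
            complex_id=cid, dg_mean=dg_mean, dg_sd=dg_sd, n_runs=n_runs,
            n_snapshots_used=len(grp), degenerate=degenerate,
            ligand=str(first["ligand"]), target=str(first["target"]),
            isotype=str(first["isotype"]), site=str(first["site"]),
        ))
    return estimates


def estimates_to_frame(estimates: list[BindingEnergyEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in estimates])


def estimates_from_frame(df: pd.DataFrame) -> list[BindingEnergyEstimate]:
    return [
        BindingEnergyEstimate(
            complex_id=str(r["complex_id"]), dg_mean=float(r["dg_mean"]),
            dg_sd=float(r["dg_sd"]), n_runs=int(r["n_runs"]),
            n_snapshots_used=int(r["n_snapshots_used"]),
            degenerate=bool(r.get("degenerate", False)),
            ligand=str(r.get("ligand", "")), target=str(r.get("target", "")),
            isotype=str(r.get("isotype", "")), site=str(r.get("site", "")),
        )
        for r in df.to_dict("records")
    ]
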