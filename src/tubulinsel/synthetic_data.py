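"""Synthetic generators with the statistical structure the analysis assumes.

The study this pipeline post-processes derives each binding energy from five
independent 2 ns production runs started from different initial conditions,
keeping the last nanosecond of each. The energy-table generator emulates that
design: per complex, ``n_runs`` replicate runs of snapshots; each run carries
a Gaussian between-run offset (different initial conditions) and each snapshot
i.i.d. Gaussian noise around a configurable true binding energy. Downstream
code only consumes the component sums, but rows are schema-complete: each
species total is split over the five MM/GBSA components in fixed, deterministic
proportions, and the solute-entropy column is zero by default.

Also here: a 1:1 depletion binding isotherm generator (the microscale-
thermophoresis dose-response shape) and a lognormal-noise experimental-affinity
generator used to exercise correlation reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, GenerationError
from .io_formats import SITES, TARGETS, AffinityRecord, validate_energy_table
from .thermo_convert import GAS_CONSTANT_J, J_PER_KCAL

# Fixed component proportions (e_elec, e_vdw, e_internal, e_gb, e_sasa) used
# to split a species' total G; arbitrary but deterministic, summing to 1.
_COMPONENT_SPLIT = {
    "complex": (0.40, 0.25, 0.20, 0.10, 0.05),
    "receptor": (0.35, 0.20, 0.30, 0.10, 0.05),
    "ligand": (0.30, 0.30, 0.25, 0.10, 0.05),
}
# Baseline species totals (kcal/mol) onto which the binding energy is added.
_G_RECEPTOR = -1000.0
_G_LIGAND = -20.0


@dataclass
class SimulationSpec:
    """Parameters of a synthetic replicate-MD energy table.

    ``true_dg`` maps (ligand, target, isotype, site) to the true binding
    energy in kcal/mol. Defaults mirror the replicate design: five 2 ns runs.
    ``sigma_run`` is the SD of the per-run offset, ``sigma_snapshot`` the SD
    of per-snapshot noise, both kcal/mol.
    """

    true_dg: dict[tuple[str, str, str, str], float]
    n_runs: int = 5
    run_length_ps: float = 2000.0
    snapshot_interval_ps: float = 10.0
    sigma_run: float = 0.0
    sigma_snapshot: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.true_dg:
            raise GenerationError("true_dg map is empty: nothing to generate")
        if self.n_runs < 1:
            raise DomainError(f"n_runs must be >= 1, got {self.n_runs}")
        if self.sigma_run < 0 or self.sigma_snapshot < 0:
            raise DomainError("sigma_run and sigma_snapshot must be >= 0")
        if not 0 < self.snapshot_interval_ps <= self.run_length_ps:
            raise DomainError(
                "snapshot_interval_ps must be in (0, run_length_ps]"
            )
        for (ligand, target, isotype, site) in self.true_dg:
            if target not in TARGETS:
                raise DomainError(f"unknown target {target!r}")
            if site not in SITES:
                raise DomainError(f"unknown site {site!r}")


def complex_id(ligand: str, target: str, isotype: str, site: str) -> str:
    return f"{ligand}|{target}|{isotype}|{site}"


def generate_energy_table(spec: SimulationSpec) -> pd.DataFrame:
    """Generate a schema-complete per-snapshot energy table.

    For every snapshot the assembled binding energy
    G_complex − (G_receptor + G_ligand) equals
    ``true_dg + run_offset + snapshot_noise``. One RNG stream seeded from
    ``spec.seed`` drives all draws, so identical specs give identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    n_snap = int(round(spec.run_length_ps / spec.snapshot_interval_ps))
    times = spec.snapshot_interval_ps * np.arange(1, n_snap + 1)

    rows = []
    for (ligand, target, isotype, site), dg_true in sorted(spec.true_dg.items()):
        cid = complex_id(ligand, target, isotype, site)
        for run in range(1, spec.n_runs + 1):
            offset = rng.normal(0.0, spec.sigma_run) if spec.sigma_run else 0.0
            noise = (
                rng.normal(0.0, spec.sigma_snapshot, size=n_snap)
                if spec.sigma_snapshot
                else np.zeros(n_snap)
            )
            dg_snap = dg_true + offset + noise
            for t, dg in zip(times, dg_snap):
                totals = {
                    "receptor": _G_RECEPTOR,
                    "ligand": _G_LIGAND,
                    "complex": _G_RECEPTOR + _G_LIGAND + dg,
                }
                for species, g_total in totals.items():
                    p = _COMPONENT_SPLIT[species]
                    e_elec = p[0] * g_total
                    e_vdw = p[1] * g_total
                    e_internal = p[2] * g_total
                    e_gb = p[3] * g_total
                    # remainder keeps the left-to-right component sum
                    # exactly equal to g_total
                    e_sasa = g_total - (e_elec + e_vdw + e_internal + e_gb)
                    rows.append({
                        "complex_id": cid, "ligand": ligand, "target": target,
                        "isotype": isotype, "site": site, "run": run,
                        "time_ps": float(t), "species": species,
                        "e_elec": e_elec, "e_vdw": e_vdw,
                        "e_internal": e_internal, "e_gb": e_gb,
                        "e_sasa": e_sasa, "ts_solute": 0.0,
                    })
    return validate_energy_table(pd.DataFrame(rows))


def fraction_bound(ligand_um, kd_um: float, t0_um: float):
    """Exact 1:1 depletion isotherm: fraction of target bound at total ligand L.

    f = ((T0 + L + Kd) − sqrt((T0 + L + Kd)² − 4·T0·L)) / (2·T0), all in µM.
    Valid at ligand excess and at target depletion alike.
    """
    L = np.asarray(ligand_um, dtype=float)
    s = t0_um + L + kd_um
    return (s - np.sqrt(s * s - 4.0 * t0_um * L)) / (2.0 * t0_um)


def generate_isotherm(
    kd: float,
    t0: float,
    ligand_dilutions: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Noisy (ligand concentration, fraction bound) points for a 1:1 isotherm.

    ``kd`` and ``t0`` (labeled-target concentration) in µM; Gaussian noise of
    SD ``noise_sd`` is added to the fraction bound, then clipped to [0, 1.05].
    """
    if kd <= 0 or t0 <= 0:
        raise DomainError("kd and t0 must be strictly positive")
    conc = np.asarray(ligand_dilutions, dtype=float)
    if (conc <= 0).any():
        raise DomainError("ligand concentrations must be strictly positive")
    f = fraction_bound(conc, kd, t0)
    if noise_sd:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    f = np.clip(f, 0.0, 1.05)
    return list(zip(conc.tolist(), f.tolist()))


def dilution_series(top_um: float, n_points: int = 16, factor: float = 2.0) -> list[float]:
    """Serial dilution from ``top_um`` downward, instrument-style (descending)."""
    return [top_um / factor**i for i in range(n_points)]


def generate_affinity_records(
    true_dg_by_ligand: dict[str, float],
    noise_log_sd: float = 0.0,
    seed: int = 0,
    target: str = "alpha_beta",
    temperature: float = 298.0,
) -> list[AffinityRecord]:
    """Synthetic experimental Kd records consistent with given true ΔG values.

    Kd = exp(ΔG/RT) in molar (1 M standard state), perturbed by lognormal
    noise of log-SD ``noise_log_sd``; reported in µM. Used to test that
    correlation reporting recovers perfect linearity at zero noise.
    """
    if noise_log_sd < 0:
        raise DomainError("noise_log_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rt = GAS_CONSTANT_J * temperature
    records = []
    for ligand, dg in sorted(true_dg_by_ligand.items()):
        log_kd = dg * J_PER_KCAL / rt
        if noise_log_sd:
            log_kd += rng.normal(0.0, noise_log_sd)
        kd_um = math.exp(log_kd) * 1e6
        records.append(
            AffinityRecord(ligand, target, kd_mean=kd_um, source="synthetic")
        )
    return records
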