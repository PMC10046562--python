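"""Boltzmann-weighted isotype-abundance averaging of binding energies.

A cell expresses several β-tubulin isotypes at tissue-dependent fractions
f_i; a ligand's effective affinity for the α-β pool is the abundance- and
Boltzmann-weighted average

    ⟨BE⟩ = Σ_i ΔG_i · f_i · exp(−ΔG_i/RT) / Σ_i f_i · exp(−ΔG_i/RT),

with R = 8.31 J/(mol·K), T = 298 K and ΔG_i in kcal/mol converted to J/mol
inside the exponent (the mixed-unit reading that makes the formula
dimensionally sound). Exponents are max-shifted (log-sum-exp style) before
exponentiation, so the average stays finite for |ΔG| well beyond 100
kcal/mol. Zero-abundance isotypes are retained with zero weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, DomainError, WeightingError
from .gbsa_aggregate import BindingEnergyEstimate
from .io_formats import normalize_isotype
from .thermo_convert import DEFAULT_TEMPERATURE_K, GAS_CONSTANT_J, J_PER_KCAL


@dataclass
class WeightedAffinity:
    """Context-weighted average binding energy for one ligand (kcal/mol)."""

    ligand: str
    context: str
    be_avg: float
    weights: dict[str, float] = field(default_factory=dict)  # isotype → effective weight


def _context_fractions(abundances: pd.DataFrame, context: str) -> dict[str, float]:
    sub = abundances[abundances["context"] == context]
    if sub.empty:
        raise DomainError(f"no abundances for context {context!r}")
    return {
        normalize_isotype(row.isotype): float(row.fraction)
        for row in sub.itertuples()
    }


def boltzmann_weighted_mean(
    dg_by_isotype: dict[str, float],
    abundances: pd.DataFrame,
    context: str,
    temperature: float = DEFAULT_TEMPERATURE_K,
    ligand: str = "",
) -> WeightedAffinity:
    """Abundance-Boltzmann average of per-isotype binding energies.

    Every isotype with nonzero abundance in ``context`` must have a ΔG_i;
    a missing one raises :class:`CoverageError` naming it. The result lies
    between the min and max input ΔG_i (over nonzero-abundance isotypes)
    and is invariant to a common shift of all ΔG_i up to that shift.
    """
    if temperature <= 0:
        raise DomainError("temperature must be positive")
    fractions = _context_fractions(abundances, context)
    dg_norm = {normalize_isotype(k): float(v) for k, v in dg_by_isotype.items()}

    isotypes, fs, dgs = [], [], []
    for iso, f in fractions.items():
        if f > 0 and iso not in dg_norm:
            raise CoverageError(
                f"no binding energy for isotype {iso!r} "
                f"(abundance {f:.3g} in context {context!r})"
            )
        if iso in dg_norm:
            isotypes.append(iso)
            fs.append(f)
            dgs.append(dg_norm[iso])
    fs = np.asarray(fs)
    dgs = np.asarray(dgs)

    rt = GAS_CONSTANT_J * temperature
    x = -dgs * J_PER_KCAL / rt          # exponent per isotype
    x_shift = x - x.max()               # log-sum-exp stabilization
    w = fs * np.exp(x_shift)
    denom = w.sum()
    if denom <= 0 or not np.isfinite(denom):
        raise WeightingError("all effective Boltzmann weights are zero")
    w = w / denom
    be_avg = float(np.dot(dgs, w))
    return WeightedAffinity(
        ligand=ligand, context=context, be_avg=be_avg,
        weights={iso: float(wi) for iso, wi in zip(isotypes, w)},
    )


def weight_all(
    estimates: list[BindingEnergyEstimate],
    abundances: pd.DataFrame,
    context: str,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> list[WeightedAffinity]:
    """One weighted affinity per ligand from per-(ligand, isotype) estimates.

    Coverage failures are raised (never silently dropped), naming the ligand
    and the missing isotype.
    """
    by_ligand: dict[str, dict[str, float]] = {}
    for est in estimates:
        by_ligand.setdefault(est.ligand, {})[est.isotype] = est.dg_mean
    results = []
    for ligand in sorted(by_ligand):
        try:
            results.append(boltzmann_weighted_mean(
                by_ligand[ligand], abundances, context,
                temperature=temperature, ligand=ligand,
            ))
        except CoverageError as exc:
            raise CoverageError(f"ligand {ligand!r}: {exc}") from exc
    return results


def weighted_to_frame(weighted: list[WeightedAffinity]) -> pd.DataFrame:
    return pd.DataFrame([
        {"ligand": w.ligand, "context": w.context, "be_avg": w.be_avg}
        for w in weighted
    ])
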