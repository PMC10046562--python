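"""Free-energy / dissociation-constant interconversion and isotherm Kd fits.

Conventions: binding energies in kcal/mol, Kd in molar under a 1 M standard
state (ΔG = RT ln Kd, Kd = exp(ΔG/RT)); the gas constant is taken as
R = 8.31 J/(mol·K) with 4184 J per kcal, matching the weighting stage, and
T defaults to 298 K. Applying the conversion to raw MM/GBSA-scale energies
(tens of kcal/mol) yields physically implausible sub-attomolar constants;
the conversion performs it verbatim and logs a caution.

The isotherm fit estimates Kd from (ligand concentration, signal) points by
least squares on the exact 1:1 depletion model with a fitted amplitude and
baseline mapping fraction bound to the instrument's normalized signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, InputError

logger = logging.getLogger(__name__)

GAS_CONSTANT_J = 8.31      # J/(mol·K), as used throughout the weighting formulas
J_PER_KCAL = 4184.0
DEFAULT_TEMPERATURE_K = 298.0

# Below this Kd the number is a formal exponential of an end-point energy,
# not an experimentally meaningful constant.
_KD_CAUTION_M = 1e-15


@dataclass
class DissociationConstant:
    """A Kd in molar, with µM convenience reporting."""

    value: float  # molar

    def __post_init__(self):
        if self.value <= 0:
            raise DomainError(f"Kd must be strictly positive, got {self.value}")

    @property
    def micromolar(self) -> float:
        return self.value * 1e6


@dataclass
class IsothermFit:
    """Result of a 1:1 depletion-isotherm least-squares fit."""

    kd_hat: float          # µM
    t0: float              # µM
    amplitude: float
    baseline: float
    residual_rms: float
    n_points: int
    converged: bool
    message: str = ""


def kd_from_energy(
    be: float, temperature: float = DEFAULT_TEMPERATURE_K
) -> DissociationConstant:
    """Kd = exp(ΔG/RT), ΔG in kcal/mol, Kd in molar (1 M standard state)."""
    if temperature <= 0:
        raise DomainError("temperature must be positive")
    rt = GAS_CONSTANT_J * temperature
    kd = math.exp(be * J_PER_KCAL / rt)
    if kd < _KD_CAUTION_M:
        logger.warning(
            "Kd = %.3g M from ΔG = %.3g kcal/mol is below any measurable "
            "range; end-point MM/GBSA energies are not absolute binding "
            "free energies", kd, be,
        )
    return DissociationConstant(kd)


def dg_from_kd(kd: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """ΔG = RT ln Kd in kcal/mol from Kd in molar."""
    if kd <= 0:
        raise DomainError(f"Kd must be strictly positive, got {kd}")
    if temperature <= 0:
        raise DomainError("temperature must be positive")
    return GAS_CONSTANT_J * temperature * math.log(kd) / J_PER_KCAL


def _isotherm_model(params, conc, t0):
    from .synthetic_data import fraction_bound

    log_kd, amplitude, baseline = params
    return baseline + amplitude * fraction_bound(conc, math.exp(log_kd), t0)


def fit_isotherm(points: list[tuple[float, float]], t0: float) -> IsothermFit:
    """Least-squares Kd estimate from a dose-response series.

    ``points`` are (total ligand µM, fraction bound / normalized signal);
    ``t0`` is the labeled-target concentration in µM. Requires at least five
    points spanning at least one decade of concentration. The start point is
    deterministic (Kd₀ = geometric mean of the concentrations), so repeated
    fits of the same data are identical.
    """
    if t0 <= 0:
        raise DomainError("t0 must be strictly positive")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise InputError("need at least 5 (concentration, signal) points")
    conc, y = pts[:, 0], pts[:, 1]
    if (conc <= 0).any():
        raise DomainError("concentrations must be strictly positive")
    if conc.max() / conc.min() < 10.0:
        raise InputError("concentrations must span at least one decade")

    if np.ptp(y) < 1e-12:
        return IsothermFit(
            kd_hat=float("nan"), t0=t0, amplitude=0.0, baseline=float(y[0]),
            residual_rms=0.0, n_points=len(y), converged=False,
            message="no binding signal: response is constant across the series",
        )

    kd0 = float(np.exp(np.mean(np.log(conc))))
    x0 = [math.log(kd0), float(np.ptp(y)), float(y.min())]
    sol = least_squares(
        lambda p: _isotherm_model(p, conc, t0) - y, x0,
        method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=10000,
    )
    resid_rms = float(np.sqrt(np.mean(sol.fun**2)))
    kd_hat = float(math.exp(sol.x[0]))
    converged = bool(sol.success) and math.isfinite(kd_hat)
    return IsothermFit(
        kd_hat=kd_hat, t0=t0, amplitude=float(sol.x[1]), baseline=float(sol.x[2]),
        residual_rms=resid_rms, n_points=len(y), converged=converged,
        message=str(sol.message),
    )
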