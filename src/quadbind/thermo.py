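"""Binding free energies, selectivity ratios, and saturation design.

Conventions: Gibbs free energy of association is dG = -R T ln K with
R = 8.314 J/(mol K), reported in kJ/mol; 25 degC maps to T = 298.15 K.
Selectivity between two binding partners a and b is the ratio K_a / K_b with
ddG = -R T ln(K_a / K_b), so a more negative ddG means a binds more tightly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .equilibria import BindingModelSpec, MixtureComposition, solve_speciation
from .exceptions import DomainError, UnreachableTargetError

__all__ = [
    "GAS_CONSTANT",
    "STANDARD_TEMPERATURE_K",
    "ThermoResult",
    "SelectivityResult",
    "free_energy",
    "selectivity",
    "design_saturation",
]

GAS_CONSTANT = 8.314  # J / (mol K)
STANDARD_TEMPERATURE_K = 298.15  # 25 degC

_EQUIVALENTS_CAP = 1e4


@dataclass(frozen=True)
class ThermoResult:
    delta_G: float  # kJ/mol
    temperature: float  # K
    K_used: float  # M^-1
    gas_constant: float = GAS_CONSTANT


@dataclass(frozen=True)
class SelectivityResult:
    ratio: float  # K_a / K_b, dimensionless
    delta_delta_G: float  # kJ/mol
    temperature: float  # K


def free_energy(K: float, T: float = STANDARD_TEMPERATURE_K) -> ThermoResult:
    """dG = -R T ln K in kJ/mol."""
    if not (K > 0 and math.isfinite(K)):
        raise DomainError(f"K must be positive and finite, got {K!r}")
    if not (T > 0 and math.isfinite(T)):
        raise DomainError(f"T must be positive and finite, got {T!r}")
    dg = -GAS_CONSTANT * T * math.log(K) / 1000.0
    return ThermoResult(delta_G=dg, temperature=T, K_used=K)


def selectivity(K_a: float, K_b: float, T: float = STANDARD_TEMPERATURE_K) -> SelectivityResult:
    """Selectivity ratio K_a/K_b and ddG = -R T ln(K_a/K_b) in kJ/mol."""
    for name, k in (("K_a", K_a), ("K_b", K_b)):
        if not (k > 0 and math.isfinite(k)):
            raise DomainError(f"{name} must be positive and finite, got {k!r}")
    if not (T > 0 and math.isfinite(T)):
        raise DomainError(f"T must be positive and finite, got {T!r}")
    ratio = K_a / K_b
    ddg = -GAS_CONSTANT * T * math.log(ratio) / 1000.0
    return SelectivityResult(ratio=ratio, delta_delta_G=ddg, temperature=T)


def _occupancy_at(model: BindingModelSpec, receptor_total: float, equivalents: float) -> float:
    mix = MixtureComposition(receptor_total, equivalents * receptor_total)
    return solve_speciation(model, mix).site_occupancy


def design_saturation(
    model: BindingModelSpec,
    receptor_total: float,
    target_fraction: float,
    tol: float = 1e-6,
) -> float:
    """Smallest ligand excess (equivalents) reaching a target site occupancy.

    Occupancy is monotone non-decreasing in the equivalents ratio, so the
    answer is found by bisection.  If even a very large excess (1e4
    equivalents) cannot reach the target - e.g. the model does not bind -
    an :class:`UnreachableTargetError` is raised.
    """
    if not (0.0 < target_fraction < 1.0):
        raise DomainError("target_fraction must lie strictly between 0 and 1")
    if not (receptor_total > 0 and math.isfinite(receptor_total)):
        raise DomainError("receptor_total must be positive and finite")
    if model.K1 <= 0:
        raise UnreachableTargetError("model has no binding (K1 = 0)")

    hi = _EQUIVALENTS_CAP
    if _occupancy_at(model, receptor_total, hi) < target_fraction:
        raise UnreachableTargetError(
            f"occupancy at {hi:g} equivalents is below target {target_fraction:g}"
        )
    lo = 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _occupancy_at(model, receptor_total, mid) >= target_fraction:
            hi = mid
        else:
            lo = mid
    return hi
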