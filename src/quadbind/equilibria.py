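"""Host-guest equilibrium speciation for 1:1 and 2:1 receptor-ligand systems.

The receptor R is the single-copy species (the nucleic-acid strand) and the
ligand L the species that can bind twice (the peptide).  The stepwise
equilibria are

    R + L  <=>  RL    (K1, M^-1)
    RL + L <=>  RL2   (K2, M^-1)

A non-cooperative "statistical" 2:1 receptor is two identical independent
sites with one microscopic per-site constant k, which forces K1 = 2 k and
K2 = k / 2 (so K1 / K2 = 4 and the cooperativity index alpha = 4 K2 / K1 = 1).

All concentrations are mol/L internally; association constants are M^-1.
Unit conversion from micromolar happens at the I/O boundary, never here.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from scipy.optimize import brentq

from .exceptions import DomainError, InternalInvariantError

__all__ = [
    "ModelId",
    "BindingModelSpec",
    "MixtureComposition",
    "SpeciationResult",
    "SaturationPoint",
    "solve_speciation",
    "statistical_from_micro",
    "saturation_curve",
]

_BRENTQ_RTOL = 4 * 2.220446049250313e-16  # smallest rtol brentq accepts
_ABS_TOL_M = 1e-15  # absolute tolerance on free-ligand concentration, mol/L


class ModelId(str, enum.Enum):
    """Stoichiometric binding models supported by the speciation solver."""

    ONE_TO_ONE = "1:1"
    TWO_TO_ONE_FULL = "2:1-full"
    TWO_TO_ONE_STATISTICAL = "2:1-statistical"


def _check_constant(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise DomainError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise DomainError(f"{name} must be >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class BindingModelSpec:
    """A stoichiometry model plus its equilibrium constants.

    Parameters
    ----------
    model_id:
        One of :class:`ModelId`.
    K1, K2:
        Stepwise association constants in M^-1.  ``K2`` must be ``None`` for
        the 1:1 model.  For the statistical model the pair must satisfy
        ``K1 = 4 * K2`` exactly; build it with :func:`statistical_from_micro`
        rather than by hand.
    """

    model_id: ModelId
    K1: float
    K2: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_id", ModelId(self.model_id))
        object.__setattr__(self, "K1", _check_constant("K1", self.K1))
        if self.model_id is ModelId.ONE_TO_ONE:
            if self.K2 is not None:
                raise DomainError("K2 is undefined for the 1:1 model")
        else:
            if self.K2 is None:
                raise DomainError(f"{self.model_id.value} requires K2")
            object.__setattr__(self, "K2", _check_constant("K2", self.K2))
            if self.model_id is ModelId.TWO_TO_ONE_STATISTICAL and self.K1 != 4 * self.K2:
                raise DomainError(
                    "statistical model requires K1 = 4*K2 exactly; "
                    f"got K1={self.K1!r}, K2={self.K2!r}"
                )

    @property
    def k_micro(self) -> float:
        """Microscopic per-site constant (statistical model only)."""
        if self.model_id is not ModelId.TWO_TO_ONE_STATISTICAL:
            raise DomainError("k_micro is defined only for the statistical model")
        return self.K1 / 2.0

    @property
    def alpha(self) -> float:
        """Cooperativity index 4*K2/K1 (1 for non-cooperative binding)."""
        if self.model_id is ModelId.ONE_TO_ONE:
            raise DomainError("alpha is undefined for the 1:1 model")
        if self.K1 == 0:
            return 1.0 if self.model_id is ModelId.TWO_TO_ONE_STATISTICAL else math.nan
        return 4.0 * self.K2 / self.K1  # type: ignore[operator]

    @property
    def n_constants(self) -> int:
        return {
            ModelId.ONE_TO_ONE: 1,
            ModelId.TWO_TO_ONE_STATISTICAL: 1,
            ModelId.TWO_TO_ONE_FULL: 2,
        }[self.model_id]


def statistical_from_micro(k_micro: float) -> BindingModelSpec:
    """Statistical 2:1 model from the microscopic per-site constant.

    Two equivalent independent sites give stepwise constants K1 = 2 k and
    K2 = k / 2 purely from the statistical factors.
    """
    k = _check_constant("k_micro", k_micro)
    return BindingModelSpec(ModelId.TWO_TO_ONE_STATISTICAL, K1=2.0 * k, K2=k / 2.0)


@dataclass(frozen=True)
class MixtureComposition:
    """Total (analytical) concentrations of receptor and ligand, mol/L."""

    receptor_total: float
    ligand_total: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "receptor_total", _check_constant("receptor_total", self.receptor_total))
        object.__setattr__(self, "ligand_total", _check_constant("ligand_total", self.ligand_total))


@dataclass(frozen=True)
class SpeciationResult:
    """Equilibrium concentrations (mol/L) and occupancy fractions at one point."""

    free_receptor: float
    free_ligand: float
    complex_RL: float
    complex_RL2: float
    site_occupancy: float
    ligand_bound_fraction: float


class SaturationPoint(NamedTuple):
    equivalents: float
    site_occupancy: float
    ligand_bound_fraction: float


def _bound_ligand(p: float, r_tot: float, k1: float, k12: float) -> float:
    """Ligand locked in complexes at free-ligand concentration p."""
    denom = 1.0 + k1 * p + k12 * p * p
    return r_tot * (k1 * p + 2.0 * k12 * p * p) / denom


def _solve_free_ligand_2to1(r_tot: float, l_tot: float, k1: float, k2: float) -> float:
    """Root of the scalar ligand mass balance h(p) = 0 on [0, ligand_total].

    h(p) = p + bound(p) - l_tot is strictly increasing in p, with h(0) < 0 and
    h(l_tot) >= 0, so the bracket is provably valid.  A bracketed solve is
    followed by Newton polishing so the mass balance closes to near machine
    precision even when receptor_total * K1 is large.
    """
    k12 = k1 * k2

    def h(p: float) -> float:
        return p + _bound_ligand(p, r_tot, k1, k12) - l_tot

    lo, hi = 0.0, l_tot
    h_lo, h_hi = h(lo), h(hi)
    if h_lo > 0 or h_hi < 0:  # pragma: no cover - impossible for valid inputs
        raise InternalInvariantError(
            f"mass balance not bracketed: h(0)={h_lo!r}, h(L)={h_hi!r}"
        )
    p = brentq(h, lo, hi, xtol=_ABS_TOL_M, rtol=_BRENTQ_RTOL)

    # Newton polish: h'(p) >= 1 always, so the step is well conditioned.
    for _ in range(6):
        denom = 1.0 + k1 * p + k12 * p * p
        dbound = r_tot * (
            (k1 + 4.0 * k12 * p) * denom
            - (k1 * p + 2.0 * k12 * p * p) * (k1 + 2.0 * k12 * p)
        ) / (denom * denom)
        step = h(p) / (1.0 + dbound)
        p = min(max(p - step, 0.0), l_tot)
        if abs(step) <= 1e-15 * p:  # converged in relative terms
            break
    return p


def _solve_free_ligand_1to1(r_tot: float, l_tot: float, k: float) -> float:
    """Closed-form (quadratic) free ligand for R + L <=> RL."""
    if k == 0.0:
        return l_tot
    # K*RL^2 - (K(R+L)+1)*RL + K*R*L = 0; the physical root is the smaller
    # one, computed in the cancellation-free form 2c / (b + sqrt(disc))
    b = k * (r_tot + l_tot) + 1.0
    disc = b * b - 4.0 * k * k * r_tot * l_tot
    rl = 2.0 * k * r_tot * l_tot / (b + math.sqrt(max(disc, 0.0)))
    rl = min(max(rl, 0.0), min(r_tot, l_tot))
    return l_tot - rl


def solve_speciation(model: BindingModelSpec, mix: MixtureComposition) -> SpeciationResult:
    """Unique physically admissible speciation of the mass-action system.

    For the 1:1 model the quadratic closed form is used; 2:1 models solve the
    scalar free-ligand mass balance by a bracketed method (see module notes).
    Mass balance closes to better than 1e-10 relative for valid inputs.
    """
    r_tot, l_tot = mix.receptor_total, mix.ligand_total
    n_sites = 1 if model.model_id is ModelId.ONE_TO_ONE else 2

    if l_tot == 0.0:
        return SpeciationResult(r_tot, 0.0, 0.0, 0.0, 0.0, 0.0)
    if r_tot == 0.0 or model.K1 == 0.0:
        # no receptor (h(p) would be 0/0-free but trivial) or no binding
        return SpeciationResult(r_tot, l_tot, 0.0, 0.0, 0.0, 0.0)

    if model.model_id is ModelId.ONE_TO_ONE:
        p = _solve_free_ligand_1to1(r_tot, l_tot, model.K1)
        rl = l_tot - p
        free_r = r_tot - rl
        rl2 = 0.0
    else:
        k1, k2 = model.K1, model.K2  # type: ignore[assignment]
        p = _solve_free_ligand_2to1(r_tot, l_tot, k1, k2)
        denom = 1.0 + k1 * p + k1 * k2 * p * p
        free_r = r_tot / denom
        rl = r_tot * k1 * p / denom
        rl2 = r_tot * k1 * k2 * p * p / denom

    occ = (rl + 2.0 * rl2) / (n_sites * r_tot)
    bound_frac = (rl + 2.0 * rl2) / l_tot
    return SpeciationResult(
        free_receptor=free_r,
        free_ligand=p,
        complex_RL=rl,
        complex_RL2=rl2,
        site_occupancy=min(max(occ, 0.0), 1.0),
        ligand_bound_fraction=min(max(bound_frac, 0.0), 1.0),
    )


def saturation_curve(
    model: BindingModelSpec,
    receptor_total: float,
    equivalents_grid: Sequence[float],
) -> list[SaturationPoint]:
    """Site occupancy and ligand-bound fraction over a grid of ligand excesses.

    Each grid value e is solved at ``ligand_total = e * receptor_total``; the
    occupancy is non-decreasing in e.
    """
    r_tot = _check_constant("receptor_total", receptor_total)
    points = []
    for e in equivalents_grid:
        e = _check_constant("equivalents", e)
        res = solve_speciation(model, MixtureComposition(r_tot, e * r_tot))
        points.append(SaturationPoint(e, res.site_occupancy, res.ligand_bound_fraction))
    return points
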