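"""CD melting-curve analysis: Tm fitting, fraction folded, stabilization tables.

A melting curve is ellipticity (mdeg) versus temperature at a fixed monitor
wavelength (260 nm for parallel G-quadruplexes, 295 nm for antiparallel).
Curves are fit to an asymmetric five-parameter logistic

    y(T) = A_unfolded + (A_folded - A_unfolded) / (1 + exp((T - T_half)/w))^s

and the melting temperature Tm is defined operationally as the temperature
at which the fitted signal crosses the midpoint between the plateaus, i.e.
where 50% of the structure has denatured.  For s = 1 this reduces to the
symmetric Boltzmann sigmoid and Tm = T_half.

The module also classifies G4 folding topology from a CD spectrum using the
canonical band signs: a parallel quadruplex shows a positive band near
262 nm and a negative band near 245 nm; an antiparallel one a positive band
near 295 nm and a trough near 232 nm.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .exceptions import DomainError, FitError, TransitionOutOfRangeError

__all__ = [
    "MeltCurve",
    "MeltFitResult",
    "MeltFitOptions",
    "FoldedFractionProfile",
    "StabilizationRow",
    "StabilizationTable",
    "CdSpectrum",
    "Topology",
    "fit_melt",
    "fraction_folded",
    "fraction_folded_profile",
    "build_stabilization_table",
    "classify_topology",
]


@dataclass(frozen=True)
class MeltCurve:
    """Ellipticity-vs-temperature trace at one monitor wavelength."""

    temperatures: np.ndarray
    ellipticity: np.ndarray
    monitor_wavelength: float
    sample_id: str = "sample"
    condition_label: str = "control"

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        y = np.asarray(self.ellipticity, dtype=float)
        if t.ndim != 1 or t.size < 20:
            raise DomainError("a melt curve needs at least 20 temperature points")
        if np.any(np.diff(t) <= 0):
            raise DomainError("temperatures must be strictly increasing")
        if y.shape != t.shape or not np.all(np.isfinite(y)):
            raise DomainError("ellipticity must be finite and match temperatures")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "ellipticity", y)


@dataclass(frozen=True)
class MeltFitOptions:
    """min_amplitude: smallest plateau-to-plateau excursion (mdeg) treated as
    a real transition; anything flatter raises transition-out-of-range."""

    min_amplitude: float = 1.0
    max_nfev: int = 2000


@dataclass(frozen=True)
class MeltFitResult:
    A_folded: float
    A_unfolded: float
    T_half: float
    width: float
    s: float
    Tm: float
    Tm_se: float
    rss: float
    covariance: np.ndarray
    sample_id: str = "sample"
    condition_label: str = "control"


def _logistic5(t: np.ndarray, a_f: float, a_u: float, t_half: float, width: float, s: float):
    z = (t - t_half) / width
    # (1 + e^z)^(-s) computed in log space to avoid overflow at the tails
    return a_u + (a_f - a_u) * np.exp(-s * np.logaddexp(0.0, z))


def fit_melt(
    curve: MeltCurve,
    orientation: str = "folded_high",
    options: MeltFitOptions | None = None,
) -> MeltFitResult:
    """Least-squares asymmetric-sigmoid fit and half-denaturation Tm.

    ``orientation`` states which plateau belongs to the folded state:
    ``folded_high`` (the usual case at 260/295 nm, folded signal above the
    unfolded baseline) or ``folded_low``.  The folded plateau is always the
    low-temperature one; orientation is used to sanity-check initialisation.

    Tm is found by bracketed root finding of ``y(T) = (A_folded+A_unfolded)/2``
    inside the measured range; its standard error comes from the delta method
    applied to that implicit equation.
    """
    if orientation not in ("folded_high", "folded_low"):
        raise DomainError(f"unknown orientation {orientation!r}")
    options = options or MeltFitOptions()
    t, y = curve.temperatures, curve.ellipticity

    if float(np.ptp(y)) <= options.min_amplitude:
        raise TransitionOutOfRangeError(
            f"signal excursion {np.ptp(y):.3g} mdeg is below the "
            f"{options.min_amplitude:.3g} mdeg amplitude floor"
        )

    n_edge = max(3, t.size // 20)
    a_f0 = float(np.mean(y[:n_edge]))   # folded = low-temperature plateau
    a_u0 = float(np.mean(y[-n_edge:]))
    if orientation == "folded_high" and a_f0 < a_u0:
        raise TransitionOutOfRangeError(
            "folded_high orientation but the low-temperature plateau is the "
            "smaller signal; no denaturation transition in range"
        )
    if orientation == "folded_low" and a_f0 > a_u0:
        raise TransitionOutOfRangeError(
            "folded_low orientation but the low-temperature plateau is the "
            "larger signal; no denaturation transition in range"
        )

    mid0 = 0.5 * (a_f0 + a_u0)
    crossings = np.nonzero(np.diff(np.sign(y - mid0)))[0]
    t_half0 = float(t[crossings[0]]) if crossings.size else float(np.median(t))
    width0 = max(0.05 * float(np.ptp(t)), 0.5)

    # width and s are kept positive via log parametrization
    def resid(theta: np.ndarray) -> np.ndarray:
        a_f, a_u, t_half, lw, ls = theta
        return _logistic5(t, a_f, a_u, t_half, math.exp(lw), math.exp(ls)) - y

    theta0 = np.array([a_f0, a_u0, t_half0, math.log(width0), 0.0])
    sol = least_squares(resid, theta0, max_nfev=options.max_nfev)
    if not sol.success:  # pragma: no cover - least_squares rarely hard-fails
        raise FitError(f"melt fit did not converge: {sol.message}")
    a_f, a_u, t_half, lw, ls = sol.x
    width, s = math.exp(lw), math.exp(ls)
    rss = float(sol.fun @ sol.fun)

    tm = _half_signal_root(sol.x, t[0], t[-1])

    dof = t.size - 5
    sigma2 = rss / dof if dof > 0 else math.nan
    jtj = sol.jac.T @ sol.jac
    cov = sigma2 * np.linalg.pinv(jtj)
    grad = _tm_gradient(sol.x, t[0], t[-1])
    tm_var = float(grad @ cov @ grad)
    tm_se = math.sqrt(tm_var) if tm_var >= 0 else math.nan

    return MeltFitResult(
        A_folded=float(a_f),
        A_unfolded=float(a_u),
        T_half=float(t_half),
        width=float(width),
        s=float(s),
        Tm=float(tm),
        Tm_se=float(tm_se),
        rss=rss,
        covariance=cov,
        sample_id=curve.sample_id,
        condition_label=curve.condition_label,
    )


def _half_signal_root(theta: np.ndarray, t_lo: float, t_hi: float) -> float:
    a_f, a_u, t_half, lw, ls = theta
    width, s = math.exp(lw), math.exp(ls)
    mid = 0.5 * (a_f + a_u)

    def g(tt: float) -> float:
        return float(_logistic5(np.array([tt]), a_f, a_u, t_half, width, s)[0]) - mid

    g_lo, g_hi = g(t_lo), g(t_hi)
    if g_lo == 0.0:
        return t_lo
    if g_hi == 0.0:
        return t_hi
    if g_lo * g_hi > 0:
        raise TransitionOutOfRangeError(
            "fitted half-denaturation point lies outside the measured range"
        )
    return float(brentq(g, t_lo, t_hi, xtol=1e-10))


def _tm_gradient(theta: np.ndarray, t_lo: float, t_hi: float, h: float = 1e-6) -> np.ndarray:
    """dTm/dtheta by central differences, re-solving the implicit root."""
    grad = np.empty(theta.size)
    for i in range(theta.size):
        step = h * max(1.0, abs(theta[i]))
        up, down = theta.copy(), theta.copy()
        up[i] += step
        down[i] -= step
        try:
            grad[i] = (
                _half_signal_root(up, t_lo, t_hi) - _half_signal_root(down, t_lo, t_hi)
            ) / (2.0 * step)
        except TransitionOutOfRangeError:
            grad[i] = math.nan
    return grad


# ---------------------------------------------------------------------------
# fraction folded
# ---------------------------------------------------------------------------

def fraction_folded(value: float, reference_folded: float, reference_unfolded: float) -> float:
    """Linear normalization against fully-folded and fully-unfolded signals.

    Values slightly outside [0, 1] are returned as-is, not clipped.
    """
    if reference_folded == reference_unfolded:
        raise DomainError("reference_folded and reference_unfolded must differ")
    return (value - reference_unfolded) / (reference_folded - reference_unfolded)


@dataclass(frozen=True)
class FoldedFractionProfile:
    temperatures: np.ndarray
    theta: np.ndarray
    reference_id: str


def fraction_folded_profile(
    curve: MeltCurve,
    reference_folded: float,
    reference_unfolded: float,
    reference_id: str,
) -> FoldedFractionProfile:
    """Fraction-folded trace of a whole melt curve against a 100% reference."""
    if reference_folded == reference_unfolded:
        raise DomainError("reference_folded and reference_unfolded must differ")
    theta = (curve.ellipticity - reference_unfolded) / (reference_folded - reference_unfolded)
    return FoldedFractionProfile(curve.temperatures, theta, reference_id)


# ---------------------------------------------------------------------------
# stabilization tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StabilizationRow:
    sequence_label: str
    Tm_control: float
    Tm_condition: float
    delta_T: float
    condition_label: str
    error: str | None = None


@dataclass(frozen=True)
class StabilizationTable:
    rows: tuple[StabilizationRow, ...]

    def to_frame(self, display_rounding: bool = True):
        """Tabular view; Tm and delta_T rounded to 0.1 degC only for display."""
        import pandas as pd

        def r(x: float) -> float:
            return round(x, 1) if display_rounding and math.isfinite(x) else x

        return pd.DataFrame(
            {
                "sequence": [row.sequence_label for row in self.rows],
                "Tm_control": [r(row.Tm_control) for row in self.rows],
                "Tm_condition": [r(row.Tm_condition) for row in self.rows],
                "delta_T": [r(row.delta_T) for row in self.rows],
                "condition": [row.condition_label for row in self.rows],
                "error": [row.error or "" for row in self.rows],
            }
        )


def build_stabilization_table(
    fits: Iterable[tuple[str, str, MeltFitResult]],
    control_label: str = "control",
) -> StabilizationTable:
    """Per-sequence Tm shifts relative to the control condition.

    ``fits`` yields ``(sequence_label, condition_label, fit)`` records.  Each
    sequence must have exactly one control; a sequence missing its control
    produces error rows rather than aborting the table.  delta_T is computed
    from unrounded Tm values; rounding happens only at serialization.
    """
    by_seq: dict[str, list[tuple[str, MeltFitResult]]] = {}
    for seq, cond, fit in fits:
        by_seq.setdefault(seq, []).append((cond, fit))

    rows: list[StabilizationRow] = []
    for seq, entries in by_seq.items():
        controls = [f for c, f in entries if c == control_label]
        if len(controls) > 1:
            raise DomainError(f"sequence {seq!r} has {len(controls)} control fits")
        conditions = [(c, f) for c, f in entries if c != control_label]
        if not controls:
            for cond, fit in conditions:
                rows.append(
                    StabilizationRow(seq, math.nan, fit.Tm, math.nan, cond, "missing-control")
                )
            continue
        tm_control = controls[0].Tm
        for cond, fit in conditions:
            rows.append(
                StabilizationRow(seq, tm_control, fit.Tm, fit.Tm - tm_control, cond)
            )
    return StabilizationTable(tuple(rows))


# ---------------------------------------------------------------------------
# CD topology classification
# ---------------------------------------------------------------------------

class Topology(str, enum.Enum):
    PARALLEL = "parallel"
    ANTIPARALLEL = "antiparallel"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class CdSpectrum:
    """Wavelength-resolved CD trace used for topology classification."""

    wavelengths: np.ndarray
    ellipticity: np.ndarray
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        y = np.asarray(self.ellipticity, dtype=float)
        if wl.ndim != 1 or np.any(np.diff(wl) <= 0):
            raise DomainError("wavelengths must be 1-D and strictly ascending")
        if y.shape != wl.shape or not np.all(np.isfinite(y)):
            raise DomainError("ellipticity must be finite and match wavelengths")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "ellipticity", y)


def _band_mean(spectrum: CdSpectrum, center: float, half_window: float = 3.0) -> float:
    mask = np.abs(spectrum.wavelengths - center) <= half_window
    if not np.any(mask):
        raise DomainError(f"no data within {half_window} nm of {center} nm")
    return float(np.mean(spectrum.ellipticity[mask]))


def classify_topology(spectrum: CdSpectrum, threshold: float = 1.0) -> Topology:
    """G4 topology call from canonical CD band signs.

    Parallel: positive band near 262 nm and negative band near 245 nm.
    Antiparallel: positive band near 295 nm and negative trough near 232 nm.
    Band values are means over a +/-3 nm window; ``threshold`` (mdeg) is the
    minimum magnitude a band must exceed to count.
    """
    wl = spectrum.wavelengths
    if wl[0] > 232.0 or wl[-1] < 300.0:
        raise DomainError(
            f"spectrum must cover 232-300 nm, got {wl[0]:.0f}-{wl[-1]:.0f} nm"
        )
    e262 = _band_mean(spectrum, 262.0)
    e245 = _band_mean(spectrum, 245.0)
    e295 = _band_mean(spectrum, 295.0)
    e232 = _band_mean(spectrum, 232.0)
    if e262 > threshold and e245 < -threshold:
        return Topology.PARALLEL
    if e295 > threshold and e232 < -threshold:
        return Topology.ANTIPARALLEL
    return Topology.UNDETERMINED
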