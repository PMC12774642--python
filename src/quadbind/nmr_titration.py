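"""Fast-exchange NMR titration isotherms: observation model, fitting, selection.

In the fast-exchange regime a nucleus on the observed species shows a single
resonance at the population-weighted average of its free and bound shifts.
Here the observed species is the ligand (the peptide, held at constant
concentration) and the titrant is the receptor (the folded nucleic acid), so

    delta_obs = (delta_free * [L] + delta_b1 * [RL] + delta_b2 * 2[RL2]) / L_tot

with the speciation supplied by :mod:`quadbind.equilibria`.  Fitting is a
global least-squares problem: equilibrium constants (shared across nuclei)
are optimised in log10 space while the shift parameters, which enter the
model linearly, are profiled out by linear projection at every constant
evaluation.  Model selection uses the small-sample corrected Akaike
information criterion

    AICc = n ln(rss / n) + 2 p + 2 p (p + 1) / (n - p - 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .equilibria import (
    BindingModelSpec,
    MixtureComposition,
    ModelId,
    solve_speciation,
    statistical_from_micro,
)
from .exceptions import DomainError, FitError

__all__ = [
    "NucleusTrace",
    "TitrationSeries",
    "merge_replicates",
    "ShiftParameters",
    "TitrationFitResult",
    "FitOptions",
    "ModelComparison",
    "predict_shifts",
    "fit_titration",
    "compare_models",
    "average_constants",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class NucleusTrace:
    """Observed chemical shifts (ppm) of one nucleus across the titration."""

    nucleus_id: str
    delta_obs: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.delta_obs, dtype=float)
        if arr.ndim != 1:
            raise DomainError("delta_obs must be one-dimensional")
        if not np.all(np.isfinite(arr)):
            raise DomainError(f"non-finite shift in trace {self.nucleus_id!r}")
        object.__setattr__(self, "delta_obs", arr)


@dataclass(frozen=True)
class TitrationSeries:
    """One titration: a fixed observed species dosed with increasing titrant.

    Parameters
    ----------
    fixed_species_total:
        Constant total concentration of the observed species (mol/L), e.g.
        a peptide held at 125e-6 M.
    equivalents:
        Titrant-to-fixed-species mole ratios, non-negative and strictly
        increasing, normally starting at 0.
    nuclei:
        One :class:`NucleusTrace` per monitored nucleus, each with one shift
        per titration point.
    titrant_total:
        Optional explicit titrant concentrations (mol/L); defaults to
        ``equivalents * fixed_species_total``.
    """

    fixed_species_total: float
    equivalents: np.ndarray
    nuclei: tuple[NucleusTrace, ...]
    titrant_total: np.ndarray | None = None
    temperature: float = 25.0
    replicate_id: str = "rep1"
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.fixed_species_total) and self.fixed_species_total > 0):
            raise DomainError("fixed_species_total must be finite and > 0")
        eq = np.asarray(self.equivalents, dtype=float)
        if eq.ndim != 1 or eq.size < 1:
            raise DomainError("equivalents must be a non-empty 1-D sequence")
        if np.any(eq < 0) or np.any(np.diff(eq) <= 0):
            raise DomainError("equivalents must be non-negative and strictly increasing")
        object.__setattr__(self, "equivalents", eq)
        if self.titrant_total is None:
            object.__setattr__(self, "titrant_total", eq * self.fixed_species_total)
        else:
            tt = np.asarray(self.titrant_total, dtype=float)
            if tt.shape != eq.shape or np.any(tt < 0):
                raise DomainError("titrant_total must match equivalents and be >= 0")
            object.__setattr__(self, "titrant_total", tt)
        nuclei = tuple(self.nuclei)
        if not nuclei:
            raise DomainError("at least one nucleus trace is required")
        for trace in nuclei:
            if trace.delta_obs.size != eq.size:
                raise DomainError(
                    f"trace {trace.nucleus_id!r} has {trace.delta_obs.size} shifts "
                    f"for {eq.size} titration points"
                )
        object.__setattr__(self, "nuclei", nuclei)

    @property
    def n_points(self) -> int:
        return int(self.equivalents.size)


@dataclass(frozen=True)
class ShiftParameters:
    """Limiting shifts (ppm) of one nucleus: free, singly and doubly bound."""

    delta_free: float
    delta_bound_1: float
    delta_bound_2: float


@dataclass(frozen=True)
class FitOptions:
    """Tunables for :func:`fit_titration`.

    noise_floor is the smallest total shift excursion (ppm) considered
    informative; traces flatter than this are flagged unidentifiable and the
    constants are reported without confidence intervals.
    """

    noise_floor: float = 0.005
    grid_log10k: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
    log10k_bounds: tuple[float, float] = (-6.0, 14.0)
    # largest physically plausible |delta_bound - delta_free| (ppm); a fit
    # needing more has slid down the K -> 0, delta_bound -> inf ridge
    max_delta_shift: float = 20.0


@dataclass(frozen=True)
class TitrationFitResult:
    model: BindingModelSpec
    shifts: dict[str, ShiftParameters]
    standard_errors: dict[str, float]
    rss: float
    n_points: int
    n_params: int
    aicc: float
    covariance: np.ndarray
    param_names: tuple[str, ...]
    unidentifiable: bool = False
    sample_id: str = "sample"
    replicate_id: str = "rep1"

    @property
    def primary_constant(self) -> float:
        """k_micro for the statistical model, K1 otherwise (M^-1)."""
        if self.model.model_id is ModelId.TWO_TO_ONE_STATISTICAL:
            return self.model.k_micro
        return self.model.K1

    @property
    def primary_constant_se(self) -> float:
        key = (
            "k_micro"
            if self.model.model_id is ModelId.TWO_TO_ONE_STATISTICAL
            else "K1"
        )
        return self.standard_errors.get(key, math.nan)


def merge_replicates(series_list: Sequence[TitrationSeries]) -> TitrationSeries:
    """Combine duplicate titrations into one series for a global fit.

    The replicates must share the fixed-species concentration and the
    titrant grid.  Each trace is re-labelled ``replicate_id:nucleus_id`` so a
    single :func:`fit_titration` call shares the equilibrium constants across
    replicates while keeping per-replicate shift parameters — the usual
    global-analysis treatment of duplicate runs, and more efficient than
    averaging separately fitted constants.
    """
    if not series_list:
        raise DomainError("at least one series is required")
    base = series_list[0]
    nuclei: list[NucleusTrace] = []
    for s in series_list:
        if s.fixed_species_total != base.fixed_species_total or not np.array_equal(
            s.titrant_total, base.titrant_total
        ):
            raise DomainError("replicates must share concentrations and grid")
        for trace in s.nuclei:
            nuclei.append(NucleusTrace(f"{s.replicate_id}:{trace.nucleus_id}", trace.delta_obs))
    return TitrationSeries(
        fixed_species_total=base.fixed_species_total,
        equivalents=base.equivalents,
        nuclei=tuple(nuclei),
        titrant_total=base.titrant_total,
        temperature=base.temperature,
        sample_id=base.sample_id,
        replicate_id="global",
    )


# ---------------------------------------------------------------------------
# observation model
# ---------------------------------------------------------------------------

def _mole_fractions(model: BindingModelSpec, series: TitrationSeries) -> np.ndarray:
    """Per-point ligand mole fractions (free, singly bound, doubly bound)."""
    l_tot = series.fixed_species_total
    out = np.empty((series.n_points, 3))
    for i, r_tot in enumerate(series.titrant_total):
        res = solve_speciation(model, MixtureComposition(float(r_tot), l_tot))
        out[i, 0] = res.free_ligand / l_tot
        out[i, 1] = res.complex_RL / l_tot
        out[i, 2] = 2.0 * res.complex_RL2 / l_tot
    return out


def predict_shifts(
    model: BindingModelSpec,
    shifts: Mapping[str, ShiftParameters],
    series: TitrationSeries,
) -> dict[str, np.ndarray]:
    """Fast-exchange predicted shift trace (ppm) for every nucleus.

    At zero titrant the ligand is entirely free and the prediction is exactly
    ``delta_free``.
    """
    missing = [t.nucleus_id for t in series.nuclei if t.nucleus_id not in shifts]
    if missing:
        raise DomainError(f"missing shift parameters for nuclei {missing}")
    x = _mole_fractions(model, series)
    out: dict[str, np.ndarray] = {}
    for trace in series.nuclei:
        s = shifts[trace.nucleus_id]
        out[trace.nucleus_id] = (
            s.delta_free * x[:, 0]
            + s.delta_bound_1 * x[:, 1]
            + s.delta_bound_2 * x[:, 2]
        )
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _model_from_log(model_id: ModelId, theta: np.ndarray) -> BindingModelSpec:
    if model_id is ModelId.ONE_TO_ONE:
        return BindingModelSpec(model_id, K1=10.0 ** theta[0])
    if model_id is ModelId.TWO_TO_ONE_STATISTICAL:
        return statistical_from_micro(10.0 ** theta[0])
    return BindingModelSpec(model_id, K1=10.0 ** theta[0], K2=10.0 ** theta[1])


def _design_matrix(model_id: ModelId, x: np.ndarray) -> np.ndarray:
    """Columns multiplying the linear shift parameters."""
    if model_id is ModelId.ONE_TO_ONE:
        return x[:, :2]
    if model_id is ModelId.TWO_TO_ONE_STATISTICAL:
        # one bound environment: delta_bound_2 == delta_bound_1
        return np.column_stack([x[:, 0], x[:, 1] + x[:, 2]])
    return x


def _n_shift_params(model_id: ModelId) -> int:
    return 3 if model_id is ModelId.TWO_TO_ONE_FULL else 2


def _shift_param_names(model_id: ModelId, nucleus_id: str) -> list[str]:
    if model_id is ModelId.TWO_TO_ONE_FULL:
        return [
            f"{nucleus_id}:delta_free",
            f"{nucleus_id}:delta_bound_1",
            f"{nucleus_id}:delta_bound_2",
        ]
    return [f"{nucleus_id}:delta_free", f"{nucleus_id}:delta_bound"]


def _profiled_residuals(
    theta: np.ndarray, model_id: ModelId, series: TitrationSeries
) -> tuple[np.ndarray, list[np.ndarray]]:
    model = _model_from_log(model_id, theta)
    X = _design_matrix(model_id, _mole_fractions(model, series))
    residuals, coefs = [], []
    for trace in series.nuclei:
        coef, *_ = np.linalg.lstsq(X, trace.delta_obs, rcond=None)
        residuals.append(trace.delta_obs - X @ coef)
        coefs.append(coef)
    return np.concatenate(residuals), coefs


def _full_residuals(
    theta_full: np.ndarray, model_id: ModelId, series: TitrationSeries
) -> np.ndarray:
    n_const = 2 if model_id is ModelId.TWO_TO_ONE_FULL else 1
    n_shift = _n_shift_params(model_id)
    model = _model_from_log(model_id, theta_full[:n_const])
    X = _design_matrix(model_id, _mole_fractions(model, series))
    residuals = []
    for j, trace in enumerate(series.nuclei):
        coef = theta_full[n_const + j * n_shift : n_const + (j + 1) * n_shift]
        residuals.append(trace.delta_obs - X @ coef)
    return np.concatenate(residuals)


def _numeric_jacobian(fun, theta: np.ndarray, n_out: int) -> np.ndarray:
    jac = np.empty((n_out, theta.size))
    for i in range(theta.size):
        h = 1e-6 * max(1.0, abs(theta[i]))
        up, down = theta.copy(), theta.copy()
        up[i] += h
        down[i] -= h
        jac[:, i] = (fun(up) - fun(down)) / (2.0 * h)
    return jac


def _aicc(n: int, p: int, rss: float) -> float:
    if n <= p + 1:
        return math.inf
    if rss <= 0.0:
        return -math.inf
    return n * math.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


def fit_titration(
    series: TitrationSeries,
    model_id: ModelId | str,
    options: FitOptions | None = None,
) -> TitrationFitResult:
    """Global least-squares fit of one titration series to a binding model.

    Equilibrium constants are optimised in log10 space (shared across nuclei);
    shift parameters are profiled out linearly.  Standard errors come from the
    numerical Jacobian at the optimum; flat traces are flagged unidentifiable
    and returned without confidence information.
    """
    model_id = ModelId(model_id)
    options = options or FitOptions()
    if series.n_points < 5:
        raise DomainError("at least 5 titration points are required")

    n_const = 2 if model_id is ModelId.TWO_TO_ONE_FULL else 1
    n_shift = _n_shift_params(model_id)
    n = series.n_points * len(series.nuclei)
    p = n_const + n_shift * len(series.nuclei)
    if n <= p:
        raise FitError(f"{n} observations cannot constrain {p} parameters")

    unidentifiable = all(
        float(np.ptp(t.delta_obs)) < options.noise_floor for t in series.nuclei
    )

    # coarse grid over log10 K seeds the optimiser to avoid local minima
    def rss_at(theta: np.ndarray) -> float:
        r, _ = _profiled_residuals(theta, model_id, series)
        return float(r @ r)

    if n_const == 1:
        grid = [np.array([g]) for g in options.grid_log10k]
    else:
        grid = [np.array([g, g - math.log10(4.0)]) for g in options.grid_log10k]
    x0 = min(grid, key=rss_at)

    lo, hi = options.log10k_bounds
    sol = least_squares(
        lambda t: _profiled_residuals(t, model_id, series)[0],
        x0,
        bounds=(np.full(n_const, lo), np.full(n_const, hi)),
        diff_step=1e-5,
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    theta_log = sol.x
    # a constant pinned at the search bounds is not constrained by the data
    # (the classic weak-binding ridge K -> 0 with delta_bound -> inf)
    if np.any(np.abs(theta_log - lo) < 1e-6) or np.any(np.abs(theta_log - hi) < 1e-6):
        unidentifiable = True
    _, coefs = _profiled_residuals(theta_log, model_id, series)
    for coef in coefs:
        if np.any(np.abs(coef[1:] - coef[0]) > options.max_delta_shift):
            unidentifiable = True
    theta_full = np.concatenate([theta_log, np.concatenate(coefs)])
    resid = _full_residuals(theta_full, model_id, series)
    rss = float(resid @ resid)

    # covariance of the full parameter vector from the Jacobian at the optimum
    jac = _numeric_jacobian(
        lambda t: _full_residuals(t, model_id, series), theta_full, n
    )
    dof = n - p
    sigma2 = rss / dof if dof > 0 else math.nan
    try:
        cov = sigma2 * np.linalg.pinv(jac.T @ jac)
    except np.linalg.LinAlgError:  # pragma: no cover
        cov = np.full((p, p), math.nan)
    se_full = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    model = _model_from_log(model_id, theta_log)
    if model_id is ModelId.ONE_TO_ONE:
        const_names = ["K1"]
        const_values = [model.K1]
    elif model_id is ModelId.TWO_TO_ONE_STATISTICAL:
        const_names = ["k_micro"]
        const_values = [model.k_micro]
    else:
        const_names = ["K1", "K2"]
        const_values = [model.K1, model.K2]

    names: list[str] = list(const_names)
    for trace in series.nuclei:
        names.extend(_shift_param_names(model_id, trace.nucleus_id))

    standard_errors: dict[str, float] = {}
    for i, (cname, cval) in enumerate(zip(const_names, const_values)):
        # delta method: K = 10^theta  =>  se_K = ln(10) * K * se_theta
        se = _LN10 * cval * se_full[i]
        standard_errors[cname] = math.nan if unidentifiable else float(se)
    for i, name in enumerate(names[n_const:], start=n_const):
        standard_errors[name] = float(se_full[i])

    shifts: dict[str, ShiftParameters] = {}
    for j, trace in enumerate(series.nuclei):
        coef = coefs[j]
        if model_id is ModelId.TWO_TO_ONE_FULL:
            sp = ShiftParameters(coef[0], coef[1], coef[2])
        else:
            sp = ShiftParameters(coef[0], coef[1], coef[1])
        shifts[trace.nucleus_id] = sp

    return TitrationFitResult(
        model=model,
        shifts=shifts,
        standard_errors=standard_errors,
        rss=rss,
        n_points=n,
        n_params=p,
        aicc=_aicc(n, p, rss),
        covariance=cov,
        param_names=tuple(names),
        unidentifiable=unidentifiable,
        sample_id=series.sample_id,
        replicate_id=series.replicate_id,
    )


# ---------------------------------------------------------------------------
# model comparison and replicate averaging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelComparison:
    """AICc-ranked candidate fits; failures are recorded, never fatal."""

    results: tuple[TitrationFitResult, ...]
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def best(self) -> TitrationFitResult:
        return self.results[0]

    def table(self):
        """Summary DataFrame (model, n_params, rss, aicc, delta_aicc)."""
        import pandas as pd

        best_aicc = min(r.aicc for r in self.results)
        return pd.DataFrame(
            {
                "model": [r.model.model_id.value for r in self.results],
                "n_params": [r.n_params for r in self.results],
                "rss": [r.rss for r in self.results],
                "aicc": [r.aicc for r in self.results],
                "delta_aicc": [r.aicc - best_aicc for r in self.results],
            }
        )


def compare_models(
    series: TitrationSeries,
    candidates: Sequence[ModelId | str],
    options: FitOptions | None = None,
) -> ModelComparison:
    """Fit every candidate model and rank by AICc (ascending).

    Candidates within 2 AICc units of the best are re-ordered by parameter
    count, so a simpler model within the tie band wins (parsimony tie-break).
    """
    if not candidates:
        raise DomainError("at least one candidate model is required")
    results: list[TitrationFitResult] = []
    failures: dict[str, str] = {}
    for cand in candidates:
        cand = ModelId(cand)
        try:
            results.append(fit_titration(series, cand, options))
        except (DomainError, FitError) as exc:
            failures[cand.value] = str(exc)
    if not results:
        raise FitError(f"all candidate fits failed: {failures}")

    results.sort(key=lambda r: r.aicc)
    best_aicc = results[0].aicc
    tied = [r for r in results if r.aicc - best_aicc < 2.0]
    rest = [r for r in results if r.aicc - best_aicc >= 2.0]
    tied.sort(key=lambda r: (r.n_params, r.aicc))
    return ModelComparison(results=tuple(tied + rest), failures=failures)


def average_constants(fits: Sequence[TitrationFitResult]) -> tuple[float, float]:
    """Inverse-variance weighted mean of the primary constant across fits.

    Returns ``(K_weighted, se)`` with the propagated standard error
    ``se = sqrt(1 / sum(1/se_i^2))``.  All fits must share one model.
    """
    if not fits:
        raise DomainError("at least one fit is required")
    model_ids = {f.model.model_id for f in fits}
    if len(model_ids) != 1:
        raise DomainError(f"mixed model ids: {sorted(m.value for m in model_ids)}")
    ks = np.array([f.primary_constant for f in fits], dtype=float)
    ses = np.array([f.primary_constant_se for f in fits], dtype=float)
    if len(fits) == 1:
        return float(ks[0]), float(ses[0])
    if not np.all(np.isfinite(ses)) or np.any(ses <= 0):
        raise DomainError("all fits need finite positive standard errors")
    w = 1.0 / ses**2
    return float(np.sum(w * ks) / np.sum(w)), float(math.sqrt(1.0 / np.sum(w)))
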