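"""Seeded synthetic titration, melt-curve, and CD-spectrum generators.

These generators emulate the experimental designs the analysis modules
expect: a fixed 125 uM observed species titrated over an equivalents grid
(0-2 in 12 steps by default), and ellipticity sampled every 0.2 degC from
5 to 95 degC.  Noise is i.i.d. Gaussian on the observed quantity.  One
global integer seed fans out to per-series substreams keyed by a stable
hash of the sample label, so adding a series never perturbs the noise of
another.

The default true association constants are synthetic, order-of-magnitude
plausible values (1e3-1e5 M^-1); the melt-curve study bundle uses a
seven-sequence by three-condition design matrix of true melting
temperatures spanning stabilizing and destabilizing conditions.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .equilibria import BindingModelSpec, statistical_from_micro
from .exceptions import DomainError
from .melt_analysis import CdSpectrum, MeltCurve
from .nmr_titration import NucleusTrace, ShiftParameters, TitrationSeries, predict_shifts

__all__ = [
    "NucleusTruth",
    "TitrationDesign",
    "MeltDesign",
    "gen_titration",
    "gen_melt",
    "gen_cd_spectrum",
    "gen_study_bundle",
    "t_half_for_tm",
]


def _rng(seed: int, label: str) -> np.random.Generator:
    """Substream keyed by a stable hash of the label; independent of order."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


# ---------------------------------------------------------------------------
# titrations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleusTruth:
    """True limiting shifts of one nucleus: delta_free and the full-binding
    excursion delta_delta (bound minus free, ppm)."""

    nucleus_id: str = "Phe_aromatic_H"
    delta_free: float = 7.300
    delta_delta: float = -0.120


@dataclass(frozen=True)
class TitrationDesign:
    fixed_species_total: float = 125e-6  # mol/L
    equivalents_grid: tuple[float, ...] = tuple(np.linspace(0.0, 2.0, 12))
    n_replicates: int = 2
    nuclei: tuple[NucleusTruth, ...] = (NucleusTruth(),)
    true_model: BindingModelSpec = field(default_factory=lambda: statistical_from_micro(5e3))
    noise_sd: float = 0.002  # ppm
    seed: int = 0
    sample_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        grid = tuple(float(e) for e in self.equivalents_grid)
        if not grid or grid[0] != 0.0:
            raise DomainError("equivalents_grid must start at 0")
        object.__setattr__(self, "equivalents_grid", grid)
        object.__setattr__(self, "nuclei", tuple(self.nuclei))


def gen_titration(design: TitrationDesign) -> tuple[list[TitrationSeries], dict]:
    """Noisy fast-exchange titration replicates plus the generating truth.

    Each replicate's shifts are ``predict_shifts(truth) + N(0, noise_sd)``;
    with ``noise_sd = 0`` the output equals the truth exactly.  Deterministic
    for a fixed seed.
    """
    shifts = {
        nuc.nucleus_id: ShiftParameters(
            nuc.delta_free, nuc.delta_free + nuc.delta_delta, nuc.delta_free + nuc.delta_delta
        )
        for nuc in design.nuclei
    }
    eq = np.asarray(design.equivalents_grid)
    template = TitrationSeries(
        fixed_species_total=design.fixed_species_total,
        equivalents=eq,
        nuclei=tuple(
            NucleusTrace(n.nucleus_id, np.zeros(eq.size)) for n in design.nuclei
        ),
        sample_id=design.sample_id,
    )
    clean = predict_shifts(design.true_model, shifts, template)

    series: list[TitrationSeries] = []
    for rep in range(design.n_replicates):
        rep_id = f"rep{rep + 1}"
        rng = _rng(design.seed, f"titration/{design.sample_id}/{rep_id}")
        traces = tuple(
            NucleusTrace(
                nuc.nucleus_id,
                clean[nuc.nucleus_id] + rng.normal(0.0, design.noise_sd, eq.size)
                if design.noise_sd > 0
                else clean[nuc.nucleus_id].copy(),
            )
            for nuc in design.nuclei
        )
        series.append(replace(template, nuclei=traces, replicate_id=rep_id))

    truth = {
        "model_id": design.true_model.model_id.value,
        "K1": design.true_model.K1,
        "K2": design.true_model.K2,
        "nuclei": {
            n.nucleus_id: {"delta_free": n.delta_free, "delta_delta": n.delta_delta}
            for n in design.nuclei
        },
        "noise_sd": design.noise_sd,
    }
    return series, truth


# ---------------------------------------------------------------------------
# melt curves
# ---------------------------------------------------------------------------

def t_half_for_tm(tm: float, width: float, s: float) -> float:
    """Position parameter giving a half-denaturation temperature of ``tm``.

    The half-signal point of the asymmetric logistic sits at
    z = ln(2^(1/s) - 1) reduced widths from T_half; for s = 1, z = 0 and
    T_half = Tm.
    """
    return tm - width * math.log(2.0 ** (1.0 / s) - 1.0)


@dataclass(frozen=True)
class MeltDesign:
    T_start: float = 5.0
    T_end: float = 95.0
    step: float = 0.2
    Tm: float = 40.0
    width: float = 3.0
    s: float = 1.5
    A_folded: float = 10.0  # mdeg, low-temperature plateau
    A_unfolded: float = 0.0
    noise_sd: float = 0.2  # mdeg
    seed: int = 0
    sample_id: str = "synthetic"
    condition_label: str = "control"
    monitor_wavelength: float = 260.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise DomainError("step must be > 0")
        if not (self.T_start <= self.Tm <= self.T_end):
            raise DomainError("Tm must lie within [T_start, T_end]")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if self.width <= 0 or self.s <= 0:
            raise DomainError("width and s must be > 0")


def _melt_truth(design: MeltDesign, t: np.ndarray) -> np.ndarray:
    t_half = t_half_for_tm(design.Tm, design.width, design.s)
    z = (t - t_half) / design.width
    return design.A_unfolded + (design.A_folded - design.A_unfolded) * np.exp(
        -design.s * np.logaddexp(0.0, z)
    )


def gen_melt(design: MeltDesign) -> MeltCurve:
    """One noisy melt curve on the design's temperature grid (451 points at
    the 5-95 degC / 0.2 degC defaults)."""
    n = int(round((design.T_end - design.T_start) / design.step)) + 1
    t = np.linspace(design.T_start, design.T_end, n)
    y = _melt_truth(design, t)
    if design.noise_sd > 0:
        rng = _rng(design.seed, f"melt/{design.sample_id}/{design.condition_label}")
        y = y + rng.normal(0.0, design.noise_sd, n)
    return MeltCurve(
        temperatures=t,
        ellipticity=y,
        monitor_wavelength=design.monitor_wavelength,
        sample_id=design.sample_id,
        condition_label=design.condition_label,
    )


def gen_cd_spectrum(
    topology: str,
    sample_id: str = "synthetic",
    amplitude: float = 8.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CdSpectrum:
    """Four-band template spectrum for a parallel or antiparallel G4.

    Gaussian bands at the canonical wavelengths only; real CD band shapes
    are not modelled beyond this topology template.
    """
    wl = np.arange(220.0, 321.0, 1.0)
    if topology == "parallel":
        bands = [(262.0, amplitude, 9.0), (245.0, -0.75 * amplitude, 7.0)]
    elif topology == "antiparallel":
        bands = [(295.0, amplitude, 9.0), (232.0, -0.75 * amplitude, 7.0)]
    else:
        raise DomainError(f"unknown topology {topology!r}")
    y = np.zeros_like(wl)
    for center, amp, sd in bands:
        y = y + amp * np.exp(-0.5 * ((wl - center) / sd) ** 2)
    if noise_sd > 0:
        rng = _rng(seed, f"spectrum/{sample_id}")
        y = y + rng.normal(0.0, noise_sd, wl.size)
    return CdSpectrum(wavelengths=wl, ellipticity=y, sample_id=sample_id)


# ---------------------------------------------------------------------------
# study bundle
# ---------------------------------------------------------------------------

# Titration conditions: nucleic-acid identity x folding state, with synthetic
# constants (the generating truths, not fitted literature values).
_TITRATION_CONDITIONS: dict[str, float] = {
    "RNA_folded": 2.0e4,
    "RNA_unfolded": 5.0e3,
    "DNA_folded": 2.0e3,
    "DNA_unfolded": 1.0e3,
}

# Melt design matrix: seven loop-variant sequences x three conditions.  The
# true Tm values (degC) reuse the printed control/peptide/K+ melting
# temperatures of the loop-mutation stabilization study, so the generated
# bundle reproduces its stabilization/destabilization sign structure.
_MELT_TM_TRUTH: dict[str, dict[str, float]] = {
    "GGGUUA_TERRA": {"control": 24.7, "peptide_16x": 34.0, "KCl_16x": 46.3},
    "G3U3": {"control": 31.3, "peptide_16x": 35.4, "KCl_16x": 45.3},
    "G3U2": {"control": 36.0, "peptide_16x": 40.9, "KCl_16x": 54.4},
    "G3U1": {"control": 50.9, "peptide_16x": 52.5, "KCl_16x": 61.8},
    "G3A3": {"control": 43.9, "peptide_16x": 41.5, "KCl_16x": 58.7},
    "G3A2": {"control": 42.7, "peptide_16x": 36.9, "KCl_16x": 45.3},
    "G3A1": {"control": 52.7, "peptide_16x": 52.5, "KCl_16x": 59.6},
}

MELT_CONDITIONS = ("control", "peptide_16x", "KCl_16x")


def gen_study_bundle(seed: int, out_dir: str | Path) -> dict:
    """Write a full synthetic study (titrations + melts + manifest) to disk.

    Produces ``titrations.csv`` and ``melts.csv`` in the documented CSV
    dialects plus ``manifest.json`` with every generating truth.  Byte
    deterministic for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    titration_rows = []
    manifest: dict = {"seed": int(seed), "titrations": {}, "melts": {}}
    for sample_id, k_micro in _TITRATION_CONDITIONS.items():
        design = TitrationDesign(
            true_model=statistical_from_micro(k_micro), seed=seed, sample_id=sample_id
        )
        series_list, truth = gen_titration(design)
        manifest["titrations"][sample_id] = {
            "k_micro": k_micro,
            "fixed_species_total_M": design.fixed_species_total,
            **truth,
        }
        for series in series_list:
            for trace in series.nuclei:
                for i in range(series.n_points):
                    titration_rows.append(
                        {
                            "sample_id": sample_id,
                            "replicate_id": series.replicate_id,
                            "equivalents": series.equivalents[i],
                            "titrant_total_M": series.titrant_total[i],
                            "nucleus_id": trace.nucleus_id,
                            "delta_ppm": trace.delta_obs[i],
                            "fixed_species_total_M": series.fixed_species_total,
                        }
                    )
    pd.DataFrame(titration_rows).to_csv(out / "titrations.csv", index=False)

    melt_rows = []
    for seq, conditions in _MELT_TM_TRUTH.items():
        for cond, tm in conditions.items():
            design = MeltDesign(Tm=tm, seed=seed, sample_id=seq, condition_label=cond)
            curve = gen_melt(design)
            manifest["melts"][f"{seq}:{cond}"] = {
                "Tm": tm,
                "width": design.width,
                "s": design.s,
                "A_folded": design.A_folded,
                "A_unfolded": design.A_unfolded,
                "noise_sd": design.noise_sd,
            }
            melt_rows.append(
                pd.DataFrame(
                    {
                        "sample_id": seq,
                        "condition_label": cond,
                        "temperature_C": curve.temperatures,
                        "ellipticity_mdeg": curve.ellipticity,
                        "wavelength_nm": curve.monitor_wavelength,
                    }
                )
            )
    pd.concat(melt_rows, ignore_index=True).to_csv(out / "melts.csv", index=False)

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
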