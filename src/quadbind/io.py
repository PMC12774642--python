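"""CSV readers and writers for titration series, melt curves, and spectra.

Dialects (UTF-8, comma-separated, decimal point, header required):

* titration CSV — sample_id, replicate_id, equivalents, titrant_total_M
  (optional), nucleus_id, delta_ppm, fixed_species_total_M (optional if the
  fixed concentration is passed explicitly to the reader)
* melt CSV — sample_id, condition_label, temperature_C, ellipticity_mdeg,
  wavelength_nm
* spectrum CSV — sample_id, wavelength_nm, ellipticity_mdeg
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .melt_analysis import CdSpectrum, MeltCurve, StabilizationTable
from .nmr_titration import NucleusTrace, TitrationSeries

__all__ = [
    "read_titration_csv",
    "read_melt_csv",
    "read_spectrum_csv",
    "write_stabilization_csv",
]

_TITRATION_REQUIRED = ["sample_id", "replicate_id", "equivalents", "nucleus_id", "delta_ppm"]
_MELT_REQUIRED = ["sample_id", "condition_label", "temperature_C", "ellipticity_mdeg", "wavelength_nm"]
_SPECTRUM_REQUIRED = ["sample_id", "wavelength_nm", "ellipticity_mdeg"]


def _load(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: no data rows") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def _numeric(df: pd.DataFrame, path: Path, columns: list[str]) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: one for the header line, one for zero-based indexing
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}"
            )
        if coerced.isna().any():
            line = int(df.index[coerced.isna()][0]) + 2
            raise SchemaError(f"{path}: empty value in column {col!r} at line {line}")
        df[col] = coerced
    return df


def read_titration_csv(
    path: str | Path, fixed_species_total: float | None = None
) -> list[TitrationSeries]:
    """Parse a titration CSV into one series per (sample_id, replicate_id).

    The fixed-species concentration comes from the ``fixed_species_total_M``
    column when present, otherwise from the ``fixed_species_total`` argument.
    """
    path = Path(path)
    df = _load(path, _TITRATION_REQUIRED)
    numeric_cols = ["equivalents", "delta_ppm"]
    if "titrant_total_M" in df.columns:
        numeric_cols.append("titrant_total_M")
    if "fixed_species_total_M" in df.columns:
        numeric_cols.append("fixed_species_total_M")
    df = _numeric(df, path, numeric_cols)

    series: list[TitrationSeries] = []
    for (sample_id, replicate_id), group in df.groupby(
        ["sample_id", "replicate_id"], sort=True
    ):
        if "fixed_species_total_M" in group.columns:
            totals = group["fixed_species_total_M"].unique()
            if len(totals) != 1:
                raise SchemaError(
                    f"{path}: inconsistent fixed_species_total_M within "
                    f"{sample_id}/{replicate_id}"
                )
            fixed = float(totals[0])
        elif fixed_species_total is not None:
            fixed = float(fixed_species_total)
        else:
            raise SchemaError(
                f"{path}: no fixed_species_total_M column and no explicit "
                "fixed_species_total given"
            )

        nuclei = []
        equivalents = None
        titrant = None
        for nucleus_id, sub in group.groupby("nucleus_id", sort=True):
            sub = sub.sort_values("equivalents")
            eq = sub["equivalents"].to_numpy()
            if equivalents is None:
                equivalents = eq
                if "titrant_total_M" in sub.columns:
                    titrant = sub["titrant_total_M"].to_numpy()
            elif eq.shape != equivalents.shape or not np.allclose(eq, equivalents):
                raise SchemaError(
                    f"{path}: nucleus {nucleus_id!r} of {sample_id}/{replicate_id} "
                    "does not share the common equivalents grid"
                )
            nuclei.append(NucleusTrace(str(nucleus_id), sub["delta_ppm"].to_numpy()))
        series.append(
            TitrationSeries(
                fixed_species_total=fixed,
                equivalents=equivalents,
                nuclei=tuple(nuclei),
                titrant_total=titrant,
                sample_id=str(sample_id),
                replicate_id=str(replicate_id),
            )
        )
    return series


def read_melt_csv(path: str | Path) -> list[MeltCurve]:
    """Parse a melt CSV into one curve per (sample_id, condition_label)."""
    path = Path(path)
    df = _load(path, _MELT_REQUIRED)
    df = _numeric(df, path, ["temperature_C", "ellipticity_mdeg", "wavelength_nm"])
    dup = df.duplicated(subset=["sample_id", "condition_label", "temperature_C"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise SchemaError(
            f"{path}: duplicate (sample, condition, temperature) row at line {line}"
        )
    curves = []
    for (sample_id, condition), group in df.groupby(
        ["sample_id", "condition_label"], sort=True
    ):
        group = group.sort_values("temperature_C")
        curves.append(
            MeltCurve(
                temperatures=group["temperature_C"].to_numpy(),
                ellipticity=group["ellipticity_mdeg"].to_numpy(),
                monitor_wavelength=float(group["wavelength_nm"].iloc[0]),
                sample_id=str(sample_id),
                condition_label=str(condition),
            )
        )
    return curves


def read_spectrum_csv(path: str | Path) -> list[CdSpectrum]:
    """Parse a CD spectrum CSV into one spectrum per sample_id."""
    path = Path(path)
    df = _load(path, _SPECTRUM_REQUIRED)
    df = _numeric(df, path, ["wavelength_nm", "ellipticity_mdeg"])
    spectra = []
    for sample_id, group in df.groupby("sample_id", sort=True):
        group = group.sort_values("wavelength_nm")
        spectra.append(
            CdSpectrum(
                wavelengths=group["wavelength_nm"].to_numpy(),
                ellipticity=group["ellipticity_mdeg"].to_numpy(),
                sample_id=str(sample_id),
            )
        )
    return spectra


def write_stabilization_csv(table: StabilizationTable, path: str | Path) -> None:
    """Serialize a stabilization table with 0.1 degC display rounding."""
    table.to_frame(display_rounding=True).to_csv(path, index=False)
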