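"""Spectrum comparison, parameter scans and pseudo-experimental fixtures.

The parameterization workflow is a grid scan: simulate the forward model
at each candidate parameter value, compare against a reference reflectance
spectrum with R^2 and RMSE, and pick the best-scoring value.  R^2 is
defined as 1 - SS_res/SS_tot (about the reference mean), not the squared
Pearson correlation, so a biased but well-shaped spectrum is penalized;
users who want the correlation form can square
``numpy.corrcoef`` themselves.

Because measured spectra are instrument output, a seed-reproducible
pseudo-experimental generator (forward model plus additive Gaussian noise)
stands in for them in tests and examples.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import LeafParams, SpecificAbsorptionSpectra, Spectrum, simulate_spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "FitMetrics",
    "compare_spectra",
    "scan",
    "make_pseudo_experimental",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "load_params",
]

SCANNABLE = {
    "s_Sp", "s_P", "F_S", "h_um", "l_um", "n_I", "f",
    "C_ChA", "C_ChB", "C_Car", "N_SpP", "beta_O1_deg", "N",
}


@dataclass(frozen=True)
class FitMetrics:
    """Coefficient of determination and RMSE between two reflectance
    spectra on a common wavelength grid (reflectance as fractions)."""

    R2: float
    RMSE: float

    def __post_init__(self) -> None:
        if self.RMSE < 0:
            raise ValueError("RMSE must be nonnegative")
        if self.R2 > 1 + 1e-12:
            raise ValueError("R2 cannot exceed 1")


def compare_spectra(model: Spectrum, reference: Spectrum) -> FitMetrics:
    """R^2 and RMSE of the model against a reference reflectance spectrum.

    The reference is linearly interpolated onto the model grid; only the
    overlapping wavelength range is compared (at least 3 points).
    """
    wl = model.wavelength_nm
    lo = max(wl[0], reference.wavelength_nm[0])
    hi = min(wl[-1], reference.wavelength_nm[-1])
    mask = (wl >= lo) & (wl <= hi)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 overlapping wavelength points")
    ref = np.interp(wl[mask], reference.wavelength_nm, reference.reflectance)
    mod = model.reflectance[mask]
    resid = mod - ref
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return FitMetrics(R2=r2, RMSE=float(np.sqrt(np.mean(resid**2))))


def scan(
    grid: dict[str, list],
    base: LeafParams,
    reference: Spectrum,
    spectra: SpecificAbsorptionSpectra | None = None,
) -> pd.DataFrame:
    """Grid scan of model parameters against a reference spectrum.

    ``grid`` maps parameter names (fields of :class:`LeafParams`, e.g.
    ``s_Sp``, ``F_S``, ``h_um``) to candidate values; the Cartesian
    product is simulated.  Returns one row per grid point with the
    parameter values, R2 and RMSE, sorted by R2 descending (ties broken
    by parameter values, so the table is deterministic).
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("scan grid must be nonempty")
    unknown = set(grid) - SCANNABLE
    if unknown:
        raise ValueError(f"unknown scan parameters: {sorted(unknown)}")
    names = list(grid)
    rows = []
    for combo in itertools.product(*(grid[n] for n in names)):
        params = base.replace(**dict(zip(names, combo)))
        m = compare_spectra(simulate_spectrum(params, spectra=spectra), reference)
        rows.append(dict(zip(names, combo)) | {"R2": m.R2, "RMSE": m.RMSE})
    df = pd.DataFrame(rows)
    return df.sort_values(
        by=["R2"] + names, ascending=[False] + [True] * len(names), kind="mergesort"
    ).reset_index(drop=True)


def make_pseudo_experimental(
    params: LeafParams,
    noise_sd: float = 0.005,
    seed: int | None = None,
    spectra: SpecificAbsorptionSpectra | None = None,
) -> Spectrum:
    """Forward spectrum plus i.i.d. Gaussian reflectance noise, clipped at 0.

    ``noise_sd`` is in reflectance-fraction units (0.005 mimics a quiet
    field spectrometer).  Seed-reproducible via numpy's Generator.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    clean = simulate_spectrum(params, spectra=spectra)
    rng = np.random.default_rng(seed)
    noisy = np.clip(
        clean.reflectance + rng.normal(0.0, noise_sd, clean.reflectance.shape),
        0.0,
        None,
    )
    return Spectrum(
        wavelength_nm=clean.wavelength_nm,
        reflectance=noisy,
        transmittance=clean.transmittance,
    )


def write_spectrum_csv(spec: Spectrum, path: str | Path) -> None:
    """Write a spectrum as CSV (wavelength_nm, reflectance [, transmittance])."""
    data = {"wavelength_nm": spec.wavelength_nm, "reflectance": spec.reflectance}
    if spec.transmittance is not None:
        data["transmittance"] = spec.transmittance
    pd.DataFrame(data).to_csv(path, index=False)


def read_spectrum_csv(path: str | Path) -> Spectrum:
    """Read a reflectance spectrum CSV.

    Requires a ``wavelength_nm`` column and a reflectance column; a column
    named ``reflectance_percent`` (or values evidently on a 0-100 scale
    under ``reflectance``) is converted to fractions with a logged notice.
    """
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise ValueError(f"{path}: missing wavelength_nm column")
    if "reflectance" in df.columns:
        r = df["reflectance"].to_numpy(float)
        if np.nanmax(r) > 1.5:
            logger.info("%s: reflectance looks like percent; dividing by 100", path)
            r = r / 100.0
    elif "reflectance_percent" in df.columns:
        logger.info("%s: reading percent reflectance", path)
        r = df["reflectance_percent"].to_numpy(float) / 100.0
    else:
        raise ValueError(f"{path}: missing reflectance column")
    t = df["transmittance"].to_numpy(float) if "transmittance" in df.columns else None
    return Spectrum(
        wavelength_nm=df["wavelength_nm"].to_numpy(float),
        reflectance=r,
        transmittance=t,
    )


def load_params(path: str | Path) -> LeafParams:
    """Load a :class:`LeafParams` from a YAML mapping of field names."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    valid = set(LeafParams.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return LeafParams(**data)
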