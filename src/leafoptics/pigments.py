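"""Wavelength-dependent absorption coefficients from pigment content.

The palisade absorption spectrum is a linear combination of the specific
absorption spectra of chlorophyll a, chlorophyll b and carotenoids weighted
by their palisade concentrations; the spongy layer carries the fraction
``N_Sp/P`` (default 0.2) of the palisade pigment concentration and hence of
its absorption.  Leaf-average concentrations (what a bulk extraction
measures) follow from thickness-weighting the two layers.

Specific absorption spectra are data, not code.  The package ships a
synthetic Gaussian-peak fixture (:func:`fixture_spectra`) with absorption
maxima at the canonical in-vivo band positions; users supply measured
spectra as CSV (columns ``wavelength_nm, a_chla_cm2_per_mg,
a_chlb_cm2_per_mg, a_car_cm2_per_mg``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PigmentSet",
    "SpecificAbsorptionSpectra",
    "palisade_absorption",
    "spongy_absorption",
    "average_concentration",
    "layer_concentration",
    "fixture_spectra",
]

CSV_COLUMNS = (
    "wavelength_nm",
    "a_chla_cm2_per_mg",
    "a_chlb_cm2_per_mg",
    "a_car_cm2_per_mg",
)


@dataclass(frozen=True)
class PigmentSet:
    """Palisade-layer pigment concentrations (mg cm^-3) and the
    spongy/palisade concentration ratio ``N_SpP``."""

    C_ChA: float = 3.19
    C_ChB: float = 2.09
    C_Car: float = 0.94
    N_SpP: float = 0.2

    def __post_init__(self) -> None:
        for name in ("C_ChA", "C_ChB", "C_Car"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0.0 <= self.N_SpP <= 1.0):
            raise ValueError(f"N_SpP={self.N_SpP} outside [0, 1]")


@dataclass(frozen=True)
class SpecificAbsorptionSpectra:
    """Specific absorption coefficient spectra (cm^2 mg^-1) of the three
    pigment pools on a common, strictly increasing wavelength grid (nm).

    ``provenance`` records where the curves came from (synthetic fixture
    vs a user-supplied file)."""

    wavelength_nm: np.ndarray
    a_ChA: np.ndarray
    a_ChB: np.ndarray
    a_Car: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be 1-D and strictly increasing")
        for name in ("a_ChA", "a_ChB", "a_Car"):
            a = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, a)
            if a.shape != wl.shape:
                raise ValueError(f"{name} shape {a.shape} != grid shape {wl.shape}")
            if np.any(a < 0):
                raise ValueError(f"{name} must be nonnegative")
        if not self.provenance:
            raise ValueError("provenance string required")

    def interp_to(self, grid_nm: np.ndarray) -> "SpecificAbsorptionSpectra":
        """Linearly interpolate all three spectra onto ``grid_nm``.

        Wavelengths outside the stored range get zero absorption (with a
        logged warning): beyond the tabulated window the pigments are
        treated as transparent rather than extrapolated.
        """
        grid = np.asarray(grid_nm, dtype=float)
        if np.any(grid < self.wavelength_nm[0]) or np.any(grid > self.wavelength_nm[-1]):
            logger.warning(
                "wavelengths outside [%g, %g] nm assigned zero absorption",
                self.wavelength_nm[0],
                self.wavelength_nm[-1],
            )
        out = {}
        for name in ("a_ChA", "a_ChB", "a_Car"):
            out[name] = np.interp(
                grid, self.wavelength_nm, getattr(self, name), left=0.0, right=0.0
            )
        return SpecificAbsorptionSpectra(
            wavelength_nm=grid, provenance=self.provenance, **out
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "wavelength_nm": self.wavelength_nm,
                "a_chla_cm2_per_mg": self.a_ChA,
                "a_chlb_cm2_per_mg": self.a_ChB,
                "a_car_cm2_per_mg": self.a_Car,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpecificAbsorptionSpectra":
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"pigment CSV {path} missing columns {missing}")
        return cls(
            wavelength_nm=df["wavelength_nm"].to_numpy(float),
            a_ChA=df["a_chla_cm2_per_mg"].to_numpy(float),
            a_ChB=df["a_chlb_cm2_per_mg"].to_numpy(float),
            a_Car=df["a_car_cm2_per_mg"].to_numpy(float),
            provenance=f"file:{path}",
        )


def palisade_absorption(p: PigmentSet, s: SpecificAbsorptionSpectra) -> np.ndarray:
    """Palisade absorption spectrum a_P(lambda) in cm^-1.

    Pointwise ``C_ChA a_ChA + C_ChB a_ChB + C_Car a_Car`` on the grid of
    ``s`` (mg cm^-3 times cm^2 mg^-1 gives cm^-1).
    """
    return p.C_ChA * s.a_ChA + p.C_ChB * s.a_ChB + p.C_Car * s.a_Car


def spongy_absorption(a_P: np.ndarray, N_SpP: float = 0.2) -> np.ndarray:
    """Spongy absorption spectrum ``a_Sp = N_SpP * a_P`` (pointwise)."""
    if N_SpP < 0:
        raise ValueError("N_SpP must be nonnegative")
    return N_SpP * np.asarray(a_P, dtype=float)


def _thickness_weight(h: float, l: float, N_SpP: float) -> float:
    if h + l <= 0:
        raise ValueError("h + l must be positive")
    return h / (h + l) + N_SpP * l / (h + l)


def average_concentration(C: float, h: float, l: float, N_SpP: float = 0.2) -> float:
    """Leaf-average pigment concentration from the palisade concentration.

    ``C_av = C (h/(h+l) + N_SpP l/(h+l))``: the palisade contributes its
    full concentration over thickness h, the spongy layer the fraction
    ``N_SpP`` over thickness l.  Any consistent length unit works for h
    and l (only the ratio enters).
    """
    return C * _thickness_weight(h, l, N_SpP)


def layer_concentration(C_av: float, h: float, l: float, N_SpP: float = 0.2) -> float:
    """Inverse of :func:`average_concentration`."""
    return C_av / _thickness_weight(h, l, N_SpP)


# (center nm, sigma nm, amplitude cm^2 mg^-1) per pigment: the two canonical
# in-vivo absorption bands plus a weak broad term standing in for the
# non-Gaussian green-window tail of the real curves
_GAUSS_COMPONENTS = {
    "a_ChA": ((430.0, 30.0, 92.0), (662.0, 24.0, 82.0), (500.0, 85.0, 10.0)),
    "a_ChB": ((460.0, 28.0, 105.0), (644.0, 22.0, 45.0), (520.0, 80.0, 8.0)),
    "a_Car": ((450.0, 30.0, 80.0), (480.0, 28.0, 70.0)),
}
# smooth roll-off so all pigment absorption ends by 720 nm (NIR transparent)
_CUT_START, _CUT_END = 690.0, 720.0


def fixture_spectra(
    kind: str = "gaussian_default",
    path: str | Path | None = None,
    wavelength_nm: np.ndarray | None = None,
) -> SpecificAbsorptionSpectra:
    """Specific absorption spectra: synthetic fixture or user CSV.

    ``kind='gaussian_default'`` builds sums of Gaussian bands with maxima
    near 430/662 nm (chl a), 460/644 nm (chl b) and 450/480 nm
    (carotenoids), smoothly rolled off to exactly zero above 720 nm so the
    NIR is pigment-transparent.  ``kind='file'`` loads ``path``.
    """
    if kind == "file":
        if path is None:
            raise ValueError("kind='file' requires a path")
        return SpecificAbsorptionSpectra.from_csv(path)
    if kind != "gaussian_default":
        raise ValueError(f"unknown kind {kind!r}")
    wl = (
        np.arange(400.0, 801.0, 1.0)
        if wavelength_nm is None
        else np.asarray(wavelength_nm, dtype=float)
    )
    rolloff = np.clip((_CUT_END - wl) / (_CUT_END - _CUT_START), 0.0, 1.0)
    rolloff = 0.5 - 0.5 * np.cos(np.pi * rolloff)  # smooth 1 -> 0 ramp
    curves = {}
    for name, comps in _GAUSS_COMPONENTS.items():
        a = np.zeros_like(wl)
        for center, sigma, amp in comps:
            a += amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
        curves[name] = a * rolloff
    return SpecificAbsorptionSpectra(
        wavelength_nm=wl,
        provenance="synthetic:gaussian_default",
        **curves,
    )
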