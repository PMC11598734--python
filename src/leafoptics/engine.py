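"""Iterative four-flux radiative transfer through the whole leaf.

One iteration carries light surface -> palisade -> spongy -> surfaces:
incident light is partitioned at the surfaces (first iteration only),
the forward flows are attenuated through the palisade and drive the
analytic Kubelka-Munk solution in the spongy layer, the backward flows
return through the palisade (gaining the backward-scattered term), and
both faces partition the arriving internal light into exiting and
internally reflected parts.  The internally reflected fluxes seed the next
iteration with the forward/backward beam angles exchanged.  Reflectance
and transmittance are the accumulated exit totals over N iterations
divided by the incident intensity.

Everything is vectorized over wavelength: the per-wavelength absorption
coefficients enter as arrays and a whole spectrum costs one pass of numpy
arithmetic per iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Any

import numpy as np

from .palisade import FluxState, PalisadeParams, js_add, palisade_backward, palisade_forward
from .pigments import (
    PigmentSet,
    SpecificAbsorptionSpectra,
    fixture_spectra,
    palisade_absorption,
    spongy_absorption,
)
from .spongy import A_SP_FLOOR, SpongyParams, build_km_matrix, km_evaluate, km_solve
from .surface import (
    OpticalGeometry,
    SurfaceTransmittances,
    exit_totals,
    surface_in,
    surface_out,
)

__all__ = [
    "IlluminationConfig",
    "IterationRecord",
    "IterationLedger",
    "Spectrum",
    "LeafParams",
    "run_iteration",
    "simulate_monochromatic",
    "simulate_spectrum",
]

UM_PER_CM = 1e4


def um_to_cm(value_um: float) -> float:
    return value_um / UM_PER_CM


@dataclass(frozen=True)
class IlluminationConfig:
    """Incident light: adaxial/abaxial intensities (umol m^-2 s^-1) and
    external incidence angles (radians)."""

    I_0: float = 1000.0
    J_0: float = 0.0
    beta_O1: float = math.radians(35.0)
    beta_O2: float = math.radians(35.0)

    def __post_init__(self) -> None:
        if self.I_0 < 0 or self.J_0 < 0:
            raise ValueError("incident intensities must be nonnegative")


@dataclass(frozen=True)
class IterationRecord:
    """Exit totals and carried-over internal fluxes of one iteration."""

    i: int
    J_out_i: float | np.ndarray
    I_out_i: float | np.ndarray
    I_C_RI: float | np.ndarray
    I_S_RI: float | np.ndarray
    J_C_RI: float | np.ndarray
    J_S_RI: float | np.ndarray
    beta_I1: float
    beta_I2: float


@dataclass
class IterationLedger:
    """Per-iteration exit totals and their running sums."""

    records: list[IterationRecord] = field(default_factory=list)

    @property
    def N(self) -> int:
        return len(self.records)

    @property
    def J_out(self):
        return sum(r.J_out_i for r in self.records)

    @property
    def I_out(self):
        return sum(r.I_out_i for r in self.records)


@dataclass(frozen=True)
class Spectrum:
    """Wavelength grid (nm) with reflectance / transmittance fractions.

    ``absorptance`` is ``1 - R - T``; the model is not exactly
    flux-conserving (the palisade backward-scattered gain is never debited
    from the forward flows), so R + T may exceed 1 by up to ~s_P*h.
    """

    wavelength_nm: np.ndarray
    reflectance: np.ndarray
    transmittance: np.ndarray | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        r = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "reflectance", r)
        if r.shape != wl.shape:
            raise ValueError("reflectance shape mismatch")
        if np.any(r < 0):
            raise ValueError("reflectance must be nonnegative")
        if self.transmittance is not None:
            t = np.asarray(self.transmittance, dtype=float)
            object.__setattr__(self, "transmittance", t)
            if t.shape != wl.shape:
                raise ValueError("transmittance shape mismatch")
            if np.any(t < 0):
                raise ValueError("transmittance must be nonnegative")

    @property
    def absorptance(self) -> np.ndarray:
        if self.transmittance is None:
            raise ValueError("absorptance needs transmittance")
        return 1.0 - self.reflectance - self.transmittance

    def band_mean(self, lo_nm: float, hi_nm: float) -> float:
        """Mean reflectance over a wavelength band (inclusive)."""
        m = (self.wavelength_nm >= lo_nm) & (self.wavelength_nm <= hi_nm)
        if not m.any():
            raise ValueError(f"no grid points in [{lo_nm}, {hi_nm}] nm")
        return float(self.reflectance[m].mean())


@dataclass(frozen=True)
class LeafParams:
    """Full parameter set of the leaf model, in user-facing units.

    Angles in degrees and thicknesses in um here; the engine converts to
    radians and cm internally.  Defaults are the parameterized set for a
    mature pea leaf: beam at 35 degrees, interior refractive index 1.415,
    15% rough surface, palisade 35.5 um with weak scattering (5 cm^-1),
    spongy 58.6 um with strong scattering (600 cm^-1), isotropic
    redistribution (f = 0.5), palisade pigment concentrations
    3.19/2.09/0.94 mg cm^-3 (chl a / chl b / carotenoids) with the spongy
    layer at 20% of those, and 6 internal-reflection iterations.
    """

    n_O: float = 1.0
    n_I: float = 1.415
    beta_O1_deg: float = 35.0
    beta_O2_deg: float | None = None
    F_S: float = 0.15
    h_um: float = 35.5
    l_um: float = 58.6
    s_P: float = 5.0
    s_Sp: float = 600.0
    f: float = 0.5
    C_ChA: float = 3.19
    C_ChB: float = 2.09
    C_Car: float = 0.94
    N_SpP: float = 0.2
    I_0: float = 1000.0
    J_0: float = 0.0
    N: int = 6
    wl_min_nm: float = 400.0
    wl_max_nm: float = 800.0
    wl_step_nm: float = 1.0

    def replace(self, **updates: Any) -> "LeafParams":
        return _dc_replace(self, **updates)

    @property
    def wavelength_nm(self) -> np.ndarray:
        n = int(round((self.wl_max_nm - self.wl_min_nm) / self.wl_step_nm)) + 1
        return self.wl_min_nm + self.wl_step_nm * np.arange(n)

    @property
    def geometry(self) -> OpticalGeometry:
        return OpticalGeometry.from_external(
            beta_O1=math.radians(self.beta_O1_deg),
            beta_O2=(
                None if self.beta_O2_deg is None else math.radians(self.beta_O2_deg)
            ),
            n_O=self.n_O,
            n_I=self.n_I,
            F_S=self.F_S,
        )

    @property
    def illumination(self) -> IlluminationConfig:
        g = self.geometry
        return IlluminationConfig(
            I_0=self.I_0, J_0=self.J_0, beta_O1=g.beta_O1, beta_O2=g.beta_O2
        )

    @property
    def pigments(self) -> PigmentSet:
        return PigmentSet(
            C_ChA=self.C_ChA, C_ChB=self.C_ChB, C_Car=self.C_Car, N_SpP=self.N_SpP
        )

    def palisade(self, a_P) -> PalisadeParams:
        return PalisadeParams(h=um_to_cm(self.h_um), a_P=a_P, s_P=self.s_P, f=self.f)

    def spongy(self, a_Sp) -> SpongyParams:
        return SpongyParams(l=um_to_cm(self.l_um), a_Sp=a_Sp, s_Sp=self.s_Sp, f=self.f)


def _desingularize_a_sp(a_Sp, s_Sp: float, f: float, beta_I1: float, beta_I2: float):
    """Nudge a_Sp off the measure-zero resonance where a collimated decay
    rate coincides with a scattered-block eigenvalue (e.g. s_Sp = 3 a_Sp at
    normal incidence), which would make the particular-solution
    denominators vanish."""
    a = np.maximum(np.asarray(a_Sp, dtype=float), A_SP_FLOOR)
    if s_Sp == 0:
        return a
    for _ in range(8):
        lam3 = 2.0 * np.sqrt(a * (a + 2.0 * s_Sp * (1.0 - f)))
        bad = np.zeros(a.shape, dtype=bool)
        for c in (math.cos(beta_I1), math.cos(beta_I2)):
            lam_c = (a + s_Sp) / c
            bad |= np.abs(lam_c - lam3) < 1e-6 * (lam_c + lam3)
        if not bad.any():
            break
        a = np.where(bad, a * (1.0 + 1e-5), a)
    return a


def run_iteration(
    inputs: FluxState,
    geom: OpticalGeometry,
    palisade: PalisadeParams,
    spongy: SpongyParams,
    first: bool,
    T: SurfaceTransmittances | None = None,
):
    """One full pass of light through the leaf.

    For the first iteration ``inputs`` holds the incident intensities
    (``I_C`` = adaxial I_0, ``J_C`` = abaxial J_0) and the surface
    partition is applied; afterwards ``inputs`` are the internally
    reflected boundary fluxes used directly as I_C(0), I_S(0), J_C(h+l),
    J_S(h+l).  Returns ``(J_out_i, I_out_i, next_inputs, next_geom,
    record)`` where ``next_geom`` has the beam-angle pairs swapped.
    """
    if T is None:
        T = SurfaceTransmittances.from_geometry(geom)
    if first:
        exch_in = surface_in(inputs.I_C, inputs.J_C, geom, T)
        ic0, is0 = exch_in.I_C_0, exch_in.I_S_0
        jc_hl, js_hl = exch_in.J_C_hl, exch_in.J_S_hl
        ro = (exch_in.J_C_RO, exch_in.J_S_RO, exch_in.I_C_RO, exch_in.I_S_RO)
    else:
        ic0, is0 = inputs.I_C, inputs.I_S
        jc_hl, js_hl = inputs.J_C, inputs.J_S
        ro = (0.0, 0.0, 0.0, 0.0)

    h = palisade.h
    # forward flows down through the palisade
    ic_h, is_h = palisade_forward(ic0, is0, palisade, geom.beta_I1)
    jsadd = js_add(ic0, is0, palisade, geom.beta_I1)
    # spongy layer couples everything; backward flows emerge at x = h
    L = build_km_matrix(spongy, geom.beta_I1, geom.beta_I2)
    sol = km_solve(ic_h, is_h, jc_hl, js_hl, spongy, L, h=h)
    top = km_evaluate(sol, h)
    bottom = km_evaluate(sol, h + spongy.l)
    # backward flows up through the palisade
    jc0, js0 = palisade_backward(top.J_C, top.J_S, palisade, geom.beta_I2, jsadd)

    exch_out = surface_out(jc0, js0, bottom.I_C, bottom.I_S, geom, T)
    exch_out.J_C_RO, exch_out.J_S_RO, exch_out.I_C_RO, exch_out.I_S_RO = ro
    j_out_i, i_out_i = exit_totals(exch_out)

    next_inputs = FluxState(
        I_C=exch_out.I_C_RI,
        I_S=exch_out.I_S_RI,
        J_C=exch_out.J_C_RI,
        J_S=exch_out.J_S_RI,
    )
    record = IterationRecord(
        i=-1,
        J_out_i=j_out_i,
        I_out_i=i_out_i,
        I_C_RI=exch_out.I_C_RI,
        I_S_RI=exch_out.I_S_RI,
        J_C_RI=exch_out.J_C_RI,
        J_S_RI=exch_out.J_S_RI,
        beta_I1=geom.beta_I1,
        beta_I2=geom.beta_I2,
    )
    return j_out_i, i_out_i, next_inputs, geom.swapped(), record


def simulate_monochromatic(
    a_P,
    a_Sp,
    params: LeafParams,
    N: int | None = None,
):
    """Reflectance and transmittance at fixed absorption coefficients.

    ``a_P``/``a_Sp`` may be scalars or per-wavelength arrays (cm^-1).
    Runs N internal-reflection iterations and returns
    ``(R, T, IterationLedger)`` with R = J_out/I_0 and T = I_out/I_0.
    """
    if N is None:
        N = params.N
    if N < 1:
        raise ValueError("N must be >= 1")
    geom = params.geometry
    a_Sp = _desingularize_a_sp(a_Sp, params.s_Sp, params.f, geom.beta_I1, geom.beta_I2)
    pal = params.palisade(np.asarray(a_P, dtype=float))
    sp = params.spongy(a_Sp)
    illum = params.illumination
    # the surface coefficients swap with the angles; precompute both parities
    T_even = SurfaceTransmittances.from_geometry(geom)
    T_odd = SurfaceTransmittances.from_geometry(geom.swapped())

    ledger = IterationLedger()
    state = FluxState(I_C=illum.I_0, J_C=illum.J_0)
    j_total: Any = 0.0
    i_total: Any = 0.0
    g = geom
    for i in range(1, N + 1):
        T = T_even if i % 2 == 1 else T_odd
        j_i, i_i, state, g, record = run_iteration(
            state, g, pal, sp, first=(i == 1), T=T
        )
        ledger.records.append(_dc_replace(record, i=i))
        j_total = j_total + j_i
        i_total = i_total + i_i
    I_0 = illum.I_0
    if I_0 <= 0:
        raise ValueError("I_0 must be positive to define R and T")
    return j_total / I_0, i_total / I_0, ledger


def simulate_spectrum(
    params: LeafParams,
    spectra: SpecificAbsorptionSpectra | None = None,
    N: int | None = None,
) -> Spectrum:
    """Forward-model a full reflectance/transmittance spectrum.

    Builds the per-wavelength absorption coefficients from the pigment
    concentrations and specific absorption spectra (the synthetic Gaussian
    fixture if none are given), interpolates them onto the model grid and
    runs the iterative engine vectorized over wavelength.
    """
    wl = params.wavelength_nm
    if spectra is None:
        spectra = fixture_spectra("gaussian_default", wavelength_nm=wl)
    elif not np.array_equal(spectra.wavelength_nm, wl):
        spectra = spectra.interp_to(wl)
    a_P = palisade_absorption(params.pigments, spectra)
    a_Sp = spongy_absorption(a_P, params.N_SpP)
    R, T, _ = simulate_monochromatic(a_P, a_Sp, params, N=N)
    return Spectrum(wavelength_nm=wl, reflectance=R, transmittance=T)
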