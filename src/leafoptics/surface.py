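"""Air-leaf boundary optics.

Refraction (Snell), collimated Fresnel transmittances, hemispherically
averaged (diffuse) transmittances, and the smooth/rough partition of light
entering and leaving the lamina.  The leaf surface is treated as a mixture
of a smooth fraction ``1 - F_S`` (specular Fresnel interface, collimated
light stays collimated) and a rough fraction ``F_S`` (light crosses with
the hemispherically averaged transmittance and emerges scattered).

All angles are radians internally; degrees are accepted only at the
config/CLI boundary.  Intensities may be scalars or numpy arrays (one
entry per wavelength); the surface coefficients themselves are
wavelength-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import integrate

__all__ = [
    "OpticalGeometry",
    "SurfaceTransmittances",
    "SurfaceExchange",
    "refract",
    "critical_angle",
    "fresnel_T_collimated",
    "transmittance_air_to_leaf",
    "transmittance_leaf_to_air",
    "hemispherical_T",
    "surface_in",
    "surface_out",
    "exit_totals",
]

HALF_PI = math.pi / 2.0
# below this incidence angle the 0/0 Fresnel ratio is replaced by its
# analytic normal-incidence limit
_NORMAL_EPS = 1e-6


def critical_angle(n_O: float = 1.0, n_I: float = 1.415) -> float:
    """Internal angle above which leaf-to-air light is totally reflected.

    ``arcsin(n_O / n_I)``; about 45 degrees for the default leaf interior
    index 1.415.
    """
    if not n_I > n_O > 0:
        raise ValueError(f"need n_I > n_O > 0, got n_O={n_O}, n_I={n_I}")
    return math.asin(n_O / n_I)


def refract(beta_O: float, n_O: float = 1.0, n_I: float = 1.415) -> float:
    """Snell refraction of an external ray into the leaf.

    Returns ``arcsin((n_O/n_I) sin(beta_O))``.  Because ``n_I > n_O`` the
    result is always below the critical angle.
    """
    if not (0.0 <= beta_O <= HALF_PI + 1e-12):
        raise ValueError(f"incidence angle {beta_O} rad outside [0, pi/2]")
    if not (n_I >= n_O > 0):
        raise ValueError(f"need n_I >= n_O > 0, got n_O={n_O}, n_I={n_I}")
    return math.asin(min(1.0, (n_O / n_I) * math.sin(min(beta_O, HALF_PI))))


def unrefract(beta_I: float, n_O: float = 1.0, n_I: float = 1.415) -> float:
    """External angle whose refraction is ``beta_I`` (inverse Snell).

    Defined only below the critical angle.
    """
    s = (n_I / n_O) * math.sin(beta_I)
    if s > 1.0 + 1e-12:
        raise ValueError(
            f"internal angle {beta_I} rad exceeds the critical angle; "
            "no external ray exists"
        )
    return math.asin(min(1.0, s))


def fresnel_T_collimated(
    beta_in: float,
    beta_out: float,
    *,
    n_in: float = 1.0,
    n_out: float = 1.415,
) -> float:
    """Unpolarized Fresnel transmittance for a collimated beam.

    ``1 - 1/2 [ (sin(b_in-b_out)/sin(b_in+b_out))^2
              + (tan(b_in-b_out)/tan(b_in+b_out))^2 ]``

    The expression is symmetric in the two angles, which is why the
    leaf-to-air coefficients equal the air-to-leaf ones below the critical
    angle.  ``n_in``/``n_out`` are used only for the normal-incidence limit
    and the total-internal-reflection check (dense-to-rare at or above the
    critical angle returns 0).
    """
    for b in (beta_in, beta_out):
        if not (0.0 <= b <= HALF_PI + 1e-12):
            raise ValueError(f"angle {b} rad outside [0, pi/2]")
    if n_in > n_out and beta_in >= math.asin(n_out / n_in) - 1e-12:
        return 0.0  # total internal reflection
    if max(beta_in, beta_out) < _NORMAL_EPS:
        r = (n_out - n_in) / (n_out + n_in)
        return 1.0 - r * r
    d = beta_in - beta_out
    s = beta_in + beta_out
    if abs(d) < 1e-15:
        return 1.0  # matched indices: no interface
    term_s = (math.sin(d) / math.sin(s)) ** 2
    # tan(s) diverges at s = pi/2 (Brewster geometry): the p-term vanishes
    term_p = 0.0 if abs(s - HALF_PI) < 1e-12 else (math.tan(d) / math.tan(s)) ** 2
    return 1.0 - 0.5 * (term_s + term_p)


def transmittance_air_to_leaf(
    beta_O: float, n_O: float = 1.0, n_I: float = 1.415
) -> float:
    """Collimated transmittance for an external ray at incidence ``beta_O``."""
    return fresnel_T_collimated(
        beta_O, refract(beta_O, n_O, n_I), n_in=n_O, n_out=n_I
    )


def transmittance_leaf_to_air(
    beta_I: float, n_O: float = 1.0, n_I: float = 1.415
) -> float:
    """Collimated transmittance for an internal ray at angle ``beta_I``.

    Zero at or above the critical angle (total internal reflection).
    """
    if beta_I >= critical_angle(n_O, n_I) - 1e-12:
        return 0.0
    return fresnel_T_collimated(
        beta_I, unrefract(beta_I, n_O, n_I), n_in=n_I, n_out=n_O
    )


@lru_cache(maxsize=32)
def hemispherical_T(
    direction: str, n_O: float = 1.0, n_I: float = 1.415
) -> float:
    """Equal-weight hemispherical average of the collimated transmittance.

    ``(2/pi) * integral_0^{pi/2} T_c(beta) d(beta)`` with equal weight in
    the angle itself (no cosine weighting).  For ``leaf_to_air`` the
    integrand is zero above the critical angle, so the integral is taken
    only up to it.  With the default indices this reproduces the diffuse
    coefficients ~0.866 (air to leaf) and ~0.469 (leaf to air).

    Results are cached per ``(direction, n_O, n_I)``.
    """
    if n_I == n_O:
        return 1.0
    if direction == "air_to_leaf":
        val, err = integrate.quad(
            lambda b: transmittance_air_to_leaf(b, n_O, n_I),
            0.0,
            HALF_PI,
            limit=200,
            epsabs=1e-10,
            epsrel=1e-10,
        )
    elif direction == "leaf_to_air":
        bc = critical_angle(n_O, n_I)
        val, err = integrate.quad(
            lambda b: transmittance_leaf_to_air(b, n_O, n_I),
            0.0,
            bc,
            limit=200,
            epsabs=1e-10,
            epsrel=1e-10,
        )
    else:
        raise ValueError(
            f"direction must be 'air_to_leaf' or 'leaf_to_air', got {direction!r}"
        )
    if err > 1e-4:
        raise RuntimeError(f"hemispherical quadrature did not converge: err={err}")
    return (2.0 / math.pi) * val


@dataclass(frozen=True)
class OpticalGeometry:
    """External/internal ray angles, refractive indices and rough fraction.

    ``beta_O1``/``beta_I1`` belong to the forward (adaxial-incident) beam,
    ``beta_O2``/``beta_I2`` to the backward beam.  Internal iterations of
    the radiative engine swap the two pairs.
    """

    n_O: float = 1.0
    n_I: float = 1.415
    beta_O1: float = 0.0
    beta_O2: float = 0.0
    beta_I1: float = 0.0
    beta_I2: float = 0.0
    F_S: float = 0.0

    def __post_init__(self) -> None:
        if not self.n_I >= self.n_O >= 1.0:
            raise ValueError(
                f"need n_I >= n_O >= 1, got n_O={self.n_O}, n_I={self.n_I}"
            )
        for name in ("beta_O1", "beta_O2", "beta_I1", "beta_I2"):
            b = getattr(self, name)
            if not (0.0 <= b <= HALF_PI + 1e-12):
                raise ValueError(f"{name}={b} rad outside [0, pi/2]")
        if not (0.0 <= self.F_S <= 1.0):
            raise ValueError(f"F_S={self.F_S} outside [0, 1]")

    @classmethod
    def from_external(
        cls,
        beta_O1: float,
        beta_O2: float | None = None,
        n_O: float = 1.0,
        n_I: float = 1.415,
        F_S: float = 0.0,
    ) -> "OpticalGeometry":
        """Build a geometry from external incidence angles via Snell's law.

        If ``beta_O2`` is omitted it defaults to ``beta_O1`` so that the
        backward internal angle is defined even when no abaxial light is
        incident.
        """
        if beta_O2 is None:
            beta_O2 = beta_O1
        return cls(
            n_O=n_O,
            n_I=n_I,
            beta_O1=beta_O1,
            beta_O2=beta_O2,
            beta_I1=refract(beta_O1, n_O, n_I),
            beta_I2=refract(beta_O2, n_O, n_I),
            F_S=F_S,
        )

    def swapped(self) -> "OpticalGeometry":
        """Geometry for the next internal-reflection iteration.

        The forward and backward angle pairs exchange roles
        (``beta_I1 <-> beta_I2`` together with their external angles).
        """
        return replace(
            self,
            beta_O1=self.beta_O2,
            beta_O2=self.beta_O1,
            beta_I1=self.beta_I2,
            beta_I2=self.beta_I1,
        )

    @property
    def critical_angle(self) -> float:
        return critical_angle(self.n_O, self.n_I)


@dataclass(frozen=True)
class SurfaceTransmittances:
    """The six surface transmittance coefficients of one geometry.

    Collimated (Fresnel, per beam angle) and hemispherically averaged
    (diffuse) values, in both crossing directions.  Below the critical
    angle the collimated coefficients are reciprocal
    (``T_Jc_IO = T_Jc_OI`` and ``T_Ic_IO = T_Ic_OI``).
    """

    T_Ic_OI: float
    T_Jc_OI: float
    T_Ic_IO: float
    T_Jc_IO: float
    T_s_OI: float
    T_s_IO: float

    def __post_init__(self) -> None:
        for name in ("T_Ic_OI", "T_Jc_OI", "T_Ic_IO", "T_Jc_IO", "T_s_OI", "T_s_IO"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError(f"{name}={v} outside [0, 1]")

    @classmethod
    def from_geometry(cls, geom: OpticalGeometry) -> "SurfaceTransmittances":
        return cls(
            T_Ic_OI=transmittance_air_to_leaf(geom.beta_O1, geom.n_O, geom.n_I),
            T_Jc_OI=transmittance_air_to_leaf(geom.beta_O2, geom.n_O, geom.n_I),
            T_Ic_IO=transmittance_leaf_to_air(geom.beta_I1, geom.n_O, geom.n_I),
            T_Jc_IO=transmittance_leaf_to_air(geom.beta_I2, geom.n_O, geom.n_I),
            T_s_OI=hemispherical_T("air_to_leaf", geom.n_O, geom.n_I),
            T_s_IO=hemispherical_T("leaf_to_air", geom.n_O, geom.n_I),
        )


@dataclass
class SurfaceExchange:
    """Partition of light at the two leaf surfaces.

    ``entering`` components feed the lamina, ``RO`` components are the
    external reflection of incident light, ``T`` components exit to air,
    and ``RI`` components are reflected back into the lamina and seed the
    next iteration.  All components share the units of the incident
    intensity and may be numpy arrays over wavelength.
    """

    # entering the lamina (from incident light)
    I_C_0: float | np.ndarray = 0.0
    I_S_0: float | np.ndarray = 0.0
    J_C_hl: float | np.ndarray = 0.0
    J_S_hl: float | np.ndarray = 0.0
    # reflected to air from incident light
    J_C_RO: float | np.ndarray = 0.0
    J_S_RO: float | np.ndarray = 0.0
    I_C_RO: float | np.ndarray = 0.0
    I_S_RO: float | np.ndarray = 0.0
    # transmitted to air from internal light
    J_C_T: float | np.ndarray = 0.0
    J_S_T: float | np.ndarray = 0.0
    I_C_T: float | np.ndarray = 0.0
    I_S_T: float | np.ndarray = 0.0
    # reflected internally
    I_C_RI: float | np.ndarray = 0.0
    I_S_RI: float | np.ndarray = 0.0
    J_C_RI: float | np.ndarray = 0.0
    J_S_RI: float | np.ndarray = 0.0


def _check_nonneg(name: str, value) -> None:
    if np.any(np.asarray(value) < 0):
        raise ValueError(f"{name} must be nonnegative")


def surface_in(
    I_0,
    J_0,
    geom: OpticalGeometry,
    T: SurfaceTransmittances | None = None,
) -> SurfaceExchange:
    """Partition incident light at both surfaces (first iteration only).

    The smooth fraction ``1-F_S`` transmits collimated light with the
    Fresnel coefficient; the rough fraction ``F_S`` transmits with the
    diffuse coefficient and converts the beam to scattered light.  The
    complementary ``1-T`` factors reflect to air, so
    ``entering + reflected_to_air`` equals the incident intensity exactly.
    """
    _check_nonneg("I_0", I_0)
    _check_nonneg("J_0", J_0)
    if T is None:
        T = SurfaceTransmittances.from_geometry(geom)
    F = geom.F_S
    return SurfaceExchange(
        I_C_0=I_0 * (1.0 - F) * T.T_Ic_OI,
        I_S_0=I_0 * F * T.T_s_OI,
        J_C_RO=I_0 * (1.0 - F) * (1.0 - T.T_Ic_OI),
        J_S_RO=I_0 * F * (1.0 - T.T_s_OI),
        J_C_hl=J_0 * (1.0 - F) * T.T_Jc_OI,
        J_S_hl=J_0 * F * T.T_s_OI,
        I_C_RO=J_0 * (1.0 - F) * (1.0 - T.T_Jc_OI),
        I_S_RO=J_0 * F * (1.0 - T.T_s_OI),
    )


def surface_out(
    J_C_0,
    J_S_0,
    I_C_hl,
    I_S_hl,
    geom: OpticalGeometry,
    T: SurfaceTransmittances | None = None,
) -> SurfaceExchange:
    """Partition internal light reaching the two surfaces.

    The backward flows ``J_C(0)``/``J_S(0)`` hit the adaxial surface; the
    forward flows ``I_C(h+l)``/``I_S(h+l)`` hit the abaxial one.  Collimated
    light on the smooth fraction exits collimated with the Fresnel
    coefficient (zero above the critical angle), on the rough fraction it
    exits as scattered light with the diffuse coefficient; scattered light
    always uses the diffuse coefficient.  ``1-T`` complements return into
    the lamina as the internally reflected fluxes.
    """
    for name, v in (
        ("J_C_0", J_C_0),
        ("J_S_0", J_S_0),
        ("I_C_hl", I_C_hl),
        ("I_S_hl", I_S_hl),
    ):
        _check_nonneg(name, v)
    if T is None:
        T = SurfaceTransmittances.from_geometry(geom)
    F = geom.F_S
    return SurfaceExchange(
        # adaxial surface: backward flows exit upward
        J_C_T=J_C_0 * (1.0 - F) * T.T_Jc_IO,
        J_S_T=J_C_0 * F * T.T_s_IO + J_S_0 * T.T_s_IO,
        I_C_RI=J_C_0 * (1.0 - F) * (1.0 - T.T_Jc_IO),
        I_S_RI=J_C_0 * F * (1.0 - T.T_s_IO) + J_S_0 * (1.0 - T.T_s_IO),
        # abaxial surface: forward flows exit downward
        I_C_T=I_C_hl * (1.0 - F) * T.T_Ic_IO,
        I_S_T=I_C_hl * F * T.T_s_IO + I_S_hl * T.T_s_IO,
        J_C_RI=I_C_hl * (1.0 - F) * (1.0 - T.T_Ic_IO),
        J_S_RI=I_C_hl * F * (1.0 - T.T_s_IO) + I_S_hl * (1.0 - T.T_s_IO),
    )


def exit_totals(exchange: SurfaceExchange):
    """Total adaxial (``J_out_i``) and abaxial (``I_out_i``) exit intensities.

    Sums the externally reflected (``RO``, nonzero only on iteration 1)
    and transmitted (``T``) components of both collimated and scattered
    light at each surface.
    """
    j_out = exchange.J_C_RO + exchange.J_C_T + exchange.J_S_RO + exchange.J_S_T
    i_out = exchange.I_C_RO + exchange.I_C_T + exchange.I_S_RO + exchange.I_S_T
    return j_out, i_out
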