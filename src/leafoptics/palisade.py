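"""Beer-Bouguer-Lambert transport through the palisade mesophyll.

The palisade layer scatters weakly (s_P ~ 5 cm^-1 against ~10^3 cm^-1 in
the spongy layer), so collimated flows are attenuated purely by absorption
along their slant path and scattered flows by absorption along a
hemispherically averaged path (factor 2).  The only scattering effect kept
is the weak backward-scattered gain J_S^Add generated by the forward flows,
evaluated in closed form.

Intensities may be scalars or per-wavelength numpy arrays; the absorption
coefficient a_P is wavelength-dependent.  Lengths are cm, coefficients
cm^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["PalisadeParams", "FluxState", "palisade_forward", "palisade_backward", "js_add"]

_GRAZING = math.pi / 2 - 1e-9


@dataclass(frozen=True)
class FluxState:
    """The four light flows at one depth or boundary.

    Forward collimated ``I_C``, forward scattered ``I_S``, backward
    collimated ``J_C``, backward scattered ``J_S`` (units of the incident
    intensity), plus the depth coordinate ``x`` in cm (0 = top of
    palisade, h+l = bottom of spongy layer).
    """

    I_C: float | np.ndarray = 0.0
    I_S: float | np.ndarray = 0.0
    J_C: float | np.ndarray = 0.0
    J_S: float | np.ndarray = 0.0
    x: float = 0.0

    def __post_init__(self) -> None:
        for name in ("I_C", "I_S", "J_C", "J_S"):
            if np.any(np.asarray(getattr(self, name)) < -1e-12):
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class PalisadeParams:
    """Palisade layer: thickness h (cm), absorption a_P (cm^-1, may be an
    array over wavelength), scattering s_P (cm^-1) and asymmetry factor f
    (0.5 = isotropic redistribution)."""

    h: float
    a_P: float | np.ndarray
    s_P: float = 5.0
    f: float = 0.5

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError(f"h={self.h} must be >= 0")
        if np.any(np.asarray(self.a_P) < 0):
            raise ValueError("a_P must be nonnegative")
        if self.s_P < 0:
            raise ValueError(f"s_P={self.s_P} must be >= 0")
        if not (0.0 <= self.f <= 1.0):
            raise ValueError(f"f={self.f} outside [0, 1]")


def _check_angle(beta: float) -> None:
    if not (0.0 <= beta < _GRAZING):
        raise ValueError(f"internal angle {beta} rad is grazing or out of range")


def palisade_forward(I_C_0, I_S_0, p: PalisadeParams, beta_I1: float):
    """Attenuate the forward flows from the top to the bottom of the layer.

    ``I_C(h) = I_C(0) exp(-a_P h / cos(beta_I1))`` (slant collimated path)
    and ``I_S(h) = I_S(0) exp(-2 a_P h)`` (hemispherically averaged diffuse
    path, factor 2).
    """
    _check_angle(beta_I1)
    a = np.asarray(p.a_P, dtype=float)
    ic_h = I_C_0 * np.exp(-a * p.h / math.cos(beta_I1))
    is_h = I_S_0 * np.exp(-2.0 * a * p.h)
    return ic_h, is_h


def palisade_backward(J_C_h, J_S_h, p: PalisadeParams, beta_I2: float, js_add=0.0):
    """Attenuate the backward flows from the bottom to the top of the layer.

    ``J_C(0) = J_C(h) exp(-a_P h / cos(beta_I2))`` and
    ``J_S(0) = J_S(h) exp(-2 a_P h) + J_S^Add`` where ``js_add`` is the
    backward-scattered gain from :func:`js_add`.
    """
    _check_angle(beta_I2)
    a = np.asarray(p.a_P, dtype=float)
    jc_0 = J_C_h * np.exp(-a * p.h / math.cos(beta_I2))
    js_0 = J_S_h * np.exp(-2.0 * a * p.h) + js_add
    return jc_0, js_0


def _one_minus_exp_over(k):
    """``(1 - exp(-k)) / k`` evaluated stably, with the k -> 0 limit 1."""
    k_arr = np.atleast_1d(np.asarray(k, dtype=float))
    out = np.ones_like(k_arr)
    nz = k_arr > 0
    out[nz] = -np.expm1(-k_arr[nz]) / k_arr[nz]
    return out if np.ndim(k) else float(out[0])


def js_add(I_C_0, I_S_0, p: PalisadeParams, beta_I1: float):
    """Backward-scattered light generated inside the palisade layer.

    Single-scattering gain: forward light scattered backwards at depth x
    (fraction ``s_P (1-f)`` per unit path) is re-attenuated on its diffuse
    way back to the top.  Closed form of the depth integral:

    ``J_S^Add = I_C(0) s_P(1-f) / (a_P (1+2 cos b)) (1 - e^{-a_P(1/cos b + 2) h})
              + I_S(0) s_P(1-f) / (2 a_P) (1 - e^{-4 a_P h})``

    evaluated through ``(1-e^-k)/k`` so the a_P -> 0 (NIR) limit
    ``I_C(0) s_P(1-f) h / cos b + 2 I_S(0) s_P(1-f) h`` is exact.
    """
    _check_angle(beta_I1)
    a = np.asarray(p.a_P, dtype=float)
    c = math.cos(beta_I1)
    sp1f = p.s_P * (1.0 - p.f)
    k1 = a * (1.0 / c + 2.0) * p.h
    k2 = 4.0 * a * p.h
    term_c = I_C_0 * sp1f * (p.h / c) * _one_minus_exp_over(k1)
    term_s = I_S_0 * sp1f * 2.0 * p.h * _one_minus_exp_over(k2)
    return term_c + term_s
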