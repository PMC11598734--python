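"""Analytical four-flux Kubelka-Munk solution for the spongy mesophyll.

The spongy layer scatters strongly (air-space/cell-wall interfaces), so
all four flows are coupled by a linear ODE system in depth.  The collimated
flows decay independently (they only lose light to absorption and to
scattering into the diffuse flows); the two scattered flows form a 2x2
block driven by the collimated ones.  This structure gives a closed-form
solution: two trivial eigenvalues for the collimated flows, the 2x2-block
eigenvalues +/-2 sqrt(a(a+2s(1-f))) for the scattered flows (the classical
Kubelka-Munk exponent), particular solutions from the collimated driving
terms, and two free constants matched to the boundary intensities
I_C(h), I_S(h) at the top and J_C(h+l), J_S(h+l) at the bottom.

Terms with positive eigenvalue times thickness are stored in a rescaled
form (constant times e^{lambda l}) so optically thick layers evaluate
without overflow.  All quantities may be per-wavelength numpy arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .palisade import FluxState

__all__ = [
    "SpongyParams",
    "KMMatrix",
    "KMSolution",
    "A_SP_FLOOR",
    "build_km_matrix",
    "km_eigenvalues",
    "km_solve",
    "km_evaluate",
]

# Minimum absorption coefficient (cm^-1).  At a_Sp = 0 the scattered-block
# eigenvalues coincide at zero and the constant formulas are singular; the
# floor keeps them distinct while being optically negligible (a_Sp * l
# ~ 1e-8 for any real leaf).
A_SP_FLOOR = 1e-6

_GRAZING_COS = 1e-9


@dataclass(frozen=True)
class SpongyParams:
    """Spongy layer: thickness l (cm), absorption a_Sp (cm^-1, scalar or
    array over wavelength; floored at ``A_SP_FLOOR``) and scattering s_Sp
    (cm^-1), with the shared asymmetry factor f."""

    l: float
    a_Sp: float | np.ndarray
    s_Sp: float = 600.0
    f: float = 0.5

    def __post_init__(self) -> None:
        if self.l < 0:
            raise ValueError(f"l={self.l} must be >= 0")
        if np.any(np.asarray(self.a_Sp) < 0):
            raise ValueError("a_Sp must be nonnegative")
        if self.s_Sp < 0:
            raise ValueError(f"s_Sp={self.s_Sp} must be >= 0")
        if not (0.0 <= self.f <= 1.0):
            raise ValueError(f"f={self.f} outside [0, 1]")
        object.__setattr__(
            self, "a_Sp", np.maximum(np.asarray(self.a_Sp, dtype=float), A_SP_FLOOR)
        )


@dataclass(frozen=True)
class KMMatrix:
    """Coefficients of the linear depth-ODE system (cm^-1).

    ``L11``/``L22`` govern the decoupled collimated flows, ``L31..L44``
    the scattered block and its collimated driving terms.  With the
    isotropic-redistribution sign convention ``L33 + L44 = 0``.
    """

    L11: float | np.ndarray
    L22: float | np.ndarray
    L31: float | np.ndarray
    L32: float | np.ndarray
    L33: float | np.ndarray
    L34: float | np.ndarray
    L41: float | np.ndarray
    L42: float | np.ndarray
    L43: float | np.ndarray
    L44: float | np.ndarray


def build_km_matrix(sp: SpongyParams, beta_I1: float, beta_I2: float) -> KMMatrix:
    """Map layer parameters and internal beam angles onto the ODE matrix.

    Collimated flows are attenuated by absorption plus total scattering
    along their slant paths; a fraction f of scattered-out light continues
    forward and 1-f reverses.  Scattered flows use the diffuse path-length
    factor 2 and exchange through ``2 s_Sp (1-f)``.
    """
    c1 = math.cos(beta_I1)
    c2 = math.cos(beta_I2)
    if c1 < _GRAZING_COS or c2 < _GRAZING_COS:
        raise ValueError("grazing internal angle: cos(beta) ~ 0")
    a = np.asarray(sp.a_Sp, dtype=float)
    s = sp.s_Sp
    f = sp.f
    return KMMatrix(
        L11=-(a + s) / c1,
        L22=+(a + s) / c2,
        L31=f * s / c1,
        L32=(1.0 - f) * s / c2,
        L33=-2.0 * (a + s * (1.0 - f)),
        L34=2.0 * s * (1.0 - f),
        L41=-(1.0 - f) * s / c1,
        L42=-f * s / c2,
        L43=-2.0 * s * (1.0 - f),
        L44=+2.0 * (a + s * (1.0 - f)),
    )


def km_eigenvalues(L: KMMatrix):
    """Eigenvalues of the ODE system.

    ``lambda1 = L11`` and ``lambda2 = L22`` (decoupled collimated flows);
    ``lambda3 >= lambda4`` are the eigenvalues of the scattered 2x2 block,
    the roots of ``lambda^2 - (L33+L44) lambda + (L33 L44 - L34 L43) = 0``.
    For physical coefficients the radicand ``((L33-L44)/2)^2 + L34 L43``
    equals ``4 a (a + 2 s (1-f)) >= 0``, so the roots are always real.
    """
    mean = (np.asarray(L.L33) + np.asarray(L.L44)) / 2.0
    radicand = ((np.asarray(L.L33) - np.asarray(L.L44)) / 2.0) ** 2 + np.asarray(
        L.L34
    ) * np.asarray(L.L43)
    if np.any(radicand < -1e-9 * np.maximum(np.asarray(L.L33) ** 2, 1.0)):
        raise AssertionError("complex scattered-block eigenvalues: unphysical input")
    root = np.sqrt(np.maximum(radicand, 0.0))
    return (
        np.asarray(L.L11, dtype=float),
        np.asarray(L.L22, dtype=float),
        mean + root,
        mean - root,
    )


@dataclass(frozen=True)
class KMSolution:
    """Constants of the analytic spongy-layer solution.

    Flows over depth x in [h, h+l] (x1 = x - h):

    ``I_C = A1 e^{l1 x1}``, ``J_C = B2 e^{l2 x1}``,
    ``I_S = C1 e^{l1 x1} + C2 e^{l2 x1} + C3 e^{l3 x1} + C4 e^{l4 x1}``
    and the same pattern with D for J_S.  The growing-exponent constants
    are stored rescaled (``B2s = B2 e^{l2 l}``, ``C3s = C3 e^{l3 l}``,
    ``D3s = D3 e^{l3 l}``) and evaluated as e^{lambda (x1 - l)} so the
    representation never overflows; the raw constants are exposed as
    properties (they may underflow to 0 for optically thick layers).
    """

    lambda1: np.ndarray
    lambda2: np.ndarray
    lambda3: np.ndarray
    lambda4: np.ndarray
    A1: np.ndarray
    B2s: np.ndarray  # = B2 e^{lambda2 l} = J_C(h+l)
    C1: np.ndarray
    D1: np.ndarray
    C2s: np.ndarray  # = C2 e^{lambda2 l}
    D2s: np.ndarray  # = D2 e^{lambda2 l}
    C3s: np.ndarray  # = C3 e^{lambda3 l}
    D3s: np.ndarray  # = D3 e^{lambda3 l}
    C4: np.ndarray
    D4: np.ndarray
    l: float
    h: float = 0.0

    @property
    def B2(self):
        return self.B2s * np.exp(-self.lambda2 * self.l)

    @property
    def C2(self):
        return self.C2s * np.exp(-self.lambda2 * self.l)

    @property
    def D2(self):
        return self.D2s * np.exp(-self.lambda2 * self.l)

    @property
    def C3(self):
        return self.C3s * np.exp(-self.lambda3 * self.l)

    @property
    def D3(self):
        return self.D3s * np.exp(-self.lambda3 * self.l)


def km_solve(
    IC_h,
    IS_h,
    JC_hl,
    JS_hl,
    sp: SpongyParams,
    L: KMMatrix | None = None,
    beta_I1: float = 0.0,
    beta_I2: float = 0.0,
    h: float = 0.0,
) -> KMSolution:
    """Match the analytic solution to the four boundary intensities.

    ``IC_h``/``IS_h`` are the forward flows entering at the top (x = h),
    ``JC_hl``/``JS_hl`` the backward flows entering at the bottom
    (x = h + l).  If ``L`` is omitted it is built from ``sp`` and the
    angles.  Raises if the boundary-matching denominator degenerates,
    which only happens when the absorption floor is bypassed.
    """
    for name, v in (("IC_h", IC_h), ("IS_h", IS_h), ("JC_hl", JC_hl), ("JS_hl", JS_hl)):
        if np.any(np.asarray(v) < 0):
            raise ValueError(f"{name} must be nonnegative")
    if L is None:
        L = build_km_matrix(sp, beta_I1, beta_I2)
    l1, l2, l3, l4 = km_eigenvalues(L)
    ll = sp.l
    IC_h = np.asarray(IC_h, dtype=float)
    IS_h = np.asarray(IS_h, dtype=float)
    JC_hl = np.asarray(JC_hl, dtype=float)
    JS_hl = np.asarray(JS_hl, dtype=float)
    L31, L32, L33, L34 = (np.asarray(L.L31), np.asarray(L.L32),
                          np.asarray(L.L33), np.asarray(L.L34))
    L41, L42, L43, L44 = (np.asarray(L.L41), np.asarray(L.L42),
                          np.asarray(L.L43), np.asarray(L.L44))

    scale = np.maximum(np.abs(L33), 1.0)

    def _delta(lam):
        return (L33 - lam) * (L44 - lam) - L34 * L43

    # particular solutions driven by the collimated exponentials; the
    # denominators vanish only on the measure-zero resonance lambda_{1,2}
    # in {lambda3, lambda4} (s_Sp = 3 a_Sp at normal incidence) -- callers
    # perturb a_Sp away from it (see engine)
    d1 = _delta(l1)
    d2 = _delta(l2)
    for name, d in (("lambda1", d1), ("lambda2", d2)):
        if np.any(np.abs(d) < 1e-10 * scale**2):
            raise FloatingPointError(
                f"collimated eigenvalue {name} resonates with the scattered "
                "block (s_Sp ~ 3 a_Sp); perturb a_Sp slightly"
            )
    A1 = IC_h
    B2s = JC_hl
    C1 = IC_h * (-L31 * (L44 - l1) + L41 * L34) / d1
    D1 = IC_h * (-L41 * (L33 - l1) + L31 * L43) / d1
    # C2/D2 carry the factor e^{-lambda2 l} from B2; the rescaled forms are finite
    C2s = JC_hl * (-L32 * (L44 - l2) + L42 * L34) / d2
    D2s = JC_hl * (-L42 * (L33 - l2) + L32 * L43) / d2

    e1l = np.exp(l1 * ll)          # decaying, <= 1
    e2ml = np.exp(-l2 * ll)        # decaying, <= 1
    e4l = np.exp(l4 * ll)          # lambda4 <= 0, <= 1
    e43 = np.exp((l4 - l3) * ll)   # <= 1
    e3ml = np.exp(-l3 * ll)        # <= 1

    P = IS_h - C1 - C2s * e2ml
    Q = -JS_hl + D1 * e1l + D2s

    degenerate = np.abs(L34) < 1e-12 * np.maximum(np.abs(L44), 1.0)
    if np.all(degenerate):
        # no diffuse exchange (s_Sp (1-f) = 0): the scattered flows are
        # decoupled first-order equations; I_S relaxes with L33, J_S with L44
        zeros = np.zeros_like(P)
        return KMSolution(
            lambda1=l1, lambda2=l2, lambda3=np.asarray(L44, float),
            lambda4=np.asarray(L33, float),
            A1=A1, B2s=B2s, C1=C1, D1=D1, C2s=C2s, D2s=D2s,
            C3s=zeros, D3s=-Q, C4=P, D4=zeros, l=ll, h=h,
        )
    if np.any(degenerate):
        raise ValueError("mixed degenerate/nondegenerate L34 across wavelengths")

    den_s = (L33 - l4) * e43 - (L33 - l3)  # = Den * e^{-lambda3 l}
    if np.any(np.abs(den_s) < 1e-10 * scale):
        raise FloatingPointError(
            "degenerate boundary-matching denominator (a_Sp ~ 0); "
            "keep the A_SP_FLOOR absorption floor"
        )
    C3s = (P * (L33 - l4) * e4l - Q * L34) / den_s
    C4 = (Q * L34 * e3ml - P * (L33 - l3)) / den_s
    D3s = -C3s * (L33 - l3) / L34
    D4 = -C4 * (L33 - l4) / L34
    return KMSolution(
        lambda1=l1, lambda2=l2, lambda3=l3, lambda4=l4,
        A1=A1, B2s=B2s, C1=C1, D1=D1, C2s=C2s, D2s=D2s,
        C3s=C3s, D3s=D3s, C4=C4, D4=D4, l=ll, h=h,
    )


def km_evaluate(sol: KMSolution, x: float) -> FluxState:
    """Evaluate the four flows at absolute depth x in [h, h+l]."""
    x1 = x - sol.h
    if not (-1e-12 <= x1 <= sol.l + 1e-12):
        raise ValueError(f"depth x={x} outside the spongy layer [h, h+l]")
    x1 = min(max(x1, 0.0), sol.l)
    e1 = np.exp(sol.lambda1 * x1)
    e2 = np.exp(sol.lambda2 * (x1 - sol.l))
    e3 = np.exp(sol.lambda3 * (x1 - sol.l))
    e4 = np.exp(sol.lambda4 * x1)
    I_C = sol.A1 * e1
    J_C = sol.B2s * e2
    I_S = sol.C1 * e1 + sol.C2s * e2 + sol.C3s * e3 + sol.C4 * e4
    J_S = sol.D1 * e1 + sol.D2s * e2 + sol.D3s * e3 + sol.D4 * e4
    # tiny negative values from cancellation are clipped to zero
    tol = 1e-9 * float(
        np.max(np.abs(I_S)) + np.max(np.abs(J_S))
        + np.max(np.abs(sol.A1)) + np.max(np.abs(sol.B2s)) + 1.0
    )
    I_S = np.where((I_S < 0) & (I_S > -tol), 0.0, I_S)
    J_S = np.where((J_S < 0) & (J_S > -tol), 0.0, J_S)
    return FluxState(I_C=I_C, I_S=I_S, J_C=J_C, J_S=J_S, x=x)
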