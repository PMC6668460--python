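"""Closed-form relaxation and exchange expressions for 15N R1rho analysis.

Pure functions, no I/O and no optimisation. Unit conventions:

* all frequency *arguments* (spin-lock nutation, offsets, spectral-density
  arguments) are angular, rad s^-1;
* user-facing quantities are converted at the boundary: spin-lock and MAS
  frequencies are quoted in kHz elsewhere, chemical shifts and CSA in ppm;
* rates are s^-1, phi_ex is rad^2 s^-2 at a declared reference field, and
  correlation times are seconds.

The fast-exchange Bloch–McConnell dispersion model is

    R1rho(omega_1) = R1rho_0 + phi_ex * kex / (omega_1^2 + kex^2)

with phi_ex = pA*pB*(delta_delta)^2 the composite exchange amplitude: in the
fast limit the populations and the chemical-shift difference between the two
states cannot be separated, so their product is the fit parameter. Data
recorded at a higher static field than the reference are modelled by scaling
phi_ex with the squared ratio of the fields (delta_delta in rad/s grows
linearly with B0).

The MAS-dependent rates (dipolar NH and 15N CSA contributions under spinning)
use the simple model-free spectral density J(w) = (1-S^2) tau / (1+(w tau)^2);
the CSA anisotropy given in ppm is converted to rad/s as delta_sigma*1e-6*w_N
before squaring, which is required for the expression to be dimensionally a
rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constants import (
    ANGSTROM,
    GAMMA_H,
    GAMMA_N,
    GAMMA_RATIO_NH,
    HBAR,
    MU0,
    TWO_PI,
)

__all__ = [
    "FieldContext",
    "SpinSystemGeometry",
    "ExchangeParameters",
    "MotionModel",
    "tilt_angle",
    "onres_r1rho",
    "bm_r1rho",
    "exchange_term",
    "field_scale",
    "smf_spectral_density",
    "dipolar_r1rho",
    "csa_r1rho",
    "two_site_s2",
    "jump_angle_from_s2",
]


@dataclass(frozen=True)
class FieldContext:
    """One static-field / spinning condition.

    Parameters
    ----------
    proton_larmor_mhz:
        1H Larmor frequency in MHz (600, 700, 850 in typical use; these
        correspond to 14.1, 16.4 and 20 T).
    mas_khz:
        Magic-angle-spinning frequency in kHz. May be 0 for expressions
        that do not involve spinning sidebands.
    label:
        Free-text identifier used in tables and reports.
    """

    proton_larmor_mhz: float
    mas_khz: float = 60.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.proton_larmor_mhz <= 0:
            raise ValueError("proton Larmor frequency must be positive")
        if self.mas_khz < 0:
            raise ValueError("MAS frequency must be nonnegative")

    @property
    def nitrogen_larmor_mhz(self) -> float:
        """15N Larmor frequency (MHz), derived from the gyromagnetic ratio."""
        return self.proton_larmor_mhz * GAMMA_RATIO_NH

    @property
    def omega_h(self) -> float:
        """1H Larmor frequency, rad s^-1."""
        return TWO_PI * self.proton_larmor_mhz * 1e6

    @property
    def omega_n(self) -> float:
        """|15N| Larmor frequency, rad s^-1."""
        return TWO_PI * self.nitrogen_larmor_mhz * 1e6

    @property
    def omega_r(self) -> float:
        """Spinning frequency, rad s^-1."""
        return TWO_PI * self.mas_khz * 1e3

    @property
    def tesla(self) -> float:
        """Static field in T (from the 1H Larmor frequency)."""
        return TWO_PI * self.proton_larmor_mhz * 1e6 / GAMMA_H


@dataclass(frozen=True)
class SpinSystemGeometry:
    """Amide 15N–1H spin-pair geometry and interaction constants.

    Defaults: r_NH = 1.02 Å and an axially symmetric 15N CSA tensor with
    delta_sigma = sigma_par - sigma_perp = -170 ppm, eta = 0, collinear with
    the NH vector.
    """

    nh_distance_angstrom: float = 1.02
    csa_delta_ppm: float = -170.0
    csa_eta: float = 0.0
    gamma_h: float = GAMMA_H
    gamma_n: float = GAMMA_N

    @property
    def dipolar_coupling(self) -> float:
        """mu0/4pi * hbar*gamma_H*gamma_N / r^3 in rad s^-1 (signed)."""
        r = self.nh_distance_angstrom * ANGSTROM
        return (MU0 / (4.0 * math.pi)) * HBAR * self.gamma_h * self.gamma_n / r**3


@dataclass(frozen=True)
class ExchangeParameters:
    """Two-site fast-exchange parameters for one residue.

    kex is the sum of the forward and backward rate constants; phi_ex is
    pA*pB*delta_delta^2 at the declared reference field (rad^2 s^-2);
    r1rho_plateau is the exchange-free base rate R1rho_0. The optional
    populations and shift difference are only carried when they are known
    (e.g. in simulations) and must then be consistent with phi_ex.
    """

    kex: float
    phi_ex: float
    r1rho_plateau: float = 0.0
    p_a: Optional[float] = None
    p_b: Optional[float] = None
    delta_delta: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kex <= 0:
            raise ValueError("kex must be positive")
        if self.phi_ex < 0:
            raise ValueError("phi_ex must be nonnegative")
        if self.r1rho_plateau < 0:
            raise ValueError("r1rho_plateau must be nonnegative")
        if None not in (self.p_a, self.p_b, self.delta_delta):
            if not math.isclose(self.p_a + self.p_b, 1.0, rel_tol=1e-9):
                raise ValueError("populations must sum to 1")
            implied = self.p_a * self.p_b * self.delta_delta**2
            if not math.isclose(implied, self.phi_ex, rel_tol=1e-9, abs_tol=1e-15):
                raise ValueError("pA*pB*delta_delta^2 inconsistent with phi_ex")


@dataclass(frozen=True)
class MotionModel:
    """Simple model-free motion: order parameter S^2 and correlation time tau (s)."""

    order_parameter: float
    correlation_time: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.order_parameter <= 1.0:
            raise ValueError("order parameter must lie in [0, 1]")
        if self.correlation_time <= 0:
            raise ValueError("correlation time must be positive")


def tilt_angle(spin_lock_nutation, offset):
    """Tilt angle theta = arctan(omega_1 / |Omega|) of the effective field.

    Both arguments in rad s^-1. Returns an angle in (0, pi/2]; on resonance
    (Omega = 0) the angle is exactly pi/2. Symmetric in the sign of the
    offset. Vectorised over both arguments.
    """
    w1 = np.asarray(spin_lock_nutation, dtype=float)
    if np.any(w1 <= 0):
        raise ValueError("spin-lock nutation frequency must be positive")
    omega = np.abs(np.asarray(offset, dtype=float))
    out = np.where(omega == 0.0, np.pi / 2.0, np.arctan2(w1, omega))
    return out if out.ndim else float(out)


def onres_r1rho(observed_rate, r1, angle):
    """Correct an off-resonance R1rho,obs to the on-resonance rate.

    R1rho = (R1rho,obs - cos^2(theta) R1) / sin^2(theta). Vectorised.
    """
    theta = np.asarray(angle, dtype=float)
    if np.any(theta <= 0) or np.any(theta > np.pi / 2 + 1e-12):
        raise ValueError("tilt angle must lie in (0, pi/2]")
    if np.any(np.asarray(r1, dtype=float) < 0):
        raise ValueError("R1 must be nonnegative")
    s2 = np.sin(theta) ** 2
    c2 = np.cos(theta) ** 2
    out = (np.asarray(observed_rate, dtype=float) - c2 * np.asarray(r1, dtype=float)) / s2
    return out if out.ndim else float(out)


def exchange_term(omega_1, kex, phi_ex, scale=1.0):
    """Exchange contribution scale * phi_ex * kex / (omega_1^2 + kex^2)."""
    w1 = np.asarray(omega_1, dtype=float)
    out = scale * phi_ex * kex / (w1**2 + kex**2)
    return out if out.ndim else float(out)


def bm_r1rho(params: ExchangeParameters, spin_lock_nutation, field_scale=1.0):
    """Fast-exchange Bloch–McConnell on-resonance R1rho.

    ``field_scale`` is the squared ratio of the static field to the reference
    field at which phi_ex is expressed (see :func:`field_scale`).
    """
    if np.any(np.asarray(spin_lock_nutation, dtype=float) < 0):
        raise ValueError("spin-lock nutation frequency must be nonnegative")
    if field_scale <= 0:
        raise ValueError("field scale must be positive")
    return params.r1rho_plateau + exchange_term(
        spin_lock_nutation, params.kex, params.phi_ex, field_scale
    )


def field_scale(field: FieldContext, reference: FieldContext) -> float:
    """Squared ratio of static fields, (B0 / B0_ref)^2, via 1H Larmor frequencies."""
    return (field.proton_larmor_mhz / reference.proton_larmor_mhz) ** 2


def smf_spectral_density(motion: MotionModel, angular_frequency):
    """Simple model-free spectral density J(w) = (1-S^2) tau / (1 + (w tau)^2).

    J is even in w; the absolute value of the argument is used, so negative
    combination frequencies (omega_1 - 2*omega_r etc.) are handled naturally.
    Returns seconds.
    """
    tau = motion.correlation_time
    w = np.abs(np.asarray(angular_frequency, dtype=float))
    out = (1.0 - motion.order_parameter) * tau / (1.0 + (w * tau) ** 2)
    return out if out.ndim else float(out)


def _spinlock_j_terms(motion, omega_1, omega_r):
    """Sum of the four spin-lock/MAS sideband terms common to Eq-style rates."""
    j = lambda w: smf_spectral_density(motion, w)  # noqa: E731
    return (
        (2.0 / 3.0) * j(omega_1 + 2.0 * omega_r)
        + (2.0 / 3.0) * j(omega_1 - 2.0 * omega_r)
        + (4.0 / 3.0) * j(omega_1 + omega_r)
        + (4.0 / 3.0) * j(omega_1 - omega_r)
    )


def dipolar_r1rho(
    geometry: SpinSystemGeometry,
    field: FieldContext,
    spin_lock_nutation: float,
    motion: MotionModel,
) -> float:
    """NH dipolar contribution to 15N R1rho under MAS.

    R = (1/20) d^2 [ 2/3 J(w1+2wr) + 2/3 J(w1-2wr) + 4/3 J(w1+wr)
        + 4/3 J(w1-wr) + 3 J(wN) + J(wH-wN) + 6 J(wH) + 6 J(wH+wN) ]

    with d = mu0/4pi * hbar gammaH gammaN / r^3. The heteronuclear
    combination frequencies use magnitudes, wH - wN = |wH| - |wN|.
    """
    if field.mas_khz <= 0:
        raise ValueError("MAS frequency must be positive for spinning rates")
    d = geometry.dipolar_coupling
    j = lambda w: smf_spectral_density(motion, w)  # noqa: E731
    wn, wh = field.omega_n, field.omega_h
    terms = (
        _spinlock_j_terms(motion, spin_lock_nutation, field.omega_r)
        + 3.0 * j(wn)
        + j(wh - wn)
        + 6.0 * j(wh)
        + 6.0 * j(wh + wn)
    )
    return 0.05 * d**2 * terms


def csa_r1rho(
    geometry: SpinSystemGeometry,
    field: FieldContext,
    spin_lock_nutation: float,
    motion: MotionModel,
) -> float:
    """15N CSA contribution to R1rho under MAS (axially symmetric tensor).

    R = (1/45) (delta_sigma * 1e-6 * wN)^2 [ 2/3 J(w1+2wr) + 2/3 J(w1-2wr)
        + 4/3 J(w1+wr) + 4/3 J(w1-wr) + 3 J(wN) ]

    The anisotropy delta_sigma = sigma_par - sigma_perp is supplied in ppm
    and converted to an angular frequency at this field before squaring.
    """
    if field.mas_khz <= 0:
        raise ValueError("MAS frequency must be positive for spinning rates")
    delta_omega = geometry.csa_delta_ppm * 1e-6 * field.omega_n
    terms = _spinlock_j_terms(motion, spin_lock_nutation, field.omega_r) + 3.0 * (
        smf_spectral_density(motion, field.omega_n)
    )
    return (1.0 / 45.0) * delta_omega**2 * terms


def two_site_s2(p_minor: float, jump_angle: float) -> float:
    """Order parameter of a two-site jump: S^2 = 1 - 3 pA pB sin^2(theta).

    ``p_minor`` is the minor-state population (0..0.5); ``jump_angle`` the
    angle between the two NH orientations in radians.
    """
    if not 0.0 <= p_minor <= 0.5:
        raise ValueError("minor population must lie in [0, 0.5]")
    if not 0.0 <= jump_angle <= math.pi / 2:
        raise ValueError("jump angle must lie in [0, pi/2]")
    pa, pb = 1.0 - p_minor, p_minor
    return 1.0 - 3.0 * pa * pb * math.sin(jump_angle) ** 2


def jump_angle_from_s2(s2: float, p_minor: float) -> float:
    """Invert the two-site jump order parameter for the jump angle (rad).

    theta = arcsin( sqrt( (1 - S^2) / (3 pA pB) ) ). For a given population
    the attainable floor is S^2 = 1 - 3 pA pB; below it no jump angle exists
    and a ValueError is raised.
    """
    if not 0.0 <= p_minor <= 0.5:
        raise ValueError("minor population must lie in [0, 0.5]")
    pa, pb = 1.0 - p_minor, p_minor
    floor = 1.0 - 3.0 * pa * pb
    if s2 > 1.0 or s2 < floor - 1e-12:
        raise ValueError(
            f"S^2={s2} not attainable for p_minor={p_minor} (floor {floor:.6f})"
        )
    arg = (1.0 - s2) / (3.0 * pa * pb)
    return math.asin(math.sqrt(min(max(arg, 0.0), 1.0)))
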