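"""Optical and transmission-line hemodynamics of an arteriovenous fistula.

The module links a vessel's geometry and mechanics to the quantities a
reflective PPG probe can observe.  Three layers are provided:

* **Optics** — Beer–Lambert attenuation of the probe light, the linear
  oxy/deoxy-hemoglobin absorption mix, and the perfusion index (PI), the
  AC/DC ratio of the photocurrent, which is proportional to the pulsatile
  light path through blood.
* **Vessel mechanics** — a lossy transmission-line ("telegrapher") analogy
  for pressure/flow wave propagation: per-unit-length resistance,
  inertance and compliance with Womersley corrections for pulsatile flow,
  plus the propagation constants and characteristic impedance that follow.
* **Clinical readouts** — degree of stenosis (DOS, % cross-sectional area
  loss) and average blood-flow volume (BFV, mL/min), each expressed both
  from vessel geometry directly (forward) and from measurable features
  (PI extrema, SpO2, blood pressures, heart rate — inverse).

All internal computation is in CGS units.  Pressures are accepted in mmHg
and converted at ``MMHG_TO_DYN_CM2`` dyn/cm² per mmHg; flows are reported
in mL/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DomainError

__all__ = [
    "MMHG_TO_DYN_CM2",
    "COMPLIANCE_CONVENTION_FACTOR",
    "OpticalConstants",
    "BloodProperties",
    "VesselState",
    "Hemodynamics",
    "LineParams",
    "CalibrationConstants",
    "received_intensity",
    "effective_absorption",
    "pi_from_path",
    "path_from_pi",
    "womersley",
    "womersley_coeffs",
    "line_params",
    "propagation_constants",
    "characteristic_impedance",
    "mean_bp",
    "average_bfv",
    "vessel_compliance",
    "vessel_thickness",
    "dos_from_geometry",
    "dos_from_thickness",
    "dos_from_features",
    "bfv_from_features",
    "features_from_vessel",
]

#: dyn/cm² per mmHg.
MMHG_TO_DYN_CM2 = 1333.22

#: Constant-factor convention relating the pressure-strain compliance
#: (area change per pressure change) to the per-unit-length line compliance
#: evaluated at the wall thickness returned by :func:`vessel_thickness`:
#: ``vessel_compliance(...) == COMPLIANCE_CONVENTION_FACTOR * LineParams.C``.
COMPLIANCE_CONVENTION_FACTOR = math.pi


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticalConstants:
    """Absorption constants of the optical probe path.

    ``tissue_exponent`` lumps the (static) tissue term ``eps_t * c_t * s_t``
    into a single attenuation exponent.
    """

    eps_HbO: float = 1.2
    eps_Hb: float = 0.8
    tissue_exponent: float = 0.5
    I0: float = 1.0

    def __post_init__(self) -> None:
        if self.eps_HbO <= 0 or self.eps_Hb <= 0:
            raise DomainError("absorption coefficients must be strictly positive")
        if self.eps_HbO == self.eps_Hb:
            raise DomainError("eps_HbO must differ from eps_Hb")
        if self.I0 <= 0:
            raise DomainError("incident intensity must be positive")


@dataclass(frozen=True)
class BloodProperties:
    """Bulk blood properties: viscosity (g/(cm·s)), density (g/cm³), SpO2."""

    eta: float = 0.035
    rho: float = 1.056
    spo2: float = 0.97

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.rho <= 0:
            raise DomainError("viscosity and density must be positive")
        if not 0.0 <= self.spo2 <= 1.0:
            raise DomainError(f"spo2 must lie in [0, 1], got {self.spo2}")


@dataclass(frozen=True)
class VesselState:
    """Geometric/mechanical state of one fistula segment (CGS units).

    ``D``/``d`` are the normal and stenotic lumen diameters, ``d0`` the
    diameter at the measuring spot, ``h1`` the baseline wall thickness,
    ``h2`` the hyperplasia thickness (total wall ``h = h1 + h2``), ``E``
    the Young's modulus (dyn/cm²), ``sigma_p`` the Poisson ratio, and
    ``d_max``/``d_min`` the pulsatile diameter extremes.
    """

    D: float
    d: float
    d0: float
    h1: float
    h2: float
    E: float
    sigma_p: float
    d_max: float
    d_min: float

    def __post_init__(self) -> None:
        if not 0 < self.d <= self.D:
            raise DomainError(f"need 0 < d <= D, got d={self.d}, D={self.D}")
        if self.h1 < 0 or self.h2 < 0:
            raise DomainError("wall thicknesses must be non-negative")
        if not self.d_min <= self.d0 <= self.d_max:
            raise DomainError("d0 must lie within [d_min, d_max]")
        if not 0 <= self.sigma_p < 0.5:
            raise DomainError("Poisson ratio must lie in [0, 0.5)")
        if self.E <= 0:
            raise DomainError("Young's modulus must be positive")

    @property
    def h(self) -> float:
        """Total wall thickness (cm)."""
        return self.h1 + self.h2


@dataclass(frozen=True)
class Hemodynamics:
    """Pressure and heart-rate context: SBP/DBP in mmHg, HR in bpm."""

    sbp: float
    dbp: float
    hr_bpm: float

    def __post_init__(self) -> None:
        if not self.sbp > self.dbp > 0:
            raise DomainError(f"need sbp > dbp > 0, got {self.sbp}/{self.dbp}")
        if not 40 <= self.hr_bpm <= 200:
            raise DomainError(f"implausible heart rate {self.hr_bpm} bpm")

    @property
    def omega(self) -> float:
        """Heart angular frequency (rad/s)."""
        return 2.0 * math.pi * self.hr_bpm / 60.0


@dataclass(frozen=True)
class LineParams:
    """Per-unit-length transmission-line quantities of the vessel.

    ``R`` resistance, ``L`` inertance, ``G`` conductance (fixed 0),
    ``C`` compliance; ``W`` the Womersley number with its correction
    factors ``c1``/``c2``; ``alpha``/``beta`` the attenuation and phase
    constants and ``Z0`` the characteristic impedance, all evaluated at
    the heart frequency used to build the instance.
    """

    R: float
    L: float
    G: float
    C: float
    W: float
    c1: float
    c2: float
    alpha: float = 0.0
    beta: float = 0.0
    Z0: complex = field(default=0j)

    def __post_init__(self) -> None:
        if self.R < 0 or self.L <= 0 or self.C <= 0:
            raise DomainError("line parameters R >= 0, L > 0, C > 0 required")
        if self.G != 0:
            raise DomainError("branch conductance G is fixed at 0 in this model")


@dataclass(frozen=True)
class CalibrationConstants:
    """Constants closing the feature -> vessel inverse map.

    ``kappa`` (cm per unit optical path) converts the blood light path
    implied by a perfusion index into a vessel diameter; ``E``,
    ``sigma_p`` and ``h1`` fix the mechanical convention; the optics and
    blood constants mirror :class:`OpticalConstants`/:class:`BloodProperties`.
    ``poiseuille_pi`` keeps the 1/pi in the Poiseuille resistance (the
    standard form); disabling it drops the pi.
    """

    eps_HbO: float = 1.2
    eps_Hb: float = 0.8
    kappa: float = 35.0
    E: float = 2.0e7
    sigma_p: float = 0.49
    h1: float = 0.03
    eta: float = 0.035
    rho: float = 1.056
    poiseuille_pi: bool = True

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise DomainError("kappa must be positive")
        if self.E <= 0 or self.h1 < 0:
            raise DomainError("E must be positive and h1 non-negative")
        if not 0 <= self.sigma_p < 0.5:
            raise DomainError("Poisson ratio must lie in [0, 0.5)")

    def optics(self) -> OpticalConstants:
        return OpticalConstants(eps_HbO=self.eps_HbO, eps_Hb=self.eps_Hb)

    def blood(self, spo2: float) -> BloodProperties:
        return BloodProperties(eta=self.eta, rho=self.rho, spo2=spo2)


# ---------------------------------------------------------------------------
# optics
# ---------------------------------------------------------------------------


def received_intensity(oc: OpticalConstants, eps_b_c_b: float, s_b: float) -> float:
    """Received light intensity after tissue and blood attenuation.

    ``I0 * exp(-tissue_exponent) * exp(-eps_b_c_b * s_b)``.  Both
    exponents attenuate (negative sign); a negative blood path is a
    domain error.
    """
    if s_b < 0:
        raise DomainError(f"blood path length must be >= 0, got {s_b}")
    return oc.I0 * math.exp(-oc.tissue_exponent) * math.exp(-eps_b_c_b * s_b)


def effective_absorption(spo2: float, oc: OpticalConstants) -> float:
    """Effective blood absorption ``eps_b * c_b`` at saturation ``spo2``.

    Linear mix: ``spo2 * eps_HbO + (1 - spo2) * eps_Hb``.
    """
    if not 0.0 <= spo2 <= 1.0:
        raise DomainError(f"spo2 must lie in [0, 1], got {spo2}")
    return spo2 * oc.eps_HbO + (1.0 - spo2) * oc.eps_Hb


def pi_from_path(s_b: float, spo2: float, oc: OpticalConstants) -> float:
    """Perfusion index from the pulsatile blood light path ``s_b``."""
    if s_b < 0:
        raise DomainError(f"blood path length must be >= 0, got {s_b}")
    return s_b * effective_absorption(spo2, oc)


def path_from_pi(pi: float, spo2: float, oc: OpticalConstants) -> float:
    """Inverse of :func:`pi_from_path`: blood light path from a PI value."""
    if pi < 0:
        raise DomainError(f"perfusion index must be >= 0, got {pi}")
    eff = effective_absorption(spo2, oc)
    if eff == 0.0:
        raise DomainError("effective absorption is zero; path is undefined")
    return pi / eff


# ---------------------------------------------------------------------------
# transmission-line mechanics
# ---------------------------------------------------------------------------


def womersley(d0: float, omega: float, bp: BloodProperties) -> float:
    """Womersley number ``d0 * sqrt(omega * rho / (4 * eta))``."""
    if d0 <= 0 or omega <= 0:
        raise DomainError("d0 and omega must be positive")
    return d0 * math.sqrt(omega * bp.rho / (4.0 * bp.eta))


def womersley_coeffs(W: float) -> tuple[float, float]:
    """Pulsatility corrections ``(c1, c2) = (0.18 W + 0.45, -0.018 W + 1.39)``."""
    if W < 0:
        raise DomainError(f"Womersley number must be >= 0, got {W}")
    return 0.18 * W + 0.45, -0.018 * W + 1.39


def propagation_constants(lp: LineParams, omega: float) -> tuple[float, float]:
    """Attenuation and phase constants from the principal root of
    ``(R + jwL)(G + jwC)``."""
    gamma = ((lp.R + 1j * omega * lp.L) * (lp.G + 1j * omega * lp.C)) ** 0.5
    return gamma.real, gamma.imag


def characteristic_impedance(lp: LineParams, omega: float) -> complex:
    """Characteristic impedance ``sqrt((R + jwL) / (G + jwC))`` (principal)."""
    denom = lp.G + 1j * omega * lp.C
    if denom == 0:
        raise DomainError("G + j*omega*C is zero; Z0 undefined")
    return ((lp.R + 1j * omega * lp.L) / denom) ** 0.5


def line_params(
    vessel: VesselState,
    hemo: Hemodynamics,
    bp: BloodProperties,
    *,
    poiseuille_pi: bool = True,
) -> LineParams:
    """Per-unit-length line parameters of the vessel at the heart frequency.

    R is the Womersley-corrected Poiseuille resistance, L the corrected
    blood inertance, G = 0, C the wall compliance
    ``(1 - sigma^2) * pi * d0^3 / (4 h E)``.  ``poiseuille_pi=False``
    drops the 1/pi from R (non-standard bookkeeping kept as a switch).
    """
    d0, h, E = vessel.d0, vessel.h, vessel.E
    if d0 <= 0 or h <= 0 or E <= 0:
        raise DomainError("d0, h and E must be positive")
    omega = hemo.omega
    W = womersley(d0, omega, bp)
    c1, c2 = womersley_coeffs(W)
    r_denom = math.pi * d0**4 if poiseuille_pi else d0**4
    R = c1 * 128.0 * bp.eta / r_denom
    L = c2 * 4.0 * bp.rho / (math.pi * d0**2)
    C = (1.0 - vessel.sigma_p**2) * math.pi * d0**3 / (4.0 * h * E)
    base = LineParams(R=R, L=L, G=0.0, C=C, W=W, c1=c1, c2=c2)
    alpha, beta = propagation_constants(base, omega)
    Z0 = characteristic_impedance(base, omega)
    return LineParams(
        R=R, L=L, G=0.0, C=C, W=W, c1=c1, c2=c2, alpha=alpha, beta=beta, Z0=Z0
    )


# ---------------------------------------------------------------------------
# clinical readouts
# ---------------------------------------------------------------------------


def mean_bp(sbp: float, dbp: float) -> float:
    """Mean blood pressure ``SBP/3 + 2 DBP/3`` (mmHg)."""
    if sbp <= dbp:
        raise DomainError(f"need sbp > dbp, got {sbp} <= {dbp}")
    return sbp / 3.0 + 2.0 * dbp / 3.0


def average_bfv(
    vessel: VesselState,
    hemo: Hemodynamics,
    bp: BloodProperties,
    *,
    poiseuille_pi: bool = True,
) -> float:
    """Average blood-flow volume through the segment, in mL/min.

    ``|MBP / Z0|`` with MBP in dyn/cm² and Z0 from the line model; the
    cm³/s magnitude is scaled by 60.
    """
    lp = line_params(vessel, hemo, bp, poiseuille_pi=poiseuille_pi)
    mbp_cgs = mean_bp(hemo.sbp, hemo.dbp) * MMHG_TO_DYN_CM2
    return abs(mbp_cgs / lp.Z0) * 60.0


def vessel_compliance(a_max: float, a_min: float, sbp: float, dbp: float) -> float:
    """Pressure-strain compliance ``(A_max - A_min) / (SBP - DBP)`` in CGS."""
    if a_max < a_min:
        raise DomainError("a_max must be >= a_min")
    if sbp <= dbp:
        raise DomainError("pulse pressure must be positive")
    return (a_max - a_min) / ((sbp - dbp) * MMHG_TO_DYN_CM2)


def vessel_thickness(vessel: VesselState, hemo: Hemodynamics) -> float:
    """Wall thickness implied by the observed diameter pulsation.

    ``h = (1 - sigma^2) * pi * d0^3 / E * (SBP - DBP) / (d_max^2 - d_min^2)``
    with pressures in dyn/cm².
    """
    return _thickness(
        vessel.d0,
        vessel.d_max,
        vessel.d_min,
        vessel.E,
        vessel.sigma_p,
        hemo.sbp,
        hemo.dbp,
    )


def _thickness(
    d0: float,
    d_max: float,
    d_min: float,
    E: float,
    sigma_p: float,
    sbp: float,
    dbp: float,
) -> float:
    if d_max <= d_min:
        raise DomainError("d_max must exceed d_min")
    if sbp <= dbp:
        raise DomainError("pulse pressure must be positive")
    dp_cgs = (sbp - dbp) * MMHG_TO_DYN_CM2
    return (1.0 - sigma_p**2) * math.pi * d0**3 / E * dp_cgs / (d_max**2 - d_min**2)


def dos_from_geometry(d: float, D: float) -> float:
    """Degree of stenosis ``100 * (1 - d^2 / D^2)`` in percent."""
    if d <= 0:
        raise DomainError("stenotic diameter must be positive")
    if d > D:
        raise DomainError(f"stenotic diameter {d} exceeds normal diameter {D}")
    return 100.0 * (1.0 - d**2 / D**2)


def dos_from_thickness(d: float, h: float, h1: float) -> float:
    """Degree of stenosis from wall hyperplasia: normal diameter is
    ``d + 2 (h - h1)``."""
    if d <= 0:
        raise DomainError("lumen diameter must be positive")
    if h1 < 0 or h < h1:
        raise DomainError("need h >= h1 >= 0")
    return 100.0 * (1.0 - d**2 / (d + 2.0 * h - 2.0 * h1) ** 2)


# ---------------------------------------------------------------------------
# feature-space inverse maps
# ---------------------------------------------------------------------------


def _diameters_from_features(
    pi_max: float,
    pi_min: float,
    spo2: float,
    cal: CalibrationConstants,
) -> tuple[float, float, float]:
    """PI extrema -> (d_max, d_min, d0) via the optical inverse and kappa."""
    if pi_max <= pi_min:
        raise DomainError(
            f"pi_max must exceed pi_min, got {pi_max} <= {pi_min}"
        )
    if pi_min <= 0:
        raise DomainError("perfusion indices must be positive")
    oc = cal.optics()
    d_max = cal.kappa * path_from_pi(pi_max, spo2, oc)
    d_min = cal.kappa * path_from_pi(pi_min, spo2, oc)
    return d_max, d_min, 0.5 * (d_max + d_min)


def dos_from_features(
    pi_max: float,
    pi_min: float,
    spo2: float,
    sbp: float,
    dbp: float,
    cal: CalibrationConstants | None = None,
) -> float:
    """Estimate DOS (%) from the five measurable features.

    Composition: PI extrema -> pulsatile diameters (optical inverse,
    kappa), mean diameter as the lumen at the measuring spot, wall
    thickness from the pulsation, then the hyperplasia form of DOS with
    the calibrated baseline thickness ``h1``.
    """
    cal = cal or CalibrationConstants()
    d_max, d_min, d0 = _diameters_from_features(pi_max, pi_min, spo2, cal)
    h = _thickness(d0, d_max, d_min, cal.E, cal.sigma_p, sbp, dbp)
    if h < cal.h1:
        # pulsation larger than the baseline wall allows -> no hyperplasia
        return 0.0
    return dos_from_thickness(d0, h, cal.h1)


def bfv_from_features(
    pi_max: float,
    pi_min: float,
    spo2: float,
    sbp: float,
    dbp: float,
    hr_bpm: float,
    cal: CalibrationConstants | None = None,
) -> float:
    """Estimate average BFV (mL/min) from the six measurable features."""
    cal = cal or CalibrationConstants()
    d_max, d_min, d0 = _diameters_from_features(pi_max, pi_min, spo2, cal)
    h = _thickness(d0, d_max, d_min, cal.E, cal.sigma_p, sbp, dbp)
    hemo = Hemodynamics(sbp=sbp, dbp=dbp, hr_bpm=hr_bpm)
    vessel = VesselState(
        D=d_max,
        d=d0,
        d0=d0,
        h1=min(cal.h1, h),
        h2=max(h - cal.h1, 0.0),
        E=cal.E,
        sigma_p=cal.sigma_p,
        d_max=d_max,
        d_min=d_min,
    )
    return average_bfv(
        vessel, hemo, cal.blood(spo2), poiseuille_pi=cal.poiseuille_pi
    )


# ---------------------------------------------------------------------------
# forward map (vessel -> features), the exact inverse of the above
# ---------------------------------------------------------------------------


def features_from_vessel(
    dos_pct: float,
    d: float,
    hemo: Hemodynamics,
    spo2: float,
    cal: CalibrationConstants | None = None,
) -> dict[str, float]:
    """Synthesize noise-free features from a latent vessel.

    Given a stenosis level and the lumen diameter at the measuring spot,
    builds the consistent :class:`VesselState` (hyperplasia thickness from
    the stenosis geometry, pulsatile diameters from the wall mechanics)
    and returns the feature dict plus the latent truths ``dos_pct`` and
    ``bfv_ml_min``.  Exact round trip:
    ``dos_from_features(**features) == dos_pct`` and likewise for BFV, up
    to floating round-off.
    """
    cal = cal or CalibrationConstants()
    if not 0.0 <= dos_pct < 100.0:
        raise DomainError("DOS must lie in [0, 100)")
    if d <= 0:
        raise DomainError("lumen diameter must be positive")
    D = d / math.sqrt(1.0 - dos_pct / 100.0)
    h2 = 0.5 * (D - d)
    h = cal.h1 + h2
    # invert the thickness relation for the pulsatile diameter spread,
    # centred on d so that the mean diameter reproduces d exactly
    dp_cgs = (hemo.sbp - hemo.dbp) * MMHG_TO_DYN_CM2
    spread_sq = (1.0 - cal.sigma_p**2) * math.pi * d**3 / cal.E * dp_cgs / h
    half = spread_sq / (4.0 * d)
    d_max, d_min = d + half, d - half
    if d_min <= 0:
        raise DomainError("pulsation exceeds the lumen diameter; infeasible vessel")
    vessel = VesselState(
        D=D, d=d, d0=d, h1=cal.h1, h2=h2, E=cal.E, sigma_p=cal.sigma_p,
        d_max=d_max, d_min=d_min,
    )
    oc = cal.optics()
    pi_max = pi_from_path(d_max / cal.kappa, spo2, oc)
    pi_min = pi_from_path(d_min / cal.kappa, spo2, oc)
    bfv = average_bfv(
        vessel, hemo, cal.blood(spo2), poiseuille_pi=cal.poiseuille_pi
    )
    return {
        "pi_max": pi_max,
        "pi_min": pi_min,
        "spo2": spo2,
        "sbp": hemo.sbp,
        "dbp": hemo.dbp,
        "hr": hemo.hr_bpm,
        "dos_pct": dos_pct,
        "bfv_ml_min": bfv,
    }
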