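"""Flight energetics: Pennycuick-style power curve, Vmp/Vmr and a daily budget.

Mechanical power of level flapping flight is modelled as the sum of three
classical components:

* induced power   P_ind(V) = k (m g)^2 / (2 rho V S_d),  S_d = pi b^2 / 4
* parasite power  P_par(V) = rho V^3 S_b C_Db / 2,       S_b = 0.00813 m^0.666
* profile power   P_pro    = X1 * min_V (P_ind + P_par), X1 = 8.4 / Ra

with Ra = b^2 / S the aspect ratio.  Chemical power adds muscle conversion
efficiency and respiration overhead:

    P_chem(V) = R (P_mech(V) / eta) + R P_maint

where P_maint is the measured resting metabolic rate.  Vmp is the speed
minimising P_chem; Vmr maximises V / P_chem (the tangent from the origin),
the speed that maximises distance per unit energy.  Soaring-gliding
flight, which replaces muscle work with atmospheric energy, is costed as
a small multiple of the resting rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar


@dataclass
class Morphology:
    """Bird morphology; defaults describe a ~130-g small falcon."""

    mass_kg: float = 0.130
    wingspan_m: float = 0.68
    wing_area_m2: float = 0.062

    def __post_init__(self) -> None:
        if min(self.mass_kg, self.wingspan_m, self.wing_area_m2) <= 0:
            raise ValueError("morphology values must be positive")

    @property
    def aspect_ratio(self) -> float:
        return self.wingspan_m ** 2 / self.wing_area_m2

    @property
    def wing_disc_area_m2(self) -> float:
        return math.pi * self.wingspan_m ** 2 / 4.0

    @property
    def body_frontal_area_m2(self) -> float:
        return 0.00813 * self.mass_kg ** 0.666


@dataclass
class ModelConstants:
    """Aerodynamic/physiological constants (Flight-program defaults)."""

    air_density: float = 1.23        # kg/m^3
    gravity: float = 9.81            # m/s^2
    induced_power_factor: float = 1.2
    body_drag_coefficient: float = 0.1
    profile_power_constant: float = 8.4   # X1 = this / aspect ratio
    conversion_efficiency: float = 0.23
    respiration_factor: float = 1.1
    respiration_on_maintenance: bool = True


@dataclass
class EnergeticsConfig:
    """Physiological inputs of the daily energy budget."""

    resting_vo2_ml_min: float = 4.03     # measured resting O2 consumption
    o2_energy_kj_per_l: float = 20.1     # oxycaloric equivalent
    soaring_multiplier: float = 1.2      # soaring power = this x resting power
    prey_energy_kj: float = 14.98        # energy content of a typical prey item
    mean_trip_duration_min: float = 69.43


@dataclass
class PowerCurve:
    """Chemical power curve with its characteristic speeds."""

    speeds_ms: np.ndarray
    p_induced_w: np.ndarray
    p_parasite_w: np.ndarray
    p_profile_w: float
    p_mech_w: np.ndarray
    p_chem_w: np.ndarray
    vmp_ms: float
    vmr_ms: float
    p_chem_at_vmp_w: float
    p_chem_at_vmr_w: float

    @property
    def vmp_kmh(self) -> float:
        return self.vmp_ms * 3.6

    @property
    def vmr_kmh(self) -> float:
        return self.vmr_ms * 3.6


@dataclass
class EnergyBudget:
    """24-h energy ledger for one flight strategy."""

    t_forage_h: float
    t_rest_h: float
    flight_power_w: float
    resting_power_w: float
    dee_forage_kj: float
    dee_rest_kj: float
    dee_total_kj: float


def resting_power(vo2_ml_min: float = 4.03,
                  o2_energy_kj_per_l: float = 20.1) -> float:
    """Resting metabolic rate in watts from O2 consumption.

    P [W] = VO2 [mL/min] x 1e-3 [L/mL] x E [kJ/L] x 1000/60 [W per kJ/min].
    """
    if vo2_ml_min < 0 or o2_energy_kj_per_l <= 0:
        raise ValueError("inputs must be non-negative / positive")
    return vo2_ml_min * 1e-3 * o2_energy_kj_per_l * 1000.0 / 60.0


def power_curve(morph: Morphology | None = None,
                const: ModelConstants | None = None,
                maintenance_power_w: float | None = None,
                v_min: float = 2.0, v_max: float = 25.0,
                grid_step: float = 0.1) -> PowerCurve:
    """Build the chemical power curve and locate Vmp and Vmr.

    ``maintenance_power_w`` defaults to the measured resting rate computed
    from the default respirometry figures.  Both characteristic speeds are
    located on a coarse grid and refined by bounded scalar minimisation to
    ~0.01 m/s.  Raises ValueError if the curve has no interior minimum on
    the grid (implausible constants).
    """
    morph = morph or Morphology()
    const = const or ModelConstants()
    if maintenance_power_w is None:
        maintenance_power_w = resting_power()

    mg = morph.mass_kg * const.gravity
    a_ind = const.induced_power_factor * mg ** 2 / (
        2.0 * const.air_density * morph.wing_disc_area_m2)
    c_par = 0.5 * const.air_density * morph.body_frontal_area_m2 * \
        const.body_drag_coefficient

    def p_ind(v):
        return a_ind / v

    def p_par(v):
        return c_par * v ** 3

    # profile power: X1 times the absolute minimum of (induced + parasite)
    v_am = (a_ind / (3.0 * c_par)) ** 0.25
    p_am = p_ind(v_am) + p_par(v_am)
    x1 = const.profile_power_constant / morph.aspect_ratio
    p_pro = x1 * p_am

    maint = maintenance_power_w * (
        const.respiration_factor if const.respiration_on_maintenance else 1.0)

    def p_mech(v):
        return p_ind(v) + p_par(v) + p_pro

    def p_chem(v):
        return const.respiration_factor * p_mech(v) / const.conversion_efficiency + maint

    v = np.arange(v_min, v_max + grid_step / 2, grid_step)
    chem = p_chem(v)
    imin = int(np.argmin(chem))
    if imin in (0, len(v) - 1):
        raise ValueError("chemical power curve has no interior minimum: check constants")

    res = minimize_scalar(p_chem, bounds=(v[imin - 1], v[imin + 1]), method="bounded",
                          options={"xatol": 1e-4})
    vmp = float(res.x)

    # Vmr: tangent from the origin = maximum of V / P_chem
    ratio = v / chem
    imax = int(np.argmax(ratio))
    lo = v[max(imax - 1, 0)]
    hi = v[min(imax + 1, len(v) - 1)]
    res2 = minimize_scalar(lambda vv: p_chem(vv) / vv, bounds=(lo, hi),
                           method="bounded", options={"xatol": 1e-4})
    vmr = float(res2.x)

    return PowerCurve(
        speeds_ms=v,
        p_induced_w=p_ind(v),
        p_parasite_w=p_par(v),
        p_profile_w=float(p_pro),
        p_mech_w=p_mech(v),
        p_chem_w=chem,
        vmp_ms=vmp,
        vmr_ms=vmr,
        p_chem_at_vmp_w=float(p_chem(vmp)),
        p_chem_at_vmr_w=float(p_chem(vmr)),
    )


def flapping_powers(curve: PowerCurve) -> tuple[float, float]:
    """Chemical power (W) at minimum-power and maximum-range speeds."""
    return curve.p_chem_at_vmp_w, curve.p_chem_at_vmr_w


def soaring_power(p_rest_w: float, soaring_multiplier: float = 1.2) -> float:
    """Chemical power of soaring-gliding flight as a multiple of resting rate."""
    if p_rest_w <= 0 or soaring_multiplier <= 0:
        raise ValueError("inputs must be positive")
    return soaring_multiplier * p_rest_w


def trip_energy(power_w: float, duration_min: float) -> float:
    """Energy (kJ) to sustain ``power_w`` for ``duration_min`` minutes."""
    if power_w < 0 or duration_min < 0:
        raise ValueError("inputs must be non-negative")
    return power_w * duration_min * 60.0 / 1000.0


def daily_energy(t_forage_h: float, p_flight_w: float,
                 p_rest_w: float) -> EnergyBudget:
    """Daily energy expenditure ledger: foraging + resting = 24 h.

    DEE components in kJ/day: power (W) x hours x 3.6.
    """
    if not 0.0 <= t_forage_h <= 24.0:
        raise ValueError("foraging time must lie in [0, 24] h")
    t_rest = 24.0 - t_forage_h
    dee_rest = p_rest_w * t_rest * 3.6
    dee_forage = p_flight_w * t_forage_h * 3.6
    return EnergyBudget(
        t_forage_h=t_forage_h, t_rest_h=t_rest,
        flight_power_w=p_flight_w, resting_power_w=p_rest_w,
        dee_forage_kj=dee_forage, dee_rest_kj=dee_rest,
        dee_total_kj=dee_forage + dee_rest)


def prey_balance(e_trip_kj: float, e_prey_kj: float, n_trips: int = 2) -> int:
    """Smallest prey count covering the cost of ``n_trips`` foraging trips."""
    if min(e_trip_kj, e_prey_kj) <= 0 or n_trips <= 0:
        raise ValueError("inputs must be positive")
    return int(math.ceil(n_trips * e_trip_kj / e_prey_kj))
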