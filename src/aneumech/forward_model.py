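"""Reduced-order forward model of the stimulated aneurysm sac.

The sac is idealized as a spherical, incompressible, isotropic Fung-type
membrane inflated by a uniform transmural pressure.  The haemodynamic load
is reduced to a pressure program: the pulsatile outlet pressure of the
parent artery plus, while the catheter stimulus is running, the stagnation
pressure of the jet issued through the catheter lumen.  This preserves the
quantity the inverse procedure consumes -- the luminal volume change
``delta V`` as a function of the wall constants ``(a, b)`` and the load --
while keeping every step closed-form checkable.

Units: interfaces use mm, um, kPa, ml/min (converted internally to SI).

Material law
------------
Strain energy ``W = (a/b) (exp(b/2 (I1 - 3)) - 1)`` with ``a`` in kPa and
``b`` dimensionless; ``I1`` is the first invariant of the right
Cauchy-Green tensor.  For the equibiaxial sphere stretch ``lam``:
``I1 = 2 lam^2 + lam^-4``, wall Cauchy stress
``sigma = (lam/2) dW_hat/dlam = 2 (lam^2 - lam^-4) dW/dI1`` and the
thin-membrane (Laplace) equilibrium reads ``P = 2 sigma h / r`` with the
deformed radius ``r = R0 lam`` and thickness ``h = H lam^-2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConvergenceError, ValidationError

__all__ = [
    "FungMaterial",
    "FluidProperties",
    "LoadProgram",
    "SacGeometry",
    "SacState",
    "StressMetrics",
    "strain_energy",
    "first_invariant",
    "equibiaxial_stress",
    "membrane_pressure",
    "inflate_membrane",
    "unloaded_radius",
    "jet_velocity",
    "stagnation_pressure",
    "transmural_pressure",
    "delta_v_numeric",
    "stress_metrics",
    "SacForwardRunner",
]

#: maximum equibiaxial stretch searched when bracketing the equilibrium root
LAMBDA_MAX = 3.0
#: thin-wall heuristic: warn above this thickness/radius ratio
THIN_WALL_RATIO = 0.15


@dataclass(frozen=True)
class FungMaterial:
    """Constants of the isotropic incompressible Fung-like law.

    a : stiffness scale, kPa.  b : dimensionless strain-stiffening exponent.
    """

    a: float
    b: float
    density: float = 1050.0  # kg/m^3

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValidationError(f"material constants must be positive, got a={self.a}, b={self.b}")
        if self.density <= 0:
            raise ValidationError("density must be positive")


@dataclass(frozen=True)
class FluidProperties:
    density: float = 1050.0  # kg/m^3
    dynamic_viscosity: float = 0.0035  # Pa s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValidationError("fluid properties must be positive")


@dataclass(frozen=True)
class SacGeometry:
    """Reference (minimum-pressure, image-derived) sac geometry."""

    r0_mm: float
    thickness_um: float = 430.0

    def __post_init__(self) -> None:
        if self.r0_mm <= 0 or self.thickness_um <= 0:
            raise ValidationError("sac radius and wall thickness must be positive")


@dataclass(frozen=True)
class SacState:
    """Equilibrium state of the inflated sac."""

    stretch: float  # equibiaxial stretch lambda (>= 1)
    radius: float  # deformed inner radius, mm
    volume: float  # luminal volume, mm^3
    sigma1: float  # first principal Cauchy stress, kPa
    pressure: float  # transmural pressure, kPa


@dataclass(frozen=True)
class StressMetrics:
    """Stress-state summary between the baseline (C1) and stimulated (C2) states."""

    mean_sigma1_c1: float  # kPa
    mean_sigma1_c2: float  # kPa
    mean_pressure_c1: float  # kPa
    mean_pressure_c2: float  # kPa
    delta_sigma1_pct: float
    delta_pressure_pct: float


@dataclass(frozen=True)
class LoadProgram:
    """Time-resolved haemodynamic and stimulus loading.

    All series share the (strictly increasing) ``time`` grid.  Velocity in
    m/s, pressure in Pa, stimulus flow in ml/min.
    """

    time: np.ndarray
    inlet_velocity: np.ndarray
    outlet_pressure: np.ndarray
    stimulus_flow: np.ndarray
    catheter_inner_diameter: float = 1.68  # mm
    catheter_outer_diameter: float = 1.87  # mm
    period: float | None = None  # cardiac period, s (metadata)
    systole_peak_time: float | None = None  # peak phase within the cycle, s

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        object.__setattr__(self, "time", t)
        for name in ("inlet_velocity", "outlet_pressure", "stimulus_flow"):
            s = np.asarray(getattr(self, name), dtype=float)
            if s.shape != t.shape:
                raise ValidationError(f"{name} does not share the time grid")
            object.__setattr__(self, name, s)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValidationError("time grid must be 1-D and strictly increasing")
        if self.catheter_inner_diameter <= 0 or self.catheter_outer_diameter <= 0:
            raise ValidationError("catheter diameters must be positive")

    def _check_t(self, t: float) -> float:
        if not (self.time[0] <= t <= self.time[-1]):
            raise ValidationError(
                f"t={t} s outside the load program grid [{self.time[0]}, {self.time[-1]}]"
            )
        return float(t)

    def outlet_pressure_at(self, t: float) -> float:
        return float(np.interp(self._check_t(t), self.time, self.outlet_pressure))

    def stimulus_at(self, t: float) -> float:
        return float(np.interp(self._check_t(t), self.time, self.stimulus_flow))

    def inlet_velocity_at(self, t: float) -> float:
        return float(np.interp(self._check_t(t), self.time, self.inlet_velocity))

    def without_stimulus(self) -> "LoadProgram":
        """Baseline (C1) program: same haemodynamics, stimulus off."""
        return replace(self, stimulus_flow=np.zeros_like(self.stimulus_flow))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "inlet_velocity_mps": self.inlet_velocity,
                "outlet_pressure_pa": self.outlet_pressure,
                "stimulus_mlmin": self.stimulus_flow,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "LoadProgram":
        df = pd.read_csv(path)
        return cls(
            time=df["time_s"].to_numpy(),
            inlet_velocity=df["inlet_velocity_mps"].to_numpy(),
            outlet_pressure=df["outlet_pressure_pa"].to_numpy(),
            stimulus_flow=df["stimulus_mlmin"].to_numpy(),
            **kwargs,
        )


# ---------------------------------------------------------------------------
# material law


def strain_energy(i1: float, material: FungMaterial) -> float:
    """Strain energy W(I1) in kPa; domain I1 >= 3."""
    i1 = float(i1)
    if i1 < 3.0 - 1e-12:
        raise ValidationError(f"I1={i1} < 3 is not attainable for an incompressible deformation")
    a, b = material.a, material.b
    return (a / b) * np.expm1(0.5 * b * (i1 - 3.0))


def dW_dI1(i1, material: FungMaterial):
    """Derivative of the strain energy with respect to I1 (kPa)."""
    return 0.5 * material.a * np.exp(0.5 * material.b * (np.asarray(i1, dtype=float) - 3.0))


def first_invariant(stretch):
    """I1 of the equibiaxial incompressible sphere stretch."""
    lam = np.asarray(stretch, dtype=float)
    return 2.0 * lam**2 + lam**-4


def equibiaxial_stress(stretch, material: FungMaterial):
    """Cauchy stress sigma(lam) (kPa) of the equibiaxially stretched membrane.

    sigma = (lam/2) dW_hat/dlam with W_hat(lam) = W(2 lam^2 + lam^-4),
    which reduces to 2 (lam^2 - lam^-4) dW/dI1.
    """
    lam = np.asarray(stretch, dtype=float)
    return 2.0 * (lam**2 - lam**-4) * dW_dI1(first_invariant(lam), material)


def membrane_pressure(stretch, r0_mm: float, thickness_um: float, material: FungMaterial):
    """Laplace equilibrium pressure P(lam) in Pa for reference radius R0 and thickness H."""
    lam = np.asarray(stretch, dtype=float)
    h_mm = (thickness_um / 1000.0) * lam**-2
    r_mm = r0_mm * lam
    sigma_pa = equibiaxial_stress(lam, material) * 1e3
    return 2.0 * sigma_pa * h_mm / r_mm


def _bracket_and_solve(f, p_of_lam, target: float) -> float:
    """Find the first root of ``f = p_of_lam - target`` above lam=1 (stable branch)."""
    from scipy.optimize import brentq

    grid = np.linspace(1.0, LAMBDA_MAX, 2001)
    p = p_of_lam(grid)
    above = np.nonzero(p >= target)[0]
    if above.size == 0 or above[0] == 0:
        if above.size == 0:
            raise ConvergenceError(
                "no equilibrium below lambda=%.1f: pressure %.1f Pa exceeds the membrane "
                "limit pressure %.1f Pa" % (LAMBDA_MAX, target, float(np.max(p)))
            )
        return 1.0  # target <= 0 handled upstream
    i = above[0]
    return float(brentq(f, grid[i - 1], grid[i], xtol=1e-14, rtol=8.9e-16, maxiter=200))


def inflate_membrane(
    r0_mm: float,
    thickness_um: float,
    material: FungMaterial,
    pressure_pa: float,
) -> SacState:
    """Solve the spherical-membrane equilibrium at transmural pressure P (Pa).

    Returns the unique state on the stable ascending branch of the
    pressure-stretch curve.  Raises :class:`ConvergenceError` (naming the
    limit pressure) when P lies beyond the membrane limit point.
    """
    if r0_mm <= 0 or thickness_um <= 0:
        raise ValidationError("radius and thickness must be positive")
    if pressure_pa < 0:
        raise ValidationError("transmural pressure must be non-negative")
    if thickness_um / 1000.0 / r0_mm > THIN_WALL_RATIO:
        warnings.warn(
            f"thin-wall assumption is marginal: H/R0 = {thickness_um / 1000.0 / r0_mm:.2f}",
            stacklevel=2,
        )
    if pressure_pa == 0.0:
        lam = 1.0
    else:
        p_of_lam = lambda g: membrane_pressure(g, r0_mm, thickness_um, material)
        f = lambda g: membrane_pressure(g, r0_mm, thickness_um, material) - pressure_pa
        lam = _bracket_and_solve(f, p_of_lam, pressure_pa)
    radius = r0_mm * lam
    return SacState(
        stretch=lam,
        radius=radius,
        volume=4.0 / 3.0 * np.pi * radius**3,
        sigma1=float(equibiaxial_stress(lam, material)),
        pressure=pressure_pa / 1e3,
    )


def unloaded_radius(
    observed_radius_mm: float,
    thickness_um: float,
    material: FungMaterial,
    pressure_pa: float,
) -> float:
    """Reference radius R0 whose inflation at P reproduces the observed radius.

    Substituting ``R0 = r_obs / lam`` into the Laplace equilibrium removes R0
    from the stretch equation, leaving a scalar root in lam:
    ``2 sigma(lam) H lam^-2 / r_obs = P``.
    """
    from scipy.optimize import brentq

    if observed_radius_mm <= 0:
        raise ValidationError("observed radius must be positive")
    if pressure_pa <= 0:
        return observed_radius_mm

    def f(lam):
        h_mm = (thickness_um / 1000.0) * lam**-2
        return 2.0 * equibiaxial_stress(lam, material) * 1e3 * h_mm / observed_radius_mm - pressure_pa

    lo = 1.0 + 1e-12
    hi = 1.5
    while f(hi) < 0 and hi < LAMBDA_MAX:
        hi = min(hi + 0.5, LAMBDA_MAX)
    if f(hi) < 0:
        raise ConvergenceError("could not invert the observed radius for R0")
    lam = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)
    return observed_radius_mm / lam


# ---------------------------------------------------------------------------
# load reduction


def jet_velocity(flow_mlmin: float, inner_diameter_mm: float) -> float:
    """Mean jet velocity (m/s) through the catheter lumen for a flow in ml/min."""
    if inner_diameter_mm <= 0:
        raise ValidationError("catheter inner diameter must be positive")
    q = flow_mlmin * 1e-6 / 60.0  # m^3/s
    area = np.pi * (inner_diameter_mm * 1e-3 / 2.0) ** 2
    return q / area


def stagnation_pressure(flow_mlmin: float, inner_diameter_mm: float, fluid: FluidProperties) -> float:
    """Dynamic (stagnation) pressure 1/2 rho v_jet^2 in Pa."""
    v = jet_velocity(flow_mlmin, inner_diameter_mm)
    return 0.5 * fluid.density * v * v


def transmural_pressure(load: LoadProgram, fluid: FluidProperties, t: float) -> float:
    """Uniform transmural pressure on the sac wall at time t (Pa).

    Outlet pressure plus the stagnation pressure of the catheter jet; with
    the stimulus off this reduces to the outlet pressure exactly.
    """
    p = load.outlet_pressure_at(t)
    q = load.stimulus_at(t)
    if q > 0:
        p += stagnation_pressure(q, load.catheter_inner_diameter, fluid)
    return p


def delta_v_numeric(
    geometry: SacGeometry,
    material: FungMaterial,
    load: LoadProgram,
    t1: float,
    t2: float,
    fluid: FluidProperties | None = None,
) -> float:
    """Luminal volume change (mm^3) between the baseline state at t1 and the
    stimulated state at t2.

    The baseline (C1) pressure is evaluated with the stimulus switched off,
    the stimulated (C2) pressure with the full load program.
    """
    fluid = fluid or FluidProperties()
    p1 = transmural_pressure(load.without_stimulus(), fluid, t1)
    p2 = transmural_pressure(load, fluid, t2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s1 = inflate_membrane(geometry.r0_mm, geometry.thickness_um, material, p1)
        s2 = inflate_membrane(geometry.r0_mm, geometry.thickness_um, material, p2)
    return s2.volume - s1.volume


def stress_metrics(state_c1: SacState, state_c2: SacState) -> StressMetrics:
    """Mean first principal Cauchy stress and pressure on the aneurysm wall,
    with their relative C1->C2 variations in percent.

    For the idealized spherical sac the area mean equals the uniform
    membrane value, so the means are the states' sigma1 and pressure.
    """
    if state_c1.sigma1 == 0 and state_c2.sigma1 != 0:
        raise ValidationError("stress variation undefined: zero C1 stress with non-zero C2 stress")
    if state_c1.pressure == 0 and state_c2.pressure != 0:
        raise ValidationError("pressure variation undefined: zero C1 pressure with non-zero C2 pressure")
    dsig = 0.0 if state_c1.sigma1 == state_c2.sigma1 else (
        (state_c2.sigma1 - state_c1.sigma1) / state_c1.sigma1 * 100.0
    )
    dp = 0.0 if state_c1.pressure == state_c2.pressure else (
        (state_c2.pressure - state_c1.pressure) / state_c1.pressure * 100.0
    )
    return StressMetrics(
        mean_sigma1_c1=state_c1.sigma1,
        mean_sigma1_c2=state_c2.sigma1,
        mean_pressure_c1=state_c1.pressure,
        mean_pressure_c2=state_c2.pressure,
        delta_sigma1_pct=dsig,
        delta_pressure_pct=dp,
    )


# ---------------------------------------------------------------------------
# multi-flow runner consumed by the inverse engine


@dataclass
class SacForwardRunner:
    """Evaluates delta V_num(a, b; t1, t2) for each stimulus flow rate.

    Two anchoring modes for the reference configuration:

    - ``r0_mm`` given: the reference radius is known (synthetic closed loop).
    - ``c1_volume_mm3`` given: the baseline image fixes the C1 luminal
      volume; for every candidate (a, b) and baseline pressure the reference
      radius is recovered with :func:`unloaded_radius`, mirroring the
      per-couple baseline models of the original procedure.
    """

    loads: Mapping[float, LoadProgram]  # flow rate (ml/min) -> C2 load program
    thickness_um: float = 430.0
    r0_mm: float | None = None
    c1_volume_mm3: float | None = None
    fluid: FluidProperties = field(default_factory=FluidProperties)

    def __post_init__(self) -> None:
        if (self.r0_mm is None) == (self.c1_volume_mm3 is None):
            raise ValidationError("provide exactly one of r0_mm or c1_volume_mm3")
        if not self.loads:
            raise ValidationError("at least one load program is required")

    @property
    def flows(self) -> Sequence[float]:
        return sorted(self.loads)

    def _states(self, flow: float, a: float, b: float, t1: float, t2: float):
        load = self.loads[flow]
        mat = FungMaterial(a=a, b=b)
        p1 = transmural_pressure(load.without_stimulus(), self.fluid, t1)
        p2 = transmural_pressure(load, self.fluid, t2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if self.r0_mm is not None:
                r0 = self.r0_mm
            else:
                r_obs = (3.0 * self.c1_volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
                r0 = unloaded_radius(r_obs, self.thickness_um, mat, p1)
            s1 = inflate_membrane(r0, self.thickness_um, mat, p1)
            s2 = inflate_membrane(r0, self.thickness_um, mat, p2)
        return s1, s2

    def delta_v(self, flow: float, a: float, b: float, t1: float, t2: float) -> float:
        s1, s2 = self._states(flow, a, b, t1, t2)
        return s2.volume - s1.volume

    def sac_states(self, flow: float, a: float, b: float, t1: float, t2: float):
        """(C1 state, C2 state) at the given times; used for stress metrics."""
        return self._states(flow, a, b, t1, t2)

    def sample(self, flow: float, couples, t1: float, t2: float) -> np.ndarray:
        """delta V_num for an iterable of (a, b) couples."""
        return np.array([self.delta_v(flow, a, b, t1, t2) for a, b in couples])
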