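"""Phantom generator: masks, waveforms and stimulus pulses with known truth.

Emulates photon-counting-CT-resolution (0.25 mm isotropic) binary lumen
segmentations of a parent vessel carrying a saccular bulge, whose
stimulated-state (C2) deformation is produced by this package's own
membrane forward model at known ground-truth wall constants ``(a, b)``.
Every downstream stage is therefore testable without any acquisition.

The cardiac waveform is a piecewise half-sine systolic peak over a
diastolic baseline (peak value, period and peak phase are exact by
construction); the stimulus is a trapezoidal flow pulse.  A voxel is lumen
when its center lies inside the analytic surface (center sampling).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ValidationError
from .forward_model import (
    FluidProperties,
    FungMaterial,
    LoadProgram,
    inflate_membrane,
    transmural_pressure,
)
from .volumetry import RegionDelimitation, SegmentationMask

__all__ = [
    "PhantomSpec",
    "WaveformSpec",
    "StimulusSpec",
    "Waveform",
    "PhantomGroundTruth",
    "generate_waveform",
    "generate_stimulus",
    "build_load_program",
    "default_acquisition_times",
    "generate_phantom_pair",
    "voxelize",
]


@dataclass(frozen=True)
class WaveformSpec:
    """Simplified pulsatile cardiac waveform parameters.

    The systolic half-sine spans ``systole_fraction`` of the cycle with its
    peak at ``systole_fraction / 2``; the remainder of the cycle is the
    diastolic baseline.  Defaults: 200 beats/min (anaesthetized rabbit),
    0.35 m/s systolic peak velocity, outlet pressure 5732-13865 Pa.
    """

    heart_rate: float = 200.0  # beats/min
    peak_velocity: float = 0.35  # m/s
    diastolic_velocity: float = 0.08  # m/s baseline
    outlet_pressure_min: float = 5732.0  # Pa
    outlet_pressure_max: float = 13865.0  # Pa
    n_samples_per_cycle: int = 300
    systole_fraction: float = 0.5  # fraction of the cycle occupied by systole

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ValidationError("heart rate must be positive")
        if self.peak_velocity <= 0 or not (0 <= self.diastolic_velocity < self.peak_velocity):
            raise ValidationError("require 0 <= diastolic velocity < peak velocity")
        if self.outlet_pressure_min >= self.outlet_pressure_max:
            raise ValidationError("outlet pressure range must be increasing")
        if int(self.n_samples_per_cycle) < 4:
            raise ValidationError("need at least 4 samples per cycle")
        if not (0 < self.systole_fraction < 1):
            raise ValidationError("systole fraction must lie in (0, 1)")

    @property
    def period(self) -> float:
        """Cardiac period in s (60 / heart rate)."""
        return 60.0 / self.heart_rate

    @property
    def systole_peak_time(self) -> float:
        """Systole-peak phase (s after start-systole at t=0)."""
        return self.systole_fraction * self.period / 2.0


@dataclass(frozen=True)
class StimulusSpec:
    """Trapezoidal catheter flow pulse (ml/min)."""

    flow_rate: float  # ml/min, e.g. 150/170/190
    duration: float = 3.0  # s at plateau+up-ramp
    onset_time: float = 0.5  # s
    ramp_time: float = 0.1  # s

    def __post_init__(self) -> None:
        if self.flow_rate <= 0:
            raise ValidationError("flow rate must be positive")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        if not (0 <= self.ramp_time < self.duration):
            raise ValidationError("ramp time must satisfy 0 <= ramp < duration")
        if self.onset_time < 0:
            raise ValidationError("onset time must be non-negative")


@dataclass(frozen=True)
class PhantomSpec:
    """Parent vessel + saccular bulge phantom.

    ``sac_radius`` is the reference (zero-transmural-pressure) sac radius;
    the generated C1/C2 masks carry the sac inflated by the membrane model
    at the acquisition-time pressures.  Lengths in mm, thickness in um.
    """

    parent_vessel_radius: float = 1.5
    parent_vessel_length: float = 12.0
    sac_radius: float = 2.0
    sac_neck_radius: float = 1.0
    voxel_size: float = 0.25  # mm, imaging resolution
    wall_thickness: float = 430.0  # um
    material_truth: FungMaterial = field(default_factory=lambda: FungMaterial(a=353.6, b=16.7))
    noise_level: float = 0.0  # fraction of boundary voxels flipped
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("parent_vessel_radius", "parent_vessel_length", "sac_radius", "sac_neck_radius", "voxel_size"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.sac_neck_radius >= self.sac_radius:
            raise ValidationError("sac neck radius must be smaller than the sac radius")
        if not (0 <= self.noise_level < 0.1):
            raise ValidationError("noise level must lie in [0, 0.1)")
        if self.wall_thickness <= 0:
            raise ValidationError("wall thickness must be positive")
        if self.sac_radius < 3.0 * self.voxel_size:
            raise ValidationError("voxel grid too coarse to resolve the sac (sac_radius < 3 voxels)")


@dataclass(frozen=True)
class Waveform:
    """Sampled periodic series over an integer number of cycles."""

    time: np.ndarray
    inlet_velocity: np.ndarray
    outlet_pressure: np.ndarray
    period: float
    systole_peak_time: float

    def to_csv(self, path, column: str = "inlet_velocity_mps") -> None:
        pd.DataFrame({"time_s": self.time, column: self.inlet_velocity}).to_csv(path, index=False)


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Known truth recorded alongside a generated phantom pair."""

    a: float
    b: float
    true_delta_v: float  # analytic sac volume change, mm^3
    t1: float
    t2: float
    pressure_c1: float  # Pa
    pressure_c2: float  # Pa
    stretch_c1: float
    stretch_c2: float
    sac_radius_c1: float  # mm, inflated
    sac_radius_c2: float  # mm
    sac_center: tuple[float, float, float]
    neck_plane_z: float  # world z of the artery/aneurysm cut plane
    seed: int

    def cut_plane(self) -> RegionDelimitation:
        return RegionDelimitation(point=(0.0, 0.0, self.neck_plane_z), normal=(0.0, 0.0, 1.0), side=1)

    def to_json(self, path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path) -> "PhantomGroundTruth":
        d = json.loads(Path(path).read_text())
        d["sac_center"] = tuple(d["sac_center"])
        return cls(**d)


# ---------------------------------------------------------------------------
# waveforms


def _pulse_shape(phase: np.ndarray, systole_fraction: float) -> np.ndarray:
    """Normalized cycle shape in [0, 1]: half-sine systole, zero diastole."""
    phase = np.mod(phase, 1.0)
    s = np.zeros_like(phase)
    in_sys = phase < systole_fraction
    s[in_sys] = np.sin(np.pi * phase[in_sys] / systole_fraction) ** 2
    return s


def generate_waveform(spec: WaveformSpec, n_cycles: int = 1) -> Waveform:
    """Sample the cardiac waveform over ``n_cycles`` cycles.

    Velocity peaks at exactly ``peak_velocity`` at the systole-peak phase
    and the outlet pressure attains exactly its configured bounds whenever
    the peak phase falls on the sampling grid (true for the defaults).
    """
    if n_cycles < 1:
        raise ValidationError("need at least one cycle")
    n = int(spec.n_samples_per_cycle)
    t = np.arange(n * n_cycles) * (spec.period / n)
    # sample one cycle and tile it: periodicity is then exact in floating point
    s = np.tile(_pulse_shape(np.arange(n) / n, spec.systole_fraction), n_cycles)
    vel = spec.diastolic_velocity + (spec.peak_velocity - spec.diastolic_velocity) * s
    pre = spec.outlet_pressure_min + (spec.outlet_pressure_max - spec.outlet_pressure_min) * s
    return Waveform(
        time=t,
        inlet_velocity=vel,
        outlet_pressure=pre,
        period=spec.period,
        systole_peak_time=spec.systole_peak_time,
    )


def generate_stimulus(spec: StimulusSpec, time: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Trapezoidal stimulus flow series (ml/min) on ``time`` (s).

    Zero before onset, linear up-ramp of ``ramp_time``, plateau at
    ``flow_rate`` until ``onset + duration``, mirrored down-ramp after; the
    time integral equals ``flow_rate * duration`` exactly.
    """
    if time is None:
        end = spec.onset_time + spec.duration + spec.ramp_time + 0.5
        time = np.arange(0.0, end, 1e-3)
    t = np.asarray(time, dtype=float)
    t0, tr, td = spec.onset_time, spec.ramp_time, spec.duration
    q = np.zeros_like(t)
    if tr > 0:
        rising = (t >= t0) & (t < t0 + tr)
        q[rising] = spec.flow_rate * (t[rising] - t0) / tr
        falling = (t >= t0 + td) & (t < t0 + td + tr)
        q[falling] = spec.flow_rate * (1.0 - (t[falling] - t0 - td) / tr)
        plateau = (t >= t0 + tr) & (t < t0 + td)
    else:
        plateau = (t >= t0) & (t < t0 + td)
    q[plateau] = spec.flow_rate
    return t, q


def build_load_program(
    waveform_spec: WaveformSpec,
    stimulus_spec: StimulusSpec | None,
    n_cycles: int | None = None,
    catheter_inner_diameter: float = 1.68,
    catheter_outer_diameter: float = 1.87,
) -> LoadProgram:
    """Assemble a LoadProgram covering the stimulus (or one cycle if none)."""
    if n_cycles is None:
        horizon = 1.0 if stimulus_spec is None else (
            stimulus_spec.onset_time + stimulus_spec.duration + stimulus_spec.ramp_time + 0.5
        )
        n_cycles = max(1, int(np.ceil(horizon / waveform_spec.period)))
    wave = generate_waveform(waveform_spec, n_cycles=n_cycles)
    if stimulus_spec is None:
        stim = np.zeros_like(wave.time)
    else:
        _, stim = generate_stimulus(stimulus_spec, wave.time)
    return LoadProgram(
        time=wave.time,
        inlet_velocity=wave.inlet_velocity,
        outlet_pressure=wave.outlet_pressure,
        stimulus_flow=stim,
        catheter_inner_diameter=catheter_inner_diameter,
        catheter_outer_diameter=catheter_outer_diameter,
        period=wave.period,
        systole_peak_time=wave.systole_peak_time,
    )


def default_acquisition_times(
    waveform_spec: WaveformSpec, stimulus_spec: StimulusSpec, delta_t: float = 0.0
) -> tuple[float, float]:
    """(t1, t2) acquisition instants.

    t2 is the first systole peak at least 2 s after the stimulus trigger
    (within the plateau); t1 is the baseline instant at the cardiac phase
    ``t2 - delta_t`` folded into one cycle.
    """
    T = waveform_spec.period
    peak = waveform_spec.systole_peak_time
    target = stimulus_spec.onset_time + 2.0
    k = int(np.ceil((target - peak) / T))
    t2 = k * T + peak
    t1 = np.mod(t2 - delta_t, T)
    return float(t1), float(t2)


# ---------------------------------------------------------------------------
# phantom voxelization


def voxelize(inside_fn, bounds_lo, bounds_hi, voxel_size: float) -> SegmentationMask:
    """Voxelize an implicit solid: a voxel is lumen when its center is inside.

    World frame in mm; identity orientation; the affine maps voxel indices
    to voxel-center world coordinates.
    """
    lo = np.asarray(bounds_lo, dtype=float)
    hi = np.asarray(bounds_hi, dtype=float)
    shape = np.ceil((hi - lo) / voxel_size).astype(int)
    axes = [lo[k] + (np.arange(shape[k]) + 0.5) * voxel_size for k in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    occ = inside_fn(X, Y, Z).astype(np.uint8)
    affine = np.diag([voxel_size] * 3 + [1.0])
    affine[:3, 3] = lo + 0.5 * voxel_size
    return SegmentationMask(occupancy=occ, voxel_size=(voxel_size,) * 3, affine=affine)


def _phantom_inside(spec: PhantomSpec, sac_radius: float, sac_center_z: float):
    """Implicit solid: parent tube along x plus the sac sphere on +z."""
    rp = spec.parent_vessel_radius
    half_l = spec.parent_vessel_length / 2.0

    def inside(x, y, z):
        tube = (y**2 + z**2 <= rp**2) & (np.abs(x) <= half_l)
        sac = x**2 + y**2 + (z - sac_center_z) ** 2 <= sac_radius**2
        return tube | sac

    return inside


def _apply_boundary_noise(occ: np.ndarray, noise_level: float, rng: np.random.Generator) -> np.ndarray:
    """Flip a fraction of the voxels within one voxel of the lumen boundary."""
    if noise_level <= 0:
        return occ
    m = occ.astype(bool)
    inner = m & ~ndimage.binary_erosion(m)
    outer = ndimage.binary_dilation(m) & ~m
    candidates = np.argwhere(inner | outer)
    n_flip = int(round(noise_level * len(candidates)))
    if n_flip == 0:
        return occ
    pick = rng.choice(len(candidates), size=n_flip, replace=False)
    out = occ.copy()
    ijk = candidates[pick]
    out[ijk[:, 0], ijk[:, 1], ijk[:, 2]] ^= 1
    return out


def generate_phantom_pair(
    spec: PhantomSpec,
    load_c2: LoadProgram,
    t1: float | None = None,
    t2: float | None = None,
    fluid: FluidProperties | None = None,
) -> tuple[SegmentationMask, SegmentationMask, PhantomGroundTruth]:
    """Generate (C1 mask, C2 mask, ground truth) for a phantom under load.

    C1 is the lumen at the baseline transmural pressure (stimulus off) at
    t1; C2 is the lumen with the sac inflated under the full load at t2.
    Both are voxelized on the same world grid.  The recorded true delta V
    is the analytic sac (sphere) volume change.
    """
    fluid = fluid or FluidProperties()
    if t2 is None:
        peak = load_c2.systole_peak_time if load_c2.systole_peak_time is not None else 0.0
        T = load_c2.period if load_c2.period is not None else (load_c2.time[-1] - load_c2.time[0])
        stim_on = load_c2.time[load_c2.stimulus_flow > 0]
        start = stim_on[0] if stim_on.size else load_c2.time[0]
        k = int(np.ceil((start + 2.0 - peak) / T))
        t2 = k * T + peak
        t2 = min(t2, float(load_c2.time[-1]))
    if t1 is None:
        T = load_c2.period if load_c2.period is not None else (load_c2.time[-1] - load_c2.time[0])
        t1 = float(np.mod(t2, T))

    import warnings as _warnings

    p1 = transmural_pressure(load_c2.without_stimulus(), fluid, t1)
    p2 = transmural_pressure(load_c2, fluid, t2)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        s1 = inflate_membrane(spec.sac_radius, spec.wall_thickness, spec.material_truth, p1)
        s2 = inflate_membrane(spec.sac_radius, spec.wall_thickness, spec.material_truth, p2)

    # sac center fixed by the C1 (imaged) state: the sphere crosses the
    # tube-top plane z = rp with a cross-section of the neck radius
    rp = spec.parent_vessel_radius
    zc = rp + float(np.sqrt(max(s1.radius**2 - spec.sac_neck_radius**2, 0.0)))
    r_max = s2.radius if s2.radius > s1.radius else s1.radius
    margin = 3.0 * spec.voxel_size
    lo = (
        -spec.parent_vessel_length / 2.0 - margin,
        -max(rp, r_max) - margin,
        -rp - margin,
    )
    hi = (
        spec.parent_vessel_length / 2.0 + margin,
        max(rp, r_max) + margin,
        zc + r_max + margin,
    )

    rng = np.random.default_rng(spec.seed)
    masks = []
    for tag, radius in (("C1", s1.radius), ("C2", s2.radius)):
        m = voxelize(_phantom_inside(spec, radius, zc), lo, hi, spec.voxel_size)
        m.occupancy = _apply_boundary_noise(m.occupancy, spec.noise_level, rng)
        m.label = tag
        masks.append(m)

    truth = PhantomGroundTruth(
        a=spec.material_truth.a,
        b=spec.material_truth.b,
        true_delta_v=s2.volume - s1.volume,
        t1=float(t1),
        t2=float(t2),
        pressure_c1=p1,
        pressure_c2=p2,
        stretch_c1=s1.stretch,
        stretch_c2=s2.stretch,
        sac_radius_c1=s1.radius,
        sac_radius_c2=s2.radius,
        sac_center=(0.0, 0.0, zc),
        neck_plane_z=rp,
        seed=spec.seed,
    )
    return masks[0], masks[1], truth
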