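"""Axisymmetric transient Pennes bioheat model of mild moxibustion.

A burning moxa stick held at height ``h`` above the skin heats a three-layer
tissue column (skin / fat / muscle) by thermal radiation.  The tissue obeys
the Pennes bioheat equation

    rho*c dT/dt = div(k grad T) + w_b*rho_b*C_b*(T_b - T) + q_m

with the net radiative flux from the moxa tip as the top boundary condition
(convection is neglected: the tip is a high-temperature source and the skin
boundary layer is thin compared with the radiative exchange).  The domain is
a cylinder, axisymmetric in (r, z): z = 0 at the skin surface increasing
downward, r = 0 on the moxibustion axis.

Two scalar efficacy indicators are extracted from each run:

* ``ST``  — peak on-axis skin-surface temperature (safety: must stay below
  the 45.5 degC comfort allowable),
* ``HPM`` — peak on-axis temperature 5 mm below the surface (thermal
  penetration, the efficacy measure).

The solver is finite-volume in space (cell-centred, per-layer uniform z
spacing so every layer boundary falls on a cell face) and backward-Euler in
time with the nonlinear T^4 surface flux handled by fixed-point iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu

__all__ = [
    "TissueLayer",
    "SkinThermalProperties",
    "MoxaSource",
    "SimulationConfig",
    "TemperatureField",
    "IndicatorResult",
    "skin_properties_from_moisture",
    "moxa_temperature",
    "disk_view_factor",
    "radiative_surface_flux",
    "run_simulation",
    "extract_indicators",
    "single_factor_analysis",
    "simulate_indicators",
    "coarse_config",
    "default_config",
]

STEFAN_BOLTZMANN = 5.67e-8  # W m^-2 K^-4
KELVIN_OFFSET = 273.15
BLOOD_DENSITY = 1060.0  # kg m^-3

# Moxibustion operating-parameter names used across the pipeline:
# t1 (degC), d (mm, stick diameter), h (mm, stick-to-skin distance),
# omega_c (percent skin moisture).
PARAMETER_NAMES = ("t1", "d", "h", "omega_c")


# ---------------------------------------------------------------------------
# Tissue and source descriptions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueLayer:
    """One horizontal tissue layer with Pennes-equation material constants."""

    name: str
    thickness: float            # mm
    density: float              # kg m^-3
    heat_capacity: float        # J kg^-1 K^-1
    conductivity: float         # W m^-1 K^-1
    perfusion: float = 5.0e-4   # s^-1, volumetric blood perfusion
    metabolic_heat: float = 420.0  # W m^-3

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"layer {self.name!r}: thickness must be > 0")
        if min(self.density, self.heat_capacity, self.conductivity) <= 0:
            raise ValueError(f"layer {self.name!r}: rho, c, k must be > 0")
        if self.perfusion < 0 or self.metabolic_heat < 0:
            raise ValueError(f"layer {self.name!r}: perfusion and q_m must be >= 0")


@dataclass(frozen=True)
class SkinThermalProperties:
    """Moisture-dependent skin thermophysics (density, heat capacity, conductivity)."""

    density: float        # kg m^-3
    heat_capacity: float  # J kg^-1 K^-1
    conductivity: float   # W m^-1 K^-1


def skin_properties_from_moisture(omega_c: float) -> SkinThermalProperties:
    """Skin thermophysical properties as a function of water content.

    ``omega_c`` is the skin moisture content as a *fraction* in (0, 1) —
    tabulated levels are usually printed in percent, divide by 100 first.

    The fits (density in g cm^-3 internally)::

        rho = 1.3 - 0.3*omega_c                     [g cm^-3]
        c   = 4.19*(0.37 + 0.67*omega_c/rho)        [kJ kg^-1 K^-1]
        k   = 0.419*(0.133 + 1.36*omega_c/rho)      [W m^-1 K^-1]

    reproduce the standard tabulated values (e.g. 40% water: 1180 kg m^-3,
    2502 J kg^-1 K^-1, 0.25 W m^-1 K^-1).  Wetter skin is denser in heat
    capacity and conductivity but lighter in density.
    """
    if not 0.0 < omega_c < 1.0:
        raise ValueError(
            f"omega_c must be a fraction in (0, 1), got {omega_c!r} "
            "(moisture tables print percent; divide by 100)"
        )
    rho_gcc = 1.3 - 0.3 * omega_c
    c = 4.19 * (0.37 + 0.67 * omega_c / rho_gcc) * 1000.0
    k = 0.419 * (0.133 + 1.36 * omega_c / rho_gcc)
    return SkinThermalProperties(density=rho_gcc * 1000.0, heat_capacity=c, conductivity=k)


@dataclass(frozen=True)
class MoxaSource:
    """The burning moxa tip, modelled as a radiating disk parallel to the skin.

    The tip temperature follows a simple harmonic between the maximum burn
    temperature ``t1`` and the ash-gathering floor temperature, emulating the
    burn / ash-gather cycle.  The hemispherical tip is reduced to its
    projected disk (diameter ``d``) for the view-factor computation.
    """

    t1: float = 600.0            # degC, maximum burning temperature
    d: float = 15.0              # mm, stick diameter
    h: float = 30.0              # mm, gap between the glowing tip and the skin
    floor_temp: float = 200.0    # degC, temperature at ash gathering
    period: float = 500.0        # s, burn/ash-gather cycle
    emissivity: float = 0.95     # skin surface emissivity
    reflectance: float = 0.05    # rho_d = 1 - emissivity
    source_emissivity: float = 0.85  # ash-covered glowing tip
    ambient_temp: float = 25.0   # degC, surroundings seen through 1 - F
    refractive_index: float = 1.0
    stefan_boltzmann: float = STEFAN_BOLTZMANN
    ash_dip: bool = False        # optional: drop to 50 degC during ash cleaning
    ash_dip_temp: float = 50.0   # degC
    ash_dip_every: float = 60.0  # s
    ash_dip_duration: float = 2.0  # s

    def __post_init__(self) -> None:
        if not self.t1 > self.floor_temp >= 0:
            raise ValueError("need t1 > floor_temp >= 0")
        if self.d <= 0 or self.h <= 0:
            raise ValueError("stick diameter and skin distance must be > 0")
        if not 0.0 <= self.emissivity <= 1.0:
            raise ValueError("emissivity must lie in [0, 1]")
        if self.refractive_index != 1.0:
            raise ValueError("only a transparent medium (n = 1) is supported")


def moxa_temperature(t: float | np.ndarray, source: MoxaSource | None = None) -> float | np.ndarray:
    """Moxa tip temperature (degC) at time ``t`` (s).

    Harmonic model ``T_a(t) = mean + amplitude*cos(2*pi*t/period)`` with
    ``mean = (t1 + floor)/2`` and ``amplitude = (t1 - floor)/2``; the default
    source (t1=600, floor=200, period=500 s) gives
    ``T_a = 400 + 200*cos(2*pi*t/500)``.
    """
    if source is None:
        source = MoxaSource()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    mean = 0.5 * (source.t1 + source.floor_temp)
    amp = 0.5 * (source.t1 - source.floor_temp)
    temp = mean + amp * np.cos(2.0 * np.pi * t / source.period)
    if source.ash_dip:
        in_dip = (t % source.ash_dip_every) < source.ash_dip_duration
        temp = np.where(in_dip, source.ash_dip_temp, temp)
    return float(temp) if temp.ndim == 0 else temp


_GAUSS_NODES, _GAUSS_WEIGHTS = leggauss(64)


def disk_view_factor(r: np.ndarray | float, disk_radius: float, height: float) -> np.ndarray | float:
    """View factor from a surface element at radial offset ``r`` to a coaxial
    parallel disk of radius ``disk_radius`` at ``height`` above the plane.

    Computed by Gauss-Legendre quadrature of the diffuse view-factor kernel
    (the azimuthal integral is closed-form); on axis it reduces to
    ``R^2 / (R^2 + h^2)``.  All lengths in consistent units.
    """
    if disk_radius <= 0 or height <= 0:
        raise ValueError("disk radius and height must be > 0")
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    # integrate 2 h^2 * rho * a / (a^2 - b^2)^(3/2) over rho in (0, R),
    # a = h^2 + r^2 + rho^2, b = 2 r rho
    rho = 0.5 * disk_radius * (_GAUSS_NODES + 1.0)          # (q,)
    w = 0.5 * disk_radius * _GAUSS_WEIGHTS
    a = height**2 + r[:, None] ** 2 + rho[None, :] ** 2     # (n, q)
    b = 2.0 * r[:, None] * rho[None, :]
    integrand = rho[None, :] * a / np.power(a**2 - b**2, 1.5)
    F = 2.0 * height**2 * (integrand @ w)
    return float(F[0]) if scalar else F


def source_view_factor(r: np.ndarray | float, source: MoxaSource) -> np.ndarray | float:
    """View factor from a skin element at radius ``r`` (mm) to the glowing tip.

    The hemispherical burning head is represented by its great-circle disk
    (radius ``d/2``); since ``h`` is the gap between the *closest point* of
    the tip and the skin, that disk sits at height ``h + d/2``.
    """
    return disk_view_factor(r, 0.5 * source.d, source.h + 0.5 * source.d)


def radiative_surface_flux(
    r: np.ndarray | float,
    surface_temp: np.ndarray | float,
    moxa_temp: float,
    source: MoxaSource,
) -> np.ndarray | float:
    """Net flux (W m^-2) absorbed from the moxa tip at radial offset ``r`` (mm).

    ``q(r) = eps_skin * eps_tip * sigma * (T_a^4 - T_s^4) * F(r)`` with
    temperatures in kelvin and ``F`` the tip view factor.  Positive toward
    the tissue; vanishes at radiative equilibrium (``T_a = T_s``) and as the
    stick is withdrawn (``h -> inf``).  Exchange with the surroundings
    through ``1 - F`` is a separate term (:func:`ambient_surface_flux`).
    """
    Ta = np.asarray(moxa_temp, dtype=float) + KELVIN_OFFSET
    Ts = np.asarray(surface_temp, dtype=float) + KELVIN_OFFSET
    if np.any(Ta < 0) or np.any(Ts < 0):
        raise ValueError("temperatures below absolute zero")
    F = source_view_factor(r, source)
    n2 = source.refractive_index**2
    eff = source.emissivity * source.source_emissivity
    return eff * source.stefan_boltzmann * n2 * (Ta**4 - Ts**4) * F


def ambient_surface_flux(
    r: np.ndarray | float, surface_temp: np.ndarray | float, source: MoxaSource
) -> np.ndarray | float:
    """Net flux (W m^-2) exchanged with the surroundings through ``1 - F``.

    Gray-diffuse exchange with an ambient enclosure at ``source.ambient_temp``
    — negative (cooling) wherever the skin is warmer than the room, which is
    what keeps the heated spot localized.
    """
    Ts = np.asarray(surface_temp, dtype=float) + KELVIN_OFFSET
    Tamb = source.ambient_temp + KELVIN_OFFSET
    F = source_view_factor(r, source)
    return source.emissivity * source.stefan_boltzmann * (1.0 - F) * (Tamb**4 - Ts**4)


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

def _default_layers() -> tuple[TissueLayer, ...]:
    # skin properties are re-derived from skin_moisture at run time
    skin = skin_properties_from_moisture(0.405)
    # perfusion: vasodilated (heated) skin, poorly perfused fat, resting muscle
    return (
        TissueLayer("skin", 2.2, skin.density, skin.heat_capacity, skin.conductivity,
                    perfusion=2.0e-3),
        TissueLayer("fat", 12.4, 911.0, 2348.0, 0.21, perfusion=5.0e-4),
        TissueLayer("muscle", 10.4, 1090.0, 3421.0, 0.49, perfusion=1.0e-3),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed for one bioheat run (lengths mm, times s, temps degC)."""

    layers: tuple[TissueLayer, ...] = field(default_factory=_default_layers)
    skin_moisture: float = 0.405       # fraction; overrides the skin layer's rho/c/k
    moxa: MoxaSource = field(default_factory=MoxaSource)
    domain_radius: float = 40.0        # mm
    dr: float = 0.5                    # mm
    dz: float = 0.5                    # mm (target; per-layer spacing is fitted)
    dt: float = 1.0                    # s
    duration: float = 1200.0           # s
    core_temp: float = 37.0            # degC, arterial blood / deep boundary
    blood_heat_capacity: float = 3770.0  # J kg^-1 K^-1
    initial_temp: float = 37.0         # degC
    probe_depth: float = 5.0           # mm, thermal-penetration read-out depth
    save_every: int = 1                # store every n-th time step

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("at least one tissue layer required")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be > 0")
        if self.dr <= 0 or self.dz <= 0 or self.domain_radius <= 0:
            raise ValueError("grid spacings and domain radius must be > 0")
        depth = sum(l.thickness for l in self.layers)
        if not 0 <= self.probe_depth <= depth:
            raise ValueError(f"probe depth {self.probe_depth} mm outside domain (0..{depth} mm)")

    @property
    def depth(self) -> float:
        return sum(l.thickness for l in self.layers)

    def resolved_layers(self) -> tuple[TissueLayer, ...]:
        """Layers with the skin layer's rho/c/k re-derived from ``skin_moisture``."""
        out = []
        for lay in self.layers:
            if lay.name == "skin":
                p = skin_properties_from_moisture(self.skin_moisture)
                lay = replace(
                    lay, density=p.density, heat_capacity=p.heat_capacity,
                    conductivity=p.conductivity,
                )
            out.append(lay)
        return tuple(out)


def default_config(**overrides) -> SimulationConfig:
    """Full-resolution configuration (0.5 mm grid, 1 s steps, 1200 s)."""
    return replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


def coarse_config(**overrides) -> SimulationConfig:
    """Reduced-fidelity preset used for surrogate training: ~1 mm grid, 2 s steps.

    Keeps >= 3 cells per tissue layer (the skin layer is thin, so its local
    spacing is finer than the nominal 1 mm).
    """
    cfg = SimulationConfig(dr=1.0, dz=1.0, dt=2.0, save_every=5)
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class TemperatureField:
    """Cell-centred axisymmetric temperature history.

    ``values[it, iz, ir]`` is the temperature (degC) at ``times[it]``, depth
    ``z[iz]`` and radius ``r[ir]``.  ``surface`` holds the reconstructed
    (flux-extrapolated) z = 0 skin-surface temperature, which a cell-centred
    grid does not sample directly.
    """

    r: np.ndarray        # mm, cell centres
    z: np.ndarray        # mm, cell centres (downward)
    times: np.ndarray    # s
    values: np.ndarray   # (nt, nz, nr) degC
    surface: np.ndarray  # (nt, nr) degC at z = 0

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format (t, r, z, T) table."""
        tt, zz, rr = np.meshgrid(self.times, self.z, self.r, indexing="ij")
        return pd.DataFrame(
            {"t": tt.ravel(), "r": rr.ravel(), "z": zz.ravel(), "T": self.values.ravel()}
        )


@dataclass
class IndicatorResult:
    """The two moxibustion efficacy indicators plus the curves behind them."""

    ST: float    # degC, peak on-axis surface temperature
    HPM: float   # degC, peak on-axis temperature at the probe depth
    surface_series: pd.Series    # on-axis surface T vs time
    depth_series: pd.Series      # on-axis probe-depth T vs time
    lateral_profile: pd.Series   # surface T vs r at final time
    vertical_profile: pd.Series  # on-axis T vs z at final time

    def to_json_dict(self) -> dict:
        return {"ST": self.ST, "HPM": self.HPM}


# ---------------------------------------------------------------------------
# Grid construction and the implicit solver
# ---------------------------------------------------------------------------

def _build_z_grid(layers: Sequence[TissueLayer], dz: float):
    """Per-layer uniform z grid with every layer boundary on a cell face.

    Returns cell centres, cell heights and per-cell layer indices.  Each
    layer gets at least 3 cells regardless of the nominal spacing.
    """
    centers, heights, layer_idx = [], [], []
    z0 = 0.0
    for li, lay in enumerate(layers):
        n = max(3, int(round(lay.thickness / dz)))
        hz = lay.thickness / n
        for j in range(n):
            centers.append(z0 + (j + 0.5) * hz)
            heights.append(hz)
            layer_idx.append(li)
        z0 += lay.thickness
    return np.asarray(centers), np.asarray(heights), np.asarray(layer_idx, dtype=int)


class _PennesSystem:
    """Assembled backward-Euler system for one configuration."""

    def __init__(self, config: SimulationConfig):
        layers = config.resolved_layers()
        nr = max(3, int(round(config.domain_radius / config.dr)))
        dr = config.domain_radius / nr * 1e-3                      # m
        self.r_centers_mm = (np.arange(nr) + 0.5) * (config.domain_radius / nr)
        zc_mm, hz_mm, lidx = _build_z_grid(layers, config.dz)
        self.z_centers_mm = zc_mm
        nz = len(zc_mm)
        self.nr, self.nz = nr, nz

        r = self.r_centers_mm * 1e-3
        hz = hz_mm * 1e-3
        rho = np.array([layers[i].density for i in lidx])
        cp = np.array([layers[i].heat_capacity for i in lidx])
        k = np.array([layers[i].conductivity for i in lidx])
        sink = np.array(
            [layers[i].perfusion * BLOOD_DENSITY * config.blood_heat_capacity for i in lidx]
        )
        qm = np.array([layers[i].metabolic_heat for i in lidx])
        self.k_top = k[0]
        self.hz_top = hz[0]

        # cell volumes (2*pi dropped throughout; it cancels)
        V = r[None, :] * dr * hz[:, None]                          # (nz, nr)
        self.cap = rho[:, None] * cp[:, None] * V / config.dt      # C/dt
        self.top_area = r * dr                                     # flux area, j = 0
        source = (qm + sink * config.core_temp)[:, None] * V

        idx = lambda j, i: j * nr + i
        n = nz * nr
        diag = self.cap.copy() + sink[:, None] * V
        rows, cols, vals = [], [], []

        # radial conduction (k constant within a row)
        for i in range(nr - 1):
            rf = (i + 1) * dr
            G = k * rf * hz / dr                                   # (nz,)
            for j in range(nz):
                g = G[j]
                diag[j, i] += g
                diag[j, i + 1] += g
                rows += [idx(j, i), idx(j, i + 1)]
                cols += [idx(j, i + 1), idx(j, i)]
                vals += [-g, -g]

        # vertical conduction, series resistance across the face
        for j in range(nz - 1):
            g_lin = 1.0 / (hz[j] / (2 * k[j]) + hz[j + 1] / (2 * k[j + 1]))
            G = g_lin * r * dr                                     # (nr,)
            for i in range(nr):
                g = G[i]
                diag[j, i] += g
                diag[j + 1, i] += g
                rows += [idx(j, i), idx(j + 1, i)]
                cols += [idx(j + 1, i), idx(j, i)]
                vals += [-g, -g]

        # bottom boundary: Dirichlet at core temperature via half-cell resistance
        g_bot = k[-1] * r * dr / (0.5 * hz[-1])
        diag[nz - 1, :] += g_bot
        bottom_src = g_bot * config.core_temp

        rows += [idx(j, i) for j in range(nz) for i in range(nr)]
        cols += [idx(j, i) for j in range(nz) for i in range(nr)]
        vals += list(diag.ravel())

        A = csc_matrix((vals, (rows, cols)), shape=(n, n))
        self.lu = splu(A)
        self.const_rhs = source
        self.const_rhs[nz - 1, :] += bottom_src
        self.config = config


def run_simulation(
    config: SimulationConfig,
    surface_flux: Callable[[np.ndarray, np.ndarray, float], np.ndarray] | None = None,
) -> TemperatureField:
    """Integrate the Pennes system and return the temperature history.

    ``surface_flux(r_mm, surface_temp_degC, t_s) -> W m^-2`` overrides the
    radiative moxa source when given (used e.g. for analytic benchmarks with
    a prescribed uniform flux).  Time stepping is backward Euler; the
    temperature-dependent surface flux is converged by fixed-point iteration
    to 1e-6 degC per step.
    """
    sys_ = _PennesSystem(config)
    nr, nz = sys_.nr, sys_.nz
    r_mm = sys_.r_centers_mm

    if surface_flux is None:
        src = config.moxa
        fview = source_view_factor(r_mm, src)
        eps_sig = src.emissivity * src.stefan_boltzmann * src.refractive_index**2
        tamb4 = (src.ambient_temp + KELVIN_OFFSET) ** 4

        def flux(r, Ts, t):
            Ta4 = (moxa_temperature(t, src) + KELVIN_OFFSET) ** 4
            Ts4 = (Ts + KELVIN_OFFSET) ** 4
            return eps_sig * (
                src.source_emissivity * fview * (Ta4 - Ts4) + (1.0 - fview) * (tamb4 - Ts4)
            )
    else:
        flux = surface_flux

    T = np.full((nz, nr), float(config.initial_temp))
    nsteps = int(round(config.duration / config.dt))
    save = max(1, int(config.save_every))

    times = [0.0]
    history = [T.copy()]
    q0 = np.asarray(flux(r_mm, T[0], 0.0), dtype=float) * np.ones(nr)
    surf = [T[0] + q0 * (0.5 * sys_.hz_top) / sys_.k_top]

    for step in range(1, nsteps + 1):
        t_new = step * config.dt
        base = sys_.cap * T + sys_.const_rhs
        Ts = T[0].copy()
        for _ in range(50):
            q = np.asarray(flux(r_mm, Ts, t_new), dtype=float) * np.ones(nr)
            rhs = base.copy()
            rhs[0] += q * sys_.top_area
            T_new = sys_.lu.solve(rhs.ravel()).reshape(nz, nr)
            if np.max(np.abs(T_new[0] - Ts)) < 1e-6:
                Ts = T_new[0]
                break
            Ts = T_new[0]
        else:
            raise RuntimeError("surface-flux fixed point failed to converge")
        if not np.all(np.isfinite(T_new)):
            raise RuntimeError(f"non-finite temperature at t = {t_new} s; reduce dt")
        T = T_new
        if step % save == 0 or step == nsteps:
            times.append(t_new)
            history.append(T.copy())
            q = np.asarray(flux(r_mm, T[0], t_new), dtype=float) * np.ones(nr)
            surf.append(T[0] + q * (0.5 * sys_.hz_top) / sys_.k_top)

    return TemperatureField(
        r=r_mm,
        z=sys_.z_centers_mm,
        times=np.asarray(times),
        values=np.asarray(history),
        surface=np.asarray(surf),
    )


# one half-cell: reconstructed surface uses T_cell0 + q*dz/2k (linear in the
# boundary flux), consistent with the discrete top-face flux balance.


def extract_indicators(field: TemperatureField, config: SimulationConfig) -> IndicatorResult:
    """Compute ST and HPM plus the time series and final-time profiles.

    ST is the maximum over time of the on-axis surface temperature; HPM the
    maximum over time of the on-axis temperature at the probe depth (linear
    interpolation between the bracketing cell centres).
    """
    zp = config.probe_depth
    if zp < field.z[0] or zp > field.z[-1]:
        warnings.warn(
            f"probe depth {zp} mm outside cell-centre span; using nearest node",
            stacklevel=2,
        )
        j = int(np.argmin(np.abs(field.z - zp)))
        depth_axis = field.values[:, j, 0]
    else:
        depth_axis = np.array(
            [np.interp(zp, field.z, field.values[it, :, 0]) for it in range(len(field.times))]
        )

    surface_axis = field.surface[:, 0]
    st = float(np.max(surface_axis))
    hpm = float(np.max(depth_axis))
    return IndicatorResult(
        ST=st,
        HPM=hpm,
        surface_series=pd.Series(surface_axis, index=field.times, name="T_surface"),
        depth_series=pd.Series(depth_axis, index=field.times, name="T_probe"),
        lateral_profile=pd.Series(field.surface[-1], index=field.r, name="T_surface_final"),
        vertical_profile=pd.Series(field.values[-1, :, 0], index=field.z, name="T_axis_final"),
    )


# ---------------------------------------------------------------------------
# Operating-parameter sweeps
# ---------------------------------------------------------------------------

def _apply_parameter(config: SimulationConfig, name: str, value: float) -> SimulationConfig:
    if name == "t1":
        return replace(config, moxa=replace(config.moxa, t1=float(value)))
    if name == "d":
        return replace(config, moxa=replace(config.moxa, d=float(value)))
    if name == "h":
        return replace(config, moxa=replace(config.moxa, h=float(value)))
    if name == "omega_c":
        return replace(config, skin_moisture=float(value) / 100.0)  # percent at the boundary
    raise ValueError(f"unknown operating parameter {name!r}; expected one of {PARAMETER_NAMES}")


def simulate_indicators(
    t1: float, d: float, h: float, omega_c: float, config: SimulationConfig | None = None
) -> tuple[float, float]:
    """Run one simulation at operating parameters (t1 degC, d mm, h mm,
    omega_c percent) and return ``(HPM, ST)`` in degC."""
    cfg = config if config is not None else coarse_config()
    cfg = replace(
        cfg,
        moxa=replace(cfg.moxa, t1=float(t1), d=float(d), h=float(h)),
        skin_moisture=float(omega_c) / 100.0,
    )
    res = extract_indicators(run_simulation(cfg), cfg)
    return res.HPM, res.ST


def single_factor_analysis(
    config: SimulationConfig, parameter: str, levels: Sequence[float]
) -> pd.DataFrame:
    """Vary one operating parameter across ``levels`` with the others fixed.

    Returns a DataFrame with one row per level (columns: the parameter, HPM,
    ST and the initial surface heating rate in degC/min over the first
    minute).  ``omega_c`` levels are in percent, matching the tabulated
    parameter levels.
    """
    if parameter not in PARAMETER_NAMES:
        raise ValueError(f"unknown operating parameter {parameter!r}; expected one of {PARAMETER_NAMES}")
    levels = list(levels)
    if len(levels) < 2:
        raise ValueError("need at least 2 levels for a single-factor sweep")
    rows = []
    for lv in levels:
        cfg = _apply_parameter(config, parameter, lv)
        res = extract_indicators(run_simulation(cfg), cfg)
        s = res.surface_series
        early = s[s.index <= 60.0]
        rate = (early.iloc[-1] - early.iloc[0]) / max(early.index[-1], 1e-9) * 60.0
        rows.append({parameter: lv, "HPM": res.HPM, "ST": res.ST, "heating_rate": rate})
    return pd.DataFrame(rows)
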