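"""Pennes bioheat solver: material laws, source model, and PDE verification."""

import math
from dataclasses import replace

import numpy as np
import pytest

from moxiopt.bioheat import (
    IndicatorResult,
    MoxaSource,
    SimulationConfig,
    TemperatureField,
    TissueLayer,
    coarse_config,
    disk_view_factor,
    extract_indicators,
    moxa_temperature,
    radiative_surface_flux,
    run_simulation,
    simulate_indicators,
    single_factor_analysis,
    skin_properties_from_moisture,
)


# ---------------------------------------------------------------------------
# moisture-dependent skin properties
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "percent, c_ref, rho_ref, k_ref, k_tol",
    [
        (29, 2222.0, 1213.0, 0.19, 0.01),
        (40, 2502.0, 1180.0, 0.25, 0.01),
        (52, 2826.0, 1144.0, 0.32, 0.011),  # tabulated 0.32 vs formula 0.315
    ],
)
def test_skin_property_table(percent, c_ref, rho_ref, k_ref, k_tol):
    """The moisture fits reproduce the tabulated skin properties to printed
    precision."""
    p = skin_properties_from_moisture(percent / 100.0)
    assert p.heat_capacity == pytest.approx(c_ref, abs=1.0)
    assert p.density == pytest.approx(rho_ref, abs=1.0)
    assert p.conductivity == pytest.approx(k_ref, abs=k_tol)


def test_skin_properties_dry_limit():
    """As moisture -> 0 the fits approach their dry-skin intercepts."""
    p = skin_properties_from_moisture(1e-9)
    assert p.density == pytest.approx(1300.0, abs=1e-3)
    assert p.heat_capacity == pytest.approx(4.19 * 0.37 * 1000, rel=1e-6)
    assert p.conductivity == pytest.approx(0.419 * 0.133, rel=1e-6)


@pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 40.0])
def test_skin_properties_rejects_non_fraction(bad):
    with pytest.raises(ValueError, match="fraction"):
        skin_properties_from_moisture(bad)


# ---------------------------------------------------------------------------
# moxa source
# ---------------------------------------------------------------------------

def test_moxa_temperature_harmonic():
    """Default harmonic: 400 + 200 cos(2 pi t / 500)."""
    assert moxa_temperature(0.0) == pytest.approx(600.0)
    assert moxa_temperature(125.0) == pytest.approx(400.0)
    assert moxa_temperature(250.0) == pytest.approx(200.0)
    hot = MoxaSource(t1=650.0)
    assert moxa_temperature(0.0, hot) == pytest.approx(650.0)
    assert moxa_temperature(250.0, hot) == pytest.approx(200.0)


def test_moxa_temperature_ash_dip_modifier():
    src = MoxaSource(ash_dip=True)
    assert moxa_temperature(60.5, src) == pytest.approx(50.0)
    assert moxa_temperature(10.0, src) == pytest.approx(moxa_temperature(10.0))


def test_moxa_temperature_rejects_negative_time():
    with pytest.raises(ValueError):
        moxa_temperature(-1.0)


def test_view_factor_on_axis_closed_form():
    """On axis the disk view factor is R^2 / (R^2 + h^2)."""
    for R, h in [(7.5, 30.0), (6.0, 25.0), (9.0, 35.0)]:
        assert disk_view_factor(0.0, R, h) == pytest.approx(R**2 / (R**2 + h**2), rel=1e-9)


def test_view_factor_decays_off_axis():
    r = np.linspace(0, 40, 30)
    F = disk_view_factor(r, 7.5, 30.0)
    assert np.all(np.diff(F) < 0)
    assert np.all((F > 0) & (F < 1))


def test_radiative_flux_equilibrium_and_withdrawal():
    src = MoxaSource(h=25.0)
    r = np.linspace(0, 30, 5)
    # radiative equilibrium: zero net source flux at every radius
    assert np.allclose(radiative_surface_flux(r, 400.0, 400.0, src), 0.0)
    far = replace(src, h=1e6)
    q_near = radiative_surface_flux(0.0, 37.0, 600.0, src)
    q_far = radiative_surface_flux(0.0, 37.0, 600.0, far)
    assert abs(q_far) < 1e-6 * abs(q_near)


def test_radiative_flux_rejects_sub_absolute_zero():
    with pytest.raises(ValueError):
        radiative_surface_flux(0.0, -300.0, 600.0, MoxaSource())


# ---------------------------------------------------------------------------
# PDE solver verification
# ---------------------------------------------------------------------------

def _quiet_config(**overrides):
    """No source, no metabolism: the exact steady state is uniform 37 degC."""
    cfg = coarse_config(duration=100.0)
    layers = tuple(replace(l, metabolic_heat=0.0) for l in cfg.layers)
    cfg = replace(cfg, layers=layers, moxa=replace(cfg.moxa, emissivity=0.0))
    return replace(cfg, **overrides) if overrides else cfg


def test_disabled_source_keeps_steady_state():
    cfg = _quiet_config()
    field = run_simulation(cfg)
    assert np.max(np.abs(field.values - 37.0)) < 1e-9
    assert np.max(np.abs(field.surface - 37.0)) < 1e-9


def test_semi_infinite_constant_flux_benchmark():
    """Uniform constant surface flux on a deep homogeneous slab: the surface
    rise matches the 1-D conduction closed form 2 q sqrt(alpha t / pi) / k."""
    rho, c, k = 1100.0, 3000.0, 0.4
    layer = TissueLayer("slab", 30.0, rho, c, k, perfusion=0.0, metabolic_heat=0.0)
    cfg = SimulationConfig(
        layers=(layer,), moxa=MoxaSource(emissivity=0.0),
        domain_radius=5.0, dr=2.0, dz=0.1, dt=0.25, duration=60.0,
        core_temp=37.0, initial_temp=37.0, probe_depth=5.0,
    )
    q0 = 500.0
    field = run_simulation(cfg, surface_flux=lambda r, Ts, t: np.full_like(np.atleast_1d(r), q0))
    alpha = k / (rho * c)
    t_end = field.times[-1]
    analytic = 37.0 + 2.0 * q0 * math.sqrt(alpha * t_end / math.pi) / k
    simulated = field.surface[-1, 0]
    assert simulated == pytest.approx(analytic, rel=0.02)


def test_matches_explicit_euler_oracle():
    """Backward-Euler solution agrees with an independent explicit (FTCS)
    integration of the same finite-volume discretization."""
    cfg = coarse_config(duration=60.0, dt=0.1, dr=2.0, save_every=600)
    field = run_simulation(cfg)

    # --- independent explicit solver over the same cell-centred grid ------
    from moxiopt.bioheat import _PennesSystem, source_view_factor, KELVIN_OFFSET

    sys_ = _PennesSystem(cfg)
    layers = cfg.resolved_layers()
    zc, hz, lidx = [], [], []
    z0 = 0.0
    for li, lay in enumerate(layers):
        n = max(3, int(round(lay.thickness / cfg.dz)))
        h = lay.thickness / n
        for j in range(n):
            zc.append(z0 + (j + 0.5) * h)
            hz.append(h)
            lidx.append(li)
        z0 += lay.thickness
    zc, hz, lidx = np.array(zc), np.array(hz) * 1e-3, np.array(lidx)
    nr = sys_.nr
    dr = cfg.domain_radius / nr * 1e-3
    r = (np.arange(nr) + 0.5) * dr
    rho = np.array([layers[i].density for i in lidx])[:, None]
    cp = np.array([layers[i].heat_capacity for i in lidx])[:, None]
    kz = np.array([layers[i].conductivity for i in lidx])
    sink = np.array(
        [layers[i].perfusion * 1060.0 * cfg.blood_heat_capacity for i in lidx]
    )[:, None]
    qm = np.array([layers[i].metabolic_heat for i in lidx])[:, None]
    nz = len(zc)
    V = r[None, :] * dr * hz[:, None]
    cap = rho * cp * V

    src = cfg.moxa
    F = source_view_factor(r * 1e3, src)
    es = src.emissivity * src.stefan_boltzmann
    tamb4 = (src.ambient_temp + KELVIN_OFFSET) ** 4

    T = np.full((nz, nr), 37.0)
    nsteps = int(round(cfg.duration / cfg.dt))
    g_r = kz[:, None] * (np.arange(1, nr) * dr)[None, :] * hz[:, None] / dr  # (nz, nr-1)
    g_z = (1.0 / (hz[:-1] / (2 * kz[:-1]) + hz[1:] / (2 * kz[1:])))[:, None] * (r * dr)[None, :]
    g_bot = kz[-1] * r * dr / (0.5 * hz[-1])
    for step in range(nsteps):
        t = step * cfg.dt
        Ta4 = (moxa_temperature(t, src) + KELVIN_OFFSET) ** 4
        q = es * (src.source_emissivity * F * (Ta4 - (T[0] + KELVIN_OFFSET) ** 4)
                  + (1 - F) * (tamb4 - (T[0] + KELVIN_OFFSET) ** 4))
        rate = np.zeros_like(T)
        fr = g_r * (T[:, 1:] - T[:, :-1])
        rate[:, :-1] += fr
        rate[:, 1:] -= fr
        fz = g_z * (T[1:, :] - T[:-1, :])
        rate[:-1, :] += fz
        rate[1:, :] -= fz
        rate[-1, :] += g_bot * (cfg.core_temp - T[-1, :])
        rate += sink * (cfg.core_temp - T) * V  # perfusion sink
        rate += qm * V
        rate[0, :] += q * r * dr
        T = T + cfg.dt * rate / cap

    assert np.max(np.abs(field.values[-1] - T)) < 0.05


def test_grid_and_timestep_convergence():
    """Halving the grid spacings and time step moves ST and HPM by < 0.1 K."""
    coarse = coarse_config(duration=600.0)
    fine = coarse_config(duration=600.0, dr=0.5, dz=0.5, dt=1.0)
    rc = extract_indicators(run_simulation(coarse), coarse)
    rf = extract_indicators(run_simulation(fine), fine)
    assert abs(rc.ST - rf.ST) < 0.1
    assert abs(rc.HPM - rf.HPM) < 0.1


def test_maximum_principle_heating_only():
    """With a non-negative surface flux the field never drops below the
    colder of the initial and core temperatures."""
    cfg = coarse_config(duration=120.0)
    flux = lambda r, Ts, t: np.full_like(np.atleast_1d(r), 300.0)
    field = run_simulation(cfg, surface_flux=flux)
    assert field.values.min() >= 37.0 - 1e-9


def test_indicator_ordering_and_plausible_range():
    """Heating-only run: ST >= HPM >= initial; the centre-domain ST lies in
    the published plausibility envelope [39.5, 58.1] degC."""
    cfg = coarse_config()
    cfg = replace(cfg, moxa=replace(cfg.moxa, t1=625.0))
    res = extract_indicators(run_simulation(cfg), cfg)
    assert res.ST >= res.HPM >= cfg.initial_temp
    assert 39.5 <= res.ST <= 58.1


# ---------------------------------------------------------------------------
# indicator extraction
# ---------------------------------------------------------------------------

def _make_field(values, r, z, times):
    surface = values[:, 0, :]
    return TemperatureField(r=r, z=z, times=times, values=values, surface=surface)


def test_extract_indicators_uniform_field():
    r = np.array([0.5, 1.5])
    z = np.array([0.5, 5.0, 10.0])
    field = _make_field(np.full((2, 3, 2), 37.0), r, z, np.array([0.0, 1.0]))
    cfg = coarse_config()
    res = extract_indicators(field, cfg)
    assert res.ST == pytest.approx(37.0)
    assert res.HPM == pytest.approx(37.0)


def test_extract_indicators_linear_depth_profile():
    """T(z) = 37 + z degC/mm reads 42 degC at the 5 mm probe."""
    z = np.linspace(0.25, 24.75, 50)
    r = np.array([0.5, 1.5])
    vals = np.tile((37.0 + z)[None, :, None], (1, 1, 2))
    field = _make_field(vals, r, z, np.array([0.0]))
    res = extract_indicators(field, coarse_config())
    assert res.HPM == pytest.approx(42.0, abs=1e-9)


# ---------------------------------------------------------------------------
# single-factor sweeps and monotone trends
# ---------------------------------------------------------------------------

def test_single_factor_validation_errors():
    cfg = coarse_config()
    with pytest.raises(ValueError, match="unknown operating parameter"):
        single_factor_analysis(cfg, "emissivity", [0.9, 0.95])
    with pytest.raises(ValueError, match="levels"):
        single_factor_analysis(cfg, "t1", [600.0])


@pytest.fixture(scope="module")
def trend_tables():
    cfg = coarse_config(duration=900.0)
    return {
        "t1": single_factor_analysis(cfg, "t1", [600.0, 650.0]),
        "d": single_factor_analysis(cfg, "d", [12.0, 18.0]),
        "h": single_factor_analysis(cfg, "h", [25.0, 35.0]),
        "omega_c": single_factor_analysis(cfg, "omega_c", [29.0, 52.0]),
    }


def test_monotone_trends(trend_tables):
    """ST and HPM rise with burning temperature and stick size, fall with
    distance; drier skin heats the surface faster."""
    for col in ("ST", "HPM"):
        assert trend_tables["t1"][col].is_monotonic_increasing
        assert trend_tables["d"][col].is_monotonic_increasing
        assert trend_tables["h"][col].is_monotonic_decreasing
    assert trend_tables["omega_c"]["heating_rate"].is_monotonic_decreasing


def test_perfusion_damping():
    """Stronger blood perfusion carries heat away: ST strictly decreases."""
    sts = []
    for wb in (1.0e-3, 4.0e-3):
        cfg = coarse_config(duration=600.0)
        layers = tuple(replace(l, perfusion=wb) for l in cfg.layers)
        cfg = replace(cfg, layers=layers)
        sts.append(extract_indicators(run_simulation(cfg), cfg).ST)
    assert sts[1] < sts[0]


def test_simulate_indicators_percent_boundary():
    """The 4-parameter entry point takes moisture in percent."""
    hpm, st = simulate_indicators(600.0, 15.0, 30.0, 40.5,
                                  config=coarse_config(duration=300.0))
    assert 37.0 < hpm < st < 70.0
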