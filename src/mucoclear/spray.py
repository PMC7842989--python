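"""Spray droplet populations and Lagrangian drag kinetics.

Droplet sizes follow a Rosin-Rammler law (mass fraction retained above a
diameter d is exp(-(d/d_m)^n); defaults d_m = 78 µm, spread n = 2.7, range
1-150 µm, 150 bins, 200 streams per bin — typical of a commercial
metered-dose nasal spray).  Individual droplets obey the discrete-phase
equation of motion

    du/dt = f_D + f_G,
    f_D = (18 mu / (rho_p d_p^2)) * (C_D Re_p / 24) * (u_air - u),

with the Morsi-Alexander piecewise drag coefficient C_D(Re_p) = a1 + a2/Re
+ a3/Re^2.  In-airway trajectories to deposition require a resolved airflow
field and are out of scope; the kinetics here are exercised in prescribed
analytic air flows (uniform streams, shear profiles) where closed-form
behaviour is available, e.g. exponential velocity relaxation with time
constant tau_p = rho_p d_p^2 / (18 mu) in the Stokes regime.

Note on the particle Reynolds number: the standard discrete-phase form uses
the *gas* density, Re_p = rho_air d_p |u_air - u| / mu, and that is the
default here; a ``reynolds_density="particle"`` toggle switches to the
particle density for comparison with formulations written that way.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "SprayConfig",
    "DropletPopulation",
    "ParticleState",
    "AirProperties",
    "rosin_rammler_retained",
    "build_droplet_population",
    "drag_coefficient",
    "particle_reynolds",
    "relaxation_time",
    "advance_particle",
    "write_population_csv",
    "MORSI_ALEXANDER_BANDS",
]

GRAVITY_M_S2 = 9.80665


@dataclass(frozen=True)
class SprayConfig:
    """Nasal spray actuation parameters."""

    mean_diameter_um: float = 78.0
    spread: float = 2.7
    d_min_um: float = 1.0
    d_max_um: float = 150.0
    n_bins: int = 150
    streams_per_bin: int = 200
    droplet_density_kg_m3: float = 1000.0
    initial_speed_m_s: float = 10.0
    cone_angle_deg: float = 50.0
    insertion_angle_deg: float = 30.0

    def __post_init__(self) -> None:
        if not (0 < self.d_min_um < self.mean_diameter_um < self.d_max_um):
            raise ValueError("require 0 < d_min < mean diameter < d_max")
        if self.spread <= 0:
            raise ValueError("spread parameter must be positive")
        if self.n_bins < 1 or self.streams_per_bin < 0:
            raise ValueError("need at least 1 bin and a non-negative stream count")
        if self.droplet_density_kg_m3 <= 0:
            raise ValueError("droplet density must be positive")


@dataclass
class DropletPopulation:
    """Binned droplet population: mass fractions and number weights per bin."""

    diameter_um: np.ndarray  # bin-centre diameters
    edges_um: np.ndarray  # bin edges, len n_bins + 1
    mass_fraction: np.ndarray  # sums to 1 over the truncated range
    number_weight: np.ndarray  # proportional to mass_fraction / d^3, normalised
    droplet_mass_kg: np.ndarray  # physical single-droplet mass rho pi d^3 / 6
    streams_per_bin: int

    def __len__(self) -> int:
        return len(self.diameter_um)


def rosin_rammler_retained(d_um, mean_diameter_um: float, spread: float):
    """Mass fraction retained above diameter d: exp(-(d/d_m)^n)."""
    d = np.asarray(d_um, dtype=float)
    if np.any(d <= 0) or mean_diameter_um <= 0 or spread <= 0:
        raise ValueError("diameters, mean diameter and spread must be positive")
    out = np.exp(-((d / mean_diameter_um) ** spread))
    return float(out) if out.ndim == 0 else out


def build_droplet_population(config: SprayConfig | None = None) -> DropletPopulation:
    """Bin the Rosin-Rammler distribution over [d_min, d_max].

    Bin mass fraction is the retained-fraction difference across the bin,
    renormalised over the truncated range; number weights follow from
    dividing by the single-droplet mass.
    """
    config = config or SprayConfig()
    edges = np.linspace(config.d_min_um, config.d_max_um, config.n_bins + 1)
    retained = rosin_rammler_retained(edges, config.mean_diameter_um, config.spread)
    mass = retained[:-1] - retained[1:]
    mass = mass / mass.sum()
    centres = 0.5 * (edges[:-1] + edges[1:])
    d_m = centres * 1e-6
    droplet_mass = config.droplet_density_kg_m3 * np.pi * d_m**3 / 6.0
    number = mass / droplet_mass
    number = number / number.sum()
    return DropletPopulation(
        diameter_um=centres,
        edges_um=edges,
        mass_fraction=mass,
        number_weight=number,
        droplet_mass_kg=droplet_mass,
        streams_per_bin=config.streams_per_bin,
    )


def write_population_csv(population: DropletPopulation, path: str | Path) -> None:
    pd.DataFrame(
        {
            "bin_diameter_um": population.diameter_um,
            "mass_fraction": population.mass_fraction,
            "number_weight": population.number_weight,
            "droplet_mass_kg": population.droplet_mass_kg,
        }
    ).to_csv(path, index=False)


# Morsi & Alexander piecewise constants (a1, a2, a3) per Reynolds band.
MORSI_ALEXANDER_BANDS: tuple[tuple[float, float, float, float], ...] = (
    # (upper Re bound, a1, a2, a3)
    (0.1, 0.0, 24.0, 0.0),
    (1.0, 3.690, 22.73, 0.0903),
    (10.0, 1.222, 29.1667, -3.8889),
    (100.0, 0.6167, 46.50, -116.67),
    (1000.0, 0.3644, 98.33, -2778.0),
    (5000.0, 0.357, 148.62, -47500.0),
    (10000.0, 0.46, -490.546, 578700.0),
    (np.inf, 0.5191, -1662.5, 5416700.0),
)


def drag_coefficient(re_p: float) -> float:
    """Morsi-Alexander drag coefficient C_D = a1 + a2/Re + a3/Re^2."""
    if re_p <= 0:
        raise ValueError("particle Reynolds number must be positive")
    for upper, a1, a2, a3 in MORSI_ALEXANDER_BANDS:
        if re_p <= upper:
            return a1 + a2 / re_p + a3 / (re_p * re_p)
    raise AssertionError("unreachable")


@dataclass
class ParticleState:
    """Point particle: position (m), velocity (m/s), size and density."""

    position_m: np.ndarray
    velocity_m_s: np.ndarray
    diameter_um: float
    density_kg_m3: float = 1000.0

    def __post_init__(self) -> None:
        self.position_m = np.asarray(self.position_m, dtype=float)
        self.velocity_m_s = np.asarray(self.velocity_m_s, dtype=float)
        if self.diameter_um <= 0 or self.density_kg_m3 <= 0:
            raise ValueError("diameter and density must be positive")


@dataclass(frozen=True)
class AirProperties:
    """Carrier gas with a prescribed analytic velocity field."""

    viscosity_Pa_s: float = 1.789e-5
    density_kg_m3: float = 1.225
    velocity_field: Callable[[np.ndarray], np.ndarray] | None = None
    reynolds_density: Literal["gas", "particle"] = "gas"

    def __post_init__(self) -> None:
        if self.viscosity_Pa_s <= 0 or self.density_kg_m3 <= 0:
            raise ValueError("air viscosity and density must be positive")

    def u_air(self, x_m: np.ndarray) -> np.ndarray:
        if self.velocity_field is None:
            return np.zeros(3)
        return np.asarray(self.velocity_field(x_m), dtype=float)


def particle_reynolds(state: ParticleState, air: AirProperties) -> float:
    """Re_p = rho d_p |u_air - u| / mu with the gas density by default."""
    rho = (
        air.density_kg_m3
        if air.reynolds_density == "gas"
        else state.density_kg_m3
    )
    slip = np.linalg.norm(air.u_air(state.position_m) - state.velocity_m_s)
    return rho * state.diameter_um * 1e-6 * slip / air.viscosity_Pa_s


def relaxation_time(diameter_um: float, density_kg_m3: float, viscosity_Pa_s: float) -> float:
    """Stokes relaxation time tau_p = rho_p d_p^2 / (18 mu), in seconds."""
    if diameter_um <= 0 or density_kg_m3 <= 0 or viscosity_Pa_s <= 0:
        raise ValueError("all inputs must be positive")
    d = diameter_um * 1e-6
    return density_kg_m3 * d * d / (18.0 * viscosity_Pa_s)


def _acceleration(
    pos: np.ndarray, vel: np.ndarray, state: ParticleState, air: AirProperties, gravity: bool
) -> np.ndarray:
    u_air = air.u_air(pos)
    slip = u_air - vel
    slip_mag = np.linalg.norm(slip)
    acc = np.zeros(3)
    if slip_mag > 0:
        rho = air.density_kg_m3 if air.reynolds_density == "gas" else state.density_kg_m3
        d = state.diameter_um * 1e-6
        re_p = rho * d * slip_mag / air.viscosity_Pa_s
        cd = drag_coefficient(re_p)
        tau = relaxation_time(state.diameter_um, state.density_kg_m3, air.viscosity_Pa_s)
        acc = acc + (cd * re_p / 24.0) / tau * slip
    if gravity:
        acc = acc + np.array([0.0, 0.0, -GRAVITY_M_S2])
    return acc


def advance_particle(
    state: ParticleState,
    air: AirProperties,
    dt_s: float,
    gravity: bool = False,
    rtol: float = 1e-10,
    atol: float = 1e-13,
) -> ParticleState:
    """Integrate the particle ODE over one interval with adaptive RK45.

    du/dt = f_D + f_G; position advanced consistently.  Raises on a step
    that blows up (non-finite relative velocity).
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")

    def rhs(_t, y):
        pos, vel = y[:3], y[3:]
        return np.concatenate([vel, _acceleration(pos, vel, state, air, gravity)])

    y0 = np.concatenate([state.position_m, state.velocity_m_s])
    sol = solve_ivp(rhs, (0.0, dt_s), y0, method="RK45", rtol=rtol, atol=atol)
    if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
        raise RuntimeError(f"particle integration failed over dt={dt_s}: {sol.message}")
    y1 = sol.y[:, -1]
    return ParticleState(
        position_m=y1[:3],
        velocity_m_s=y1[3:],
        diameter_um=state.diameter_um,
        density_kg_m3=state.density_kg_m3,
    )
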