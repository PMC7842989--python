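"""Drug solute diffusion through the mucus gel layer and absorption bookkeeping.

The analytical core of the package.  A deposited droplet is assumed to
dissolve instantly at the top surface of the mucin gel layer (thickness
``h_g``, default 10 µm).  The released solute diffuses one-dimensionally
toward the epithelium: the top of the gel is reflective (zero flux) and the
bottom is fully absorbing (the watery periciliary layer offers no mucin
obstruction, so solute reaching it is taken up immediately).  Separation of
variables gives the normalised concentration

    c(x, t) = (2/h_g) * sum_n exp(-(2n+1)^2 pi^2 D_g t / (4 h_g^2))
                          * cos((2n+1) pi x / (2 h_g))

and integrating over the layer gives the cumulative absorbed fraction

    A(t) = 1 - (4/pi) * sum_n (-1)^n / (2n+1)
                          * exp(-(2n+1)^2 pi^2 D_g t / (4 h_g^2)).

The gel diffusivity ``D_g`` follows the Obstruction-Scaling model for a
solute of effective radius ``r_s`` in a mucin fibre network (fibre radius
``r_f``, mesh spacing ``r_g``), applied to the aqueous Stokes-Einstein
diffusivity ``D_0``:

    D_g = D_0 * exp(-(pi/4) * ((r_s + r_f) / (r_g + r_f))^2),
    D_0 = k_B T / (6 pi mu_0 r_s).

Per-particle absorbed mass is accumulated interval-by-interval along the
particle's passage through anatomical regions: an interval (region, t_in,
t_out) credits ``alpha * m * [A(t_out) - A(t_in)]`` to that region if its
epithelium absorbs, or to a "lost" bucket while the particle sits on the
non-absorbing vestibule.  Solute still in the gel when the carrier is
cleared at the nasopharynx outlet is "cleared unabsorbed"; solute still in
the gel at the simulation horizon is "residual".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from mucoclear.clearance import ClearanceResult, RegionPassage, passages_to_arrays
from mucoclear.domain import DEFAULT_REGIONS, RegionSpec, region_name

__all__ = [
    "DiffusionConstants",
    "GelLayer",
    "SoluteSpec",
    "ParticleAbsorption",
    "AbsorptionResult",
    "diffusivity_water",
    "diffusivity_mucus",
    "concentration_profile",
    "absorption_fraction",
    "particle_absorption",
    "regional_absorption_summary",
    "dosage",
    "absorption_radius_sweep",
]

BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass(frozen=True)
class DiffusionConstants:
    """Physical constants for the diffusivity chain.

    ``temperature_K`` and ``water_viscosity_Pa_s`` default to body
    temperature and the viscosity of water at 37 °C.
    """

    fibre_radius_nm: float = 3.5
    mesh_spacing_nm: float = 50.0
    boltzmann_J_per_K: float = BOLTZMANN_J_PER_K
    temperature_K: float = 310.15
    water_viscosity_Pa_s: float = 6.913e-4

    def __post_init__(self) -> None:
        for name in (
            "fibre_radius_nm",
            "mesh_spacing_nm",
            "boltzmann_J_per_K",
            "temperature_K",
            "water_viscosity_Pa_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class GelLayer:
    """Mucus gel layer geometry: reflective top, fully absorbing bottom."""

    thickness_um: float = 10.0
    periciliary_um: float = 5.0  # metadata; transport below the gel is instantaneous

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError("gel thickness must be positive")

    @property
    def thickness_m(self) -> float:
        return self.thickness_um * 1e-6


@dataclass(frozen=True)
class SoluteSpec:
    """Drug solute: effective radius, mass fraction in the carrier, concentration."""

    radius_nm: float
    mass_fraction: float = 1.0
    concentration_kg_m3: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError("solute radius must be positive")
        if not 0.0 < self.mass_fraction <= 1.0:
            raise ValueError("mass fraction must be in (0, 1]")


def diffusivity_water(radius_nm: float, constants: DiffusionConstants | None = None) -> float:
    """Stokes-Einstein aqueous diffusivity D_0 = k_B T / (6 pi mu_0 r_s), in m^2/s."""
    constants = constants or DiffusionConstants()
    if radius_nm <= 0:
        raise ValueError("solute radius must be positive")
    r_m = radius_nm * 1e-9
    return constants.boltzmann_J_per_K * constants.temperature_K / (
        6.0 * np.pi * constants.water_viscosity_Pa_s * r_m
    )


def diffusivity_mucus(
    radius_nm: float,
    d0_m2_s: float | None = None,
    constants: DiffusionConstants | None = None,
) -> float:
    """Obstruction-Scaling gel diffusivity, in m^2/s.

    D_g = D_0 exp(-(pi/4) ((r_s + r_f)/(r_g + r_f))^2).  If ``d0_m2_s`` is
    omitted the Stokes-Einstein value for ``radius_nm`` is used.
    """
    constants = constants or DiffusionConstants()
    if radius_nm <= 0:
        raise ValueError("solute radius must be positive")
    if d0_m2_s is None:
        d0_m2_s = diffusivity_water(radius_nm, constants)
    ratio = (radius_nm + constants.fibre_radius_nm) / (
        constants.mesh_spacing_nm + constants.fibre_radius_nm
    )
    return d0_m2_s * np.exp(-(np.pi / 4.0) * ratio * ratio)


_MAX_TERMS = 10_000
# below this dimensionless time (pi^2 D t / (4 h^2)) essentially no solute
# has reached the absorbing wall: A(t) < 2 erfc(1/(2 sqrt(tau))) ~ 1e-269,
# an exact zero in double precision, while the alternating series would
# need ~1/sqrt(beta) terms to notice
_BETA_FLOOR = 1e-3


def absorption_fraction(
    t_s,
    d_g_m2_s: float,
    gel: GelLayer | None = None,
    tol: float = 1e-12,
):
    """Cumulative absorbed fraction A(t) in [0, 1].

    Alternating series truncated when the next term's magnitude bounds the
    remainder below ``tol``; A(0) is returned as exactly 0.  Accepts scalar
    or array ``t_s``.
    """
    gel = gel or GelLayer()
    if d_g_m2_s <= 0:
        raise ValueError("diffusivity must be positive")
    t = np.asarray(t_s, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    h = gel.thickness_m
    beta = (np.pi**2) * d_g_m2_s * t / (4.0 * h * h)
    out = np.zeros_like(beta)
    pos = beta >= _BETA_FLOOR
    if np.any(pos):
        b = beta[pos]
        acc = np.zeros_like(b)
        bound = tol * np.pi / 4.0
        converged = False
        for n in range(_MAX_TERMS):
            k = 2 * n + 1
            term = np.exp(-(k * k) * b) / k
            acc += term if n % 2 == 0 else -term
            # remainder of an alternating series with decreasing terms is
            # bounded by the magnitude of the next term
            k2 = k + 2
            nxt = np.exp(-(k2 * k2) * b) / k2
            if float(np.max(nxt)) < bound:
                converged = True
                break
        if not converged:
            raise RuntimeError(
                f"absorption series did not converge within {_MAX_TERMS} terms"
            )
        out[pos] = 1.0 - (4.0 / np.pi) * acc
    np.clip(out, 0.0, 1.0, out=out)
    if scalar:
        return float(out[0])
    return out


def concentration_profile(
    x_m,
    t_s: float,
    d_g_m2_s: float,
    gel: GelLayer | None = None,
    tol: float = 1e-12,
):
    """Normalised solute concentration c(x, t) in the gel, per metre.

    ``x`` is depth from the gel's free surface (0) to the absorbing bottom
    (``h_g``); the integral of c over the layer equals 1 - A(t).
    """
    gel = gel or GelLayer()
    if d_g_m2_s <= 0:
        raise ValueError("diffusivity must be positive")
    if t_s < 0:
        raise ValueError("time must be non-negative")
    h = gel.thickness_m
    x = np.asarray(x_m, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any((x < 0) | (x > h)):
        raise ValueError("x must lie inside the gel layer [0, h_g]")
    beta = (np.pi**2) * d_g_m2_s * t_s / (4.0 * h * h)
    acc = np.zeros_like(x)
    for n in range(_MAX_TERMS):
        k = 2 * n + 1
        amp = np.exp(-(k * k) * beta)
        acc += amp * np.cos(k * np.pi * x / (2.0 * h))
        k2 = k + 2
        if np.exp(-(k2 * k2) * beta) < tol:
            break
    else:
        raise RuntimeError(
            f"concentration series did not converge within {_MAX_TERMS} terms"
        )
    out = (2.0 / h) * acc
    if scalar:
        return float(out[0])
    return out


@dataclass
class ParticleAbsorption:
    """Per-particle mass bookkeeping (kg of solute)."""

    particle_id: int
    deposition_region_id: int
    solute_mass_kg: float
    absorbed_by_region_kg: dict[int, float] = field(default_factory=dict)
    lost_vestibule_kg: float = 0.0
    cleared_unabsorbed_kg: float = 0.0
    residual_kg: float = 0.0

    @property
    def absorbed_kg(self) -> float:
        return sum(self.absorbed_by_region_kg.values())

    def conservation_error(self) -> float:
        total = (
            self.absorbed_kg
            + self.lost_vestibule_kg
            + self.cleared_unabsorbed_kg
            + self.residual_kg
        )
        return abs(total - self.solute_mass_kg) / self.solute_mass_kg


@dataclass
class AbsorptionResult:
    """Aggregated absorption accounting for one solute radius."""

    radius_nm: float
    rows: list[ParticleAbsorption]
    total_solute_kg: float

    def summary(self) -> "AbsorptionSummary":
        return regional_absorption_summary(self)


@dataclass
class AbsorptionSummary:
    """Percent-of-dose views of an AbsorptionResult."""

    radius_nm: float
    total_absorbed_pct: float
    regional_pct: dict[str, float]        # where the solute was absorbed
    contribution_pct: dict[str, float]    # grouped by the particle's deposition region
    lost_vestibule_pct: float
    cleared_unabsorbed_pct: float
    residual_pct: float


def particle_absorption(
    passage: RegionPassage,
    particle_mass_kg: float,
    solute: SoluteSpec,
    gel: GelLayer,
    regions: Mapping[int, RegionSpec] | None = None,
    d_g_m2_s: float | None = None,
    constants: DiffusionConstants | None = None,
) -> ParticleAbsorption:
    """Accumulate one particle's absorbed solute along its region passage.

    Each interval (region, t_in, t_out) contributes
    ``alpha * m * [A(t_out) - A(t_in)]`` to the region if it absorbs, or to
    the lost bucket otherwise; the absorption clock runs from deposition
    regardless of region.  The undelivered remainder goes to the cleared or
    residual bucket according to the passage's terminal status.
    """
    regions = regions or DEFAULT_REGIONS
    if d_g_m2_s is None:
        d_g_m2_s = diffusivity_mucus(solute.radius_nm, constants=constants)
    passage.validate()
    alpha_m = solute.mass_fraction * particle_mass_kg
    times = np.array(
        [iv[1] for iv in passage.intervals] + [passage.intervals[-1][2]], dtype=float
    )
    a_vals = absorption_fraction(times, d_g_m2_s, gel)
    row = ParticleAbsorption(
        particle_id=passage.particle_id,
        deposition_region_id=passage.intervals[0][0],
        solute_mass_kg=alpha_m,
    )
    for i, (rid, _t_in, _t_out) in enumerate(passage.intervals):
        amount = alpha_m * (a_vals[i + 1] - a_vals[i])
        if regions[rid].absorbing:
            row.absorbed_by_region_kg[rid] = row.absorbed_by_region_kg.get(rid, 0.0) + amount
        else:
            row.lost_vestibule_kg += amount
    remainder = alpha_m * (1.0 - a_vals[-1])
    if passage.status == "cleared":
        row.cleared_unabsorbed_kg = remainder
    else:
        row.residual_kg = remainder
    return row


def regional_absorption_summary(result: AbsorptionResult) -> AbsorptionSummary:
    """Percent-of-total-solute views: where absorbed, and by deposition origin."""
    total = result.total_solute_kg
    if total <= 0:
        raise ValueError("total solute mass must be positive")
    regional: dict[str, float] = {}
    contribution: dict[str, float] = {}
    lost = cleared = residual = 0.0
    for row in result.rows:
        for rid, kg in row.absorbed_by_region_kg.items():
            name = region_name(rid)
            regional[name] = regional.get(name, 0.0) + kg
        dep = region_name(row.deposition_region_id)
        contribution[dep] = contribution.get(dep, 0.0) + row.absorbed_kg
        lost += row.lost_vestibule_kg
        cleared += row.cleared_unabsorbed_kg
        residual += row.residual_kg
    to_pct = lambda kg: 100.0 * kg / total  # noqa: E731
    return AbsorptionSummary(
        radius_nm=result.radius_nm,
        total_absorbed_pct=to_pct(sum(regional.values())),
        regional_pct={k: to_pct(v) for k, v in regional.items()},
        contribution_pct={k: to_pct(v) for k, v in contribution.items()},
        lost_vestibule_pct=to_pct(lost),
        cleared_unabsorbed_pct=to_pct(cleared),
        residual_pct=to_pct(residual),
    )


def dosage(
    final_fractions: Sequence[float],
    droplet_radii_m: Sequence[float],
    concentration_kg_m3: float,
) -> float:
    """Absorbed drug mass (kg): dosage = (4/3) pi c sum_i A_i r_i^3.

    ``final_fractions`` are each droplet's final absorbed fraction A_i and
    ``droplet_radii_m`` the carrier droplet radii.
    """
    a = np.asarray(final_fractions, dtype=float)
    r = np.asarray(droplet_radii_m, dtype=float)
    if a.shape != r.shape:
        raise ValueError("fractions and radii must have the same length")
    return float((4.0 / 3.0) * np.pi * concentration_kg_m3 * np.sum(a * r**3))


def _bulk_absorption(
    clearance: ClearanceResult,
    masses_kg: np.ndarray,
    alpha: float,
    d_g: float,
    gel: GelLayer,
    regions: Mapping[int, RegionSpec],
) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """Vectorised interval accounting over all particles for one diffusivity.

    Returns (absorbed_kg_by_region_id, contribution_kg_by_region_id,
    lost_kg, cleared_kg, residual_kg); the region-indexed arrays are dense
    over region ids.
    """
    tab = passages_to_arrays(clearance.passages)
    a_in = absorption_fraction(tab.t_in_s, d_g, gel)
    a_out = absorption_fraction(tab.t_out_s, d_g, gel)
    inc = alpha * masses_kg[tab.particle_index] * (a_out - a_in)
    n_regions = max(int(tab.region_id.max()), max(regions)) + 1 if len(tab.region_id) else 1
    absorbing = np.zeros(n_regions, dtype=bool)
    for rid, spec in regions.items():
        if rid < n_regions:
            absorbing[rid] = spec.absorbing
    is_abs = absorbing[tab.region_id]
    absorbed = np.zeros(n_regions)
    np.add.at(absorbed, tab.region_id[is_abs], inc[is_abs])
    lost = float(np.sum(inc[~is_abs]))
    # remainder buckets from each particle's final time
    a_end = absorption_fraction(tab.end_time_s, d_g, gel)
    remainder = alpha * masses_kg * (1.0 - a_end)
    cleared = float(np.sum(remainder[tab.cleared]))
    residual = float(np.sum(remainder[~tab.cleared]))
    # contribution grouped by deposition region
    per_particle_abs = np.zeros(len(masses_kg))
    np.add.at(per_particle_abs, tab.particle_index[is_abs], inc[is_abs])
    contribution = np.zeros(n_regions)
    np.add.at(contribution, tab.deposition_region_id, per_particle_abs)
    return absorbed, contribution, lost, cleared, residual


def absorption_radius_sweep(
    clearance: ClearanceResult,
    masses_kg: Sequence[float],
    radii_nm: Iterable[float],
    gel: GelLayer | None = None,
    constants: DiffusionConstants | None = None,
    regions: Mapping[int, RegionSpec] | None = None,
    alpha: float = 1.0,
) -> pd.DataFrame:
    """Total/regional/contribution absorption curves versus solute radius.

    The region passages are radius-independent and are reused for every
    radius; only the gel diffusivity and the absorption accounting are
    recomputed.  Returns a tidy frame with one row per radius.
    """
    gel = gel or GelLayer()
    constants = constants or DiffusionConstants()
    regions = regions or DEFAULT_REGIONS
    radii = list(radii_nm)
    if not radii:
        raise ValueError("radius list must not be empty")
    masses = np.asarray(masses_kg, dtype=float)
    total = alpha * float(masses.sum())
    rows = []
    for r_nm in radii:
        d_g = diffusivity_mucus(r_nm, constants=constants)
        absorbed, contribution, lost, cleared, residual = _bulk_absorption(
            clearance, masses, alpha, d_g, gel, regions
        )
        row: dict[str, float] = {
            "r_s_nm": r_nm,
            "d_g_m2_s": d_g,
            "total_pct": 100.0 * absorbed.sum() / total,
            "lost_vestibule_pct": 100.0 * lost / total,
            "cleared_unabsorbed_pct": 100.0 * cleared / total,
            "residual_pct": 100.0 * residual / total,
        }
        for rid, spec in regions.items():
            if rid < len(absorbed):
                row[f"absorbed_{spec.name}_pct"] = 100.0 * absorbed[rid] / total
                row[f"from_{spec.name}_pct"] = 100.0 * contribution[rid] / total
        rows.append(row)
    return pd.DataFrame(rows)
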