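"""Size-stratified synthetic deposition patterns on the nasal-wall surface.

Impaction of sprayed droplets in the airway is not simulated here (it needs
a resolved 3-D airflow); instead the generator reproduces the *pattern* such
simulations and in-vitro measurements report: deposition is concentrated in
size-dependent hot-spots — large droplets (> 60 µm) impact a band across
the posterior vestibule / anterior septum and the middle-turbinate tip,
medium droplets (20-60 µm) reach the anterior main passage and the ostium
vicinity, and only small droplets (< 20 µm) penetrate to the nasopharynx —
with an overall mass split of about 79.8 % vestibule, 19 % main cavity and
1.2 % nasopharynx, at 100 % total deposition efficiency.

Hot-spots are 2-D Gaussian mixtures anchored to named locations on the
domain (all in the right chamber, where the nozzle is inserted).  Each
component is truncated to its target region group, and the mixture weights
are rebalanced once at build time so the expected regional mass split hits
the configured targets exactly; the realised split then fluctuates only
with sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mucoclear.domain import REGION_IDS, ConfigurationError, SurfaceDomain, region_name
from mucoclear.spray import DropletPopulation

__all__ = [
    "HotSpot",
    "DepositionConfig",
    "DepositionSet",
    "DepositedParticle",
    "default_hotspots",
    "generate_deposition",
    "regional_mass_fractions",
    "load_deposition_csv",
    "write_deposition_csv",
]

# region groups used for the mass-split bookkeeping: the vestibule, the main
# cavity (everything between vestibule and nasopharynx) and the nasopharynx
GROUPS = ("vestibule", "main_cavity", "nasopharynx")
_GROUP_REGIONS = {
    "vestibule": ("vestibule",),
    "main_cavity": ("main_passage", "septum", "olfactory"),
    "nasopharynx": ("nasopharynx",),
}


@dataclass(frozen=True)
class HotSpot:
    """One Gaussian deposition component, truncated to its region group."""

    name: str
    x_mm: float
    y_mm: float
    sigma_mm: float
    weight: float
    group: str

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ConfigurationError("hot-spot weights must be non-negative")
        if self.sigma_mm < 0:
            raise ConfigurationError("hot-spot spread must be non-negative")
        if self.group not in GROUPS:
            raise ConfigurationError(f"unknown region group {self.group!r}")


@dataclass(frozen=True)
class DepositionConfig:
    """Hot-spot mixtures per size class and the target regional mass split."""

    large_hotspots: tuple[HotSpot, ...] = ()
    medium_hotspots: tuple[HotSpot, ...] = ()
    small_hotspots: tuple[HotSpot, ...] = ()
    large_threshold_um: float = 60.0
    small_threshold_um: float = 20.0
    # target mass split over (vestibule, main cavity, nasopharynx), percent
    regional_split_pct: tuple[float, float, float] = (79.8, 19.0, 1.2)

    def __post_init__(self) -> None:
        if abs(sum(self.regional_split_pct) - 100.0) > 1e-9:
            raise ConfigurationError("regional split must sum to 100 %")


def _chamber_band_centre(
    domain: SurfaceDomain, region: str, chamber_rows: slice
) -> tuple[float, float]:
    rid = REGION_IDS[region]
    sub = domain.region_id[chamber_rows, :] == rid
    rows = np.nonzero(sub.any(axis=1))[0]
    cols = np.nonzero(sub.any(axis=0))[0]
    if len(rows) == 0:
        raise ConfigurationError(f"region {region!r} absent from the chamber")
    dx = domain.cell_size_mm
    y = (chamber_rows.start + rows.mean() + 0.5) * dx
    x = (cols.mean() + 0.5) * dx
    return x, y


def default_hotspots(domain: SurfaceDomain) -> DepositionConfig:
    """Hot-spot anchors in the right chamber matching the reported pattern.

    Large (> 60 µm): posterior vestibule + anterior septum (the impaction
    band) and the middle-turbinate tip; medium: anterior main passage (with
    its vestibule-side lobe) and the ostium vicinity; small (< 20 µm): the
    nasopharynx tail plus an anterior main-passage residue.
    """
    dx = domain.cell_size_mm
    ny_half = domain.ny // 2
    right = slice(ny_half, domain.ny)
    vest = domain.region_id[right, :] == REGION_IDS["vestibule"]
    vest_cols = np.nonzero(vest.any(axis=0))[0]
    if len(vest_cols) == 0:
        raise ConfigurationError("default hot-spots require a vestibule")
    x_vest_end = (vest_cols[-1] + 1) * dx

    sep = domain.region_id[right, :] == REGION_IDS["septum"]
    sep_rows = np.nonzero(sep.any(axis=1))[0]
    y_sep = (ny_half + sep_rows.mean() + 0.5) * dx
    mp = domain.region_id[right, :] == REGION_IDS["main_passage"]
    mp_rows = np.nonzero(mp.any(axis=1))[0]
    mp_cols = np.nonzero(mp.any(axis=0))[0]
    y_mp = (ny_half + mp_rows.mean() + 0.5) * dx
    x_mp0 = (mp_cols[0] + 0.5) * dx
    zone_len = (mp_cols[-1] - mp_cols[0] + 1) * dx

    ost = np.argwhere(domain.is_ostium[right, :])
    if len(ost):
        y_ost = (ny_half + ost[:, 0].mean() + 0.5) * dx
        x_ost = (ost[:, 1].mean() + 0.5) * dx
    else:
        x_ost, y_ost = x_mp0 + 0.5 * zone_len, y_mp

    naso = domain.region_id == REGION_IDS["nasopharynx"]
    n_rows = np.nonzero(naso.any(axis=1))[0]
    n_cols = np.nonzero(naso.any(axis=0))[0]
    y_naso = (n_rows.mean() + 0.5) * dx
    x_naso = (n_cols[0] + 0.25 * (n_cols[-1] - n_cols[0]) + 0.5) * dx

    # posterior-vestibule anchors sit near the vestibule/septum corner
    y_vest = y_sep - 4.0
    large = (
        HotSpot("posterior_vestibule_band", x_vest_end - 3.0, y_vest, 5.0, 0.55, "vestibule"),
        HotSpot("anterior_septum_band", x_vest_end + 6.0, y_sep, 5.0, 0.30, "main_cavity"),
        HotSpot("middle_turbinate_tip", x_mp0 + 0.35 * zone_len, y_mp, 5.0, 0.15, "main_cavity"),
    )
    medium = (
        HotSpot("vestibule_lateral", x_vest_end - 3.0, y_mp, 6.0, 0.45, "vestibule"),
        HotSpot("anterior_main_passage", x_mp0 + 0.10 * zone_len, y_mp, 7.0, 0.35, "main_cavity"),
        HotSpot("ostium_vicinity", x_ost, y_ost, 5.0, 0.20, "main_cavity"),
    )
    small = (
        HotSpot("nasopharynx_tail", x_naso, y_naso, 8.0, 0.5, "nasopharynx"),
        HotSpot("anterior_passage_fines", x_mp0 + 0.10 * zone_len, y_mp, 10.0, 0.5, "main_cavity"),
    )
    return DepositionConfig(
        large_hotspots=large, medium_hotspots=medium, small_hotspots=small
    )


@dataclass
class DepositionSet:
    """Deposited particle streams (arrays; one row per stream)."""

    particle_id: np.ndarray
    diameter_um: np.ndarray
    mass_kg: np.ndarray  # carrier mass per stream; total normalised to the dose
    x_mm: np.ndarray
    y_mm: np.ndarray
    region_id: np.ndarray
    rejected_rows: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.particle_id)

    def total_mass_kg(self) -> float:
        return float(self.mass_kg.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.particle_id,
                "d_um": self.diameter_um,
                "mass_kg": self.mass_kg,
                "x_mm": self.x_mm,
                "y_mm": self.y_mm,
                "region": [region_name(r) for r in self.region_id],
            }
        )


@dataclass(frozen=True)
class DepositedParticle:
    """A single carrier droplet's deposition state (time 0 by convention)."""

    particle_id: int
    diameter_um: float
    mass_kg: float
    x_mm: float
    y_mm: float
    region_id: int
    time_s: float = 0.0


def _group_masks(domain: SurfaceDomain) -> dict[str, np.ndarray]:
    """Cells eligible per region group; chamber regions restricted to the
    right chamber (the sprayed side), the nasopharynx shared."""
    ny_half = domain.ny // 2
    right = np.zeros_like(domain.region_id, dtype=bool)
    right[ny_half:, :] = True
    masks = {}
    for group, regions in _GROUP_REGIONS.items():
        m = np.isin(domain.region_id, [REGION_IDS[r] for r in regions])
        if group != "nasopharynx":
            m &= right
        masks[group] = m
    return masks


def _class_of(d_um: np.ndarray, config: DepositionConfig) -> np.ndarray:
    cls = np.full(len(d_um), 1)  # medium
    cls[d_um > config.large_threshold_um] = 2
    cls[d_um < config.small_threshold_um] = 0
    return cls


def _rebalanced_weights(
    population: DropletPopulation, config: DepositionConfig
) -> list[tuple[HotSpot, float]]:
    """Per-component sampling weights, rebalanced so the expected group mass
    split equals the configured targets.

    The small class alone feeds the nasopharynx; the vestibule target is
    shared between the large and medium classes in proportion to their mass.
    """
    cls = _class_of(population.diameter_um, config)
    m_small = float(population.mass_fraction[cls == 0].sum())
    m_med = float(population.mass_fraction[cls == 1].sum())
    m_large = float(population.mass_fraction[cls == 2].sum())
    t_vest, t_main, t_naso = (p / 100.0 for p in config.regional_split_pct)

    spots = {
        0: list(config.small_hotspots),
        1: list(config.medium_hotspots),
        2: list(config.large_hotspots),
    }
    for c, lst in spots.items():
        if not lst and (m_small, m_med, m_large)[c] > 0:
            raise ConfigurationError(f"size class {c} has mass but no hot-spots")

    # group fractions per class
    f: dict[int, dict[str, float]] = {c: {g: 0.0 for g in GROUPS} for c in spots}
    if m_small > 0:
        f[0]["nasopharynx"] = min(1.0, t_naso / m_small)
        f[0]["main_cavity"] = 1.0 - f[0]["nasopharynx"]
    phi = t_vest / (m_large + m_med) if (m_large + m_med) > 0 else 0.0
    if phi > 1.0:
        raise ConfigurationError(
            "vestibule mass target exceeds the large+medium class mass"
        )
    for c in (1, 2):
        f[c]["vestibule"] = phi
        f[c]["main_cavity"] = 1.0 - phi

    out: list[tuple[HotSpot, float]] = []
    for c, lst in spots.items():
        by_group: dict[str, float] = {}
        for h in lst:
            by_group[h.group] = by_group.get(h.group, 0.0) + h.weight
        for g, target in f[c].items():
            if target > 0 and by_group.get(g, 0.0) == 0.0:
                raise ConfigurationError(
                    f"size class {c} needs a hot-spot in group {g!r} to meet the"
                    " regional split"
                )
        for h in lst:
            scale = f[c][h.group] / by_group[h.group] if by_group.get(h.group) else 0.0
            out.append((replace(h, weight=h.weight * scale), c))
    # regroup per class
    return out


def generate_deposition(
    population: DropletPopulation,
    domain: SurfaceDomain,
    config: DepositionConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> DepositionSet:
    """Sample deposition positions for every droplet stream.

    Each stream carries mass_fraction/streams_per_bin of a unit (1 kg)
    dose.  Positions are drawn from the size class's rebalanced hot-spot
    mixture, truncated to the component's region group, and snapped to the
    containing cell.  Reproducible under a fixed seed.
    """
    if len(population) == 0:
        raise ConfigurationError("empty droplet population")
    config = config or default_hotspots(domain)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    masks = _group_masks(domain)
    dx = domain.cell_size_mm
    group_cells = {}
    for g, m in masks.items():
        iy, ix = np.nonzero(m)
        if len(iy) == 0:
            raise ConfigurationError(f"domain has no cells for group {g!r}")
        group_cells[g] = (domain.x_mm[ix], domain.y_mm[iy])

    weighted = _rebalanced_weights(population, config)
    comps_by_class: dict[int, list[HotSpot]] = {0: [], 1: [], 2: []}
    for h, c in weighted:
        comps_by_class[c].append(h)
    for c, lst in comps_by_class.items():
        for h in lst:
            hx, hy = h.x_mm, h.y_mm
            if domain.region_at(hx, hy) == 0:
                raise ConfigurationError(
                    f"hot-spot {h.name!r} centred outside the domain at"
                    f" ({hx:.1f}, {hy:.1f}) mm"
                )

    cls = _class_of(population.diameter_um, config)
    n_streams = population.streams_per_bin
    n_total = len(population) * n_streams
    if n_total == 0:
        return DepositionSet(
            particle_id=np.empty(0, dtype=np.int64),
            diameter_um=np.empty(0),
            mass_kg=np.empty(0),
            x_mm=np.empty(0),
            y_mm=np.empty(0),
            region_id=np.empty(0, dtype=np.int64),
        )

    ids = np.arange(n_total)
    d_um = np.repeat(population.diameter_um, n_streams)
    mass = np.repeat(population.mass_fraction / n_streams, n_streams)
    xs = np.empty(n_total)
    ys = np.empty(n_total)

    stream_cls = np.repeat(cls, n_streams)
    for c, lst in comps_by_class.items():
        sel = np.nonzero(stream_cls == c)[0]
        if len(sel) == 0:
            continue
        w = np.array([h.weight for h in lst], dtype=float)
        if w.sum() <= 0:
            raise ConfigurationError(f"size class {c} has zero total hot-spot weight")
        comp = rng.choice(len(lst), size=len(sel), p=w / w.sum())
        for k, h in enumerate(lst):
            pick = sel[comp == k]
            if len(pick) == 0:
                continue
            xs[pick], ys[pick] = _sample_truncated(
                rng, h, masks[h.group], group_cells[h.group], domain, len(pick)
            )
    # snap to cell centres
    iy, ix = domain.cell_index(xs, ys)
    rid = domain.region_id[iy, ix]
    return DepositionSet(
        particle_id=ids,
        diameter_um=d_um,
        mass_kg=mass,
        x_mm=xs,
        y_mm=ys,
        region_id=rid,
    )


def _sample_truncated(
    rng: np.random.Generator,
    h: HotSpot,
    mask: np.ndarray,
    cells: tuple[np.ndarray, np.ndarray],
    domain: SurfaceDomain,
    n: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n points from the Gaussian component, truncated to its group."""
    cx, cy = cells
    if h.sigma_mm == 0:
        iy, ix = domain.cell_index(h.x_mm, h.y_mm)
        return np.full(n, domain.x_mm[ix]), np.full(n, domain.y_mm[iy])
    xs = np.empty(n)
    ys = np.empty(n)
    todo = np.arange(n)
    for _ in range(100):
        px = rng.normal(h.x_mm, h.sigma_mm, size=len(todo))
        py = rng.normal(h.y_mm, h.sigma_mm, size=len(todo))
        iy, ix = domain.cell_index(px, py)
        dxc = domain.cell_size_mm
        inside = (
            (px >= 0)
            & (px <= domain.nx * dxc)
            & (py >= 0)
            & (py <= domain.ny * dxc)
            & mask[iy, ix]
        )
        xs[todo[inside]] = px[inside]
        ys[todo[inside]] = py[inside]
        todo = todo[~inside]
        if len(todo) == 0:
            break
    if len(todo):
        # stubborn samples: snap to the nearest eligible cell centre
        px = rng.normal(h.x_mm, h.sigma_mm, size=len(todo))
        py = rng.normal(h.y_mm, h.sigma_mm, size=len(todo))
        d2 = (cx[np.newaxis, :] - px[:, np.newaxis]) ** 2 + (
            cy[np.newaxis, :] - py[:, np.newaxis]
        ) ** 2
        j = np.argmin(d2, axis=1)
        xs[todo] = cx[j]
        ys[todo] = cy[j]
    return xs, ys


def regional_mass_fractions(particles: DepositionSet, domain: SurfaceDomain) -> pd.Series:
    """Mass-weighted deposition percentage per region (sums to 100)."""
    if len(particles) == 0:
        raise ValueError("empty particle set")
    df = pd.DataFrame(
        {
            "region": [region_name(r) for r in particles.region_id],
            "mass": particles.mass_kg,
        }
    )
    out = df.groupby("region")["mass"].sum()
    return 100.0 * out / out.sum()


def group_mass_fractions(particles: DepositionSet, domain: SurfaceDomain) -> pd.Series:
    """Mass split over (vestibule, main cavity, nasopharynx), percent."""
    region_to_group = {}
    for g, regions in _GROUP_REGIONS.items():
        for r in regions:
            region_to_group[REGION_IDS[r]] = g
    groups = [region_to_group.get(r, "other") for r in particles.region_id]
    df = pd.DataFrame({"group": groups, "mass": particles.mass_kg})
    out = df.groupby("group")["mass"].sum()
    return 100.0 * out / out.sum()


_DEPOSITION_COLUMNS = ["id", "d_um", "mass_kg", "x_mm", "y_mm"]


def write_deposition_csv(particles: DepositionSet, path: str | Path) -> None:
    particles.to_frame().to_csv(path, index=False)


def load_deposition_csv(
    path: str | Path, domain: SurfaceDomain, strict: bool = False
) -> DepositionSet:
    """Load externally produced deposition tables (id, d_um, mass_kg, x_mm, y_mm).

    Rows falling outside the domain are rejected and listed in
    ``rejected_rows`` (0-based data row indices); with ``strict`` they raise.
    """
    df = pd.read_csv(path)
    missing = [c for c in _DEPOSITION_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"deposition CSV missing columns: {missing}")
    rid = domain.region_at(df["x_mm"].to_numpy(), df["y_mm"].to_numpy())
    bad = np.nonzero(rid == 0)[0].tolist()
    if bad and strict:
        raise ConfigurationError(f"rows outside the domain: {bad}")
    good = rid > 0
    return DepositionSet(
        particle_id=df["id"].to_numpy()[good],
        diameter_um=df["d_um"].to_numpy(dtype=float)[good],
        mass_kg=df["mass_kg"].to_numpy(dtype=float)[good],
        x_mm=df["x_mm"].to_numpy(dtype=float)[good],
        y_mm=df["y_mm"].to_numpy(dtype=float)[good],
        region_id=rid[good],
        rejected_rows=bad,
    )
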