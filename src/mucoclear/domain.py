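"""Unwrapped 2-D nasal-wall surface with labelled anatomical regions.

The nasal-cavity wall is represented, as in surface-mapped mucus transport
studies, by a flat rectangular strip per chamber: the vestibule at the
anterior end, then a main zone banded (from the shared chamber boundary
outward) into septum, main passage, olfactory and maxillary-sinus strips,
with both chambers merging into a single nasopharynx strip that ends at the
outlet edge.  Cells are square in the unwrapped plane but carry an
individual surface area so that each region's summed area matches the
configured anatomical areas exactly (unwrapping a curved wall distorts
local area).  A metric width factor emulates the local circumference of the
real passage; it shrinks across the nasopharynx strip, which accelerates
the mucus film there.

Maxillary sinuses carry area (for the regional bookkeeping) but are
excluded from the surface flow and never receive deposition; their mucus
production enters the main domain through ostium patches marked inside each
chamber's main-passage band.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RegionSpec",
    "DomainConfig",
    "SurfaceDomain",
    "DEFAULT_REGIONS",
    "REGION_IDS",
    "region_name",
    "build_synthetic_domain",
    "load_domain_csv",
    "write_domain_csv",
    "region_area_table",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Invalid domain or scenario configuration."""


REGION_NAMES = (
    "vestibule",
    "main_passage",
    "septum",
    "olfactory",
    "maxillary_sinus",
    "nasopharynx",
    "ostium_patch",
)
REGION_IDS: dict[str, int] = {name: i + 1 for i, name in enumerate(REGION_NAMES)}
_ID_TO_NAME = {i: n for n, i in REGION_IDS.items()}


def region_name(region_id: int) -> str:
    return _ID_TO_NAME[region_id]


@dataclass(frozen=True)
class RegionSpec:
    """Anatomical region: absorption and mucus-production behaviour.

    The vestibule is squamous (non-ciliated) epithelium: it neither absorbs
    drug solute nor produces mucus.  All respiratory-epithelium regions
    absorb.
    """

    region_id: int
    name: str
    chamber: str = "shared"  # left | right | shared
    absorbing: bool = True
    mucus_producing: bool = True

    def __post_init__(self) -> None:
        if self.name not in REGION_IDS:
            raise ConfigurationError(f"unknown region name: {self.name!r}")
        if self.chamber not in ("left", "right", "shared"):
            raise ConfigurationError(f"unknown chamber: {self.chamber!r}")
        if self.name == "vestibule" and (self.absorbing or self.mucus_producing):
            raise ConfigurationError(
                "the vestibule neither absorbs drug solute nor produces mucus"
            )


def _default_regions() -> dict[int, RegionSpec]:
    flags = {
        # name: (absorbing, mucus_producing)
        "vestibule": (False, False),
        "main_passage": (True, True),
        "septum": (True, True),
        "olfactory": (True, True),
        # sinus mucus enters through the ostium patches; the sinus interior
        # is not part of the surface flow
        "maxillary_sinus": (True, False),
        "nasopharynx": (True, False),
        "ostium_patch": (True, True),
    }
    return {
        REGION_IDS[name]: RegionSpec(REGION_IDS[name], name, "shared", *flags[name])
        for name in REGION_NAMES
    }


DEFAULT_REGIONS: dict[int, RegionSpec] = _default_regions()

# Anatomical surface areas (cm^2) per chamber; nasopharynx is shared.
MEASURED_AREAS_CM2: dict[str, tuple[float, float]] = {
    "vestibule": (8.04, 8.42),
    "main_passage": (56.3, 54.1),
    "septum": (20.8, 20.4),
    "olfactory": (9.12, 9.87),
    "maxillary_sinus": (15.4, 10.9),
}
MEASURED_NASOPHARYNX_CM2 = 11.7


@dataclass(frozen=True)
class DomainConfig:
    """Parametric layout of the synthetic unwrapped domain.

    Areas default to the measured anatomical areas; the strip dimensions
    (the aspect ratio of the unwrapped rectangles, which anatomy does not
    pin down) are tunable.
    """

    areas_cm2: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(MEASURED_AREAS_CM2)
    )
    nasopharynx_area_cm2: float = MEASURED_NASOPHARYNX_CM2
    cell_size_mm: float = 1.0
    vestibule_length_mm: float = 8.0
    main_zone_length_mm: float = 75.0
    nasopharynx_length_mm: float = 25.0
    chamber_height_mm: float = 90.0
    nasopharynx_width_mm: float = 40.0
    # metric width factor: 1 in the chambers, decaying linearly across the
    # nasopharynx strip to this value at the outlet
    nasopharynx_width_factor: float = 0.4
    # ostium patch: centre position along the main zone (fraction) and size
    ostium_x_fraction: float = 0.4
    ostium_size_mm: float = 4.0

    def validate(self) -> None:
        if self.cell_size_mm <= 0:
            raise ConfigurationError("cell size must be positive")
        for name, (al, ar) in self.areas_cm2.items():
            if name not in REGION_IDS:
                raise ConfigurationError(f"unknown region name: {name!r}")
            if al < 0 or ar < 0:
                raise ConfigurationError(f"negative area for region {name!r}")
        if self.nasopharynx_area_cm2 <= 0:
            raise ConfigurationError("nasopharynx area must be positive")
        if min(
            self.main_zone_length_mm,
            self.nasopharynx_length_mm,
            self.chamber_height_mm,
            self.nasopharynx_width_mm,
        ) <= 0:
            raise ConfigurationError("strip dimensions must be positive")
        if self.vestibule_length_mm < 0:
            raise ConfigurationError("vestibule length must be non-negative")
        if not 0 < self.nasopharynx_width_factor <= 1:
            raise ConfigurationError("nasopharynx width factor must be in (0, 1]")


@dataclass
class SurfaceDomain:
    """Structured-grid unwrapped nasal-wall surface.

    Arrays are (ny, nx), row-major; row index grows with y.  ``region_id``
    is 0 on void cells (outside the surface).  Left-chamber rows lie below
    ``ny // 2``, right-chamber rows above; the nasopharynx strip is shared.
    """

    cell_size_mm: float
    x_mm: np.ndarray  # (nx,) cell-centre coordinates
    y_mm: np.ndarray  # (ny,)
    region_id: np.ndarray  # (ny, nx) int, 0 = void
    area_cm2: np.ndarray  # (ny, nx)
    width_factor: np.ndarray  # (ny, nx)
    is_outlet: np.ndarray  # (ny, nx) bool
    is_ostium: np.ndarray  # (ny, nx) bool
    chamber: np.ndarray  # (ny, nx) int8: 0 left, 1 right, 2 shared, -1 void
    regions: dict[int, RegionSpec] = field(default_factory=_default_regions)

    @property
    def nx(self) -> int:
        return len(self.x_mm)

    @property
    def ny(self) -> int:
        return len(self.y_mm)

    @property
    def active(self) -> np.ndarray:
        return self.region_id > 0

    @property
    def flow_active(self) -> np.ndarray:
        """Cells that take part in the surface mucus flow (sinuses excluded)."""
        return self.active & (self.region_id != REGION_IDS["maxillary_sinus"])

    def total_area_cm2(self) -> float:
        return float(self.area_cm2[self.active].sum())

    def cell_index(self, x_mm, y_mm) -> tuple[np.ndarray, np.ndarray]:
        """Grid indices (iy, ix) of the cells containing the points (clipped)."""
        dx = self.cell_size_mm
        ix = np.clip(np.floor(np.asarray(x_mm) / dx).astype(int), 0, self.nx - 1)
        iy = np.clip(np.floor(np.asarray(y_mm) / dx).astype(int), 0, self.ny - 1)
        return iy, ix

    def region_at(self, x_mm, y_mm) -> np.ndarray:
        """Region id at the given points; 0 where the point is off-surface."""
        x = np.asarray(x_mm, dtype=float)
        y = np.asarray(y_mm, dtype=float)
        iy, ix = self.cell_index(x, y)
        rid = self.region_id[iy, ix]
        dx = self.cell_size_mm
        inside = (x >= 0) & (x <= self.nx * dx) & (y >= 0) & (y <= self.ny * dx)
        return np.where(inside, rid, 0)

    def validate(self, area_rtol: float = 5e-3) -> None:
        if np.any(self.width_factor[self.active] <= 0):
            raise ConfigurationError("metric width factor must be positive")
        if np.any(self.region_id[self.is_outlet] != REGION_IDS["nasopharynx"]):
            raise ConfigurationError("outlet cells must belong to the nasopharynx")
        if not self.is_outlet.any():
            raise ConfigurationError("domain has no outlet cells")

    def to_frame(self) -> pd.DataFrame:
        iy, ix = np.nonzero(self.active)
        return pd.DataFrame(
            {
                "x_mm": self.x_mm[ix],
                "y_mm": self.y_mm[iy],
                "area_cm2": self.area_cm2[iy, ix],
                "region": [region_name(r) for r in self.region_id[iy, ix]],
                "width_factor": self.width_factor[iy, ix],
                "is_outlet": self.is_outlet[iy, ix].astype(int),
                "is_ostium": self.is_ostium[iy, ix].astype(int),
            }
        )


def _band_counts(total_rows: int, shares: dict[str, float]) -> dict[str, int]:
    """Integer row counts per band, largest-remainder rounding to the total."""
    raw = {k: total_rows * v for k, v in shares.items()}
    counts = {k: int(np.floor(r)) for k, r in raw.items()}
    remainder = total_rows - sum(counts.values())
    order = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:remainder]:
        counts[k] += 1
    return counts


def build_synthetic_domain(config: DomainConfig | None = None) -> SurfaceDomain:
    """Build the parametric unwrapped domain satisfying all area invariants.

    Regions with zero configured area are absent.  Raises
    ``ConfigurationError`` for non-positive cell size or negative areas, or
    when a region with positive target area receives no cells at the given
    resolution.
    """
    config = config or DomainConfig()
    config.validate()
    dx = config.cell_size_mm

    n_vest = int(round(config.vestibule_length_mm / dx))
    n_main = int(round(config.main_zone_length_mm / dx))
    n_naso = int(round(config.nasopharynx_length_mm / dx))
    ny_half = int(round(config.chamber_height_mm / dx))
    if min(n_main, n_naso, ny_half) < 1:
        raise ConfigurationError("strip dimensions too small for the cell size")
    nx = n_vest + n_main + n_naso
    ny = 2 * ny_half

    region_id = np.zeros((ny, nx), dtype=np.int64)
    area = np.zeros((ny, nx))
    width = np.ones((ny, nx))
    is_outlet = np.zeros((ny, nx), dtype=bool)
    is_ostium = np.zeros((ny, nx), dtype=bool)
    chamber = np.full((ny, nx), -1, dtype=np.int8)

    areas = dict(config.areas_cm2)
    zone_names = ("septum", "main_passage", "olfactory", "maxillary_sinus")

    for side, rows in (("left", slice(0, ny_half)), ("right", slice(ny_half, ny))):
        ci = 0 if side == "left" else 1
        # vestibule occupies all rows of the anterior columns
        vest_area = areas.get("vestibule", (0.0, 0.0))[ci]
        if vest_area > 0:
            if n_vest < 1:
                raise ConfigurationError(
                    "vestibule area requested but vestibule length is below one cell;"
                    " achievable area is 0"
                )
            region_id[rows, :n_vest] = REGION_IDS["vestibule"]
        # main zone bands, ordered from the shared boundary outward
        zone_areas = {n: areas.get(n, (0.0, 0.0))[ci] for n in zone_names}
        zone_total = sum(zone_areas.values())
        if zone_total > 0:
            shares = {n: a / zone_total for n, a in zone_areas.items() if a > 0}
            counts = _band_counts(ny_half, shares)
            for name, cnt in counts.items():
                if cnt < 1:
                    raise ConfigurationError(
                        f"region {name!r} cannot be tiled at cell size {dx} mm;"
                        f" achievable area is 0"
                    )
            # left chamber: shared boundary is its TOP row (ny_half - 1);
            # right chamber: shared boundary is its BOTTOM row (ny_half)
            offsets = np.cumsum([0] + [counts[n] for n in shares])
            for k, name in enumerate(shares):
                lo, hi = offsets[k], offsets[k + 1]
                if side == "left":
                    band = slice(ny_half - hi, ny_half - lo)
                else:
                    band = slice(ny_half + lo, ny_half + hi)
                region_id[band, n_vest : n_vest + n_main] = REGION_IDS[name]
        chamber[rows, : n_vest + n_main] = ci
        # ostium patch inside the main-passage band
        if zone_areas.get("maxillary_sinus", 0.0) > 0 and "main_passage" in shares:
            ox = n_vest + int(config.ostium_x_fraction * n_main)
            half = max(1, int(round(config.ostium_size_mm / (2 * dx))))
            mp_rows = np.nonzero(
                region_id[rows, ox] == REGION_IDS["main_passage"]
            )[0]
            if len(mp_rows) == 0:
                raise ConfigurationError("no main-passage band to host the ostium patch")
            # anchor at the outer edge of the main-passage band (next to the
            # olfactory/sinus side, mirroring the real ostium position)
            anchor = mp_rows[0] if side == "left" else mp_rows[-1]
            r0 = rows.start + max(mp_rows[0], min(anchor - half, mp_rows[-1] - 2 * half + 1))
            sel = (slice(r0, r0 + 2 * half), slice(ox - half, ox + half))
            is_ostium[sel] = region_id[sel] == REGION_IDS["main_passage"]

    # shared nasopharynx strip, centred on the chamber boundary
    n_naso_rows = int(round(config.nasopharynx_width_mm / dx))
    n_naso_rows = max(1, min(n_naso_rows, ny))
    r0 = ny_half - n_naso_rows // 2
    naso_rows = slice(r0, r0 + n_naso_rows)
    naso_cols = slice(n_vest + n_main, nx)
    region_id[naso_rows, naso_cols] = REGION_IDS["nasopharynx"]
    chamber[naso_rows, naso_cols] = 2
    is_outlet[naso_rows, nx - 1] = True
    # width factor decays linearly across the nasopharynx strip
    taper = np.linspace(1.0, config.nasopharynx_width_factor, n_naso)
    width[:, n_vest + n_main : nx] = taper[np.newaxis, :]

    # per-cell areas: each (region, chamber) group shares its target evenly
    for side_idx, (side_rows,) in enumerate([(slice(0, ny_half),), (slice(ny_half, ny),)]):
        for name, pair in areas.items():
            target = pair[side_idx]
            rid = REGION_IDS[name]
            mask = np.zeros((ny, nx), dtype=bool)
            mask[side_rows, :] = True
            mask &= region_id == rid
            n_cells = int(mask.sum())
            if target > 0 and n_cells == 0:
                raise ConfigurationError(
                    f"region {name!r} ({'left' if side_idx == 0 else 'right'}) has"
                    f" target area {target} cm^2 but received no cells;"
                    " achievable area is 0"
                )
            if n_cells:
                area[mask] = target / n_cells
    naso_mask = region_id == REGION_IDS["nasopharynx"]
    area[naso_mask] = config.nasopharynx_area_cm2 / naso_mask.sum()

    domain = SurfaceDomain(
        cell_size_mm=dx,
        x_mm=(np.arange(nx) + 0.5) * dx,
        y_mm=(np.arange(ny) + 0.5) * dx,
        region_id=region_id,
        area_cm2=area,
        width_factor=width,
        is_outlet=is_outlet,
        is_ostium=is_ostium,
        chamber=chamber,
    )
    domain.validate()
    return domain


_CSV_COLUMNS = ["x_mm", "y_mm", "area_cm2", "region", "width_factor", "is_outlet", "is_ostium"]


def write_domain_csv(domain: SurfaceDomain, path: str | Path) -> None:
    domain.to_frame().to_csv(path, index=False)


def load_domain_csv(path: str | Path | io.IOBase) -> SurfaceDomain:
    """Load a domain from CSV (columns: x_mm, y_mm, area_cm2, region,
    width_factor, is_outlet, is_ostium).

    Malformed rows (unknown region names, duplicate coordinates) are
    reported with their row numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"domain CSV missing columns: {missing}")
    bad = df.index[~df["region"].isin(REGION_IDS)].tolist()
    if bad:
        vals = df.loc[bad, "region"].unique().tolist()
        raise ConfigurationError(
            f"unknown region names {vals} at rows {[b + 2 for b in bad]}"
        )
    dup = df.duplicated(subset=["x_mm", "y_mm"])
    if dup.any():
        raise ConfigurationError(
            f"duplicate cell coordinates at rows {[i + 2 for i in df.index[dup]]}"
        )
    xs = np.sort(df["x_mm"].unique())
    ys = np.sort(df["y_mm"].unique())
    steps = np.concatenate([np.diff(xs), np.diff(ys)])
    dx = float(steps.min()) if len(steps) else 1.0
    nx = int(round(xs.max() / dx + 0.5))
    ny = int(round(ys.max() / dx + 0.5))
    region_id = np.zeros((ny, nx), dtype=np.int64)
    area = np.zeros((ny, nx))
    width = np.ones((ny, nx))
    is_outlet = np.zeros((ny, nx), dtype=bool)
    is_ostium = np.zeros((ny, nx), dtype=bool)
    ix = np.round(df["x_mm"].to_numpy() / dx - 0.5).astype(int)
    iy = np.round(df["y_mm"].to_numpy() / dx - 0.5).astype(int)
    if np.any((ix < 0) | (iy < 0)):
        raise ConfigurationError("negative cell coordinates in domain CSV")
    region_id[iy, ix] = [REGION_IDS[r] for r in df["region"]]
    area[iy, ix] = df["area_cm2"].to_numpy()
    width[iy, ix] = df["width_factor"].to_numpy()
    is_outlet[iy, ix] = df["is_outlet"].to_numpy().astype(bool)
    is_ostium[iy, ix] = df["is_ostium"].to_numpy().astype(bool)
    ny_half = ny // 2
    chamber = np.full((ny, nx), -1, dtype=np.int8)
    chamber[:ny_half, :][region_id[:ny_half, :] > 0] = 0
    chamber[ny_half:, :][region_id[ny_half:, :] > 0] = 1
    chamber[region_id == REGION_IDS["nasopharynx"]] = 2
    domain = SurfaceDomain(
        cell_size_mm=dx,
        x_mm=(np.arange(nx) + 0.5) * dx,
        y_mm=(np.arange(ny) + 0.5) * dx,
        region_id=region_id,
        area_cm2=area,
        width_factor=width,
        is_outlet=is_outlet,
        is_ostium=is_ostium,
        chamber=chamber,
    )
    domain.validate()
    return domain


def region_area_table(domain: SurfaceDomain) -> pd.DataFrame:
    """Per-region surface area and percentage of the total.

    Areas are summed over cells (both chambers); percentages are reported
    unrounded in ``percent`` and rounded to two decimals in ``percent_2dp``.
    """
    rows = []
    total = domain.total_area_cm2()
    for rid, spec in domain.regions.items():
        mask = domain.region_id == rid
        if not mask.any():
            continue
        a = float(domain.area_cm2[mask].sum())
        rows.append({"region": spec.name, "area_cm2": a, "percent": 100.0 * a / total})
    df = pd.DataFrame(rows)
    df["percent_2dp"] = df["percent"].round(2)
    return df
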