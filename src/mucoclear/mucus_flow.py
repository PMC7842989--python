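"""Steady, mass-balanced mucus surface velocity field from distributed sources.

The mucus film on the nasal wall creeps at ~6 mm/min with a Reynolds number
around 1e-4, so inertia is irrelevant and the film responds instantly to
mass injection: new mucus produced over the mucosa (and entering through the
maxillary ostia) must leave through the nasopharynx outlet.  This module
solves the resulting source-driven continuity problem as a potential flow on
the unwrapped plane:

    div(w grad(phi)) = -w s,   v = -grad(phi),

with phi = 0 on the outlet cells (pressure outlet) and zero normal
derivative on every other boundary (slip walls).  ``w`` is the metric width
factor emulating the local circumference of the real passage; where it
shrinks (the nasopharynx strip) the film accelerates.  ``s`` is the areal
mucus injection speed per cell.

The absolute source strength is never prescribed; it is calibrated so the
area-weighted mean speed over the main cavity wall (main passage + septum +
olfactory, excluding vestibules and sinuses) equals the physiological
6 mm/min.  By linearity this is a single rescale.

An optional divergence-free "swirl" perturbation (stream-function vortices)
recreates the recirculation that a full thin-film solve produces near the
vestibule and anterior to the maxillary ostia; it moves particles without
altering the net source/outlet balance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from mucoclear.domain import REGION_IDS, ConfigurationError, SurfaceDomain

__all__ = [
    "MucusProperties",
    "MucusField",
    "SwirlBump",
    "SwirlConfig",
    "default_source_layout",
    "default_swirl",
    "solve_mucus_field",
    "calibrate_source_strength",
    "check_mass_balance",
    "write_field_csv",
    "load_field_csv",
    "FlowError",
]


class FlowError(RuntimeError):
    """Mucus flow solve failure (singular system or non-convergence)."""


@dataclass(frozen=True)
class MucusProperties:
    """Physical constants of the mucus film."""

    density_kg_m3: float = 1000.0
    viscosity_Pa_s: float = 12.0
    gel_thickness_um: float = 10.0
    periciliary_um: float = 5.0
    target_mean_speed_mm_min: float = 6.0

    def __post_init__(self) -> None:
        for name in (
            "density_kg_m3",
            "viscosity_Pa_s",
            "gel_thickness_um",
            "periciliary_um",
            "target_mean_speed_mm_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SwirlBump:
    """One stream-function vortex: centre, radius scale, peak speed."""

    x_mm: float
    y_mm: float
    sigma_mm: float
    peak_mm_min: float
    sense: int = 1  # +1 anticlockwise


@dataclass(frozen=True)
class SwirlConfig:
    bumps: tuple[SwirlBump, ...] = ()
    enabled: bool = True


@dataclass
class MucusField:
    """Solved surface velocity field (mm/min) with mass-balance bookkeeping."""

    domain: SurfaceDomain
    vx_mm_min: np.ndarray
    vy_mm_min: np.ndarray
    source: np.ndarray  # areal injection speed per cell (calibrated units)
    potential: np.ndarray
    source_flux: float
    outlet_flux: float
    calibration_factor: float = 1.0

    def speed_mm_min(self) -> np.ndarray:
        return np.hypot(self.vx_mm_min, self.vy_mm_min)

    def mean_speed_mm_min(self, mask: np.ndarray | None = None) -> float:
        """Area-weighted mean speed over ``mask`` (default: calibration cells)."""
        if mask is None:
            mask = calibration_mask(self.domain)
        w = self.domain.area_cm2[mask]
        return float(np.sum(self.speed_mm_min()[mask] * w) / np.sum(w))

    def velocity_at(self, x_mm, y_mm) -> tuple[np.ndarray, np.ndarray]:
        """Bilinear interpolation of the cell-centred velocity at points."""
        return _bilinear(self.domain, self.vx_mm_min, x_mm, y_mm), _bilinear(
            self.domain, self.vy_mm_min, x_mm, y_mm
        )


def calibration_mask(domain: SurfaceDomain) -> np.ndarray:
    """Main cavity wall: main passage + septum + olfactory (no vestibule/sinus)."""
    ids = [REGION_IDS[n] for n in ("main_passage", "septum", "olfactory")]
    return np.isin(domain.region_id, ids)


def default_source_layout(domain: SurfaceDomain, ostium_fraction: float = 0.6) -> np.ndarray:
    """Per-cell source weights: uniform over mucus-producing mucosa plus
    concentrated ostium injection carrying ``ostium_fraction`` of the total."""
    if not 0 <= ostium_fraction < 1:
        raise ConfigurationError("ostium fraction must be in [0, 1)")
    producing = np.zeros_like(domain.region_id, dtype=bool)
    for rid, spec in domain.regions.items():
        if spec.mucus_producing:
            producing |= domain.region_id == rid
    producing &= domain.flow_active
    weights = np.zeros(domain.region_id.shape)
    weights[producing] = 1.0
    n_ost = int(domain.is_ostium.sum())
    if n_ost and ostium_fraction > 0:
        mucosa_total = float(weights.sum())
        extra = ostium_fraction / (1.0 - ostium_fraction) * mucosa_total / n_ost
        weights[domain.is_ostium] += extra
    return weights


def default_swirl(domain: SurfaceDomain, peak_mm_min: float = 2.5) -> SwirlConfig:
    """Recirculation bumps per chamber: one at the vestibule/septum corner
    (sweeps vestibule-deposited particles into the mainstream) and one in
    the anterior main passage (the anterior detour seen upstream of the
    ostia)."""
    dx = domain.cell_size_mm
    bumps: list[SwirlBump] = []
    ny_half = domain.ny // 2
    vest_cols = np.nonzero((domain.region_id == REGION_IDS["vestibule"]).any(axis=0))[0]
    x_vest_end = (vest_cols[-1] + 1) * dx if len(vest_cols) else 0.0
    for side, rows in (("left", slice(0, ny_half)), ("right", slice(ny_half, domain.ny))):
        sub = domain.region_id[rows, :]
        sep_rows = np.nonzero((sub == REGION_IDS["septum"]).any(axis=1))[0]
        mp_rows = np.nonzero((sub == REGION_IDS["main_passage"]).any(axis=1))[0]
        if len(sep_rows) == 0 or len(mp_rows) == 0:
            continue
        y0 = rows.start * dx
        y_sep = y0 + (sep_rows.mean() + 0.5) * dx
        y_mp = y0 + (mp_rows.mean() + 0.5) * dx
        sense = 1 if side == "left" else -1
        # the vestibule sweep vortex sits just inside the vestibule so the
        # anterior-septum deposits stay on the direct mainstream
        bumps.append(SwirlBump(x_vest_end - 3.0, y_sep, 5.0, peak_mm_min, sense))
        # the anterior-main-passage vortex covers the deposits anterior to
        # the ostium (turbinate tip + anterior passage), detouring them
        # toward the vestibule before the mainstream takes over
        mp_cols = np.nonzero((sub == REGION_IDS["main_passage"]).any(axis=0))[0]
        zone_len = (mp_cols[-1] - mp_cols[0] + 1) * dx if len(mp_cols) else 0.0
        bumps.append(
            SwirlBump(
                x_vest_end + 0.22 * zone_len, y_mp, 12.0, 0.8 * peak_mm_min, sense
            )
        )
        bumps.append(SwirlBump(x_vest_end - 3.0, y_mp, 6.0, peak_mm_min, sense))
    return SwirlConfig(bumps=tuple(bumps))


def _swirl_velocity(
    domain: SurfaceDomain, swirl: SwirlConfig, x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Velocity of the stream-function bumps, v = (d psi/dy, -d psi/dx)."""
    vx = np.zeros(np.broadcast(x, y).shape)
    vy = np.zeros_like(vx)
    if not swirl.enabled:
        return vx, vy
    for b in swirl.bumps:
        dxp = x - b.x_mm
        dyp = y - b.y_mm
        r2 = dxp * dxp + dyp * dyp
        # psi = a exp(-r^2 / 2 sigma^2); |v| peaks at r = sigma with value
        # a exp(-1/2) / sigma, so a = peak * sigma * e^(1/2)
        a = b.sense * b.peak_mm_min * b.sigma_mm * np.exp(0.5)
        g = a * np.exp(-r2 / (2.0 * b.sigma_mm**2)) / b.sigma_mm**2
        vx += -dyp * g
        vy += dxp * g
    return vx, vy


def _connectivity(domain: SurfaceDomain):
    """Face transmissibilities on the structured grid.

    Faces are open between flow-active cells of the same chamber, or where
    either cell is shared (the nasopharynx merge); the left/right interface
    is closed elsewhere (the two walls only meet at the choanae).
    """
    act = domain.flow_active
    ch = domain.chamber
    w = domain.width_factor
    faces = []
    ny, nx = act.shape
    idx = -np.ones((ny, nx), dtype=np.int64)
    cells = np.argwhere(act)
    idx[act] = np.arange(len(cells))
    for axis in (0, 1):
        if axis == 0:
            a = (slice(0, ny - 1), slice(None))
            b = (slice(1, ny), slice(None))
        else:
            a = (slice(None), slice(0, nx - 1))
            b = (slice(None), slice(1, nx))
        open_face = act[a] & act[b] & (
            (ch[a] == ch[b]) | (ch[a] == 2) | (ch[b] == 2)
        )
        ia, ib = idx[a][open_face], idx[b][open_face]
        # harmonic mean of the metric width factors
        t = 2.0 * w[a][open_face] * w[b][open_face] / (w[a][open_face] + w[b][open_face])
        faces.append((ia, ib, t))
    ia = np.concatenate([f[0] for f in faces])
    ib = np.concatenate([f[1] for f in faces])
    t = np.concatenate([f[2] for f in faces])
    return idx, ia, ib, t


def solve_mucus_field(
    domain: SurfaceDomain,
    props: MucusProperties | None = None,
    source_layout: np.ndarray | None = None,
    swirl: SwirlConfig | None = None,
    calibrate: bool = True,
) -> MucusField:
    """Solve the metric-weighted Poisson problem for the mucus potential.

    Velocity is ``v = -grad(phi)`` with phi = 0 on outlet cells and zero
    normal derivative elsewhere; when ``calibrate`` is true the field is
    rescaled so the mean speed over the calibration cells equals the target
    (6 mm/min by default).  The swirl perturbation, if any, is added after
    calibration.
    """
    props = props or MucusProperties()
    if source_layout is None:
        source_layout = default_source_layout(domain)
    s = np.asarray(source_layout, dtype=float)
    if s.shape != domain.region_id.shape:
        raise ConfigurationError("source layout shape does not match the domain")
    if np.any(s < 0):
        raise ConfigurationError("source weights must be non-negative")
    vest = domain.region_id == REGION_IDS["vestibule"]
    if np.any(s[vest] > 0):
        raise ConfigurationError("no mucus source may be placed on vestibule cells")
    if not domain.is_outlet.any():
        raise FlowError("domain has no outlet cells: the system is singular")

    dx = domain.cell_size_mm
    act = domain.flow_active
    idx, ia, ib, t = _connectivity(domain)
    n = int(act.sum())
    dirichlet = domain.is_outlet[act]

    # assemble A phi = b over non-outlet unknowns
    free = ~dirichlet
    free_idx = -np.ones(n, dtype=np.int64)
    free_idx[free] = np.arange(int(free.sum()))
    diag = np.zeros(n)
    np.add.at(diag, ia, t)
    np.add.at(diag, ib, t)
    both_free = free[ia] & free[ib]
    rows = np.concatenate([free_idx[ia[both_free]], free_idx[ib[both_free]]])
    cols = np.concatenate([free_idx[ib[both_free]], free_idx[ia[both_free]]])
    vals = np.concatenate([-t[both_free], -t[both_free]])
    nf = int(free.sum())
    a_mat = sp.coo_matrix(
        (
            np.concatenate([vals, diag[free]]),
            (
                np.concatenate([rows, np.arange(nf)]),
                np.concatenate([cols, np.arange(nf)]),
            ),
        ),
        shape=(nf, nf),
    ).tocsc()
    w_cells = domain.width_factor[act]
    b = (w_cells * s[act] * dx * dx)[free]
    if not np.any(b != 0):
        phi_free = np.zeros(nf)
    else:
        try:
            phi_free = spla.spsolve(a_mat, b)
        except Exception as exc:  # pragma: no cover - singular/factorisation failure
            raise FlowError(f"mucus potential solve failed: {exc}") from exc
        res = float(np.linalg.norm(a_mat @ phi_free - b))
        scale = float(np.linalg.norm(b)) or 1.0
        if not np.isfinite(res) or res / scale > 1e-8:
            raise FlowError(f"mucus potential solve did not converge: residual {res:.3e}")

    phi_cells = np.zeros(n)
    phi_cells[free] = phi_free
    phi = np.zeros(act.shape)
    phi[act] = phi_cells

    vx, vy = _gradient_velocity(domain, phi)
    source_flux = float(np.sum((w_cells * s[act] * dx * dx)[free]))
    # discrete flux into the outlet cells through open faces
    to_outlet = dirichlet[ib] & free[ia]
    from_outlet = dirichlet[ia] & free[ib]
    outlet_flux = float(
        np.sum(t[to_outlet] * phi_cells[ia[to_outlet]])
        + np.sum(t[from_outlet] * phi_cells[ib[from_outlet]])
    )

    factor = 1.0
    fld = MucusField(
        domain=domain,
        vx_mm_min=vx,
        vy_mm_min=vy,
        source=s.copy(),
        potential=phi,
        source_flux=source_flux,
        outlet_flux=outlet_flux,
    )
    if calibrate:
        factor = calibrate_source_strength(domain, props, source_layout, _field=fld)
        fld = MucusField(
            domain=domain,
            vx_mm_min=factor * vx,
            vy_mm_min=factor * vy,
            source=factor * s,
            potential=factor * phi,
            source_flux=factor * source_flux,
            outlet_flux=factor * outlet_flux,
            calibration_factor=factor,
        )
    if swirl is not None and swirl.enabled and swirl.bumps:
        gx, gy = np.meshgrid(domain.x_mm, domain.y_mm)
        sx, sy = _swirl_velocity(domain, swirl, gx, gy)
        sx[~domain.flow_active] = 0.0
        sy[~domain.flow_active] = 0.0
        fld.vx_mm_min = fld.vx_mm_min + sx
        fld.vy_mm_min = fld.vy_mm_min + sy
    return fld


def _gradient_velocity(domain: SurfaceDomain, phi: np.ndarray):
    """v = -grad(phi), central where both neighbours are connected, else one-sided."""
    act = domain.flow_active
    ch = domain.chamber
    dx = domain.cell_size_mm
    ny, nx = phi.shape

    def open_pair(sl_a, sl_b):
        return act[sl_a] & act[sl_b] & (
            (ch[sl_a] == ch[sl_b]) | (ch[sl_a] == 2) | (ch[sl_b] == 2)
        )

    vx = np.zeros_like(phi)
    vy = np.zeros_like(phi)
    for axis, v in ((1, vx), (0, vy)):
        has_m = np.zeros(phi.shape, dtype=bool)
        has_p = np.zeros(phi.shape, dtype=bool)
        dphi_m = np.zeros_like(phi)
        dphi_p = np.zeros_like(phi)
        if axis == 1:
            good = open_pair((slice(None), slice(0, nx - 1)), (slice(None), slice(1, nx)))
            has_p[:, :-1] = good
            has_m[:, 1:] = good
            dphi_p[:, :-1] = phi[:, 1:] - phi[:, :-1]
            dphi_m[:, 1:] = phi[:, 1:] - phi[:, :-1]
        else:
            good = open_pair((slice(0, ny - 1), slice(None)), (slice(1, ny), slice(None)))
            has_p[:-1, :] = good
            has_m[1:, :] = good
            dphi_p[:-1, :] = phi[1:, :] - phi[:-1, :]
            dphi_m[1:, :] = phi[1:, :] - phi[:-1, :]
        both = has_m & has_p
        v[both] = -(dphi_m[both] + dphi_p[both]) / (2.0 * dx)
        only_m = has_m & ~has_p
        v[only_m] = -dphi_m[only_m] / dx
        only_p = has_p & ~has_m
        v[only_p] = -dphi_p[only_p] / dx
    vx[~act] = 0.0
    vy[~act] = 0.0
    return vx, vy


def calibrate_source_strength(
    domain: SurfaceDomain,
    props: MucusProperties | None = None,
    source_layout: np.ndarray | None = None,
    _field: MucusField | None = None,
) -> float:
    """Multiplicative source scaling giving the target mean speed.

    By linearity of the potential problem a single rescale suffices; the
    mean is area-weighted over main passage + septum + olfactory cells.
    """
    props = props or MucusProperties()
    fld = _field or solve_mucus_field(domain, props, source_layout, calibrate=False)
    mean = fld.mean_speed_mm_min()
    if mean <= 0:
        raise FlowError("baseline mean speed is zero; cannot calibrate")
    return props.target_mean_speed_mm_min / mean


def check_mass_balance(fld: MucusField) -> float:
    """Relative residual |total source flux - outlet flux| / total source flux.

    Both fluxes are recomputed from the field itself: the source flux from
    the per-cell injection, the outlet flux from the velocity at the outlet
    cells (times the face transmissibility), so a corrupted velocity field
    is detected.  With the one-sided gradient used at the outlet column the
    velocity-based flux equals the discrete finite-volume face flux exactly.
    """
    d = fld.domain
    dx = d.cell_size_mm
    act = d.flow_active
    _idx, ia, ib, t = _connectivity(d)
    outlet = d.is_outlet[act]
    vx_cells = fld.vx_mm_min[act]
    source_flux = float(
        np.sum((d.width_factor * fld.source * dx * dx)[act & ~d.is_outlet])
    )
    if source_flux == 0:
        return 0.0
    # free <-> outlet faces; in this layout the outlet sits on the +x
    # boundary so these are x-faces and the outlet cell's one-sided vx
    # carries the face flux
    flux = 0.0
    for a, b in ((ia, ib), (ib, ia)):
        m = outlet[b] & ~outlet[a]
        flux += float(np.sum(t[m] * vx_cells[b[m]])) * dx
    return abs(source_flux - flux) / abs(source_flux)


def _bilinear(domain: SurfaceDomain, grid: np.ndarray, x_mm, y_mm) -> np.ndarray:
    """Bilinear interpolation of a cell-centred field; clamped at the edges."""
    dx = domain.cell_size_mm
    x = np.asarray(x_mm, dtype=float)
    y = np.asarray(y_mm, dtype=float)
    fx = np.clip(x / dx - 0.5, 0.0, domain.nx - 1.0)
    fy = np.clip(y / dx - 0.5, 0.0, domain.ny - 1.0)
    ix0 = np.floor(fx).astype(int)
    iy0 = np.floor(fy).astype(int)
    ix1 = np.minimum(ix0 + 1, domain.nx - 1)
    iy1 = np.minimum(iy0 + 1, domain.ny - 1)
    tx = fx - ix0
    ty = fy - iy0
    return (
        grid[iy0, ix0] * (1 - tx) * (1 - ty)
        + grid[iy0, ix1] * tx * (1 - ty)
        + grid[iy1, ix0] * (1 - tx) * ty
        + grid[iy1, ix1] * tx * ty
    )


_FIELD_COLUMNS = ["x_mm", "y_mm", "vx_mm_per_min", "vy_mm_per_min", "source"]


def write_field_csv(fld: MucusField, path: str | Path) -> None:
    d = fld.domain
    iy, ix = np.nonzero(d.active)
    pd.DataFrame(
        {
            "x_mm": d.x_mm[ix],
            "y_mm": d.y_mm[iy],
            "vx_mm_per_min": fld.vx_mm_min[iy, ix],
            "vy_mm_per_min": fld.vy_mm_min[iy, ix],
            "source": fld.source[iy, ix],
        }
    ).to_csv(path, index=False)


def load_field_csv(path: str | Path, domain: SurfaceDomain) -> MucusField:
    """Read an externally produced surface velocity field with the same schema."""
    df = pd.read_csv(path)
    missing = [c for c in _FIELD_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"field CSV missing columns: {missing}")
    vx = np.zeros(domain.region_id.shape)
    vy = np.zeros_like(vx)
    src = np.zeros_like(vx)
    iy, ix = domain.cell_index(df["x_mm"].to_numpy(), df["y_mm"].to_numpy())
    vx[iy, ix] = df["vx_mm_per_min"].to_numpy()
    vy[iy, ix] = df["vy_mm_per_min"].to_numpy()
    src[iy, ix] = df["source"].to_numpy()
    dx = domain.cell_size_mm
    source_flux = float(np.sum(src * domain.width_factor * dx * dx))
    return MucusField(
        domain=domain,
        vx_mm_min=vx,
        vy_mm_min=vy,
        source=src,
        potential=np.zeros_like(vx),
        source_flux=source_flux,
        outlet_flux=np.nan,
    )
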