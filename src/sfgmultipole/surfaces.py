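"""Interface location: Gibbs dividing surface and Willard–Chandler surface.

The Gibbs dividing surface (GDS) is the planar equimolar surface of the
laterally averaged density profile: the position where the integrated
density deficit on the liquid side equals the excess on the vapor side.
The Willard–Chandler surface (WCS) is the instantaneous corrugated
interface defined as an iso-level of a Gaussian coarse-grained density
field built from molecular centers of mass.

Depths follow the package convention: liquid at negative depth, vapor at
positive.  A slab has two equivalent interfaces; the lower one is handled
by reflection (z → −z), which flips the sign of any observable odd in z.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import ndimage

from .core_io import Frame, Trajectory


class SurfaceNotFound(Exception):
    """No liquid/vapor density contrast in the trajectory."""


@dataclass
class SurfaceDefinition:
    """Located interface(s).

    For ``kind="GDS"``: ``z_upper``/``z_lower`` are the planar equimolar
    positions (Å, lab frame).  For ``kind="WCS"``: ``height`` holds the
    per-frame height fields h(x, y, t) of the upper (vapor-facing) surface
    on a periodic lateral grid, plus the coarse-graining width ξ and
    iso-level used.
    """
    kind: str
    z_upper: float | None = None
    z_lower: float | None = None
    height: np.ndarray | None = None      # (n_frames, nx, ny)
    lateral_shape: tuple[int, int] | None = None
    xi: float | None = None
    iso_fraction: float | None = None
    z_center: float | None = None

    def mean_height(self) -> float:
        if self.kind == "GDS":
            return self.z_upper
        return float(np.mean(self.height))


# --------------------------------------------------------------------------
# density profiles and the GDS
# --------------------------------------------------------------------------

def density_profile(traj: Trajectory, bin_width: float = 0.25
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Laterally averaged molecular number density ρ(z) (Å⁻³), averaged
    over frames.  Returns (bin centers, density)."""
    Lz = traj.box[2]
    edges = np.arange(0.0, Lz + bin_width, bin_width)
    coms = traj.com_positions()[..., 2].ravel() % Lz
    hist, _ = np.histogram(coms, bins=edges)
    vol = traj.area * np.diff(edges)
    rho = hist / (vol * len(traj))
    return 0.5 * (edges[:-1] + edges[1:]), rho


def gds_from_profile(z: np.ndarray, rho: np.ndarray) -> float:
    """Equimolar surface of a single liquid→vapor profile (liquid at small
    z).  Solves ∫ρ dz = ρ_bulk·(z_GDS − z₀) over the transition window.

    A step profile returns the step position exactly; a linear ramp over
    [a, b] returns (a+b)/2.
    """
    z = np.asarray(z, dtype=float)
    rho = np.asarray(rho, dtype=float)
    rho_b = float(rho[:max(1, len(rho) // 10)].mean())
    rho_v = float(rho[-max(1, len(rho) // 10):].mean())
    if rho_b <= 0 or (rho_b - rho_v) < 0.5 * rho_b:
        raise SurfaceNotFound("no liquid/vapor density contrast in profile")
    # conservation: ρ_b·(z_GDS − z[0]) = ∫ρ dz  (vapor density ≈ 0 subtracted)
    total = np.trapezoid(rho - rho_v, z)
    return float(z[0] + total / (rho_b - rho_v))


def gibbs_dividing_surface(traj: Trajectory,
                           bin_width: float = 0.25) -> SurfaceDefinition:
    """Planar equimolar surfaces of a slab, one per interface."""
    z, rho = density_profile(traj, bin_width)
    if rho.max() <= 0:
        raise SurfaceNotFound("empty density profile")
    # slab center = density-weighted mean z
    zc = float((z * rho).sum() / rho.sum())
    upper = z >= zc
    lower = z < zc
    rho_bulk = rho[(z > zc - 2.5) & (z < zc + 2.5)].mean()
    if rho_bulk <= 0 or rho.min() > 0.5 * rho_bulk:
        raise SurfaceNotFound(
            "density profile has no vapor region — bulk-only box?")
    z_up = gds_from_profile(z[upper], rho[upper])
    # lower interface: reflect z → −z so the liquid is again at small z
    z_lo = -gds_from_profile(-z[lower][::-1], rho[lower][::-1])
    return SurfaceDefinition(kind="GDS", z_upper=z_up, z_lower=z_lo,
                             z_center=zc)


# --------------------------------------------------------------------------
# Willard–Chandler surface
# --------------------------------------------------------------------------

def willard_chandler_surface(frame: Frame, xi: float = 2.4,
                             iso_fraction: float = 0.5,
                             lateral_spacing: float = 1.0,
                             z_spacing: float = 0.25,
                             masses=(15.999, 1.008, 1.008),
                             side: str = "upper",
                             z_center: float | None = None
                             ) -> SurfaceDefinition:
    """Instantaneous surface from the Gaussian coarse-grained density.

    Molecular centers of mass are deposited on a periodic 3D grid and
    smoothed with a Gaussian of width ξ (periodic in all directions); the
    height field h(x, y) is the uppermost crossing of
    iso_fraction·ρ_bulk per lateral cell.  Cells without a crossing are
    filled by lateral interpolation (with a warning).
    """
    if frame.positions.shape[0] % len(masses):
        raise ValueError("site count incompatible with the site masses")
    m = np.asarray(masses, dtype=float)
    pos = frame.positions.reshape(-1, len(masses), 3)
    com = np.einsum("s,nsi->ni", m, pos) / m.sum()
    if com.shape[0] < 1:
        raise ValueError("need at least one molecule")
    box = frame.box
    if lateral_spacing > xi / 2.0:
        lateral_spacing = xi / 2.0
    nx = max(4, int(round(box[0] / lateral_spacing)))
    ny = max(4, int(round(box[1] / lateral_spacing)))
    nz = max(8, int(round(box[2] / z_spacing)))
    com_w = com % box
    idx = np.floor(com_w / box * [nx, ny, nz]).astype(int)
    idx[:, 0] %= nx
    idx[:, 1] %= ny
    idx[:, 2] %= nz
    field = np.zeros((nx, ny, nz))
    np.add.at(field, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    cell = box / [nx, ny, nz]
    field /= np.prod(cell)
    sigma = xi / cell
    field = ndimage.gaussian_filter(field, sigma=sigma, mode="wrap")

    zgrid = (np.arange(nz) + 0.5) * cell[2]
    if z_center is None:
        prof = field.mean(axis=(0, 1))
        z_center = float((zgrid * prof).sum() / prof.sum())
    bulk_sel = np.abs(zgrid - z_center) < 2.5
    rho_bulk = float(field[:, :, bulk_sel].mean())
    iso = iso_fraction * rho_bulk

    ic = int(round(z_center / cell[2] - 0.5))
    h = np.full((nx, ny), np.nan)
    # uppermost crossing above (side=upper) / below (side=lower) the center
    for ix in range(nx):
        col = field[ix]                       # (ny, nz)
        for iy in range(ny):
            prof = col[iy]
            if side == "upper":
                rng = range(nz - 2, ic - 1, -1)
                for k in rng:
                    if prof[k] >= iso > prof[k + 1]:
                        frac = (prof[k] - iso) / (prof[k] - prof[k + 1])
                        h[ix, iy] = zgrid[k] + frac * cell[2]
                        break
            else:
                rng = range(1, ic + 1)
                for k in rng:
                    if prof[k] >= iso > prof[k - 1]:
                        frac = (prof[k] - iso) / (prof[k] - prof[k - 1])
                        h[ix, iy] = zgrid[k] - frac * cell[2]
                        break
    missing = np.isnan(h)
    if missing.all():
        raise SurfaceNotFound("iso-level never crossed — no interface")
    if missing.any():
        warnings.warn(f"{missing.sum()} lateral cells without iso-crossing "
                      "filled by lateral interpolation")
        good = ~missing
        gx, gy = np.mgrid[0:nx, 0:ny]
        from scipy.interpolate import griddata
        h[missing] = griddata(
            np.column_stack([gx[good], gy[good]]), h[good],
            np.column_stack([gx[missing], gy[missing]]), method="nearest")
    return SurfaceDefinition(kind="WCS", height=h[None], xi=xi,
                             iso_fraction=iso_fraction,
                             lateral_shape=(nx, ny), z_center=z_center)


# --------------------------------------------------------------------------
# depth mapping
# --------------------------------------------------------------------------

def map_depths(traj: Trajectory, surface: SurfaceDefinition) -> np.ndarray:
    """Per-molecule depth series (n_frames, n_molecules), negative in the
    liquid.  Molecules are wrapped into the box, assigned to the nearer
    interface, and the lower interface is reflected (depth = z_lo − z)."""
    coms = traj.com_positions()
    box = traj.box
    z = coms[..., 2] % box[2]
    if surface.kind == "GDS":
        zc = surface.z_center if surface.z_center is not None else \
            0.5 * (surface.z_upper + surface.z_lower)
        upper = z >= zc
        depth = np.where(upper, z - surface.z_upper, surface.z_lower - z)
        return depth
    if surface.kind == "WCS":
        nx, ny = surface.lateral_shape
        hh = surface.height
        nfr = len(traj)
        depth = np.empty_like(z)
        for f in range(nfr):
            hmap = hh[f if hh.shape[0] > 1 else 0]
            ix = np.floor(coms[f, :, 0] % box[0] / box[0] * nx).astype(int) % nx
            iy = np.floor(coms[f, :, 1] % box[1] / box[1] * ny).astype(int) % ny
            depth[f] = z[f] - hmap[ix, iy]
        return depth
    raise ValueError(f"unknown surface kind {surface.kind}")
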