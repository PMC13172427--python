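"""Molecular frames, Euler angles, orientation statistics and the
orientation-only second-order susceptibility.

The body frame follows the interfacial-water convention: z′ along the
permanent dipole (HOH bisector), x′ out of the molecular plane, y′ = z′×x′.
Euler angles use the intrinsic z′y′z′ convention, so θ is the tilt of the
molecular dipole from the surface normal and ψ the spin about the dipole
axis.  The biaxial order parameter q₃₂ = cosθ·sin²θ·(cos²ψ−sin²ψ) is the
quantity that distinguishes inward- from outward-oriented molecules even
when the uniaxial moments cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core_io import DepthGrid, Frame, MoleculeTopology

SPECIES = ("inward", "outward", "planar", "other")

#: angular deviation (deg) from the idealized orientations that still
#: counts as a member of an orientational species
SPECIES_CONE_DEG = 36.0


class FrameError(Exception):
    """Degenerate molecular geometry (collinear sites)."""


# --------------------------------------------------------------------------
# order parameters
# --------------------------------------------------------------------------

def q10(theta):
    """First Legendre polynomial of cosθ."""
    return np.cos(theta)


def q30(theta):
    """Third Legendre polynomial of cosθ."""
    c = np.cos(theta)
    return 0.5 * (5.0 * c ** 3 - 3.0 * c)


def q32(theta, psi):
    """Biaxiality parameter cosθ·sin²θ·(cos²ψ − sin²ψ)."""
    return np.cos(theta) * np.sin(theta) ** 2 * np.cos(2.0 * np.asarray(psi))


# --------------------------------------------------------------------------
# molecular frame and Euler angles
# --------------------------------------------------------------------------

def molecular_frame_from_sites(sites: np.ndarray,
                               masses=None, eckart: bool = False,
                               reference: np.ndarray | None = None
                               ) -> np.ndarray:
    """Lab→body rotation matrix from one molecule's (O, H1, H2) sites.

    Rows of the returned matrix are the body axes in lab coordinates.  The
    default is the bisector frame; with ``eckart=True`` a mass-weighted
    rotational fit of the displaced geometry to the equilibrium
    ``reference`` sites is used instead, which minimizes rotation–vibration
    coupling for vibrating molecules.
    """
    sites = np.asarray(sites, dtype=float)
    b1 = sites[1] - sites[0]
    b2 = sites[2] - sites[0]
    n1, n2 = np.linalg.norm(b1), np.linalg.norm(b2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise FrameError("zero-length OH bond")
    u1, u2 = b1 / n1, b2 / n2
    x_ax = np.cross(u1, u2)
    if np.linalg.norm(x_ax) < 1e-10:
        raise FrameError("collinear sites: molecular plane undefined")
    if eckart:
        if reference is None or masses is None:
            raise ValueError("eckart frame needs reference sites and masses")
        m = np.asarray(masses, dtype=float)
        com = m @ sites / m.sum()
        rot, _ = Rotation.align_vectors(sites - com, reference, weights=m)
        return rot.as_matrix().T
    z_ax = u1 + u2
    z_ax = z_ax / np.linalg.norm(z_ax)
    x_ax = x_ax / np.linalg.norm(x_ax)
    y_ax = np.cross(z_ax, x_ax)
    return np.stack([x_ax, y_ax, z_ax])


def bisector_frames_batch(sites: np.ndarray) -> np.ndarray:
    """Vectorized lab→body bisector frames for (..., 3 sites, 3) arrays of
    (O, H1, H2) positions; rows of each output matrix are the body axes."""
    s = np.asarray(sites, dtype=float)
    b1 = s[..., 1, :] - s[..., 0, :]
    b2 = s[..., 2, :] - s[..., 0, :]
    u1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    u2 = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    z_ax = u1 + u2
    z_ax /= np.linalg.norm(z_ax, axis=-1, keepdims=True)
    x_ax = np.cross(u1, u2)
    nx = np.linalg.norm(x_ax, axis=-1, keepdims=True)
    if np.any(nx < 1e-10):
        raise FrameError("collinear sites: molecular plane undefined")
    x_ax /= nx
    y_ax = np.cross(z_ax, x_ax)
    return np.stack([x_ax, y_ax, z_ax], axis=-2)


def molecular_frame(frame: Frame, molecule: int,
                    topology: MoleculeTopology,
                    eckart: bool = False) -> np.ndarray:
    """Lab→body rotation of one molecule in a frame (see
    :func:`molecular_frame_from_sites`)."""
    sl = topology.molecule_slices()[molecule]
    sites = frame.positions[sl]
    ref = None
    if eckart:
        from .synthetic import ToyWaterModel, body_sites
        model = ToyWaterModel(bond_length=topology.bond_length,
                              bond_angle=topology.bond_angle)
        ref = body_sites(model)
    return molecular_frame_from_sites(
        sites, masses=topology.masses, eckart=eckart, reference=ref)


def euler_angles(rotation: np.ndarray, tol: float = 1e-7) -> np.ndarray:
    """(φ, θ, ψ) in the intrinsic z′y′z′ convention from a lab→body
    rotation matrix; recomposition reproduces the matrix to machine
    precision.

    At gimbal lock (sinθ below ``tol``; the default leaves headroom over
    the ~√ε noise of arccos) ψ is set to 0 and the full azimuthal rotation
    is absorbed into φ — a deterministic, continuous limit.
    """
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8) \
            or np.linalg.det(R) < 0:
        raise ValueError("input is not a proper rotation matrix")
    M = R.T                          # body→lab = Rz(φ)·Ry(θ)·Rz(ψ)
    c = np.clip(M[2, 2], -1.0, 1.0)
    theta = np.arccos(c)
    if np.sin(theta) < tol:
        psi = 0.0
        if c > 0:                                    # θ = 0: M = Rz(φ+ψ)
            phi = np.arctan2(M[1, 0], M[0, 0])
        else:                                        # θ = π: M = Rz(φ−ψ)·Ry(π)
            phi = np.arctan2(-M[1, 0], -M[0, 0])
    else:
        phi = np.arctan2(M[1, 2], M[0, 2])
        psi = np.arctan2(M[2, 1], -M[2, 0])
    return np.array([phi % (2 * np.pi), theta, psi % (2 * np.pi)])


def euler_angles_batch(rotations: np.ndarray) -> np.ndarray:
    """Vectorized :func:`euler_angles` for (..., 3, 3) lab→body matrices."""
    R = np.asarray(rotations, dtype=float)
    flat = R.reshape(-1, 3, 3)
    return np.stack([euler_angles(m) for m in flat]).reshape(
        R.shape[:-2] + (3,))


# --------------------------------------------------------------------------
# distribution and moments
# --------------------------------------------------------------------------

@dataclass
class OrientationDistribution:
    """Depth-resolved histogram ρ_ORI(θ, ψ), normalized per depth bin so
    ∫dφ ∫sinθ dθ ∫dψ ρ_ORI = 1 (the φ integral contributes 2π)."""
    density: np.ndarray       # (n_depth, n_theta, n_psi)
    theta_edges: np.ndarray
    psi_edges: np.ndarray
    counts: np.ndarray        # raw counts, same shape
    n_samples: np.ndarray     # per depth bin
    depth_grid: DepthGrid | None = None

    @property
    def empty_bins(self) -> np.ndarray:
        """Depth bins that received no samples (flagged, not zero-filled)."""
        return self.n_samples == 0

    def normalization(self) -> np.ndarray:
        """Quadrature of the normalization integral per depth bin (the
        exact bin measure 2π·Δcosθ·Δψ is used)."""
        dcos = -np.diff(np.cos(self.theta_edges))
        dps = np.diff(self.psi_edges)
        w = 2.0 * np.pi * dcos[:, None] * dps[None, :]
        return np.einsum("ztp,tp->z", self.density, w)


def orientation_distribution(angles: np.ndarray,
                             depths: np.ndarray | None = None,
                             grid: DepthGrid | None = None,
                             n_theta: int = 36, n_psi: int = 36
                             ) -> OrientationDistribution:
    """Histogram Euler angles into ρ_ORI(θ, ψ) per depth bin.

    ``angles`` is (N, 3) of (φ, θ, ψ); φ is integrated out (the slab is
    laterally isotropic).  Without a grid all samples land in one bin.
    """
    ang = np.asarray(angles, dtype=float)
    theta_edges = np.linspace(0.0, np.pi, n_theta + 1)
    psi_edges = np.linspace(0.0, 2.0 * np.pi, n_psi + 1)
    if grid is None:
        bin_idx = np.zeros(ang.shape[0], dtype=int)
        nz = 1
    else:
        if depths is None:
            raise ValueError("depths required with a depth grid")
        bin_idx = grid.assign(np.asarray(depths, dtype=float))
        nz = grid.n_bins
    counts = np.zeros((nz, n_theta, n_psi))
    ok = bin_idx >= 0
    th = np.clip(np.searchsorted(theta_edges, ang[ok, 1], "right") - 1,
                 0, n_theta - 1)
    ps = np.clip(np.searchsorted(psi_edges, ang[ok, 2] % (2 * np.pi),
                                 "right") - 1, 0, n_psi - 1)
    np.add.at(counts, (bin_idx[ok], th, ps), 1.0)
    n_samples = counts.sum(axis=(1, 2))
    # exact per-bin Haar measure 2π·Δcosθ·Δψ (the continuum prefactor
    # 1/(2π·sinθ·N) integrated over the bin) — avoids midpoint bias
    dcos = -np.diff(np.cos(theta_edges))
    dps = np.diff(psi_edges)
    norm = (2.0 * np.pi * dcos[None, :, None] * dps[None, None, :]
            * np.where(n_samples > 0, n_samples, 1.0)[:, None, None])
    return OrientationDistribution(counts / norm, theta_edges, psi_edges,
                                   counts, n_samples, grid)


@dataclass
class OrientationMoments:
    """Depth profiles of number density and Legendre/biaxial moments."""
    rho: np.ndarray          # Å⁻³
    q10: np.ndarray
    q30: np.ndarray
    q32: np.ndarray
    grid: DepthGrid
    counts: np.ndarray

    @property
    def empty_bins(self) -> np.ndarray:
        return self.counts == 0


def legendre_moments(angles: np.ndarray, depths: np.ndarray,
                     grid: DepthGrid, area: float,
                     n_frames: int = 1) -> OrientationMoments:
    """Per-depth-bin averages of q₁₀, q₃₀, q₃₂ and the molecular number
    density ρ(z) = counts/(A·Δz·n_frames)."""
    ang = np.asarray(angles, dtype=float)
    idx = grid.assign(np.asarray(depths, dtype=float))
    ok = idx >= 0
    vals = np.stack([q10(ang[ok, 1]), q30(ang[ok, 1]),
                     q32(ang[ok, 1], ang[ok, 2])], axis=1)
    nz = grid.n_bins
    counts = np.bincount(idx[ok], minlength=nz).astype(float)
    sums = np.zeros((nz, 3))
    np.add.at(sums, idx[ok], vals)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts[:, None] > 0, sums / counts[:, None], 0.0)
    rho = counts / (area * grid.width * n_frames)
    return OrientationMoments(rho, means[:, 0], means[:, 1], means[:, 2],
                              grid, counts)


# --------------------------------------------------------------------------
# orientational species
# --------------------------------------------------------------------------

def classify_oh_vectors(u1: np.ndarray, u2: np.ndarray,
                        cone_deg: float = SPECIES_CONE_DEG) -> np.ndarray:
    """Species labels from lab-frame OH unit vectors (broadcastable
    (..., 3)).  Inward: either OH within the cone around −ẑ; outward:
    around +ẑ; planar: both OH elevations within the cone of the xy plane.
    The rules are mutually exclusive for the water geometry (HOH > 2·36°).
    """
    cone = np.deg2rad(cone_deg)
    cz = np.cos(cone)
    z1 = np.asarray(u1)[..., 2]
    z2 = np.asarray(u2)[..., 2]
    inward = (z1 <= -cz) | (z2 <= -cz)
    outward = (z1 >= cz) | (z2 >= cz)
    planar = (np.abs(z1) <= np.sin(cone)) & (np.abs(z2) <= np.sin(cone))
    out = np.full(np.shape(z1), "other", dtype=object)
    out[planar] = "planar"
    out[outward & ~planar] = "outward"
    out[inward & ~planar & ~outward] = "inward"
    return out


def classify_species(frame: Frame, molecule: int,
                     topology: MoleculeTopology,
                     cone_deg: float = SPECIES_CONE_DEG) -> str:
    """Orientational species of one molecule (liquid at negative depth)."""
    sl = topology.molecule_slices()[molecule]
    sites = frame.positions[sl]
    b1 = sites[1] - sites[0]
    b2 = sites[2] - sites[0]
    u1 = b1 / np.linalg.norm(b1)
    u2 = b2 / np.linalg.norm(b2)
    return str(classify_oh_vectors(u1, u2, cone_deg))


def species_fractions(u1: np.ndarray, u2: np.ndarray,
                      cone_deg: float = SPECIES_CONE_DEG) -> dict:
    labels = classify_oh_vectors(u1, u2, cone_deg)
    n = labels.size
    return {s: float(np.sum(labels == s)) / n for s in SPECIES}


def oh_vectors_from_angles(angles: np.ndarray, half_angle: float
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Lab OH unit vectors for Euler angles (N, 3); ``half_angle`` is half
    the HOH angle in radians."""
    from .synthetic import rotations_from_euler
    R = rotations_from_euler(angles)          # body→lab
    s, c = np.sin(half_angle), np.cos(half_angle)
    u1 = np.array([0.0, s, c])
    u2 = np.array([0.0, -s, c])
    return R @ u1, R @ u2


# --------------------------------------------------------------------------
# hyperpolarizability decomposition
# --------------------------------------------------------------------------

_COMP = {"x": 0, "y": 1, "z": 2}


def beta_lab_component(beta_body: np.ndarray, component: str,
                       theta: np.ndarray, psi: np.ndarray,
                       n_phi: int = 8) -> np.ndarray:
    """φ-averaged lab-frame component of a body-frame rank-3 tensor.

    β_lab_ijk(θ, ψ) = ⟨R_ia R_jb R_kc⟩_φ β_body_abc with R = body→lab.
    The φ average uses an ``n_phi``-point uniform quadrature, exact for the
    trigonometric polynomials (degree ≤ 3) that arise from a rank-3 tensor.
    ``beta_body`` may carry trailing axes (e.g. a frequency axis) after the
    three tensor indices: shape (3, 3, 3, ...).
    """
    i, j, k = (_COMP[c] for c in component)
    th = np.asarray(theta, dtype=float).ravel()
    ps = np.asarray(psi, dtype=float).ravel()
    if th.shape != ps.shape:
        raise ValueError("theta and psi must have matching shapes")
    phis = 2.0 * np.pi * np.arange(n_phi) / n_phi
    acc = 0.0
    for phi in phis:
        ang = np.column_stack([np.full_like(th, phi), th, ps])
        R = Rotation.from_euler("ZYZ", ang).as_matrix()   # (N, 3, 3)
        acc = acc + np.einsum("na,nb,nc,abc...->n...",
                              R[:, i], R[:, j], R[:, k], beta_body)
    out = acc / n_phi
    return out.reshape(np.shape(theta) + beta_body.shape[3:])


@dataclass
class HyperpolarizabilityCoefficients:
    """Projection of β(θ, ψ) onto {q₁₀, q₃₀, q₃₂}; ``residual`` is the
    RMS misfit over the angular grid (same trailing shape as the data)."""
    b10: np.ndarray
    b30: np.ndarray
    b32: np.ndarray
    residual: np.ndarray

    def reconstruct(self, theta, psi):
        th = np.asarray(theta)[..., None] if np.ndim(self.b10) else theta
        ps = np.asarray(psi)[..., None] if np.ndim(self.b10) else psi
        return (q10(th) * self.b10 + q30(th) * self.b30
                + q32(th, ps) * self.b32)


def beta_quadrature_grid(n_theta: int = 64, n_psi: int = 64):
    """Gauss–Legendre nodes in cosθ × uniform ψ with Haar weights
    sinθ dθ dψ; returns (theta, psi, weights) as flat arrays."""
    x, wx = np.polynomial.legendre.leggauss(n_theta)
    theta = np.arccos(x)
    psi = (np.arange(n_psi) + 0.5) * 2.0 * np.pi / n_psi
    wpsi = 2.0 * np.pi / n_psi
    TH, PS = np.meshgrid(theta, psi, indexing="ij")
    W = np.broadcast_to((wx * wpsi)[:, None], TH.shape)
    return TH.ravel(), PS.ravel(), W.ravel()


def decompose_hyperpolarizability(beta_values: np.ndarray,
                                  theta: np.ndarray, psi: np.ndarray,
                                  weights: np.ndarray | None = None
                                  ) -> HyperpolarizabilityCoefficients:
    """Weighted least-squares projection of sampled β(θ, ψ) onto the
    uniaxial/biaxial basis {q₁₀(θ), q₃₀(θ), q₃₂(θ, ψ)}.

    ``beta_values`` has shape (N, ...) over the flattened angular grid with
    optional trailing axes (frequency); complex data is supported.
    """
    th = np.asarray(theta, dtype=float).ravel()
    ps = np.asarray(psi, dtype=float).ravel()
    vals = np.asarray(beta_values)
    if vals.shape[0] != th.size:
        raise ValueError("beta grid does not match the angular grid")
    design = np.column_stack([q10(th), q30(th), q32(th, ps)])
    w = np.ones_like(th) if weights is None else np.asarray(weights, float)
    if w.min() < 0:
        raise ValueError("negative quadrature weights")
    sw = np.sqrt(w)
    A = design * sw[:, None]
    gram = A.T @ A
    if np.linalg.cond(gram) > 1e10:
        raise np.linalg.LinAlgError(
            "degenerate angular grid: basis functions are not resolved")
    flat = vals.reshape(th.size, -1)
    coef = np.linalg.solve(gram, A.conj().T @ (flat * sw[:, None]))
    resid = flat - design @ coef
    rms = np.sqrt((w[:, None] * np.abs(resid) ** 2).sum(0) / w.sum())
    trailing = vals.shape[1:]
    return HyperpolarizabilityCoefficients(
        coef[0].reshape(trailing), coef[1].reshape(trailing),
        coef[2].reshape(trailing), rms.reshape(trailing))


def chi2_ori(moments: OrientationMoments,
             coeffs: HyperpolarizabilityCoefficients) -> np.ndarray:
    """Orientation-only susceptibility profile
    χ^(2,ORI)(z, ν) = ρ(z)·[q₁₀(z)β¹⁰ + q₃₀(z)β³⁰ + q₃₂(z)β³²]."""
    b10, b30, b32 = (np.atleast_1d(b)
                     for b in (coeffs.b10, coeffs.b30, coeffs.b32))
    if not (b10.shape == b30.shape == b32.shape):
        raise ValueError("coefficient grids differ")
    out = (moments.q10[:, None] * b10[None, :]
           + moments.q30[:, None] * b30[None, :]
           + moments.q32[:, None] * b32[None, :])
    return moments.rho[:, None] * out
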