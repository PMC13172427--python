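"""Synthetic polarizable toy-water trajectories with known ground truth.

The generator produces bulk boxes and liquid slabs of rigid/harmonic
water-like molecules whose electrostatic and vibrational response is fully
prescribed: site charges, an isotropic electronic dipole polarizability, a
small quadrupole polarizability, three internal modes (bend, symmetric and
antisymmetric stretch) with harmonic frequencies and Langevin friction, and
analytic dipole/polarizability derivatives along each mode.  Because every
parameter is assigned rather than emergent, each downstream stage (surfaces,
orientation statistics, local fields, response functions) can be checked
against closed forms.

Molecules never interact in the *dynamics* — internal modes are independent
damped harmonic oscillators and orientations are static per trajectory.
Collective electrostatics enter only through the induced-dipole local-field
solver, which keeps the ground truth analytic.

Coordinate conventions: interfaces lie in the xy plane, the liquid sits at
negative depth below the upper surface.  The molecular body frame has z′
along the permanent dipole (HOH bisector, pointing from O towards the H
side) and x′ out of the molecular plane.  "Inward" orientation puts one OH
bond along −ẑ (towards the liquid), "outward" along +ẑ, "planar" puts both
OH bonds in the xy plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core_io import Frame, MoleculeTopology, Trajectory
from .units import KB_AMU, wavenumber_to_angular

MODE_NAMES = ("bend", "sym", "asym")


class PackingError(Exception):
    """Could not place molecules at the requested density."""


class IntegrationError(Exception):
    """Time step too coarse for the fastest internal mode."""


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

def _c2v_quadrupole_polarizability(amplitude: float) -> np.ndarray:
    """Body-frame quadrupole polarizability α^QD_ijk (Å⁴), symmetric in the
    quadrupole indices (i, j), with a C2v-allowed sparsity pattern."""
    a = np.zeros((3, 3, 3))
    a[2, 2, 2] = 1.0 * amplitude
    a[0, 0, 2] = 0.4 * amplitude
    a[1, 1, 2] = 0.6 * amplitude
    a[0, 2, 0] = a[2, 0, 0] = 0.3 * amplitude
    a[1, 2, 1] = a[2, 1, 1] = 0.5 * amplitude
    return a


@dataclass
class ToyWaterModel:
    """Water-like rigid/harmonic molecule with assigned response parameters.

    Mode coordinates (all in Å): q_bend = r_eq·δα, q_sym = (δr₁+δr₂)/√2,
    q_asym = (δr₁−δr₂)/√2.  Each mode is a harmonic oscillator with
    effective mass ``mode_masses`` (amu), angular frequency from
    ``mode_wavenumbers`` (cm⁻¹), and Langevin friction ``friction`` (ps⁻¹).

    ``dalpha_dq`` are body-frame dα^DD/dq tensors (Å²/Å per mode) with the
    C2v symmetry of the corresponding mode; ``dalphaq_dq`` scales the
    quadrupole-polarizability pattern along each mode (Å³/Å).  dμ/dq needs
    no parameter: it follows from the fixed site charges and the geometry
    derivative (see :func:`dipole_derivatives`).
    """

    bond_length: float = 0.9572         # Å
    bond_angle: float = 104.52          # deg
    charges: tuple[float, float, float] = (-0.8476, 0.4238, 0.4238)  # O,H,H
    masses: tuple[float, float, float] = (15.999, 1.008, 1.008)
    alpha_e: float = 1.47               # Å³, isotropic electronic α/(4πε0)
    alphaq_e: float = 0.3               # Å⁴, quadrupole polarizability scale
    mode_wavenumbers: tuple[float, float, float] = (1650.0, 3650.0, 3750.0)
    mode_masses: tuple[float, float, float] = (1.0, 1.0, 1.0)   # amu
    friction: float = 4.0               # ps⁻¹, per mode
    dalpha_dq: tuple[np.ndarray, ...] | None = None
    dalphaq_dq: tuple[float, float, float] = (0.15, 0.25, 0.10)

    def __post_init__(self):
        if abs(sum(self.charges)) > 1e-12:
            raise ValueError("site charges must sum to zero")
        if any(nu <= 0 for nu in self.mode_wavenumbers):
            raise ValueError("mode wavenumbers must be positive")
        if self.alpha_e < 0:
            raise ValueError("electronic polarizability must be >= 0")
        if self.dalpha_dq is None:
            # Body-frame Raman tensors: A1 modes (bend, sym) are diagonal,
            # the B2 asymmetric stretch couples y′ and z′.
            self.dalpha_dq = (
                np.diag([0.20, 0.50, 0.80]),
                np.diag([0.60, 0.90, 1.20]),
                np.array([[0.0, 0.0, 0.0],
                          [0.0, 0.0, 0.70],
                          [0.0, 0.70, 0.0]]),
            )
        self.dalpha_dq = tuple(np.asarray(a, dtype=float)
                               for a in self.dalpha_dq)

    @property
    def angle_rad(self) -> float:
        return np.deg2rad(self.bond_angle)

    @property
    def mode_omegas(self) -> np.ndarray:
        """Angular mode frequencies in rad/fs."""
        return wavenumber_to_angular(np.asarray(self.mode_wavenumbers))

    def topology(self, n_molecules: int) -> MoleculeTopology:
        return MoleculeTopology(
            n_molecules=n_molecules, masses=self.masses,
            bond_length=self.bond_length, bond_angle=self.bond_angle)

    def site_charges(self, n_molecules: int) -> np.ndarray:
        return np.tile(self.charges, n_molecules)

    def quadrupole_polarizability(self) -> np.ndarray:
        return _c2v_quadrupole_polarizability(self.alphaq_e)


@dataclass
class Seed:
    """Integer RNG seed; a fixed seed reproduces trajectories bit for bit."""
    value: int

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.value)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, Seed):
        return seed.rng()
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class Layer:
    """Orientation recipe for one depth range (depth = z − z_surface,
    liquid negative).  ``weights`` mix the four orientational species and
    ``spread`` is the angular perturbation stddev (deg) about the ideal
    orientation for the non-isotropic species."""
    z_range: tuple[float, float]
    weights: dict[str, float] = field(
        default_factory=lambda: {"isotropic": 1.0})
    spread: float = 12.0

    def __post_init__(self):
        tot = sum(self.weights.values())
        if any(w < 0 for w in self.weights.values()) or tot <= 0:
            raise ValueError("layer weights must be >= 0 and sum > 0")
        for k in self.weights:
            if k not in ("isotropic", "inward", "outward", "planar"):
                raise ValueError(f"unknown orientational species '{k}'")
        self.weights = {k: w / tot for k, w in self.weights.items()}


@dataclass
class SlabSpec:
    """Liquid slab filling the box center, interfaces normal to z.

    Defaults mirror the study conditions this package is exercised under:
    a 20×20×60 Å box with 352 molecules in a ≈26 Å slab (bulk number
    density 0.0334 Å⁻³) and two equivalent planar interfaces.
    """
    box: tuple[float, float, float] = (20.0, 20.0, 60.0)
    n_molecules: int = 352
    thickness: float = 26.3
    layers: tuple[Layer, ...] = ()
    min_distance: float = 2.4           # Å, molecular centers

    def __post_init__(self):
        zr = sorted(self.layers, key=lambda l: l.z_range[0])
        for a, b in zip(zr[:-1], zr[1:]):
            if a.z_range[1] > b.z_range[0] + 1e-9:
                raise ValueError("layers overlap")
        density = self.n_molecules / (self.box[0] * self.box[1]
                                      * self.thickness)
        if density > 0.05:
            raise ValueError("slab density above liquid range")


def biaxial_triple_layer(spread: float = 12.0) -> tuple[Layer, ...]:
    """Three-layer inward/planar/outward ordering emulating the interfacial
    triple layer, on top of an isotropic interior.  Depth ranges are
    measured from the nominal slab surface (liquid negative), inside the
    region where molecules are actually placed."""
    return (
        Layer((-60.0, -5.0), {"isotropic": 1.0}),
        Layer((-5.0, -2.5), {"inward": 0.7, "isotropic": 0.3}, spread),
        Layer((-2.5, -1.0), {"planar": 0.7, "isotropic": 0.3}, spread),
        Layer((-1.0, 0.5), {"outward": 0.7, "isotropic": 0.3}, spread),
    )


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def body_sites(model: ToyWaterModel, r1: float | np.ndarray | None = None,
               r2=None, angle=None) -> np.ndarray:
    """Body-frame site positions (O, H1, H2) with the center of mass at the
    origin, z′ along the bisector, molecule in the y′z′ plane.

    Scalar or broadcastable arrays of (r1, r2, angle) are accepted; the
    site axis is second to last, e.g. shape (..., 3 sites, 3).
    """
    r1 = model.bond_length if r1 is None else r1
    r2 = model.bond_length if r2 is None else r2
    angle = model.angle_rad if angle is None else angle
    r1, r2, angle = np.broadcast_arrays(r1, r2, angle)
    h = angle / 2.0
    zero = np.zeros_like(r1)
    u1 = np.stack([zero, np.sin(h), np.cos(h)], axis=-1)
    u2 = np.stack([zero, -np.sin(h), np.cos(h)], axis=-1)
    H1 = r1[..., None] * u1
    H2 = r2[..., None] * u2
    mO, mH = model.masses[0], model.masses[1]
    M = mO + 2 * mH
    # O at the origin of the internal construction; shift COM to 0
    com = (mH * (H1 + H2)) / M
    O = -com
    return np.stack([O, H1 - com, H2 - com], axis=-2)


def dipole_derivatives(model: ToyWaterModel) -> np.ndarray:
    """Body-frame dμ/dq for (bend, sym, asym), shape (3 modes, 3).  Follows
    from μ = q_H(r₁u₁ + r₂u₂) and the mode definitions."""
    qH = model.charges[1]
    h = model.angle_rad / 2.0
    return np.array([
        [0.0, 0.0, -qH * np.sin(h)],              # bend (q_b = r_eq δα)
        [0.0, 0.0, qH * np.sqrt(2.0) * np.cos(h)],  # symmetric stretch
        [0.0, qH * np.sqrt(2.0) * np.sin(h), 0.0],  # antisymmetric stretch
    ])


def mode_coordinates(traj: Trajectory, model: ToyWaterModel) -> np.ndarray:
    """Extract (q_bend, q_sym, q_asym) per molecule, shape (n_frames,
    n_molecules, 3), from bond lengths and angle."""
    pos = traj.positions_array().reshape(
        len(traj), traj.topology.n_molecules, 3, 3)
    b1 = pos[..., 1, :] - pos[..., 0, :]
    b2 = pos[..., 2, :] - pos[..., 0, :]
    r1 = np.linalg.norm(b1, axis=-1)
    r2 = np.linalg.norm(b2, axis=-1)
    cosang = np.einsum("...i,...i", b1, b2) / (r1 * r2)
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    dr1 = r1 - model.bond_length
    dr2 = r2 - model.bond_length
    q_b = model.bond_length * (ang - model.angle_rad)
    return np.stack([q_b, (dr1 + dr2) / np.sqrt(2.0),
                     (dr1 - dr2) / np.sqrt(2.0)], axis=-1)


def _mode_jacobian(model: ToyWaterModel) -> np.ndarray:
    """∂(site positions)/∂q_m at equilibrium, shape (3 modes, 3 sites, 3).
    Used to map mode velocities onto site velocities."""
    eps = 1e-6
    jac = np.empty((3, 3, 3))
    for m in range(3):
        dq = np.zeros(3)
        dq[m] = eps
        jac[m] = (_sites_from_modes(model, dq) -
                  _sites_from_modes(model, -dq)) / (2 * eps)
    return jac


def _sites_from_modes(model: ToyWaterModel, q: np.ndarray) -> np.ndarray:
    """Body-frame sites for mode displacements q = (q_b, q_s, q_a);
    q may carry leading batch axes."""
    q = np.asarray(q, dtype=float)
    q_b, q_s, q_a = q[..., 0], q[..., 1], q[..., 2]
    dr1 = (q_s + q_a) / np.sqrt(2.0)
    dr2 = (q_s - q_a) / np.sqrt(2.0)
    dang = q_b / model.bond_length
    return body_sites(model, model.bond_length + dr1,
                      model.bond_length + dr2, model.angle_rad + dang)


# --------------------------------------------------------------------------
# orientations
# --------------------------------------------------------------------------

def sample_isotropic_orientations(n: int, seed) -> np.ndarray:
    """Draw n Euler-angle triples (φ, θ, ψ), z′y′z′ convention, from the
    Haar measure: φ, ψ uniform on [0, 2π), cosθ uniform on [−1, 1]."""
    if n <= 0:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    psi = rng.uniform(0.0, 2.0 * np.pi, n)
    theta = np.arccos(rng.uniform(-1.0, 1.0, n))
    return np.column_stack([phi, theta, psi])


def rotations_from_euler(angles: np.ndarray) -> np.ndarray:
    """Body→lab rotation matrices from (φ, θ, ψ) in the intrinsic z′y′z′
    convention, shape (..., 3, 3); columns are the body axes in lab
    coordinates."""
    a = np.atleast_2d(angles)
    mats = Rotation.from_euler("ZYZ", a).as_matrix()
    return mats if np.ndim(angles) > 1 else mats[0]


def ideal_species_angles(model: ToyWaterModel, species: str,
                         rng: np.random.Generator) -> np.ndarray:
    """Euler angles of one idealized orientational species; φ (and discrete
    mirror choices) randomized, so repeated draws tile the symmetry-
    equivalent configurations."""
    h = model.angle_rad / 2.0
    phi = rng.uniform(0.0, 2.0 * np.pi)
    if species == "inward":        # OH1 along −ẑ
        theta, psi = np.pi - h, -np.pi / 2.0
    elif species == "outward":     # OH1 along +ẑ
        theta, psi = h, np.pi / 2.0
    elif species == "planar":      # both OH in the xy plane
        theta, psi = np.pi / 2.0, 0.0 if rng.random() < 0.5 else np.pi
    else:
        raise ValueError(f"no ideal orientation for species '{species}'")
    if species in ("inward", "outward") and rng.random() < 0.5:
        psi = -psi                 # swap which OH is the vertical one
    return np.array([phi, theta, psi % (2.0 * np.pi)])


def _sample_layer_rotation(model: ToyWaterModel, layer: Layer,
                           rng: np.random.Generator) -> np.ndarray:
    names = list(layer.weights)
    probs = np.array([layer.weights[k] for k in names])
    species = names[rng.choice(len(names), p=probs)]
    if species == "isotropic":
        ang = sample_isotropic_orientations(1, rng)[0]
        return rotations_from_euler(ang)
    ideal = rotations_from_euler(ideal_species_angles(model, species, rng))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    wobble = Rotation.from_rotvec(
        axis * np.deg2rad(rng.normal(0.0, layer.spread))).as_matrix()
    return wobble @ ideal


def _mirror_rotation_z(R: np.ndarray) -> np.ndarray:
    """Reflect an orientation through the xy plane.  Water is achiral, so
    the mirrored configuration is again a proper rotation of the body frame
    (reflection about the molecular plane is absorbed into diag(−1,1,1))."""
    Mz = np.diag([1.0, 1.0, -1.0])
    Mx = np.diag([-1.0, 1.0, 1.0])
    return Mz @ R @ Mx


# --------------------------------------------------------------------------
# placement and slab/bulk builders
# --------------------------------------------------------------------------

def _place_centers(n: int, box: np.ndarray, z_range: tuple[float, float],
                   min_dist: float, rng: np.random.Generator,
                   max_tries: int = 800, periodic_z: bool = False
                   ) -> np.ndarray:
    """Random sequential insertion with a minimum center distance (periodic
    in x and y, and in z for bulk boxes; slab z distances are plain)."""
    centers = np.empty((n, 3))
    wrap = np.asarray(box[:3] if periodic_z else box[:2])
    nwrap = wrap.size
    placed = 0
    for i in range(n):
        for attempt in range(max_tries):
            c = np.array([rng.uniform(0, box[0]), rng.uniform(0, box[1]),
                          rng.uniform(*z_range)])
            if placed == 0:
                break
            d = centers[:placed] - c
            d[:, :nwrap] -= wrap * np.round(d[:, :nwrap] / wrap)
            if np.min(np.einsum("ij,ij->i", d, d)) > min_dist ** 2:
                break
        else:
            raise PackingError(
                f"could not place molecule {i + 1}/{n} after {max_tries} "
                "tries — density too high for the minimum distance")
        centers[placed] = c
        placed += 1
    return centers


def _assemble_frame(model: ToyWaterModel, centers: np.ndarray,
                    rotations: np.ndarray, box: np.ndarray,
                    q: np.ndarray | None = None,
                    qdot: np.ndarray | None = None,
                    time: float = 0.0) -> Frame:
    n = centers.shape[0]
    if q is None:
        sites_body = np.broadcast_to(body_sites(model), (n, 3, 3))
    else:
        sites_body = _sites_from_modes(model, q)
    pos = centers[:, None, :] + np.einsum(
        "nij,nsj->nsi", rotations, sites_body)
    vel = None
    if qdot is not None:
        jac = _mode_jacobian(model)            # (mode, site, 3)
        v_body = np.einsum("nm,msj->nsj", qdot, jac)
        vel = np.einsum("nij,nsj->nsi", rotations, v_body)
        vel = vel.reshape(-1, 3)
    return Frame(pos.reshape(-1, 3), box=np.asarray(box, float),
                 velocities=vel,
                 charges=model.site_charges(n), time=time)


def build_slab(spec: SlabSpec, model: ToyWaterModel, seed,
               n_frames: int = 1, temperature: float = 298.0) -> Trajectory:
    """Static-configuration slab ensemble: ``n_frames`` independently drawn
    packings with layer-resolved orientations.  Use
    :func:`langevin_dynamics` on a frame for vibrating trajectories."""
    rng = _as_rng(seed)
    box = np.asarray(spec.box, float)
    zc = box[2] / 2.0
    z_lo, z_hi = zc - spec.thickness / 2.0, zc + spec.thickness / 2.0
    frames = []
    for k in range(n_frames):
        centers = _place_centers(spec.n_molecules, box, (z_lo, z_hi),
                                 spec.min_distance, rng)
        rots = np.empty((spec.n_molecules, 3, 3))
        for i, c in enumerate(centers):
            # depth from the nearer interface; lower half mirrors the recipe
            lower = c[2] < zc
            depth = (z_lo - c[2]) if lower else (c[2] - z_hi)
            layer = None
            for lay in spec.layers:
                if lay.z_range[0] <= depth < lay.z_range[1]:
                    layer = lay
                    break
            if layer is None:
                layer = Layer(z_range=(-1e9, 1e9))
            R = _sample_layer_rotation(model, layer, rng)
            rots[i] = _mirror_rotation_z(R) if lower else R
        frames.append(_assemble_frame(model, centers, rots, box,
                                      time=float(k)))
    traj = Trajectory(frames, model.topology(spec.n_molecules), dt=1.0,
                      temperature=temperature, label="toy slab")
    return traj


def build_bulk(model: ToyWaterModel, seed, n_molecules: int = 297,
               density: float = 0.0334, n_frames: int = 1,
               min_distance: float = 2.4,
               temperature: float = 298.0) -> Trajectory:
    """Isotropic disordered bulk box at the given number density (Å⁻³).
    Defaults match the liquid-phase density of the slab system."""
    rng = _as_rng(seed)
    L = (n_molecules / density) ** (1.0 / 3.0)
    box = np.array([L, L, L])
    frames = []
    for k in range(n_frames):
        centers = _place_centers(n_molecules, box, (0.0, L),
                                 min_distance, rng, periodic_z=True)
        angles = sample_isotropic_orientations(n_molecules, rng)
        rots = rotations_from_euler(angles)
        frames.append(_assemble_frame(model, centers, rots, box,
                                      time=float(k)))
    return Trajectory(frames, model.topology(n_molecules), dt=1.0,
                      temperature=temperature, label="toy bulk")


# --------------------------------------------------------------------------
# dynamics
# --------------------------------------------------------------------------

def _frame_structure(frame: Frame, topo: MoleculeTopology,
                     model: ToyWaterModel):
    """Decompose a frame into per-molecule (centers, rotations, modes)."""
    from .orientation import molecular_frame_from_sites

    n = topo.n_molecules
    pos = frame.positions.reshape(n, 3, 3)
    m = np.asarray(model.masses)
    centers = np.einsum("s,nsi->ni", m, pos) / m.sum()
    rots = np.stack([molecular_frame_from_sites(pos[i]).T for i in range(n)])
    b1 = pos[:, 1] - pos[:, 0]
    b2 = pos[:, 2] - pos[:, 0]
    r1 = np.linalg.norm(b1, axis=1)
    r2 = np.linalg.norm(b2, axis=1)
    ang = np.arccos(np.clip(np.einsum("ni,ni->n", b1, b2) / (r1 * r2),
                            -1, 1))
    q = np.stack([model.bond_length * (ang - model.angle_rad),
                  (r1 + r2 - 2 * model.bond_length) / np.sqrt(2.0),
                  (r1 - r2) / np.sqrt(2.0)], axis=1)
    return centers, rots, q


def _ou_propagator(m: float, omega: float, gamma: float, kT: float,
                   dt: float):
    """Exact discrete-time propagator of the damped harmonic Langevin
    oscillator: x(t+dt) = Φ·x(t) + L·ξ with x = (q, p), Φ = e^{A·dt} and
    noise covariance Σ = Σ_st − Φ·Σ_st·Φᵀ (Σ_st the stationary
    covariance).  Being the exact Gaussian transition kernel, the scheme
    has no time-step error at any dt; with γ = 0 and T = 0 it reduces to
    an exact phase-space rotation that conserves energy to machine
    precision."""
    from scipy.linalg import expm

    A = np.array([[0.0, 1.0 / m], [-m * omega ** 2, -gamma]])
    Phi = expm(A * dt)
    Sst = np.diag([kT / (m * omega ** 2), m * kT])
    Sigma = Sst - Phi @ Sst @ Phi.T
    Sigma = 0.5 * (Sigma + Sigma.T)
    if kT > 0 and gamma > 0:
        w, V = np.linalg.eigh(Sigma)
        L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    else:
        L = np.zeros((2, 2))
    return Phi, L


def langevin_dynamics(start: Frame, model: ToyWaterModel, steps: int,
                      dt: float, T: float, seed,
                      stride: int = 1) -> Trajectory:
    """Evolve the internal modes of every molecule as independent damped
    harmonic Langevin oscillators; centers of mass and orientations stay
    fixed.  Every ``stride``-th step is stored, with site velocities
    mapped from the mode velocities.

    Each mode is propagated with the exact Gaussian transition kernel of
    the damped harmonic oscillator (no discretization error), so the
    stored correlation functions match the continuous-time closed forms
    exactly up to sampling noise.  ``dt`` must still resolve the fastest
    mode so that stored frames are not aliased.
    """
    omega = model.mode_omegas
    if dt * omega.max() > 2.0:
        raise IntegrationError(
            f"dt = {dt} fs does not resolve the fastest mode "
            f"({max(model.mode_wavenumbers):.0f} cm⁻¹): stored frames "
            f"would alias; use dt <= {2.0 / omega.max():.2f} fs")
    rng = _as_rng(seed)
    topo = model.topology(start.positions.shape[0] // 3)
    centers, rots, q = _frame_structure(start, topo, model)
    n = topo.n_molecules
    mmass = np.asarray(model.mode_masses)
    gamma = model.friction * 1e-3          # ps⁻¹ → fs⁻¹
    kT = KB_AMU * T
    p = (rng.normal(size=(n, 3)) * np.sqrt(mmass * kT)) if T > 0 \
        else np.zeros((n, 3))
    props = [_ou_propagator(mmass[m], omega[m], gamma, kT, dt)
             for m in range(3)]
    # block-diagonal propagation of all three modes at once
    Phi6 = np.zeros((6, 6))
    L6 = np.zeros((6, 6))
    for m, (Phi, L) in enumerate(props):
        Phi6[2 * m:2 * m + 2, 2 * m:2 * m + 2] = Phi
        L6[2 * m:2 * m + 2, 2 * m:2 * m + 2] = L
    noisy = L6.any()
    x = np.empty((6, n))
    x[0::2] = q.T
    x[1::2] = p.T

    frames = []
    for istep in range(steps):
        x = Phi6 @ x
        if noisy:
            x += L6 @ rng.normal(size=(6, n))
        q = x[0::2].T
        p = x[1::2].T
        if (istep + 1) % stride == 0:
            frames.append(_assemble_frame(
                model, centers, rots, start.box, q=q, qdot=p / mmass,
                time=(istep + 1) * dt))
    traj = Trajectory(frames, topo, dt=dt * stride, temperature=max(T, 1e-12),
                      label="toy langevin")
    return traj


def mirror_trajectory(traj: Trajectory) -> Trajectory:
    """Reflect every configuration through the slab midplane (z → Lz − z,
    velocity z-components negated).  Observables with an odd number of z
    indices change sign under this operation."""
    frames = []
    for f in traj.frames:
        pos = f.positions.copy()
        pos[:, 2] = f.box[2] - pos[:, 2]
        vel = None
        if f.velocities is not None:
            vel = f.velocities.copy()
            vel[:, 2] *= -1.0
        frames.append(Frame(pos, f.box.copy(), velocities=vel,
                            charges=None if f.charges is None
                            else f.charges.copy(), time=f.time))
    return Trajectory(frames, traj.topology, dt=traj.dt,
                      temperature=traj.temperature,
                      label=traj.label + " (z-mirrored)")


def mode_energies(traj: Trajectory, model: ToyWaterModel) -> dict:
    """Kinetic/potential energy per mode (amu·Å²/fs²) from stored frames,
    for equipartition and conservation checks."""
    q = mode_coordinates(traj, model)                   # (f, n, 3)
    jac = _mode_jacobian(model)                         # (m, s, 3)
    vel = traj.velocities_array().reshape(len(traj), -1, 3, 3)
    rots = []
    from .orientation import molecular_frame_from_sites
    pos0 = traj.frames[0].positions.reshape(-1, 3, 3)
    rots = np.stack([molecular_frame_from_sites(pos0[i]).T
                     for i in range(pos0.shape[0])])
    v_body = np.einsum("nji,fnsj->fnsi", rots, vel)     # lab→body (R^T v)
    # least-squares projection of site velocities on the mode patterns
    jmat = jac.reshape(3, 9).T                          # (9, modes)
    proj = np.linalg.pinv(jmat)                         # (modes, 9)
    qdot = np.einsum("mk,fnk->fnm", proj, v_body.reshape(len(traj), -1, 9))
    mmass = np.asarray(model.mode_masses)
    omega = model.mode_omegas
    kin = 0.5 * mmass * qdot ** 2
    pot = 0.5 * mmass * omega ** 2 * q ** 2
    return {"kinetic": kin, "potential": pot}
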