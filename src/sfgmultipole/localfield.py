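"""Self-consistent induced-multipole solver and local-field factors.

External-field convention: the spatially constant driving amplitude F is an
E-field for lateral polarizations (x, y) and D/ε0 for the surface-normal
polarization (z).  In the reduced electrostatic units of this package
(k_e = 1, ε0 = 1/4π) the z-driving is realized by a 3D Ewald sum under
tinfoil boundary conditions plus the planar (slab) shape term
E_z ← −4π·M_z/V, which converts the driven amplitude from an E- into a
D-field.  Lateral driving uses plain tinfoil Ewald, for which the applied
amplitude is the macroscopic E-field.

On a cubic lattice of isotropic point polarizabilities this machinery
reproduces the Lorentz/Clausius–Mossotti relations exactly:
f_x = (2+ε)/3 and f_z = (2+ε)/(3ε) with (ε−1)/(ε+2) = 4πα/(3v).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

from .core_io import DepthGrid, Frame

BANDS = ("SFG", "VIS", "IR")

#: molecules closer than this (Å, center distance) make the point-dipole
#: system ill-conditioned and are rejected
CONTACT_THRESHOLD = 1.2


class SolverError(Exception):
    """Non-convergent or ill-conditioned induced-dipole system."""


@dataclass
class ExternalFieldSpec:
    """Driving field: polarization ∈ {x, y, z}, amplitude (e/Å² scale) and
    frequency band.  For x/y the amplitude is an E-field, for z it is
    D/ε0."""
    polarization: str = "z"
    amplitude: float = 1.0
    band: str = "VIS"

    def __post_init__(self):
        if self.polarization not in ("x", "y", "z"):
            raise ValueError("polarization must be x, y or z")
        if self.band not in BANDS:
            raise ValueError(f"band must be one of {BANDS}")

    @property
    def axis(self) -> int:
        return {"x": 0, "y": 1, "z": 2}[self.polarization]


@dataclass
class InducedMoments:
    """Per-molecule induced dipoles (e·Å) and traceless quadrupoles
    (e·Å²) for one driven configuration."""
    dipoles: np.ndarray
    quadrupoles: np.ndarray | None = None


@dataclass
class LocalFieldFactors:
    """Per-molecule 3×3 field-dressing tensors f^n (column i = local
    E-field for unit external F_i) and the band they were solved for."""
    tensors: np.ndarray          # (N, 3, 3)
    band: str = "VIS"

    def diagonal(self, axis: int) -> np.ndarray:
        return self.tensors[:, axis, axis]


# --------------------------------------------------------------------------
# Ewald summation
# --------------------------------------------------------------------------

class EwaldSummation:
    """Ewald-summed electrostatics of point dipoles and point quadrupoles
    in an orthorhombic periodic box (tinfoil boundary conditions).

    Accuracy is controlled by a single relative target: the real-space
    cutoff is min(L)/2 and the splitting parameter / k-space cutoff follow
    from the requested accuracy.
    """

    def __init__(self, box, accuracy: float = 1e-6, rcut: float | None = None):
        self.box = np.asarray(box, dtype=float)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")
        self.volume = float(np.prod(self.box))
        self.rcut = float(rcut) if rcut else float(self.box.min()) / 2.0
        s = np.sqrt(-np.log(accuracy))          # erfc(s) ≈ accuracy
        self.eta = s / self.rcut
        kmax = 2.0 * self.eta * s
        nmax = np.ceil(kmax * self.box / (2.0 * np.pi)).astype(int)
        grids = [np.arange(-n, n + 1) for n in nmax]
        nx, ny, nz = np.meshgrid(*grids, indexing="ij")
        n_all = np.column_stack([nx.ravel(), ny.ravel(), nz.ravel()])
        # half space (±k pairs handled analytically)
        keep = ((n_all[:, 0] > 0)
                | ((n_all[:, 0] == 0) & (n_all[:, 1] > 0))
                | ((n_all[:, 0] == 0) & (n_all[:, 1] == 0)
                   & (n_all[:, 2] > 0)))
        k = 2.0 * np.pi * n_all[keep] / self.box
        k2 = np.einsum("ij,ij->i", k, k)
        sel = k2 <= kmax ** 2
        self.kvecs = k[sel]
        self.k2 = k2[sel]
        self.kweight = np.exp(-self.k2 / (4.0 * self.eta ** 2))

    # -- real-space kernels -------------------------------------------------
    def _bfuncs(self, r: np.ndarray, nmax: int) -> list[np.ndarray]:
        """Screened interaction kernels B_0…B_nmax with
        B_0 = erfc(ηr)/r and B_{n+1} = [(2n+1)B_n + g_n]/r²,
        g_n = (2η²)^n·(2η/√π)·exp(−η²r²)."""
        eta = self.eta
        g = (2.0 * eta / np.sqrt(np.pi)) * np.exp(-(eta * r) ** 2)
        out = [erfc(eta * r) / r]
        r2 = r * r
        for n in range(nmax):
            out.append(((2 * n + 1) * out[-1] + g) / r2)
            g = g * (2.0 * eta ** 2)
        return out

    def _pair_geometry(self, positions: np.ndarray):
        d = positions[:, None, :] - positions[None, :, :]
        d -= self.box * np.round(d / self.box)
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        return d, r

    # -- dipoles ------------------------------------------------------------
    def dipole_field_matrix(self, positions: np.ndarray) -> np.ndarray:
        """(3N, 3N) matrix G with E = G·μ: the Ewald field at every
        molecular center created by all point dipoles (self dipole excluded,
        its periodic images included)."""
        pos = np.asarray(positions, dtype=float)
        N = pos.shape[0]
        d, r = self._pair_geometry(pos)
        mask = (r > 1e-12) & (r < self.rcut)
        rs = np.where(mask, r, 1.0)
        B0, B1, B2 = self._bfuncs(rs, 2)
        B1 = np.where(mask, B1, 0.0)
        B2 = np.where(mask, B2, 0.0)
        # E_i = −B1 μ_i + B2 (μ·r) r_i
        G = np.zeros((N, 3, N, 3))
        for a in range(3):
            G[:, a, :, a] -= B1
        G += np.einsum("ij,ija,ijb->iajb", B2, d, d)
        # reciprocal part: E = −(4π/V) Σ_k w_k (k̂k̂·μ) cos(k·r_ij), ±k → ×2
        if self.kvecs.size:
            phase = pos @ self.kvecs.T               # (N, nk)
            c, s_ = np.cos(phase), np.sin(phase)
            khat = self.kvecs / np.sqrt(self.k2)[:, None]
            pref = -2.0 * (4.0 * np.pi / self.volume) * self.kweight
            for a in range(3):
                for b in range(a, 3):
                    kk = pref * khat[:, a] * khat[:, b]
                    m = (c * kk) @ c.T + (s_ * kk) @ s_.T
                    G[:, a, :, b] += m
                    if a != b:
                        G[:, b, :, a] += m
        # remove the spurious screened self-field, restore i=j images only
        self_term = 4.0 * self.eta ** 3 / (3.0 * np.sqrt(np.pi))
        for a in range(3):
            G[np.arange(N), a, np.arange(N), a] += self_term
        return G.reshape(3 * N, 3 * N)

    # -- quadrupoles ---------------------------------------------------------
    def quadrupole_field_matrix(self, positions: np.ndarray,
                                quadrupoles: np.ndarray) -> np.ndarray:
        """Field at each center from every source quadrupole separately:
        (N_target, 3, N_source); the diagonal (self) entry is the field of
        the molecule's own periodic images."""
        pos = np.asarray(positions, dtype=float)
        Q = np.asarray(quadrupoles, dtype=float)
        N = pos.shape[0]
        if Q.shape != (N, 3, 3):
            raise ValueError("quadrupoles must be (N, 3, 3)")
        d, r = self._pair_geometry(pos)
        if np.any((r < 1e-9) & ~np.eye(N, dtype=bool)):
            i, j = np.argwhere((r < 1e-9) & ~np.eye(N, dtype=bool))[0]
            raise SolverError(f"overlapping molecular centers {i} and {j}")
        mask = (r > 1e-12) & (r < self.rcut)
        rs = np.where(mask, r, 1.0)
        _, _, B2, B3 = self._bfuncs(rs, 3)
        B2 = np.where(mask, B2, 0.0)
        B3 = np.where(mask, B3, 0.0)
        # E(r) from Q at origin: −B2·(Q·r) + (B3/2)·(r·Q·r)·r,  r = target−source
        Qr = np.einsum("jab,ijb->ija", Q, d)         # (i,j,3)
        rQr = np.einsum("ija,ija->ij", Qr, d)
        E = -np.einsum("ij,ija->iaj", B2, Qr) \
            + 0.5 * np.einsum("ij,ij,ija->iaj", B3, rQr, d)
        if self.kvecs.size:
            phase = pos @ self.kvecs.T               # (N, nk)
            c, s_ = np.cos(phase), np.sin(phase)
            kQk = np.einsum("ka,nab,kb->nk", self.kvecs, Q, self.kvecs)
            inv = self.kweight / self.k2
            # E_a(r_i ← j) = −2(2π/V) Σ_k k_a w_k (k·Q_j·k/k²)
            #                × [s_i c_j − c_i s_j]   (±k pairs → factor 2)
            pref = -2.0 * (2.0 * np.pi / self.volume)
            for a in range(3):
                V_a = (kQk * inv).T * self.kvecs[:, a:a + 1]   # (nk, N)
                E[:, a, :] += pref * (s_ @ (V_a * c.T) - c @ (V_a * s_.T))
        return E

    def quadrupole_fields(self, positions: np.ndarray,
                          quadrupoles: np.ndarray) -> np.ndarray:
        """E-field (N, 3) at every molecular center from all *other*
        molecules' traceless point quadrupoles (second-moment convention:
        the bare potential is φ = ½·Q_jk·∂_j∂_k(1/r)); the field of a
        molecule's own periodic images is included, its central self-field
        vanishes by symmetry."""
        return self.quadrupole_field_matrix(positions,
                                            quadrupoles).sum(axis=2)


def dipole_field_direct(position: np.ndarray, dipole: np.ndarray,
                        targets: np.ndarray) -> np.ndarray:
    """Bare (non-periodic) point-dipole field at target points."""
    d = np.atleast_2d(targets) - position
    r = np.linalg.norm(d, axis=1)
    return (3.0 * d * (d @ dipole)[:, None] / r[:, None] ** 5
            - dipole / r[:, None] ** 3)


def quadrupole_field_direct(position: np.ndarray, Q: np.ndarray,
                            targets: np.ndarray) -> np.ndarray:
    """Bare field of one traceless point quadrupole (second-moment
    convention) at target points: E = −3(Q·r)/r⁵ + (15/2)(r·Q·r)·r/r⁷."""
    d = np.atleast_2d(targets) - position
    r = np.linalg.norm(d, axis=1)
    Qr = d @ Q
    rQr = np.einsum("ia,ia->i", Qr, d)
    return (-3.0 * Qr / r[:, None] ** 5
            + 7.5 * rQr[:, None] * d / r[:, None] ** 7)


# --------------------------------------------------------------------------
# self-consistent solver
# --------------------------------------------------------------------------

class InducedDipoleSolver:
    """Linear self-consistent solution of the induced-dipole equations
    μ^n = α^n·E_loc^n,  E_loc^n = F_ext + Σ_m G^{nm} μ^m (+ slab term),
    solved as one dense system (I − α·G)·μ = α·F.

    The same factorized operator also provides the linear dipole response
    to arbitrary source fields, which is what the DQ (dipole–quadrupole
    cross) channel needs.
    """

    def __init__(self, positions: np.ndarray, box,
                 alphas: np.ndarray | float, accuracy: float = 1e-6,
                 contact: float = CONTACT_THRESHOLD):
        self.positions = np.asarray(positions, dtype=float)
        self.N = self.positions.shape[0]
        self.ewald = EwaldSummation(box, accuracy=accuracy)
        d, r = self.ewald._pair_geometry(self.positions)
        off = r + np.eye(self.N) * 1e9
        if self.N > 1 and off.min() < contact:
            i, j = np.unravel_index(np.argmin(off), off.shape)
            raise SolverError(
                f"molecules {i} and {j} are {off.min():.2f} Å apart — "
                "below the point-dipole contact threshold")
        if np.isscalar(alphas):
            A = np.zeros((self.N, 3, 3))
            A[:] = np.eye(3) * float(alphas)
        else:
            A = np.asarray(alphas, dtype=float)
            if A.shape == (self.N,):
                A = A[:, None, None] * np.eye(3)
        self.alphas = A
        self.G = self.ewald.dipole_field_matrix(self.positions)
        self._lu = {}

    def _alpha_block(self) -> np.ndarray:
        blk = np.zeros((3 * self.N, 3 * self.N))
        for n in range(self.N):
            blk[3 * n:3 * n + 3, 3 * n:3 * n + 3] = self.alphas[n]
        return blk

    def _operator(self, slab_z: bool) -> np.ndarray:
        G = self.G.copy()
        if slab_z:
            # planar shape term: uniform E_z ← −(4π/V)·M_z at every center
            zsel = np.arange(self.N) * 3 + 2
            G[np.ix_(zsel, zsel)] -= 4.0 * np.pi / self.ewald.volume
        return G

    def _solve_system(self, slab_z: bool, rhs_fields: np.ndarray
                      ) -> np.ndarray:
        """Dipoles (3N, n_rhs) for external/source fields (3N, n_rhs)."""
        key = bool(slab_z)
        if key not in self._lu:
            from scipy.linalg import lu_factor
            A = np.eye(3 * self.N) - self._alpha_block() @ self._operator(
                slab_z)
            self._lu[key] = (lu_factor(A), self._operator(slab_z))
        from scipy.linalg import lu_solve
        lu, G = self._lu[key]
        rhs = self._alpha_block() @ rhs_fields
        mu = lu_solve(lu, rhs)
        # residual of the fixed-point equation
        eloc = rhs_fields + G @ mu
        res = mu - self._alpha_block() @ eloc
        scale = np.abs(mu).max()
        if scale > 0 and np.abs(res).max() / scale > 1e-10:
            raise SolverError("self-consistent residual above 1e-10 — "
                              "system is ill-conditioned")
        return mu

    def solve(self, ext: ExternalFieldSpec) -> tuple[np.ndarray, np.ndarray]:
        """Induced dipoles (N, 3) and local fields (N, 3) for a uniform
        driving amplitude along ``ext.polarization``."""
        F = np.zeros((3 * self.N, 1))
        F[ext.axis::3, 0] = ext.amplitude
        slab_z = ext.polarization == "z"
        mu = self._solve_system(slab_z, F)
        eloc = F + self._operator(slab_z) @ mu
        return mu.reshape(self.N, 3), eloc.reshape(self.N, 3)

    def dipole_response(self, source_fields: np.ndarray,
                        slab_z: bool = False) -> np.ndarray:
        """Linear induced-dipole response (N, 3, ...) to given source
        E-fields (N, 3, ...) — the operator behind the DQ channel."""
        f = np.asarray(source_fields, dtype=float)
        flat = f.reshape(3 * self.N, -1)
        mu = self._solve_system(slab_z, flat)
        return mu.reshape(f.shape)

    def field_factors(self, band: str = "VIS") -> LocalFieldFactors:
        """Per-molecule f^n: column i is the local E-field for unit
        external amplitude along i (E for x/y, D/ε0 for z)."""
        tensors = np.empty((self.N, 3, 3))
        for i, pol in enumerate(("x", "y", "z")):
            _, eloc = self.solve(ExternalFieldSpec(pol, 1.0, band))
            tensors[:, :, i] = eloc
        return LocalFieldFactors(tensors, band)


def solve_local_fields(frame: Frame, model, ext: ExternalFieldSpec,
                       accuracy: float = 1e-6
                       ) -> tuple[LocalFieldFactors, InducedMoments]:
    """Self-consistent local fields and induced multipoles for one frame of
    a toy-water trajectory (molecular centers of mass, isotropic electronic
    polarizability, C2v quadrupole polarizability)."""
    from .orientation import bisector_frames_batch

    n = frame.positions.shape[0] // 3
    pos = frame.positions.reshape(n, 3, 3)
    masses = np.asarray(model.masses)
    centers = np.einsum("s,nsi->ni", masses, pos) / masses.sum()
    solver = InducedDipoleSolver(centers, frame.box, model.alpha_e,
                                 accuracy=accuracy)
    mu, eloc = solver.solve(ext)
    lf = solver.field_factors(ext.band)
    # induced quadrupoles from the body-frame QD polarizability
    R = bisector_frames_batch(pos)                      # lab→body
    aq_body = model.quadrupole_polarizability()
    aq_lab = np.einsum("nai,nbj,nck,ijk->nabc", R.transpose(0, 2, 1),
                       R.transpose(0, 2, 1), R.transpose(0, 2, 1), aq_body)
    quad = np.einsum("nabc,nc->nab", aq_lab, eloc)
    quad = 0.5 * (quad + quad.transpose(0, 2, 1))
    quad -= np.eye(3) * np.trace(quad, axis1=1, axis2=2)[:, None, None] / 3.0
    return lf, InducedMoments(mu, quad)


def averaged_field_factors(lf: LocalFieldFactors, depths: np.ndarray,
                           grid: DepthGrid) -> dict:
    """Laterally averaged local-field-factor profiles f_i(z): per-bin mean
    of the diagonal local-to-external amplitude ratio.  Returns
    {"f_x", "f_y", "f_z", "counts"}; empty bins are NaN-flagged."""
    idx = grid.assign(np.asarray(depths, dtype=float))
    ok = idx >= 0
    nz = grid.n_bins
    counts = np.bincount(idx[ok], minlength=nz).astype(float)
    out = {"counts": counts}
    for i, name in enumerate(("f_x", "f_y", "f_z")):
        sums = np.bincount(idx[ok], weights=lf.diagonal(i)[ok], minlength=nz)
        with np.errstate(invalid="ignore"):
            out[name] = np.where(counts > 0, sums / np.maximum(counts, 1),
                                 np.nan)
    return out


def quadrupole_source_fields(moments: InducedMoments, frame: Frame,
                             centers: np.ndarray | None = None,
                             accuracy: float = 1e-6) -> np.ndarray:
    """Ewald-summed E-field of every molecule's traceless source quadrupole
    at all other molecular centers (self term excluded)."""
    if centers is None:
        n = frame.positions.shape[0] // 3
        pos = frame.positions.reshape(n, 3, 3)
        centers = pos.mean(axis=1)
    ew = EwaldSummation(frame.box, accuracy=accuracy)
    return ew.quadrupole_fields(centers, moments.quadrupoles)
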