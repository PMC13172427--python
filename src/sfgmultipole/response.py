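"""Linear and second-order response profiles, multipole decomposition and
SFG spectra from classical fluctuation–dissipation relations.

All response functions are classical Kubo transforms of equilibrium
correlation functions: for an observable correlated with the total dipole
moment P (the conjugate variable of the IR driving −P·F), the response is
χ(ν) = (1/kBT)·[C(0) + iω·C̃(ν)] with C̃ the one-sided windowed transform.
The time derivative is taken analytically in the frequency domain.  No
quantum-correction factor is applied anywhere: the classical response
function is the leading-order harmonic approximation of its quantum
counterpart, and factors like ħωβ/(1−e^{−ħωβ}) relate correlation
functions, not response functions.

Second-order channels (β labels):

* ``D``   — electric dipole density: correlation of the dressed dipole
  polarizability α^DD·f binned at the molecular center with P.
* ``Q``   — electric quadrupole density: same with the izl component of
  the quadrupole polarizability α^QD·f and an extra ∂/∂z on the binned
  correlation.
* ``DQ``  — linear induced-dipole response to the electrostatic fields of
  the second-order source quadrupoles (Ewald-summed), correlated with P.
* ``DD``  — D − DQ, the pure electric dipole (interface-structure) term.
* ``M``   — magnetic dipole bulk term from molecular magnetic moments
  m = ½·Σ Δr×(q·v); yyz only, zzz vanishes by symmetry.

Orientations of the toy molecules are static, so rotation-dependent
structure tensors are evaluated once per trajectory (a timescale-separation
choice that matches the generator); mode coordinates carry the full time
dependence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import (DepthGrid, SpectralGrid, Trajectory,
                      causal_correlation, kubo_transform)
from .localfield import (EwaldSummation, InducedDipoleSolver,
                         LocalFieldFactors)
from .orientation import bisector_frames_batch
from .synthetic import (ToyWaterModel, dipole_derivatives, mode_coordinates)
from .units import C0_CM_FS, EA_TO_AMU, KB_EA, wavenumber_to_angular

#: no harmonic quantum-correction factor is applied (or available) anywhere
APPLIES_QUANTUM_CORRECTION = False

FOUR_PI = 4.0 * np.pi
_AX = {"x": 0, "y": 1, "z": 2}


class ResponseError(Exception):
    pass


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class LinearResponseProfile:
    """s(1,P)_ij(z, ν): reduced polarization response (4πP_i per unit
    driving amplitude), components xx (lateral average) and zz."""
    s_xx: np.ndarray
    s_zz: np.ndarray
    grid: DepthGrid
    frequencies: np.ndarray


@dataclass
class DielectricProfile:
    eps_xx: np.ndarray
    eps_zz: np.ndarray
    eps_iso: np.ndarray
    grid: DepthGrid
    frequencies: np.ndarray

    def absorption(self, component: str = "iso") -> np.ndarray:
        """ω·ε″(z, ν) (rad/fs units for ω)."""
        eps = {"xx": self.eps_xx, "zz": self.eps_zz,
               "iso": self.eps_iso}[component]
        return wavenumber_to_angular(self.frequencies)[None, :] * eps.imag


@dataclass
class SecondOrderProfile:
    """Depth-resolved second-order response s(2,β)_ijk(z, ν)."""
    values: np.ndarray            # (nz, nfreq) complex
    grid: DepthGrid
    frequencies: np.ndarray
    component: str = "yyz"
    beta: str = "D"

    def __add__(self, other):
        self._check(other)
        return SecondOrderProfile(self.values + other.values, self.grid,
                                  self.frequencies, self.component, "sum")

    def __sub__(self, other):
        self._check(other)
        return SecondOrderProfile(self.values - other.values, self.grid,
                                  self.frequencies, self.component, "diff")

    def _check(self, other):
        if self.values.shape != other.values.shape:
            raise ValueError("profile shapes differ")


@dataclass
class SFGSpectrum:
    """Depth-integrated spectrum S(2,β)_ijk(ν) with wavevector mismatch
    and red-shift metadata."""
    values: np.ndarray
    frequencies: np.ndarray
    dkz: float = 0.0              # nm⁻¹
    component: str = "yyz"
    beta: str = "D"
    redshift: dict = field(default_factory=dict)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass
class Chi2DL:
    """Second-order electric dipole susceptibility χ(2,DL)(z, ν) =
    s(2,DD)/(f_SFG·f_VIS·f_IR) and the field-factor product used."""
    values: np.ndarray
    f_product: np.ndarray         # (nz,)
    grid: DepthGrid
    frequencies: np.ndarray
    component: str = "yyz"

    def reconstruct_sdd(self) -> np.ndarray:
        """f³-product × χ — reproduces s(2,DD) exactly where unmasked."""
        return self.values * self.f_product[:, None]


# --------------------------------------------------------------------------
# trajectory pre-processing
# --------------------------------------------------------------------------

class TrajectoryObservables:
    """Per-frame molecular observables shared by the response channels:
    mode coordinates, static body→lab rotations (frame 0), permanent
    molecular dipoles and the total box dipole."""

    def __init__(self, traj: Trajectory, model: ToyWaterModel):
        self.traj = traj
        self.model = model
        self.n_mol = traj.topology.n_molecules
        pos = traj.positions_array().reshape(len(traj), self.n_mol, 3, 3)
        self.q = mode_coordinates(traj, model)          # (nf, nmol, 3)
        self.R0 = bisector_frames_batch(pos[0])          # (nmol, 3, 3) lab→body
        charges = np.asarray(model.charges)
        # molecular dipoles about the molecular center (origin-free, neutral)
        coms = traj.com_positions()
        self.mol_dipoles = np.einsum(
            "s,fnsi->fni", charges, pos - coms[:, :, None, :])
        self.P = self.mol_dipoles.sum(axis=1)            # (nf, 3)
        self.coms = coms

    def lab_raman_tensors(self) -> np.ndarray:
        """Static body→lab rotated dα/dq tensors, (nmol, nmode, 3, 3)."""
        A = np.stack(self.model.dalpha_dq)               # (nmode, 3, 3)
        Rt = self.R0.transpose(0, 2, 1)                  # body→lab
        return np.einsum("nia,njb,mab->nmij", Rt, Rt, A)

    def lab_quad_pattern(self) -> np.ndarray:
        """Static rotated unit quadrupole-polarizability pattern,
        (nmol, 3, 3, 3)."""
        from .synthetic import _c2v_quadrupole_polarizability
        P = _c2v_quadrupole_polarizability(1.0)
        Rt = self.R0.transpose(0, 2, 1)
        return np.einsum("nia,njb,nkc,abc->nijk", Rt, Rt, Rt, P)

    def quad_scalar_series(self) -> np.ndarray:
        """s_q(t) = αq_e + Σ_m (dα^QD/dq)_m q_m(t), shape (nf, nmol)."""
        daq = np.asarray(self.model.dalphaq_dq)
        return self.model.alphaq_e + np.einsum("fnm,m->fn", self.q, daq)

    def alpha_dd_series(self, i: int, j: int,
                        lf: LocalFieldFactors | None = None) -> np.ndarray:
        """[α^DD(t)·f]_{ij} per molecule, shape (nf, nmol)."""
        B = self.lab_raman_tensors()                     # (n, m, 3, 3)
        if lf is None:
            out = np.einsum("fnm,nmij->fnij", self.q, B)[:, :, i, j]
            if i == j:
                out = out + self.model.alpha_e
            return out
        f = lf.tensors                                   # (n, 3, 3)
        af = np.einsum("nmik,nkj->nmij", B, f)
        out = np.einsum("fnm,nm->fn", self.q, af[:, :, i, j])
        return out + self.model.alpha_e * f[:, i, j]


def _bin_series(weights: np.ndarray, depths: np.ndarray,
                signs: np.ndarray | None, grid: DepthGrid) -> np.ndarray:
    """Σ_n w^n(t)·sign^n(t)·1[z^n(t) ∈ bin] → (n_bins, nt)."""
    nf, nm = weights.shape
    idx = grid.assign(depths.reshape(-1)).reshape(nf, nm)
    w = weights if signs is None else weights * signs
    out = np.zeros((grid.n_bins, nf))
    ok = idx >= 0
    frame_idx = np.broadcast_to(np.arange(nf)[:, None], idx.shape)
    np.add.at(out, (idx[ok], frame_idx[ok]), w[ok])
    return out


def _kubo_profile(binned: np.ndarray, conjugate: np.ndarray,
                  sgrid: SpectralGrid, prefactor: float) -> np.ndarray:
    """Mean-subtracted causal correlation of per-bin series with the
    conjugate dipole component, Kubo-transformed."""
    b = binned - binned.mean(axis=1, keepdims=True)
    p = conjugate - conjugate.mean()
    corr = causal_correlation(b, p, sgrid.n_lags)
    return prefactor * kubo_transform(corr, sgrid)


def _component_sign_parity(component: str) -> bool:
    """True when the lower slab interface must be sign-flipped (odd number
    of z indices)."""
    return component.count("z") % 2 == 1


def interface_signs(depth_like: np.ndarray, sides: np.ndarray | None,
                    component: str) -> np.ndarray | None:
    if sides is None or not _component_sign_parity(component):
        return None
    return sides


# --------------------------------------------------------------------------
# linear response and dielectric profiles
# --------------------------------------------------------------------------

def linear_polarization_response(traj: Trajectory, model: ToyWaterModel,
                                 depths: np.ndarray, grid: DepthGrid,
                                 sgrid: SpectralGrid,
                                 n_interfaces: int = 1,
                                 conjugate: str = "total"
                                 ) -> LinearResponseProfile:
    """Depth-resolved vibrational polarization response from the causal
    correlation of the binned molecular dipole density with the total
    dipole, scaled by 4π/(A·Δz·kBT).

    x and y channels are averaged (the slab is laterally isotropic).
    ``n_interfaces=2`` when both slab interfaces are folded onto one depth
    axis (the effective sampling area doubles).  ``conjugate="self"``
    correlates each molecule with its own dipole — identical in
    expectation for dynamically uncoupled molecules, far lower variance.
    """
    obs = TrajectoryObservables(traj, model)
    kT = KB_EA * traj.temperature
    pref = FOUR_PI / (n_interfaces * traj.area * grid.width * kT)
    out = {}
    for comp in ("xx", "yy", "zz"):
        i = _AX[comp[0]]
        if conjugate == "total":
            binned = _bin_series(obs.mol_dipoles[:, :, i], depths, None,
                                 grid)
            out[comp] = _kubo_profile(binned, obs.P[:, i], sgrid, pref)
        elif conjugate == "self":
            out[comp] = _self_conjugate_profile(
                obs.mol_dipoles[:, :, i], obs.mol_dipoles[:, :, i],
                depths, None, grid, sgrid, pref)
        else:
            raise ValueError("conjugate must be 'total' or 'self'")
    return LinearResponseProfile(
        s_xx=0.5 * (out["xx"] + out["yy"]), s_zz=out["zz"],
        grid=grid, frequencies=sgrid.frequencies)


def dielectric_profiles(lin: LinearResponseProfile,
                        electronic_eps: float | None = None
                        ) -> DielectricProfile:
    """Pointwise maps ε_xx = 1 + s_xx and ε_zz = 1/(1 − s_zz), isotropic
    average (2ε_xx + ε_zz)/3; poles of the zz map are masked (NaN) with a
    warning.  ``electronic_eps`` optionally adds a constant electronic
    background to the vibrational response before mapping."""
    sxx, szz = lin.s_xx, lin.s_zz
    if electronic_eps is not None:
        sxx = sxx + (electronic_eps - 1.0)
        szz = szz + 1.0 - 1.0 / electronic_eps
    denom = 1.0 - szz
    bad = np.abs(denom) < 1e-6
    if bad.any():
        warnings.warn(f"{bad.sum()} grid points at the ε_zz pole masked")
        denom = np.where(bad, np.nan, denom)
    eps_xx = 1.0 + sxx
    eps_zz = 1.0 / denom
    return DielectricProfile(eps_xx, eps_zz, (2.0 * eps_xx + eps_zz) / 3.0,
                             lin.grid, lin.frequencies)


def lorentz_oscillator_epsilon(model: ToyWaterModel, density: float,
                               nu: np.ndarray) -> np.ndarray:
    """Closed-form dielectric function of an isotropic gas of independent
    harmonic dipole oscillators (no local-field coupling):
    ε(ν) = 1 + (4πρ/3)·Σ_m |dμ/dq|²·EA_TO_AMU / (m_m·(ω_m²−ω²−iγω))."""
    omega = wavenumber_to_angular(np.asarray(nu, dtype=float))
    dmu = dipole_derivatives(model)
    gamma = model.friction * 1e-3
    eps = np.ones_like(omega, dtype=complex)
    for m in range(3):
        denom = (model.mode_omegas[m] ** 2 - omega ** 2
                 - 1j * gamma * omega) * model.mode_masses[m]
        eps += (FOUR_PI * density / 3.0) * (dmu[m] @ dmu[m]) \
            * EA_TO_AMU / denom
    return eps


def oscillator_response(model: ToyWaterModel, mode: int,
                        nu: np.ndarray) -> np.ndarray:
    """Classical response ⟨q; q⟩ of one internal mode in reduced units:
    EA_TO_AMU/(m·(ω₀² − ω² − iγω))."""
    omega = wavenumber_to_angular(np.asarray(nu, dtype=float))
    gamma = model.friction * 1e-3
    return EA_TO_AMU / (model.mode_masses[mode]
                        * (model.mode_omegas[mode] ** 2 - omega ** 2
                           - 1j * gamma * omega))


def molecular_hyperpolarizability(model: ToyWaterModel,
                                  nu: np.ndarray) -> np.ndarray:
    """Body-frame double-harmonic hyperpolarizability β_abc(ν),
    shape (3, 3, 3, n_freq):
    β = 4π·Σ_m (dα/dq)_m,ab·(dμ/dq)_m,c·⟨q; q⟩_m(ν).

    The 4π puts β on the same reduced scale as the response profiles, so
    (1/V)·Σ_n β_lab matches χ(2,DL) directly.
    """
    dmu = dipole_derivatives(model)
    beta = np.zeros((3, 3, 3, len(np.atleast_1d(nu))), dtype=complex)
    for m in range(3):
        osc = oscillator_response(model, m, nu)
        beta += FOUR_PI * np.einsum(
            "ab,c,f->abcf", model.dalpha_dq[m], dmu[m], osc)
    return beta


# --------------------------------------------------------------------------
# second-order profiles
# --------------------------------------------------------------------------

def second_order_dipole_profile(traj: Trajectory, model: ToyWaterModel,
                                depths: np.ndarray, grid: DepthGrid,
                                sgrid: SpectralGrid,
                                components=("yyz", "zzz"),
                                lf: LocalFieldFactors | None = None,
                                sides: np.ndarray | None = None,
                                origin_offset: np.ndarray | None = None,
                                conjugate: str = "total",
                                n_interfaces: int = 1
                                ) -> dict[str, SecondOrderProfile]:
    """Electric dipole response profile s(2,D)_ijk(z, ν) (Kubo transform of
    the dressed-polarizability/dipole correlation).

    ``depths`` is (nf, nmol); ``sides`` (±1) symmetrizes the two slab
    interfaces for z-odd components; ``origin_offset`` shifts the
    molecular expansion origin by a body-frame vector (Å).

    ``conjugate`` selects the IR-side dipole in the correlator: ``total``
    is the full fluctuation–dissipation form (total box dipole);
    ``self`` correlates each molecule with its own dipole, which has the
    same expectation for dynamically uncoupled molecules but a far
    smaller variance — the per-molecule estimator used for
    hyperpolarizability extraction.
    """
    if model.dalpha_dq is None:
        raise ResponseError("model supplies no dα/dq")
    _check_nyquist(model, sgrid)
    obs = TrajectoryObservables(traj, model)
    kT = KB_EA * traj.temperature
    pref = FOUR_PI / (n_interfaces * traj.area * grid.width * kT)
    depths = _shift_depths(depths, obs, origin_offset)
    out = {}
    for comp in components:
        i, j, k = (_AX[c] for c in comp)
        w = obs.alpha_dd_series(i, j, lf)
        sg = interface_signs(depths, sides, comp)
        if conjugate == "total":
            binned = _bin_series(w, depths, sg, grid)
            vals = _kubo_profile(binned, obs.P[:, k], sgrid, pref)
        elif conjugate == "self":
            vals = _self_conjugate_profile(
                w, obs.mol_dipoles[:, :, k], depths, sg, grid, sgrid, pref)
        else:
            raise ValueError("conjugate must be 'total' or 'self'")
        out[comp] = SecondOrderProfile(vals, grid, sgrid.frequencies,
                                       comp, "D")
    return out


def _self_conjugate_profile(w: np.ndarray, mol_dip: np.ndarray,
                            depths: np.ndarray, signs: np.ndarray | None,
                            grid: DepthGrid, sgrid: SpectralGrid,
                            prefactor: float) -> np.ndarray:
    """Per-molecule correlation ⟨w^n(t)·μ^n_k(0)⟩ binned by the molecule's
    mean depth (valid for static molecular centers)."""
    a = (w - w.mean(axis=0)).T                       # (nmol, nt)
    b = (mol_dip - mol_dip.mean(axis=0)).T
    corr = causal_correlation(a, b, sgrid.n_lags)    # (nmol, nlags)
    if signs is not None:
        corr = corr * signs.mean(axis=0)[:, None]
    idx = grid.assign(depths.mean(axis=0))
    binned = np.zeros((grid.n_bins, sgrid.n_lags))
    ok = idx >= 0
    np.add.at(binned, idx[ok], corr[ok])
    return prefactor * kubo_transform(binned, sgrid)


def second_order_quadrupole_profile(traj: Trajectory, model: ToyWaterModel,
                                    depths: np.ndarray, grid: DepthGrid,
                                    sgrid: SpectralGrid,
                                    components=("yyz", "zzz"),
                                    lf: LocalFieldFactors | None = None,
                                    sides: np.ndarray | None = None,
                                    origin_offset: np.ndarray | None = None,
                                    n_interfaces: int = 1
                                    ) -> dict[str, SecondOrderProfile]:
    """Electric quadrupole response profile s(2,Q)_ijk(z, ν): the izl
    component of α^QD·f binned at the molecular center, Kubo-transformed,
    with ∂/∂z applied as a central difference on the binned correlation
    (one-sided at the grid ends) and an overall sign opposite to the D
    channel."""
    _check_nyquist(model, sgrid)
    obs = TrajectoryObservables(traj, model)
    kT = KB_EA * traj.temperature
    pref = FOUR_PI / (n_interfaces * traj.area * grid.width * kT)
    sq = obs.quad_scalar_series()                 # (nf, nmol)
    pattern = obs.lab_quad_pattern()              # (n, 3, 3, 3)
    depths0 = _shift_depths(depths, obs, origin_offset)
    out = {}
    for comp in components:
        i, j, k = (_AX[c] for c in comp)
        if lf is None:
            g_static = pattern[:, i, 2, j]
        else:
            g_static = np.einsum("nl,nl->n", pattern[:, i, 2, :],
                                 lf.tensors[:, :, j])
        w = sq * g_static[None, :]
        if origin_offset is not None:
            # Q about a shifted origin: α'^QD_izl = α^QD_izl
            #   − d_i·α^DD_zl − d_z·α^DD_il  (d in lab coordinates)
            dlab = np.einsum("nab,b->na", obs.R0.transpose(0, 2, 1),
                             np.asarray(origin_offset, float))
            w = w - dlab[None, :, i] * obs.alpha_dd_series(2, j, lf) \
                  - dlab[None, :, 2] * obs.alpha_dd_series(i, j, lf)
        sg = interface_signs(depths0, sides, comp)
        binned = _bin_series(w, depths0, sg, grid)
        b = binned - binned.mean(axis=1, keepdims=True)
        p = obs.P[:, k] - obs.P[:, k].mean()
        corr = causal_correlation(b, p, sgrid.n_lags)
        corr = -_d_dz(corr, grid.width)   # Q channel: +Θ∂z∂t (D has −Θ∂t)
        vals = pref * kubo_transform(corr, sgrid)
        out[comp] = SecondOrderProfile(vals, grid, sgrid.frequencies,
                                       comp, "Q")
    return out


def _d_dz(arr: np.ndarray, dz: float) -> np.ndarray:
    """Central difference along the leading (depth) axis, one-sided at the
    ends."""
    return np.gradient(arr, dz, axis=0)


def _shift_depths(depths, obs: TrajectoryObservables, origin_offset):
    if origin_offset is None:
        return np.asarray(depths, dtype=float)
    dlab = np.einsum("nab,b->na", obs.R0.transpose(0, 2, 1),
                     np.asarray(origin_offset, dtype=float))
    return np.asarray(depths, dtype=float) + dlab[None, :, 2]


def _check_nyquist(model: ToyWaterModel, sgrid: SpectralGrid):
    nyq = 1.0 / (2.0 * sgrid.dt * C0_CM_FS)
    if max(model.mode_wavenumbers) > nyq:
        raise ResponseError(
            f"write-out interval {sgrid.dt} fs too coarse: Nyquist "
            f"{nyq:.0f} cm⁻¹ below the stretch band "
            f"{max(model.mode_wavenumbers):.0f} cm⁻¹")


# --------------------------------------------------------------------------
# DD/DQ split
# --------------------------------------------------------------------------

def split_dd_dq(traj: Trajectory, model: ToyWaterModel,
                d_profiles: dict[str, SecondOrderProfile],
                depths: np.ndarray, grid: DepthGrid, sgrid: SpectralGrid,
                lf: LocalFieldFactors | None = None,
                sides: np.ndarray | None = None,
                coupling: bool = True, accuracy: float = 1e-6,
                n_interfaces: int = 1) -> tuple[dict, dict]:
    """Split the D channel into DD (pure dipole) and DQ (dipole response to
    source-quadrupole fields): DQ is computed from the Ewald fields of the
    per-molecule second-order source quadrupoles, optionally dressed by the
    self-consistent dipole–dipole coupling; DD = D − DQ pointwise.

    If the model carries no quadrupole channel (αq_e = 0 and zero
    derivatives) the split degenerates to DD = D with a warning.
    """
    obs = TrajectoryObservables(traj, model)
    if model.alphaq_e == 0 and not any(model.dalphaq_dq):
        warnings.warn("no quadrupole channel in the model: DD = D")
        dq = {c: SecondOrderProfile(np.zeros_like(p.values), grid,
                                    sgrid.frequencies, c, "DQ")
              for c, p in d_profiles.items()}
        dd = {c: SecondOrderProfile(p.values.copy(), grid,
                                    sgrid.frequencies, c, "DD")
              for c, p in d_profiles.items()}
        return dd, dq
    kT = KB_EA * traj.temperature
    pref = FOUR_PI / (n_interfaces * traj.area * grid.width * kT)
    pattern = obs.lab_quad_pattern()
    centers0 = obs.coms[0]
    ew = EwaldSummation(traj.box, accuracy=accuracy)
    solver = InducedDipoleSolver(centers0, traj.box, model.alpha_e,
                                 accuracy=accuracy) if coupling else None
    sq = obs.quad_scalar_series()
    dd_out, dq_out = {}, {}
    for comp, dprof in d_profiles.items():
        i, j, k = (_AX[c] for c in comp)
        # unit source quadrupole structure per molecule (VIS polarization j)
        if lf is None:
            Qhat = pattern[:, :, :, j]
        else:
            Qhat = np.einsum("nabl,nl->nab", pattern, lf.tensors[:, :, j])
        Qhat = 0.5 * (Qhat + Qhat.transpose(0, 2, 1))
        tr = np.trace(Qhat, axis1=1, axis2=2)
        Qhat = Qhat - np.eye(3)[None] * tr[:, None, None] / 3.0
        # response matrix W[i_target, n_source]: dipole i at target per unit s_q
        F = ew.quadrupole_field_matrix(centers0, Qhat)    # (N, 3, N)
        N = centers0.shape[0]
        if coupling:
            mu_resp = solver.dipole_response(
                F.reshape(N * 3, N), slab_z=False).reshape(N, 3, N)
        else:
            mu_resp = model.alpha_e * F
        W = mu_resp[:, i, :]                              # (target, source)
        w_series = np.einsum("ts,fs->ft", W, sq)          # (nf, nmol)
        sg = interface_signs(depths, sides, comp)
        binned = _bin_series(w_series, depths, sg, grid)
        vals = _kubo_profile(binned, obs.P[:, k], sgrid, pref)
        dq_out[comp] = SecondOrderProfile(vals, grid, sgrid.frequencies,
                                          comp, "DQ")
        dd_out[comp] = SecondOrderProfile(dprof.values - vals, grid,
                                          sgrid.frequencies, comp, "DD")
    return dd_out, dq_out


# --------------------------------------------------------------------------
# magnetic dipole bulk contribution
# --------------------------------------------------------------------------

def magnetic_bulk_contribution(traj: Trajectory, model: ToyWaterModel,
                               sgrid: SpectralGrid,
                               omega_vis_thz: float = 2730.0
                               ) -> dict[str, SFGSpectrum]:
    """Leading-order magnetic dipole contribution to the SFG spectrum from
    a bulk trajectory.

    Molecular magnetic moments m^n = ½·Σ_sites Δr×(q·v) are correlated
    with the total dipole and Kubo-transformed; the result carries the
    1/ω_VIS prefactor of the magnetic multipole expansion.  Only yyz is
    non-zero; zzz vanishes because (∇×m)_z cannot couple two lateral
    polarizations in a laterally isotropic system.  This classical
    estimator is approximate and flagged as such in the metadata.
    """
    vel = traj.velocities_array()
    if sgrid.dt > 0.5:
        raise ResponseError(
            "magnetic channel needs fine write-out (<= 0.5 fs)")
    n = traj.topology.n_molecules
    pos = traj.positions_array().reshape(len(traj), n, 3, 3)
    v = vel.reshape(len(traj), n, 3, 3)
    charges = np.asarray(model.charges)
    m_mass = np.asarray(model.masses)
    coms = np.einsum("s,fnsi->fni", m_mass, pos) / m_mass.sum()
    dr = pos - coms[:, :, None, :]
    mag = 0.5 * np.einsum("s,fnsi->fni",
                          charges, np.cross(dr, v))      # (nf, nmol, 3)
    M = mag.sum(axis=1)                                  # (nf, 3)
    kT = KB_EA * traj.temperature
    volume = float(np.prod(traj.box))
    omega_vis = 2.0 * np.pi * omega_vis_thz * 1e-3       # THz → rad/fs
    pref = FOUR_PI / (volume * kT * omega_vis)
    Mx = M[:, 0] - M[:, 0].mean()
    Pz = traj.total_dipole()[:, 2]
    Pz = Pz - Pz.mean()
    corr = causal_correlation(Mx[None, :], Pz, sgrid.n_lags)
    vals = (pref * kubo_transform(corr, sgrid))[0]
    meta = {"estimator": "classical molecular magnetic moment, approximate",
            "omega_vis_thz": omega_vis_thz}
    return {
        "yyz": SFGSpectrum(vals, sgrid.frequencies, 0.0, "yyz", "M", meta),
        "zzz": SFGSpectrum(np.zeros_like(vals), sgrid.frequencies, 0.0,
                           "zzz", "M", meta),
    }


# --------------------------------------------------------------------------
# spectra, susceptibilities, band integrals
# --------------------------------------------------------------------------

def integrate_spectrum(profile: SecondOrderProfile, dkz: float = 0.0,
                       z_window: tuple[float, float] | None = None
                       ) -> SFGSpectrum:
    """S(2,β)_ijk(ν) = ∫dz e^{−iΔk_z·z}·s(2,β)(z, ν) over the depth grid
    (or a sub-window).  Δk_z in nm⁻¹.  Warns when the profile has not
    decayed at the window ends."""
    z = profile.grid.centers
    vals = profile.values
    if z_window is not None:
        sel = (z >= z_window[0]) & (z <= z_window[1])
        z, vals = z[sel], vals[sel]
    scale = np.abs(vals).max()
    if scale > 0:
        tails = max(np.abs(vals[0]).max(), np.abs(vals[-1]).max()) / scale
        if tails > 0.05:
            warnings.warn(
                f"profile tail magnitude {tails:.2f}×max at the grid "
                "boundary — depth integral may miss bulk contributions")
    phase = np.exp(-1j * (dkz / 10.0) * z)       # nm⁻¹ → Å⁻¹
    S = (phase[:, None] * vals).sum(axis=0) * profile.grid.width
    return SFGSpectrum(S, profile.frequencies, dkz, profile.component,
                       profile.beta)


def chi2_dl(dd: SecondOrderProfile, f_profiles: dict,
            threshold: float = 0.05) -> Chi2DL:
    """χ(2,DL)(z, ν) = s(2,DD)/(f_i^SFG·f_j^VIS·f_k^IR) with the band
    approximation f^α ≈ f^VIS.  Bins where the field-factor product falls
    below ``threshold`` (deep vacuum noise) are masked NaN."""
    comp = dd.component
    prof_for = {"x": f_profiles["f_x"], "y": f_profiles["f_y"],
                "z": f_profiles["f_z"]}
    fprod = np.ones(dd.grid.n_bins)
    for c in comp:
        fprod = fprod * prof_for[c]
    bad = ~np.isfinite(fprod) | (np.abs(fprod) < threshold)
    safe = np.where(bad, np.nan, fprod)
    with np.errstate(invalid="ignore"):
        vals = dd.values / safe[:, None]
    return Chi2DL(vals, safe, dd.grid, dd.frequencies, comp)


def band_integral(values: np.ndarray, frequencies: np.ndarray,
                  nu1: float = 1507.0, nu2: float = 1772.0) -> np.ndarray:
    """Σχ(z) = c0·∫_{ν1}^{ν2} dν·Im χ(z, ν) over the bending band
    (defaults 1507–1772 cm⁻¹)."""
    if nu1 < frequencies[0] or nu2 > frequencies[-1]:
        raise ValueError("band outside the spectral grid")
    sel = (frequencies >= nu1) & (frequencies <= nu2)
    vals = np.atleast_2d(values)[:, sel]
    out = C0_CM_FS * np.trapezoid(np.imag(vals), frequencies[sel], axis=1)
    return out if np.ndim(values) > 1 else out[0]


def effective_eps_relations(spectrum: SFGSpectrum | SecondOrderProfile,
                            eps_eff: dict) -> np.ndarray:
    """Effective-dielectric-constant relations: χ_yyz = ε_eff^IR·s_yyz,
    χ_zzz = ε_eff^SFG·ε_eff^VIS·ε_eff^IR·s_zzz."""
    comp = spectrum.component
    if comp == "yyz":
        factor = eps_eff.get("IR", 1.0)
    elif comp == "zzz":
        factor = (eps_eff.get("SFG", 1.0) * eps_eff.get("VIS", 1.0)
                  * eps_eff.get("IR", 1.0))
    else:
        raise ValueError(f"no effective-ε relation for component {comp}")
    return spectrum.values * factor


def apply_redshift(spec: SFGSpectrum, bend_shift: float = 28.0,
                   stretch_shift: float = 166.0,
                   boundary: float = 2500.0) -> SFGSpectrum:
    """Red-shift the frequency axis piecewise (bend band below ``boundary``,
    stretch band above) to align double-harmonic predictions with
    experiment; intensities are untouched (pure relabeling).

    Raises when the two shifted segments overlap *and* both carry signal
    there (stitching would be ambiguous)."""
    nu = spec.frequencies
    if boundary <= nu[0] or boundary >= nu[-1]:
        lower = nu - (bend_shift if boundary >= nu[-1] else stretch_shift)
        return SFGSpectrum(spec.values.copy(), lower, spec.dkz,
                           spec.component, spec.beta,
                           {**spec.redshift, "bend_shift": bend_shift,
                            "stretch_shift": stretch_shift,
                            "boundary": boundary})
    lo = nu < boundary
    nu_lo = nu[lo] - bend_shift
    nu_hi = nu[~lo] - stretch_shift
    overlap = nu_hi < nu_lo[-1] if nu_lo.size and nu_hi.size else \
        np.zeros(0, dtype=bool)
    if np.any(overlap):
        mags = np.abs(spec.values[~lo][overlap])
        near_top = np.abs(spec.values[lo][nu_lo >= nu_hi.min()]) \
            if np.any(nu_lo >= nu_hi.min()) else np.zeros(1)
        scale = np.abs(spec.values).max()
        if scale > 0 and mags.max() > 0.05 * scale \
                and near_top.max() > 0.05 * scale:
            raise ResponseError(
                "shifted segments overlap where both carry signal — "
                "cannot stitch the red-shifted axis")
    new_nu = np.concatenate([nu_lo, nu_hi])
    meta = {**spec.redshift, "bend_shift": bend_shift,
            "stretch_shift": stretch_shift, "boundary": boundary}
    return SFGSpectrum(spec.values.copy(), new_nu, spec.dkz,
                       spec.component, spec.beta, meta)


def total_spectrum(spectra: list[SFGSpectrum]) -> SFGSpectrum:
    """Σ_β S(2,β) over the supplied channels (matching grids required)."""
    vals = np.zeros_like(spectra[0].values)
    for s in spectra:
        if s.frequencies.shape != spectra[0].frequencies.shape:
            raise ValueError("spectra live on different grids")
        vals = vals + s.values
    return SFGSpectrum(vals, spectra[0].frequencies, spectra[0].dkz,
                       spectra[0].component, "total")
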