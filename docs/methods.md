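# Methods

`sfgmultipole` computes multipole-resolved sum-frequency-generation (SFG)
observables of a planar liquid/vapor interface from molecular-dynamics
trajectories: depth-resolved linear dielectric and absorption profiles,
second-order response profiles split into electric-dipole (DD),
dipole–quadrupole cross (DQ), electric-quadrupole (Q) and magnetic-dipole
(M) channels, local-field-factor profiles from a self-consistent
induced-dipole solver, and a biaxial orientation analysis that links the
electric-dipole signal to layered molecular ordering.  Everything is
exercised end to end on a built-in polarizable toy-water generator whose
ground truth is analytic.

## Field convention and units

The driving fields are taken spatially constant across the (thin)
interfacial region: an E-field for polarizations parallel to the interface
(x, y) and D/ε0 for the surface normal (z).  With this choice the
dielectric profile follows from two algebraic maps of the reduced
polarization response s(z, ν) ≡ 4πP/F,

    ε_zz(z, ν) = 1 / (1 − s_zz(z, ν)),      ε_xx(z, ν) = 1 + s_xx(z, ν),

and no assumption about the interfacial structure enters.  Internally the
package uses Å, fs, e, amu, K with Coulomb constant k_e = 1 (so ε0 = 1/4π
and every SI ε0⁻¹ prefactor becomes 4π).  Frequencies are reported in
cm⁻¹; the wavenumber axis of a causal transform over `n_lags` lags of
spacing `dt` has native resolution 1/(n_lags·dt·c0).

An important consistency point for the *toy* system: the molecules carry
no dipole–dipole coupling in their dynamics, so thermal polarization
fluctuations are single-molecule objects.  For such a gas the parallel map
ε_xx = 1 + s is the consistent one; the perpendicular map
ε_zz = 1/(1 − s_zz) presupposes that the sampled fluctuations contain the
dipolar depolarization interaction (as they do in real polarizable MD).
Closed-form comparisons against the Lorentz-oscillator dielectric function
therefore use ε_xx.  The solver route (below) drives the configuration
explicitly and is exact under both maps.

## Response functions

All spectra are classical Kubo transforms of equilibrium correlation
functions.  For an observable A correlated with the total dipole moment P
(conjugate to the IR perturbation −P·F),

    χ(ν) = (1/kBT) · [ C(0) + iω·C̃(ν) ],      C(t) = ⟨A(t) P(0)⟩,

where C̃ is the one-sided transform of the apodized correlation (Hann
window by default; the t = 0 sample enters with trapezoidal half weight).
The time derivative of the correlation is taken analytically in the
frequency domain, which avoids finite-difference noise.  No
quantum-correction factor is applied anywhere: the classical response
function is already the leading-order harmonic approximation of its
quantum counterpart; factors such as ħωβ/(1−e^{−ħωβ}) relate correlation
functions, not response functions.

The second-order channels are:

* **D** — per molecule, the dressed polarizability (α^DD·f)_{ij}(t) binned
  at the molecular center z^n(t), correlated with P_k(0) and scaled by
  4π/(A·Δz·kBT).
* **Q** — same with the izl component of the quadrupole polarizability
  α^QD·f, an extra ∂/∂z applied as a central difference on the binned
  correlation (one-sided at the grid ends), and the opposite overall sign.
* **DQ** — the source quadrupoles induced at second order create
  electrostatic fields (Ewald-summed point-quadrupole fields) at all other
  molecular centers; the linear induced-dipole response to those fields,
  binned and correlated with P, is the cross term.  DD = D − DQ holds
  pointwise by construction.
* **M** — from a finely sampled bulk trajectory (write-out ≤ 0.5 fs):
  molecular magnetic moments m^n = ½·ΣΔr×(q·v) correlated with P_z and
  scaled by 1/ω_VIS (default 2730 THz).  Only yyz is non-zero; zzz
  vanishes because the curl of a laterally averaged magnetization cannot
  couple two lateral polarizations.  This classical estimator is a
  leading-order approximation and is flagged as such in the output
  metadata.

Spectra follow by depth integration S(ν) = ∫dz e^{−iΔk_z z} s(z, ν) with
Δk_z = 0 by default (a typical experimental mismatch of 0.02 nm⁻¹ changes
the integral negligibly over an ~8 Å interface).  Integrating a Q profile
from the bulk interior to the vapor telescopes to the bulk boundary value
— this is how a "bulk" channel survives depth integration.  Over a full
box whose ends sit in vacuum the Q integral vanishes, which makes the
expansion-origin test exact: shifting every molecular expansion origin by
a fixed intramolecular offset changes the D and Q profiles individually
but not D+Q at Δk_z = 0.

**Estimators.**  The default correlator uses the total box dipole (the
strict fluctuation–dissipation form).  Its variance is dominated by
cross-molecule terms that do not average down with system size, only with
trajectory length.  Because the toy molecules are dynamically uncoupled,
the package also provides a per-molecule ("self") estimator that
correlates each molecule with its own dipole — identical in expectation,
with variance smaller by roughly the molecule number.  The self estimator
is what makes the per-molecule hyperpolarizability extraction and the
layered-slab recovery test statistically sharp; it requires static
molecular centers (true for the generator) and is not the default.

Error bars, where quoted, are standard errors over ≥ 3 independent
realizations or ≥ 8 contiguous trajectory blocks.

## Local fields

The induced-dipole equations μ^n = α^n·E^n, with E^n the field of all
other induced dipoles plus the driving, are solved as one dense linear
system per configuration.  Dipole–dipole interactions use 3D Ewald
summation under tinfoil boundary conditions (real-space cutoff min(L)/2,
splitting and k-space cutoff from a 10⁻⁶ relative accuracy target); for
z-polarized driving the planar shape term E_z ← −4π·M_z/V is added, which
converts the driven amplitude from an E- into a D-field.  Point
quadrupole fields use the analogous Ewald kernels (second-moment
convention, bare potential ½·Q_jk·∂_j∂_k(1/r)).  Short-range damping is
off by default (point polarizabilities; the generator guarantees
non-overlapping configurations) and molecules closer than 1.2 Å are
rejected as ill-conditioned.

On a simple cubic lattice this machinery reproduces the
Clausius–Mossotti/Lorentz results exactly: ε from (ε−1)/(ε+2) = 4πα/(3v),
local-field factors f_x = (2+ε)/3 and f_z = (2+ε)/(3ε).  Disordered
liquid-density configurations (ρ = 0.0334 Å⁻³, α/(4πε0) = 1.47 Å³) give
ε ≈ 1.79–1.80, a few percent above the Clausius–Mossotti value of 1.78 —
positional correlations of a disordered fluid shift the plateau slightly
upward.  Per-molecule field-dressing tensors f^n (columns = local field
per unit driving along each axis) are laterally averaged into profiles
f_i(z); empty depth bins are NaN-flagged.  The frequency dependence of
f_i is neglected across the SFG/VIS/IR bands (the factors are dominated by
their nearly constant real part), so a single electronic solve serves all
three bands.

## Surfaces and depth mapping

The Gibbs dividing surface is the equimolar plane of the laterally
averaged density profile, one per interface; a step profile returns the
step position exactly and a linear ramp its midpoint.  The
Willard–Chandler surface is the uppermost crossing of
iso_fraction × ρ_bulk of a Gaussian coarse-grained density field
(ξ = 2.4 Å, iso = 0.5 — the conventional values; the lateral grid spacing
is capped at ξ/2).  Lateral cells without a crossing are filled by
nearest-neighbor interpolation with a warning.  Depths are measured with
liquid at negative values; the two equivalent interfaces of a slab are
folded onto one axis by reflecting the lower one, which flips the sign of
observables with an odd number of z indices and doubles the effective
sampling area (profile prefactors take `n_interfaces=2`).

## Orientation analysis

The body frame puts z′ along the permanent dipole (HOH bisector) and x′
out of the molecular plane; Euler angles use the intrinsic z′y′z′
convention (gimbal lock below sinθ = 10⁻⁷ resolves to ψ = 0
deterministically).  For vibrating molecules an Eckart-style mass-weighted
rotational fit to the equilibrium geometry is available; it coincides with
the bisector frame for rigid geometry.

ρ_ORI(θ, ψ) is normalized with the exact per-bin Haar measure
2π·Δcosθ·Δψ, so an isotropic ensemble is flat at 1/(8π²) without midpoint
bias.  Orientational species use a cone criterion with half-angle 36°:
inward/outward if either OH bond lies within the cone around ∓ẑ, planar
if both OH elevations stay within 36° of the interface plane.  Because
the HOH angle exceeds 72° the rules are mutually exclusive, and the
isotropic baseline fraction is the closed-form cone solid angle
1 − cos 36° ≈ 19.1% for inward and outward each.

The molecular hyperpolarizability of the toy model is double-harmonic and
closed-form,

    β_abc(ν) = 4π · Σ_m (dα/dq)_m,ab · (dμ/dq)_m,c / (m_m(ω_m² − ω² − iγω)),

with dμ/dq following analytically from the fixed site charges and the
geometry derivative.  Its φ-averaged lab components decompose exactly into
the uniaxial/biaxial basis {q10 = cosθ, q30 = (5cos³θ−3cosθ)/2,
q32 = cosθ·sin²θ·cos2ψ}; the φ average uses an 8-point uniform quadrature,
exact for the degree ≤ 3 trigonometric polynomials of a rank-3 tensor, and
the projection is a weighted least squares on a Gauss–Legendre(cosθ) ×
uniform(ψ) grid (64×64 default) with the residual reported.  The
orientation-only susceptibility is then
χ^(2,ORI)(z, ν) = ρ(z)·[q10(z)β¹⁰ + q30(z)β³⁰ + q32(z)β³²], and
χ^(2,DL)(z, ν) = s^(2,DD)/(f_i f_j f_k) is its measured counterpart.

## The synthetic generator

The toy molecule is rigid water geometry (0.9572 Å, 104.52°) with SPC/E
charges, an isotropic electronic polarizability of 1.47 Å³ (reproducing
the ε = 1.77 optical plateau at liquid density), a C2v-patterned
quadrupole polarizability (0.3 Å⁴ scale), and three internal modes — bend
1650, symmetric stretch 3650, antisymmetric stretch 3750 cm⁻¹ — with unit
effective masses, Langevin friction 4 ps⁻¹ (≈21 cm⁻¹ linewidth) and
C2v-symmetric Raman tensors per mode (A1 modes diagonal, the B2 mode
coupling y′z′).  The dα/dq scales are chosen so the double-harmonic χ(2)
of one oriented molecule is O(1) in internal units.  Slab defaults mirror
the study conditions the package emulates: 352 molecules, 20×20×60 Å box,
≈26 Å slab (bulk density 0.0334 Å⁻³, equal to 297 molecules in a 20.7 Å
cube); placement is random sequential insertion with a 2.4 Å center
distance.

Orientations are drawn per layer from mixtures of {isotropic, inward,
outward, planar} with a Gaussian angular wobble (default 12°) about the
ideal orientations; the bundled "biaxial triple layer" recipe stacks
inward (−5…−2.5 Å), planar (−2.5…−1 Å) and outward (−1…0.5 Å) layers at
70% purity over an isotropic interior, emulating the layered interfacial
ordering the bending-band analysis resolves.  Lower-interface molecules
receive the z-mirrored recipe (water is achiral, so the mirror image is
again a proper orientation).

Internal modes are propagated with the **exact Gaussian transition
kernel** of the damped harmonic Langevin oscillator (Φ = e^{A·dt}, noise
covariance Σ_st − Φ·Σ_st·Φᵀ).  This has no time-step error at any dt —
a velocity-Verlet-type scheme shifts a 3750 cm⁻¹ line by ~17 cm⁻¹ at
dt = 0.5 fs, comparable to the linewidth — and at T = 0, γ = 0 it reduces
to an exact phase-space rotation that conserves energy to machine
precision.  Molecular centers and orientations are static; collective
electrostatics enter only through the induced-dipole solver
(timescale-separation, matching the generator's design).

What the generator does **not** emulate: hydrogen-bond networks and their
spectral diffusion, rotational dynamics, intermolecular vibrational
coupling, anharmonicity, nuclear quantum effects, and realistic
thermodynamics.  Passing tests therefore demonstrate that the *machinery*
(surfaces, orientation statistics, local fields, FD transforms, multipole
split) is correct against analytic ground truth — not that any particular
real-water spectrum is reproduced.

## Numerical choices

* Depth bins 0.5 Å (≈10 bins across a 5 Å interfacial region); nearest-bin
  assignment for δ[z−z^n] (an optional Gaussian kernel is deliberately not
  the default).
* Hann apodization on all correlation functions; window length is the
  dominant line-shape systematic (a 4096 fs window adds ≈4% L2 distortion
  to a 21 cm⁻¹ Lorentzian) — oracle tests use windows ≥ 16 ps.
* Ewald accuracy 10⁻⁶; ε_zz poles (|1−s_zz| < 10⁻⁶) masked with a
  warning; field-factor products below 0.05 masked in χ^(2,DL).
* Red shifts are pure axis relabelings (defaults 28/166 cm⁻¹, boundary
  2500 cm⁻¹); the shifted segments may only overlap where the spectrum
  carries no signal, otherwise a stitching error is raised.
* Problem sizes in the test-suite: slabs of 96–352 molecules, 2–16 k
  stored frames, 20 disordered boxes of 297 molecules for the dielectric
  plateau — sizes at which every statistical check resolves its target
  within the quoted error bars.

## Known limitations

The DD/DQ split and the magnetic channel are implemented at the level of
a timescale-separated, quasi-static local-field treatment (structure
tensors from the initial frame); molecules that reorient during a
trajectory would need the per-frame path, which is not the default.  The
magnetic estimator omits the induced-current contribution to m^n.  The
perpendicular dielectric map applied to dynamically uncoupled toys is
inconsistent at second order in (ε−1) (see above).  WCS mapping supports
vertical (non-curvature-resolved) depth assignment only.
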