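# sfgmultipole

Multipole-resolved sum-frequency-generation (SFG) spectra, depth-resolved
dielectric profiles, local-field factors and biaxial orientation analysis
from molecular-dynamics slab trajectories.

SFG spectroscopy is interface-specific only in the electric-dipole
approximation.  Beyond it, electric-quadrupole and magnetic-dipole terms
contribute bulk signals that overlap the interfacial one, and separating
them is what makes the spectrum interpretable in terms of molecular
ordering.  This package implements that separation for a planar
liquid/vapor slab: the second-order response profile s⁽²⁾ᵢⱼₖ(z, ν) is
computed from classical fluctuation–dissipation (Kubo) transforms of
equilibrium correlation functions and decomposed into

    S⁽²⁾ = S⁽²,DD⁾ + S⁽²,DQ⁾ + S⁽²,Q⁾ + S⁽²,M⁾,

where DD is the pure electric-dipole (interface-structure) term, DQ the
dipole response to second-order source-quadrupole fields, Q the electric
quadrupole and M the magnetic dipole bulk terms.  Driving fields follow
the E-parallel / D-perpendicular convention, so the linear dielectric
profile is algebraic in the polarization response: ε_zz = 1/(1 − s_zz),
ε_xx = 1 + s_xx.  Local fields at the molecular centers are obtained from
a self-consistent Ewald-summed induced-dipole solver; in the bulk they
reach the Lorentz limits f_x = (2+ε)/3 and f_z = (2+ε)/(3ε).  The
electric-dipole susceptibility χ⁽²,DL⁾ = s⁽²,DD⁾/(f_i f_j f_k) is linked
to molecular orientation through the exact uniaxial/biaxial decomposition
of the molecular hyperpolarizability,

    β(θ, ψ) = q₁₀(θ)β¹⁰ + q₃₀(θ)β³⁰ + q₃₂(θ, ψ)β³²,
    q₃₂ = cosθ·sin²θ·(cos²ψ − sin²ψ),

which resolves layered inward/planar/outward interfacial ordering that a
uniaxial analysis misses.

Everything runs on a built-in polarizable toy-water generator (rigid
geometry, harmonic bend/stretch modes, assigned polarizabilities and
layer-wise orientation recipes), so every stage is testable against
analytic ground truth without external data.  Readers of extended-XYZ and
LAMMPS text dumps accept real trajectories with the same API.

Intended users: simulators of aqueous and soft-matter interfaces who want
depth-resolved linear/nonlinear optical response from their trajectories,
and spectroscopists who need the non-interface-specific multipole
background quantified.

## Worked example

```python
import numpy as np
from sfgmultipole.synthetic import (ToyWaterModel, build_bulk,
                                    sample_isotropic_orientations)
from sfgmultipole.orientation import oh_vectors_from_angles, species_fractions
from sfgmultipole.localfield import InducedDipoleSolver, ExternalFieldSpec

model = ToyWaterModel()

# orientation statistics of an isotropic ensemble
ang = sample_isotropic_orientations(200_000, seed=1)
u1, u2 = oh_vectors_from_angles(ang, model.angle_rad / 2)
fr = species_fractions(u1, u2)
print("isotropic species fractions: "
      + ", ".join(f"{k}={100*v:.1f}%" for k, v in fr.items()))

# bulk optical dielectric constant from the induced-dipole solver
traj = build_bulk(model, seed=2, n_molecules=297)
solver = InducedDipoleSolver(traj.com_positions()[0], traj.box, model.alpha_e)
V = float(np.prod(traj.box))
mu_x, _ = solver.solve(ExternalFieldSpec("x", 1.0))
mu_z, _ = solver.solve(ExternalFieldSpec("z", 1.0))
eps_xx = 1 + 4 * np.pi * mu_x[:, 0].sum() / V
eps_zz = 1 / (1 - 4 * np.pi * mu_z[:, 2].sum() / V)
print(f"bulk optical dielectric constant: eps_xx={eps_xx:.3f}, eps_zz={eps_zz:.3f}")
lf = solver.field_factors()
print(f"local-field factors (bulk mean):  f_x={lf.diagonal(0).mean():.3f}, "
      f"f_z={lf.diagonal(2).mean():.3f}")
```

prints

```
isotropic species fractions: inward=19.1%, outward=19.1%, planar=26.9%, other=34.9%
bulk optical dielectric constant: eps_xx=1.793, eps_zz=1.801
local-field factors (bulk mean):  f_x=1.286, f_z=0.721
```

The inward/outward fractions equal the 36°-cone solid angle 1 − cos 36°
≈ 19.1% — the isotropic baseline against which interfacial ordering is
measured.  The dielectric constant of the disordered liquid-density box
sits at ≈1.79–1.80, the optical plateau of the slab's interior (the
Clausius–Mossotti value for α = 1.47 Å³ at 0.0334 Å⁻³ is 1.78), and the
local-field factors agree with the Lorentz expressions evaluated at that
ε.

The full pipeline — slab generation, Gibbs-dividing and Willard–Chandler
surfaces, orientation moments, local-field profiles, dielectric profiles,
second-order spectra with the DD/DQ/Q/M decomposition and band-integrated
χ⁽²,DL⁾ vs χ⁽²,ORI⁾ comparison — runs from one config:

```sh
sfgmultipole run               # bundled toy-biaxial-slab configuration
sfgmultipole gen-slab -o slab.extxyz
sfgmultipole surfaces slab.extxyz
sfgmultipole orient slab.extxyz -o moments.csv
```

Outputs land in `out/`: `profiles.h5` (depth×frequency datasets),
per-component spectrum CSVs, `band_integrals.csv` and a `summary.json`
whose dataset hash is bit-reproducible for a fixed config and seed.

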