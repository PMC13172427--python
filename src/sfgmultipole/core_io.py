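"""Trajectory data model, file readers/writers and spectral machinery.

The in-memory containers are deliberately small: a :class:`Trajectory` is an
ordered list of :class:`Frame` objects sharing one :class:`MoleculeTopology`.
Positions are Å, velocities Å/fs, charges e, the box is orthorhombic.

Two text formats are supported:

* extended XYZ with a ``Lattice="..."`` comment entry and per-atom columns
  ``species:S:1:pos:R:3[:vel:R:3]`` plus a ``Time=`` tag, and
* the LAMMPS text dump (``id mol type x y z [vx vy vz]``), read through
  MDAnalysis and written by a small formatter.

The spectral side provides :class:`SpectralGrid` (wavenumber axis tied to a
lag window), the causal cross-correlation transform
:func:`correlation_spectrum` and the classical Kubo response transform
:func:`kubo_transform` used by the response module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .units import C0_CM_FS, wavenumber_to_angular


class TrajectoryError(Exception):
    """Malformed or inconsistent trajectory input."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class MoleculeTopology:
    """Per-molecule site layout shared by all frames.

    ``roles`` are site labels per molecule (e.g. ``["O", "H1", "H2"]``),
    ``masses`` amu per site, ``bonds`` index pairs within one molecule,
    and the equilibrium geometry (bond length Å, bond angle deg) anchors
    mode projections and Eckart fits.
    """

    n_molecules: int
    roles: tuple[str, ...] = ("O", "H1", "H2")
    masses: tuple[float, ...] = (15.999, 1.008, 1.008)
    bonds: tuple[tuple[int, int], ...] = ((0, 1), (0, 2))
    bond_length: float = 0.9572
    bond_angle: float = 104.52

    @property
    def sites_per_molecule(self) -> int:
        return len(self.roles)

    @property
    def n_sites(self) -> int:
        return self.n_molecules * self.sites_per_molecule

    def molecule_slices(self) -> list[slice]:
        k = self.sites_per_molecule
        return [slice(i * k, (i + 1) * k) for i in range(self.n_molecules)]


@dataclass
class Frame:
    """One stored configuration: per-site positions/velocities/charges."""

    positions: np.ndarray              # (n_sites, 3) Å
    box: np.ndarray                    # (3,) Å, orthorhombic
    velocities: np.ndarray | None = None   # (n_sites, 3) Å/fs
    charges: np.ndarray | None = None      # (n_sites,) e
    time: float = 0.0                  # fs

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise TrajectoryError("frame contains non-finite coordinates")

    def validate_neutral(self, topology: MoleculeTopology, tol: float = 1e-10):
        """Check that charges sum to zero molecule by molecule."""
        if self.charges is None:
            return
        q = self.charges.reshape(topology.n_molecules, -1)
        if np.any(np.abs(q.sum(axis=1)) > tol):
            raise TrajectoryError("molecules are not charge neutral")


@dataclass
class Trajectory:
    """Ordered frames with uniform time step and fixed topology (NVT)."""

    frames: list[Frame]
    topology: MoleculeTopology
    dt: float = 3.2          # fs between stored frames
    temperature: float = 298.0
    label: str = ""

    def __post_init__(self):
        if self.dt <= 0:
            raise TrajectoryError("dt must be positive")
        if not self.frames:
            raise TrajectoryError("trajectory has no frames")
        n = self.frames[0].positions.shape[0]
        for i, f in enumerate(self.frames):
            if f.positions.shape[0] != n:
                raise TrajectoryError(f"inconsistent site count at frame {i}")
        if n != self.topology.n_sites:
            raise TrajectoryError(
                f"topology declares {self.topology.n_sites} sites, frames have {n}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def box(self) -> np.ndarray:
        return self.frames[0].box

    @property
    def area(self) -> float:
        """Interfacial area Lx·Ly (Å²) — interfaces lie in the xy plane."""
        return float(self.box[0] * self.box[1])

    def positions_array(self) -> np.ndarray:
        """(n_frames, n_sites, 3) stacked positions."""
        return np.stack([f.positions for f in self.frames])

    def velocities_array(self) -> np.ndarray:
        if any(f.velocities is None for f in self.frames):
            raise TrajectoryError("trajectory has no stored velocities")
        return np.stack([f.velocities for f in self.frames])

    def com_positions(self) -> np.ndarray:
        """(n_frames, n_molecules, 3) molecular centers of mass."""
        m = np.asarray(self.topology.masses)
        pos = self.positions_array().reshape(
            len(self), self.topology.n_molecules, self.topology.sites_per_molecule, 3)
        return np.einsum("s,fnsi->fni", m, pos) / m.sum()

    def total_dipole(self) -> np.ndarray:
        """(n_frames, 3) total permanent dipole Σ q·r (e·Å)."""
        out = np.empty((len(self), 3))
        for i, f in enumerate(self.frames):
            if f.charges is None:
                raise TrajectoryError("frames carry no charges")
            out[i] = f.charges @ f.positions
        return out


@dataclass
class SpectralGrid:
    """Wavenumber axis consistent with a lag window of ``n_lags`` steps.

    The native resolution of a causal transform over ``n_lags`` lags of
    spacing ``dt`` is Δν = 1/(n_lags·dt·c0); the stored axis uses that
    spacing up to the Nyquist limit 1/(2·dt·c0) unless an explicit
    ``nu_max`` is requested.
    """

    dt: float                      # fs
    n_lags: int
    window: str = "hann"
    nu_max: float | None = None    # cm⁻¹

    def __post_init__(self):
        if self.dt <= 0 or self.n_lags < 2:
            raise ValueError("need dt > 0 and n_lags >= 2")
        nyquist = 1.0 / (2.0 * self.dt * C0_CM_FS)
        if self.nu_max is None:
            self.nu_max = nyquist
        if self.nu_max > nyquist * (1 + 1e-12):
            raise ValueError(
                f"nu_max {self.nu_max:.1f} cm⁻¹ exceeds Nyquist {nyquist:.1f} cm⁻¹")

    @property
    def dnu(self) -> float:
        """Frequency spacing in cm⁻¹."""
        return 1.0 / (self.n_lags * self.dt * C0_CM_FS)

    @property
    def frequencies(self) -> np.ndarray:
        """Wavenumber axis (cm⁻¹), from 0 to nu_max."""
        n = int(math.floor(self.nu_max / self.dnu)) + 1
        return np.arange(n) * self.dnu

    @property
    def lag_times(self) -> np.ndarray:
        return np.arange(self.n_lags) * self.dt

    def window_values(self) -> np.ndarray:
        """One-sided apodization over the lag window, w(0)=1, w(end)→0."""
        t = np.arange(self.n_lags)
        if self.window == "hann":
            return 0.5 * (1.0 + np.cos(np.pi * t / self.n_lags))
        if self.window in ("none", "boxcar"):
            return np.ones(self.n_lags)
        raise ValueError(f"unknown window '{self.window}'")


@dataclass
class DepthGrid:
    """Bins along the surface normal z.  ``reference`` names the frame in
    which depths are measured: raw ``lab`` coordinates, the planar Gibbs
    dividing surface (``GDS``) or the instantaneous Willard–Chandler
    surface (``WCS``).  Liquid sits at negative depth, vapor at positive.
    """

    edges: np.ndarray
    reference: str = "GDS"

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.ndim != 1 or self.edges.size < 2:
            raise ValueError("need at least two bin edges")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.reference not in ("lab", "GDS", "WCS"):
            raise ValueError("reference must be lab, GDS or WCS")

    @classmethod
    def regular(cls, z_min: float, z_max: float, width: float = 0.5,
                reference: str = "GDS") -> "DepthGrid":
        n = int(round((z_max - z_min) / width))
        return cls(z_min + width * np.arange(n + 1), reference)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def width(self) -> float:
        return float(np.mean(np.diff(self.edges)))

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    def assign(self, depths: np.ndarray) -> np.ndarray:
        """Nearest-bin index per depth; -1 outside the grid."""
        idx = np.searchsorted(self.edges, depths, side="right") - 1
        idx[(depths < self.edges[0]) | (depths >= self.edges[-1])] = -1
        return idx


# --------------------------------------------------------------------------
# extended-XYZ reader/writer
# --------------------------------------------------------------------------

def _parse_extxyz_comment(line: str) -> dict:
    out, i, n = {}, 0, len(line)
    while i < n:
        while i < n and line[i] in " \t":
            i += 1
        j = i
        while j < n and line[j] not in "= \t":
            j += 1
        key = line[i:j]
        if not key:
            break
        if j < n and line[j] == "=":
            j += 1
            if j < n and line[j] == '"':
                k = line.index('"', j + 1)
                out[key] = line[j + 1:k]
                i = k + 1
            else:
                k = j
                while k < n and line[k] not in " \t":
                    k += 1
                out[key] = line[j:k]
                i = k
        else:
            out[key] = True
            i = j
    return out


def write_extxyz(path, traj: Trajectory):
    """Write a trajectory as extended XYZ (Lattice, optional velocities)."""
    roles = list(traj.topology.roles) * traj.topology.n_molecules
    with open(path, "w") as fh:
        for f in traj.frames:
            has_v = f.velocities is not None
            props = "species:S:1:pos:R:3" + (":vel:R:3" if has_v else "")
            lat = (f"{f.box[0]:.10g} 0.0 0.0 0.0 {f.box[1]:.10g} 0.0 "
                   f"0.0 0.0 {f.box[2]:.10g}")
            fh.write(f"{f.positions.shape[0]}\n")
            fh.write(f'Lattice="{lat}" Properties={props} Time={f.time:.10g} '
                     f"dt={traj.dt:.10g}\n")
            for s in range(f.positions.shape[0]):
                row = f"{roles[s].rstrip('12')} " + " ".join(
                    f"{x:.12g}" for x in f.positions[s])
                if has_v:
                    row += " " + " ".join(f"{x:.12g}" for x in f.velocities[s])
                fh.write(row + "\n")


def _read_extxyz(path, topology: MoleculeTopology | None) -> Trajectory:
    frames: list[Frame] = []
    dt = None
    with open(path) as fh:
        lines = fh.readlines()
    i, iframe = 0, 0
    nsites_ref = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryError(
                f"frame {iframe}: bad atom-count line {lines[i]!r}") from exc
        meta = _parse_extxyz_comment(lines[i + 1])
        if "Lattice" not in meta:
            raise TrajectoryError(f"frame {iframe}: missing Lattice entry")
        lat = np.fromstring(meta["Lattice"], sep=" ").reshape(3, 3)
        box = np.diag(lat)
        has_v = "vel" in meta.get("Properties", "")
        body = lines[i + 2:i + 2 + nat]
        if len(body) < nat:
            raise TrajectoryError(f"frame {iframe}: truncated atom block")
        try:
            data = np.array([ln.split()[1:] for ln in body], dtype=float)
        except ValueError as exc:
            raise TrajectoryError(
                f"frame {iframe}: malformed atom line") from exc
        pos = data[:, :3]
        if not np.all(np.isfinite(pos)):
            raise TrajectoryError(f"frame {iframe}: non-finite coordinate")
        vel = data[:, 3:6] if has_v and data.shape[1] >= 6 else None
        t = float(meta.get("Time", iframe))
        if dt is None and "dt" in meta:
            dt = float(meta["dt"])
        if nsites_ref is None:
            nsites_ref = nat
        elif nat != nsites_ref:
            raise TrajectoryError(f"frame {iframe}: site count changed")
        frames.append(Frame(pos, box, velocities=vel, time=t))
        i += 2 + nat
        iframe += 1
    if dt is None:
        dt = (frames[1].time - frames[0].time) if len(frames) > 1 else 1.0
    if topology is None:
        if nsites_ref % 3:
            raise TrajectoryError("cannot infer water topology: sites not /3")
        topology = MoleculeTopology(n_molecules=nsites_ref // 3)
    return Trajectory(frames, topology, dt=dt if dt > 0 else 1.0)


# --------------------------------------------------------------------------
# LAMMPS text dump
# --------------------------------------------------------------------------

def write_lammps_dump(path, traj: Trajectory):
    """Write the ``id mol type x y z vx vy vz`` text dump."""
    k = traj.topology.sites_per_molecule
    ntypes = {r.rstrip("12"): None for r in traj.topology.roles}
    tmap = {r: i + 1 for i, r in enumerate(ntypes)}
    with open(path, "w") as fh:
        for istep, f in enumerate(traj.frames):
            has_v = f.velocities is not None
            fh.write("ITEM: TIMESTEP\n%d\n" % istep)
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % f.positions.shape[0])
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for d in range(3):
                fh.write(f"0.0 {f.box[d]:.10g}\n")
            cols = "id mol type x y z" + (" vx vy vz" if has_v else "")
            fh.write(f"ITEM: ATOMS {cols}\n")
            for s in range(f.positions.shape[0]):
                mol = s // k + 1
                typ = tmap[traj.topology.roles[s % k].rstrip("12")]
                row = f"{s + 1} {mol} {typ} " + " ".join(
                    f"{x:.12g}" for x in f.positions[s])
                if has_v:
                    row += " " + " ".join(f"{x:.12g}" for x in f.velocities[s])
                fh.write(row + "\n")


def _read_lammps_dump(path, topology: MoleculeTopology | None,
                      dt: float | None) -> Trajectory:
    import MDAnalysis as mda

    frames: list[Frame] = []
    steps = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format="LAMMPSDUMP",
                         lengthunit="A", timeunit="fs")
        for ts in u.trajectory:
            pos = u.atoms.positions.astype(float).copy()
            if not np.all(np.isfinite(pos)):
                raise TrajectoryError(
                    f"frame {ts.frame}: non-finite coordinate")
            vel = None
            if u.trajectory.ts.has_velocities:
                vel = u.atoms.velocities.astype(float).copy()
            box = np.asarray(ts.dimensions[:3], dtype=float)
            frames.append(Frame(pos, box, velocities=vel))
            steps.append(ts.data.get("step", ts.frame))
    n = frames[0].positions.shape[0]
    if topology is None:
        if n % 3:
            raise TrajectoryError("cannot infer water topology: sites not /3")
        topology = MoleculeTopology(n_molecules=n // 3)
    if dt is None:
        dt = float(steps[1] - steps[0]) if len(steps) > 1 else 1.0
        dt = dt if dt > 0 else 1.0
    for i, f in enumerate(frames):
        f.time = i * dt
    return Trajectory(frames, topology, dt=dt)


def read_trajectory(path, format: str = "xyz-ext",
                    topology: MoleculeTopology | None = None,
                    dt: float | None = None) -> Trajectory:
    """Read a trajectory from disk.

    Parameters
    ----------
    path : str or Path
    format : {"xyz-ext", "lammps-dump"}
    topology : optional explicit topology; water (O,H,H triplets) inferred
        from the site count when omitted.
    dt : stored-frame spacing in fs; inferred from time stamps / step
        numbers when omitted.
    """
    if format == "xyz-ext":
        traj = _read_extxyz(path, topology)
        if dt is not None:
            traj.dt = dt
        return traj
    if format == "lammps-dump":
        return _read_lammps_dump(path, topology, dt)
    raise ValueError(f"unknown trajectory format '{format}'")


def write_trajectory(path, traj: Trajectory, format: str = "xyz-ext"):
    if format == "xyz-ext":
        write_extxyz(path, traj)
    elif format == "lammps-dump":
        write_lammps_dump(path, traj)
    else:
        raise ValueError(f"unknown trajectory format '{format}'")


# --------------------------------------------------------------------------
# correlation spectra
# --------------------------------------------------------------------------

def causal_correlation(series_a: np.ndarray, series_b: np.ndarray,
                       n_lags: int) -> np.ndarray:
    """⟨a(t)·b(0)⟩ for lags t = 0 … n_lags−1 (stationary average).

    ``series_a`` may be multi-channel with shape (..., n_t); the lag axis is
    appended last.  Uses FFT-based correlation.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    nt = a.shape[-1]
    if b.shape[-1] != nt:
        raise ValueError("series lengths differ")
    if nt < 2 * n_lags:
        raise ValueError(
            f"series of length {nt} too short for n_lags={n_lags} "
            "(need >= 2·n_lags)")
    nfft = 1 << int(np.ceil(np.log2(nt + n_lags)))
    fa = np.fft.rfft(a, nfft, axis=-1)
    fb = np.fft.rfft(b, nfft)
    corr = np.fft.irfft(fa * np.conj(fb), nfft, axis=-1)[..., :n_lags]
    counts = nt - np.arange(n_lags)
    return corr / counts


def one_sided_transform(corr: np.ndarray, grid: SpectralGrid,
                        windowed: bool = True) -> np.ndarray:
    """C̃(ν) = ∫₀^∞ dt e^{iωt} C(t) over the windowed lag range.

    The t = 0 sample enters with trapezoidal half weight.  Shape of the
    result is corr.shape[:-1] + (n_freq,).
    """
    c = np.asarray(corr)
    if c.shape[-1] != grid.n_lags:
        raise ValueError("correlation length does not match grid.n_lags")
    w = grid.window_values() if windowed else np.ones(grid.n_lags)
    w = w.copy()
    w[0] *= 0.5
    t = grid.lag_times
    omega = wavenumber_to_angular(grid.frequencies)
    cw = c * w
    out = np.empty(c.shape[:-1] + (omega.size,), dtype=complex)
    chunk = max(1, int(4e6 / max(grid.n_lags, 1)))
    for lo in range(0, omega.size, chunk):
        phase = np.exp(1j * np.outer(t, omega[lo:lo + chunk]))
        out[..., lo:lo + chunk] = cw @ phase
    return out * grid.dt


def correlation_spectrum(series_a: np.ndarray, series_b: np.ndarray,
                         grid: SpectralGrid) -> np.ndarray:
    """One-sided Fourier transform of the causal cross-correlation
    ⟨a(t)b(0)⟩, t ≥ 0, with the grid's apodization window applied.

    Causality (Θ(t)) is built in: negative lags never enter.
    """
    corr = causal_correlation(series_a, series_b, grid.n_lags)
    return one_sided_transform(corr, grid)


def kubo_transform(corr: np.ndarray, grid: SpectralGrid,
                   kBT: float = 1.0) -> np.ndarray:
    """Classical linear-response (Kubo) transform of a correlation function.

    χ(ν) = (1/kBT)·[C(0) + iω·C̃(ν)] — the frequency-domain form of
    −(1/kBT)∫₀^∞ e^{iωt} ∂_t C(t) dt.  The time derivative is taken
    analytically in the frequency domain after windowing.
    """
    omega = wavenumber_to_angular(grid.frequencies)
    ctil = one_sided_transform(corr, grid)
    c0 = np.asarray(corr)[..., 0][..., None]
    return (c0 + 1j * omega * ctil) / kBT


def block_slices(n_frames: int, n_blocks: int) -> list[slice]:
    """Contiguous equal blocks for block-averaged error bars."""
    size = n_frames // n_blocks
    if size < 2:
        raise ValueError("too few frames for the requested block count")
    return [slice(i * size, (i + 1) * size) for i in range(n_blocks)]
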