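"""Residue-level implicit-solvent energy model for disordered proteins.

One bead per residue.  Neighboring residues are linked by harmonic bonds
(equilibrium 0.38 nm, force constant 8033 kJ mol⁻¹ nm⁻²).  Nonbonded
interactions combine an Ashbaugh–Hatch "stickiness" term scaled by the
per-residue hydropathy λ (truncated at 2 nm) with a truncated-and-shifted
Debye–Hückel potential for salt-screened electrostatics (cutoff 4 nm).
Units throughout: nm, ps, Da, kJ/mol, elementary charges, Kelvin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CANONICAL_AA, IDRSequence

KB = 0.00831446261815324  # Boltzmann constant, kJ/mol/K
R_GAS = 8.31446261815324e-3  # gas constant, kJ/mol/K
COULOMB = 138.935458  # e^2 * N_A / (4 pi eps0), kJ mol^-1 nm e^-2
AVOGADRO = 6.02214076e23

# defaults matching the slab protocol
R0_BOND = 0.38  # nm
K_BOND = 8033.0  # kJ mol^-1 nm^-2
CUTOFF_NONEL = 2.0  # nm
CUTOFF_EL = 4.0  # nm
EPSILON_LJ = 0.2 * 4.184  # 0.2 kcal/mol in kJ/mol
TEMPERATURE = 293.0  # K
IONIC_STRENGTH = 0.15  # mol/L
DIST_FLOOR = 1e-4  # nm; pair distances below this abort the energy call


class ForcefieldError(ValueError):
    pass


def water_dielectric(temperature: float) -> float:
    """Empirical relative permittivity of water as a function of T (K)."""
    t = temperature
    return 5321.0 / t + 233.76 - 0.9297 * t + 1.417e-3 * t**2 - 8.292e-7 * t**3


def debye_length(ionic_strength: float, temperature: float,
                 dielectric: float | None = None) -> float:
    """Debye screening length (nm) for a 1:1 salt at the given molarity."""
    if ionic_strength <= 0:
        raise ForcefieldError("ionic strength must be positive")
    if dielectric is None:
        dielectric = water_dielectric(temperature)
    rt = R_GAS * temperature  # kJ/mol
    bjerrum = COULOMB / (dielectric * rt)  # nm
    # number density of a 1 mol/L species in nm^-3
    rho = ionic_strength * AVOGADRO * 1e-24
    kappa_sq = 8.0 * np.pi * bjerrum * rho
    return float(1.0 / np.sqrt(kappa_sq))


@dataclass(frozen=True)
class ResidueParameterTable:
    """Per-residue λ/σ/q/mass plus the model's global constants."""

    lam: dict
    sigma: dict
    q: dict
    mass: dict
    epsilon_lj: float = EPSILON_LJ
    r0_bond: float = R0_BOND
    k_bond: float = K_BOND
    cutoff_nonel: float = CUTOFF_NONEL
    cutoff_el: float = CUTOFF_EL
    temperature: float = TEMPERATURE

    def __post_init__(self):
        for name, d in (("lambda", self.lam), ("sigma", self.sigma),
                        ("q", self.q), ("mass", self.mass)):
            missing = set(CANONICAL_AA) - set(d)
            if missing:
                raise ForcefieldError(f"{name} table missing residues {sorted(missing)}")
        if any(not (0.0 <= v <= 1.0) for v in self.lam.values()):
            raise ForcefieldError("lambda values must lie in [0, 1]")
        if any(v <= 0 for v in self.sigma.values()):
            raise ForcefieldError("sigma values must be positive")
        if any(v <= 0 for v in self.mass.values()):
            raise ForcefieldError("masses must be positive")
        for c in (self.epsilon_lj, self.r0_bond, self.k_bond,
                  self.cutoff_nonel, self.cutoff_el, self.temperature):
            if c <= 0:
                raise ForcefieldError("global constants must be positive")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **constants) -> "ResidueParameterTable":
        df = df.set_index("aa")
        return cls(
            lam=df["lambda"].to_dict(),
            sigma=df["sigma_nm"].to_dict(),
            q=df["q"].astype(float).to_dict(),
            mass=df["mass_Da"].to_dict(),
            **constants,
        )

    @classmethod
    def from_tsv(cls, path, **constants) -> "ResidueParameterTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls.from_frame(df, **constants)

    @classmethod
    def default(cls, **constants) -> "ResidueParameterTable":
        """The bundled hydropathy scale (λ from CALVADOS 2)."""
        with resources.as_file(
            resources.files("idrslab.data") / "calvados2.tsv"
        ) as p:
            return cls.from_tsv(p, **constants)

    def with_constants(self, **constants) -> "ResidueParameterTable":
        return replace(self, **constants)


def bond_energy(r: float, r0: float = R0_BOND, k: float = K_BOND) -> float:
    """Harmonic bond energy ½·k·(r − r0)² in kJ/mol."""
    if r <= 0:
        raise ForcefieldError(f"bond length must be positive, got {r}")
    return 0.5 * k * (r - r0) ** 2


def dh_energy(qi: float, qj: float, r: float, *,
              debye: float, dielectric: float,
              cutoff: float = CUTOFF_EL) -> float:
    """Truncated-and-shifted Debye–Hückel pair energy (kJ/mol).

    Screened Coulomb ``C·qi·qj/(ε_r) · exp(−r/λ_D)/r`` with the value at
    the cutoff subtracted, exactly zero for r ≥ cutoff.
    """
    if r <= 0:
        raise ForcefieldError(f"distance must be positive, got {r}")
    if r >= cutoff or qi == 0.0 or qj == 0.0:
        return 0.0
    pref = COULOMB * qi * qj / dielectric
    return pref * (np.exp(-r / debye) / r - np.exp(-cutoff / debye) / cutoff)


def stickiness_energy(r: float, lambda_ij: float, sigma_ij: float,
                      epsilon: float = EPSILON_LJ,
                      cutoff: float = CUTOFF_NONEL,
                      shift: bool = True) -> float:
    """Ashbaugh–Hatch hydropathy pair energy (kJ/mol).

    The 12-6 potential is split at its minimum 2^{1/6}σ: below it the full
    repulsive well is kept and offset by (1−λ)ε; beyond it the attractive
    tail is scaled by λ.  With ``shift=True`` (default) the λ-scaled value
    at the cutoff is subtracted so the term is continuous at the cutoff.
    """
    if r <= 0:
        raise ForcefieldError(f"distance must be positive, got {r}")
    if r >= cutoff:
        return 0.0

    def lj(x):
        sr6 = (sigma_ij / x) ** 6
        return 4.0 * epsilon * (sr6 * sr6 - sr6)

    rmin = 2.0 ** (1.0 / 6.0) * sigma_ij
    if r <= rmin:
        e = lj(r) + (1.0 - lambda_ij) * epsilon
    else:
        e = lambda_ij * lj(r)
    if shift:
        e -= lambda_ij * lj(cutoff)
    return e


@dataclass(frozen=True)
class SlabSystem:
    """Bead topology of a many-copy slab system of one IDR type."""

    n_chains: int
    chain_length: int
    lam: np.ndarray  # (N,) per-bead stickiness
    sigma: np.ndarray  # (N,) per-bead diameter, nm
    q: np.ndarray  # (N,) per-bead charge, e
    mass: np.ndarray  # (N,) per-bead mass, Da
    chain_id: np.ndarray  # (N,) chain index per bead
    bonds: np.ndarray  # (B, 2) bonded bead index pairs
    box: np.ndarray  # (3,) Lx, Ly, Lz in nm
    ionic_strength: float
    dielectric: float
    debye: float
    table: ResidueParameterTable
    sequence: str

    @property
    def n_beads(self) -> int:
        return self.n_chains * self.chain_length

    @property
    def has_charges(self) -> bool:
        return bool(np.any(self.q != 0.0))

    @property
    def max_cutoff(self) -> float:
        return self.table.cutoff_el if self.has_charges else self.table.cutoff_nonel

    def chain_slice(self, c: int) -> slice:
        return slice(c * self.chain_length, (c + 1) * self.chain_length)


def build_system(idr: IDRSequence, copies: int, box,
                 table: ResidueParameterTable | None = None,
                 ionic_strength: float = IONIC_STRENGTH,
                 terminal_charges: bool = False) -> SlabSystem:
    """Assemble `copies` identical chains of one IDR into a periodic slab.

    The Debye length is computed from the ionic strength and the table's
    temperature.  By default termini carry no extra charge; with
    ``terminal_charges=True`` the N-terminus gets +1 and the C-terminus −1.
    """
    if table is None:
        table = ResidueParameterTable.default()
    if copies < 1:
        raise ForcefieldError(f"need at least one chain copy, got {copies}")
    seq = idr.sequence
    missing = sorted(set(seq) - set(table.lam))
    if missing:
        raise ForcefieldError(
            f"IDR {idr.id!r}: residue(s) {missing} have no forcefield parameters"
        )
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ForcefieldError("box must be three positive lengths (nm)")

    n = len(seq)
    lam1 = np.array([table.lam[a] for a in seq])
    sig1 = np.array([table.sigma[a] for a in seq])
    q1 = np.array([table.q[a] for a in seq], dtype=float)
    m1 = np.array([table.mass[a] for a in seq])
    if terminal_charges:
        q1 = q1.copy()
        q1[0] += 1.0
        q1[-1] -= 1.0

    lam = np.tile(lam1, copies)
    sigma = np.tile(sig1, copies)
    q = np.tile(q1, copies)
    mass = np.tile(m1, copies)
    chain_id = np.repeat(np.arange(copies), n)

    if n > 1:
        within = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
        bonds = np.concatenate([within + c * n for c in range(copies)])
    else:
        bonds = np.empty((0, 2), dtype=int)

    has_charges = bool(np.any(q != 0.0))
    max_cut = table.cutoff_el if has_charges else table.cutoff_nonel
    if box[0] < 2 * max_cut or box[1] < 2 * max_cut:
        raise ForcefieldError(
            f"box x/y ({box[0]}, {box[1]}) smaller than twice the largest "
            f"cutoff ({max_cut} nm)"
        )

    dielectric = water_dielectric(table.temperature)
    return SlabSystem(
        n_chains=copies, chain_length=n,
        lam=lam, sigma=sigma, q=q, mass=mass,
        chain_id=chain_id, bonds=bonds.astype(np.int64), box=box,
        ionic_strength=ionic_strength, dielectric=dielectric,
        debye=debye_length(ionic_strength, table.temperature, dielectric),
        table=table, sequence=seq,
    )


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def total_energy_and_forces(coords: np.ndarray, system: SlabSystem,
                            shift_nonel: bool = True):
    """Reference all-pairs energy and analytic forces (numpy, O(N²)).

    Minimum-image convention in all three dimensions; bonded pairs are
    excluded from the nonbonded sums.  Forces are −∇E.  This is the
    contract implementation the fast cell-list kernels are tested against;
    use it directly only for small systems.
    """
    x = np.asarray(coords, dtype=float)
    if x.shape != (system.n_beads, 3):
        raise ForcefieldError(
            f"coordinates shape {x.shape} != ({system.n_beads}, 3)"
        )
    box = system.box
    t = system.table
    eps = t.epsilon_lj
    energy = 0.0
    forces = np.zeros_like(x)

    # bonded
    if len(system.bonds):
        bi, bj = system.bonds[:, 0], system.bonds[:, 1]
        d = _min_image(x[bi] - x[bj], box)
        r = np.linalg.norm(d, axis=1)
        if np.any(r < DIST_FLOOR):
            raise ForcefieldError("bonded bead pair below distance floor")
        energy += float(np.sum(0.5 * t.k_bond * (r - t.r0_bond) ** 2))
        f = (-t.k_bond * (r - t.r0_bond) / r)[:, None] * d
        np.add.at(forces, bi, f)
        np.add.at(forces, bj, -f)

    # nonbonded (all unique pairs, minus bonded exclusions)
    n = system.n_beads
    iu, ju = np.triu_indices(n, k=1)
    bonded = (system.chain_id[iu] == system.chain_id[ju]) & (ju - iu == 1)
    iu, ju = iu[~bonded], ju[~bonded]
    d = _min_image(x[iu] - x[ju], box)
    r = np.linalg.norm(d, axis=1)
    if np.any(r < DIST_FLOOR):
        raise ForcefieldError("nonbonded bead pair below distance floor")

    lam_ij = 0.5 * (system.lam[iu] + system.lam[ju])
    sig_ij = 0.5 * (system.sigma[iu] + system.sigma[ju])

    # Ashbaugh-Hatch stickiness
    within = r < t.cutoff_nonel
    rw, lw, sw = r[within], lam_ij[within], sig_ij[within]
    sr6 = (sw / rw) ** 6
    lj = 4.0 * eps * (sr6 * sr6 - sr6)
    dlj = -24.0 * eps * (2.0 * sr6 * sr6 - sr6) / rw
    rmin = 2.0 ** (1.0 / 6.0) * sw
    rep = rw <= rmin
    e_ah = np.where(rep, lj + (1.0 - lw) * eps, lw * lj)
    de_ah = np.where(rep, dlj, lw * dlj)
    if shift_nonel:
        src6 = (sw / t.cutoff_nonel) ** 6
        e_ah = e_ah - lw * 4.0 * eps * (src6 * src6 - src6)
    energy += float(np.sum(e_ah))
    fmag = (-de_ah / rw)[:, None] * d[within]
    np.add.at(forces, iu[within], fmag)
    np.add.at(forces, ju[within], -fmag)

    # Debye-Hückel electrostatics
    qq = system.q[iu] * system.q[ju]
    el = (qq != 0.0) & (r < t.cutoff_el)
    if np.any(el):
        re, qqe = r[el], qq[el]
        pref = COULOMB * qqe / system.dielectric
        kap = 1.0 / system.debye
        e_dh = pref * (np.exp(-kap * re) / re
                       - np.exp(-kap * t.cutoff_el) / t.cutoff_el)
        de_dh = -pref * np.exp(-kap * re) * (kap * re + 1.0) / re**2
        energy += float(np.sum(e_dh))
        fmag = (-de_dh / re)[:, None] * d[el]
        np.add.at(forces, iu[el], fmag)
        np.add.at(forces, ju[el], -fmag)

    return energy, forces
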