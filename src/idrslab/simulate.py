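"""Langevin dynamics engine and the slab simulation protocol.

Chains are initialized as compact random walks inside a central z-window
so a condensate nucleus exists at t = 0, then propagated with a BAOAB
Langevin integrator (dt = 0.01 ps, γ = 0.01 ps⁻¹, T = 293 K by default).
Production frames are recorded at fixed intervals, wrapped into the
primary box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .forcefield import COULOMB, KB, SlabSystem

DEFAULT_SKIN = 0.4  # nm added to the pair-list cutoff


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Integrator and protocol settings (ps, nm, K)."""

    n_steps: int
    dt: float = 0.01
    gamma: float = 0.01
    temperature: float = 293.0
    save_interval_ps: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        steps = self.save_interval_ps / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("save_interval_ps must be a multiple of dt")

    @property
    def save_every(self) -> int:
        return int(round(self.save_interval_ps / self.dt))


@dataclass
class Trajectory:
    """Recorded frames (wrapped into the primary box) plus provenance."""

    times: np.ndarray  # (F,) ps, strictly increasing
    frames: np.ndarray  # (F, N, 3) nm
    box: np.ndarray  # (3,) nm
    seed: int
    config: SimulationConfig | None = None
    kinetic_temperatures: np.ndarray | None = None
    potential_energies: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.times)


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Instantaneous kinetic temperature: Σ½mv² = (3N/2)·k_B·T_kin."""
    v = np.asarray(velocities, dtype=float)
    m = np.asarray(masses, dtype=float)
    if v.ndim != 2 or v.shape[0] < 1:
        raise ValueError("need at least one bead")
    twice_ke = float(np.sum(m[:, None] * v**2))
    return twice_ke / (3.0 * v.shape[0] * KB)


def maxwell_boltzmann_velocities(masses, temperature, rng) -> np.ndarray:
    """Velocities drawn from the Maxwell–Boltzmann distribution (nm/ps)."""
    m = np.asarray(masses, dtype=float)
    sd = np.sqrt(KB * temperature / m)
    return rng.standard_normal((len(m), 3)) * sd[:, None]


def wrap_coordinates(x: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap into the primary box centered on the origin: (-L/2, L/2]."""
    return x - box * np.round(x / box)


def initialize_slab(system: SlabSystem, seed: int,
                    z_window_fraction: float = 0.2,
                    min_separation: float = 0.2,
                    relax_separation: float = 0.4,
                    max_retries: int = 5) -> np.ndarray:
    """Random-walk chains packed into a central z-window.

    Each chain is grown as a fixed-step (r0_bond) random walk reflected at
    the window boundaries, then a geometric overlap relaxation pushes all
    bead pairs out to `relax_separation` nm (≈0.7σ, where the 12-power
    repulsion is still mild enough for the integrator) and the result is
    checked against the hard `min_separation` floor.  Deterministic per
    seed.
    """
    rng = np.random.default_rng(seed)
    box = system.box
    half_window = 0.5 * z_window_fraction * box[2]
    step = system.table.r0_bond
    if half_window < step:
        raise SimulationError("box z too small for the requested z-window")

    for attempt in range(max_retries):
        coords = np.empty((system.n_beads, 3))
        for c in range(system.n_chains):
            sl = system.chain_slice(c)
            pos = np.empty((system.chain_length, 3))
            pos[0] = [
                rng.uniform(-box[0] / 2, box[0] / 2),
                rng.uniform(-box[1] / 2, box[1] / 2),
                rng.uniform(-half_window, half_window),
            ]
            for k in range(1, system.chain_length):
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                nxt = pos[k - 1] + step * u
                # reflect z back into the central window
                if nxt[2] > half_window:
                    nxt[2] = 2 * half_window - nxt[2]
                elif nxt[2] < -half_window:
                    nxt[2] = -2 * half_window - nxt[2]
                pos[k] = nxt
            coords[sl] = pos
        # clean up steric overlaps while keeping bonds near r0
        it = K.relax_overlaps(
            coords, box, system.chain_id.astype(np.int64),
            system.bonds, relax_separation, step, 500,
        )
        if it >= 0 and K.min_pair_distance(coords, box) >= min_separation:
            return minimize_energy(system, coords)
    raise SimulationError(
        f"could not satisfy {min_separation} nm overlap floor "
        f"after {max_retries} placement attempts"
    )


class _PairState:
    """Wrapped coordinates plus short-range and electrostatic pair lists."""

    def __init__(self, system: SlabSystem, coords, skin: float):
        self.system = system
        self.skin = skin
        self.rl_nl = system.table.cutoff_nonel + skin
        self.rl_el = system.table.cutoff_el + skin
        self.chain_id = system.chain_id.astype(np.int64)
        self.charged_idx = np.flatnonzero(system.q != 0.0).astype(np.int64)
        self.x = np.ascontiguousarray(coords, dtype=float)
        cap = max(4096, system.n_beads * 192)
        self.pi = np.empty(cap, dtype=np.int64)
        self.pj = np.empty(cap, dtype=np.int64)
        qcap = max(1024, len(self.charged_idx) * 256)
        self.qi = np.empty(qcap, dtype=np.int64)
        self.qj = np.empty(qcap, dtype=np.int64)
        self.rebuild()

    def rebuild(self):
        for _ in range(8):
            n_nl, n_el = K._rebuild(
                self.x, self.system.box, self.chain_id, self.charged_idx,
                self.rl_nl, self.rl_el, self.pi, self.pj, self.qi, self.qj,
            )
            if n_nl < 0:
                self.pi = np.empty(2 * len(self.pi), dtype=np.int64)
                self.pj = np.empty(2 * len(self.pj), dtype=np.int64)
                continue
            if n_el < 0:
                self.qi = np.empty(2 * len(self.qi), dtype=np.int64)
                self.qj = np.empty(2 * len(self.qj), dtype=np.int64)
                continue
            self.n_nl, self.n_el = n_nl, n_el
            return
        raise SimulationError("neighbor list capacity growth failed")

    def ff_args(self, shift_nonel: bool):
        t = self.system.table
        return (t.epsilon_lj, t.cutoff_nonel, t.cutoff_el,
                1.0 / self.system.debye, COULOMB / self.system.dielectric,
                t.r0_bond, t.k_bond, shift_nonel)


def fast_energy_forces(coords: np.ndarray, system: SlabSystem,
                       shift_nonel: bool = True,
                       skin: float = DEFAULT_SKIN):
    """Pair-list energy/forces (numba path used by `run`)."""
    ps = _PairState(system, coords, skin)
    f = np.zeros_like(ps.x)
    e, err = K.compute_forces(
        ps.x, system.box, ps.pi, ps.pj, ps.n_nl, ps.qi, ps.qj, ps.n_el,
        system.lam, system.sigma, system.q, system.bonds, f,
        *ps.ff_args(shift_nonel),
    )
    if err == K.ERR_FLOOR:
        raise SimulationError("bead pair below the 1e-4 nm distance floor")
    return e, f


def minimize_energy(system: SlabSystem, coords: np.ndarray,
                    n_iter: int = 400, max_disp: float = 0.01,
                    skin: float = DEFAULT_SKIN) -> np.ndarray:
    """Capped steepest-descent minimization (drains packing energy)."""
    ps = _PairState(system, coords.copy(), skin)
    f = np.zeros_like(ps.x)
    ref = ps.x.copy()
    e, n_nl, n_el, err = K.descend(
        ps.x, f, ref, system.box, ps.chain_id, ps.charged_idx, system.bonds,
        ps.pi, ps.pj, ps.qi, ps.qj, ps.n_nl, ps.n_el,
        system.lam, system.sigma, system.q,
        *ps.ff_args(True), ps.rl_nl, ps.rl_el, skin, n_iter, max_disp,
    )
    if err != K.ERR_OK:
        raise SimulationError("minimization failed (distance floor/overflow)")
    return ps.x


def run(system: SlabSystem, config: SimulationConfig,
        start: np.ndarray, shift_nonel: bool = True,
        skin: float = DEFAULT_SKIN) -> Trajectory:
    """Propagate a slab system and record frames.

    BAOAB splitting; one sequential random stream per run seeded from
    ``config.seed`` (velocities first, then the thermostat noise), so
    trajectories are bitwise reproducible.  Frames (including t = 0) are
    wrapped into the primary box on output.
    """
    t = system.table
    x = np.array(start, dtype=float)
    if x.shape != (system.n_beads, 3):
        raise SimulationError(
            f"start coordinates shape {x.shape} != ({system.n_beads}, 3)"
        )
    rng = np.random.default_rng(config.seed)
    v = maxwell_boltzmann_velocities(system.mass, config.temperature, rng)
    kt = KB * config.temperature

    ps = _PairState(system, x, skin)
    x = ps.x
    ref = x.copy()
    f = np.zeros_like(x)
    e, err = K.compute_forces(
        x, system.box, ps.pi, ps.pj, ps.n_nl, ps.qi, ps.qj, ps.n_el,
        system.lam, system.sigma, system.q, system.bonds, f,
        *ps.ff_args(shift_nonel),
    )
    if err != K.ERR_OK:
        raise SimulationError("invalid start configuration (distance floor)")

    save_every = config.save_every
    times = [0.0]
    frames = [wrap_coordinates(x, system.box)]
    ktemps = [kinetic_temperature(v, system.mass)]
    epots = [e]

    done = 0
    while done < config.n_steps:
        n_seg = min(save_every, config.n_steps - done)
        remaining = n_seg
        while remaining > 0:
            noise = rng.standard_normal((remaining, system.n_beads, 3))
            e, n_nl, n_el, err, s = K.run_segment(
                x, v, f, ref, system.box, system.mass, system.lam,
                system.sigma, system.q, ps.chain_id, ps.charged_idx,
                system.bonds, ps.pi, ps.pj, ps.qi, ps.qj, ps.n_nl, ps.n_el,
                config.dt, config.gamma, kt, noise,
                *ps.ff_args(shift_nonel), ps.rl_nl, ps.rl_el, skin,
            )
            ps.n_nl, ps.n_el = max(n_nl, 0), max(n_el, 0)
            if err == K.ERR_OVERFLOW:
                ps.rebuild()  # grows capacity and rebuilds
                ref[:] = x
                remaining -= s
                continue
            if err in (K.ERR_FLOOR, K.ERR_NONFINITE):
                raise SimulationError(
                    f"simulation aborted at step {done + (n_seg - remaining) + s}: "
                    + ("distance floor violated" if err == K.ERR_FLOOR
                       else "non-finite coordinate/energy")
                )
            remaining = 0
        done += n_seg
        if n_seg == save_every:
            times.append(done * config.dt)
            frames.append(wrap_coordinates(x, system.box))
            ktemps.append(kinetic_temperature(v, system.mass))
            epots.append(e)

    return Trajectory(
        times=np.asarray(times),
        frames=np.asarray(frames),
        box=system.box.copy(),
        seed=config.seed,
        config=config,
        kinetic_temperatures=np.asarray(ktemps),
        potential_energies=np.asarray(epots),
    )


def write_xyz(traj: Trajectory, path, labels=None) -> None:
    """Plain-text XYZ export; the comment line carries time and box."""
    n = traj.frames.shape[1]
    if labels is None:
        labels = ["C"] * n
    with open(path, "w") as fh:
        for t, frame in zip(traj.times, traj.frames):
            fh.write(f"{n}\n")
            fh.write(
                f"t_ps={t:.6g} box_nm={traj.box[0]:.6g},"
                f"{traj.box[1]:.6g},{traj.box[2]:.6g}\n"
            )
            for lab, (xx, yy, zz) in zip(labels, frame):
                fh.write(f"{lab} {xx:.6f} {yy:.6f} {zz:.6f}\n")


def read_xyz(path) -> Trajectory:
    """Read a trajectory previously written by :func:`write_xyz`."""
    times, frames = [], []
    box = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        meta = dict(kv.split("=") for kv in lines[i + 1].split())
        times.append(float(meta["t_ps"]))
        box = np.array([float(v) for v in meta["box_nm"].split(",")])
        frame = np.array(
            [[float(v) for v in lines[i + 2 + k].split()[1:4]] for k in range(n)]
        )
        frames.append(frame)
        i += 2 + n
    if not frames:
        raise SimulationError(f"{path}: no frames")
    return Trajectory(times=np.asarray(times), frames=np.asarray(frames),
                      box=box, seed=-1)
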