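"""Coexistence analysis of slab trajectories.

Condensates are re-centered along z per frame (phase of the first Fourier
mode of the bead z-density), chain-center concentrations are histogrammed
into a z-profile in mM, the profile is fitted with a symmetric tanh
interface, and the excess transfer free energy between the coexisting
phases is ΔG_trans = RT·ln(c_dilute/c_dense).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .forcefield import AVOGADRO, R_GAS, SlabSystem
from .simulate import Trajectory

# chains-per-nm^3 -> mM: 1 / (N_A * 1e-24 L/nm^3) / 1e-3
MM_PER_PER_NM3 = 1e3 / (AVOGADRO * 1e-24)


class PhaseAnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class DensityProfile:
    """Time-averaged z-concentration profile (chain molarity, mM)."""

    z_centers: np.ndarray  # nm, spanning (-Lz/2, Lz/2)
    concentration: np.ndarray  # mM per bin
    n_frames_averaged: int
    bin_width: float  # nm
    box: np.ndarray  # (3,)
    n_chains: int

    @property
    def total_chains(self) -> float:
        """Integral of the profile (should equal n_chains per frame)."""
        area = self.box[0] * self.box[1]
        return float(
            np.sum(self.concentration) * self.bin_width * area / MM_PER_PER_NM3
        )


@dataclass(frozen=True)
class CoexistenceFit:
    c_dense: float  # mM
    c_dilute: float  # mM
    z0: float  # interface position, nm
    w: float  # interface width, nm
    delta_g_trans: float  # kJ/mol
    fit_rms: float  # mM
    phase_separated: bool
    dilute_is_bound: bool = False  # c_dilute reported as an occupancy floor


def center_shift(z: np.ndarray, lz: float) -> float:
    """Periodic z-shift that moves the density's circular mean to 0.

    Uses the phase of the first Fourier mode; a degenerate (uniform)
    distribution with vanishing resultant returns 0.
    """
    theta = 2.0 * np.pi * z / lz
    s, c = np.mean(np.sin(theta)), np.mean(np.cos(theta))
    if np.hypot(s, c) < 1e-9:
        return 0.0
    return lz * np.arctan2(s, c) / (2.0 * np.pi)


def center_condensate(frame: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Shift a frame along z so the condensate sits at z = 0 (x, y kept)."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape[0] < 1:
        raise PhaseAnalysisError("empty frame")
    shift = center_shift(frame[:, 2], box[2])
    out = frame.copy()
    out[:, 2] -= shift
    out[:, 2] -= box[2] * np.round(out[:, 2] / box[2])
    return out


def chain_centers(frame: np.ndarray, system: SlabSystem) -> np.ndarray:
    """Mass-weighted chain centers with bonds reconstructed by minimum image.

    Frames are stored wrapped, so each chain is first unwrapped by walking
    along the backbone before its center of mass is taken; centers are then
    wrapped back into the primary box.
    """
    box = system.box
    n, L = system.n_chains, system.chain_length
    pos = frame.reshape(n, L, 3)
    steps = pos[:, 1:] - pos[:, :-1]
    steps -= box * np.round(steps / box)
    unwrapped = np.concatenate(
        [pos[:, :1], pos[:, :1] + np.cumsum(steps, axis=1)], axis=1
    )
    m = system.mass[:L]
    com = np.sum(unwrapped * m[None, :, None], axis=1) / np.sum(m)
    return com - box * np.round(com / box)


def density_profile(traj: Trajectory, system: SlabSystem,
                    equilibration_cut: float = None,
                    bin_width: float = 1.0,
                    species: str = "chain") -> DensityProfile:
    """Time-averaged, per-frame-centered z-concentration profile.

    ``equilibration_cut`` is a time in ps; frames at or before it are
    discarded (default: the first 25% of the trajectory).  ``species``
    selects chain centers (default) or raw beads as the counted particle.
    """
    if equilibration_cut is None:
        equilibration_cut = 0.25 * traj.times[-1]
    keep = traj.times > equilibration_cut
    if not np.any(keep):
        raise PhaseAnalysisError("no frames left after the equilibration cut")
    box = traj.box
    lz = box[2]
    nbins = max(1, int(round(lz / bin_width)))
    bw = lz / nbins
    edges = np.linspace(-lz / 2, lz / 2, nbins + 1)
    hist = np.zeros(nbins)
    n_frames = 0
    for frame in traj.frames[keep]:
        centered = center_condensate(frame, box)
        if species == "chain":
            z = chain_centers(centered, system)[:, 2]
        elif species == "bead":
            z = centered[:, 2]
        else:
            raise PhaseAnalysisError(f"unknown species {species!r}")
        h, _ = np.histogram(z, bins=edges)
        hist += h
        n_frames += 1
    bin_volume = box[0] * box[1] * bw
    conc = hist / n_frames / bin_volume * MM_PER_PER_NM3
    return DensityProfile(
        z_centers=0.5 * (edges[:-1] + edges[1:]),
        concentration=conc,
        n_frames_averaged=n_frames,
        bin_width=bw,
        box=box.copy(),
        n_chains=system.n_chains,
    )


def delta_g_trans(c_dilute: float, c_dense: float, temperature: float) -> float:
    """Excess transfer free energy RT·ln(c_dilute/c_dense) in kJ/mol."""
    if c_dilute <= 0 or c_dense <= 0:
        raise PhaseAnalysisError("concentrations must be positive")
    return R_GAS * temperature * np.log(c_dilute / c_dense)


def _tanh_profile(z, c_dense, c_dilute, z0, w):
    return 0.5 * (c_dense + c_dilute) - 0.5 * (c_dense - c_dilute) * np.tanh(
        (np.abs(z) - z0) / w
    )


def fit_coexistence(profile: DensityProfile, temperature: float = 293.0,
                    dilute_floor: bool = True) -> CoexistenceFit:
    """Fit the symmetric tanh interface profile and derive ΔG_trans.

    A profile without a resolvable interface (flat, or a step smaller than
    the fit residual) is flagged as not phase separated with
    ΔG_trans = 0.  When the fitted dilute concentration falls below one
    chain per dilute-region volume, it is reported as that occupancy bound
    and the fit flagged (finite sampling cannot resolve less).
    """
    z = np.asarray(profile.z_centers)
    c = np.asarray(profile.concentration)
    if len(z) < 10:
        raise PhaseAnalysisError("need at least 10 bins to fit")
    lz = profile.box[2]
    mean_c = float(np.mean(c))
    if mean_c <= 0:
        raise PhaseAnalysisError("empty profile")

    # initial guesses from the profile itself
    central = np.abs(z) < 0.15 * lz
    outer = np.abs(z) > 0.35 * lz
    cd0 = max(float(np.mean(c[central])), mean_c)
    cl0 = max(float(np.mean(c[outer])), 1e-12)
    above = np.abs(z)[c > 0.5 * (cd0 + cl0)]
    z00 = float(np.max(above)) if len(above) else 0.1 * lz
    p0 = [cd0, cl0, max(z00, 1e-2), 1.0]

    flat = CoexistenceFit(
        c_dense=mean_c, c_dilute=mean_c, z0=0.0, w=0.0,
        delta_g_trans=0.0, fit_rms=float(np.std(c)), phase_separated=False,
    )
    try:
        popt, _ = curve_fit(
            _tanh_profile, z, c, p0=p0,
            bounds=([0.0, 0.0, 0.0, 1e-3],
                    [np.inf, np.inf, lz / 2, lz]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return flat
    cd, cl, z0, w = (float(v) for v in popt)
    resid = c - _tanh_profile(z, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))

    # no interface: step below noise, inverted, or not meaningfully dense
    if cd <= cl or (cd - cl) < 3.0 * rms or cd < 1.2 * mean_c:
        return flat

    bound = False
    if dilute_floor:
        dilute_volume = profile.box[0] * profile.box[1] * max(lz - 2 * z0, profile.bin_width)
        floor = MM_PER_PER_NM3 / dilute_volume
        if cl < floor:
            cl = floor
            bound = True

    return CoexistenceFit(
        c_dense=cd, c_dilute=cl, z0=z0, w=w,
        delta_g_trans=delta_g_trans(cl, cd, temperature),
        fit_rms=rms, phase_separated=True, dilute_is_bound=bound,
    )


def profile_frame(profile: DensityProfile):
    """Profile as a two-column DataFrame (z_nm, concentration_mM)."""
    import pandas as pd

    return pd.DataFrame(
        {"z_nm": profile.z_centers, "concentration_mM": profile.concentration}
    )


def fit_frame(fit: CoexistenceFit):
    """One-row summary DataFrame of a coexistence fit."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "c_dense_mM": fit.c_dense,
                "c_dilute_mM": fit.c_dilute,
                "z0_nm": fit.z0,
                "w_nm": fit.w,
                "delta_g_trans_kJ_mol": fit.delta_g_trans,
                "fit_rms_mM": fit.fit_rms,
                "phase_separated": fit.phase_separated,
                "dilute_is_bound": fit.dilute_is_bound,
            }
        ]
    )
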