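"""Synthetic inputs with the statistical structure the analysis assumes.

Three generator families, all pure functions of (spec, seed):

* IDR-like sequences with controlled length, mean stickiness λ̄, net
  charge and charge arrangement — uniform scatter, an N-terminal-acidic
  "dipole" (net negative charge accumulating toward the N-terminus,
  recovering toward the C-terminus), or its mirror image;
* noisy tanh-shaped slab concentration profiles with known coexistence
  densities, for exercising the coexistence fit;
* gapped alignments with a known gap-column mask, for exercising
  complete deletion.

Dipole and uniform sequences drawn from the same spec share one residue
multiset, so net charge and λ̄ are composition-matched and arrangement is
the only variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import residue_charge
from .forcefield import ResidueParameterTable
from .io import CANONICAL_AA, AlignmentMatrix, IDRSequence
from .phase import MM_PER_PER_NM3, DensityProfile

ARRANGEMENTS = ("uniform", "dipole", "reverse_dipole")

# charged residues used to realize the net-charge target
_NEG, _POS = ("D", "E"), ("K", "R")


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceSpec:
    length: int
    lambda_bar: float
    net_charge: int = 0
    arrangement: str = "uniform"
    charged_fraction: float = 0.15  # total fraction of charged residues
    seed: int = 0

    def __post_init__(self):
        if self.length < 4:
            raise GenerationError("length must be >= 4")
        if self.arrangement not in ARRANGEMENTS:
            raise GenerationError(f"unknown arrangement {self.arrangement!r}")
        if not 0.0 <= self.charged_fraction < 1.0:
            raise GenerationError("charged_fraction must be in [0, 1)")


@dataclass(frozen=True)
class ProfileSpec:
    c_dense: float  # mM
    c_dilute: float  # mM
    z0: float  # nm
    w: float  # nm
    lz: float = 100.0  # nm
    lx: float = 15.0
    ly: float = 15.0
    bins: int = 100
    noise: float = 0.0  # multiplicative Gaussian sd
    seed: int = 0

    def __post_init__(self):
        if not self.c_dense >= self.c_dilute >= 0:
            raise GenerationError("need c_dense >= c_dilute >= 0")
        if self.bins < 2 or self.lz <= 0 or self.w <= 0:
            raise GenerationError("invalid profile geometry")


def _charged_counts(spec: SequenceSpec, table: ResidueParameterTable):
    """Choose how many +1 and -1 residues realize the net charge."""
    n_charged = int(round(spec.charged_fraction * spec.length))
    need = abs(spec.net_charge)
    if n_charged < need or (n_charged - need) % 2 == 1:
        n_charged = need + 2 * ((max(n_charged - need, 0) + 1) // 2)
    if n_charged > spec.length:
        raise GenerationError("net charge infeasible at this length")
    n_pos = (n_charged + spec.net_charge) // 2
    n_neg = n_charged - n_pos
    if n_pos < 0 or n_neg < 0:
        raise GenerationError("net charge infeasible at this length")
    return n_pos, n_neg


def _residue_multiset(spec: SequenceSpec, table: ResidueParameterTable):
    """A residue multiset matching the target λ̄ and net charge."""
    n_pos, n_neg = _charged_counts(spec, table)
    charged = []
    charged += [_POS[0]] * (n_pos // 2) + [_POS[1]] * (n_pos - n_pos // 2)
    charged += [_NEG[0]] * (n_neg // 2) + [_NEG[1]] * (n_neg - n_neg // 2)
    n_fill = spec.length - len(charged)
    lam_charged = sum(table.lam[a] for a in charged)
    # fill remaining slots greedily with neutral residues: each slot takes
    # the residue whose λ is closest to the per-slot mean still needed
    neutral = sorted(
        (a for a in table.lam if residue_charge(a) == 0),
        key=lambda a: table.lam[a],
    )
    want = spec.lambda_bar * spec.length - lam_charged
    fill: list[str] = []
    remaining = want
    for slot in range(n_fill, 0, -1):
        target = remaining / slot
        pick = min(neutral, key=lambda a: abs(table.lam[a] - target))
        fill.append(pick)
        remaining -= table.lam[pick]
    residues = charged + fill
    realized = sum(table.lam[a] for a in residues) / spec.length
    if abs(realized - spec.lambda_bar) > 0.02:
        raise GenerationError(
            f"realized lambda_bar {realized:.3f} misses target "
            f"{spec.lambda_bar:.3f} by more than 0.02"
        )
    return residues


def generate_idr(spec: SequenceSpec,
                 table: ResidueParameterTable | None = None) -> IDRSequence:
    """Generate an IDR-like sequence meeting the spec's targets.

    The realized λ̄ is within 0.02 of the target (else an error).  The
    dipole arrangement places acidic residues in the N-terminal 40% and
    basic residues in the C-terminal 40% (shuffled within blocks), giving
    a cumulative-charge minimum in the first half; uniform shuffles the
    whole multiset.
    """
    if table is None:
        table = ResidueParameterTable.default()
    rng = np.random.default_rng(spec.seed)
    residues = _residue_multiset(spec, table)
    neg = [a for a in residues if residue_charge(a) < 0]
    pos = [a for a in residues if residue_charge(a) > 0]
    neu = [a for a in residues if residue_charge(a) == 0]

    if spec.arrangement == "uniform":
        seq = list(residues)
        rng.shuffle(seq)
    else:
        if spec.arrangement == "reverse_dipole":
            neg, pos = pos, neg
        n = spec.length
        n_head = int(round(0.4 * n))
        n_tail = int(round(0.4 * n))
        if len(neg) > n_head or len(pos) > n_tail:
            raise GenerationError("too many charged residues for dipole blocks")
        rng.shuffle(neu)
        head = neg + neu[: n_head - len(neg)]
        tail = pos + neu[n_head - len(neg): n_head - len(neg) + n_tail - len(pos)]
        mid = neu[n_head - len(neg) + n_tail - len(pos):]
        rng.shuffle(head)
        rng.shuffle(tail)
        rng.shuffle(mid)
        seq = head + mid + tail
    name = f"syn_L{spec.length}_lam{spec.lambda_bar:g}_q{spec.net_charge}_" \
           f"{spec.arrangement}_s{spec.seed}"
    return IDRSequence(id=name, sequence="".join(seq))


def generate_tanh_profile(spec: ProfileSpec) -> DensityProfile:
    """Evaluate the tanh coexistence form on a bin grid, with optional noise."""
    rng = np.random.default_rng(spec.seed)
    edges = np.linspace(-spec.lz / 2, spec.lz / 2, spec.bins + 1)
    z = 0.5 * (edges[:-1] + edges[1:])
    c = 0.5 * (spec.c_dense + spec.c_dilute) - 0.5 * (
        spec.c_dense - spec.c_dilute
    ) * np.tanh((np.abs(z) - spec.z0) / spec.w)
    if spec.noise > 0:
        c = c * (1.0 + spec.noise * rng.standard_normal(spec.bins))
        c = np.clip(c, 0.0, None)
    # implied chain count so the profile's bookkeeping is self-consistent
    area = spec.lx * spec.ly
    n_chains = int(round(np.sum(c) * (spec.lz / spec.bins) * area / MM_PER_PER_NM3))
    return DensityProfile(
        z_centers=z, concentration=c, n_frames_averaged=1,
        bin_width=spec.lz / spec.bins,
        box=np.array([spec.lx, spec.ly, spec.lz]),
        n_chains=max(n_chains, 1),
    )


def fixture_alignment(n_seqs: int, n_cols: int, gap_fraction: float,
                      seed: int = 0, divergence: float = 0.2):
    """Alignment of mutated copies of one ancestor, with a known gap mask.

    Each row substitutes a random residue at each site with probability
    ``divergence`` (keeping observed differences below the Equal-Input
    saturation bound).  Returns ``(AlignmentMatrix, gap_columns)`` where
    ``gap_columns`` is the set of 0-based columns containing at least one
    gap, so the expected complete-deletion survivor count is
    ``n_cols - len(gap_columns)``.
    """
    if n_seqs < 2:
        raise GenerationError("need at least two sequences")
    rng = np.random.default_rng(seed)
    aa = np.array(list(CANONICAL_AA))
    ancestor = rng.choice(aa, size=n_cols)
    rows = np.tile(ancestor, (n_seqs, 1))
    mutate = rng.random((n_seqs, n_cols)) < divergence
    rows[mutate] = rng.choice(aa, size=int(mutate.sum()))
    gap_columns = set(
        int(j) for j in np.nonzero(rng.random(n_cols) < gap_fraction)[0]
    )
    if len(gap_columns) == n_cols:  # keep at least one survivor
        gap_columns.discard(min(gap_columns))
    for j in gap_columns:
        k = rng.integers(0, n_seqs, size=max(1, int(rng.integers(1, n_seqs))))
        rows[np.unique(k), j] = "-"
    ids = tuple(f"seq{i}" for i in range(n_seqs))
    aln = AlignmentMatrix(ids=ids, rows=tuple("".join(r) for r in rows))
    return aln, gap_columns


def synthetic_table(seed: int = 0) -> ResidueParameterTable:
    """A random-but-valid residue parameter table for forcefield tests."""
    rng = np.random.default_rng(seed)
    aas = list(CANONICAL_AA)
    lam = {a: float(v) for a, v in zip(aas, rng.uniform(0.0, 1.0, 20))}
    sigma = {a: float(v) for a, v in zip(aas, rng.uniform(0.45, 0.68, 20))}
    mass = {a: float(v) for a, v in zip(aas, rng.uniform(57.0, 186.0, 20))}
    q = {a: float(residue_charge(a)) for a in aas}
    return ResidueParameterTable(lam=lam, sigma=sigma, q=q, mass=mass)


def fixture_idr_panel(table: ResidueParameterTable | None = None):
    """Six deterministic IDRs: low/high λ̄ × three charge arrangements."""
    if table is None:
        table = ResidueParameterTable.default()
    panel = []
    for lam_bar in (0.35, 0.65):
        for arr in ARRANGEMENTS:
            spec = SequenceSpec(length=50, lambda_bar=lam_bar, net_charge=-4,
                                arrangement=arr, seed=7)
            panel.append(generate_idr(spec, table))
    return panel
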