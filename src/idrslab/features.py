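"""Sequence-level IDR analytics: charge patterning, composition, stickiness.

The charge rule follows the convention used for the cumulative-charge
analysis of YTHDF IDRs: Arg and Lys carry +1, Asp and Glu carry -1, every
other residue type (including His) carries 0 elementary charges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CANONICAL_AA, IDRSequence, SequenceError

_CHARGE = {aa: 0 for aa in CANONICAL_AA}
_CHARGE.update({"R": 1, "K": 1, "D": -1, "E": -1})


@dataclass(frozen=True)
class ChargeProfile:
    """Per-residue charges and their running (N→C) sum."""

    per_residue_q: tuple
    cumulative_q: tuple

    @property
    def net_charge(self) -> int:
        return self.cumulative_q[-1]


@dataclass(frozen=True)
class StickinessSummary:
    lambda_bar: float


def residue_charge(aa: str) -> int:
    """Integer charge of a canonical residue (R/K +1, D/E -1, else 0)."""
    try:
        return _CHARGE[aa]
    except KeyError:
        raise SequenceError(f"non-canonical residue {aa!r} has no charge") from None


def cumulative_charge(seq: IDRSequence) -> ChargeProfile:
    """Running N→C sum of residue charges along the sequence."""
    q = [residue_charge(aa) for aa in seq.sequence]
    return ChargeProfile(
        per_residue_q=tuple(q), cumulative_q=tuple(np.cumsum(q).tolist())
    )


def composition(seq: IDRSequence) -> dict[str, float]:
    """Amino-acid fractions over the 20 canonical residues (sums to 1)."""
    n = seq.length
    counts = {aa: 0 for aa in CANONICAL_AA}
    for aa in seq.sequence:
        if aa not in counts:
            raise SequenceError(f"IDR {seq.id!r}: residue {aa!r} not canonical")
        counts[aa] += 1
    return {aa: c / n for aa, c in counts.items()}


def mean_stickiness(seq: IDRSequence, table) -> StickinessSummary:
    """Mean hydropathy λ̄ of the sequence under a residue parameter table.

    Equals the dot product of the composition vector with the λ scale.
    """
    lam = []
    for aa in seq.sequence:
        try:
            lam.append(table.lam[aa])
        except KeyError:
            raise SequenceError(
                f"IDR {seq.id!r}: residue {aa!r} absent from parameter table"
            ) from None
    return StickinessSummary(lambda_bar=float(np.mean(lam)))


def dipole_index(seq: IDRSequence) -> int:
    """Net charge of the N-terminal half minus that of the C-terminal half.

    Convenience scalar for the qualitative "charge dipole" pattern (net
    negative charge accumulating toward the N-terminus, recovering toward
    the C-terminus).  Negative values indicate an acidic-N dipole.  This is
    an extension beyond the cumulative-charge plot itself.
    """
    q = [residue_charge(aa) for aa in seq.sequence]
    half = len(q) // 2
    return int(sum(q[:half]) - sum(q[len(q) - half:]))


def charge_profile_frame(seq: IDRSequence):
    """Per-residue charge track as a DataFrame (index, aa, q, cumulative_q)."""
    import pandas as pd

    prof = cumulative_charge(seq)
    return pd.DataFrame(
        {
            "index": np.arange(1, seq.length + 1),
            "aa": list(seq.sequence),
            "q": prof.per_residue_q,
            "cumulative_q": prof.cumulative_q,
        }
    )


def summary_frame(idrs, table):
    """One summary row per IDR: length, net charge, λ̄, dipole index."""
    import pandas as pd

    rows = []
    for idr in idrs:
        prof = cumulative_charge(idr)
        rows.append(
            {
                "id": idr.id,
                "length": idr.length,
                "net_charge": prof.net_charge,
                "lambda_bar": mean_stickiness(idr, table).lambda_bar,
                "dipole_index": dipole_index(idr),
            }
        )
    return pd.DataFrame(rows)


def plot_cumulative_charge(idrs, path, normalize_length: bool = False):
    """Cumulative-charge curves, on an absolute residue axis or a 0..1 axis.

    ``normalize_length=True`` rescales position to 0..1 so IDRs of very
    different lengths can be compared on one panel.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for idr in idrs:
        cq = cumulative_charge(idr).cumulative_q
        x = np.arange(1, idr.length + 1)
        if normalize_length:
            x = x / idr.length
        ax.plot(x, cq, label=idr.id)
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("relative position" if normalize_length else "residue")
    ax.set_ylabel("cumulative charge (e)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
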