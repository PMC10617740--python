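"""Equal-Input evolutionary distances with complete-deletion filtering.

Alignment columns containing any gap ('-') or missing-data character
('X', '?') are removed before distance calculation (complete deletion).
Pairwise distances follow the Equal Input model:

    d = -b * ln(1 - p/b),   b = 1 - sum_i g_i^2

with p the observed mismatch fraction and g the amino-acid frequencies
(pooled over the retained columns by default, or uniform 1/20).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AlignmentMatrix, SequenceError

MISSING = {"-", "X", "?"}


class DistanceError(ValueError):
    pass


@dataclass(frozen=True)
class FilteredAlignment:
    """Gap-free alignment left by complete deletion."""

    ids: tuple
    rows: tuple
    retained_index_map: tuple  # original (0-based) column indices

    @property
    def retained_columns(self) -> int:
        return len(self.retained_index_map)


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple
    matrix: np.ndarray  # symmetric, zero diagonal, substitutions/site

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise DistanceError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise DistanceError("matrix not symmetric")
        if np.any(np.diag(m) != 0):
            raise DistanceError("nonzero diagonal")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=list(self.ids),
                            columns=list(self.ids))

    def to_long_frame(self):
        import pandas as pd

        rows = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                rows.append(
                    {"id_a": self.ids[i], "id_b": self.ids[j],
                     "distance": self.matrix[i, j]}
                )
        return pd.DataFrame(rows)


def complete_deletion(aln: AlignmentMatrix) -> FilteredAlignment:
    """Drop every column containing a gap or missing-data character."""
    keep = [
        j for j in range(aln.n_columns)
        if not any(row[j] in MISSING for row in aln.rows)
    ]
    if not keep:
        raise DistanceError("complete deletion removed every column")
    rows = tuple("".join(row[j] for j in keep) for row in aln.rows)
    return FilteredAlignment(ids=aln.ids, rows=rows,
                             retained_index_map=tuple(keep))


def amino_acid_frequencies(rows) -> dict[str, float]:
    """Residue frequencies pooled over all sequences and columns."""
    counts: dict[str, int] = {}
    total = 0
    for row in rows:
        for aa in row:
            counts[aa] = counts.get(aa, 0) + 1
            total += 1
    if total == 0:
        raise DistanceError("empty alignment rows")
    return {aa: c / total for aa, c in counts.items()}


def equal_input_distance(row_a: str, row_b: str, freqs,
                         saturated: str = "error") -> float:
    """Equal-Input distance between two gap-free aligned sequences.

    ``saturated`` controls behavior when p >= b (the correction diverges):
    "error" raises; "sentinel" returns inf.
    """
    if len(row_a) != len(row_b):
        raise DistanceError("rows have unequal lengths")
    if len(row_a) == 0:
        raise DistanceError("empty rows")
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-6:
        raise DistanceError(f"frequencies sum to {total}, not 1")
    p = sum(a != b for a, b in zip(row_a, row_b)) / len(row_a)
    if p == 0.0:
        return 0.0
    b = 1.0 - sum(g * g for g in freqs.values())
    if p >= b:
        if saturated == "sentinel":
            return float("inf")
        raise DistanceError(
            f"saturated distance: observed difference p={p:.4f} >= b={b:.4f}"
        )
    return float(-b * np.log(1.0 - p / b))


def distance_matrix(aln: AlignmentMatrix,
                    frequency_mode: str = "empirical",
                    saturated: str = "error"):
    """Complete deletion followed by all-pairs Equal-Input distances.

    Returns ``(DistanceMatrix, FilteredAlignment)`` so callers can report
    the retained-column count alongside the distances.
    """
    filt = complete_deletion(aln)
    if frequency_mode == "empirical":
        freqs = amino_acid_frequencies(filt.rows)
    elif frequency_mode == "equal":
        from .io import CANONICAL_AA

        freqs = {aa: 1.0 / 20.0 for aa in CANONICAL_AA}
    else:
        raise DistanceError(f"unknown frequency mode {frequency_mode!r}")

    n = len(filt.ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = equal_input_distance(filt.rows[i], filt.rows[j], freqs,
                                     saturated=saturated)
            m[i, j] = m[j, i] = d
    return DistanceMatrix(ids=filt.ids, matrix=m), filt
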