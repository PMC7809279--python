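"""Kimura 2-parameter (K2P) pairwise distances.

The K2P model separates transitions (A<->G, C<->T; proportion P of
compared sites) from transversions (proportion Q) and estimates the
distance in substitutions/site as

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q).

The estimator diverges when 1 - 2P - Q <= 0 or 1 - 2Q <= 0; such pairs
are *saturated* and are flagged rather than silently dropped. The
deletion policy mirrors the standard barcoding workflow: ``complete``
(default) strips every column with a gap/missing character once for the
whole alignment; ``pairwise`` uses each pair's jointly unambiguous
columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import _is_transition
from .msa_io import BASES, Alignment, AlignmentError, complete_deletion


class SaturatedPairError(ValueError):
    """K2P estimate undefined: too many substitutions between the pair."""

    def __init__(self, P: float, Q: float):
        self.P, self.Q = P, Q
        super().__init__(
            f"saturated pair: P={P:.4f}, Q={Q:.4f} "
            f"(1-2P-Q={1 - 2 * P - Q:.4f}, 1-2Q={1 - 2 * Q:.4f})"
        )


@dataclass(frozen=True)
class PairCounts:
    """Transition/transversion proportions over jointly unambiguous columns."""

    L_eff: int
    P: float
    Q: float


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric K2P distance matrix with taxonomy annotation.

    Saturated or incomparable cells hold NaN in ``d`` and are listed in
    ``flagged`` as (i, j) index pairs.
    """

    labels: tuple[str, ...]
    species: tuple[str, ...]
    genera: tuple[str, ...]
    d: np.ndarray
    deletion_policy: str
    flagged: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def to_phylip(self) -> str:
        lines = [f"{self.n}"]
        for lab, row in zip(self.labels, self.d):
            lines.append(lab + "  " + "  ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def pair_counts(a: str, b: str) -> PairCounts:
    """Count transition/transversion proportions between two aligned rows."""
    if len(a) != len(b):
        raise AlignmentError("sequences differ in length")
    L_eff = ts = tv = 0
    for x, y in zip(a, b):
        if x not in BASES or y not in BASES:
            continue
        L_eff += 1
        if x == y:
            continue
        if _is_transition(x, y):
            ts += 1
        else:
            tv += 1
    if L_eff == 0:
        raise AlignmentError("no comparable sites between the pair")
    return PairCounts(L_eff=L_eff, P=ts / L_eff, Q=tv / L_eff)


def k2p_distance(pc: PairCounts) -> float:
    """K2P distance from transition/transversion proportions.

    Raises :class:`SaturatedPairError` when either log argument is <= 0.
    """
    w1 = 1.0 - 2.0 * pc.P - pc.Q
    w2 = 1.0 - 2.0 * pc.Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturatedPairError(pc.P, pc.Q)
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_pairwise(a: str, b: str) -> float:
    """Convenience: K2P distance directly from two aligned rows."""
    return k2p_distance(pair_counts(a, b))


def distance_matrix(aln: Alignment, deletion: str = "complete") -> DistanceMatrix:
    """All-pairs K2P distances under the chosen deletion policy.

    ``complete`` applies alignment-wide complete deletion first so every
    pair is compared over the same columns; ``pairwise`` compares each
    pair over its own jointly unambiguous columns. Saturated or
    incomparable pairs become NaN cells recorded in ``flagged``; it is an
    error only if every off-diagonal cell fails.
    """
    if aln.n < 2:
        raise AlignmentError("distance_matrix needs at least 2 sequences")
    if deletion not in ("complete", "pairwise"):
        raise AlignmentError(f"unknown deletion policy {deletion!r}")
    work = complete_deletion(aln)[0] if deletion == "complete" else aln
    n = work.n
    d = np.zeros((n, n))
    flagged: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dij = k2p_pairwise(work.records[i].residues, work.records[j].residues)
            except (SaturatedPairError, AlignmentError):
                dij = math.nan
                flagged.append((i, j))
            d[i, j] = d[j, i] = dij
    if n > 1 and len(flagged) == n * (n - 1) // 2:
        raise AlignmentError("every sequence pair is saturated or incomparable")
    return DistanceMatrix(
        labels=tuple(r.record_id for r in work.records),
        species=tuple(r.species for r in work.records),
        genera=tuple(r.genus for r in work.records),
        d=d,
        deletion_policy=deletion,
        flagged=tuple(flagged),
    )
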