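"""Barcoding-gap analysis and Best-Close-Match identification.

A usable barcode locus separates conspecific (intraspecific) from
heterospecific (interspecific) K2P distances: the *barcoding gap* is
``min(inter) - max(intra)``, positive exactly when the two distributions
are disjoint.

*Best Close Match* (BCM) scores identification success by leave-one-out:
each sequence is queried against all others; its nearest references
(within a tie tolerance of the minimum distance) determine the outcome —

* ``no_id``    nearest distance exceeds the threshold;
* ``correct``  all nearest references are conspecific;
* ``fuzzy``    nearest references mix conspecific and heterospecific;
* ``error``    all nearest references are heterospecific.

The threshold defaults to the 95th percentile of intraspecific distances
(the Meier et al. convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msa_io import AlignmentError
from .distances import DistanceMatrix

CATEGORIES = ("correct", "fuzzy", "error", "no_id")


@dataclass(frozen=True)
class DistancePartition:
    intra: tuple[float, ...]
    inter: tuple[float, ...]
    n_flagged: int  # saturated/incomparable pairs excluded


@dataclass(frozen=True)
class GapReport:
    bin_edges: np.ndarray
    intra_counts: np.ndarray
    inter_counts: np.ndarray
    max_intra: float
    min_inter: float
    gap: float
    overlap: float  # fraction of inter distances below max_intra


@dataclass(frozen=True)
class BCMReport:
    threshold: float
    categories: tuple[str, ...]  # per-query category, matrix label order
    summary: dict[str, float]  # category -> percentage over all queries
    summary_multi: dict[str, float]  # restricted to species with >= 2 members
    n_queries: int
    n_queries_multi: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [self.summary, self.summary_multi],
            index=["all_queries", "species_with_2plus"],
        )


def partition_distances(dm: DistanceMatrix) -> DistancePartition:
    """Split pairwise distances by species-label equality."""
    intra: list[float] = []
    inter: list[float] = []
    flagged = set(dm.flagged)
    n_flagged = 0
    for i in range(dm.n):
        for j in range(i + 1, dm.n):
            if (i, j) in flagged or not np.isfinite(dm.d[i, j]):
                n_flagged += 1
                continue
            (intra if dm.species[i] == dm.species[j] else inter).append(dm.d[i, j])
    return DistancePartition(tuple(intra), tuple(inter), n_flagged)


def barcoding_gap(part: DistancePartition, bin_width: float = 0.005) -> GapReport:
    """Histogram and gap/overlap summary of the two distance classes."""
    if not part.intra:
        raise AlignmentError("no intraspecific distances (no species with >= 2 sequences)")
    if not part.inter:
        raise AlignmentError("no interspecific distances (single species)")
    max_intra = max(part.intra)
    min_inter = min(part.inter)
    top = max(max(part.intra), max(part.inter))
    n_bins = max(int(np.ceil(top / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    intra_counts, _ = np.histogram(part.intra, bins=edges)
    inter_counts, _ = np.histogram(part.inter, bins=edges)
    overlap = float(np.mean(np.array(part.inter) < max_intra)) if part.inter else 0.0
    return GapReport(
        bin_edges=edges,
        intra_counts=intra_counts,
        inter_counts=inter_counts,
        max_intra=max_intra,
        min_inter=min_inter,
        gap=min_inter - max_intra,
        overlap=overlap,
    )


def bcm_threshold(part: DistancePartition, percentile: float = 0.95) -> float:
    """Percentile of intraspecific distances (linear interpolation)."""
    if not part.intra:
        raise AlignmentError("no intraspecific distances for threshold")
    if not 0.0 <= percentile <= 1.0:
        raise ValueError("percentile must be in [0, 1]")
    return float(np.quantile(part.intra, percentile, method="linear"))


def best_close_match(
    dm: DistanceMatrix,
    threshold: float,
    tie_tol: float = 1e-12,
) -> BCMReport:
    """Leave-one-out Best-Close-Match identification over all sequences.

    Every query receives a category; the report carries summary
    percentages over all queries and, separately, over queries whose
    species has >= 2 sequences (singleton species can never be "correct",
    and which denominator a study uses varies).
    """
    if dm.n < 3:
        raise AlignmentError("best_close_match needs at least 3 sequences")
    species = dm.species
    multi = {
        sp for sp in set(species) if sum(1 for s in species if s == sp) >= 2
    }
    cats: list[str] = []
    for q in range(dm.n):
        row = dm.d[q].copy()
        row[q] = np.inf
        row[~np.isfinite(row)] = np.inf
        dmin = row.min()
        if not np.isfinite(dmin) or dmin > threshold:
            cats.append("no_id")
            continue
        nearest = np.flatnonzero(row <= dmin + tie_tol)
        match = [species[i] == species[q] for i in nearest]
        if all(match):
            cats.append("correct")
        elif any(match):
            cats.append("fuzzy")
        else:
            cats.append("error")

    def summarize(idx: list[int]) -> dict[str, float]:
        if not idx:
            return dict.fromkeys(CATEGORIES, 0.0)
        return {
            c: 100.0 * sum(1 for i in idx if cats[i] == c) / len(idx)
            for c in CATEGORIES
        }

    all_idx = list(range(dm.n))
    multi_idx = [i for i in all_idx if species[i] in multi]
    return BCMReport(
        threshold=threshold,
        categories=tuple(cats),
        summary=summarize(all_idx),
        summary_multi=summarize(multi_idx),
        n_queries=len(all_idx),
        n_queries_multi=len(multi_idx),
    )
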