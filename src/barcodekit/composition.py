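"""Descriptive alignment statistics: base composition, nucleotide-pair
frequencies, and site classification.

These reproduce the classic MEGA-style summary tables for a candidate
barcode locus: per-codon-position AT/GC content, the average number of
identical (ii), transitional (si) and transversional (sv) nucleotide pairs
per sequence pair with the R = si/sv ratio, and the partition of alignment
columns into conserved / variable / parsimony-informative / singleton
sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .msa_io import BASES, Alignment, AlignmentError

#: Transition pairs (purine<->purine, pyrimidine<->pyrimidine).
TRANSITIONS = frozenset({frozenset("AG"), frozenset("CT")})

_PER_POS_KEYS = ("avg", "pos1", "pos2", "pos3")


def _is_transition(a: str, b: str) -> bool:
    return frozenset((a, b)) in TRANSITIONS


@dataclass(frozen=True)
class BaseComposition:
    """Overall base percentages and per-codon-position AT/GC content."""

    freq: dict[str, float]  # base -> percentage over unambiguous residues
    at_gc_by_codon_pos: dict[str, float]  # keys AT-1, GC-1, ..., AT-3, GC-3

    def to_frame(self) -> pd.DataFrame:
        row = {**{f"{b}%": v for b, v in sorted(self.freq.items())},
               **self.at_gc_by_codon_pos}
        return pd.DataFrame([row])


@dataclass(frozen=True)
class PairFrequencies:
    """Average per-pair counts of identical/transition/transversion sites.

    Each of ``ii``, ``si``, ``sv`` maps {"avg","pos1","pos2","pos3"} to the
    mean count over all unordered sequence pairs; ``r`` is si/sv with None
    where sv = 0.
    """

    ii: dict[str, float]
    si: dict[str, float]
    sv: dict[str, float]
    r: dict[str, float | None]

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for name, d in (("ii", self.ii), ("si", self.si), ("sv", self.sv),
                        ("R", self.r)):
            rows[name] = {k: d[k] for k in _PER_POS_KEYS}
        return pd.DataFrame(rows).T


@dataclass(frozen=True)
class SiteClassification:
    """Partition of considered columns into the four variability classes."""

    conserved: int
    variable: int
    parsimony_informative: int
    singleton: int
    considered: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "conserved": self.conserved,
            "variable": self.variable,
            "parsimony_informative": self.parsimony_informative,
            "singleton": self.singleton,
            "considered": self.considered,
        }])


def codon_position(column: int, frame_offset: int = 0) -> int:
    """1-based codon position of a 0-based alignment column.

    The reading frame is a reporting convention: position 1 starts at
    column ``frame_offset``.
    """
    return ((column - frame_offset) % 3) + 1


def base_frequencies(aln: Alignment, frame_offset: int = 0) -> BaseComposition:
    """Base percentages over unambiguous residues, overall and per codon position."""
    counts = {b: 0 for b in "ACGT"}
    pos_counts = {p: {"AT": 0, "GC": 0} for p in (1, 2, 3)}
    for j in range(aln.length):
        p = codon_position(j, frame_offset)
        for r in aln.records:
            c = r.residues[j]
            if c in BASES:
                counts[c] += 1
                pos_counts[p]["AT" if c in "AT" else "GC"] += 1
    total = sum(counts.values())
    if total == 0:
        raise AlignmentError("no unambiguous residues in alignment")
    freq = {b: 100.0 * c / total for b, c in counts.items()}
    at_gc: dict[str, float] = {}
    for p in (1, 2, 3):
        ptot = pos_counts[p]["AT"] + pos_counts[p]["GC"]
        at_gc[f"AT-{p}"] = 100.0 * pos_counts[p]["AT"] / ptot if ptot else 0.0
        at_gc[f"GC-{p}"] = 100.0 * pos_counts[p]["GC"] / ptot if ptot else 0.0
    return BaseComposition(freq=freq, at_gc_by_codon_pos=at_gc)


def pair_frequencies(aln: Alignment, frame_offset: int = 0) -> PairFrequencies:
    """Average ii/si/sv counts per unordered sequence pair, with R = si/sv.

    For every pair, only columns where both residues are unambiguous bases
    are compared; per pair these counts sum to the shared column count.
    Averages are exact; rounding is a display concern.
    """
    if aln.n < 2:
        raise AlignmentError("pair_frequencies needs at least 2 sequences")
    keys = _PER_POS_KEYS
    tot_ii = dict.fromkeys(keys, 0.0)
    tot_si = dict.fromkeys(keys, 0.0)
    tot_sv = dict.fromkeys(keys, 0.0)
    npairs = 0
    pos_of = [codon_position(j, frame_offset) for j in range(aln.length)]
    for ra, rb in combinations(aln.records, 2):
        npairs += 1
        for j, (a, b) in enumerate(zip(ra.residues, rb.residues)):
            if a not in BASES or b not in BASES:
                continue
            pk = f"pos{pos_of[j]}"
            if a == b:
                tot_ii["avg"] += 1
                tot_ii[pk] += 1
            elif _is_transition(a, b):
                tot_si["avg"] += 1
                tot_si[pk] += 1
            else:
                tot_sv["avg"] += 1
                tot_sv[pk] += 1
    ii = {k: v / npairs for k, v in tot_ii.items()}
    si = {k: v / npairs for k, v in tot_si.items()}
    sv = {k: v / npairs for k, v in tot_sv.items()}
    r = {k: (si[k] / sv[k] if sv[k] > 0 else None) for k in keys}
    return PairFrequencies(ii=ii, si=si, sv=sv, r=r)


def classify_sites(aln: Alignment, policy: str = "pairwise_ignore") -> SiteClassification:
    """Classify each column as conserved / variable, and variable columns
    further as parsimony-informative or singleton.

    ``policy="pairwise_ignore"`` (default) drops gap/ambiguity characters
    within each column and considers the column if >= 2 unambiguous
    residues remain; ``policy="complete"`` first restricts to columns with
    no missing character at all (MEGA's complete-deletion parity).

    A variable column is parsimony-informative if >= 2 distinct bases each
    occur in >= 2 sequences; it is a singleton if it shows exactly 2
    distinct bases and the rarer occurs once. Variable columns with > 2
    distinct bases and only one duplicated base fall in neither subclass.
    """
    if aln.n < 2:
        raise AlignmentError("classify_sites needs at least 2 sequences")
    if policy not in ("pairwise_ignore", "complete"):
        raise AlignmentError(f"unknown policy {policy!r}")
    conserved = variable = pinf = singleton = considered = 0
    for j in range(aln.length):
        col = aln.column(j)
        if policy == "complete" and any(c not in BASES for c in col):
            continue
        bases = [c for c in col if c in BASES]
        if len(bases) < 2:
            continue
        considered += 1
        counts = {b: bases.count(b) for b in set(bases)}
        if len(counts) == 1:
            conserved += 1
            continue
        variable += 1
        n_dup = sum(1 for c in counts.values() if c >= 2)
        if n_dup >= 2:
            pinf += 1
        elif len(counts) == 2 and min(counts.values()) == 1:
            singleton += 1
    return SiteClassification(
        conserved=conserved,
        variable=variable,
        parsimony_informative=pinf,
        singleton=singleton,
        considered=considered,
    )
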