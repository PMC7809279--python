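"""Aligned-FASTA input/output and alignment bookkeeping.

Every analysis in this package operates on an :class:`Alignment`: an ordered
set of equal-length, upper-cased nucleotide rows, each carrying a taxonomy
(genus + binomial species) parsed from its FASTA header. This module also
implements the two data preparations used throughout:

* **complete deletion** — removal of every column containing a gap,
  ``N`` or IUPAC ambiguity code, so that all downstream statistics see
  only fully resolved sites; and
* **supermatrix concatenation** — joining loci on a shared key (species
  or record id), padding loci absent for a key with gap runs.

Coordinates are 0-based half-open internally; reports print 1-based
inclusive positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: Unambiguous nucleotide states.
BASES = frozenset("ACGT")

#: Characters treated as "missing" by complete deletion: alignment gaps,
#: N, and every IUPAC ambiguity code.
MISSING = frozenset("N-RYSWKMBDHV?.")

#: Default header grammar: "<id> <Genus> <epithet> [trailing text]".
DEFAULT_HEADER_RE = re.compile(
    r"^(?P<id>\S+)[\s_]+(?P<genus>[A-Za-z][\w.\-]*)[\s_]+(?P<epithet>[\w.\-]+)"
)


class AlignmentError(ValueError):
    """Raised for malformed or degenerate alignment input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence with its taxonomic identity.

    ``species`` is the binomial ("Genus epithet") and always begins with
    ``genus``; ``residues`` is upper-case over {A,C,G,T,N,-, ambiguity}.
    """

    record_id: str
    genus: str
    species: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlignmentError(f"record {self.record_id!r} has empty residues")
        if not self.species.startswith(self.genus):
            raise AlignmentError(
                f"record {self.record_id!r}: species {self.species!r} does not "
                f"begin with genus {self.genus!r}"
            )


@dataclass(frozen=True)
class Alignment:
    """An ordered multiple sequence alignment for one locus."""

    locus_name: str
    records: tuple[SequenceRecord, ...]
    #: Per-locus column offsets recorded by :func:`concatenate`
    #: (locus name -> (start, end), 0-based half-open).
    locus_offsets: dict[str, tuple[int, int]] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError(f"alignment {self.locus_name!r} has no records")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            bad = next(
                r for r in self.records if len(r.residues) != len(self.records[0].residues)
            )
            raise AlignmentError(
                f"alignment {self.locus_name!r} is not aligned: record "
                f"{bad.record_id!r} has length {len(bad.residues)}, expected "
                f"{len(self.records[0].residues)}"
            )
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise AlignmentError(f"duplicate record id {dup!r} in {self.locus_name!r}")

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.records)

    def species_of(self) -> list[str]:
        return [r.species for r in self.records]

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)

    def columns(self) -> Iterable[str]:
        for j in range(self.length):
            yield self.column(j)


def parse_taxon_label(
    header: str, header_re: re.Pattern[str] | None = None
) -> tuple[str, str, str]:
    """Split a FASTA header into (record_id, genus, binomial species).

    The default grammar is ``"<id> <Genus> <epithet> [trailing text]"``,
    whitespace- or underscore-delimited; pass ``header_re`` with named
    groups ``id``, ``genus`` and ``epithet`` to override.
    """
    pat = header_re or DEFAULT_HEADER_RE
    m = pat.match(header.strip())
    if not m:
        raise AlignmentError(
            f"cannot parse taxonomy from header {header!r}: expected "
            "'<id> <Genus> <epithet> ...'"
        )
    genus = m.group("genus")
    return m.group("id"), genus, f"{genus} {m.group('epithet')}"


def read_alignment(
    path: str | Path,
    locus_name: str,
    header_re: re.Pattern[str] | None = None,
) -> Alignment:
    """Read an aligned FASTA file; residues are upper-cased and U mapped to T."""
    path = Path(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid, genus, species = parse_taxon_label(rec.description, header_re)
        residues = str(rec.seq).upper().replace("U", "T")
        records.append(SequenceRecord(rid, genus, species, residues))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment(locus_name, tuple(records))


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as FASTA with '<id> <species>' headers."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.record_id, description=r.species)
        for r in aln.records
    ]
    SeqIO.write(bio, str(path), "fasta")


def complete_deletion(aln: Alignment) -> tuple[Alignment, list[int]]:
    """Drop every column containing a gap, N or ambiguity code.

    Returns the filtered alignment and the retained-column index map
    (original 0-based column index of each surviving column, in order),
    for coordinate back-translation. Idempotent.
    """
    keep: list[int] = []
    for j in range(aln.length):
        if all(r.residues[j] in BASES for r in aln.records):
            keep.append(j)
    if not keep:
        raise AlignmentError(
            f"no complete columns in {aln.locus_name!r}: every column has a "
            "gap, N or ambiguity code"
        )
    records = tuple(
        replace(r, residues="".join(r.residues[j] for j in keep)) for r in aln.records
    )
    return Alignment(aln.locus_name, records), keep


def concatenate(
    alns: Sequence[Alignment],
    join_on: str = "species",
    on_duplicate: str = "error",
    locus_name: str | None = None,
) -> Alignment:
    """Supermatrix concatenation of loci on a shared key.

    ``join_on`` is ``"species"`` or ``"record_id"``. One output row per key
    present in at least one locus; a locus missing for a key contributes a
    gap run of that locus length. Per-locus column offsets are recorded in
    ``locus_offsets`` of the result, so slicing the combined row at the
    offset recovers the input row. ``on_duplicate="first"`` keeps the first
    record when a key repeats within one locus; the default errors.
    """
    if len(alns) < 2:
        raise AlignmentError("concatenate needs at least 2 alignments")
    if join_on not in ("species", "record_id"):
        raise AlignmentError(f"unknown join key {join_on!r}")

    per_locus: list[dict[str, SequenceRecord]] = []
    key_order: list[str] = []
    seen: set[str] = set()
    for aln in alns:
        table: dict[str, SequenceRecord] = {}
        for rec in aln.records:
            key = rec.species if join_on == "species" else rec.record_id
            if key in table:
                if on_duplicate == "first":
                    continue
                raise AlignmentError(
                    f"duplicate join key {key!r} in locus {aln.locus_name!r}"
                )
            table[key] = rec
            if key not in seen:
                seen.add(key)
                key_order.append(key)
        per_locus.append(table)

    offsets: dict[str, tuple[int, int]] = {}
    pos = 0
    for aln in alns:
        offsets[aln.locus_name] = (pos, pos + aln.length)
        pos += aln.length

    out: list[SequenceRecord] = []
    for key in key_order:
        parts: list[str] = []
        template: SequenceRecord | None = None
        for aln, table in zip(alns, per_locus):
            rec = table.get(key)
            if rec is None:
                parts.append("-" * aln.length)
            else:
                parts.append(rec.residues)
                template = template or rec
        assert template is not None
        rid = key if join_on == "species" else template.record_id
        out.append(
            SequenceRecord(rid, template.genus, template.species, "".join(parts))
        )
    name = locus_name or "+".join(a.locus_name for a in alns)
    return Alignment(name, tuple(out), locus_offsets=offsets)
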