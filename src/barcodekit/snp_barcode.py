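"""Species-specific barcode design from diagnostic SNP sites.

A *diagnostic site* for a target species is an alignment column at which
every target sequence carries one unambiguous base and that base occurs
in no other sequence of the dataset. Around each diagnostic site a
fragment window is cut, ungapped, and kept only if it passes the direct
specificity screen:

* the fragment occurs (as an exact ungapped substring, forward strand)
  in **every** target-species sequence, and
* in **no** non-target sequence of the dataset.

Accepted overlapping windows are merged, ranked by the number of
diagnostic sites they contain (ties: leftmost first), and the best few
are reported per species. Each barcode can be serialized to a compact
text payload (``BEKv1|species|locus|start-end|fragment``) and rendered
as a scannable QR image.

Specificity is evaluated against the supplied dataset only; whether a
fragment is unique beyond it (e.g. in a public database) is a separate
verification step outside this package, and reports say so.
"""

from __future__ import annotations

from dataclasses import dataclass

from .msa_io import BASES, Alignment, AlignmentError
from . import qr as _qr

PAYLOAD_TAG = "BEKv1"


@dataclass(frozen=True)
class DiagnosticSite:
    column: int  # 0-based alignment coordinate
    target_state: str
    background_states: frozenset[str]


@dataclass(frozen=True)
class DiagnosticBarcode:
    species: str
    locus: str
    start: int  # 0-based inclusive alignment column
    end: int  # 0-based inclusive alignment column
    fragment: str  # ungapped residues
    diagnostic_columns: tuple[DiagnosticSite, ...]

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        return self.end + 1


def diagnostic_sites(aln: Alignment, target: str) -> list[DiagnosticSite]:
    """All columns where the target species is fixed for a base absent
    from every non-target sequence.

    Columns with a gap or ambiguity code in any target sequence are
    ineligible.
    """
    targets = [r for r in aln.records if r.species == target]
    others = [r for r in aln.records if r.species != target]
    if not targets:
        raise AlignmentError(f"species {target!r} absent from alignment")
    if not others:
        raise AlignmentError("no non-target species in alignment")
    sites: list[DiagnosticSite] = []
    for j in range(aln.length):
        states = {r.residues[j] for r in targets}
        if len(states) != 1:
            continue
        state = next(iter(states))
        if state not in BASES:
            continue
        background = {r.residues[j] for r in others}
        if state in background:
            continue
        sites.append(DiagnosticSite(j, state, frozenset(background)))
    return sites


def _ungap(s: str) -> str:
    return s.replace("-", "")


def _window_fragment(
    targets: list[str], center: int, W: int, length: int
) -> tuple[int, int, str] | None:
    """Cut a W-column window centered on ``center`` (shifted at edges);
    return (start, end, fragment) if all target rows yield the same
    pure-ACGT ungapped fragment."""
    start = max(0, min(center - W // 2, length - W))
    end = min(length, start + W) - 1
    frags = {_ungap(t[start:end + 1]) for t in targets}
    if len(frags) != 1:
        return None
    frag = next(iter(frags))
    if not frag or any(c not in BASES for c in frag):
        return None
    return start, end, frag


def _is_specific(frag: str, targets: list[str], others: list[str]) -> bool:
    return all(frag in _ungap(t) for t in targets) and not any(
        frag in _ungap(o) for o in others
    )


def extract_barcodes(
    aln: Alignment,
    target: str,
    window: int = 40,
    max_per_species: int = 2,
) -> list[DiagnosticBarcode]:
    """Species-specific barcode fragments around diagnostic sites.

    An empty list is a valid "no specific barcode" outcome.
    """
    sites = diagnostic_sites(aln, target)
    if not sites:
        return []
    targets = [r.residues for r in aln.records if r.species == target]
    others = [r.residues for r in aln.records if r.species != target]

    accepted: list[tuple[int, int]] = []  # (start, end) alignment windows
    for site in sites:
        win = _window_fragment(targets, site.column, window, aln.length)
        if win is None:
            continue
        start, end, frag = win
        if _is_specific(frag, targets, others):
            accepted.append((start, end))
    if not accepted:
        return []

    # merge overlapping windows
    accepted.sort()
    merged: list[list[int]] = [list(accepted[0])]
    for start, end in accepted[1:]:
        if start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])

    barcodes: list[DiagnosticBarcode] = []
    for start, end in merged:
        frags = {_ungap(t[start:end + 1]) for t in targets}
        if len(frags) != 1:
            continue
        frag = next(iter(frags))
        if not _is_specific(frag, targets, others):
            continue
        inside = tuple(s for s in sites if start <= s.column <= end)
        if not inside:
            continue
        barcodes.append(
            DiagnosticBarcode(
                species=target,
                locus=aln.locus_name,
                start=start,
                end=end,
                fragment=frag,
                diagnostic_columns=inside,
            )
        )
    barcodes.sort(key=lambda b: (-len(b.diagnostic_columns), b.start))
    return barcodes[:max_per_species]


# ---------------------------------------------------------------------------
# QR payloads
# ---------------------------------------------------------------------------

def qr_payload(bc: DiagnosticBarcode) -> str:
    """Serialize a barcode as ``BEKv1|species|locus|start-end|fragment``
    with 1-based inclusive coordinates."""
    if any(c not in BASES for c in bc.fragment):
        raise ValueError("fragment contains non-ACGT characters")
    return (
        f"{PAYLOAD_TAG}|{bc.species}|{bc.locus}|"
        f"{bc.start_1based}-{bc.end_1based}|{bc.fragment}"
    )


def decode_payload(payload: str) -> DiagnosticBarcode:
    """Inverse of :func:`qr_payload` (diagnostic columns are not carried)."""
    parts = payload.split("|")
    if len(parts) != 5 or parts[0] != PAYLOAD_TAG:
        raise ValueError(f"not a {PAYLOAD_TAG} payload: {payload!r}")
    _, species, locus, span, fragment = parts
    start_s, end_s = span.split("-")
    return DiagnosticBarcode(
        species=species,
        locus=locus,
        start=int(start_s) - 1,
        end=int(end_s) - 1,
        fragment=fragment,
        diagnostic_columns=(),
    )


def render_qr(payload: str, path) -> None:
    """Render a payload as a QR PNG and self-check by decoding it back."""
    if not payload:
        raise ValueError("empty payload")
    matrix = _qr.encode_matrix(payload)
    if _qr.decode_matrix(matrix) != payload:
        raise RuntimeError("QR self-decode mismatch")  # pragma: no cover
    _qr.render_png(matrix, path)
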