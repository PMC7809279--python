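"""Synthetic alignments with known truth.

Two generators make every stage of the toolkit testable without
downloading sequence data:

``simulate_hierarchical``
    A two-level taxonomy (genera > species > individuals) evolved from a
    random root by Jukes-Cantor-style Poisson substitution, with expected
    divergence decreasing down the levels (d_genus > d_species > d_intra)
    so that intraspecific distances are much smaller than interspecific
    ones — the regime in which a barcoding gap exists. Optional *planted*
    species-diagnostic columns are overwritten last and re-verified, so
    the returned truth record is guaranteed to hold in the emitted
    alignment.

``simulate_coalescent``
    A constant-size Kingman coalescent with infinite-sites mutation,
    used to calibrate the neutrality statistics (E[S] = theta * a1,
    E[k] = theta, E[D] ~ 0).

Both are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa_io import Alignment, SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Synthetic genus/species name stems (orchid-flavoured, purely cosmetic).
_GENUS_STEMS = [
    "Dendrobium", "Liparis", "Spiranthes", "Cremastra", "Anathallis",
    "Neuwiedia", "Epiblema", "Cymbidium", "Phalaenopsis", "Bulbophyllum",
    "Oncidium", "Vanda", "Paphiopedilum", "Calanthe", "Habenaria",
]
_EPITHET_STEMS = [
    "scoriarum", "loeselii", "sinensis", "appendiculata", "obovata",
    "thelymitra", "cocflorum", "ensifolium", "amabilis", "odoratum",
    "gracile", "coerulea", "insigne", "discolor", "radiata", "fimbriata",
    "petiolata", "nervosa", "tortilis", "viridis",
]


@dataclass(frozen=True)
class HierarchicalParams:
    """Shape and divergence of the simulated taxonomy.

    Divergences are expected substitutions/site accumulated on the branch
    leading into each level; defaults give a clearly positive barcoding
    gap (intraspecific ~0.005 vs interspecific >= 0.08), the qualitative
    regime reported for chloroplast barcodes across a plant family.
    """

    n_genera: int = 5
    species_per_genus: int = 4
    seqs_per_species: int = 4
    L: int = 800
    d_genus: float = 0.10
    d_species: float = 0.08
    d_intra: float = 0.005
    planted_diagnostics: dict[str, list[int]] = field(default_factory=dict)
    seed: int = 0
    indel_rate: float = 0.0  # per-column probability of a masked character

    def __post_init__(self) -> None:
        if not (0 <= self.d_intra < self.d_species < self.d_genus < 0.7):
            raise ValueError("need 0 <= d_intra < d_species < d_genus < 0.7")
        if self.L < 1:
            raise ValueError("L must be >= 1")


@dataclass(frozen=True)
class SimTruth:
    """Generator-side record of what was simulated."""

    species_names: tuple[str, ...]
    genus_of: dict[str, str]
    planted: dict[str, dict[int, str]]  # species -> {column: target state}
    realized_divergence: dict[str, float]  # level -> mean realized p-distance


def _mutate(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor-style substitution: Poisson(d * L) events, each moving
    a uniform random column to a uniform different base."""
    out = seq.copy()
    n_events = rng.poisson(d * len(seq))
    for _ in range(n_events):
        j = int(rng.integers(len(seq)))
        current = out[j]
        choices = _BASES[_BASES != current]
        out[j] = choices[int(rng.integers(3))]
    return out


def _species_name(gi: int, si: int) -> tuple[str, str]:
    genus = _GENUS_STEMS[gi % len(_GENUS_STEMS)]
    if gi >= len(_GENUS_STEMS):
        genus = f"{genus}{gi // len(_GENUS_STEMS) + 1}"
    epithet = _EPITHET_STEMS[si % len(_EPITHET_STEMS)]
    if si >= len(_EPITHET_STEMS):
        epithet = f"{epithet}{si // len(_EPITHET_STEMS) + 1}"
    return genus, f"{genus} {epithet}"


def simulate_hierarchical(
    p: HierarchicalParams, locus_name: str = "sim", max_retries: int = 5
) -> tuple[Alignment, SimTruth]:
    """Simulate a genus/species/individual alignment with optional planted
    diagnostic columns.

    Raises if a planted diagnostic cannot be made exclusive (all four
    bases already present among non-target sequences at that column)
    after ``max_retries`` fresh draws.
    """
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([p.seed, attempt]))
        result = _simulate_once(p, rng, locus_name)
        if result is not None:
            return result
    raise RuntimeError(
        "could not plant all diagnostic columns: state collision persisted "
        f"after {max_retries} retries"
    )


def _simulate_once(
    p: HierarchicalParams, rng: np.random.Generator, locus_name: str
):
    root = _BASES[rng.integers(4, size=p.L)]
    rows: list[tuple[str, str, str, np.ndarray]] = []  # (id, genus, species, seq)
    species_names: list[str] = []
    genus_of: dict[str, str] = {}
    counter = 0
    for gi in range(p.n_genera):
        genus_anc = _mutate(root, p.d_genus, rng)
        for si in range(p.species_per_genus):
            genus, species = _species_name(gi, gi * p.species_per_genus + si)
            species_names.append(species)
            genus_of[species] = genus
            sp_anc = _mutate(genus_anc, p.d_species, rng)
            for _ in range(p.seqs_per_species):
                counter += 1
                seq = _mutate(sp_anc, p.d_intra, rng)
                rows.append((f"SYN{counter:04d}", genus, species, seq))

    # plant diagnostics last: target state fixed in the species, absent
    # from every other sequence at that column
    planted: dict[str, dict[int, str]] = {}
    for species, cols in p.planted_diagnostics.items():
        if species not in genus_of:
            raise ValueError(f"unknown species for planting: {species!r}")
        planted[species] = {}
        for col in cols:
            others = {
                row[3][col] for row in rows if row[2] != species
            }
            free = [b for b in _BASES if b not in others]
            if not free:
                return None  # collision: every base used by non-targets
            state = free[int(rng.integers(len(free)))]
            for row in rows:
                if row[2] == species:
                    row[3][col] = state
            planted[species][col] = state.decode()

    if p.indel_rate > 0:
        # mask random positions with '-' to exercise complete deletion;
        # planted columns stay untouched
        protected = {c for cols in planted.values() for c in cols}
        for row in rows:
            for j in range(p.L):
                if j not in protected and rng.random() < p.indel_rate:
                    row[3][j] = b"-"

    records = tuple(
        SequenceRecord(rid, genus, species, seq.tobytes().decode())
        for rid, genus, species, seq in rows
    )
    aln = Alignment(locus_name, records)

    # self-verification of the planted-diagnostic contract
    from .snp_barcode import diagnostic_sites

    for species, cols in planted.items():
        found = {s.column for s in diagnostic_sites(aln, species)}
        if not set(cols).issubset(found):
            return None

    realized = _realized_divergence(rows, genus_of)
    return aln, SimTruth(
        species_names=tuple(species_names),
        genus_of=genus_of,
        planted=planted,
        realized_divergence=realized,
    )


def _realized_divergence(rows, genus_of) -> dict[str, float]:
    intra, inter_sp, inter_gen = [], [], []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = rows[i], rows[j]
            pdist = float(np.mean(a[3] != b[3]))
            if a[2] == b[2]:
                intra.append(pdist)
            elif a[1] == b[1]:
                inter_sp.append(pdist)
            else:
                inter_gen.append(pdist)
    mean = lambda v: float(np.mean(v)) if v else float("nan")
    return {"intra": mean(intra), "species": mean(inter_sp), "genus": mean(inter_gen)}


# ---------------------------------------------------------------------------
# Constant-size coalescent with infinite-sites mutation
# ---------------------------------------------------------------------------

def simulate_coalescent(
    n: int, theta: float, L: int, seed: int, locus_name: str = "coalescent"
) -> Alignment:
    """Sample one alignment under the standard neutral coalescent.

    A Kingman genealogy for ``n`` lineages (exponential waiting times with
    rate C(k,2) while k lineages remain), mutations Poisson with rate
    theta/2 per unit branch length, each mutation on its own column of an
    otherwise monomorphic-'A' background of length ``L`` (infinite
    sites). Deterministic per seed.
    """
    if n < 2:
        raise ValueError("coalescent needs n >= 2")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    rng = np.random.default_rng(seed)

    # genealogy: each lineage carries the set of sampled leaves below it
    lineages: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    branches: list[tuple[frozenset[int], float]] = []  # (subtended leaves, length)
    elapsed = {ln: 0.0 for ln in lineages}
    while len(lineages) > 1:
        kk = len(lineages)
        t = rng.exponential(2.0 / (kk * (kk - 1)))
        for ln in lineages:
            elapsed[ln] += t
        i, j = sorted(rng.choice(kk, size=2, replace=False))
        a, b = lineages[int(j)], lineages[int(i)]
        lineages.pop(int(j)), lineages.pop(int(i))
        branches.append((a, elapsed.pop(a)))
        branches.append((b, elapsed.pop(b)))
        merged = a | b
        lineages.append(merged)
        elapsed[merged] = 0.0

    total_len = sum(b for _, b in branches)
    n_mut = rng.poisson(theta / 2.0 * total_len) if theta > 0 else 0
    if n_mut > L:
        raise ValueError(
            f"{n_mut} mutations exceed {L} available columns; increase L"
        )

    seqs = np.full((n, L), b"A", dtype="S1")
    if n_mut:
        cols = rng.choice(L, size=n_mut, replace=False)
        weights = np.array([b for _, b in branches]) / total_len
        which = rng.choice(len(branches), size=n_mut, p=weights)
        derived = np.frombuffer(b"CGT", dtype="S1")
        for col, bi in zip(cols, which):
            carriers = list(branches[bi][0])
            seqs[carriers, col] = derived[int(rng.integers(3))]

    records = tuple(
        SequenceRecord(f"C{i:04d}", "Simulatia", "Simulatia neutralis",
                       seqs[i].tobytes().decode())
        for i in range(n)
    )
    return Alignment(locus_name, records)
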