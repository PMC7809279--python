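"""End-to-end barcode evaluation for one or more loci.

``run_report`` executes the full workflow per locus (and per configured
locus combination): composition tables, diversity/neutrality statistics,
NJ tree with bootstrap supports and a genus-monophyly report, the
barcoding-gap report, Best-Close-Match scoring, and species-specific
barcodes with QR images. All outputs are plain text (TSV / JSON /
Newick / FASTA) plus PNG for the QR codes, and a manifest records every
setting actually used so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .msa_io import Alignment, read_alignment, concatenate, write_alignment
from .composition import base_frequencies, pair_frequencies, classify_sites
from .distances import distance_matrix
from .popgen import (
    diversity_stats, tajimas_d, fus_fs, mismatch_distribution,
    UndefinedStatistic,
)
from .phylo import bootstrap_supports, genus_monophyly, to_newick
from .barcode_eval import (
    partition_distances, barcoding_gap, bcm_threshold, best_close_match,
)
from .snp_barcode import extract_barcodes, qr_payload, render_qr


@dataclass
class RunConfig:
    """Every knob of the workflow, with the package defaults."""

    loci: dict[str, str]  # locus name -> aligned FASTA path
    combinations: list[list[str]] = field(default_factory=list)
    combine_join: str = "species"  # or "record_id"
    combine_on_duplicate: str = "error"  # or "first"
    out_dir: str = "bek_out"
    deletion: str = "complete"
    frame_offset: int = 0
    bootstrap_B: int = 1000
    seed: int = 0
    bcm_percentile: float = 0.95
    tie_tol: float = 1e-12
    barcode_window: int = 40
    max_barcodes_per_species: int = 2
    gap_bin_width: float = 0.005
    fs_reps: int = 1000
    render_qr_images: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _num(x):
    if x is None:
        return "NA"
    if isinstance(x, float) and not math.isfinite(x):
        return "inf" if x > 0 else "-inf"
    return x


def _locus_report(aln: Alignment, cfg: RunConfig, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    errors: dict[str, str] = {}
    skipped: dict[str, str] = {}

    # Composition (Tables 1-3 analogues)
    comp = base_frequencies(aln, cfg.frame_offset)
    comp.to_frame().to_csv(out / "base_composition.tsv", sep="\t", index=False)
    pf = pair_frequencies(aln, cfg.frame_offset)
    pf.to_frame().to_csv(out / "pair_frequencies.tsv", sep="\t")
    sites = classify_sites(aln)
    sites.to_frame().to_csv(out / "site_classification.tsv", sep="\t", index=False)

    # Diversity / neutrality (Table 4 analogue)
    stats = diversity_stats(aln)
    row = {
        "n": stats.n, "S": stats.S, "Eta": stats.Eta, "k": stats.k,
        "h": stats.h, "Hd": stats.Hd, "theta_per_site": stats.theta_w,
        "pi": stats.pi, "L_complete": stats.L_eff,
    }
    try:
        d = tajimas_d(stats)
        row["Tajima_D"], row["D_p_band"] = d.value, d.p_band
    except UndefinedStatistic as exc:
        row["Tajima_D"], row["D_p_band"] = "NA", "NA"
        errors["tajimas_d"] = str(exc)
    try:
        fs = fus_fs(aln, n_reps=cfg.fs_reps, seed=cfg.seed)
        row["Fu_Fs"], row["Fs_p_band"] = fs.value, fs.p_band
    except UndefinedStatistic as exc:
        row["Fu_Fs"], row["Fs_p_band"] = "NA", "NA"
        errors["fus_fs"] = str(exc)
    pd.DataFrame([{k: _num(v) for k, v in row.items()}]).to_csv(
        out / "diversity.tsv", sep="\t", index=False
    )

    mm = mismatch_distribution(aln)
    pd.DataFrame({"differences": np.arange(len(mm.x)), "frequency": mm.x}).to_csv(
        out / "mismatch_distribution.tsv", sep="\t", index=False
    )
    pd.DataFrame([{
        "raggedness_r": mm.r, "R2": _num(mm.R2), "tau": mm.tau, "CV": _num(mm.cv),
    }]).to_csv(out / "mismatch_stats.tsv", sep="\t", index=False)

    # Distances, tree, monophyly
    dm = distance_matrix(aln, deletion=cfg.deletion)
    dm.to_frame().to_csv(out / "k2p_distances.tsv", sep="\t")
    tree_info = {}
    if dm.n >= 3:
        tree, diag = bootstrap_supports(
            aln, B=cfg.bootstrap_B, seed=cfg.seed, deletion=cfg.deletion
        )
        (out / "nj_tree.nwk").write_text(to_newick(tree) + "\n")
        genus_of = {lab: gen for lab, gen in zip(dm.labels, dm.genera)}
        mono = genus_monophyly(tree, genus_of)
        pd.DataFrame(
            [{"genus": g, "monophyletic": v} for g, v in sorted(mono.items())]
        ).to_csv(out / "genus_monophyly.tsv", sep="\t", index=False)
        tree_info = {"bootstrap_skipped_fraction": diag["skipped_fraction"]}

    # Barcoding gap + BCM
    part = partition_distances(dm)
    gap_info = {}
    try:
        gap = barcoding_gap(part, bin_width=cfg.gap_bin_width)
        pd.DataFrame({
            "bin_start": gap.bin_edges[:-1],
            "bin_end": gap.bin_edges[1:],
            "intra": gap.intra_counts,
            "inter": gap.inter_counts,
        }).to_csv(out / "gap_histogram.tsv", sep="\t", index=False)
        gap_info = {
            "max_intra": gap.max_intra, "min_inter": gap.min_inter,
            "gap": gap.gap, "overlap": gap.overlap,
        }
        thr = bcm_threshold(part, cfg.bcm_percentile)
        bcm = best_close_match(dm, thr, cfg.tie_tol)
        bcm.to_frame().to_csv(out / "bcm_summary.tsv", sep="\t")
        pd.DataFrame({
            "record": dm.labels, "species": dm.species,
            "category": bcm.categories,
        }).to_csv(out / "bcm_per_query.tsv", sep="\t", index=False)
        gap_info["bcm_threshold"] = thr
    except Exception as exc:  # degenerate taxon structure: report, keep going
        errors["barcoding_gap_bcm"] = str(exc)

    # Species-specific barcodes
    barcode_rows = []
    fasta_lines = []
    all_species = sorted(set(r.species for r in aln.records))
    for sp in all_species if len(all_species) >= 2 else []:
        for i, bc in enumerate(
            extract_barcodes(aln, sp, cfg.barcode_window,
                             cfg.max_barcodes_per_species)
        ):
            payload = qr_payload(bc)
            barcode_rows.append({
                "species": sp, "locus": bc.locus,
                "start": bc.start_1based, "end": bc.end_1based,
                "n_diagnostic_sites": len(bc.diagnostic_columns),
                "fragment": bc.fragment, "payload": payload,
            })
            fasta_lines.append(
                f">{sp.replace(' ', '_')}|{bc.locus}|"
                f"{bc.start_1based}-{bc.end_1based}\n{bc.fragment}"
            )
            if cfg.render_qr_images:
                qr_dir = out / "qr"
                qr_dir.mkdir(exist_ok=True)
                fname = f"{sp.replace(' ', '_')}_{i + 1}.png"
                try:
                    render_qr(payload, qr_dir / fname)
                except ValueError as exc:
                    # fragment beyond QR capacity: the barcode itself is
                    # still valid and reported; only the image is skipped
                    skipped[f"qr:{sp}"] = str(exc)
    pd.DataFrame(
        barcode_rows or [],
        columns=["species", "locus", "start", "end",
                 "n_diagnostic_sites", "fragment", "payload"],
    ).to_csv(out / "specific_barcodes.tsv", sep="\t", index=False)
    if fasta_lines:
        (out / "specific_barcodes.fasta").write_text("\n".join(fasta_lines) + "\n")

    return {
        "locus": aln.locus_name, "n": aln.n, "length": aln.length,
        **tree_info, **gap_info, "n_specific_barcodes": len(barcode_rows),
        "errors": errors, "skipped": skipped,
    }


def run_report(cfg: RunConfig) -> dict:
    """Run the full workflow; returns (and writes) the manifest."""
    out_root = Path(cfg.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    loci: dict[str, Alignment] = {
        name: read_alignment(path, name) for name, path in cfg.loci.items()
    }
    manifest: dict = {
        "barcodekit_version": __version__,
        "config": {k: v for k, v in asdict(cfg).items()},
        "loci": {},
    }
    targets: dict[str, Alignment] = dict(loci)
    for combo in cfg.combinations:
        name = "+".join(combo)
        combined = concatenate(
            [loci[c] for c in combo],
            join_on=cfg.combine_join,
            on_duplicate=cfg.combine_on_duplicate,
        )
        write_alignment(combined, out_root / f"{name.replace('+', '_')}.fasta")
        targets[name] = combined

    failures = 0
    for name, aln in targets.items():
        sub = out_root / name.replace("+", "_")
        try:
            manifest["loci"][name] = _locus_report(aln, cfg, sub)
            if manifest["loci"][name]["errors"]:
                failures += 1
        except Exception as exc:
            manifest["loci"][name] = {"fatal_error": str(exc)}
            failures += 1
    manifest["n_failed_loci"] = failures
    with open(out_root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
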