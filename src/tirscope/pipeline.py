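"""End-to-end orchestration: run all analysis stages and emit report tables.

`run_pipeline` executes the stages in dependency order (io -> expression ->
composition / structure / promoters / trinucleotides), writes each stage's
TSVs into the output directory, and records a run manifest (resolved
configuration, seeds, and per-stage gene-exclusion counts) so every number
in every report is reproducible from the manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import expression as xp
from . import promoters as pm
from . import rna_structure as rs
from . import tir_composition as tc
from . import trinucleotide as tn
from .sequence_io import (
    extract_tir_window,
    extract_upstream_of_tss,
    read_annotations,
    read_genome,
    read_tss_table,
)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    genome_fasta: str
    annotations_gff: str
    rna_counts: list[str]
    ribo_counts: list[str]
    out_dir: str
    tss_table: str | None = None
    feature_type: str = "CDS"
    id_attribute: str = "locus_tag"
    representative_fraction: float = 1.0 / 3.0
    n_octiles: int = 8
    alpha: float = 0.05
    window_upstream: int = 30
    window_downstream: int = 30
    fold_window: int = 100
    fold_octiles: tuple[int, int] = (1, 8)
    max_fold_genes_per_octile: int = 50
    upstream_tss_nt: int = 50
    consensus_scan_pattern: str = pm.SEED_PATTERN
    run_structure: bool = True
    seed: int = 0

    def resolved(self) -> dict:
        d = asdict(self)
        d["fold_octiles"] = list(self.fold_octiles)
        return d


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig(**data)


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(
            ([df.index.name or "index"] if index else []) + list(map(str, df.columns))
        ) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=index)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to the out dir)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.resolved(), "stages": {}}

    for path in [config.genome_fasta, config.annotations_gff, *config.rna_counts,
                 *config.ribo_counts]:
        if not Path(path).exists():
            raise FileNotFoundError(f"required input missing: {path}")

    genomes = read_genome(config.genome_fasta)
    annotations = read_annotations(
        config.annotations_gff, config.feature_type, config.id_attribute
    )
    rna_tables = [xp.read_counts_table(p, "rna") for p in config.rna_counts]
    ribo_tables = [xp.read_counts_table(p, "ribo") for p in config.ribo_counts]

    # --- expression ---
    table = xp.build_expression_table(
        rna_tables, ribo_tables, annotations,
        fraction=config.representative_fraction, n_octiles=config.n_octiles,
    )
    table.index.name = "gene_id"
    _write(table, out / "expression.tsv")
    n_rep = int(table["representative"].sum())
    manifest["stages"]["expression"] = {
        "n_genes": len(table),
        "n_representative": n_rep,
        "n_zero_rna": int((table["rna_count"] == 0).sum()),
        "n_octile_assigned": int(table["octile"].notna().sum()),
        "n_octile_unassigned_remainder": n_rep - int(table["octile"].notna().sum()),
    }
    if len(rna_tables) > 1 or rna_tables[0].counts.shape[1] > 1:
        rep_corr = xp.replicate_spearman(rna_tables)
        _write(rep_corr, out / "replicate_spearman_rna.tsv")
    if len(ribo_tables) > 1 or ribo_tables[0].counts.shape[1] > 1:
        rep_corr = xp.replicate_spearman(ribo_tables)
        _write(rep_corr, out / "replicate_spearman_ribo.tsv")

    by_id = {a.gene_id: a for a in annotations}
    octile_windows: dict[int, list] = {}
    n_windows_with_n = 0
    for gene_id, octile in table["octile"].dropna().items():
        w = extract_tir_window(
            genomes, by_id[gene_id], config.window_upstream, config.window_downstream
        )
        if w.has_n:
            n_windows_with_n += 1
        octile_windows.setdefault(int(octile), []).append(w)
    manifest["stages"]["windows"] = {
        "n_windows": sum(len(v) for v in octile_windows.values()),
        "n_with_ambiguous_bases": n_windows_with_n,
    }

    # --- TIR composition ---
    positions = range(-config.window_upstream, config.window_downstream + 1)
    all_windows = [w for ws in octile_windows.values() for w in ws]
    profile = tc.positional_frequencies(all_windows, positions)
    _write(profile, out / "tir_frequencies_all.tsv")
    for nt in ("A", "C", "G", "U"):
        contrast = tc.octile_contrast(
            octile_windows, positions, nt,
            octiles=(1, config.n_octiles), alpha=config.alpha,
        )
        _write(contrast, out / f"tir_contrast_{nt}.tsv", index=False)
    trend = pd.DataFrame(
        {
            f"A@{p}": tc.frequency_by_octile(octile_windows, p, "A")
            for p in (-3, -6, -12, -13)
        }
    )
    trend.index.name = "octile"
    _write(trend, out / "tir_A_frequency_by_octile.tsv")
    manifest["stages"]["composition"] = {"positions": [positions[0], positions[-1]]}

    # --- RNA structure ---
    if config.run_structure:
        lo, hi = config.fold_octiles
        model = rs.FoldingModel()
        profiles = {}
        for octile in (lo, hi):
            chosen = octile_windows.get(octile, [])[: config.max_fold_genes_per_octile]
            profiles[octile] = [
                rs.fold_tir(
                    genomes, by_id[w.gene_id], model,
                    config.fold_window, config.fold_window,
                )
                for w in chosen
            ]
        means, comparison = rs.average_pairing_by_set(
            profiles, contrast=(lo, hi), alpha=config.alpha
        )
        _write(means, out / "pairing_means.tsv", index=False)
        _write(comparison, out / "pairing_contrast.tsv", index=False)
        manifest["stages"]["structure"] = {
            "octiles": [lo, hi],
            "n_folded": {str(k): len(v) for k, v in profiles.items()},
        }

    # --- promoters ---
    if config.tss_table is not None:
        tss_records = read_tss_table(config.tss_table)
        upstream = {
            t.gene_id: extract_upstream_of_tss(genomes, t, config.upstream_tss_nt)
            for t in tss_records
            if t.gene_id in by_id
        }
        hits = pm.find_candidate_elements(
            upstream, "consensus_scan", config.consensus_scan_pattern
        )
        hist = pm.spacing_histogram(hits)
        probable = pm.filter_probable_promoters(hits)
        model_p = pm.build_promoter_model(probable, upstream, flank=0)
        consensus = pm.derive_consensus(model_p)
        leaders, leader_summary = pm.leader_lengths(tss_records, annotations)
        hits_df = pd.DataFrame(
            [
                {
                    "gene_id": h.gene_id,
                    "element": h.element_seq,
                    "spacing": h.spacing,
                    "score": h.score,
                }
                for h in hits
            ]
        )
        _write(hits_df, out / "promoter_hits.tsv", index=False)
        hist_df = pd.DataFrame(
            {"spacing": list(hist), "proportion": list(hist.values())}
        )
        _write(hist_df, out / "promoter_spacing_histogram.tsv", index=False)
        _write(model_p.frequencies, out / "promoter_frequencies.tsv")
        leaders_df = pd.DataFrame(
            {"gene_id": list(leaders), "leader": list(leaders.values())}
        )
        _write(leaders_df, out / "leader_lengths.tsv", index=False)
        manifest["stages"]["promoters"] = {
            "n_tss": len(tss_records),
            "n_candidates": len(hits),
            "n_probable": len(probable),
            "consensus": consensus,
            "leader_summary": leader_summary,
        }

    # --- trinucleotide bias ---
    ratios = tn.genome_ratios(genomes, annotations, genome_id="run")
    _write(tn.ratios_table([ratios]), out / "trinucleotide_ratios.tsv", index=False)
    manifest["stages"]["trinucleotide"] = {
        "n_genes": ratios.n_genes,
        "n_genes_midgene": ratios.n_genes_midgene,
        "n_too_short_for_midgene": ratios.n_genes - ratios.n_genes_midgene,
        "ratios": {
            w: {f"AUG/{nrm}": ratios.ratio(w, nrm) for nrm in tn.NORMALIZERS}
            for w in tn.WINDOW_NAMES
        },
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
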