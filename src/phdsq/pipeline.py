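"""End-to-end screen orchestration: design -> simulate -> count -> QC -> score.

``run_screen`` drives a fully simulated screen from one seeded config and
writes every intermediate as plain text (TSV/FASTA/FASTQ/YAML), so each
stage remains independently inspectable and the whole run is reproducible
byte-for-byte from the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets, qc, score
from .barcodes import BarcodeMap, make_barcode_map
from .demux import CountMatrix, aggregate_to_genes, count_reads
from .layout import LibraryLayout, default_layout, to_yaml
from .panel import ProbePanel, write_panel_fasta, write_panel_tsv
from .simulate import (GroundTruth, SimConfig, make_control_profiles,
                       make_screen_profiles, sample_sheet, simulate_fastq)


@dataclass
class RunConfig:
    """One simulated screen, fully determined by its seed."""

    seed: int
    out_dir: str
    n_kf: int = 6
    n_ad: int = 6
    n_compounds: int = 84
    effect_sizes: dict[str, float] | None = None  # None -> uniform [0,1]
    reads_per_well: int = 10_000
    noise_cv: float = 0.1
    substitution_error_rate: float = 0.001
    pcr_duplication: float = 3.0
    dynamic_range: float = 10.0
    umi_collapse: str = "exact"
    gzip_fastq: bool = False


@dataclass
class ScreenBundle:
    """Everything a finished run produced, in memory."""

    panel: ProbePanel
    layout: LibraryLayout
    barcodes: BarcodeMap
    ground_truth: GroundTruth
    probe_counts: CountMatrix
    gene_counts: CountMatrix
    gene_cpm: pd.DataFrame
    probe_cpm: pd.DataFrame
    pearson: pd.DataFrame
    si: score.SIResult
    effect_sizes: pd.Series
    roles: pd.Series
    output_files: dict[str, Path] = field(default_factory=dict)


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def run_screen(cfg: RunConfig) -> ScreenBundle:
    """Execute every stage in order; any stage failure raises with its label."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    files: dict[str, Path] = {}

    # ---- stage: design ----------------------------------------------------
    try:
        design = datasets.default_panel()
        if design.failures:
            raise RuntimeError(f"panel design failed for {[f.gene_id for f in design.failures]}")
        panel = design.panel
        layout = default_layout()
        write_panel_tsv(panel, out / "panel.tsv")
        write_panel_fasta(panel, out / "panel_reference.fasta")
        to_yaml(layout, out / "layout.yaml")
        files |= {"panel": out / "panel.tsv", "panel_fasta": out / "panel_reference.fasta",
                  "layout": out / "layout.yaml"}
    except Exception as e:
        raise RuntimeError(f"[stage design] {e}") from e

    # ---- stage: simulate --------------------------------------------------
    try:
        kf, ad = make_control_profiles(
            panel, datasets.FIBROSIS_GENES, datasets.ADIPOCYTE_GENES,
            datasets.HOUSEKEEPING_GENES, dynamic_range=cfg.dynamic_range, rng=rng)
        if cfg.effect_sizes is None:
            effects = {f"CPD_{i + 1:03d}": float(e)
                       for i, e in enumerate(rng.uniform(0, 1, size=cfg.n_compounds))}
        else:
            effects = dict(cfg.effect_sizes)
        profiles = make_screen_profiles(panel, make_barcode_map(1), kf, ad,
                                        cfg.n_kf, cfg.n_ad, effects,
                                        noise_cv=cfg.noise_cv, rng=rng)
        sheet = sample_sheet(profiles)
        barcodes = make_barcode_map(1, samples=sheet)
        suffix = ".fastq.gz" if cfg.gzip_fastq else ".fastq"
        r1, r2 = out / f"reads_R1{suffix}", out / f"reads_R2{suffix}"
        sim_cfg = SimConfig(rng_seed=int(rng.integers(0, 2**31 - 1)),
                            reads_per_well=cfg.reads_per_well,
                            substitution_error_rate=cfg.substitution_error_rate,
                            pcr_duplication=cfg.pcr_duplication)
        truth = simulate_fastq(profiles, panel, layout, barcodes, sim_cfg, r1, r2)
        truth.to_tsv(out / "ground_truth.tsv")
        barcodes.to_tsv(out / "barcodes.tsv", out / "samples.tsv")
        files |= {"r1": r1, "r2": r2, "ground_truth": out / "ground_truth.tsv",
                  "barcodes": out / "barcodes.tsv", "samples": out / "samples.tsv"}
    except Exception as e:
        raise RuntimeError(f"[stage simulate] {e}") from e

    # ---- stage: count ------------------------------------------------------
    try:
        probe_counts = count_reads(r1, r2, panel, barcodes, layout,
                                   umi_collapse=cfg.umi_collapse)
        gene_counts = aggregate_to_genes(probe_counts, panel)
        probe_counts.to_tsv(out / "counts_probe.tsv")
        gene_counts.to_tsv(out / "counts_gene.tsv")
        _write_tsv(probe_counts.stats.reset_index(), out / "demux_stats.tsv")
        _write_tsv(probe_counts.fail_counts.reset_index(names="plate"),
                   out / "demux_failures.tsv")
        files |= {"counts_probe": out / "counts_probe.tsv",
                  "counts_gene": out / "counts_gene.tsv",
                  "demux_stats": out / "demux_stats.tsv"}
    except Exception as e:
        raise RuntimeError(f"[stage count] {e}") from e

    # ---- stage: qc ---------------------------------------------------------
    try:
        probe_cpm = qc.cpm(probe_counts)
        gene_cpm = qc.cpm(gene_counts)
        pearson = qc.pearson_matrix(gene_cpm)
        _write_tsv(gene_cpm, out / "cpm_gene.tsv", index_label="gene")
        _write_tsv(probe_cpm, out / "cpm_probe.tsv", index_label="probe")
        _write_tsv(pearson, out / "qc_pearson.tsv", index_label="sample")
        files |= {"cpm_gene": out / "cpm_gene.tsv", "pearson": out / "qc_pearson.tsv"}
    except Exception as e:
        raise RuntimeError(f"[stage qc] {e}") from e

    # ---- stage: score ------------------------------------------------------
    try:
        roles = sheet.set_index("sample_id")["role"]
        si = score.score_screen(gene_cpm, roles)
        si_table = pd.DataFrame({
            "sample_id": si.raw_si.index,
            "role": [roles[s] for s in si.raw_si.index],
            "raw_si": si.raw_si.to_numpy(),
            "normalized_si": si.normalized_si.to_numpy(),
        })
        _write_tsv(si_table, out / "si_table.tsv")
        _write_tsv(si.hits, out / "hits.tsv")
        zp = si.z_prime_report
        _write_tsv(pd.DataFrame([asdict(zp)]), out / "z_prime.tsv")
        files |= {"si_table": out / "si_table.tsv", "hits": out / "hits.tsv",
                  "z_prime": out / "z_prime.tsv"}
    except Exception as e:
        raise RuntimeError(f"[stage score] {e}") from e

    # conservation checks between stages
    assert probe_counts.total_reads == int(
        probe_counts.stats["assigned_reads"].sum() + probe_counts.fail_counts.to_numpy().sum())
    nonzero = gene_cpm.sum(axis=0) > 0
    assert np.allclose(gene_cpm.loc[:, nonzero].sum(axis=0), 1e6)

    cfg_doc = asdict(cfg)
    cfg_doc["effect_sizes"] = effects
    (out / "run_config.yaml").write_text(yaml.safe_dump(cfg_doc, sort_keys=False))

    effect_series = pd.Series({**{p.sample_id: p.effect_size for p in profiles}},
                              name="effect_size")
    return ScreenBundle(panel, layout, barcodes, truth, probe_counts, gene_counts,
                        gene_cpm, probe_cpm, pearson, si, effect_series, roles, files)


def output_hashes(bundle: ScreenBundle) -> dict[str, str]:
    """SHA-256 of every written output, for byte-level reproducibility checks."""
    out = {}
    for name, path in sorted(bundle.output_files.items()):
        out[name] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return out


def run_from_yaml(path: str | Path) -> ScreenBundle:
    doc = yaml.safe_load(Path(path).read_text())
    return run_screen(RunConfig(**doc))
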