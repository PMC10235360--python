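"""Synthetic study materials: the marker-gene panel and a toy transcriptome.

The default panel follows the fibroblast-to-adipocyte reprogramming screen
this toolkit was built around: fibroblast/fibrosis markers (high in keloid
fibroblasts, the negative control), adipocyte markers (high in the
adipocyte-differentiation positive control), and housekeeping genes spanning
a wide expression range.  Eight genes carry a redundant second probe pair so
probe-level concordance can be checked.

Transcript sequences here are synthetic stand-ins generated from a seeded
RNG: real transcript sequence is irrelevant to every algorithm in the
toolkit (only lengths, exon boundaries, SNPs and base composition matter),
and synthetic transcripts keep the whole pipeline testable offline.
"""

from __future__ import annotations

import numpy as np

from .panel import DesignResult, TranscriptRecord, design_panel

FIBROSIS_GENES = ["PRRX1", "THY1", "ACTA2", "FBN1", "COL1A1", "COL3A1", "MMP1", "TIMP1"]
ADIPOCYTE_GENES = ["FABP4", "ADIPOQ", "EBF2", "CEBPA", "ATF2", "ZNF423", "LEP",
                   "ZNF516", "PRDM16", "PPARG", "PPARGC1A", "FNDC5", "UCP1",
                   "INSR", "SLC2A4"]
HOUSEKEEPING_GENES = ["ACTB", "CYC", "GAPDH", "HMBS", "PPIA", "SDHA", "TBP", "YWHAZ"]
PANEL_GENES = FIBROSIS_GENES + ADIPOCYTE_GENES + HOUSEKEEPING_GENES

# genes probed with two independent pairs for concordance QC
REDUNDANT_GENES = ["PRDM16", "UCP1", "EBF2", "ADIPOQ", "COL1A1", "ACTB", "GAPDH", "THY1"]

_BASES = np.array(list("ACGT"))


def synthetic_transcriptome(genes: list[str] | None = None,
                            transcript_length: int = 400,
                            n_snps: int = 3,
                            seed: int = 20230401) -> list[TranscriptRecord]:
    """One seeded random transcript per gene, with an internal exon boundary
    and a few SNP positions.

    Base composition is drawn near 50% GC so that probe arms satisfying the
    40-60% GC rule exist at many junctions.
    """
    if genes is None:
        genes = PANEL_GENES
    rng = np.random.default_rng(seed)
    out = []
    for gene in genes:
        gc = rng.uniform(0.45, 0.55)
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seq = "".join(_BASES[rng.choice(4, size=transcript_length, p=p)])
        boundary = int(rng.integers(transcript_length // 3, 2 * transcript_length // 3))
        snps = frozenset(int(x) for x in rng.choice(transcript_length, size=n_snps,
                                                    replace=False))
        out.append(TranscriptRecord(gene, f"{gene}_T1", seq, (boundary,), snps))
    return out


from functools import lru_cache


@lru_cache(maxsize=4)
def _design_default(seed: int, transcript_length: int) -> tuple:
    transcripts = synthetic_transcriptome(seed=seed, transcript_length=transcript_length)
    singles = [g for g in PANEL_GENES if g not in REDUNDANT_GENES]
    res1 = design_panel(transcripts, singles, pairs_per_gene=1)
    res2 = design_panel(transcripts, REDUNDANT_GENES, pairs_per_gene=2)
    pairs = res1.panel.pairs + res2.panel.pairs
    order = {g: i for i, g in enumerate(PANEL_GENES)}
    pairs.sort(key=lambda p: (order[p.gene_id], p.probe_id))
    return tuple(pairs), tuple(res1.failures + res2.failures)


def default_panel(seed: int = 20230401, transcript_length: int = 400) -> DesignResult:
    """Design the default screen panel on the synthetic transcriptome.

    Redundant-QC genes get two probe pairs; all other genes get one.  The
    design is deterministic in (seed, transcript_length) and cached.
    """
    from .panel import ProbePanel  # local import avoids a cycle at module load
    pairs, failures = _design_default(seed, transcript_length)
    return DesignResult(panel=ProbePanel(list(pairs)), failures=list(failures))
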