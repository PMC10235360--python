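"""Demultiplexing and UMI-deduplicated counting.

Reads are mapped by exact/near-exact matching against the panel's 54-nt
references (the "left probe plus right probe" mapping step of this assay
family) after the plate and well barcodes and the two 4-nt UMIs have been
extracted according to the library layout.  Counting is probe-level first —
gene aggregation is a separate step — so redundant-probe QC stays possible.

The counter is a streaming single pass over the read pairs: memory scales
with panel x samples x distinct UMIs, never with read count.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .barcodes import BarcodeMap, hamming
from .layout import LayoutError, LibraryLayout
from .panel import ProbePanel
from .simulate import revcomp

FAIL_REASONS = ("none", "barcode", "probe", "layout")


@dataclass(frozen=True)
class ReadAssignment:
    """Outcome of demultiplexing one read pair."""

    plate_id: str | None
    well_id: str | None
    probe_id: str | None
    umi8: str | None
    fail_reason: str = "none"

    def __post_init__(self) -> None:
        assigned = all(x is not None for x in (self.plate_id, self.well_id, self.probe_id))
        if (self.fail_reason == "none") != assigned:
            raise ValueError("fail_reason must be 'none' iff all assignments were made")


@dataclass
class CountMatrix:
    """UMI-deduplicated molecule counts, probes (or genes) x samples.

    ``stats`` carries per-sample assigned-read counts; ``fail_counts`` the
    reads lost at each stage, per plate (index ``unassigned`` for reads whose
    plate barcode itself failed).
    """

    counts: pd.DataFrame
    stats: pd.DataFrame
    fail_counts: pd.DataFrame
    axis: str = "probe"

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total_reads(self) -> int:
        return int(self.stats["assigned_reads"].sum() + self.fail_counts.to_numpy().sum())

    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label=self.axis)

    @staticmethod
    def read_tsv(path: str | Path, axis: str = "probe") -> "CountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        empty_stats = pd.DataFrame({"sample_id": counts.columns,
                                    "assigned_reads": 0}).set_index("sample_id")
        fails = pd.DataFrame(0, index=["unassigned"], columns=list(FAIL_REASONS[1:]))
        return CountMatrix(counts=counts, stats=empty_stats, fail_counts=fails, axis=axis)


# ---------------------------------------------------------------------------
# matching primitives


def match_barcode(observed: str, barcode_map: dict[str, str],
                  max_mismatch: int = 1) -> str | None:
    """Unique barcode id within ``max_mismatch`` substitutions, else None.

    Ties (two barcodes at the same minimal distance) are unassigned: with
    distance >= 3 barcode sets this can only happen for reads with two or
    more errors, which carry no safe identity.
    """
    lengths = {len(b) for b in barcode_map}
    if lengths and len(observed) not in lengths:
        raise LayoutError(f"observed barcode length {len(observed)} does not match map")
    if observed in barcode_map:
        return barcode_map[observed]
    if max_mismatch == 0:
        return None
    best_id, best_d, tied = None, max_mismatch + 1, False
    for seq, bid in barcode_map.items():
        d = hamming(observed, seq)
        if d < best_d:
            best_id, best_d, tied = bid, d, False
        elif d == best_d:
            tied = True
    if best_d <= max_mismatch and not tied:
        return best_id
    return None


def match_probe(left_obs: str, right_obs: str, panel: ProbePanel,
                max_mismatch_per_arm: int = 2) -> str | None:
    """Unique best probe pair with per-arm Hamming distance within tolerance.

    The best hit is the pair minimizing total (left+right) distance among
    those satisfying the per-arm cap; ties are unassigned.
    """
    best_id, best_d, tied = None, None, False
    for p in panel:
        dl = hamming(left_obs, p.left.arm_seq)
        if dl > max_mismatch_per_arm:
            continue
        dr = hamming(right_obs, p.right.arm_seq)
        if dr > max_mismatch_per_arm:
            continue
        d = dl + dr
        if best_d is None or d < best_d:
            best_id, best_d, tied = p.probe_id, d, False
        elif d == best_d:
            tied = True
    return None if tied else best_id


def _extract(read: str, layout: LibraryLayout, which: str) -> dict[str, str]:
    """Pull the variable elements off one mate; raises LayoutError if short."""
    elements = layout.read1 if which == "read1" else layout.read2
    need = layout.read_length(elements)
    if len(read) < need:
        raise LayoutError(f"{which} shorter ({len(read)}) than layout requires ({need})")
    out = {}
    for element, sl, rc in layout.read_slices(elements):
        seq = read[sl]
        out[element.name] = revcomp(seq) if rc else seq
    return out


def assign_read(r1: str, r2: str, layout: LibraryLayout, barcodes: BarcodeMap,
                panel: ProbePanel, max_mismatch_barcode: int = 1,
                max_mismatch_per_arm: int = 2) -> ReadAssignment:
    """Demultiplex one read pair into (plate, well, probe, UMI)."""
    try:
        fields = _extract(r1, layout, "read1") | _extract(r2, layout, "read2")
    except LayoutError:
        return ReadAssignment(None, None, None, None, "layout")
    wb_name = layout.element_by_kind("well_barcode").name
    pb_name = layout.element_by_kind("plate_barcode").name
    well = match_barcode(fields[wb_name], barcodes.well, max_mismatch_barcode)
    plate = match_barcode(fields[pb_name], barcodes.plate, max_mismatch_barcode)
    if well is None or plate is None:
        return ReadAssignment(plate, None, None, None, "barcode") if plate else \
            ReadAssignment(None, None, None, None, "barcode")
    la_name = layout.element_by_kind("left_arm").name
    ra_name = layout.element_by_kind("right_arm").name
    probe = match_probe(fields[la_name], fields[ra_name], panel, max_mismatch_per_arm)
    umi8 = "".join(fields[n] for n in layout.umi_names_in_order())
    if probe is None:
        return ReadAssignment(plate, well, None, None, "probe")
    return ReadAssignment(plate, well, probe, umi8, "none")


# ---------------------------------------------------------------------------
# UMI collapse


def _directional_cluster_count(counter: dict[str, int]) -> int:
    """Directional adjacency collapse (UMI-tools style) on one UMI family.

    An edge runs from UMI a to b when hamming(a, b) == 1 and
    count(a) >= 2*count(b) - 1; connected reachable sets from the
    highest-count roots merge into one molecule each.
    """
    umis = sorted(counter, key=lambda u: (-counter[u], u))
    parent = {u: u for u in umis}

    def find(u: str) -> str:
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for i, a in enumerate(umis):
        for b in umis[i + 1:]:
            if counter[a] >= 2 * counter[b] - 1 and hamming(a, b) == 1:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    return len({find(u) for u in umis})


def collapse_umis(assignments: Iterable[ReadAssignment],
                  sample_sheet: pd.DataFrame,
                  panel: ProbePanel,
                  method: str = "exact") -> CountMatrix:
    """Fold a stream of read assignments into a deduplicated count matrix.

    ``method``: "exact" counts distinct 8-nt UMI pairs; "directional"
    additionally merges Hamming-1 neighbours under the directional rule;
    "none" counts raw reads without deduplication.
    """
    if method not in ("exact", "directional", "none"):
        raise ValueError(f"unknown UMI collapse method {method!r}")
    lookup = {(r.plate_id, r.well_id): (r.sample_id, r.role)
              for r in sample_sheet.itertuples(index=False)}
    sample_ids = list(sample_sheet["sample_id"])
    probe_ids = panel.probe_ids
    umi_store: dict[tuple[str, str], dict[str, int]] = {}
    raw: dict[tuple[str, str], int] = {}
    assigned = {s: 0 for s in sample_ids}
    plates = sorted({r.plate_id for r in sample_sheet.itertuples(index=False)})
    fails = pd.DataFrame(0, index=plates + ["unassigned"],
                         columns=["barcode", "probe", "layout"])
    for a in assignments:
        if a.fail_reason != "none":
            plate = a.plate_id if a.plate_id in fails.index else "unassigned"
            fails.loc[plate, a.fail_reason] += 1
            continue
        entry = lookup.get((a.plate_id, a.well_id))
        if entry is None:
            fails.loc[a.plate_id if a.plate_id in fails.index else "unassigned",
                      "barcode"] += 1
            continue
        sample_id, _ = entry
        assigned[sample_id] += 1
        key = (sample_id, a.probe_id)
        if method == "none":
            raw[key] = raw.get(key, 0) + 1
        else:
            umi_store.setdefault(key, {})
            umi_store[key][a.umi8] = umi_store[key].get(a.umi8, 0) + 1

    counts = pd.DataFrame(0, index=probe_ids, columns=sample_ids, dtype=int)
    if method == "none":
        for (s, p), n in raw.items():
            counts.loc[p, s] = n
    else:
        for (s, p), counter in umi_store.items():
            if method == "exact":
                counts.loc[p, s] = len(counter)
            else:
                counts.loc[p, s] = _directional_cluster_count(counter)
    stats = pd.DataFrame({"sample_id": sample_ids,
                          "assigned_reads": [assigned[s] for s in sample_ids]}
                         ).set_index("sample_id")
    return CountMatrix(counts=counts, stats=stats, fail_counts=fails, axis="probe")


# ---------------------------------------------------------------------------
# streaming FASTQ counting


def read_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (seq1, seq2) from paired FASTQ files (.gz transparent)."""

    def _open(p):
        p = str(p)
        return gzip.open(p, "rt") if p.endswith(".gz") else open(p)

    with _open(r1_path) as f1, _open(r2_path) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        for (t1, s1, _), (t2, s2, _) in zip(it1, it2, strict=True):
            yield s1, s2


def assignments_from_fastq(r1_path: str | Path, r2_path: str | Path,
                           layout: LibraryLayout, barcodes: BarcodeMap,
                           panel: ProbePanel, max_mismatch_barcode: int = 1,
                           max_mismatch_per_arm: int = 2) -> Iterator[ReadAssignment]:
    # exact-lookup fast path; near-matching only for reads that miss it
    wb_name = layout.element_by_kind("well_barcode").name
    pb_name = layout.element_by_kind("plate_barcode").name
    la_name = layout.element_by_kind("left_arm").name
    ra_name = layout.element_by_kind("right_arm").name
    slices1 = layout.read_slices(layout.read1)
    slices2 = layout.read_slices(layout.read2)
    need1 = layout.read_length(layout.read1)
    need2 = layout.read_length(layout.read2)
    exact_probe = {(p.left.arm_seq, p.right.arm_seq): p.probe_id for p in panel}
    umi_order = layout.umi_names_in_order()

    for s1, s2 in read_pairs(r1_path, r2_path):
        if len(s1) < need1 or len(s2) < need2:
            yield ReadAssignment(None, None, None, None, "layout")
            continue
        fields = {}
        for element, sl, rc in slices1:
            seq = s1[sl]
            fields[element.name] = revcomp(seq) if rc else seq
        for element, sl, rc in slices2:
            seq = s2[sl]
            fields[element.name] = revcomp(seq) if rc else seq
        well = barcodes.well.get(fields[wb_name]) or match_barcode(
            fields[wb_name], barcodes.well, max_mismatch_barcode)
        plate = barcodes.plate.get(fields[pb_name]) or match_barcode(
            fields[pb_name], barcodes.plate, max_mismatch_barcode)
        if well is None or plate is None:
            yield (ReadAssignment(plate, None, None, None, "barcode") if plate
                   else ReadAssignment(None, None, None, None, "barcode"))
            continue
        arms = (fields[la_name], fields[ra_name])
        probe = exact_probe.get(arms) or match_probe(arms[0], arms[1], panel,
                                                     max_mismatch_per_arm)
        if probe is None:
            yield ReadAssignment(plate, well, None, None, "probe")
            continue
        yield ReadAssignment(plate, well, probe,
                             "".join(fields[n] for n in umi_order), "none")


def count_reads(r1_path: str | Path, r2_path: str | Path, panel: ProbePanel,
                barcodes: BarcodeMap, layout: LibraryLayout,
                sample_sheet: pd.DataFrame | None = None,
                max_mismatch_barcode: int = 1, max_mismatch_per_arm: int = 2,
                umi_collapse: str = "exact") -> CountMatrix:
    """Single-pass FASTQ -> deduplicated probe-level CountMatrix."""
    if sample_sheet is None:
        sample_sheet = barcodes.samples
    if sample_sheet is None or len(sample_sheet) == 0:
        raise ValueError("a sample sheet mapping (plate, well) to samples is required")
    assignments = assignments_from_fastq(r1_path, r2_path, layout, barcodes, panel,
                                         max_mismatch_barcode, max_mismatch_per_arm)
    return collapse_umis(assignments, sample_sheet, panel, method=umi_collapse)


def aggregate_to_genes(cm: CountMatrix, panel: ProbePanel) -> CountMatrix:
    """Sum probe-level counts to genes (redundant pairs included)."""
    if cm.axis != "probe":
        raise ValueError("aggregate_to_genes expects a probe-level matrix")
    missing = set(cm.counts.index) - set(panel.probe_ids)
    if missing:
        raise KeyError(f"probes absent from panel: {sorted(missing)}")
    gene_of = {p.probe_id: p.gene_id for p in panel}
    grouped = cm.counts.groupby(cm.counts.index.map(gene_of)).sum()
    grouped = grouped.reindex(list(panel.gene_to_probes)).fillna(0).astype(int)
    grouped.index.name = "gene"
    return CountMatrix(counts=grouped, stats=cm.stats.copy(),
                       fail_counts=cm.fail_counts.copy(), axis="gene")
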