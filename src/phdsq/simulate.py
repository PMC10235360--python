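"""Ground-truth read simulator for probe hybridization-ligation libraries.

Each simulated molecule is one captured ligation product: a probe pair drawn
multinomially from the well's expression profile, flanked by two independent
random 4-nt UMIs.  PCR duplication re-emits the same molecule (same UMIs) as
multiple reads; sequencing noise applies independent base substitutions.
The simulator returns the exact ground truth — molecules and distinct UMI
pairs per (plate, well, probe) — so every downstream stage can be verified
without external data.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

from .barcodes import BarcodeMap
from .layout import LibraryLayout, default_layout
from .panel import ProbePanel

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

ROLES = ("KF_control", "AD_control", "compound")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ExpressionProfile:
    """Expected molecule abundance per probe for one well.

    ``gene_abundance`` holds the underlying per-gene values; ``abundances``
    expands them to probes (redundant probes of a gene share the gene's
    abundance, as both sample the same transcript pool).
    """

    sample_id: str
    plate_id: str
    well_id: str
    role: str
    abundances: pd.Series  # indexed by probe_id
    effect_size: float | None = None
    gene_abundance: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        vals = np.asarray(self.abundances, dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError(f"{self.sample_id}: abundances must be finite and >= 0")


@dataclass
class SimConfig:
    """Sequencing-run knobs.  The seed is mandatory: every run is replayable."""

    rng_seed: int
    reads_per_well: int = 10_000
    substitution_error_rate: float = 0.0
    pcr_duplication: float = 1.0

    def __post_init__(self) -> None:
        if self.reads_per_well < 0 or self.substitution_error_rate < 0 \
                or self.pcr_duplication < 1:
            raise ValueError("reads_per_well and error rate must be >= 0; duplication >= 1")


@dataclass
class GroundTruth:
    """Exact per-(plate, well, probe) molecule and distinct-UMI-pair counts."""

    table: pd.DataFrame  # plate_id, well_id, sample_id, probe_id, molecules, distinct_umis
    umi_pairs: dict[tuple[str, str, str], set[str]] = field(default_factory=dict)

    def dedup_counts(self, probe_ids: list[str], sample_ids: list[str]) -> pd.DataFrame:
        """Distinct-UMI counts as a probes x samples matrix (zeros filled)."""
        piv = self.table.pivot_table(index="probe_id", columns="sample_id",
                                     values="distinct_umis", aggfunc="sum", fill_value=0)
        return piv.reindex(index=probe_ids, columns=sample_ids, fill_value=0).astype(int)

    def molecule_counts(self, probe_ids: list[str], sample_ids: list[str]) -> pd.DataFrame:
        piv = self.table.pivot_table(index="probe_id", columns="sample_id",
                                     values="molecules", aggfunc="sum", fill_value=0)
        return piv.reindex(index=probe_ids, columns=sample_ids, fill_value=0).astype(int)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def construct_length(layout: LibraryLayout) -> int:
    """Re-export of the layout-sum operation (see :mod:`phdsq.layout`)."""
    from .layout import construct_length as _cl
    return _cl(layout)


# ---------------------------------------------------------------------------
# expression profiles


def make_control_profiles(panel: ProbePanel,
                          fibrosis_genes: list[str],
                          adipocyte_genes: list[str],
                          housekeeping_genes: list[str],
                          dynamic_range: float = 10.0,
                          rng: np.random.Generator | None = None,
                          base_range: tuple[float, float] = (250.0, 2000.0),
                          ) -> tuple[pd.Series, pd.Series]:
    """Expected per-gene abundances for the two control states.

    The negative control (KF, keloid fibroblast) is high in fibrosis genes
    and low in adipocyte genes; the positive control (AD, adipocyte
    differentiation) is the reverse; housekeeping genes are equal in both.
    ``dynamic_range`` is the KF/AD fold change of a signature gene; base
    abundances are drawn log-uniformly over ``base_range`` so the panel spans
    low- and high-abundance transcripts.

    The defaults emulate a balanced probe pool: control separation is
    ten-fold per signature gene, and the abundance span is capped so that at
    the platform's working depth (1e4 reads/well) every panel gene keeps a
    quantifiable expected count (>= ~10 molecules) in both control states —
    the design premise of a targeted panel that carries housekeeping probes
    precisely to keep low-abundance markers countable.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    sets = [set(fibrosis_genes), set(adipocyte_genes), set(housekeeping_genes)]
    for i in range(3):
        for j in range(i + 1, 3):
            if sets[i] & sets[j]:
                raise ValueError(f"gene sets overlap: {sorted(sets[i] & sets[j])}")
    genes = list(panel.gene_to_probes)
    if set(genes) - (sets[0] | sets[1] | sets[2]):
        raise ValueError("gene sets must cover every panel gene")
    lo, hi = base_range
    base = pd.Series(np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(genes))),
                     index=genes)
    half = np.sqrt(dynamic_range)
    kf, ad = base.copy(), base.copy()
    for g in genes:
        if g in sets[0]:          # fibrosis: high in KF
            kf[g] *= half
            ad[g] /= half
        elif g in sets[1]:        # adipocyte: high in AD
            kf[g] /= half
            ad[g] *= half
    return kf, ad


def interpolate_compound(kf: pd.Series, ad: pd.Series, e: float,
                         noise_cv: float = 0.0,
                         rng: np.random.Generator | None = None) -> pd.Series:
    """Per-gene abundance of a compound of effect size ``e`` on the KF->AD axis.

    Expected value is KF + e*(AD - KF); multiplicative lognormal noise with
    coefficient of variation ``noise_cv`` is applied around it (mean-one
    lognormal, so the expectation is preserved).
    """
    if not 0 <= e <= 1:
        raise ValueError("effect size must lie in [0, 1]")
    mean = kf + e * (ad - kf)
    if noise_cv <= 0:
        return mean
    if rng is None:
        rng = np.random.default_rng(0)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    noise = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=len(mean))
    return mean * noise


def expand_to_probes(gene_abundance: pd.Series, panel: ProbePanel) -> pd.Series:
    """Map per-gene abundance to per-probe abundance (shared within a gene)."""
    return pd.Series({p.probe_id: float(gene_abundance[p.gene_id]) for p in panel})


def make_profile(sample_id: str, plate_id: str, well_id: str, role: str,
                 gene_abundance: pd.Series, panel: ProbePanel,
                 effect_size: float | None = None) -> ExpressionProfile:
    return ExpressionProfile(sample_id, plate_id, well_id, role,
                             expand_to_probes(gene_abundance, panel),
                             effect_size, gene_abundance)


# ---------------------------------------------------------------------------
# read generation


def _random_umis(rng: np.random.Generator, n: int, length: int) -> list[str]:
    if n == 0:
        return []
    arr = _BASES[rng.integers(0, 4, size=(n, length))]
    return [bytes(row).decode() for row in arr]


def _apply_substitutions(reads: list[str], rate: float,
                         rng: np.random.Generator) -> list[str]:
    """Independent per-base substitutions to a uniformly chosen other base."""
    if rate <= 0 or not reads:
        return reads
    length = len(reads[0])
    arr = np.frombuffer("".join(reads).encode(), dtype=np.uint8).reshape(len(reads), length).copy()
    mask = rng.random(arr.shape) < rate
    n_err = int(mask.sum())
    if n_err:
        # map base -> index, add 1..3 mod 4, map back
        idx = np.zeros(256, dtype=np.uint8)
        idx[_BASES] = np.arange(4)
        shifted = (idx[arr[mask]] + rng.integers(1, 4, size=n_err)) % 4
        arr[mask] = _BASES[shifted]
    return [bytes(row).decode() for row in arr]


def _open_text(path: str | Path, mode: str) -> TextIO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def simulate_fastq(profiles: Iterable[ExpressionProfile], panel: ProbePanel,
                   layout: LibraryLayout, barcodes: BarcodeMap, cfg: SimConfig,
                   r1_path: str | Path, r2_path: str | Path,
                   quality_char: str = "?") -> GroundTruth:
    """Simulate a paired-end run and write the two FASTQ files.

    Per well: ``reads_per_well / pcr_duplication`` molecules are drawn
    multinomially over probes proportionally to the profile's abundances;
    each molecule carries two independent random UMIs and is emitted as
    ``pcr_duplication`` reads (exactly, when integer; 1 + Poisson otherwise).
    Substitution errors hit every written base independently.  Identical
    seeds give byte-identical FASTQ output.

    Default base quality is the constant Phred+33 character ``?`` (Q30).
    """
    umi_lengths = {e.length for e in layout.elements_of_kind("umi")}
    if len(umi_lengths) != 1:
        raise ValueError("the two UMI elements must share one length")
    umi_len = umi_lengths.pop()
    arm_len = layout.arm_length
    for pair in panel:
        if len(pair.left.arm_seq) != arm_len or len(pair.right.arm_seq) != arm_len:
            raise ValueError(f"{pair.probe_id}: arm length does not match layout ({arm_len})")

    rng = np.random.default_rng(cfg.rng_seed)
    probe_ids = panel.probe_ids
    left_arm = {p.probe_id: p.left.arm_seq for p in panel}
    right_arm_rc = {p.probe_id: revcomp(p.right.arm_seq) for p in panel}

    n_mol_target = max(1, int(round(cfg.reads_per_well / cfg.pcr_duplication)))
    int_dup = float(cfg.pcr_duplication).is_integer()
    q1 = quality_char * layout.read_length(layout.read1)
    q2 = quality_char * layout.read_length(layout.read2)

    rows = []
    umi_pairs: dict[tuple[str, str, str], set[str]] = {}
    serial = 0
    with _open_text(r1_path, "w") as f1, _open_text(r2_path, "w") as f2:
        for prof in profiles:
            wbc = barcodes.seq_of_well(prof.well_id)
            pbc = barcodes.seq_of_plate(prof.plate_id)
            ab = prof.abundances.reindex(probe_ids).fillna(0.0).to_numpy(dtype=float)
            total = ab.sum()
            if total <= 0:
                raise ValueError(f"{prof.sample_id}: profile has zero total abundance")
            counts = rng.multinomial(n_mol_target, ab / total)
            r1_reads: list[str] = []
            r2_reads: list[str] = []
            names: list[str] = []
            for pid, c in zip(probe_ids, counts):
                if c == 0:
                    continue
                ul = _random_umis(rng, int(c), umi_len)
                ur = _random_umis(rng, int(c), umi_len)
                pairs8 = {a + b for a, b in zip(ul, ur)}
                key = (prof.plate_id, prof.well_id, pid)
                umi_pairs[key] = pairs8
                rows.append((prof.plate_id, prof.well_id, prof.sample_id, pid,
                             int(c), len(pairs8)))
                if int_dup:
                    dups = np.full(int(c), int(cfg.pcr_duplication))
                else:
                    dups = 1 + rng.poisson(cfg.pcr_duplication - 1, size=int(c))
                la, ra = left_arm[pid], right_arm_rc[pid]
                for m in range(int(c)):
                    r1 = wbc + ul[m] + la
                    r2 = pbc + ur[m] + ra
                    for _ in range(int(dups[m])):
                        serial += 1
                        names.append(f"sim_{serial}")
                        r1_reads.append(r1)
                        r2_reads.append(r2)
            r1_reads = _apply_substitutions(r1_reads, cfg.substitution_error_rate, rng)
            r2_reads = _apply_substitutions(r2_reads, cfg.substitution_error_rate, rng)
            f1.write("".join(f"@{n}/1\n{s}\n+\n{q1}\n" for n, s in zip(names, r1_reads)))
            f2.write("".join(f"@{n}/2\n{s}\n+\n{q2}\n" for n, s in zip(names, r2_reads)))

    table = pd.DataFrame(rows, columns=["plate_id", "well_id", "sample_id",
                                        "probe_id", "molecules", "distinct_umis"])
    return GroundTruth(table=table, umi_pairs=umi_pairs)


# ---------------------------------------------------------------------------
# screen assembly


def make_screen_profiles(panel: ProbePanel, barcodes: BarcodeMap,
                         kf: pd.Series, ad: pd.Series,
                         n_kf: int, n_ad: int,
                         compound_effects: dict[str, float],
                         noise_cv: float = 0.1,
                         rng: np.random.Generator | None = None,
                         plate_id: str = "P1") -> list[ExpressionProfile]:
    """Lay out controls and compounds on one plate, row-major, with noise.

    Controls are simulated through the same noisy interpolation at e=0 (KF)
    and e=1 (AD), so replicate wells differ by biological noise plus depth.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    from .barcodes import default_well_ids
    n_total = n_kf + n_ad + len(compound_effects)
    wells = default_well_ids(96)[:n_total]
    if len(wells) < n_total:
        raise ValueError("more samples than wells on the plate")
    profiles = []
    i = 0
    for r in range(n_kf):
        g = interpolate_compound(kf, ad, 0.0, noise_cv, rng)
        profiles.append(make_profile(f"KF_{r + 1}", plate_id, wells[i], "KF_control", g, panel, 0.0))
        i += 1
    for r in range(n_ad):
        g = interpolate_compound(kf, ad, 1.0, noise_cv, rng)
        profiles.append(make_profile(f"AD_{r + 1}", plate_id, wells[i], "AD_control", g, panel, 1.0))
        i += 1
    for name, e in compound_effects.items():
        g = interpolate_compound(kf, ad, e, noise_cv, rng)
        profiles.append(make_profile(name, plate_id, wells[i], "compound", g, panel, e))
        i += 1
    return profiles


def sample_sheet(profiles: list[ExpressionProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plate_id": [p.plate_id for p in profiles],
            "well_id": [p.well_id for p in profiles],
            "sample_id": [p.sample_id for p in profiles],
            "role": [p.role for p in profiles],
        }
    )
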