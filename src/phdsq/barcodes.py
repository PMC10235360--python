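"""Plate/well barcode sets and the sample sheet.

Well barcodes (7 nt, in the P5 primer) distinguish wells within a plate;
plate barcodes (6 nt, in the P7 primer) distinguish pooled plates.  Barcode
sets are generated greedily at pairwise Hamming distance >= 3 so that a
single sequencing error can never convert one barcode into another.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_BASES = "ACGT"


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def generate_barcodes(n: int, length: int, min_distance: int = 3,
                      seed: int = 20230301, max_tries: int = 200_000) -> list[str]:
    """Greedy seeded barcode design at pairwise Hamming distance >= min_distance.

    Deterministic for a given (n, length, min_distance, seed).
    """
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    for _ in range(max_tries):
        if len(accepted) == n:
            break
        cand = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
        if len(set(cand)) == 1:  # homopolymers are poor sequencing substrates
            continue
        if all(hamming(cand, b) >= min_distance for b in accepted):
            accepted.append(cand)
    if len(accepted) < n:
        raise RuntimeError(
            f"could not place {n} barcodes of length {length} at distance {min_distance}"
        )
    return accepted


def default_well_ids(n_wells: int = 96) -> list[str]:
    """Standard plate well ids A01..H12 (row-major), truncated to n_wells."""
    ids = [f"{row}{col:02d}" for row in "ABCDEFGH" for col in range(1, 13)]
    if n_wells > len(ids):
        raise ValueError("at most 96 wells per plate are supported")
    return ids[:n_wells]


@dataclass
class BarcodeMap:
    """Barcode -> id lookups plus the (plate, well) -> sample assignment sheet.

    ``samples`` has columns plate_id, well_id, sample_id, role; roles are
    KF_control, AD_control or compound.
    """

    well: dict[str, str]
    plate: dict[str, str]
    samples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["plate_id", "well_id", "sample_id", "role"]
        )
    )

    def __post_init__(self) -> None:
        for name, mapping in (("well", self.well), ("plate", self.plate)):
            ids = list(mapping.values())
            if len(set(ids)) != len(ids):
                raise ValueError(f"{name} barcode ids must be unique")
            lengths = {len(s) for s in mapping}
            if len(lengths) > 1:
                raise ValueError(f"{name} barcodes must share one length")
        self.validate_distances()

    def validate_distances(self, min_distance: int = 3) -> bool:
        ok = True
        for name, mapping in (("well", self.well), ("plate", self.plate)):
            for a, b in itertools.combinations(mapping, 2):
                if hamming(a, b) < min_distance:
                    warnings.warn(
                        f"{name} barcodes {a}/{b} are at Hamming distance "
                        f"{hamming(a, b)} < {min_distance}", stacklevel=2)
                    ok = False
        return ok

    @property
    def well_length(self) -> int:
        return len(next(iter(self.well)))

    @property
    def plate_length(self) -> int:
        return len(next(iter(self.plate)))

    def seq_of_well(self, well_id: str) -> str:
        return {v: k for k, v in self.well.items()}[well_id]

    def seq_of_plate(self, plate_id: str) -> str:
        return {v: k for k, v in self.plate.items()}[plate_id]

    def sample_lookup(self) -> dict[tuple[str, str], tuple[str, str]]:
        """(plate_id, well_id) -> (sample_id, role)."""
        return {
            (r.plate_id, r.well_id): (r.sample_id, r.role)
            for r in self.samples.itertuples(index=False)
        }

    # -- serialization -------------------------------------------------------

    def to_tsv(self, barcode_path: str | Path, sample_path: str | Path | None = None) -> None:
        rows = [("well", seq, wid) for seq, wid in self.well.items()]
        rows += [("plate", seq, pid) for seq, pid in self.plate.items()]
        pd.DataFrame(rows, columns=["kind", "barcode", "id"]).to_csv(
            barcode_path, sep="\t", index=False)
        if sample_path is not None:
            self.samples.to_csv(sample_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, barcode_path: str | Path,
                 sample_path: str | Path | None = None) -> "BarcodeMap":
        df = pd.read_csv(barcode_path, sep="\t", dtype=str)
        well = {r.barcode: r.id for r in df.itertuples(index=False) if r.kind == "well"}
        plate = {r.barcode: r.id for r in df.itertuples(index=False) if r.kind == "plate"}
        samples = (pd.read_csv(sample_path, sep="\t", dtype=str)
                   if sample_path is not None else None)
        if samples is None:
            return cls(well=well, plate=plate)
        return cls(well=well, plate=plate, samples=samples)


def make_barcode_map(n_plates: int = 1, n_wells: int = 96,
                     well_length: int = 7, plate_length: int = 6,
                     seed: int = 20230301,
                     samples: pd.DataFrame | None = None) -> BarcodeMap:
    """Build a deterministic barcode map for an n-plate screen."""
    well_seqs = generate_barcodes(n_wells, well_length, seed=seed)
    plate_seqs = generate_barcodes(n_plates, plate_length, seed=seed + 1)
    well_ids = default_well_ids(n_wells)
    plate_ids = [f"P{i + 1}" for i in range(n_plates)]
    kwargs = {} if samples is None else {"samples": samples}
    return BarcodeMap(well=dict(zip(well_seqs, well_ids)),
                      plate=dict(zip(plate_seqs, plate_ids)), **kwargs)
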