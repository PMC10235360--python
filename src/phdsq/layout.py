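"""Sequencing library layout: the ordered element map of the amplicon.

The amplicon produced by the assay is, 5' to 3':

    P5 adapter | well barcode (7 nt) | read-1 primer site | UMI (4 nt) |
    left arm (27 nt) | right arm (27 nt) | UMI (4 nt) | read-2 primer site |
    plate barcode (6 nt) | P7 adapter

Read 1 starts after the read-1 primer site is reached through the well
barcode, so by default read 1 carries well barcode + left UMI + left arm and
read 2 carries plate barcode + right UMI + the reverse complement of the
right arm.  The layout is data, not code: dialect changes (barcode lengths,
UMI placement, which mate carries which element) are YAML edits.

The default element lengths sum to the 208-bp amplicon observed on gels for
this library design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

VARIABLE_KINDS = ("well_barcode", "plate_barcode", "umi", "left_arm", "right_arm")
KINDS = ("constant",) + VARIABLE_KINDS


class LayoutError(ValueError):
    """Raised for malformed layouts or reads inconsistent with the layout."""


@dataclass(frozen=True)
class LayoutElement:
    name: str
    kind: str
    length: int
    fixed_seq: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise LayoutError(f"unknown element kind {self.kind!r}")
        if self.kind == "constant":
            if self.fixed_seq is None:
                raise LayoutError(f"constant element {self.name!r} needs a fixed_seq")
            if len(self.fixed_seq) != self.length:
                raise LayoutError(f"element {self.name!r}: fixed_seq length mismatch")
        if self.length <= 0:
            raise LayoutError(f"element {self.name!r}: length must be positive")


@dataclass(frozen=True)
class ReadElement:
    """Reference to an amplicon element as it appears on a sequencing read."""

    name: str
    revcomp: bool = False


@dataclass
class LibraryLayout:
    """Ordered amplicon elements plus the element order on each mate."""

    amplicon: list[LayoutElement]
    read1: list[ReadElement]
    read2: list[ReadElement]

    def __post_init__(self) -> None:
        names = [e.name for e in self.amplicon]
        if len(set(names)) != len(names):
            raise LayoutError("amplicon element names must be unique")
        kinds = [e.kind for e in self.amplicon]
        if kinds.count("well_barcode") != 1 or kinds.count("plate_barcode") != 1:
            raise LayoutError("layout needs exactly one well barcode and one plate barcode")
        if kinds.count("umi") != 2:
            raise LayoutError("layout needs exactly two UMI elements")
        if kinds.count("left_arm") != 1 or kinds.count("right_arm") != 1:
            raise LayoutError("layout needs exactly one left and one right arm")
        for re_list in (self.read1, self.read2):
            for el in re_list:
                if el.name not in names:
                    raise LayoutError(f"read element {el.name!r} not in amplicon")

    def element(self, name: str) -> LayoutElement:
        for e in self.amplicon:
            if e.name == name:
                return e
        raise KeyError(name)

    def elements_of_kind(self, kind: str) -> list[LayoutElement]:
        return [e for e in self.amplicon if e.kind == kind]

    @property
    def arm_length(self) -> int:
        return self.element_by_kind("left_arm").length

    def element_by_kind(self, kind: str) -> LayoutElement:
        found = self.elements_of_kind(kind)
        if len(found) != 1:
            raise LayoutError(f"expected exactly one {kind} element")
        return found[0]

    def umi_names_in_order(self) -> list[str]:
        """UMI element names in amplicon order (left UMI first by default)."""
        return [e.name for e in self.amplicon if e.kind == "umi"]

    def read_length(self, read: list[ReadElement]) -> int:
        return sum(self.element(el.name).length for el in read)

    def read_slices(self, read: list[ReadElement]) -> list[tuple[LayoutElement, slice, bool]]:
        """(element, slice-on-read, revcomp) triples for parsing one mate."""
        out, offset = [], 0
        for el in read:
            e = self.element(el.name)
            out.append((e, slice(offset, offset + e.length), el.revcomp))
            offset += e.length
        return out


def construct_length(layout: LibraryLayout) -> int:
    """Total amplicon length in nt: the sum of all element lengths."""
    return sum(e.length for e in layout.amplicon)


# Illumina flow-cell graft sequences; the primer-site constants are pinned so
# the complete amplicon totals 208 nt, matching the band this library design
# shows on gels.
_P5 = "AATGATACGGCGACCACCGAGATCTACAC"                       # 29 nt
_READ1_PRIMER = "ACACTCTTTCCCTACACGACGCTCTTCCGATCT" + "ACGACG"   # 39 nt
_READ2_PRIMER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC" + "GTCAGTC"  # 41 nt
_P7 = "ATCTCGTATGCCGTCTTCTGCTTG"                             # 24 nt


def default_layout(arm_length: int = 27, umi_length: int = 4,
                   well_barcode_length: int = 7, plate_barcode_length: int = 6) -> LibraryLayout:
    """The shipped default: 208-nt amplicon, dual 4-nt UMIs flanking the arms."""
    amplicon = [
        LayoutElement("p5_adapter", "constant", len(_P5), _P5),
        LayoutElement("well_barcode", "well_barcode", well_barcode_length),
        LayoutElement("read1_primer", "constant", len(_READ1_PRIMER), _READ1_PRIMER),
        LayoutElement("umi_left", "umi", umi_length),
        LayoutElement("left_arm", "left_arm", arm_length),
        LayoutElement("right_arm", "right_arm", arm_length),
        LayoutElement("umi_right", "umi", umi_length),
        LayoutElement("read2_primer", "constant", len(_READ2_PRIMER), _READ2_PRIMER),
        LayoutElement("plate_barcode", "plate_barcode", plate_barcode_length),
        LayoutElement("p7_adapter", "constant", len(_P7), _P7),
    ]
    read1 = [ReadElement("well_barcode"), ReadElement("umi_left"), ReadElement("left_arm")]
    read2 = [ReadElement("plate_barcode"), ReadElement("umi_right"),
             ReadElement("right_arm", revcomp=True)]
    return LibraryLayout(amplicon, read1, read2)


def to_yaml(layout: LibraryLayout, path: str | Path) -> None:
    doc = {
        "amplicon": [
            {"name": e.name, "kind": e.kind, "length": e.length,
             **({"fixed_seq": e.fixed_seq} if e.fixed_seq else {})}
            for e in layout.amplicon
        ],
        "read1": [{"name": el.name, "revcomp": el.revcomp} for el in layout.read1],
        "read2": [{"name": el.name, "revcomp": el.revcomp} for el in layout.read2],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def from_yaml(path: str | Path) -> LibraryLayout:
    doc = yaml.safe_load(Path(path).read_text())
    amplicon = [LayoutElement(d["name"], d["kind"], int(d["length"]), d.get("fixed_seq"))
                for d in doc["amplicon"]]
    read1 = [ReadElement(d["name"], bool(d.get("revcomp", False))) for d in doc["read1"]]
    read2 = [ReadElement(d["name"], bool(d.get("revcomp", False))) for d in doc["read2"]]
    return LibraryLayout(amplicon, read1, read2)
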