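"""Transcript models and coordinate arithmetic.

All internal coordinates are 0-based, half-open, on the genomic forward
strand. Transcript ("spliced") coordinates run 5'->3' along the mature
transcript, so for minus-strand genes transcript offset 0 corresponds to the
*largest* genomic exon coordinate.

Region classes are ``utr5``, ``cds`` and ``utr3``. The ``cds`` region here
includes the stop codon (its last three nucleotides); the stop-codon anchor
used for windowed site counting is the transcript coordinate of the first
base of that codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

REGION_CLASSES = ("utr5", "cds", "utr3")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """One transcript isoform of a gene.

    Parameters
    ----------
    exons
        Genomic intervals, 0-based half-open, sorted by start.
    regions
        Mapping of region class to genomic intervals (subsets of exons).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    ccds_id: str | None = None
    transcript_support_level: int | None = None
    level: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for a, b in self.exons:
            if b <= a:
                raise ValueError(f"empty exon interval ({a}, {b})")
        for cls, ivs in self.regions.items():
            self.regions[cls] = sorted((int(a), int(b)) for a, b in ivs)

    # ---- lengths -----------------------------------------------------
    @property
    def spliced_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    def region_length(self, cls: str) -> int:
        return sum(b - a for a, b in self.regions.get(cls, []))

    # ---- coordinate maps ---------------------------------------------
    def _tx_ordered_exons(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    def genomic_to_transcript(self, pos: int) -> int | None:
        """Transcript offset of genomic position ``pos``, or None if intronic."""
        off = 0
        for a, b in self._tx_ordered_exons():
            if a <= pos < b:
                return off + (pos - a if self.strand == "+" else b - 1 - pos)
            off += b - a
        return None

    def transcript_to_genomic(self, off: int) -> int:
        if off < 0 or off >= self.spliced_length:
            raise IndexError(f"transcript offset {off} out of range")
        for a, b in self._tx_ordered_exons():
            n = b - a
            if off < n:
                return a + off if self.strand == "+" else b - 1 - off
            off -= n
        raise AssertionError("unreachable")

    def region_transcript_intervals(self, cls: str) -> list[tuple[int, int]]:
        """Transcript-coordinate intervals (half-open) of a region class."""
        out = []
        for a, b in self.regions.get(cls, []):
            five_prime = a if self.strand == "+" else b - 1
            start = self.genomic_to_transcript(five_prime)
            if start is None:
                raise ValueError(
                    f"region interval ({a},{b}) of {self.transcript_id} not exonic"
                )
            out.append((start, start + (b - a)))
        return sorted(out)

    @property
    def stop_codon_offset(self) -> int | None:
        """Transcript coordinate of the first base of the stop codon.

        The stop codon is the last three nucleotides of the CDS region.
        """
        ivs = self.region_transcript_intervals("cds")
        if not ivs:
            return None
        end = max(b for _, b in ivs)
        if end < 3:
            return None
        return end - 3

    # ---- sequence extraction -----------------------------------------
    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        chrom_seq = genome[self.chrom]
        seq = "".join(chrom_seq[a:b] for a, b in self.exons)
        return reverse_complement(seq) if self.strand == "-" else seq

    def region_sequence(self, genome: Mapping[str, str], cls: str) -> str:
        """Sense-strand sequence of a region class, fragments in 5'->3' order."""
        chrom_seq = genome[self.chrom]
        ivs = self.regions.get(cls, [])
        if self.strand == "+":
            return "".join(chrom_seq[a:b] for a, b in sorted(ivs))
        return "".join(
            reverse_complement(chrom_seq[a:b]) for a, b in sorted(ivs, reverse=True)
        )


def chromosome_class(chrom: str, x_aliases: tuple[str, ...] = ("X", "chrX")) -> str:
    return "X" if chrom in x_aliases else "autosome"
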