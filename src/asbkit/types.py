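"""Core domain types shared across the toolkit.

The unit of all downstream inference is a heterozygous biallelic SNV
(:class:`HetSNP`) together with its allelic read counts
(:class:`AlleleCount`).  Coordinate conventions: SNP positions are 1-based
(VCF style); intervals are 0-based half-open (BED style).  All conversions
between the two go through :func:`pos_to_zero_based`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_BASES = frozenset("ACGT")

#: Window half-width around each SNP used for motif scanning (bp).
WINDOW_FLANK = 20
#: Total window length: SNP at the center of ±WINDOW_FLANK bp.
WINDOW_LENGTH = 2 * WINDOW_FLANK + 1
#: 0-based index of the SNP within each window.
WINDOW_CENTER = WINDOW_FLANK


def pos_to_zero_based(pos: int) -> int:
    """Convert a 1-based SNP position to its 0-based coordinate."""
    return pos - 1


@dataclass(frozen=True, order=True)
class HetSNP:
    """A heterozygous biallelic SNV.

    Attributes
    ----------
    chrom : str
        Chromosome name.
    pos : int
        1-based position.
    rsid : str
        dbSNP identifier, or "" when unknown.
    ref_allele, alt_allele : str
        Single bases in {A, C, G, T}; must differ.
    """

    chrom: str
    pos: int
    rsid: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP position must be >= 1, got {self.pos}")
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise ValueError(
                f"alleles must be single bases in ACGT, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass(frozen=True)
class GenomicInterval:
    """A labeled genomic interval, 0-based half-open [start, end)."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def contains(self, zero_based_pos: int) -> bool:
        return self.start <= zero_based_pos < self.end


@dataclass(frozen=True)
class AllelePairWindows:
    """Paired 41-bp sequence windows carrying the two alleles of one SNP.

    Both windows are identical except at the center base, which carries
    ``snp.ref_allele`` in ``ref_window`` and ``snp.alt_allele`` in
    ``alt_window``.
    """

    snp: HetSNP
    ref_window: str
    alt_window: str
    offset_of_snp: int = WINDOW_CENTER

    def __post_init__(self) -> None:
        for name, win in (("ref", self.ref_window), ("alt", self.alt_window)):
            if len(win) != WINDOW_LENGTH:
                raise ValueError(
                    f"{name}_window must be {WINDOW_LENGTH} bp, got {len(win)}"
                )
        c = self.offset_of_snp
        if self.ref_window[c] != self.snp.ref_allele:
            raise ValueError("center of ref_window must equal ref_allele")
        if self.alt_window[c] != self.snp.alt_allele:
            raise ValueError("center of alt_window must equal alt_allele")
        if self.ref_window[:c] != self.alt_window[:c] or (
            self.ref_window[c + 1 :] != self.alt_window[c + 1 :]
        ):
            raise ValueError("windows may differ only at the center base")


@dataclass(frozen=True)
class AssociationRecord:
    """An rsID-keyed association: eQTL target gene or GWAS trait."""

    rsid: str
    kind: str  # "eQTL" or "GWAS"
    payload: str

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("association record requires a non-empty rsid")
        if self.kind not in ("eQTL", "GWAS"):
            raise ValueError(f"kind must be 'eQTL' or 'GWAS', got {self.kind!r}")


@dataclass(frozen=True)
class AlleleCount:
    """Reference/alternative read counts at one heterozygous SNP."""

    snp: HetSNP
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def total(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def ref_ratio(self) -> float:
        """Fraction of reads supporting the reference allele (total > 0)."""
        if self.total == 0:
            raise ZeroDivisionError("ref_ratio undefined for zero total")
        return self.ref_count / self.total


@dataclass
class GeneModel:
    """A minimal transcript model for region labeling.

    Coordinates are 0-based half-open.  ``exons``/``utr5``/``utr3`` are
    lists of (start, end) tuples; UTRs are subsets of exons.
    """

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name} has invalid strand {self.strand!r}")
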