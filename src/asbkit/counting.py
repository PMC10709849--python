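"""Per-SNP allelic read counting and the count/peak filters.

Input alignments are assumed bias-filtered and deduplicated upstream
(mapping-bias removal is not re-done here).  Each template (read pair,
keyed by query name) contributes at most one base call per SNP; when the
two mates disagree at the SNP the first mate encountered wins.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pysam

from .io import IntervalIndex
from .types import AlleleCount, GenomicInterval, HetSNP, pos_to_zero_based

logger = logging.getLogger("asbkit")

DEFAULT_MIN_MAPQ = 10
DEFAULT_MIN_BASEQ = 10

#: Read-depth filter: keep SNPs with total counts strictly greater than this.
DEFAULT_MIN_TOTAL = 6


def count_alleles_at_snps(
    alignments: str | Path | pysam.AlignmentFile,
    snps: list[HetSNP],
    *,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
) -> list[AlleleCount]:
    """Count reads supporting each allele at each heterozygous SNP.

    A read contributes when its mapping quality is >= ``min_mapq``, the
    base quality at the SNP is >= ``min_baseq``, and the aligned base
    equals one of the two alleles; deletions, reference skips and
    third-allele bases are ignored.  Requires a coordinate-sorted,
    indexed BAM (or CRAM).
    """
    own = not isinstance(alignments, pysam.AlignmentFile)
    bam = (
        pysam.AlignmentFile(str(alignments)) if own else alignments
    )
    try:
        if not bam.has_index():
            raise ValueError(
                f"{bam.filename!r} must be coordinate-sorted and indexed"
            )
        valid_chroms = set(bam.references)
        out: list[AlleleCount] = []
        for snp in snps:
            if snp.chrom not in valid_chroms:
                logger.warning(
                    "chromosome %s absent from alignment header; "
                    "SNP %s:%d gets counts (0, 0)",
                    snp.chrom, snp.chrom, snp.pos,
                )
                out.append(AlleleCount(snp, 0, 0))
                continue
            pos0 = pos_to_zero_based(snp.pos)
            seen: dict[str, str] = {}  # template -> base (first mate wins)
            for read in bam.fetch(snp.chrom, pos0, pos0 + 1):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.mapping_quality < min_mapq
                ):
                    continue
                qpos = _query_position(read, pos0)
                if qpos is None:
                    continue
                if read.query_qualities is not None and (
                    read.query_qualities[qpos] < min_baseq
                ):
                    continue
                base = read.query_sequence[qpos].upper()
                seen.setdefault(read.query_name, base)
            ref_n = sum(1 for b in seen.values() if b == snp.ref_allele)
            alt_n = sum(1 for b in seen.values() if b == snp.alt_allele)
            out.append(AlleleCount(snp, ref_n, alt_n))
        return out
    finally:
        if own:
            bam.close()


def _query_position(read: pysam.AlignedSegment, pos0: int) -> int | None:
    """Query offset aligned to reference position pos0, or None for
    deletions/skips/soft-clips at that position."""
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos == pos0:
            return qpos
    return None


def restrict_to_peaks(
    counts: list[AlleleCount],
    peaks: list[GenomicInterval] | IntervalIndex | None,
) -> list[AlleleCount]:
    """Keep counts whose SNP falls inside at least one peak interval.

    ``peaks=None`` means no peak file was supplied and is the identity.
    """
    if peaks is None:
        return list(counts)
    index = peaks if isinstance(peaks, IntervalIndex) else IntervalIndex(peaks)
    return [
        c for c in counts
        if index.at(c.snp.chrom, pos_to_zero_based(c.snp.pos))
    ]


def filter_counts(
    counts: list[AlleleCount], min_total: int = DEFAULT_MIN_TOTAL
) -> list[AlleleCount]:
    """Drop SNPs whose total read count is not strictly greater than
    ``min_total`` (low counts lack statistical power)."""
    if min_total < 0:
        raise ValueError("min_total must be non-negative")
    kept = [c for c in counts if c.total > min_total]
    dropped = len(counts) - len(kept)
    if dropped:
        logger.info("filter_counts dropped %d SNP(s) with total <= %d",
                    dropped, min_total)
    return kept
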