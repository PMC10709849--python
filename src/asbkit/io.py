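"""Readers and writers for the external formats the toolkit consumes.

VCF goes through pysam (plain or bgzipped), FASTA through pyfaidx, and
interval overlap through intervaltree.  Motif matrices are accepted either
as HOCOMOCO-style plain-text count matrices (``>name`` header, one row of
four numbers per motif position, columns A C G T) or in MEME minimal
format (parsed with Bio.motifs).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .motif import PWMModel
from .types import (
    AlleleCount,
    AllelePairWindows,
    AssociationRecord,
    GeneModel,
    GenomicInterval,
    HetSNP,
    WINDOW_FLANK,
    pos_to_zero_based,
)

logger = logging.getLogger("asbkit")

HET_GENOTYPES = {(0, 1), (1, 0)}


class FormatError(ValueError):
    """A file violated the expected format."""


# ---------------------------------------------------------------------------
# VCF

def parse_het_vcf(path: str | Path) -> list[HetSNP]:
    """Read heterozygous biallelic SNVs from a VCF (plain or bgzipped).

    Multi-allelic records and indels are skipped.  If a sample column is
    present the genotype must be heterozygous (0/1, 0|1 or 1|0); without
    sample columns the file is assumed to be pre-filtered to het SNPs.
    Records are returned sorted by (chrom, pos); duplicates at the same
    position are dropped (first record wins) with a warning.
    """
    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    out: dict[tuple[str, int], HetSNP] = {}
    n_dup = 0
    with vcf:
        for i, rec in enumerate(vcf.fetch(), start=1):
            try:
                ref = rec.ref or ""
                alts = rec.alts or ()
            except ValueError as exc:
                raise FormatError(
                    f"malformed VCF record #{i} in {path}: {exc}"
                ) from exc
            if len(alts) != 1:
                continue
            alt = alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref == alt:
                continue
            if ref not in "ACGT" or alt not in "ACGT":
                continue
            if rec.samples:
                gt = rec.samples[0].get("GT")
                if tuple(gt or ()) not in HET_GENOTYPES:
                    continue
            key = (rec.chrom, rec.pos)
            if key in out:
                n_dup += 1
                continue
            out[key] = HetSNP(rec.chrom, rec.pos, rec.id or "", ref, alt)
    if n_dup:
        logger.warning("%d duplicate SNP position(s) dropped (first record kept)",
                       n_dup)
    snps = sorted(out.values(), key=lambda s: (s.chrom, s.pos))
    if not snps:
        logger.warning("no heterozygous SNVs found in %s", path)
    return snps


def write_het_vcf(snps: list[HetSNP], path: str | Path,
                  sample: str = "SAMPLE") -> None:
    """Write SNPs as a minimal single-sample VCF with 0/1 genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted({s.chrom for s in snps}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for s in sorted(snps, key=lambda x: (x.chrom, x.pos)):
            fh.write(f"{s.chrom}\t{s.pos}\t{s.rsid or '.'}\t{s.ref_allele}\t"
                     f"{s.alt_allele}\t.\tPASS\t.\tGT\t0/1\n")


# ---------------------------------------------------------------------------
# Motif matrices

def _parse_hocomoco_pcm(lines: list[str], path: str) -> tuple[str, np.ndarray]:
    name = "motif"
    rows: list[list[float]] = []
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if rows:
                raise FormatError(
                    f"{path}: multiple motifs in one file are not supported"
                )
            name = line[1:].strip() or name
            continue
        fields = line.split()
        if len(fields) != 4:
            raise FormatError(
                f"{path} line {ln}: expected 4 numbers (A C G T), "
                f"got {len(fields)}"
            )
        try:
            row = [float(x) for x in fields]
        except ValueError as exc:
            raise FormatError(f"{path} line {ln}: non-numeric value") from exc
        if any(v < 0 for v in row):
            raise FormatError(f"{path} line {ln}: negative count")
        rows.append(row)
    if not rows:
        raise FormatError(f"{path}: motif has width 0")
    return name, np.array(rows).T  # rows are positions -> 4 x width


def _parse_meme_minimal(path: str) -> tuple[str, np.ndarray]:
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    if len(records) == 0:
        raise FormatError(f"{path}: no motifs found")
    m = records[0]
    counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
    if counts.shape[1] < 1:
        raise FormatError(f"{path}: motif has width 0")
    return m.name or "motif", counts


def parse_pwm(
    path: str | Path,
    *,
    pseudocount: float = 0.1,
    background: np.ndarray | None = None,
) -> PWMModel:
    """Parse a HOCOMOCO plain-text PCM or MEME minimal motif file.

    The pseudocount is distributed across bases by the background
    (uniform by default) before normalizing columns to probabilities.
    """
    path = str(path)
    with open(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    if stripped.startswith("MEME version"):
        name, counts = _parse_meme_minimal(path)
    else:
        name, counts = _parse_hocomoco_pcm(text.splitlines(), path)
    return PWMModel.from_counts(
        counts, name=name, pseudocount=pseudocount, background=background
    )


# ---------------------------------------------------------------------------
# Intervals (BED)

def parse_intervals(path: str | Path) -> list[GenomicInterval]:
    """Parse a BED3+ file; columns beyond the third are joined as the label."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path} line {ln}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path} line {ln}: non-integer coordinates"
                ) from exc
            label = ",".join(fields[3:]) if len(fields) > 3 else ""
            try:
                out.append(GenomicInterval(chrom, start, end, label))
            except ValueError as exc:
                raise FormatError(f"{path} line {ln}: {exc}") from exc
    return out


def write_intervals(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            label = f"\t{iv.label}" if iv.label else ""
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}{label}\n")


class IntervalIndex:
    """Chromosome-keyed interval tree for point/interval overlap queries."""

    def __init__(self, intervals: list[GenomicInterval]):
        self._trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, iv
            )

    def at(self, chrom: str, zero_based_pos: int) -> list[GenomicInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (hit.data for hit in tree.at(zero_based_pos)),
            key=lambda iv: (iv.start, iv.end, iv.label),
        )


# ---------------------------------------------------------------------------
# Allele windows

def extract_allele_windows(
    snps: list[HetSNP], genome: str | Path | Fasta
) -> list[AllelePairWindows]:
    """Build ±20 bp ref/alt window pairs around each SNP from a FASTA.

    Windows are uppercased.  A SNP within 20 bp of a contig end is skipped
    with a warning; a genome base matching neither allele still yields a
    pair, with a mismatch warning.
    """
    fasta = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    out: list[AllelePairWindows] = []
    for snp in snps:
        if snp.chrom not in fasta:
            raise KeyError(f"chromosome {snp.chrom} absent from FASTA")
        contig = fasta[snp.chrom]
        start0 = pos_to_zero_based(snp.pos) - WINDOW_FLANK
        end0 = pos_to_zero_based(snp.pos) + WINDOW_FLANK + 1
        if start0 < 0 or end0 > len(contig):
            logger.warning(
                "SNP %s %s:%d within %d bp of contig end; skipped",
                snp.rsid or ".", snp.chrom, snp.pos, WINDOW_FLANK,
            )
            continue
        seq = str(contig[start0:end0]).upper()
        center = WINDOW_FLANK
        genome_base = seq[center]
        if genome_base not in (snp.ref_allele, snp.alt_allele):
            logger.warning(
                "genome base %s at %s:%d matches neither allele of SNP %s",
                genome_base, snp.chrom, snp.pos, snp.rsid or ".",
            )
        ref_win = seq[:center] + snp.ref_allele + seq[center + 1 :]
        alt_win = seq[:center] + snp.alt_allele + seq[center + 1 :]
        out.append(AllelePairWindows(snp, ref_win, alt_win))
    return out


# ---------------------------------------------------------------------------
# Counts tables

COUNTS_COLUMNS = ["chrom", "pos", "rsid", "ref", "alt", "ref_count", "alt_count"]


def read_counts_tsv(path: str | Path) -> list[AlleleCount]:
    """Read a per-SNP allelic counts table (header-bearing TSV)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "rsid": str})
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df["rsid"] = df["rsid"].fillna("")
    out = []
    for row in df.itertuples(index=False):
        snp = HetSNP(row.chrom, int(row.pos), str(row.rsid), row.ref, row.alt)
        out.append(AlleleCount(snp, int(row.ref_count), int(row.alt_count)))
    return out


def write_counts_tsv(counts: list[AlleleCount], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(COUNTS_COLUMNS) + "\n")
        for c in counts:
            s = c.snp
            fh.write(f"{s.chrom}\t{s.pos}\t{s.rsid}\t{s.ref_allele}\t"
                     f"{s.alt_allele}\t{c.ref_count}\t{c.alt_count}\n")


# ---------------------------------------------------------------------------
# Association tables

def read_associations(path: str | Path, kind: str) -> list[AssociationRecord]:
    """Read an rsID-keyed association TSV.

    Requires columns ``rsid`` plus ``gene`` (kind="eQTL") or ``trait``
    (kind="GWAS").
    """
    payload_col = {"eQTL": "gene", "GWAS": "trait"}.get(kind)
    if payload_col is None:
        raise ValueError(f"kind must be 'eQTL' or 'GWAS', got {kind!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("rsid", payload_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        rsid = getattr(row, "rsid")
        payload = getattr(row, payload_col)
        if not rsid or pd.isna(rsid):
            continue
        out.append(AssociationRecord(rsid, kind, "" if pd.isna(payload) else payload))
    return out


# ---------------------------------------------------------------------------
# Gene models (minimal GTF)

def parse_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse transcript models from a minimal GTF.

    Recognized features: ``transcript`` (span), ``exon``,
    ``five_prime_utr``, ``three_prime_utr``.  Transcripts are keyed by the
    ``transcript_id`` (falling back to ``gene_id``) attribute.  GTF
    coordinates (1-based inclusive) are converted to 0-based half-open.
    """
    models: dict[str, GeneModel] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path} line {ln}: fewer than 9 columns")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path} line {ln}: missing or invalid strand {strand!r}"
                )
            ident = None
            for key in ("transcript_id", "gene_id"):
                marker = key + ' "'
                if marker in attrs:
                    ident = attrs.split(marker, 1)[1].split('"', 1)[0]
                    break
            if ident is None:
                raise FormatError(f"{path} line {ln}: no transcript_id/gene_id")
            s0, e0 = int(start) - 1, int(end)
            model = models.get(ident)
            if model is None:
                model = models[ident] = GeneModel(ident, chrom, strand, s0, e0)
            model.tx_start = min(model.tx_start, s0)
            model.tx_end = max(model.tx_end, e0)
            if feature == "exon":
                model.exons.append((s0, e0))
            elif feature == "five_prime_utr":
                model.utr5.append((s0, e0))
            elif feature == "three_prime_utr":
                model.utr3.append((s0, e0))
    return list(models.values())
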