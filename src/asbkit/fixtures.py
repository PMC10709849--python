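"""Synthetic inputs with known ground truth for every pipeline stage.

The count generator emulates a ChIP-seq allelic-imbalance experiment:
null SNPs draw reference counts from the symmetric beta-binomial at
p = 0.5 with overdispersion ``rho_true``; a planted fraction (10% by
default) of truly imbalanced SNPs draw from a binomial whose odds are
uniform in 1.5:1 to 5:1, with a random imbalance direction.  Depths are
uniform integers in [10, 60] by default, straddling the >6 count filter.

Everything is deterministic given the seed, and the writers emit the same
VCF/TSV/BED/FASTA dialects the parsers read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .detection import BetaBinomialNull, simulate_null_counts
from .motif import BASES, PWMModel
from .types import (
    AlleleCount,
    AllelePairWindows,
    GeneModel,
    GenomicInterval,
    HetSNP,
    WINDOW_CENTER,
    WINDOW_LENGTH,
)

#: Toy genome: 2 chromosomes x 100 kb, uniform base composition.
TOY_CHROMS = {"chrS1": 100_000, "chrS2": 100_000}

DEFAULT_DEPTH_RANGE = (10, 60)
DEFAULT_ASB_FRACTION = 0.10
DEFAULT_EFFECT_RANGE = (1.5, 5.0)


@dataclass
class SimulatedSample:
    """Allelic counts with per-SNP ground truth."""

    counts: list[AlleleCount]
    truth_is_asb: list[bool]
    rho_true: float
    effect_sizes: list[float]  # ref:alt odds per planted SNP, 0 for null SNPs
    seed: int

    def __post_init__(self) -> None:
        if not (len(self.counts) == len(self.truth_is_asb)
                == len(self.effect_sizes)):
            raise ValueError("parallel lists must have equal length")


def _random_snps(n: int, rng: np.random.Generator) -> list[HetSNP]:
    chroms = sorted(TOY_CHROMS)
    per_chrom = {c: [] for c in chroms}
    assignments = rng.integers(0, len(chroms), size=n)
    for i, ci in enumerate(assignments):
        per_chrom[chroms[ci]].append(i)
    snps: list[HetSNP | None] = [None] * n
    lo, hi = WINDOW_CENTER + 1, min(TOY_CHROMS.values()) - WINDOW_CENTER
    for chrom, idxs in per_chrom.items():
        positions = rng.choice(np.arange(lo, hi), size=len(idxs), replace=False)
        positions.sort()
        for i, pos in zip(idxs, positions):
            ref, alt = rng.choice(list(BASES), size=2, replace=False)
            snps[i] = HetSNP(chrom, int(pos), f"rs{900000 + i}", ref, alt)
    return snps  # type: ignore[return-value]


def simulate_counts_dataset(
    n_snps: int,
    *,
    rho_true: float = 0.2,
    depth_range: tuple[int, int] = DEFAULT_DEPTH_RANGE,
    fixed_depth: int | None = None,
    asb_fraction: float = DEFAULT_ASB_FRACTION,
    effect_range: tuple[float, float] = DEFAULT_EFFECT_RANGE,
    seed: int = 0,
) -> SimulatedSample:
    """Generate a per-SNP counts table with planted allelic imbalance."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not 0.0 <= asb_fraction <= 1.0:
        raise ValueError("asb_fraction must be in [0, 1]")
    if effect_range[0] <= 1.0 or effect_range[1] < effect_range[0]:
        raise ValueError("effect_range must lie within (1, inf), lo <= hi")
    rng = np.random.default_rng(seed)
    snps = _random_snps(n_snps, rng)
    if fixed_depth is not None:
        totals = np.full(n_snps, fixed_depth, dtype=np.int64)
    else:
        totals = rng.integers(depth_range[0], depth_range[1] + 1, size=n_snps)
    n_asb = int(round(asb_fraction * n_snps))
    is_asb = np.zeros(n_snps, dtype=bool)
    if n_asb:
        is_asb[rng.choice(n_snps, size=n_asb, replace=False)] = True
    null = BetaBinomialNull(rho_true)
    refs = np.empty(n_snps, dtype=np.int64)
    null_idx = np.flatnonzero(~is_asb)
    if len(null_idx):
        refs[null_idx] = simulate_null_counts(totals[null_idx], null, rng)
    effects = np.zeros(n_snps)
    for i in np.flatnonzero(is_asb):
        e = rng.uniform(*effect_range)
        effects[i] = e
        p = e / (1.0 + e)
        if rng.random() < 0.5:  # random imbalance direction
            p = 1.0 - p
        refs[i] = rng.binomial(totals[i], p)
    counts = [
        AlleleCount(s, int(r), int(t - r))
        for s, r, t in zip(snps, refs, totals)
    ]
    return SimulatedSample(
        counts, list(map(bool, is_asb)), rho_true, list(effects), seed
    )


# ---------------------------------------------------------------------------
# Motif window fixtures

@dataclass
class SimulatedWindows:
    """Paired allele windows with planted motif disruptions."""

    pairs: list[AllelePairWindows]
    truth_disrupting: list[bool]
    seed: int


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def simulate_motif_windows(
    pwm: PWMModel,
    n_disrupting: int,
    n_background: int,
    seed: int = 0,
) -> SimulatedWindows:
    """Plant consensus motifs across window centers and break them in alt.

    Disrupting pairs embed the PWM consensus so that it covers the center;
    the ref center base is the consensus base at that motif position and
    the alt center base is that column's weakest base.  Background pairs
    are uniform-random sequences with a random center substitution.
    """
    if pwm.width > WINDOW_LENGTH:
        raise ValueError("PWM wider than the window")
    rng = np.random.default_rng(seed)
    pairs: list[AllelePairWindows] = []
    truth: list[bool] = []
    consensus = pwm.consensus
    weakest = [BASES[i] for i in pwm.prob_matrix.argmin(axis=0)]
    pos_counter = 1000
    for i in range(n_disrupting):
        # offset such that the motif covers the center
        off_lo = max(0, WINDOW_CENTER - pwm.width + 1)
        off_hi = min(WINDOW_CENTER, WINDOW_LENGTH - pwm.width)
        offset = int(rng.integers(off_lo, off_hi + 1))
        motif_pos = WINDOW_CENTER - offset
        seq = list(_random_seq(WINDOW_LENGTH, rng))
        seq[offset : offset + pwm.width] = consensus
        ref_base = consensus[motif_pos]
        alt_base = weakest[motif_pos]
        if alt_base == ref_base:  # fully flat column; pick any other base
            alt_base = next(b for b in BASES if b != ref_base)
        seq[WINDOW_CENTER] = ref_base
        ref_win = "".join(seq)
        alt_win = ref_win[:WINDOW_CENTER] + alt_base + ref_win[WINDOW_CENTER + 1:]
        snp = HetSNP("chrS1", pos_counter, f"rsM{i}", ref_base, alt_base)
        pos_counter += 100
        pairs.append(AllelePairWindows(snp, ref_win, alt_win))
        truth.append(True)
    for i in range(n_background):
        seq = _random_seq(WINDOW_LENGTH, rng)
        ref_base = seq[WINDOW_CENTER]
        alt_base = str(rng.choice([b for b in BASES if b != ref_base]))
        alt_win = seq[:WINDOW_CENTER] + alt_base + seq[WINDOW_CENTER + 1:]
        snp = HetSNP("chrS2", pos_counter, f"rsB{i}", ref_base, alt_base)
        pos_counter += 100
        pairs.append(AllelePairWindows(snp, seq, alt_win))
        truth.append(False)
    return SimulatedWindows(pairs, truth, seed)


# ---------------------------------------------------------------------------
# Genome / interval / annotation fixtures

def write_toy_genome(
    path: str | Path,
    *,
    chroms: dict[str, int] | None = None,
    snps: list[HetSNP] | None = None,
    seed: int = 0,
) -> Path:
    """Write a uniform-random FASTA; if SNPs are given, the genome carries
    each SNP's reference allele at its position."""
    chroms = dict(chroms or TOY_CHROMS)
    rng = np.random.default_rng(seed)
    seqs = {c: list(_random_seq(n, rng)) for c, n in chroms.items()}
    for snp in snps or []:
        seqs[snp.chrom][snp.pos - 1] = snp.ref_allele
    path = Path(path)
    with open(path, "w") as fh:
        for chrom in sorted(seqs):
            fh.write(f">{chrom}\n")
            s = "".join(seqs[chrom])
            for i in range(0, len(s), 70):
                fh.write(s[i : i + 70] + "\n")
    return path


def make_toy_ccres(snps: list[HetSNP], rng: np.random.Generator) -> list[GenomicInterval]:
    """One cCRE interval over a random subset of SNPs, cycling the classes."""
    classes = ["PLS", "pELS", "dELS", "DNase-H3K4me3", "CTCF-only", "DNase-only"]
    out = []
    for i, snp in enumerate(snps):
        if rng.random() < 0.5:
            continue
        cls = classes[i % len(classes)]
        label = cls + ("," + "CTCF-bound" if rng.random() < 0.5 else "")
        start = max(0, snp.pos - 1 - int(rng.integers(0, 100)))
        out.append(GenomicInterval(snp.chrom, start, snp.pos + 100, label))
    return out


def make_toy_genes(chrom: str = "chrS1") -> list[GeneModel]:
    """Two toy transcripts (one per strand) with exons and UTRs."""
    fwd = GeneModel(
        "TX1", chrom, "+", 10_000, 16_000,
        exons=[(10_000, 10_500), (12_000, 12_500), (15_500, 16_000)],
        utr5=[(10_000, 10_200)],
        utr3=[(15_800, 16_000)],
    )
    rev = GeneModel(
        "TX2", chrom, "-", 40_000, 46_000,
        exons=[(40_000, 40_600), (45_000, 46_000)],
        utr5=[(45_800, 46_000)],
        utr3=[(40_000, 40_200)],
    )
    return [fwd, rev]


def write_toy_gtf(genes: list[GeneModel], path: str | Path) -> Path:
    """Write gene models as a minimal GTF the parser reads back."""
    path = Path(path)
    with open(path, "w") as fh:
        for g in genes:
            attr = f'gene_id "{g.name}"; transcript_id "{g.name}";'
            rows = [("transcript", g.tx_start, g.tx_end)]
            rows += [("exon", s, e) for s, e in g.exons]
            rows += [("five_prime_utr", s, e) for s, e in g.utr5]
            rows += [("three_prime_utr", s, e) for s, e in g.utr3]
            for feature, s, e in rows:
                fh.write(
                    f"{g.chrom}\ttoy\t{feature}\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\t{attr}\n"
                )
    return path


def write_associations_tsv(
    records: list[tuple[str, str]], path: str | Path, kind: str
) -> Path:
    """Write an rsID-keyed association table ((rsid, payload) tuples)."""
    payload_col = {"eQTL": "gene", "GWAS": "trait"}[kind]
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"rsid\t{payload_col}\n")
        for rsid, payload in records:
            fh.write(f"{rsid}\t{payload}\n")
    return path


# ---------------------------------------------------------------------------
# Alignment fixtures (SAM)

def write_sam_for_counts(
    counts: list[AlleleCount],
    genome_path: str | Path,
    out_sam: str | Path,
    *,
    read_length: int = 36,
    mapq: int = 60,
    baseq_char: str = "I",
) -> Path:
    """Write a SAM whose pileup reproduces the given allelic counts.

    Each supporting read spans the SNP with the allele substituted at the
    SNP column; reads are sorted by coordinate.
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(genome_path))
    lengths = {name: len(fasta[name]) for name in fasta.keys()}
    rows = []
    for c in counts:
        snp = c.snp
        start0 = snp.pos - 1 - read_length // 2
        start0 = max(0, min(start0, lengths[snp.chrom] - read_length))
        template = str(fasta[snp.chrom][start0 : start0 + read_length]).upper()
        snp_off = snp.pos - 1 - start0
        for allele, n in ((snp.ref_allele, c.ref_count),
                          (snp.alt_allele, c.alt_count)):
            seq = template[:snp_off] + allele + template[snp_off + 1 :]
            for i in range(n):
                qname = f"{snp.rsid or snp.pos}_{allele}_{i}"
                rows.append((snp.chrom, start0, qname, seq))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    out_sam = Path(out_sam)
    with open(out_sam, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name in sorted(lengths):
            fh.write(f"@SQ\tSN:{name}\tLN:{lengths[name]}\n")
        for chrom, start0, qname, seq in rows:
            fh.write(
                f"{qname}\t0\t{chrom}\t{start0 + 1}\t{mapq}\t"
                f"{len(seq)}M\t*\t0\t0\t{seq}\t{baseq_char * len(seq)}\n"
            )
    return out_sam


def sam_to_indexed_bam(sam_path: str | Path, bam_path: str | Path) -> Path:
    """Convert a coordinate-sorted SAM to an indexed BAM (via pysam)."""
    import pysam

    bam_path = str(bam_path)
    with pysam.AlignmentFile(str(sam_path)) as sam, pysam.AlignmentFile(
        bam_path, "wb", template=sam
    ) as bam:
        for read in sam:
            bam.write(read)
    pysam.index(bam_path)
    return Path(bam_path)
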