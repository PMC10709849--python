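"""Regulatory and phenotypic context for each called SNP.

Attaches an ENCODE cCRE class, a lightweight genomic-region label and
rsID-keyed eQTL/GWAS associations, and groups calls per chromosome for
the cytogenetic map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .detection import ASBCall
from .io import IntervalIndex
from .types import GeneModel, GenomicInterval, pos_to_zero_based

logger = logging.getLogger("asbkit")

#: ENCODE cCRE classes, highest priority first.  A SNP overlapping several
#: cCREs gets the highest-priority class (promoter-like beats enhancer-like).
CCRE_PRIORITY = (
    "PLS",
    "pELS",
    "dELS",
    "DNase-H3K4me3",
    "CTCF-only",
    "DNase-only",
)
CCRE_UNCLASSIFIED = "unclassified"
CTCF_BOUND_TOKEN = "CTCF-bound"

REGION_LABELS = (
    "exon",
    "5_prime_UTR",
    "3_prime_UTR",
    "intron",
    "upstream_gene",
    "downstream_gene",
    "intergenic",
)

DEFAULT_FLANK = 5000

URL_TEMPLATES = {
    "dbsnp": "https://www.ncbi.nlm.nih.gov/snp/{rsid}",
    "genome_browser": (
        "https://genome.ucsc.edu/cgi-bin/hgTracks?db=hg38&position="
        "{chrom}%3A{pos}"
    ),
    "variant_viewer": "https://www.ncbi.nlm.nih.gov/variation/view/?q={rsid}",
    "gtex": "https://gtexportal.org/home/snp/{rsid}",
}


@dataclass
class AnnotatedSNP:
    """An ASB call joined to its regulatory and phenotypic context."""

    call: ASBCall
    ccre_label: str = CCRE_UNCLASSIFIED
    ctcf_bound: bool = False
    region_label: str = "intergenic"
    eqtl_genes: list[str] = field(default_factory=list)
    gwas_traits: list[str] = field(default_factory=list)

    @property
    def links(self) -> dict[str, str]:
        """Database hyperlinks (empty when the SNP has no rsID where one
        is required)."""
        snp = self.call.count.snp
        out = {
            "genome_browser": URL_TEMPLATES["genome_browser"].format(
                chrom=snp.chrom, pos=snp.pos
            )
        }
        if snp.rsid:
            for key in ("dbsnp", "variant_viewer", "gtex"):
                out[key] = URL_TEMPLATES[key].format(rsid=snp.rsid)
        return out


def _split_ccre_label(label: str) -> tuple[str | None, bool]:
    """Split a SCREEN-style label into (class, CTCF-bound flag)."""
    tokens = [t.strip() for t in label.split(",") if t.strip()]
    ctcf_bound = CTCF_BOUND_TOKEN in tokens
    classes = [t for t in tokens if t in CCRE_PRIORITY]
    unknown = [t for t in tokens if t not in CCRE_PRIORITY
               and t != CTCF_BOUND_TOKEN]
    if classes:
        return classes[0], ctcf_bound
    if unknown:
        logger.warning("unknown cCRE label token %r kept verbatim", unknown[0])
        return unknown[0], ctcf_bound
    return None, ctcf_bound


def annotate_ccre(
    annotated: list[AnnotatedSNP],
    ccres: list[GenomicInterval] | IntervalIndex,
) -> list[AnnotatedSNP]:
    """Assign each SNP exactly one cCRE class (or "unclassified")."""
    index = ccres if isinstance(ccres, IntervalIndex) else IntervalIndex(ccres)
    rank = {c: i for i, c in enumerate(CCRE_PRIORITY)}
    for a in annotated:
        snp = a.call.count.snp
        best_class: str | None = None
        ctcf = False
        for iv in index.at(snp.chrom, pos_to_zero_based(snp.pos)):
            cls, bound = _split_ccre_label(iv.label)
            ctcf = ctcf or bound
            if cls is None:
                continue
            if best_class is None or rank.get(cls, len(rank)) < rank.get(
                best_class, len(rank)
            ):
                best_class = cls
        a.ccre_label = best_class or CCRE_UNCLASSIFIED
        a.ctcf_bound = ctcf
    return annotated


def _in_any(pos0: int, blocks: list[tuple[int, int]]) -> bool:
    return any(s <= pos0 < e for s, e in blocks)


def region_label_for_position(
    chrom: str, pos0: int, genes: list[GeneModel], flank: int = DEFAULT_FLANK
) -> str:
    """Label one 0-based position against a set of transcript models.

    Precedence: UTR (a refinement of exonic sequence) > exon > intron >
    upstream_gene (within ``flank`` bp 5' of the TSS, strand-aware) >
    downstream_gene (within ``flank`` bp 3' of the TES) > intergenic.
    """
    best = "intergenic"
    rank = {lab: i for i, lab in enumerate(
        ("5_prime_UTR", "3_prime_UTR", "exon", "intron",
         "upstream_gene", "downstream_gene", "intergenic"))}

    def better(candidate: str) -> str:
        return candidate if rank[candidate] < rank[best] else best

    for g in genes:
        if g.chrom != chrom:
            continue
        if g.tx_start <= pos0 < g.tx_end:
            if _in_any(pos0, g.utr5):
                best = better("5_prime_UTR")
            elif _in_any(pos0, g.utr3):
                best = better("3_prime_UTR")
            elif _in_any(pos0, g.exons):
                best = better("exon")
            else:
                best = better("intron")
        elif g.strand == "+":
            if g.tx_start - flank <= pos0 < g.tx_start:
                best = better("upstream_gene")
            elif g.tx_end <= pos0 < g.tx_end + flank:
                best = better("downstream_gene")
        else:
            if g.tx_end <= pos0 < g.tx_end + flank:
                best = better("upstream_gene")
            elif g.tx_start - flank <= pos0 < g.tx_start:
                best = better("downstream_gene")
    return best


def annotate_region(
    annotated: list[AnnotatedSNP],
    genes: list[GeneModel],
    flank: int = DEFAULT_FLANK,
) -> list[AnnotatedSNP]:
    """Assign each SNP one genomic-region label."""
    for a in annotated:
        snp = a.call.count.snp
        a.region_label = region_label_for_position(
            snp.chrom, pos_to_zero_based(snp.pos), genes, flank
        )
    return annotated


def join_associations(annotated, records) -> list[AnnotatedSNP]:
    """Exact-match join on rsID; duplicates deduplicated preserving order."""
    eqtl: dict[str, list[str]] = {}
    gwas: dict[str, list[str]] = {}
    for rec in records:
        table = eqtl if rec.kind == "eQTL" else gwas
        bucket = table.setdefault(rec.rsid, [])
        if rec.payload and rec.payload not in bucket:
            bucket.append(rec.payload)
    for a in annotated:
        rsid = a.call.count.snp.rsid
        a.eqtl_genes = list(eqtl.get(rsid, [])) if rsid else []
        a.gwas_traits = list(gwas.get(rsid, [])) if rsid else []
    return annotated


def annotate_calls(
    calls: list[ASBCall],
    *,
    ccres=None,
    genes: list[GeneModel] | None = None,
    associations=None,
    flank: int = DEFAULT_FLANK,
) -> list[AnnotatedSNP]:
    """Wrap calls and apply whichever annotation layers were supplied."""
    annotated = [AnnotatedSNP(call=c) for c in calls]
    if ccres is not None:
        annotate_ccre(annotated, ccres)
    if genes is not None:
        annotate_region(annotated, genes, flank)
    if associations is not None:
        join_associations(annotated, associations)
    return annotated


def chromosome_distribution(
    calls: list[ASBCall],
    chrom_lengths: dict[str, int] | None = None,
) -> dict[str, dict]:
    """Position-sorted ASB / non-ASB positions per chromosome.

    The per-group totals across chromosomes equal the input size.
    """
    out: dict[str, dict] = {}
    for c in calls:
        snp = c.count.snp
        entry = out.setdefault(snp.chrom, {"asb": [], "non_asb": [], "length": 0})
        entry["asb" if c.is_asb else "non_asb"].append(snp.pos)
    for chrom, entry in out.items():
        entry["asb"].sort()
        entry["non_asb"].sort()
        observed_max = max(entry["asb"][-1:] + entry["non_asb"][-1:])
        entry["length"] = (
            chrom_lengths.get(chrom, observed_max)
            if chrom_lengths else observed_max
        )
    return out
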