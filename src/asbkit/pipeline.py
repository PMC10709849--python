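"""File-level pipeline steps composed by the CLI.

Each step reads the standard input formats, runs the corresponding
library stage and writes TSV/JSON artifacts into an output directory.
``run_all`` chains the same step functions, so its outputs are identical
to running the subcommands one by one with the same seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from . import io as aio
from .annotation import AnnotatedSNP, annotate_calls
from .counting import filter_counts, restrict_to_peaks
from .detection import (
    ASBCall,
    DetectionConfig,
    DetectionResult,
    FDRCurve,
    OverdispersionFit,
    call_asb,
)
from .motif import (
    DEFAULT_ALPHA,
    CorrelationResult,
    PairScanResult,
    disruption_profile,
    enrichment_test,
    ratio_score_correlation,
    scan_pair,
    score_pvalue_table,
)
from .report import ReportBundle, render_report, write_calls_tsv
from .types import AlleleCount


def _snp_key(snp) -> str:
    return snp.rsid or f"{snp.chrom}:{snp.pos}"


# ---------------------------------------------------------------------------
# detect

def step_detect(
    counts_tsv: str | Path,
    out_dir: str | Path,
    *,
    peaks_bed: str | Path | None = None,
    fdr_target: float = 0.10,
    min_total: int = 6,
    n_sim_rounds: int = 10,
    seed: int = 0,
    rho_fixed: float | None = None,
) -> DetectionResult:
    """Counts table -> filtered counts -> ASB calls (+ sidecars)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = aio.read_counts_tsv(counts_tsv)
    if peaks_bed is not None:
        counts = restrict_to_peaks(counts, aio.parse_intervals(peaks_bed))
    counts = filter_counts(counts, min_total)
    cfg = DetectionConfig(
        fdr_target=fdr_target, n_sim_rounds=n_sim_rounds, seed=seed,
        rho_fixed=rho_fixed,
    )
    result = call_asb(counts, cfg)
    bundle = ReportBundle("sample", result, [])
    write_calls_tsv(bundle, out_dir / "calls.tsv")
    from .report import write_detection_json

    write_detection_json(bundle, out_dir / "detection.json")
    return result


def load_detection(out_dir: str | Path) -> DetectionResult:
    """Rebuild a DetectionResult from calls.tsv + detection.json."""
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "detection.json").read_text())
    import pandas as pd

    df = pd.read_csv(out_dir / "calls.tsv", sep="\t",
                     dtype={"chrom": str, "rsid": str})
    df["rsid"] = df["rsid"].fillna("")
    calls = []
    for row in df.itertuples(index=False):
        from .types import HetSNP

        snp = HetSNP(row.chrom, int(row.pos), str(row.rsid), row.ref, row.alt)
        count = AlleleCount(snp, int(row.ref_count), int(row.alt_count))
        calls.append(ASBCall(count, float(row.pvalue), bool(row.is_asb)))
    fit = OverdispersionFit(
        tuple(meta["grid"]), tuple(meta["sse_per_r"]), meta["rho_hat"], 21
    )
    fdr = FDRCurve(
        tuple(meta["fdr_curve"]["thresholds"]),
        tuple(meta["fdr_curve"]["fdr"]),
        meta["chosen_threshold"],
        meta["fdr_target"],
    )
    cfg = DetectionConfig(fdr_target=meta["fdr_target"],
                          n_sim_rounds=meta["n_sim_rounds"],
                          seed=meta["seed"])
    return DetectionResult(calls, fit, fdr, cfg)


# ---------------------------------------------------------------------------
# motif

@dataclass
class MotifStepResult:
    scans: list[PairScanResult]
    enrichment: object | None
    profile: object | None
    corr_asb: CorrelationResult | None
    corr_nonasb: CorrelationResult | None
    in_motif_by_key: dict[str, bool]


def step_motif(
    detection: DetectionResult,
    fasta_path: str | Path,
    pwm_path: str | Path,
    out_dir: str | Path,
    *,
    alpha: float = DEFAULT_ALPHA,
    iterations: int = 10_000,
    seed: int = 0,
) -> MotifStepResult:
    """Scan ref/alt windows of every called SNP and compute motif stats."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pwm = aio.parse_pwm(pwm_path)
    null = score_pvalue_table(pwm)
    snps = [c.count.snp for c in detection.calls]
    pairs = aio.extract_allele_windows(snps, fasta_path)
    by_snp = {p.snp: p for p in pairs}
    counts_by_snp = {c.count.snp: c.count for c in detection.calls}
    asb_scans, nonasb_scans, scans = [], [], []
    for call in detection.calls:
        pair = by_snp.get(call.count.snp)
        if pair is None:
            continue
        res = scan_pair(pair, pwm, null=null, alpha=alpha)
        scans.append(res)
        (asb_scans if call.is_asb else nonasb_scans).append(res)
    enrichment = None
    if asb_scans and len(nonasb_scans) >= len(asb_scans):
        enrichment = enrichment_test(
            asb_scans, nonasb_scans, iterations=iterations, seed=seed
        )
    corr_asb = ratio_score_correlation(
        [(r, counts_by_snp[r.snp]) for r in asb_scans]
    ) if asb_scans else None
    corr_nonasb = ratio_score_correlation(
        [(r, counts_by_snp[r.snp]) for r in nonasb_scans]
    ) if nonasb_scans else None
    profile = disruption_profile(asb_scans, pwm) if asb_scans else None
    # per-SNP scan table
    header = ["chrom", "pos", "rsid", "is_asb", "in_motif", "anchor_offset",
              "anchor_strand", "ref_score", "alt_score", "score_change"]
    rows = []
    is_asb_by_snp = {c.count.snp: c.is_asb for c in detection.calls}
    for r in scans:
        s = r.snp
        rows.append([
            s.chrom, str(s.pos), s.rsid,
            "1" if is_asb_by_snp[s] else "0",
            "1" if r.in_motif else "0",
            str(r.anchor[0]) if r.anchor else "-",
            r.anchor[1] if r.anchor else "-",
            "%.6g" % r.ref_score if r.ref_score is not None else "-",
            "%.6g" % r.alt_score if r.alt_score is not None else "-",
            "%.6g" % r.score_change if r.score_change is not None else "-",
        ])
    with open(out_dir / "scan.tsv", "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    payload: dict = {"correlations": {}}
    for name, corr in (("asb", corr_asb), ("nonasb", corr_nonasb)):
        if corr is not None:
            payload["correlations"][name] = {
                "n": corr.n, "r": corr.r, "pvalue": corr.pvalue,
                "flag": corr.flag,
            }
    if enrichment is not None:
        payload["enrichment"] = {
            "n_asb_in_motif": enrichment.n_asb_in_motif,
            "n_asb_total": enrichment.n_asb_total,
            "n_nonasb_in_motif": enrichment.n_nonasb_in_motif,
            "n_nonasb_total": enrichment.n_nonasb_total,
            "control_mean": enrichment.control_mean,
            "control_sd": enrichment.control_sd,
            "z": enrichment.z,
            "pvalue": enrichment.pvalue,
            "iterations": enrichment.iterations,
            "degenerate_sd": enrichment.degenerate_sd,
        }
    if profile is not None:
        payload["profile"] = {
            "freq_per_position": [float(x) for x in profile.freq_per_position],
            "ic_per_position": [float(x) for x in profile.ic_per_position],
            "pearson_r": profile.pearson_r,
            "pearson_p": profile.pearson_p,
            "consistency_ratio": (
                None if profile.consistency_ratio != profile.consistency_ratio
                else profile.consistency_ratio
            ),
            "flag": profile.flag,
        }
    (out_dir / "motif.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    in_motif = {_snp_key(r.snp): r.in_motif for r in scans}
    return MotifStepResult(scans, enrichment, profile, corr_asb,
                           corr_nonasb, in_motif)


def load_motif(out_dir: str | Path) -> MotifStepResult | None:
    """Rebuild the motif-step summary objects from motif.json + scan.tsv."""
    import numpy as np

    from .motif import DisruptionProfile, EnrichmentResult

    out_dir = Path(out_dir)
    if not (out_dir / "motif.json").exists():
        return None
    payload = json.loads((out_dir / "motif.json").read_text())
    enrichment = None
    if "enrichment" in payload:
        e = payload["enrichment"]
        enrichment = EnrichmentResult(**e)
    profile = None
    if "profile" in payload:
        p = payload["profile"]
        profile = DisruptionProfile(
            np.array(p["freq_per_position"]),
            np.array(p["ic_per_position"]),
            p["pearson_r"], p["pearson_p"],
            float("nan") if p["consistency_ratio"] is None
            else p["consistency_ratio"],
            p["flag"],
        )
    corrs = {}
    for name in ("asb", "nonasb"):
        c = payload["correlations"].get(name)
        corrs[name] = (
            CorrelationResult(c["n"], c["r"], c["pvalue"], c["flag"])
            if c else None
        )
    in_motif: dict[str, bool] = {}
    scan_path = out_dir / "scan.tsv"
    if scan_path.exists():
        with open(scan_path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                key = row["rsid"] or f"{row['chrom']}:{row['pos']}"
                in_motif[key] = row["in_motif"] == "1"
    return MotifStepResult([], enrichment, profile, corrs["asb"],
                           corrs["nonasb"], in_motif)


# ---------------------------------------------------------------------------
# annotate

def step_annotate(
    detection: DetectionResult,
    out_dir: str | Path,
    *,
    ccre_bed: str | Path | None = None,
    genes_gtf: str | Path | None = None,
    eqtl_tsv: str | Path | None = None,
    gwas_tsv: str | Path | None = None,
    flank: int = 5000,
) -> list[AnnotatedSNP]:
    """Attach cCRE / region / association context and write annotated.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ccres = aio.parse_intervals(ccre_bed) if ccre_bed else None
    genes = aio.parse_gene_models(genes_gtf) if genes_gtf else None
    associations = []
    if eqtl_tsv:
        associations += aio.read_associations(eqtl_tsv, "eQTL")
    if gwas_tsv:
        associations += aio.read_associations(gwas_tsv, "GWAS")
    annotated = annotate_calls(
        detection.calls,
        ccres=ccres,
        genes=genes,
        associations=associations if (eqtl_tsv or gwas_tsv) else None,
        flank=flank,
    )
    from .report import write_annotated_tsv

    bundle = ReportBundle("sample", detection, annotated)
    write_annotated_tsv(bundle, out_dir / "annotated.tsv")
    return annotated


def load_annotated(
    out_dir: str | Path, detection: DetectionResult
) -> list[AnnotatedSNP]:
    """Rebuild annotated SNPs from annotated.tsv, matched to the calls."""
    out_dir = Path(out_dir)
    path = out_dir / "annotated.tsv"
    if not path.exists():
        return [AnnotatedSNP(call=c) for c in detection.calls]
    by_key = {(c.count.snp.chrom, c.count.snp.pos): c
              for c in detection.calls}
    annotated = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            call = by_key[(row["chrom"], int(row["pos"]))]
            annotated.append(AnnotatedSNP(
                call=call,
                ccre_label=row["ccre"],
                ctcf_bound=row["ctcf_bound"] == "1",
                region_label=row["region"],
                eqtl_genes=[g for g in row["eqtl_genes"].split(",") if g],
                gwas_traits=[t for t in row["gwas_traits"].split(",") if t],
            ))
    return annotated


# ---------------------------------------------------------------------------
# report / run-all

def step_report(
    sample_name: str,
    detection: DetectionResult,
    annotated: list[AnnotatedSNP],
    motif_result: MotifStepResult | None,
    out_dir: str | Path,
    *,
    provenance: dict | None = None,
) -> Path:
    bundle = ReportBundle(
        sample_name=sample_name,
        detection=detection,
        annotated=annotated,
        enrichment=motif_result.enrichment if motif_result else None,
        profile=motif_result.profile if motif_result else None,
        correlation_asb=motif_result.corr_asb if motif_result else None,
        correlation_nonasb=motif_result.corr_nonasb if motif_result else None,
        in_motif_by_rsid=motif_result.in_motif_by_key if motif_result else {},
        provenance=provenance or {},
    )
    return render_report(bundle, out_dir)


def run_all(
    counts_tsv: str | Path,
    out_dir: str | Path,
    *,
    sample_name: str = "sample",
    fasta_path: str | Path | None = None,
    pwm_path: str | Path | None = None,
    peaks_bed: str | Path | None = None,
    ccre_bed: str | Path | None = None,
    genes_gtf: str | Path | None = None,
    eqtl_tsv: str | Path | None = None,
    gwas_tsv: str | Path | None = None,
    fdr_target: float = 0.10,
    min_total: int = 6,
    n_sim_rounds: int = 10,
    alpha: float = DEFAULT_ALPHA,
    iterations: int = 10_000,
    seed: int = 0,
) -> Path:
    """The whole pipeline in one call; equals the chained subcommands."""
    out_dir = Path(out_dir)
    detection = step_detect(
        counts_tsv, out_dir, peaks_bed=peaks_bed, fdr_target=fdr_target,
        min_total=min_total, n_sim_rounds=n_sim_rounds, seed=seed,
    )
    motif_result = None
    if fasta_path is not None and pwm_path is not None:
        motif_result = step_motif(
            detection, fasta_path, pwm_path, out_dir,
            alpha=alpha, iterations=iterations, seed=seed,
        )
    annotated = step_annotate(
        detection, out_dir, ccre_bed=ccre_bed, genes_gtf=genes_gtf,
        eqtl_tsv=eqtl_tsv, gwas_tsv=gwas_tsv,
    )
    return step_report(
        sample_name, detection, annotated, motif_result, out_dir,
        provenance={"seed": seed},
    )
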