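"""Per-sample report assembly: navigator table, sidecar files, HTML.

Every number rendered in the HTML is also present in a TSV/JSON sidecar;
sidecars are byte-stable given an identical bundle.  The cytogenetic map
is emitted as a small self-contained SVG embedded in the HTML.
"""

from __future__ import annotations

import html
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotation import AnnotatedSNP, chromosome_distribution
from .detection import DetectionResult
from .motif import CorrelationResult, DisruptionProfile, EnrichmentResult

_NUM_FMT = "%.6g"


def _fmt(x) -> str:
    if x is None:
        return "-"
    if isinstance(x, bool):
        return "YES" if x else "-"
    if isinstance(x, float):
        return _NUM_FMT % x
    return str(x)


@dataclass
class ReportBundle:
    """Everything the per-sample report renders."""

    sample_name: str
    detection: DetectionResult
    annotated: list[AnnotatedSNP]
    enrichment: EnrichmentResult | None = None
    profile: DisruptionProfile | None = None
    correlation_asb: CorrelationResult | None = None
    correlation_nonasb: CorrelationResult | None = None
    in_motif_by_rsid: dict[str, bool] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


NAVIGATOR_COLUMNS = [
    "chrom", "pos", "rsid", "ref", "alt", "ref_count", "alt_count",
    "p.val", "cCRE", "motif", "genome_browser", "variant_viewer",
    "eqtl_genes", "gwas_traits",
]


def summarize_sample(bundle: ReportBundle) -> list[dict[str, str]]:
    """One navigator row per ASB SNP, sorted by ascending imbalance p-value."""
    rows = []
    asb = [a for a in bundle.annotated if a.call.is_asb]
    asb.sort(key=lambda a: (a.call.pvalue, a.call.count.snp.chrom,
                            a.call.count.snp.pos))
    for a in asb:
        snp = a.call.count.snp
        links = a.links
        ccre = a.ccre_label + (", CTCF-bound" if a.ctcf_bound else "")
        in_motif = bundle.in_motif_by_rsid.get(snp.rsid or f"{snp.chrom}:{snp.pos}")
        rows.append({
            "chrom": snp.chrom,
            "pos": str(snp.pos),
            "rsid": snp.rsid or "-",
            "ref": snp.ref_allele,
            "alt": snp.alt_allele,
            "ref_count": str(a.call.count.ref_count),
            "alt_count": str(a.call.count.alt_count),
            "p.val": _fmt(a.call.pvalue),
            "cCRE": ccre,
            "motif": _fmt(bool(in_motif)) if in_motif is not None else "-",
            "genome_browser": links.get("genome_browser", "-"),
            "variant_viewer": links.get("variant_viewer", "-"),
            "eqtl_genes": ",".join(a.eqtl_genes) or "-",
            "gwas_traits": ",".join(a.gwas_traits) or "-",
        })
    return rows


def _write_tsv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_calls_tsv(bundle: ReportBundle, path: Path) -> None:
    header = ["chrom", "pos", "rsid", "ref", "alt", "ref_count", "alt_count",
              "ref_ratio", "pvalue", "is_asb"]
    rows = []
    for call in bundle.detection.calls:
        s = call.count.snp
        rows.append([
            s.chrom, str(s.pos), s.rsid, s.ref_allele, s.alt_allele,
            str(call.count.ref_count), str(call.count.alt_count),
            _fmt(call.count.ref_ratio), _fmt(call.pvalue),
            "1" if call.is_asb else "0",
        ])
    _write_tsv(path, header, rows)


def write_annotated_tsv(bundle: ReportBundle, path: Path) -> None:
    header = ["chrom", "pos", "rsid", "ref", "alt", "ref_count", "alt_count",
              "pvalue", "is_asb", "ccre", "ctcf_bound", "region",
              "eqtl_genes", "gwas_traits"]
    rows = []
    for a in bundle.annotated:
        s = a.call.count.snp
        rows.append([
            s.chrom, str(s.pos), s.rsid, s.ref_allele, s.alt_allele,
            str(a.call.count.ref_count), str(a.call.count.alt_count),
            _fmt(a.call.pvalue), "1" if a.call.is_asb else "0",
            a.ccre_label, "1" if a.ctcf_bound else "0", a.region_label,
            ",".join(a.eqtl_genes), ",".join(a.gwas_traits),
        ])
    _write_tsv(path, header, rows)


def write_enrichment_tsv(bundle: ReportBundle, path: Path) -> None:
    header = ["sample", "ASB_inmotif", "ASB_total", "non-ASB_inmotif",
              "non-ASB_total", "Control_mean", "Control_sd", "Z", "P.Val",
              "degenerate_sd"]
    rows = []
    e = bundle.enrichment
    if e is not None:
        rows.append([
            bundle.sample_name, str(e.n_asb_in_motif), str(e.n_asb_total),
            str(e.n_nonasb_in_motif), str(e.n_nonasb_total),
            _fmt(e.control_mean), _fmt(e.control_sd), _fmt(e.z),
            _fmt(e.pvalue), "1" if e.degenerate_sd else "0",
        ])
    _write_tsv(path, header, rows)


def write_profile_tsv(bundle: ReportBundle, path: Path) -> None:
    header = ["motif_position", "disrupted_freq", "ic_bits"]
    rows = []
    p = bundle.profile
    if p is not None:
        for j, (f, ic) in enumerate(zip(p.freq_per_position,
                                        p.ic_per_position)):
            rows.append([str(j), _fmt(float(f)), _fmt(float(ic))])
    _write_tsv(path, header, rows)


def write_detection_json(bundle: ReportBundle, path: Path) -> None:
    det = bundle.detection
    payload = {
        "rho_hat": det.fit.rho_hat,
        "grid": list(det.fit.grid),
        "sse_per_r": list(det.fit.sse_per_r),
        "fdr_target": det.fdr.target,
        "chosen_threshold": det.fdr.chosen_threshold,
        "fdr_curve": {
            "thresholds": list(det.fdr.thresholds),
            "fdr": list(det.fdr.fdr_at_threshold),
        },
        "n_asb": det.n_asb,
        "n_snps": len(det.calls),
        "seed": det.config.seed,
        "n_sim_rounds": det.config.n_sim_rounds,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def cytogenetic_svg(distribution: dict[str, dict],
                    width: int = 720, row_h: int = 34) -> str:
    """Chromosome ideogram strips with ASB/non-ASB tick marks."""
    chroms = sorted(distribution)
    height = row_h * max(1, len(chroms)) + 30
    max_len = max((d["length"] for d in distribution.values()), default=1) or 1
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" font-family="sans-serif" font-size="11">',
        '<text x="8" y="14">ASB (purple) and non-ASB (orange) SNPs per '
        "chromosome</text>",
    ]
    x0, bar_w = 70, width - 110
    for i, chrom in enumerate(chroms):
        d = distribution[chrom]
        y = 24 + i * row_h
        scale = bar_w / max(d["length"], 1)
        parts.append(f'<text x="8" y="{y + 14}">{html.escape(chrom)}</text>')
        parts.append(
            f'<rect x="{x0}" y="{y + 4}" width="{bar_w}" height="14" '
            'fill="#eeeeee" stroke="#999999"/>'
        )
        for pos in d["non_asb"]:
            x = x0 + pos * scale
            parts.append(f'<line x1="{x:.1f}" y1="{y + 4}" x2="{x:.1f}" '
                         f'y2="{y + 18}" stroke="#e6862c" stroke-width="1"/>')
        for pos in d["asb"]:
            x = x0 + pos * scale
            parts.append(f'<line x1="{x:.1f}" y1="{y + 2}" x2="{x:.1f}" '
                         f'y2="{y + 20}" stroke="#7030a0" stroke-width="1.5"/>')
    parts.append("</svg>")
    return "\n".join(parts)


def _html_table(header: list[str], rows: list[list[str]],
                link_cols: set[str] | None = None) -> str:
    link_cols = link_cols or set()
    out = ["<table border='1' cellspacing='0' cellpadding='3'>", "<tr>"]
    out += [f"<th>{html.escape(h)}</th>" for h in header]
    out.append("</tr>")
    for row in rows:
        out.append("<tr>")
        for h, cell in zip(header, row):
            if h in link_cols and cell.startswith("http"):
                out.append(f'<td><a href="{html.escape(cell)}">link</a></td>')
            else:
                out.append(f"<td>{html.escape(cell)}</td>")
        out.append("</tr>")
    out.append("</table>")
    return "\n".join(out)


def render_report(bundle: ReportBundle, out_dir: str | Path) -> Path:
    """Write the HTML report and all machine-readable sidecars.

    Returns the path of the HTML file.  Two runs on identical bundles
    produce identical sidecars.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_calls_tsv(bundle, out_dir / "calls.tsv")
    write_annotated_tsv(bundle, out_dir / "annotated.tsv")
    write_enrichment_tsv(bundle, out_dir / "enrichment.tsv")
    write_profile_tsv(bundle, out_dir / "profile.tsv")
    write_detection_json(bundle, out_dir / "detection.json")
    (out_dir / "provenance.json").write_text(
        json.dumps(
            {"sample": bundle.sample_name, "asbkit_version": __version__,
             **bundle.provenance},
            indent=2, sort_keys=True,
        ) + "\n"
    )
    nav_rows = summarize_sample(bundle)
    dist = chromosome_distribution(bundle.detection.calls)
    svg = cytogenetic_svg(dist)
    det = bundle.detection
    n_asb = det.n_asb
    body = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>",
        f"<title>ASB report: {html.escape(bundle.sample_name)}</title></head><body>",
        f"<h1>Allele-specific binding report — {html.escape(bundle.sample_name)}</h1>",
        f"<p>{len(det.calls)} SNPs tested; <b>{n_asb} ASB SNPs</b> at "
        f"FDR target {_fmt(det.fdr.target)}; fitted overdispersion "
        f"rho = {_fmt(det.fit.rho_hat)}.</p>",
    ]
    if n_asb == 0:
        body.append("<p><i>Zero ASB SNPs were called in this sample.</i></p>")
    body.append("<h2>Cytogenetic map</h2>")
    body.append(svg)
    if bundle.enrichment is not None:
        e = bundle.enrichment
        body.append("<h2>Motif enrichment</h2>")
        if e.degenerate_sd:
            body.append("<p><b>Degenerate control SD (0):</b> z undefined; "
                        "p-value reported as below machine floor.</p>")
        body.append(_html_table(
            ["ASB_inmotif", "ASB_total", "non-ASB_inmotif", "non-ASB_total",
             "Control_mean", "Control_sd", "Z", "P.Val"],
            [[str(e.n_asb_in_motif), str(e.n_asb_total),
              str(e.n_nonasb_in_motif), str(e.n_nonasb_total),
              _fmt(e.control_mean), _fmt(e.control_sd), _fmt(e.z),
              _fmt(e.pvalue)]],
        ))
    for name, corr in (("ASB", bundle.correlation_asb),
                       ("non-ASB", bundle.correlation_nonasb)):
        if corr is None:
            continue
        body.append(f"<h2>Allele ratio vs motif score change ({name})</h2>")
        if corr.flag:
            body.append(f"<p>Correlation undefined: {html.escape(corr.flag)} "
                        f"(n = {corr.n}).</p>")
        else:
            body.append(f"<p>Pearson r = {_fmt(corr.r)}, "
                        f"p = {_fmt(corr.pvalue)} (n = {corr.n}).</p>")
    if bundle.profile is not None and not bundle.profile.flag:
        p = bundle.profile
        body.append("<h2>Disrupted positions vs conservation</h2>")
        body.append(
            f"<p>Pearson r = {_fmt(p.pearson_r)}, p = {_fmt(p.pearson_p)}; "
            f"consistency ratio = {_fmt(p.consistency_ratio)}.</p>"
        )
    body.append("<h2>ASB SNP navigator</h2>")
    body.append(_html_table(
        NAVIGATOR_COLUMNS,
        [[r[c] for c in NAVIGATOR_COLUMNS] for r in nav_rows],
        link_cols={"genome_browser", "variant_viewer"},
    ))
    body.append("</body></html>")
    html_path = out_dir / "report.html"
    html_path.write_text("\n".join(body) + "\n")
    (out_dir / "cytomap.svg").write_text(svg + "\n")
    return html_path
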