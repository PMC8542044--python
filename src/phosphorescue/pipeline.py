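"""End-to-end orchestration of the phosphoproteome and RNA-seq arms."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .differential_phospho import (
    RegulationThresholds,
    assign_temporal_pattern,
    call_sites,
    export_calls,
    pca_profiles,
)
from .enrichment_network import (
    GeneSetCollection,
    annotate_modules,
    enrichment_to_table,
    hypergeom_enrich,
    mcode_find_modules,
)
from .motif_enrichment import MotifConfig, extract_windows, find_motifs, motifs_to_table
from .phospho_io import (
    QcPolicy,
    apply_qc,
    compute_site_quant,
    summarize_global,
    write_qc_report,
)
from .rnaseq_cascade import (
    CascadeResult,
    CascadeThresholds,
    DeTable,
    ddct,
    ddct_summary,
    log2_expression_ratio,
    median_of_ratios_size_factors,
    run_cascade,
    simple_de,
)


@dataclass
class RunReport:
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    parameters: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    version: str = __version__
    wall_time_s: float = 0.0

    def record(self, stage: str, **counts: Any) -> None:
        if stage in self.stages:
            raise ValueError(f"stage {stage!r} recorded twice")
        self.stages[stage] = counts

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "version": self.version,
                    "wall_time_s": self.wall_time_s,
                    "parameters": self.parameters,
                    "stages": self.stages,
                    "warnings": self.warnings,
                },
                indent=2,
                default=str,
            )
            + "\n"
        )


def _artifact_header(params: dict) -> str:
    return f"# phosphorescue {__version__} " + json.dumps(params, default=str)


def run_phospho_arm(
    records,
    outdir: str | Path,
    timepoints,
    qc_policy: QcPolicy | None = None,
    thresholds: RegulationThresholds | None = None,
    motif_config: MotifConfig | None = None,
    gene_sets: GeneSetCollection | None = None,
    graph=None,
) -> RunReport:
    """QC -> quantification -> regulation calls -> dependence -> temporal
    patterns -> motif discovery, plus optional enrichment and module
    detection when gene sets / a network are supplied.

    Deterministic for fixed inputs; artifacts are written under ``outdir``.
    """
    start = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    qc_policy = qc_policy or QcPolicy()
    thresholds = thresholds or RegulationThresholds()
    motif_config = motif_config or MotifConfig()
    report = RunReport(
        parameters={
            "qc": vars(qc_policy),
            "thresholds": vars(thresholds),
            "motifs": vars(motif_config),
        }
    )

    kept, qc_report = apply_qc(records, qc_policy)
    write_qc_report(qc_report, outdir / "qc_report.json")
    report.record("qc", n_input=len(records), n_kept=len(kept))
    if not kept:
        report.warnings.append("no records passed QC; downstream outputs empty")

    quants = []
    for rec in kept:
        try:
            quants.append(compute_site_quant(rec))
        except ValueError:
            report.warnings.append(f"site {rec.site_id}: no quantifiable ratios")
    report.record("quant", n_quantified=len(quants))
    summary = summarize_global(kept, quants)
    (outdir / "global_summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    calls = call_sites(quants, timepoints, thresholds)
    patterns = {}
    by_site: dict[str, list] = {}
    for c in calls:
        by_site.setdefault(c.site_id, []).append(c)
    for site_id, site_calls in by_site.items():
        patterns[site_id] = assign_temporal_pattern(site_calls, timepoints)
    calls_df = export_calls(calls, patterns, outdir / "regulation_calls.tsv")
    class_counts = (
        calls_df.groupby(["timepoint", "direction", "dependence"])
        .size()
        .reset_index(name="n")
    )
    class_counts.to_csv(outdir / "class_counts.tsv", sep="\t", index=False)
    report.record(
        "calls",
        n_calls=len(calls),
        n_regulated=int((calls_df["direction"] != "ns").sum()),
        n_dependent=int(calls_df["dependence"].isin(["inhibited", "rescued"]).sum()),
    )

    # PCA of mean log2 ratio profiles: samples are (arm, timepoint)
    if quants:
        site_ids = [q.site_id for q in quants]
        rows, labels = [], []
        for arm, attr in (("T", "mean_log2r_T"), ("TN", "mean_log2r_TN")):
            for tp in timepoints:
                rows.append([getattr(q, attr).get(tp, np.nan) for q in quants])
                labels.append(f"{arm}_{tp}")
        mat = np.array(rows)
        try:
            coords, explained = pca_profiles(mat)
            pd.DataFrame(
                {"sample": labels, "pc1": coords[:, 0], "pc2": coords[:, 1]}
            ).to_csv(outdir / "pca_coordinates.tsv", sep="\t", index=False)
            report.record("pca", explained_pc1=float(explained[0]))
        except ValueError as exc:
            report.warnings.append(f"pca skipped: {exc}")

    # motif discovery: foreground = up + inhibited at the last timepoint
    late_tp = timepoints[-1]
    fg_ids = {
        c.site_id
        for c in calls
        if c.timepoint == late_tp and c.direction == "up" and c.dependence == "inhibited"
    }
    fg = extract_windows(r.window for r in kept if r.site_id in fg_ids)
    bg = extract_windows(r.window for r in kept)
    motifs = find_motifs(fg, bg, motif_config) if fg else []
    motifs_to_table(motifs).to_csv(outdir / "motifs.tsv", sep="\t", index=False)
    report.record("motifs", n_foreground=len(fg), n_motifs=len(motifs))

    dep_site_ids = {
        c.site_id for c in calls if c.dependence in ("inhibited", "rescued")
    }
    dep_genes = sorted({r.gene for r in kept if r.site_id in dep_site_ids})
    if gene_sets is not None and dep_genes:
        rows = hypergeom_enrich(dep_genes, gene_sets)
        enrichment_to_table(rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        report.record("enrichment", n_terms_tested=len(rows))
    if graph is not None:
        modules = mcode_find_modules(graph)
        mod_rows = [
            {
                "module_id": f"module{i}",
                "score": m.mcode_score,
                "density": m.density,
                "n_nodes": len(m.nodes),
                "nodes": ";".join(sorted(m.nodes)),
            }
            for i, m in enumerate(modules)
        ]
        pd.DataFrame(
            mod_rows, columns=["module_id", "score", "density", "n_nodes", "nodes"]
        ).to_csv(outdir / "modules.tsv", sep="\t", index=False)
        report.record("mcode", n_modules=len(modules))
        if gene_sets is not None and modules:
            annotated = annotate_modules(modules, gene_sets)
            pd.DataFrame(
                [
                    {
                        "module_id": f"module{i}",
                        "top_term": row.term_id if row else "",
                        "p_adjusted": row.p_adjusted if row else float("nan"),
                    }
                    for i, (m, row) in enumerate(annotated)
                ]
            ).to_csv(outdir / "module_annotation.tsv", sep="\t", index=False)

    report.wall_time_s = time.time() - start
    report.to_json(outdir / "phospho_run_report.json")
    return report


def run_rnaseq_arm(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    outdir: str | Path,
    thresholds: CascadeThresholds | None = None,
    external_de: DeTable | None = None,
    qpcr_ct: pd.DataFrame | None = None,
) -> tuple[RunReport, CascadeResult]:
    """Normalization -> DE (internal or external) -> panel ratios -> cascade
    -> optional qPCR cross-check."""
    start = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = thresholds or CascadeThresholds()
    report = RunReport(parameters={"cascade": vars(thresholds)})

    factors = median_of_ratios_size_factors(counts)
    factors.to_frame().to_csv(outdir / "size_factors.tsv", sep="\t")
    report.record("normalize", n_samples=len(factors))

    def _samples(genotype, treatment):
        mask = (sample_sheet["genotype"] == genotype) & (
            sample_sheet["treatment"] == treatment
        )
        return list(sample_sheet.index[mask])

    if external_de is not None:
        de = external_de
        report.record("de", source="external", n_genes=len(de.table))
    else:
        de = simple_de(
            counts,
            _samples("WT", "TSZ"),
            _samples("WT", "vehicle"),
            contrast="WT TSZ vs WT vehicle",
        )
        report.record("de", source="internal", n_genes=len(de.table))
    de.table.to_csv(outdir / "de_table.tsv", sep="\t")

    ratios = {}
    for label, (ga, gb) in {
        "ko_vs_wt": ("KO", "WT"),
        "d_vs_wt": ("S473D", "WT"),
        "d_vs_a": ("S473D", "S473A"),
    }.items():
        ratios[label] = log2_expression_ratio(
            counts, sample_sheet, ga, gb, "TSZ", size_factors=factors
        )
    pd.DataFrame(ratios).to_csv(outdir / "panel_log2_ratios.tsv", sep="\t")

    result = run_cascade(
        de,
        ratios["ko_vs_wt"].to_dict(),
        ratios["d_vs_wt"].to_dict(),
        ratios["d_vs_a"].to_dict(),
        thresholds,
    )
    for stage in ("s1_up", "s1_down", "s2", "s3", "s4", "s5"):
        genes = sorted(getattr(result, stage))
        (outdir / f"cascade_{stage}.txt").write_text("\n".join(genes) + "\n")
    (outdir / "cascade_counts.json").write_text(
        json.dumps(result.counts, indent=2) + "\n"
    )
    report.record("cascade", **result.counts)

    if qpcr_ct is not None:
        per_rep = ddct(qpcr_ct)
        per_rep.to_csv(outdir / "qpcr_ddct.tsv", sep="\t", index=False)
        ddct_summary(per_rep).to_csv(outdir / "qpcr_summary.tsv", sep="\t", index=False)
        report.record("qpcr", n_genes=per_rep["gene"].nunique())

    report.wall_time_s = time.time() - start
    report.to_json(outdir / "rnaseq_run_report.json")
    return report, result
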