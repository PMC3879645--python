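"""End-to-end orchestration: QC -> anchor-PCA correction -> DMPs -> DMRs ->
BPT correlation, with a run manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from . import cognition, dmp, dmr, io, pca, preprocess
from .datatypes import InputError, QCData


@dataclass
class PipelineConfig:
    """Thresholds and knobs for one pipeline run (defaults follow the study)."""

    seed: int = 0
    detection_p: float = 0.01
    min_beads: int = 3
    fdr: float = 0.01
    min_delta: float = 0.10
    corr_fdr: float = 0.01
    min_range: float = 0.10
    group_p: float = 0.05
    allsample_filter_p: float = 0.05
    min_abs_association: float = 0.8
    maxgap: int = 500
    window: int = 3
    cutoff: float = 0.10
    n_permutations: int = 250
    scale: str = "beta"                   # PCA/subtraction scale: "beta" or "m"
    epsilon: float = 1e-6
    allow_uncorrected: bool = False       # proceed without PCA correction if no tissue PC
    enrichment_chromosome: str = "chr21"

    def validate(self) -> None:
        if self.scale not in ("m", "beta"):
            raise InputError("scale must be 'm' or 'beta'")
        for name in ("detection_p", "fdr", "min_delta", "corr_fdr", "min_range",
                     "group_p", "allsample_filter_p", "min_abs_association", "cutoff"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InputError(f"{name} must lie in [0, 1], got {v}")
        if self.window < 1 or self.window % 2 == 0:
            raise InputError("window must be odd and >= 1")
        if self.maxgap < 1 or self.n_permutations < 1:
            raise InputError("maxgap and n_permutations must be positive")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything a run produces, plus the manifest."""

    filter_report: Any
    corrected: Any
    test_result: Any
    dmps: Any
    regions: list
    bh_dmp_ids: list
    bpt_hits: pd.DataFrame
    cohort_summary: dict
    enrichment: dict
    island_test: dict
    tss_summary: dict
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    beta: pd.DataFrame,
    qc: QCData,
    annotation: pd.DataFrame,
    sheet: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs and return all stage outputs."""
    config = config or PipelineConfig()
    config.validate()
    counts: dict[str, int] = {"input_probes": int(beta.shape[0]),
                              "input_samples": int(beta.shape[1])}

    # stage 1: probe QC
    filtered, report = preprocess.filter_probes(
        beta, qc, annotation, detection_p_max=config.detection_p,
        min_beads=config.min_beads,
    )
    counts["probes_after_filter"] = int(filtered.shape[0])

    info = sheet.set_index("sample_id")
    anchor_ids = [s for s in filtered.columns if info.loc[s, "anchor"]]
    target_ids = [s for s in filtered.columns if not info.loc[s, "anchor"]]

    # stage 2: anchor-PCA tissue correction
    if config.scale == "m":
        work = preprocess.beta_to_m(filtered, epsilon=config.epsilon)
    else:
        work = filtered
    corrected = None
    if anchor_ids:
        try:
            corrected = pca.correct_with_anchors(
                work[target_ids], work[anchor_ids], sheet,
                min_abs_association=config.min_abs_association,
            )
        except pca.TissueComponentNotFound:
            if not config.allow_uncorrected:
                raise
    if corrected is not None:
        corrected_work = corrected.values
    else:
        corrected_work = work[target_ids]
    if config.scale == "m":
        m_corr = corrected_work
        beta_corr = preprocess.m_to_beta(corrected_work)
    else:
        beta_corr = corrected_work.clip(0, 1)
        m_corr = preprocess.beta_to_m(beta_corr, epsilon=config.epsilon)
    counts["probes_into_tests"] = int(m_corr.shape[0])

    # stage 3: moderated t DMP calling + diagnostics
    groups = info.loc[target_ids, "group"]
    result = dmp.moderated_ttest(m_corr, beta_corr, groups)
    dmps = dmp.call_dmps(result, fdr=config.fdr, min_delta=config.min_delta)
    ann_used = annotation.loc[m_corr.index]
    oddsratio, fisher_p, fisher_table = dmp.chromosome_enrichment(
        dmps, ann_used, chromosome=config.enrichment_chromosome
    )
    enrichment = {
        "chromosome": config.enrichment_chromosome,
        "odds_ratio": oddsratio,
        "p": fisher_p,
        "table": fisher_table.to_dict(),
    }
    island = (
        dmp.island_class_test(dmps, ann_used)
        if dmps.probe_ids
        else {"statistic": float("nan"), "p": float("nan"), "df": 3}
    )
    tss_table, tss_summary = dmp.tss_distance_summary(dmps, ann_used)
    counts["n_dmps"] = len(dmps.probe_ids)

    # stage 4: bump hunting
    ann_sorted = ann_used.sort_values(["chromosome", "position"])
    clusters = dmr.cluster_probes(ann_sorted, maxgap=config.maxgap)
    smoothed = dmr.smooth_effects(
        result.table["delta_beta"].reindex(ann_sorted.index), clusters,
        window=config.window,
    )
    regions = dmr.find_bumps(smoothed, clusters, ann_sorted, cutoff=config.cutoff)
    regions = dmr.permutation_region_p(
        beta_corr, groups, regions, clusters, B=config.n_permutations,
        seed=config.seed, cutoff=config.cutoff, window=config.window,
    )
    bh_dmp_ids = dmr.intersect_dmps_dmrs(dmps, regions, ann_used)
    counts["n_dmrs"] = len(regions)
    counts["n_bh_dmps"] = len(bh_dmp_ids)

    # stage 5: cognition correlation + cohort summary
    bpt_hits = cognition.call_bpt_probes(
        beta_corr, sheet, dmps, fdr=config.corr_fdr, min_range=config.min_range,
        group_p=config.group_p, allsample_filter_p=config.allsample_filter_p,
    )
    counts["n_bpt_hits"] = int(len(bpt_hits))
    summary = cognition.descriptive_stats(sheet)

    manifest = {
        "version": __version__,
        "config_hash": config.content_hash(),
        "config": asdict(config),
        "stage_counts": counts,
        "pca": corrected.provenance if corrected is not None else None,
    }
    return PipelineResult(
        filter_report=report,
        corrected=corrected,
        test_result=result,
        dmps=dmps,
        regions=regions,
        bh_dmp_ids=bh_dmp_ids,
        bpt_hits=bpt_hits,
        cohort_summary=summary,
        enrichment=enrichment,
        island_test=island,
        tss_summary=tss_summary,
        manifest=manifest,
    )


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Persist a run bundle as plain-text tables under one directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_filter_report(result.filter_report, outdir / "filter_report.json",
                           exclusion_dir=outdir / "exclusions")
    result.test_result.table.to_csv(outdir / "moderated_t.tsv", sep="\t",
                                    index_label="probe_id", float_format=io.FLOAT_FMT)
    result.dmps.table.to_csv(outdir / "dmps.tsv", sep="\t", index_label="probe_id",
                             float_format=io.FLOAT_FMT)
    (outdir / "dmp_probe_ids.txt").write_text(
        "\n".join(result.dmps.probe_ids) + ("\n" if result.dmps.probe_ids else "")
    )
    dmr.regions_to_frame(result.regions).to_csv(outdir / "dmrs.tsv", sep="\t",
                                                index=False, float_format=io.FLOAT_FMT)
    io.write_dmrs_bed(result.regions, outdir / "dmrs.bed")
    (outdir / "bh_dmp_probe_ids.txt").write_text(
        "\n".join(result.bh_dmp_ids) + ("\n" if result.bh_dmp_ids else "")
    )
    result.bpt_hits.to_csv(outdir / "bpt_hits.tsv", sep="\t", index_label="probe_id",
                           float_format=io.FLOAT_FMT)
    io.write_json(result.cohort_summary, outdir / "cohort_summary.json")
    io.write_json(result.enrichment, outdir / "enrichment.json")
    io.write_json(result.island_test, outdir / "island_class_test.json")
    io.write_json(result.tss_summary, outdir / "tss_summary.json")
    io.write_json(result.manifest, outdir / "manifest.json")
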