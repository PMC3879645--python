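"""Readers and writers for the pipeline's plain-text interchange formats.

Matrices travel as TSV with probes as rows and sample ids as the header;
sample sheets as CSV; the probe annotation and truth tables as TSV; DMRs as
BED (0-based half-open, converted from 1-based inclusive probe positions)
with a TSV sidecar carrying full statistics.  All writers round-trip
losslessly through the matching readers (floats are emitted with 17
significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import FilterReport, QCData

FLOAT_FMT = "%.17g"


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id", float_format=FLOAT_FMT)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    sheet["anchor"] = sheet["anchor"].astype(bool)
    sheet["bpt_score"] = pd.to_numeric(sheet["bpt_score"], errors="coerce")
    return sheet


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index_label="probe_id", float_format=FLOAT_FMT)


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="probe_id",
                      dtype={"gene": str, "flags": str}, keep_default_na=False)
    ann["position"] = ann["position"].astype(np.int64)
    ann["tss_distance"] = ann["tss_distance"].astype(np.int64)
    return ann


def write_truth(truth, path_probes: str | Path, path_samples: str | Path,
                path_regions: str | Path) -> None:
    truth.probes.to_csv(path_probes, sep="\t", index_label="probe_id",
                        float_format=FLOAT_FMT)
    truth.contamination.rename_axis("sample_id").to_frame().to_csv(
        path_samples, sep="\t", float_format=FLOAT_FMT
    )
    truth.regions.to_csv(path_regions, sep="\t", index=False, float_format=FLOAT_FMT)


def read_truth(path_probes: str | Path, path_samples: str | Path,
               path_regions: str | Path):
    from .datatypes import TruthTable

    probes = pd.read_csv(path_probes, sep="\t", index_col="probe_id",
                         dtype={"effect_class": str, "region_id": str},
                         keep_default_na=False)
    probes["delta"] = probes["delta"].astype(float)
    probes["slope"] = probes["slope"].astype(float)
    contamination = pd.read_csv(path_samples, sep="\t", index_col="sample_id")[
        "contamination_fraction"
    ]
    regions = pd.read_csv(path_regions, sep="\t")
    return TruthTable(probes=probes, contamination=contamination, regions=regions)


def write_qc(qc: QCData, prefix: str | Path) -> None:
    prefix = Path(prefix)
    write_matrix(qc.detection_p, prefix.with_suffix(".detection_p.tsv"))
    write_matrix(qc.bead_count, prefix.with_suffix(".bead_count.tsv"))
    write_matrix(qc.missing_mask.astype(int), prefix.with_suffix(".missing.tsv"))


def read_qc(prefix: str | Path) -> QCData:
    prefix = Path(prefix)
    return QCData(
        detection_p=read_matrix(prefix.with_suffix(".detection_p.tsv")),
        bead_count=read_matrix(prefix.with_suffix(".bead_count.tsv")),
        missing_mask=read_matrix(prefix.with_suffix(".missing.tsv")).astype(bool),
    )


def write_filter_report(report: FilterReport, path: str | Path,
                        exclusion_dir: str | Path | None = None) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    if exclusion_dir is not None:
        exclusion_dir = Path(exclusion_dir)
        exclusion_dir.mkdir(parents=True, exist_ok=True)
        for category, ids in report.removed_by_category.items():
            (exclusion_dir / f"excluded_{category}.txt").write_text(
                "\n".join(ids) + ("\n" if ids else "")
            )


def write_dmrs_bed(regions, path: str | Path) -> None:
    """BED6: 0-based half-open intervals, score = 1000 * min(1, area)."""
    lines = []
    for i, r in enumerate(regions):
        score = int(round(1000 * min(1.0, r.area)))
        strand = "+" if r.mean_smoothed_effect >= 0 else "-"
        lines.append(
            f"{r.chromosome}\t{r.start - 1}\t{r.end}\tregion{i:03d}\t{score}\t{strand}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def write_pca_model(model, directory: str | Path, include_projections: bool = False) -> None:
    """Serialise a PCAModel as TSV members in one directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"sample_id": model.sample_ids, "mean_profile": model.mean_profile}).to_csv(
        directory / "mean_profile.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    comp = pd.DataFrame(model.components, columns=model.sample_ids)
    comp.insert(0, "variance_fraction", model.variance_fraction)
    comp.to_csv(directory / "components.tsv", sep="\t",
                index_label="component", float_format=FLOAT_FMT)
    if include_projections:
        pd.DataFrame(model.projections, index=pd.Index(model.probe_ids, name="probe_id")).to_csv(
            directory / "projections.tsv", sep="\t", float_format=FLOAT_FMT
        )
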