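"""Probe-level QC filtering and beta <-> M-value transformation.

Filtering mirrors standard 450K practice: measurement failures (detection
p > 0.01 in any sample, missing betas, fewer than three beads), then
sex-chromosome probes, then SNP-assay probes, then probes flagged as
polymorphic at the CpG or cross-reactive.  Categories are applied
sequentially and counted disjointly so the report's total is the plain sum
of the four category counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import FilterReport, InputError, QCData

DETECTION_P_MAX = 0.01
MIN_BEADS = 3


def filter_probes(
    beta: pd.DataFrame,
    qc: QCData,
    annotation: pd.DataFrame,
    detection_p_max: float = DETECTION_P_MAX,
    min_beads: int = MIN_BEADS,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove failing probes and return the filtered matrix plus an accounting
    report.

    A probe falls in category 1 if, in any sample, its detection p-value
    exceeds ``detection_p_max``, its beta is missing, or fewer than
    ``min_beads`` beads contributed; category 2 collects sex-chromosome
    probes; category 3 SNP-assay probes; category 4 polymorphic or
    cross-reactive probes.  Each probe is counted once, in the first category
    that catches it.
    """
    missing_qc = beta.index.difference(qc.detection_p.index)
    if len(missing_qc):
        raise InputError(f"probes absent from QC data: {list(missing_qc[:5])}")
    missing_ann = beta.index.difference(annotation.index)
    if len(missing_ann):
        raise InputError(f"probes absent from annotation: {list(missing_ann[:5])}")

    det = qc.detection_p.loc[beta.index, beta.columns].to_numpy()
    beads = qc.bead_count.loc[beta.index, beta.columns].to_numpy()
    miss = qc.missing_mask.loc[beta.index, beta.columns].to_numpy()
    ann = annotation.loc[beta.index]
    flags = ann["flags"].fillna("")

    cat1 = (
        (det > detection_p_max).any(axis=1)
        | miss.any(axis=1)
        | np.isnan(beta.to_numpy()).any(axis=1)
        | (beads < min_beads).any(axis=1)
    )
    sex = (
        flags.str.contains("sex_chromosome").to_numpy()
        | ann["chromosome"].isin(["chrX", "chrY"]).to_numpy()
    )
    snp = flags.str.contains("snp_probe").to_numpy() | beta.index.str.startswith("rs")
    poly = (
        flags.str.contains("polymorphic").to_numpy()
        | flags.str.contains("cross_reactive").to_numpy()
    )

    cat2 = sex & ~cat1
    cat3 = snp & ~cat1 & ~cat2
    cat4 = poly & ~cat1 & ~cat2 & ~cat3
    removed = cat1 | cat2 | cat3 | cat4
    retained = beta.loc[~removed]

    report = FilterReport(
        removed_detection_missing_bead=int(cat1.sum()),
        removed_sex_chromosome=int(cat2.sum()),
        removed_snp_probes=int(cat3.sum()),
        removed_polymorphic_crossreactive=int(cat4.sum()),
        retained_probe_ids=list(retained.index),
        removed_by_category={
            "detection_missing_bead": list(beta.index[cat1]),
            "sex_chromosome": list(beta.index[cat2]),
            "snp_probes": list(beta.index[cat3]),
            "polymorphic_crossreactive": list(beta.index[cat4]),
        },
    )
    return retained, report


def beta_to_m_array(beta: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """M = log2((beta + eps) / (1 - beta + eps)); eps keeps {0,1} finite."""
    if epsilon < 0:
        raise InputError("epsilon must be non-negative")
    beta = np.asarray(beta, dtype=float)
    if np.nanmin(beta) < 0 or np.nanmax(beta) > 1:
        raise InputError("beta values outside [0, 1]")
    return np.log2((beta + epsilon) / (1.0 - beta + epsilon))


def m_to_beta_array(m: np.ndarray) -> np.ndarray:
    """Inverse logistic map: beta = 2^M / (2^M + 1), evaluated stably."""
    m = np.asarray(m, dtype=float)
    # expit formulated to avoid overflow for large |M|
    out = np.empty_like(m)
    pos = m >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-m[pos]))
    e = np.exp2(m[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def beta_to_m(beta: pd.DataFrame, epsilon: float = 1e-6) -> pd.DataFrame:
    return pd.DataFrame(
        beta_to_m_array(beta.to_numpy(), epsilon), index=beta.index, columns=beta.columns
    )


def m_to_beta(m: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(m_to_beta_array(m.to_numpy()), index=m.index, columns=m.columns)
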