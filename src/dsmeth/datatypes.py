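"""Shared data containers for the methylation pipeline.

Matrices (beta values, M-values, detection p, bead counts) are plain pandas
DataFrames with probes as rows and samples as columns; these dataclasses wrap
the pieces that need to travel together with bookkeeping attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

PROBE_FLAGS = ("snp_probe", "polymorphic", "cross_reactive", "sex_chromosome")
ISLAND_CLASSES = ("HC", "IC", "ICshore", "LC")


class InputError(ValueError):
    """Raised when caller-supplied data violates a precondition."""


@dataclass
class TissueProfileSet:
    """Per-probe baseline methylation for the two source tissues.

    ``divergent_idx`` records which probes were planted as tissue-divergent
    (|buccal - blood| >= 0.2 before clamping), so downstream checks can audit
    the construction.
    """

    probe_ids: list[str]
    buccal_baseline: np.ndarray
    blood_baseline: np.ndarray
    divergent_idx: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.probe_ids)
        if len(self.buccal_baseline) != n or len(self.blood_baseline) != n:
            raise InputError("baseline lengths do not match probe ids")
        for arr in (self.buccal_baseline, self.blood_baseline):
            if np.any((arr < 0) | (arr > 1)):
                raise InputError("tissue baselines must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


@dataclass
class TruthTable:
    """Planted ground truth for a synthetic cohort.

    ``probes`` is indexed by probe_id with columns ``effect_class`` (one of
    null/ds_dmp/ds_dmr_member/cognition), ``delta`` (signed DS - control beta
    difference), ``slope`` (beta change per BPT point) and ``region_id``
    (planted region label, or "" for non-members).  ``contamination`` maps
    sample_id -> blood fraction f in [0, 1].  ``regions`` summarises the
    planted DMRs (one row per region: chromosome, start, end, n_probes).
    """

    probes: pd.DataFrame
    contamination: pd.Series
    regions: pd.DataFrame

    def __post_init__(self) -> None:
        null_rows = self.probes["effect_class"] == "null"
        if np.any(self.probes.loc[null_rows, "delta"] != 0) or np.any(
            self.probes.loc[null_rows, "slope"] != 0
        ):
            raise InputError("null probes must have delta == slope == 0")
        f = self.contamination.to_numpy(dtype=float)
        if np.any((f < 0) | (f > 1)):
            raise InputError("contamination fractions must lie in [0, 1]")

    def true_group_contrast(self, mean_case_bpt: float, control_bpt: float = 100.0) -> pd.Series:
        """Noiseless DS - control group mean difference implied by the truth.

        Group-effect probes contribute their delta; cognition probes differ
        between groups through the slope term because controls sit at the
        reference score.
        """
        return self.probes["delta"] + self.probes["slope"] * (mean_case_bpt - control_bpt)


@dataclass
class QCData:
    """Detection p-values, bead counts and missingness accompanying a beta matrix."""

    detection_p: pd.DataFrame
    bead_count: pd.DataFrame
    missing_mask: pd.DataFrame

    def __post_init__(self) -> None:
        shape = self.detection_p.shape
        if self.bead_count.shape != shape or self.missing_mask.shape != shape:
            raise InputError("QC matrices must share one shape")


@dataclass
class FilterReport:
    """Sequential, disjoint accounting of probe-level QC exclusions.

    Categories are applied in order (a probe is counted once, in the first
    category that catches it): detection/missing/bead failures, sex-chromosome
    probes, SNP-assay probes, polymorphic or cross-reactive probes.
    """

    removed_detection_missing_bead: int
    removed_sex_chromosome: int
    removed_snp_probes: int
    removed_polymorphic_crossreactive: int
    retained_probe_ids: list[str] = field(default_factory=list)
    removed_by_category: dict[str, list[str]] = field(default_factory=dict)

    @property
    def total_removed(self) -> int:
        return (
            self.removed_detection_missing_bead
            + self.removed_sex_chromosome
            + self.removed_snp_probes
            + self.removed_polymorphic_crossreactive
        )

    def to_dict(self) -> dict[str, int]:
        return {
            "removed_detection_missing_bead": self.removed_detection_missing_bead,
            "removed_sex_chromosome": self.removed_sex_chromosome,
            "removed_snp_probes": self.removed_snp_probes,
            "removed_polymorphic_crossreactive": self.removed_polymorphic_crossreactive,
            "total_removed": self.total_removed,
            "retained": len(self.retained_probe_ids),
        }


@dataclass
class PCAModel:
    """Sample-space principal component decomposition of a probe x sample matrix.

    Every probe pattern x_i (a vector over samples) decomposes as
    ``x_i = mean_profile + sum_j projections[i, j] * components[j]``, where the
    mean profile is taken over probes and the components are orthonormal
    vectors over samples, ranked by explained variance.
    """

    sample_ids: list[str]
    probe_ids: list[str]
    mean_profile: np.ndarray          # (n_samples,)
    components: np.ndarray            # (n_components, n_samples), orthonormal rows
    projections: np.ndarray           # (n_probes, n_components)
    variance_fraction: np.ndarray     # (n_components,), non-increasing, sums to 1

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.mean_profile + self.projections @ self.components


@dataclass
class CorrectedMatrix:
    """Matrix with one principal component's contribution subtracted out."""

    values: pd.DataFrame
    removed_component_index: int
    provenance: dict[str, Any] = field(default_factory=dict)


@dataclass
class ModeratedTestResult:
    """Per-probe empirical-Bayes moderated two-group test results.

    ``table`` is indexed by probe_id with columns mean_beta_case,
    mean_beta_control, delta_beta, s2_g, t_mod, df_total, p, q.  ``d0`` and
    ``s0_2`` are the fitted prior degrees of freedom and prior variance
    (``d0`` may be ``inf`` when the variances are exchangeable).
    """

    table: pd.DataFrame
    d0: float
    s0_2: float
    case_label: str
    control_label: str


@dataclass
class DMPSet:
    """Probes passing both the FDR and the |delta beta| thresholds."""

    table: pd.DataFrame  # indexed by probe_id; columns delta_beta, q, direction
    fdr: float
    min_delta: float

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_hyper(self) -> int:
        return int((self.table["direction"] == "hyper").sum())

    @property
    def n_hypo(self) -> int:
        return int((self.table["direction"] == "hypo").sum())


@dataclass
class ProbeCluster:
    """Genomically contiguous probes with inter-probe gaps below maxgap."""

    cluster_id: int
    chromosome: str
    probe_ids: list[str]
    positions: np.ndarray

    @property
    def span(self) -> int:
        return int(self.positions[-1] - self.positions[0])

    def __len__(self) -> int:
        return len(self.probe_ids)


@dataclass
class DMRRegion:
    """A candidate differentially methylated region."""

    chromosome: str
    start: int                      # 1-based inclusive probe positions
    end: int
    probe_ids: list[str]
    mean_smoothed_effect: float
    area: float
    cluster_id: int
    permutation_p: float | None = None

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def validate_beta_matrix(beta: pd.DataFrame) -> None:
    """Check the basic beta-matrix contract (values in [0,1], unique ids)."""
    if beta.index.has_duplicates or beta.columns.has_duplicates:
        raise InputError("duplicated probe or sample identifiers")
    vals = beta.to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or vals.min() < 0 or vals.max() > 1:
        raise InputError("beta values must be finite and lie in [0, 1]")


def validate_sample_sheet(sheet: pd.DataFrame) -> None:
    if sheet["sample_id"].duplicated().any():
        raise InputError("sample_id values must be unique")
    non_anchor = sheet[~sheet["anchor"]]
    if non_anchor["bpt_score"].isna().any():
        raise InputError("bpt_score required for all non-anchor samples")
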