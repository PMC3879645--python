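"""Scoring of pipeline output against a synthetic cohort's planted truth.

These helpers are shared by the test suite and the acceptance script: they
measure sensitivity, empirical FDR, spurious-call rates among
tissue-divergent null probes, per-region Jaccard overlap for planted DMRs,
and recovery of BPT-linked probes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dmp as dmp_mod
from . import preprocess
from .pipeline import PipelineResult
from .synthetic import SyntheticCohort


def _tested_truth(cohort: SyntheticCohort, result: PipelineResult) -> pd.DataFrame:
    return cohort.truth.probes.loc[result.test_result.table.index]


def dmp_metrics(
    cohort: SyntheticCohort, result: PipelineResult, strong_delta: float = 0.15
) -> dict:
    """Sensitivity (|delta| >= strong_delta), empirical FDR, and spurious-call
    count among tissue-divergent null probes, all over the probes that
    survived QC (an unmeasured probe cannot be called)."""
    truth = _tested_truth(cohort, result)
    called = set(result.dmps.probe_ids)
    group_probes = truth[truth["effect_class"].isin(["ds_dmp", "ds_dmr_member"])]
    strong = group_probes[group_probes["delta"].abs() >= strong_delta]
    sensitivity = (
        float(np.mean([p in called for p in strong.index])) if len(strong) else float("nan")
    )
    nulls = set(truth.index[truth["effect_class"] == "null"])
    false_calls = called & nulls
    empirical_fdr = len(false_calls) / len(called) if called else 0.0
    divergent = set(np.asarray(cohort.profiles.probe_ids)[cohort.profiles.divergent_idx])
    spurious_divergent = len(called & nulls & divergent)
    return {
        "n_called": len(called),
        "sensitivity_strong": sensitivity,
        "n_strong_planted": int(len(strong)),
        "empirical_fdr": empirical_fdr,
        "spurious_divergent_calls": spurious_divergent,
        "hyper_fraction": result.dmps.n_hyper / len(called) if called else float("nan"),
    }


def uncorrected_spurious_divergent(
    cohort: SyntheticCohort,
    result: PipelineResult,
    fdr: float = 0.01,
    min_delta: float = 0.10,
) -> int:
    """Spurious DMP calls among tissue-divergent null probes when the
    moderated test runs on the *uncorrected* (contaminated) matrix."""
    tested = result.test_result.table.index
    info = cohort.sheet.set_index("sample_id")
    target = [s for s in cohort.beta.columns if not info.loc[s, "anchor"]]
    beta = cohort.beta.loc[tested, target]
    m = preprocess.beta_to_m(beta)
    groups = info.loc[target, "group"]
    res = dmp_mod.moderated_ttest(m, beta, groups)
    called = set(dmp_mod.call_dmps(res, fdr=fdr, min_delta=min_delta).probe_ids)
    truth = cohort.truth.probes.loc[tested]
    nulls = set(truth.index[truth["effect_class"] == "null"])
    divergent = set(np.asarray(cohort.profiles.probe_ids)[cohort.profiles.divergent_idx])
    return len(called & nulls & divergent)


def dmr_jaccard(cohort: SyntheticCohort, result: PipelineResult) -> dict:
    """Mean per-planted-region Jaccard overlap between planted and called
    probe sets (best-matching called region per planted region)."""
    truth = cohort.truth.probes
    called_sets = [set(r.probe_ids) for r in result.regions]
    scores = []
    for region_id in cohort.truth.regions["region_id"]:
        planted = set(truth.index[truth["region_id"] == region_id])
        planted &= set(result.test_result.table.index)
        if not planted:
            continue
        best = 0.0
        for cs in called_sets:
            inter = len(planted & cs)
            if inter:
                best = max(best, inter / len(planted | cs))
        scores.append(best)
    return {
        "mean_jaccard": float(np.mean(scores)) if scores else float("nan"),
        "n_regions_scored": len(scores),
        "per_region": scores,
    }


def cognition_recovery(cohort: SyntheticCohort, result: PipelineResult) -> dict:
    """Recovery of planted BPT-linked probes by the two-approach calling.

    A call is counted false when the called probe's planted class is not
    "cognition" (probes carrying a planted group effect count as false calls
    for the cognition task even though their corrected values may genuinely
    correlate with the score)."""
    truth = _tested_truth(cohort, result)
    planted = set(truth.index[truth["effect_class"] == "cognition"])
    hits = set(result.bpt_hits.index)
    return {
        "n_planted": len(planted),
        "n_recovered": len(planted & hits),
        "n_false": len(hits - planted),
        "false_classes": truth.loc[sorted(hits - planted), "effect_class"]
        .value_counts()
        .to_dict(),
    }
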