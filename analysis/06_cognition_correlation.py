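#!/usr/bin/env python
"""Probes correlated with the Brief Praxis Test score, and cohort summaries.

Two-approach calling: genome-wide case-only Spearman at BH 0.01 with range
and group-difference filters, the same test restricted to the DMP list, union
taken, then the all-sample correlation filter.  Also reproduces the cohort
descriptive statistics and runs the targeted per-gene analysis on the first
annotated gene carrying planted effects.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dsmeth import cognition, dmp as dmp_mod, io

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    beta_corr = io.read_matrix(ROOT / "scratch" / "beta_corrected.tsv").clip(0, 1)
    sheet = io.read_sample_sheet(ROOT / "scratch" / "cohort" / "samples.csv")
    truth = io.read_truth(
        ROOT / "scratch" / "cohort" / "truth_probes.tsv",
        ROOT / "scratch" / "cohort" / "truth_samples.tsv",
        ROOT / "scratch" / "cohort" / "truth_regions.tsv",
    )
    moderated = pd.read_csv(ROOT / "scratch" / "moderated_t.tsv", sep="\t",
                            index_col="probe_id")
    dmps = dmp_mod.call_dmps(
        dmp_mod.ModeratedTestResult(moderated, d0=np.nan, s0_2=np.nan,
                                    case_label="DS", control_label="control")
    )

    hits = cognition.call_bpt_probes(beta_corr, sheet, dmps)
    hits = hits.join(truth.probes[["effect_class", "slope"]])
    hits.to_csv(ROOT / "results" / "06_bpt_hits.tsv", sep="\t",
                index_label="probe_id", float_format="%.6g")

    planted = set(truth.probes.index[truth.probes["effect_class"] == "cognition"])
    recovered = planted & set(hits.index)
    stats20 = cognition.descriptive_stats(sheet)
    summary = {
        "n_bpt_hits": int(len(hits)),
        "n_planted_cognition": len(planted),
        "n_recovered": len(recovered),
        "n_false": int(len(set(hits.index) - planted)),
        "descriptives": stats20,
    }
    (ROOT / "results" / "06_cognition_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    print(f"{len(hits)} probes called as praxis-correlated "
          f"({len(recovered)}/{len(planted)} planted recovered, "
          f"{summary['n_false']} extra).")
    print(f"Cohort: DS mean age {stats20['case']['mean_age']:.2f} "
          f"(SD {stats20['case']['sd_age']:.2f}), controls "
          f"{stats20['control']['mean_age']:.2f} (SD {stats20['control']['sd_age']:.2f}); "
          f"Welch age p = {stats20['welch_age_p']:.2f}; "
          f"praxis~age Spearman p = {stats20['bpt_age_spearman_p']:.2f}.")


if __name__ == "__main__":
    main()
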