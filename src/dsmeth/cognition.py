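"""Correlation of probe methylation with the Brief Praxis Test (BPT) score.

The calling procedure combines two routes: (1) a genome-wide case-only
two-sided Spearman test at BH FDR 0.01, filtered for a case beta range above
10% and a case-vs-control t-test below 0.05; (2) the same correlation test
restricted to the DMP set, with multiplicity corrected within that subset.
The union is then pruned of probes poorly correlated with BPT when all
(case + control) samples are considered.  Controls all carry the ceiling
score, so the all-sample correlation is heavily tied; average ranks handle
this.  A targeted per-gene mode applies the same machinery with multiplicity
limited to one gene's probes, and cohort descriptive statistics (Welch
t-tests, Spearman of BPT against age) round out the module.
"""

from __future__ import annotations

import warnings
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DMPSet, InputError
from .dmp import bh_adjust

EXACT_N_MAX = 9


def _t_approx_p(rho: float, n: int) -> float:
    """Two-sided p for a rank correlation via the t transform on n-2 df."""
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(
    x: np.ndarray, y: np.ndarray, exact_n_max: int = EXACT_N_MAX
) -> tuple[float, float]:
    """Two-sided Spearman correlation with average-rank ties.

    For n <= ``exact_n_max`` the p-value is exact, by full enumeration of the
    n! rank permutations; otherwise the t approximation on n-2 degrees of
    freedom is used.  A constant vector yields (nan, 1.0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise InputError("x and y must have equal length")
    if n < 3:
        raise InputError("need at least 3 observations")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = _rank_corr(rx, ry)
    if not np.isfinite(rho):
        return float("nan"), 1.0
    if n <= exact_n_max:
        perms = np.array(list(permutations(range(n))))
        ry_perm = ry[perms]                      # n! x n
        rxc = rx - rx.mean()
        ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc**2).sum() * (ryc**2).sum(axis=1))
        rho_null = (ryc @ rxc) / denom
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
    else:
        p = _t_approx_p(rho, n)
    return rho, p


def spearman_matrix(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman of a probes x samples matrix against one covariate
    (t-approximation p-values; constant rows get rho = nan, p = 1)."""
    n = X.shape[1]
    rX = stats.rankdata(X, axis=1)
    ry = stats.rankdata(y)
    rXc = rX - rX.mean(axis=1, keepdims=True)
    ryc = ry - ry.mean()
    sx = np.sqrt((rXc**2).sum(axis=1))
    sy = np.sqrt((ryc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rXc @ ryc) / (sx * sy)
    rho = np.where(sx == 0, np.nan, rho)
    safe = np.clip(np.abs(rho), 0, 1 - 1e-15)
    t = safe * np.sqrt((n - 2) / (1 - safe**2))
    p = np.where(np.isnan(rho), 1.0, 2 * stats.t.sf(t, df=n - 2))
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, p


def _welch_p_rows(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Row-wise Welch t-test p-values (unequal variances)."""
    with warnings.catch_warnings():
        # near-constant rows trip scipy's precision-loss warning; their p is 1
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(X1, X2, axis=1, equal_var=False)
    return np.nan_to_num(res.pvalue, nan=1.0)


def call_bpt_probes(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    dmps: DMPSet,
    fdr: float = 0.01,
    min_range: float = 0.10,
    group_p: float = 0.05,
    allsample_filter_p: float = 0.05,
    case_label: str = "DS",
    control_label: str = "control",
) -> pd.DataFrame:
    """Two-approach BPT-correlation calling with range, group and all-sample
    filters; returns one row per surviving probe with provenance
    (approach1 / approach2 / both).
    """
    info = sheet.set_index("sample_id")
    case_ids = [s for s in beta.columns if not info.loc[s, "anchor"]
                and info.loc[s, "group"] == case_label]
    control_ids = [s for s in beta.columns if not info.loc[s, "anchor"]
                   and info.loc[s, "group"] == control_label]
    if len(case_ids) < 3:
        raise InputError("need at least 3 cases for correlation calling")
    bpt_cases = info.loc[case_ids, "bpt_score"].to_numpy(dtype=float)
    if np.all(bpt_cases == bpt_cases[0]):
        raise InputError("BPT score is constant among cases")

    Xc = beta[case_ids].to_numpy(dtype=float)
    rho, p = spearman_matrix(Xc, bpt_cases)
    beta_range = Xc.max(axis=1) - Xc.min(axis=1)
    t_p = _welch_p_rows(Xc, beta[control_ids].to_numpy(dtype=float))

    per_probe = pd.DataFrame(
        {"rho": rho, "p": p, "beta_range_cases": beta_range, "group_t_p": t_p},
        index=beta.index,
    )

    # approach 1: genome-wide, BH over everything tested
    q1 = bh_adjust(per_probe["p"].to_numpy())
    a1 = (q1 <= fdr) & (beta_range > min_range) & (t_p < group_p)

    # approach 2: restricted to the DMP set, BH within that subset
    in_dmps = per_probe.index.isin(set(dmps.probe_ids))
    a2 = np.zeros(len(per_probe), dtype=bool)
    if in_dmps.any():
        q2_sub = bh_adjust(per_probe.loc[in_dmps, "p"].to_numpy())
        pass2 = (
            (q2_sub <= fdr)
            & (beta_range[in_dmps] > min_range)
            & (t_p[in_dmps] < group_p)
        )
        a2[np.flatnonzero(in_dmps)[pass2]] = True

    union = a1 | a2
    result = per_probe.loc[union].copy()
    result["q_approach1"] = q1[union]
    result["provenance"] = np.select(
        [a1[union] & a2[union], a1[union]], ["both", "approach1"], default="approach2"
    )

    # final filter: drop probes poorly correlated over all non-anchor samples
    all_ids = case_ids + control_ids
    bpt_all = info.loc[all_ids, "bpt_score"].to_numpy(dtype=float)
    rho_all, p_all = spearman_matrix(beta.loc[result.index, all_ids].to_numpy(dtype=float), bpt_all)
    result["allsample_rho"] = rho_all
    result["allsample_p"] = p_all
    return result.loc[result["allsample_p"] <= allsample_filter_p]


def targeted_gene_analysis(
    gene: str,
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    sheet: pd.DataFrame,
    t_p: float = 0.05,
    corr_fdr: float = 0.05,
    case_label: str = "DS",
    control_label: str = "control",
) -> pd.DataFrame:
    """Per-probe analysis restricted to one gene: Welch t-test for a group
    difference and case-only Spearman against BPT, BH-corrected within the
    gene's probe set only."""
    probe_ids = annotation.index[annotation["gene"] == gene]
    probe_ids = probe_ids.intersection(beta.index)
    if len(probe_ids) == 0:
        raise InputError(f"no probes annotated to gene {gene!r}")
    info = sheet.set_index("sample_id")
    case_ids = [s for s in beta.columns if not info.loc[s, "anchor"]
                and info.loc[s, "group"] == case_label]
    control_ids = [s for s in beta.columns if not info.loc[s, "anchor"]
                   and info.loc[s, "group"] == control_label]
    sub = beta.loc[probe_ids]
    Xc = sub[case_ids].to_numpy(dtype=float)
    bpt_cases = info.loc[case_ids, "bpt_score"].to_numpy(dtype=float)

    welch = _welch_p_rows(Xc, sub[control_ids].to_numpy(dtype=float))
    rho, p = spearman_matrix(Xc, bpt_cases)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "t_test_p": welch,
            "rho": rho,
            "corr_p": p,
            "corr_q": q,
            "group_different": welch < t_p,
            "bpt_correlated": q <= corr_fdr,
        },
        index=probe_ids,
    )


def descriptive_stats(
    sheet: pd.DataFrame, case_label: str = "DS", control_label: str = "control"
) -> dict:
    """Cohort summary: per-group age statistics, Welch t-tests, and the
    case-only Spearman correlation of BPT with age.

    The score-split comparisons partition the cases into the halves with the
    highest and lowest BPT scores and compare their scores and their ages
    (Welch t, Welch-Satterthwaite df); sample SDs use the n-1 denominator.
    """
    non_anchor = sheet[~sheet["anchor"]]
    cases = non_anchor[non_anchor["group"] == case_label]
    controls = non_anchor[non_anchor["group"] == control_label]
    if len(cases) < 2 or len(controls) < 2:
        raise InputError("each group needs at least 2 samples")

    age_case = cases["age"].to_numpy(dtype=float)
    age_control = controls["age"].to_numpy(dtype=float)
    bpt = cases["bpt_score"].to_numpy(dtype=float)

    welch_age = stats.ttest_ind(age_case, age_control, equal_var=False)
    rho_age, p_age = spearman(bpt, cases["age"].to_numpy(dtype=float), exact_n_max=0)

    ranked = cases.sort_values(["bpt_score", "sample_id"], ascending=[False, True])
    half = len(ranked) // 2
    hi, lo = ranked.head(half), ranked.tail(len(ranked) - half)
    welch_split_score = stats.ttest_ind(
        hi["bpt_score"].astype(float), lo["bpt_score"].astype(float), equal_var=False
    )
    welch_split_age = stats.ttest_ind(
        hi["age"].astype(float), lo["age"].astype(float), equal_var=False
    )

    return {
        "case": {
            "n": int(len(cases)),
            "mean_age": float(age_case.mean()),
            "sd_age": float(age_case.std(ddof=1)),
            "bpt_min": float(bpt.min()),
            "bpt_max": float(bpt.max()),
        },
        "control": {
            "n": int(len(controls)),
            "mean_age": float(age_control.mean()),
            "sd_age": float(age_control.std(ddof=1)),
            "bpt_unique": sorted(set(controls["bpt_score"].astype(float))),
        },
        "welch_age_p": float(welch_age.pvalue),
        "bpt_age_spearman_rho": float(rho_age),
        "bpt_age_spearman_p": float(p_age),
        "bpt_split_score_welch_p": float(welch_split_score.pvalue),
        "bpt_split_age_welch_p": float(welch_split_age.pvalue),
    }
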