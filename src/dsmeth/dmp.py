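"""Group differential methylation: empirical-Bayes moderated t-tests, FDR
control, delta-beta filtering, and enrichment diagnostics.

The per-probe statistic follows the standard moderated-t formulation: the
probe-wise pooled variance s2_g (d_g degrees of freedom) is shrunk toward a
global prior s0^2 with prior degrees of freedom d0,

    s2_tilde = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g),

and the moderated t uses s2_tilde with d0 + d_g degrees of freedom.  d0 and
s0^2 are estimated by moment-matching the log sample variances through
digamma/trigamma identities; when the observed log-variance dispersion is no
larger than expected under a common variance, d0 is infinite and every
s2_tilde equals s0^2.  Tests run on M-values; delta beta is reported on the
beta scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import DMPSet, InputError, ModeratedTestResult


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    trigamma is convex and decreasing, so Newton from the large-y/ small-y
    asymptotic start converges monotonically.
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_variance_prior(
    s2: np.ndarray, df: float, d0: float | None = None
) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from probe-wise sample variances.

    Uses the identities E[log s2] = psi(df/2) - log(df/2) + log sigma^2 and
    Var[log s2] = psi'(df/2) + psi'(d0/2) under the scaled-inverse-chi-square
    prior.  Zero variances are excluded from the fit (they are handled by the
    prior downstream).  A caller-supplied ``d0`` skips its estimation but
    still yields the matching s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise InputError("need at least two positive probe variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = e.mean()
    n = len(e)
    if d0 is None:
        excess = ((e - ebar) ** 2).sum() / (n - 1) - special.polygamma(1, df / 2.0)
        d0 = np.inf if excess <= 0 else 2.0 * trigamma_inverse(excess)
    if np.isinf(d0):
        s0_2 = float(np.exp(ebar))
    else:
        s0_2 = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_2


def moderated_ttest(
    m: pd.DataFrame,
    beta: pd.DataFrame,
    groups: pd.Series,
    case_label: str = "DS",
    control_label: str = "control",
    d0_override: float | None = None,
) -> ModeratedTestResult:
    """Empirical-Bayes moderated two-group comparison on M-values.

    ``groups`` maps sample_id -> group label and must cover every column of
    ``m``.  ``d0_override`` forces the prior degrees of freedom (0 recovers
    the ordinary pooled t, ``inf`` full shrinkage); by default d0 is
    estimated from the data.
    """
    groups = groups.reindex(m.columns)
    if groups.isna().any():
        raise InputError("groups must cover every sample in the matrix")
    case_cols = groups.index[groups == case_label]
    control_cols = groups.index[groups == control_label]
    n1, n2 = len(case_cols), len(control_cols)
    if n1 < 2 or n2 < 2:
        raise InputError("each group needs at least 2 samples")

    M1 = m[case_cols].to_numpy(dtype=float)
    M2 = m[control_cols].to_numpy(dtype=float)
    mean1, mean2 = M1.mean(axis=1), M2.mean(axis=1)
    ss1 = ((M1 - mean1[:, None]) ** 2).sum(axis=1)
    ss2 = ((M2 - mean2[:, None]) ** 2).sum(axis=1)
    df_resid = n1 + n2 - 2
    s2 = (ss1 + ss2) / df_resid

    if d0_override is None:
        d0, s0_2 = fit_variance_prior(s2, df_resid)
    elif d0_override == 0:
        d0, s0_2 = 0.0, float("nan")
    else:
        d0, s0_2 = fit_variance_prior(s2, df_resid, d0=float(d0_override))

    if d0 == 0:
        s2_tilde = s2
        df_total = float(df_resid)
    elif np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    diff = mean1 - mean2
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, diff / se, 0.0)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2 * stats.t.sf(np.abs(t_mod), df=df_total)
    q = bh_adjust(p)

    b1 = beta[case_cols].to_numpy(dtype=float).mean(axis=1)
    b2 = beta[control_cols].to_numpy(dtype=float).mean(axis=1)
    table = pd.DataFrame(
        {
            "mean_beta_case": b1,
            "mean_beta_control": b2,
            "delta_beta": b1 - b2,
            "s2_g": s2,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "q": q,
        },
        index=m.index,
    )
    return ModeratedTestResult(
        table=table, d0=float(d0), s0_2=float(s0_2) if s0_2 == s0_2 else float("nan"),
        case_label=case_label, control_label=control_label,
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dmps(
    result: ModeratedTestResult, fdr: float = 0.01, min_delta: float = 0.10
) -> DMPSet:
    """Probes with q <= fdr and |delta beta| >= min_delta (both inclusive)."""
    tab = result.table
    mask = (tab["q"] <= fdr) & (tab["delta_beta"].abs() >= min_delta)
    hits = tab.loc[mask, ["delta_beta", "t_mod", "p", "q"]].copy()
    hits["direction"] = np.where(hits["delta_beta"] > 0, "hyper", "hypo")
    return DMPSet(table=hits, fdr=fdr, min_delta=min_delta)


def chromosome_enrichment(
    dmps: DMPSet, annotation: pd.DataFrame, chromosome: str = "chr21"
) -> tuple[float, float, pd.DataFrame]:
    """Two-sided Fisher exact test of hit enrichment on one chromosome.

    The background is every annotated (i.e. analyzed) probe.  Returns the
    conditional-MLE odds ratio, the exact p (probability-summation
    definition), and the 2x2 table.  With an empty hit set the test is
    vacuous: p = 1 and the odds ratio is undefined (NaN).
    """
    hit_ids = set(dmps.probe_ids)
    on = annotation["chromosome"] == chromosome
    is_hit = annotation.index.isin(hit_ids)
    a = int((on & is_hit).sum())          # hits on chromosome
    b = int((~on & is_hit).sum())
    c = int((on & ~is_hit).sum())
    d = int((~on & ~is_hit).sum())
    table = pd.DataFrame(
        [[a, b], [c, d]],
        index=["hit", "non_hit"],
        columns=["on_chromosome", "off_chromosome"],
    )
    if a + b == 0:
        return float("nan"), 1.0, table
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b == 0 or c == 0:
        oddsratio = float("inf") if a > 0 else float("nan")
    else:
        oddsratio = float(
            stats.contingency.odds_ratio([[a, b], [c, d]], kind="conditional").statistic
        )
    return oddsratio, float(p), table


def island_class_test(
    dmps: DMPSet,
    annotation: pd.DataFrame,
    classes: tuple[str, ...] = ("HC", "IC", "ICshore", "LC"),
) -> dict:
    """Pearson chi-square of the hits' CpG-island class mix against the array
    background proportions (df = number of classes - 1)."""
    background = annotation["island_class"].value_counts()
    hits = annotation.loc[annotation.index.isin(set(dmps.probe_ids)), "island_class"]
    observed = np.array([int((hits == c).sum()) for c in classes], dtype=float)
    bg = np.array([int(background.get(c, 0)) for c in classes], dtype=float)
    if bg.sum() == 0 or observed.sum() == 0:
        raise InputError("empty background or hit set for island-class test")
    expected = bg / bg.sum() * observed.sum()
    if np.any(expected == 0):
        raise InputError("island class with zero expected count; merge classes first")
    stat, p = stats.chisquare(observed, f_exp=expected)
    return {
        "statistic": float(stat),
        "df": len(classes) - 1,
        "p": float(p),
        "observed": dict(zip(classes, observed.astype(int))),
        "expected": dict(zip(classes, expected)),
        "low_expected_warning": bool(np.any(expected < 5)),
    }


def tss_distance_summary(
    dmps: DMPSet, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Scatter table of (TSS distance, delta beta) for hits plus a monotone
    trend statistic (Spearman of |delta| vs |distance|)."""
    tab = dmps.table.join(annotation[["tss_distance"]], how="left")
    n_missing = int(tab["tss_distance"].isna().sum())
    tab = tab.dropna(subset=["tss_distance"])
    if len(tab) >= 3 and tab["delta_beta"].abs().nunique() > 1:
        rho, p = stats.spearmanr(tab["delta_beta"].abs(), tab["tss_distance"].abs())
    else:
        rho, p = 0.0, 1.0
    summary = {"spearman_rho": float(rho), "p": float(p), "n_missing_distance": n_missing,
               "n": int(len(tab))}
    return tab[["tss_distance", "delta_beta"]], summary
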