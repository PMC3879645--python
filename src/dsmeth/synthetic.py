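"""Synthetic buccal/blood 450K-style cohort generator with planted ground truth.

The generator emulates the statistical structure of a small adult Down syndrome
(DS) buccal-swab methylation study: bimodal beta baselines, a divergent blood
methylome, blood contamination of buccal swabs confounded with the cognitive
phenotype, isolated group-effect probes with a ~2:1 hypermethylation bias,
genomically clustered effect runs (DMR material), and probes whose methylation
tracks a Brief Praxis Test (BPT) score linearly within cases.  Every planted
feature is recorded in a :class:`~dsmeth.datatypes.TruthTable` so recovery can
be scored exactly.

Baselines are drawn from a three-component mixture (low mode ~Beta(2,18), high
mode ~Beta(18,2), 10% intermediate ~Beta(5,5)) whose component labels follow a
Markov chain along the genome (persistence 0.9): neighbouring CpGs on the
array share methylation state, which is what makes multi-probe regions with a
shared-sign effect plantable with headroom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    ISLAND_CLASSES,
    InputError,
    QCData,
    TissueProfileSet,
    TruthTable,
    validate_beta_matrix,
)
from .preprocess import beta_to_m_array, m_to_beta_array

CONTROL_BPT = 100.0

# Verbatim participant table: 10 controls, 10 DS adults with sex, age at
# sampling, and total Brief Praxis Test score (controls all score 100).
_TABLE1_ROWS = [
    ("C1", "control", "F", 30.00, 100),
    ("C2", "control", "M", 28.00, 100),
    ("C3", "control", "F", 45.00, 100),
    ("C4", "control", "M", 47.00, 100),
    ("C5", "control", "M", 33.00, 100),
    ("C6", "control", "F", 30.00, 100),
    ("C7", "control", "F", 38.00, 100),
    ("C8", "control", "M", 30.00, 100),
    ("C9", "control", "M", 29.00, 100),
    ("C10", "control", "F", 35.00, 100),
    ("DS01", "DS", "M", 46.56, 35),
    ("DS02", "DS", "F", 38.40, 80),
    ("DS03", "DS", "F", 30.27, 80),
    ("DS04", "DS", "F", 40.68, 74),
    ("DS05", "DS", "F", 35.69, 76),
    ("DS06", "DS", "M", 29.55, 70),
    ("DS07", "DS", "M", 29.52, 80),
    ("DS08", "DS", "F", 30.38, 78),
    ("DS09", "DS", "M", 32.96, 64),
    ("DS10", "DS", "M", 27.29, 67),
]


def fixture_table1() -> pd.DataFrame:
    """The 20-participant study sample sheet (cases and controls, no anchors)."""
    sheet = pd.DataFrame(
        _TABLE1_ROWS, columns=["sample_id", "group", "sex", "age", "bpt_score"]
    )
    sheet["bpt_score"] = sheet["bpt_score"].astype(float)
    sheet["tissue"] = "buccal"
    sheet["anchor"] = False
    return sheet


def add_anchor_samples(sheet: pd.DataFrame, n_anchors: int = 10, seed: int = 0) -> pd.DataFrame:
    """Append unrelated whole-blood anchor samples (no phenotype scores)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_anchors):
        rows.append(
            {
                "sample_id": f"B{i + 1}",
                "group": "anchor_blood",
                "sex": "M" if i % 2 == 0 else "F",
                "age": float(np.round(rng.uniform(25, 50), 2)),
                "bpt_score": np.nan,
                "tissue": "blood",
                "anchor": True,
            }
        )
    return pd.concat([sheet, pd.DataFrame(rows)], ignore_index=True)


def default_sample_sheet(seed: int = 0, n_anchors: int = 10) -> pd.DataFrame:
    """Study participants plus blood anchors — the default simulation design."""
    return add_anchor_samples(fixture_table1(), n_anchors=n_anchors, seed=seed)


# ---------------------------------------------------------------------------
# tissue profiles and annotation
# ---------------------------------------------------------------------------

def _markov_components(n: int, rng: np.random.Generator,
                       weights=(0.45, 0.45, 0.10), persistence: float = 0.9) -> np.ndarray:
    """Mixture-component labels with genomic persistence (0=low, 1=high, 2=mid)."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    comp = np.empty(n, dtype=np.int64)
    comp[0] = rng.choice(3, p=w)
    stay = rng.random(n) < persistence
    fresh = rng.choice(3, size=n, p=w)
    for i in range(1, n):
        comp[i] = comp[i - 1] if stay[i] else fresh[i]
    return comp


def generate_tissue_profiles(
    n_probes: int,
    tissue_divergent_fraction: float,
    seed: int,
) -> TissueProfileSet:
    """Draw bimodal buccal baselines and a blood methylome diverging on a subset.

    The divergent subset is shifted by a magnitude drawn from U(0.2, 0.6),
    directed away from the nearer boundary so that clamping to [0, 1] never
    erodes the planted |buccal - blood| >= 0.2 separation.
    """
    if n_probes < 100:
        raise InputError("n_probes must be at least 100")
    if not 0 <= tissue_divergent_fraction <= 1:
        raise InputError("tissue_divergent_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    comp = _markov_components(n_probes, rng)
    buccal = np.empty(n_probes)
    buccal[comp == 0] = rng.beta(2, 18, size=int((comp == 0).sum()))
    buccal[comp == 1] = rng.beta(18, 2, size=int((comp == 1).sum()))
    buccal[comp == 2] = rng.beta(5, 5, size=int((comp == 2).sum()))
    buccal = np.clip(buccal, 0.005, 0.995)

    n_div = int(round(tissue_divergent_fraction * n_probes))
    divergent_idx = np.sort(rng.choice(n_probes, size=n_div, replace=False))
    blood = buccal.copy()
    if n_div:
        magnitude = rng.uniform(0.2, 0.6, size=n_div)
        direction = np.where(buccal[divergent_idx] > 0.5, -1.0, 1.0)
        blood[divergent_idx] = np.clip(
            buccal[divergent_idx] + direction * magnitude, 0.0, 1.0
        )
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    return TissueProfileSet(probe_ids, buccal, blood, divergent_idx)


def make_annotation(
    n_probes: int,
    seed: int,
    chr21_fraction: float = 0.01,
    small_gap_prob: float = 0.9,
    flag_rates: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Synthetic probe annotation: chromosome, position, gene, TSS distance,
    CpG-island class and exclusion flags.

    Probes are laid out contiguously per chromosome (chr1..chr22, with chr21
    holding ~1% of probes, echoing its share of the real array) with mostly
    small inter-probe gaps so that gap-clustering yields multi-probe clusters.
    """
    rng = np.random.default_rng(seed)
    if flag_rates is None:
        flag_rates = {
            "sex_chromosome": 0.020,
            "snp_probe": 0.002,
            "polymorphic": 0.030,
            "cross_reactive": 0.030,
        }
    other = (1.0 - chr21_fraction) / 21.0
    weights = np.full(22, other)
    weights[20] = chr21_fraction  # chr21
    counts = rng.multinomial(n_probes, weights)
    chroms = np.repeat([f"chr{i}" for i in range(1, 23)], counts)

    small = rng.random(n_probes) < small_gap_prob
    gaps = np.where(
        small, rng.integers(50, 401, size=n_probes), rng.integers(2000, 20001, size=n_probes)
    )
    positions = np.empty(n_probes, dtype=np.int64)
    start = 0
    for c in range(22):
        stop = start + counts[c]
        positions[start:stop] = 10_000 + np.cumsum(gaps[start:stop])
        start = stop

    genes = []
    gid, left = 0, 0
    for _ in range(n_probes):
        if left == 0:
            gid += 1
            left = int(rng.integers(8, 25))
            named = rng.random() < 0.6
            current = f"GENE{gid:05d}" if named else ""
        genes.append(current)
        left -= 1

    island = rng.choice(ISLAND_CLASSES, size=n_probes, p=[0.31, 0.14, 0.20, 0.35])
    tss = np.round(rng.laplace(0, 20_000, size=n_probes)).astype(np.int64)

    flags = np.array([""] * n_probes, dtype=object)
    for name, rate in flag_rates.items():
        hit = rng.random(n_probes) < rate
        flags[hit] = np.where(
            flags[hit] == "", name, flags[hit] + "," + name
        )

    ann = pd.DataFrame(
        {
            "probe_id": [f"cg{i:08d}" for i in range(n_probes)],
            "chromosome": chroms,
            "position": positions,
            "gene": genes,
            "tss_distance": tss,
            "island_class": island,
            "flags": flags,
        }
    ).set_index("probe_id")
    return ann


# ---------------------------------------------------------------------------
# effect planting
# ---------------------------------------------------------------------------

def _eligible_mask(annotation: pd.DataFrame) -> np.ndarray:
    return (annotation["flags"] == "").to_numpy()


def _runs(ok: np.ndarray, annotation: pd.DataFrame, maxgap: int = 400) -> list[tuple[int, int]]:
    """Maximal index runs of consecutive eligible probes on one chromosome
    with inter-probe gaps <= maxgap.  Returns (start, stop) half-open pairs."""
    chrom = annotation["chromosome"].to_numpy()
    pos = annotation["position"].to_numpy()
    runs = []
    i, n = 0, len(ok)
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i + 1
        while (
            j < n
            and ok[j]
            and chrom[j] == chrom[j - 1]
            and pos[j] - pos[j - 1] <= maxgap
        ):
            j += 1
        runs.append((i, j))
        i = j
    return runs


def plant_effects(
    profiles: TissueProfileSet,
    annotation: pd.DataFrame,
    n_dmp: int = 150,
    hyper_fraction: float = 2190 / 3300,
    n_dmr_regions: int = 10,
    probes_per_region: tuple[int, int] = (5, 30),
    n_cognition: int = 10,
    seed: int = 0,
    sheet: pd.DataFrame | None = None,
    bpt_span: tuple[float, float] = (35.0, 80.0),
    contamination_range: tuple[float, float] = (0.2, 0.5),
    n_contaminated: int = 5,
) -> TruthTable:
    """Plant group effects, DMR runs and cognition-linked probes; assign
    contamination fractions.

    Isolated group-effect probes get a signed delta (positive, i.e. DS-hyper,
    with probability ``hyper_fraction``) of magnitude U(0.10, 0.35).  Each DMR
    region places a shared delta on 5-30 consecutive probes of a run whose
    baselines leave headroom for the chosen sign.  Cognition probes sit at
    intermediate baselines and get a slope such that the implied beta range
    across the case BPT span is U(0.20, 0.30) — large enough that, with
    controls at the reference score of 100, the induced group contrast clears
    the DMP thresholds (the study's cognition hits were themselves DMPs).

    If ``sheet`` is given, the ``n_contaminated`` lowest-BPT cases receive a
    blood fraction drawn from U(*contamination_range*); everyone else, and all
    controls and anchors, get f = 0.
    """
    rng = np.random.default_rng(seed)
    n_probes = profiles.n_probes
    if len(annotation) != n_probes:
        raise InputError("annotation does not cover the profile set")
    if n_dmp + n_cognition + n_dmr_regions * probes_per_region[1] > n_probes:
        raise InputError("requested plantings exceed the number of probes")
    if not 0 <= hyper_fraction <= 1:
        raise InputError("hyper_fraction must lie in [0, 1]")

    buccal = profiles.buccal_baseline
    span = bpt_span[1] - bpt_span[0]
    used = np.zeros(n_probes, dtype=bool)
    eligible = _eligible_mask(annotation)

    effect_class = np.array(["null"] * n_probes, dtype=object)
    delta = np.zeros(n_probes)
    slope = np.zeros(n_probes)
    region_id = np.array([""] * n_probes, dtype=object)
    region_rows = []

    # --- DMR regions on runs with headroom for the drawn sign ---------------
    margin = 0.02
    lo, hi = probes_per_region
    runs = _runs(eligible & ~used, annotation)
    if n_dmr_regions > 0 and not any(r[1] - r[0] >= lo for r in runs):
        raise InputError("no probe run long enough for the requested region size")
    rng.shuffle(runs)
    run_iter = iter(runs)
    placed = 0
    attempts = 0
    while placed < n_dmr_regions:
        attempts += 1
        if attempts > 20 * n_dmr_regions + len(runs):
            raise InputError("could not place all requested DMR regions")
        try:
            a, b = next(run_iter)
        except StopIteration:
            runs = _runs(eligible & ~used, annotation)
            rng.shuffle(runs)
            run_iter = iter(runs)
            continue
        length = int(rng.integers(lo, hi + 1))
        if b - a < length:
            continue
        offset = int(rng.integers(0, b - a - length + 1))
        idx = np.arange(a + offset, a + offset + length)
        sign = 1.0 if rng.random() < hyper_fraction else -1.0
        # headroom on both tissues: the participant's blood carries the same
        # effect, and clamping either tissue would distort the planted truth
        blood = profiles.blood_baseline
        if sign > 0:
            headroom = float((1 - margin - np.maximum(buccal[idx], blood[idx])).min())
        else:
            headroom = float((np.minimum(buccal[idx], blood[idx]) - margin).min())
        if headroom < 0.12:
            continue
        magnitude = rng.uniform(0.10, min(0.35, headroom))
        effect_class[idx] = "ds_dmr_member"
        delta[idx] = sign * magnitude
        used[idx] = True
        name = f"region{placed:03d}"
        region_id[idx] = name
        region_rows.append(
            {
                "region_id": name,
                "chromosome": annotation["chromosome"].iloc[idx[0]],
                "start": int(annotation["position"].iloc[idx[0]]),
                "end": int(annotation["position"].iloc[idx[-1]]),
                "n_probes": length,
                "delta": sign * magnitude,
            }
        )
        placed += 1

    # --- isolated group-effect probes (keep a 2-probe buffer around them) ---
    signs = np.where(rng.random(n_dmp) < hyper_fraction, 1.0, -1.0)
    magnitudes = rng.uniform(0.10, 0.35, size=n_dmp)
    candidates = np.flatnonzero(eligible & ~used)
    rng.shuffle(candidates)
    placed = 0
    blocked = used.copy()
    blood = profiles.blood_baseline
    for cand in candidates:
        if placed >= n_dmp:
            break
        if blocked[max(0, cand - 2): cand + 3].any():
            continue
        s, mag = signs[placed], magnitudes[placed]
        if s > 0:
            head = 1 - margin - max(buccal[cand], blood[cand])
        else:
            head = min(buccal[cand], blood[cand]) - margin
        if head < mag:
            continue
        effect_class[cand] = "ds_dmp"
        delta[cand] = s * mag
        used[cand] = True
        blocked[cand] = True
        placed += 1
    if placed < n_dmp:
        raise InputError("could not place all requested isolated effect probes")

    # --- cognition probes at intermediate baselines -------------------------
    # The case beta range (|slope| * span) is drawn from U(0.25, 0.35) and the
    # baseline window depends on the slope sign, leaving headroom for the full
    # excursion down to the lowest case score: positive slopes push the lowest
    # scorers below baseline, negative ones above.
    ranges = rng.uniform(0.25, 0.35, size=n_cognition)
    cog_signs = np.where(rng.random(n_cognition) < 0.5, 1.0, -1.0)
    chosen = np.empty(n_cognition, dtype=np.int64)
    for i in range(n_cognition):
        if cog_signs[i] > 0:
            window_ok = (buccal >= 0.52) & (buccal <= 0.62) & (blood >= 0.52) & (blood <= 0.98)
        else:
            window_ok = (buccal >= 0.38) & (buccal <= 0.48) & (blood <= 0.48) & (blood >= 0.02)
        pool = np.flatnonzero(eligible & ~used & window_ok)
        if len(pool) == 0:
            raise InputError("not enough intermediate-baseline probes for cognition effects")
        chosen[i] = rng.choice(pool)
        used[chosen[i]] = True
    slope[chosen] = cog_signs * ranges / span
    effect_class[chosen] = "cognition"

    probes = pd.DataFrame(
        {
            "effect_class": effect_class,
            "delta": delta,
            "slope": slope,
            "region_id": region_id,
        },
        index=pd.Index(profiles.probe_ids, name="probe_id"),
    )

    # --- contamination fractions -------------------------------------------
    if sheet is not None:
        contamination = pd.Series(0.0, index=sheet["sample_id"], name="contamination_fraction")
        cases = sheet[(sheet["group"] == "DS") & (~sheet["anchor"])]
        low = cases.sort_values(["bpt_score", "sample_id"]).head(n_contaminated)
        contamination.loc[low["sample_id"]] = rng.uniform(
            *contamination_range, size=len(low)
        )
    else:
        contamination = pd.Series(dtype=float, name="contamination_fraction")

    regions = pd.DataFrame(
        region_rows,
        columns=["region_id", "chromosome", "start", "end", "n_probes", "delta"],
    )
    return TruthTable(probes=probes, contamination=contamination, regions=regions)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    profiles: TissueProfileSet,
    truth: TruthTable,
    sheet: pd.DataFrame,
    noise_sd_m: float = 0.10,
    seed: int = 0,
    detection_fail_rate: float = 2e-5,
    low_bead_rate: float = 2e-5,
    missing_rate: float = 0.0,
) -> tuple[pd.DataFrame, QCData]:
    """Mix tissue baselines, planted effects and contamination into a beta
    matrix, add M-scale Gaussian noise, and fabricate QC matrices.

    For a non-anchor sample with blood fraction f, the noiseless signal is
    ``(1 - f) * buccal_eff + f * blood_eff`` where each tissue's effective
    beta is its baseline plus the sample's planted group delta and BPT slope
    (clamped to [0, 1]): the contaminating blood is the participant's own
    tissue, so it carries the participant's effects, while anchor samples
    (unrelated donors) receive the plain blood baseline.  For null probes the
    mixture reduces to ``(1 - f) * buccal + f * blood`` exactly.  With
    ``noise_sd_m == 0`` the mixture is returned untransformed, exactly linear
    in f.
    """
    if noise_sd_m < 0:
        raise InputError("noise_sd_m must be non-negative")
    if len(truth.probes) != profiles.n_probes:
        raise InputError("truth table does not match the profile set")
    groups = set(sheet["group"])
    if not {"DS", "control"} <= groups:
        raise InputError("sheet must contain DS and control samples")
    rng = np.random.default_rng(seed)

    n_probes = profiles.n_probes
    sample_ids = list(sheet["sample_id"])
    buccal = profiles.buccal_baseline
    blood = profiles.blood_baseline
    delta = truth.probes["delta"].to_numpy()
    slope = truth.probes["slope"].to_numpy()

    values = np.empty((n_probes, len(sample_ids)))
    n_clamped = 0
    for j, row in enumerate(sheet.itertuples(index=False)):
        if row.anchor:
            values[:, j] = blood
            continue
        effect = delta * (row.group == "DS") + slope * (row.bpt_score - CONTROL_BPT)
        buccal_eff = np.clip(buccal + effect, 0.0, 1.0)
        blood_eff = np.clip(blood + effect, 0.0, 1.0)
        n_clamped += int((buccal_eff != buccal + effect).sum())
        n_clamped += int((blood_eff != blood + effect).sum())
        f = float(truth.contamination.get(row.sample_id, 0.0))
        values[:, j] = (1.0 - f) * buccal_eff + f * blood_eff

    if noise_sd_m > 0:
        m = beta_to_m_array(values, epsilon=1e-6)
        m += rng.normal(0.0, noise_sd_m, size=m.shape)
        values = m_to_beta_array(m)

    beta = pd.DataFrame(values, index=pd.Index(profiles.probe_ids, name="probe_id"),
                        columns=sample_ids)
    beta.attrs["n_clamped"] = n_clamped
    validate_beta_matrix(beta)

    shape = values.shape
    detection_p = rng.uniform(0.0, 0.005, size=shape)
    fail = rng.random(shape) < detection_fail_rate
    detection_p[fail] = rng.uniform(0.011, 0.5, size=int(fail.sum()))
    bead = rng.integers(8, 31, size=shape)
    low = rng.random(shape) < low_bead_rate
    bead[low] = rng.integers(1, 3, size=int(low.sum()))
    missing = rng.random(shape) < missing_rate
    qc = QCData(
        detection_p=pd.DataFrame(detection_p, index=beta.index, columns=beta.columns),
        bead_count=pd.DataFrame(bead, index=beta.index, columns=beta.columns),
        missing_mask=pd.DataFrame(missing, index=beta.index, columns=beta.columns),
    )
    return beta, qc


@dataclass
class SyntheticCohort:
    """Everything one simulation produces, bundled for convenience."""

    beta: pd.DataFrame
    qc: QCData
    annotation: pd.DataFrame
    sheet: pd.DataFrame
    truth: TruthTable
    profiles: TissueProfileSet


def simulate_default_cohort(
    seed: int = 0,
    n_probes: int = 20_000,
    tissue_divergent_fraction: float = 0.10,
    n_dmp: int = 150,
    hyper_fraction: float = 2190 / 3300,
    n_dmr_regions: int = 10,
    probes_per_region: tuple[int, int] = (5, 30),
    n_cognition: int = 10,
    noise_sd_m: float = 0.10,
    contaminate: bool = True,
    n_anchors: int = 10,
    **cohort_kwargs,
) -> SyntheticCohort:
    """One-call default study: the packaged participant table + blood anchors, planted
    effects, contamination on the five lowest-BPT cases.

    Sub-seeds for the independent stages are derived from ``seed`` via
    ``numpy`` SeedSequence spawning, so any identical (seed, parameters) pair
    reproduces the cohort bitwise.
    """
    ss = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    profiles = generate_tissue_profiles(n_probes, tissue_divergent_fraction, seed=int(ss[0]))
    annotation = make_annotation(n_probes, seed=int(ss[1]))
    sheet = default_sample_sheet(seed=int(ss[1]), n_anchors=n_anchors)
    truth = plant_effects(
        profiles,
        annotation,
        n_dmp=n_dmp,
        hyper_fraction=hyper_fraction,
        n_dmr_regions=n_dmr_regions,
        probes_per_region=probes_per_region,
        n_cognition=n_cognition,
        seed=int(ss[2]),
        sheet=sheet if contaminate else None,
        n_contaminated=5 if contaminate else 0,
    )
    if not contaminate:
        truth.contamination = pd.Series(0.0, index=sheet["sample_id"],
                                        name="contamination_fraction")
    beta, qc = simulate_cohort(
        profiles, truth, sheet, noise_sd_m=noise_sd_m, seed=int(ss[3]), **cohort_kwargs
    )
    return SyntheticCohort(beta, qc, annotation, sheet, truth, profiles)
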