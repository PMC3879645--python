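"""Bump-hunting detection of differentially methylated regions.

Probes are gap-clustered along each chromosome, per-probe beta-scale group
effects are smoothed within clusters by a centred running mean, and maximal
runs of probes whose smoothed effect clears a cutoff (with a consistent sign)
become candidate regions.  Region significance is assessed by permuting group
labels and comparing each region's area (sum of |smoothed effect| over member
probes) against the null distribution of the per-permutation maximum area,
giving family-wise p-values p = (1 + #{null max >= observed}) / (B + 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

from .datatypes import DMPSet, DMRRegion, InputError, ProbeCluster


def cluster_probes(annotation: pd.DataFrame, maxgap: int = 500) -> list[ProbeCluster]:
    """Greedy gap clustering: a new cluster starts when the chromosome changes
    or the gap to the previous probe exceeds maxgap.

    The annotation must be position-sorted within each chromosome.
    """
    chrom = annotation["chromosome"].to_numpy()
    pos = annotation["position"].to_numpy()
    ids = annotation.index.to_numpy()
    same = chrom[1:] == chrom[:-1]
    if np.any(same & (np.diff(pos) <= 0)):
        raise InputError("annotation positions must be strictly increasing per chromosome")
    breaks = np.flatnonzero(~same | (np.diff(pos) > maxgap)) + 1
    starts = np.concatenate([[0], breaks])
    stops = np.concatenate([breaks, [len(pos)]])
    return [
        ProbeCluster(
            cluster_id=i,
            chromosome=str(chrom[a]),
            probe_ids=list(ids[a:b]),
            positions=pos[a:b].copy(),
        )
        for i, (a, b) in enumerate(zip(starts, stops))
    ]


def _smoothing_matrix(clusters: list[ProbeCluster], window: int, n_probes: int) -> sparse.csr_matrix:
    """Sparse operator applying a truncated centred running mean per cluster.

    Clusters shorter than 3 probes pass through unchanged.
    """
    half = window // 2
    rows, cols, vals = [], [], []
    offset = 0
    for cl in clusters:
        L = len(cl)
        if L < 3 or window == 1:
            for i in range(L):
                rows.append(offset + i)
                cols.append(offset + i)
                vals.append(1.0)
        else:
            for i in range(L):
                a, b = max(0, i - half), min(L, i + half + 1)
                w = 1.0 / (b - a)
                for j in range(a, b):
                    rows.append(offset + i)
                    cols.append(offset + j)
                    vals.append(w)
        offset += L
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n_probes, n_probes))


def smooth_effects(
    delta: pd.Series, clusters: list[ProbeCluster], window: int = 3
) -> pd.Series:
    """Centred running mean of per-probe effects within each cluster (edges
    truncated to the available neighbours)."""
    if window < 1 or window % 2 == 0:
        raise InputError("window must be odd and >= 1")
    order = [pid for cl in clusters for pid in cl.probe_ids]
    vec = delta.reindex(order)
    if vec.isna().any():
        raise InputError("delta does not cover every clustered probe")
    S = _smoothing_matrix(clusters, window, len(order))
    smoothed = pd.Series(S @ vec.to_numpy(dtype=float), index=order, name="smoothed")
    return smoothed.reindex(delta.index)


def _regions_from_vector(
    smoothed: np.ndarray, clusters: list[ProbeCluster], cutoff: float
) -> list[tuple[int, int, int, float]]:
    """(cluster_idx, start_offset, stop_offset, area) for maximal same-sign
    runs with |smoothed| >= cutoff, on the cluster-concatenated vector."""
    out = []
    offset = 0
    for ci, cl in enumerate(clusters):
        L = len(cl)
        seg = smoothed[offset: offset + L]
        state = np.where(seg >= cutoff, 1, np.where(seg <= -cutoff, -1, 0))
        i = 0
        while i < L:
            if state[i] == 0:
                i += 1
                continue
            j = i + 1
            while j < L and state[j] == state[i]:
                j += 1
            out.append((ci, i, j, float(np.abs(seg[i:j]).sum())))
            i = j
        offset += L
    return out


def find_bumps(
    smoothed: pd.Series,
    clusters: list[ProbeCluster],
    annotation: pd.DataFrame,
    cutoff: float = 0.10,
) -> list[DMRRegion]:
    """Candidate regions: within-cluster maximal runs of consecutive probes
    whose smoothed effect is >= cutoff (or <= -cutoff, same sign throughout)."""
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    order = [pid for cl in clusters for pid in cl.probe_ids]
    vec = smoothed.reindex(order).to_numpy(dtype=float)
    regions = []
    for ci, i, j, area in _regions_from_vector(vec, clusters, cutoff):
        cl = clusters[ci]
        member_ids = cl.probe_ids[i:j]
        seg = smoothed.reindex(member_ids).to_numpy(dtype=float)
        regions.append(
            DMRRegion(
                chromosome=cl.chromosome,
                start=int(cl.positions[i]),
                end=int(cl.positions[j - 1]),
                probe_ids=member_ids,
                mean_smoothed_effect=float(seg.mean()),
                area=area,
                cluster_id=cl.cluster_id,
            )
        )
    return regions


def permutation_region_p(
    beta: pd.DataFrame,
    groups: pd.Series,
    regions: list[DMRRegion],
    clusters: list[ProbeCluster],
    B: int = 250,
    seed: int = 0,
    cutoff: float = 0.10,
    window: int = 3,
    case_label: str = "DS",
    control_label: str = "control",
) -> list[DMRRegion]:
    """Attach family-wise permutation p-values to candidate regions.

    Group labels are permuted B times; for each permutation the full pipeline
    (delta beta -> smoothing -> bump formation) is rerun and the maximum
    region area recorded.  Each observed region's p is the fraction of null
    maxima at least as large, with the +1 correction, so p >= 1/(B+1).
    """
    if B < 1:
        raise InputError("need at least one permutation")
    if not regions:
        return regions
    groups = groups.reindex(beta.columns)
    labels = groups.to_numpy()
    keep = np.isin(labels, [case_label, control_label])
    X = beta.loc[:, keep].to_numpy(dtype=float)
    lab = labels[keep]
    n1 = int((lab == case_label).sum())
    n2 = int((lab == control_label).sum())

    order = [pid for cl in clusters for pid in cl.probe_ids]
    Xo = pd.DataFrame(X, index=beta.index).reindex(order).to_numpy(dtype=float)
    S = _smoothing_matrix(clusters, window, len(order))

    rng = np.random.default_rng(seed)
    # contrast weights per permutation: +1/n1 for permuted-case, -1/n2 otherwise
    W = np.empty((Xo.shape[1], B))
    base = np.concatenate([np.full(n1, 1.0 / n1), np.full(n2, -1.0 / n2)])
    for b in range(B):
        W[:, b] = rng.permutation(base)
    null_delta = Xo @ W                      # probes x B
    null_smoothed = S @ null_delta
    null_max = np.zeros(B)
    for b in range(B):
        areas = [a for (_, _, _, a) in _regions_from_vector(null_smoothed[:, b], clusters, cutoff)]
        null_max[b] = max(areas) if areas else 0.0

    for region in regions:
        region.permutation_p = float(
            (1 + int((null_max >= region.area).sum())) / (B + 1)
        )
    return regions


def intersect_dmps_dmrs(
    dmps: DMPSet, regions: list[DMRRegion], annotation: pd.DataFrame
) -> list[str]:
    """DMP probes whose genomic positions fall inside any region's interval on
    the same chromosome (the BH-DMP set)."""
    if not regions or not dmps.probe_ids:
        return []
    ann = annotation.loc[annotation.index.isin(set(dmps.probe_ids))]
    hits: list[str] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chromosome, []).append((r.start, r.end))
    for chrom, intervals in by_chrom.items():
        sub = ann[ann["chromosome"] == chrom]
        if sub.empty:
            continue
        pos = sub["position"].to_numpy()
        inside = np.zeros(len(pos), dtype=bool)
        for start, end in intervals:
            inside |= (pos >= start) & (pos <= end)
        hits.extend(sub.index[inside])
    return sorted(hits)


def regions_to_frame(regions: list[DMRRegion]) -> pd.DataFrame:
    rows = [
        {
            "chromosome": r.chromosome,
            "start": r.start,
            "end": r.end,
            "n_probes": r.n_probes,
            "mean_smoothed_effect": r.mean_smoothed_effect,
            "area": r.area,
            "cluster_id": r.cluster_id,
            "permutation_p": r.permutation_p,
            "probe_ids": ",".join(r.probe_ids),
        }
        for r in regions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome", "start", "end", "n_probes", "mean_smoothed_effect",
            "area", "cluster_id", "permutation_p", "probe_ids",
        ],
    )
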