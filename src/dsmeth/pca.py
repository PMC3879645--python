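"""Anchor-sample PCA decomposition and tissue-component subtraction.

The methylation pattern of probe *i* across samples is a vector x_i that
decomposes as ``x_i = xbar + sum_j a_ij v_j``, where xbar is the mean profile
over probes, the v_j are orthonormal principal components over samples, and
a_ij are per-probe projections.  Adding pure blood "anchor" samples to a
buccal cohort exposes the tissue axis as a dominant component; subtracting
that component from every probe (``x*_i = xbar + sum_{j != k} a_ij v_j``)
removes variation due to blood contamination without dropping probes or
samples.  Components carry no probe standardisation: patterns are only
centred by the mean profile.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy import stats

from .datatypes import CorrectedMatrix, InputError, PCAModel


class TissueComponentNotFound(RuntimeError):
    """No component associates with tissue strongly enough to subtract."""


def fit_pca(m: pd.DataFrame) -> PCAModel:
    """Decompose a probe x sample matrix into sample-space components.

    Equivalent to the eigendecomposition of the second-moment structure of
    centred probe patterns; computed via the thin SVD of the centred matrix.
    Component signs are fixed so each eigenvector's largest-magnitude entry is
    positive.
    """
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise InputError("need at least 2 probes and 2 samples")
    X = m.to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise InputError("matrix contains missing or non-finite values; filter first")
    xbar = X.mean(axis=0)
    Xc = X - xbar
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|entry| of each component positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    projections = U * s * flip[None, :]
    total = float((s**2).sum())
    variance_fraction = s**2 / total if total > 0 else np.zeros_like(s)
    return PCAModel(
        sample_ids=list(m.columns),
        probe_ids=list(m.index),
        mean_profile=xbar,
        components=Vt,
        projections=projections,
        variance_fraction=variance_fraction,
    )


def _point_biserial(scores: np.ndarray, indicator: np.ndarray) -> float:
    if scores.std() == 0 or indicator.std() == 0:
        return np.nan
    return float(np.corrcoef(scores, indicator)[0, 1])


def identify_tissue_pc(
    model: PCAModel,
    sheet: pd.DataFrame,
    min_abs_association: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Find the component whose sample scores separate the tissue labels.

    For every component the point-biserial correlation between its sample
    entries and the blood/buccal indicator is computed; the component with the
    largest |correlation| is returned provided it exceeds the threshold,
    otherwise :class:`TissueComponentNotFound` is raised (subtraction should
    not proceed on a component that does not clearly track tissue).
    """
    tissue = (
        sheet.set_index("sample_id").loc[model.sample_ids, "tissue"] == "blood"
    ).to_numpy(dtype=float)
    if len(np.unique(tissue)) < 2:
        raise InputError("need both tissue labels among the model's samples")
    rows = []
    for j in range(model.n_components):
        r = _point_biserial(model.components[j], tissue)
        rows.append({"component": j, "abs_correlation": abs(r) if np.isfinite(r) else 0.0,
                     "correlation": r})
    table = pd.DataFrame(rows).set_index("component")
    best = int(table["abs_correlation"].idxmax())
    if not table.loc[best, "abs_correlation"] > min_abs_association:
        raise TissueComponentNotFound(
            f"no tissue component detected: max |r| = "
            f"{table['abs_correlation'].max():.3f} <= {min_abs_association}"
        )
    return best, table


def subtract_pc(m: pd.DataFrame, model: PCAModel, k: int) -> CorrectedMatrix:
    """Remove component k's contribution from every probe pattern."""
    if list(m.index) != model.probe_ids or list(m.columns) != model.sample_ids:
        raise InputError("matrix ids/order do not match the fitted model")
    if not 0 <= k < model.n_components:
        raise InputError(f"component {k} out of range")
    X = m.to_numpy(dtype=float)
    corrected = X - np.outer(model.projections[:, k], model.components[k])
    values = pd.DataFrame(corrected, index=m.index, columns=m.columns)
    prov = {
        "removed_component_index": k,
        "removed_variance_fraction": float(model.variance_fraction[k]),
    }
    return CorrectedMatrix(values=values, removed_component_index=k, provenance=prov)


def correct_with_anchors(
    target: pd.DataFrame,
    anchors: pd.DataFrame,
    sheet: pd.DataFrame,
    min_abs_association: float = 0.8,
) -> CorrectedMatrix:
    """Augment the target cohort with anchor columns, subtract the tissue
    component, and return the corrected target matrix.

    Probes absent from either matrix are dropped (and counted in the
    provenance record); anchors are used only to expose the tissue axis and
    their corrected values are discarded.
    """
    if anchors.shape[1] < 2:
        raise InputError("need at least 2 anchor samples")
    common = target.index.intersection(anchors.index)
    dropped = (len(target.index) - len(common)) + (len(anchors.index) - len(common))
    combined = pd.concat([target.loc[common], anchors.loc[common]], axis=1)
    model = fit_pca(combined)
    k, assoc = identify_tissue_pc(model, sheet, min_abs_association)
    corrected = subtract_pc(combined, model, k)
    out = corrected.values[list(target.columns)]
    prov = dict(corrected.provenance)
    prov.update(
        {
            "n_common_probes": int(len(common)),
            "n_probes_dropped": int(dropped),
            "n_anchor_samples": int(anchors.shape[1]),
            "tissue_association": float(assoc.loc[k, "correlation"]),
        }
    )
    return CorrectedMatrix(values=out, removed_component_index=k, provenance=prov)


def pc_covariate_table(model: PCAModel, sheet: pd.DataFrame) -> pd.DataFrame:
    """Associate each component's sample scores with cohort covariates.

    Binary covariates (group, sex) use point-biserial correlation; ordinal
    ones (BPT score, age) use Spearman.  Samples missing a covariate (e.g.
    anchors without BPT) are dropped pairwise; a constant covariate yields an
    undefined (NaN) association rather than an error.
    """
    info = sheet.set_index("sample_id").loc[model.sample_ids]
    covariates = {
        "group": (info["group"] == "DS").astype(float).where(~info["anchor"]),
        "bpt_score": info["bpt_score"].astype(float),
        "age": info["age"].astype(float),
        "sex": (info["sex"] == "M").astype(float),
    }
    kinds = {"group": "pointbiserial", "bpt_score": "spearman",
             "age": "spearman", "sex": "pointbiserial"}
    rows = []
    for j in range(model.n_components):
        scores = pd.Series(model.components[j], index=model.sample_ids)
        for name, cov in covariates.items():
            mask = cov.notna()
            x, y = scores[mask].to_numpy(), cov[mask].to_numpy(dtype=float)
            if len(x) < 3 or np.std(y) == 0 or np.std(x) == 0:
                coef, p = np.nan, np.nan
            elif kinds[name] == "spearman":
                coef, p = stats.spearmanr(x, y)
            else:
                coef = _point_biserial(x, y)
                # two-sided p via the t transform of a Pearson correlation
                n = len(x)
                t = coef * np.sqrt((n - 2) / max(1 - coef**2, 1e-300))
                p = 2 * stats.t.sf(abs(t), df=n - 2)
            rows.append({"component": j, "covariate": name,
                         "coefficient": coef, "p": p})
    return pd.DataFrame(rows)


class LinkageTree(NamedTuple):
    """scipy linkage matrix plus the leaf labels it refers to."""

    linkage: np.ndarray
    labels: list[str]

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Serialise the dendrogram as a Newick string with merge-height branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return walk(tree, tree.dist) + ";"


def hierarchical_cluster(m: pd.DataFrame, method: str = "complete") -> LinkageTree:
    """Agglomerate sample columns by Euclidean distance."""
    if m.shape[1] < 2:
        raise InputError("need at least 2 samples to cluster")
    dists = pdist(m.to_numpy(dtype=float).T, metric="euclidean")
    Z = hierarchy.linkage(dists, method=method)
    return LinkageTree(linkage=Z, labels=list(m.columns))
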