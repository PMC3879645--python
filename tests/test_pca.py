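"""PCA decomposition, tissue-component identification, subtraction identities,
anchor correction, covariate association and clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import cophenet

from dsmeth import pca, preprocess
from dsmeth.datatypes import InputError


def _random_matrix(n_probes, n_samples, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n_probes, n_samples)),
        index=[f"p{i}" for i in range(n_probes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )


class TestFitPCA:
    def test_rank_one_matrix(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=6)
        v /= np.linalg.norm(v)
        c = rng.normal(size=40)
        m = pd.DataFrame(np.outer(c, v), columns=[f"s{j}" for j in range(6)])
        model = pca.fit_pca(m)
        assert model.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(model.variance_fraction[1:] < 1e-12)

    def test_variance_fractions_sum_to_one_and_nonincreasing(self):
        model = pca.fit_pca(_random_matrix(50, 8))
        assert model.variance_fraction.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(model.variance_fraction) <= 1e-15)

    def test_matches_dense_eigendecomposition_oracle(self):
        """Components and projections agree (up to sign) with a brute-force
        eigendecomposition of the sample-space second-moment matrix of
        centred probe patterns."""
        m = _random_matrix(50, 6, seed=4)
        model = pca.fit_pca(m)
        X = m.to_numpy()
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)     # 6x6, ascending
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for j in range(6):
            v_oracle = evecs[:, j]
            dot = float(v_oracle @ model.components[j])
            sign = np.sign(dot) if dot != 0 else 1.0
            np.testing.assert_allclose(model.components[j], sign * v_oracle, atol=1e-8)
            np.testing.assert_allclose(
                model.projections[:, j], sign * (Xc @ v_oracle), atol=1e-8
            )
        np.testing.assert_allclose(
            model.variance_fraction, evals / evals.sum(), atol=1e-12
        )

    def test_reconstruction_identity(self):
        m = _random_matrix(30, 5, seed=2)
        model = pca.fit_pca(m)
        np.testing.assert_allclose(model.reconstruct(), m.to_numpy(), atol=1e-8)

    def test_orthonormal_components(self):
        model = pca.fit_pca(_random_matrix(40, 7, seed=3))
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(model.n_components), atol=1e-10)

    def test_missing_values_rejected(self):
        m = _random_matrix(10, 4)
        m.iloc[0, 0] = np.nan
        with pytest.raises(InputError):
            pca.fit_pca(m)


class TestSubtractPC:
    def test_subtracting_every_component_leaves_mean_profile(self):
        m = _random_matrix(20, 4, seed=5)
        model = pca.fit_pca(m)
        X = m.to_numpy().astype(float)
        for k in range(model.n_components):
            X = X - np.outer(model.projections[:, k], model.components[k])
        np.testing.assert_allclose(X, np.tile(model.mean_profile, (20, 1)), atol=1e-8)

    def test_projection_onto_removed_component_is_zero(self):
        m = _random_matrix(30, 6, seed=6)
        model = pca.fit_pca(m)
        corrected = pca.subtract_pc(m, model, 1)
        resid = corrected.values.to_numpy() - model.mean_profile
        proj = resid @ model.components[1]
        assert np.abs(proj).max() < 1e-10

    def test_subtraction_idempotent(self):
        m = _random_matrix(30, 6, seed=7)
        model = pca.fit_pca(m)
        once = pca.subtract_pc(m, model, 0).values
        model2 = pca.fit_pca(once)
        # refitting on corrected data finds ~zero variance along the removed axis
        overlap = np.abs(model2.components @ model.components[0])
        var_along = float((model2.variance_fraction * overlap**2).sum())
        assert var_along < 1e-8

    def test_variance_bookkeeping(self):
        m = _random_matrix(40, 6, seed=8)
        model = pca.fit_pca(m)
        X = m.to_numpy()
        total_before = float(((X - X.mean(axis=0)) ** 2).sum())
        corrected = pca.subtract_pc(m, model, 0).values.to_numpy()
        total_after = float(((corrected - corrected.mean(axis=0)) ** 2).sum())
        removed = total_before * model.variance_fraction[0]
        assert total_after == pytest.approx(total_before - removed, rel=1e-8)

    def test_id_mismatch_rejected(self):
        m = _random_matrix(10, 4)
        model = pca.fit_pca(m)
        with pytest.raises(InputError):
            pca.subtract_pc(m.iloc[::-1], model, 0)


class TestIdentifyTissuePC:
    def test_default_cohort_tissue_component_found(self, default_cohort):
        c = default_cohort
        info = c.sheet.set_index("sample_id")
        model = pca.fit_pca(c.beta)
        k, table = pca.identify_tissue_pc(model, c.sheet)
        assert table.loc[k, "abs_correlation"] > 0.9

    def test_no_divergence_no_tissue_component(self):
        from dsmeth import synthetic

        c = synthetic.simulate_default_cohort(seed=2, n_probes=1000,
                                              tissue_divergent_fraction=0.0,
                                              n_dmp=20, n_dmr_regions=2,
                                              n_cognition=2)
        model = pca.fit_pca(c.beta)
        with pytest.raises(pca.TissueComponentNotFound):
            pca.identify_tissue_pc(model, c.sheet)

    def test_permuted_labels_rarely_beat_observed(self, default_cohort):
        c = default_cohort
        model = pca.fit_pca(c.beta)
        k, table = pca.identify_tissue_pc(model, c.sheet)
        observed = table["abs_correlation"].max()
        tissue = (c.sheet.set_index("sample_id")
                  .loc[model.sample_ids, "tissue"] == "blood").to_numpy(float)
        rng = np.random.default_rng(0)
        beat = 0
        for _ in range(200):
            perm = rng.permutation(tissue)
            rs = [abs(np.corrcoef(model.components[j], perm)[0, 1])
                  for j in range(model.n_components)
                  if model.components[j].std() > 0]
            beat += max(rs) >= observed
        assert beat <= 10  # >= 95% of permutations fall below the observed value


class TestCorrectWithAnchors:
    def test_identical_tissues_guard(self):
        from dsmeth import synthetic

        c = synthetic.simulate_default_cohort(seed=3, n_probes=1000,
                                              tissue_divergent_fraction=0.0,
                                              n_dmp=10, n_dmr_regions=1,
                                              n_cognition=1)
        info = c.sheet.set_index("sample_id")
        target = [s for s in c.beta.columns if not info.loc[s, "anchor"]]
        anchor = [s for s in c.beta.columns if info.loc[s, "anchor"]]
        with pytest.raises(pca.TissueComponentNotFound):
            pca.correct_with_anchors(c.beta[target], c.beta[anchor], c.sheet)

    def test_probe_intersection_bookkeeping(self):
        m = _random_matrix(1000, 4, seed=9)
        anchors = _random_matrix(1000, 3, seed=10).iloc[:900]
        # probe-varying divergence guarantees a strong separating component
        rng = np.random.default_rng(11)
        anchors = anchors.add(pd.Series(rng.normal(0, 4, 900), index=anchors.index),
                              axis=0)
        sheet = pd.DataFrame(
            {
                "sample_id": list(m.columns) + list(anchors.columns),
                "group": ["DS", "DS", "control", "control"] + ["anchor_blood"] * 3,
                "sex": "M",
                "age": 30.0,
                "bpt_score": [50, 60, 100, 100] + [np.nan] * 3,
                "tissue": ["buccal"] * 4 + ["blood"] * 3,
                "anchor": [False] * 4 + [True] * 3,
            }
        )
        anchors.columns = [f"b{j}" for j in range(3)]
        sheet.loc[4:, "sample_id"] = list(anchors.columns)
        corrected = pca.correct_with_anchors(m, anchors, sheet,
                                             min_abs_association=0.8)
        assert corrected.values.shape == (900, 4)
        assert corrected.provenance["n_probes_dropped"] == 100

    def test_confounded_cluster_separation_vanishes(self, default_cohort):
        """Separation between the contaminated low-BPT cases and the other
        cases along the tissue-associated component drops by far more than
        half after correction."""
        c = default_cohort
        info = c.sheet.set_index("sample_id")
        target = [s for s in c.beta.columns if not info.loc[s, "anchor"]]
        anchor = [s for s in c.beta.columns if info.loc[s, "anchor"]]
        cases = [s for s in target if info.loc[s, "group"] == "DS"]
        low5 = list(info.loc[cases].sort_values("bpt_score").head(5).index)
        rest = [s for s in cases if s not in set(low5)]

        def tissue_separation(tmat):
            combined = pd.concat([tmat, c.beta[anchor].loc[tmat.index]], axis=1)
            model = pca.fit_pca(combined)
            k, _ = pca.identify_tissue_pc(model, c.sheet, min_abs_association=0.5)
            v = pd.Series(model.components[k], index=model.sample_ids)
            return abs(v[low5].mean() - v[rest].mean())

        corrected = pca.correct_with_anchors(c.beta[target], c.beta[anchor], c.sheet)
        before = tissue_separation(c.beta[target])
        after = tissue_separation(corrected.values)
        assert after < 0.5 * before

    def test_correction_moves_contaminated_samples_toward_truth(self, default_cohort):
        """On tissue-divergent probes, the contaminated samples' deviations
        from the probe mean are far closer to their f = 0 ground truth after
        correction.  (Subtraction leaves every probe at its tissue-mixture
        mean level, so raw values carry a per-probe constant offset; group
        contrasts and correlations live in the deviations.)"""
        from dsmeth import synthetic

        c = default_cohort
        clean = synthetic.simulate_default_cohort(seed=0, contaminate=False)
        info = c.sheet.set_index("sample_id")
        target = [s for s in c.beta.columns if not info.loc[s, "anchor"]]
        anchor = [s for s in c.beta.columns if info.loc[s, "anchor"]]
        corrected = pca.correct_with_anchors(c.beta[target], c.beta[anchor], c.sheet)
        contaminated = list(
            c.truth.contamination[c.truth.contamination > 0].index
        )
        divergent = corrected.values.index.intersection(
            np.asarray(c.profiles.probe_ids)[c.profiles.divergent_idx]
        )

        def centered(mat):
            sub = mat.loc[divergent, target]
            return sub.sub(sub.mean(axis=1), axis=0)[contaminated]

        truth_dev = centered(clean.beta)
        mae_before = (centered(c.beta) - truth_dev).abs().mean().mean()
        mae_after = (centered(corrected.values) - truth_dev).abs().mean().mean()
        assert mae_after < 0.25 * mae_before

    def test_too_few_anchors_rejected(self):
        m = _random_matrix(100, 4)
        with pytest.raises(InputError):
            pca.correct_with_anchors(m, m.iloc[:, :1], None)


class TestPCCovariateTable:
    def _sheet(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "sample_id": [f"s{j}" for j in range(n)],
                "group": ["DS"] * (n // 2) + ["control"] * (n - n // 2),
                "sex": rng.choice(["M", "F"], n),
                "age": rng.uniform(25, 50, n),
                "bpt_score": rng.integers(30, 100, n).astype(float),
                "tissue": "buccal",
                "anchor": False,
            }
        )

    def test_group_indicator_eigenvector_gives_unit_association(self):
        sheet = self._sheet()
        indicator = (sheet["group"] == "DS").to_numpy(float)
        v = indicator - indicator.mean()
        v /= np.linalg.norm(v)
        rng = np.random.default_rng(1)
        m = pd.DataFrame(np.outer(rng.normal(size=50), v) , columns=sheet["sample_id"])
        model = pca.fit_pca(m)
        table = pca.pc_covariate_table(model, sheet)
        row = table[(table["component"] == 0) & (table["covariate"] == "group")]
        assert abs(row["coefficient"].iloc[0]) == pytest.approx(1.0, abs=1e-10)

    def test_matches_bruteforce_rank_correlation(self):
        sheet = self._sheet(10, seed=3)
        m = _random_matrix(60, 10, seed=3)
        m.columns = sheet["sample_id"]
        model = pca.fit_pca(m)
        table = pca.pc_covariate_table(model, sheet)
        for j in range(3):
            scores = model.components[j]
            expected_rho = stats.spearmanr(scores, sheet["age"]).statistic
            row = table[(table["component"] == j) & (table["covariate"] == "age")]
            assert row["coefficient"].iloc[0] == pytest.approx(expected_rho, abs=1e-12)

    def test_constant_covariate_reported_as_undefined(self):
        sheet = self._sheet()
        sheet["sex"] = "M"
        m = _random_matrix(30, 10)
        m.columns = sheet["sample_id"]
        table = pca.pc_covariate_table(pca.fit_pca(m), sheet)
        sex_rows = table[table["covariate"] == "sex"]
        assert sex_rows["coefficient"].isna().all()

    def test_null_association_p_uniform(self):
        """Against covariates independent of the data, association p-values
        are uniform (KS at alpha = 0.01)."""
        rng = np.random.default_rng(42)
        pvals = []
        for rep in range(120):
            sheet = self._sheet(20, seed=rep)
            m = pd.DataFrame(rng.normal(size=(40, 20)), columns=sheet["sample_id"])
            table = pca.pc_covariate_table(pca.fit_pca(m), sheet)
            sub = table[table["covariate"].isin(["age", "bpt_score"])]
            pvals.extend(sub["p"].dropna().head(8).tolist())
        ks = stats.kstest(np.asarray(pvals), "uniform")
        assert ks.pvalue > 0.01


class TestHierarchicalCluster:
    def test_identical_samples_merge_at_zero(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [5.0, 9.0]})
        tree = pca.hierarchical_cluster(m)
        assert tree.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_outlier_merges_last(self):
        m = pd.DataFrame({"a": [0.0], "b": [0.1], "c": [100.0]})
        tree = pca.hierarchical_cluster(m)
        # the final merge joins the outlier: its height is the largest distance
        assert tree.linkage[-1, 2] == pytest.approx(100.0, rel=1e-6)

    def test_cophenetic_matches_bruteforce_agglomeration(self):
        """Complete-linkage cophenetic distances on 6 samples match a hand
        agglomeration over explicit cluster sets."""
        m = _random_matrix(12, 6, seed=13)
        tree = pca.hierarchical_cluster(m)
        coph = cophenet(tree.linkage)

        # brute force: merge the closest pair under complete linkage each step
        from itertools import combinations

        points = [m.iloc[:, j].to_numpy() for j in range(6)]
        def complete(c1, c2):
            return max(
                np.linalg.norm(points[i] - points[j]) for i in c1 for j in c2
            )
        clusters = [{j} for j in range(6)]
        expected = np.zeros((6, 6))
        while len(clusters) > 1:
            best = min(
                combinations(range(len(clusters)), 2),
                key=lambda ij: complete(clusters[ij[0]], clusters[ij[1]]),
            )
            i, j = best
            h = complete(clusters[i], clusters[j])
            for a in clusters[i]:
                for b in clusters[j]:
                    expected[a, b] = expected[b, a] = h
            clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)] + [
                clusters[i] | clusters[j]
            ]
        iu = np.triu_indices(6, 1)
        np.testing.assert_allclose(coph, expected[iu], rtol=1e-10)

    def test_newick_roundtrip_leaves(self):
        m = _random_matrix(10, 4, seed=14)
        tree = pca.hierarchical_cluster(m)
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        for label in m.columns:
            assert label in nwk
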