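import numpy as np
import pandas as pd
import pytest
from scipy import linalg
from sklearn.metrics import adjusted_rand_score

from regland import cluster as cl
from regland.counts import NormalizedMatrix, SampleTable
from regland.errors import ParameterError, ValidationError


def sample_table(conds, n_rep=2):
    rows = [(f"{ct}.d{d}.sag{s}.r{r}", ct, s, d, r)
            for ct, d, s in conds for r in range(1, n_rep + 1)]
    return SampleTable(pd.DataFrame(
        rows, columns=["sample_id", "cell_type", "sag_nM", "day",
                       "replicate"]))


def norm_from(values, samples):
    df = pd.DataFrame(values, index=[f"e{i}" for i in
                                     range(np.shape(values)[0])],
                      columns=samples.sample_ids)
    return NormalizedMatrix(df, pd.Series(1.0, index=df.columns), "vst")


CONDS = [("NMP", 3, 0), ("p2", 4, 10), ("p2", 5, 10), ("p3", 4, 500),
         ("p3", 5, 500)]


def profile_fixture(rng, n_per=40, noise=0.05):
    """Five well-separated condition patterns over CONDS, z-scorable."""
    samples = sample_table(CONDS)
    patterns = np.array([
        [1, 0, 0, 0, 0],
        [0, 1, 1, 1, 1],
        [0, 0, 0, 1, 1],
        [0, 0, 1, 0, 1],
        [0, 1, 0, 1, 0],
    ], dtype=float)
    truth = np.repeat(np.arange(5), n_per)
    base = patterns[truth]
    reps = np.repeat(base, 2, axis=1) * 3.0
    vals = reps + rng.normal(0, noise, reps.shape) + 5.0
    return norm_from(vals, samples), samples, truth


class TestBuildProfiles:
    def test_condition_means_before_scaling(self):
        samples = sample_table([("p2", 5, 10), ("p2", 6, 10)])
        norm = norm_from([[2.0, 4.0, 8.0, 10.0]], samples)
        prof = cl.build_profiles(norm, samples, ["e0"])
        assert prof.raw_means.iloc[0].tolist() == [3.0, 9.0]

    def test_constant_row_dropped_with_warning(self, rng):
        samples = sample_table(CONDS)
        vals = np.vstack([rng.normal(size=10), np.full(10, 2.0)])
        norm = norm_from(vals, samples)
        with pytest.warns(UserWarning, match="zero-variance"):
            prof = cl.build_profiles(norm, samples, ["e0", "e1"])
        assert list(prof.dropped) == ["e1"]

    def test_rows_are_z_scored(self, rng):
        norm, samples, _ = profile_fixture(rng)
        prof = cl.build_profiles(norm, samples, norm.values.index)
        assert np.allclose(prof.values.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(prof.values.std(axis=1, ddof=0), 1.0, atol=1e-12)

    def test_empty_selection_errors(self, rng):
        norm, samples, _ = profile_fixture(rng)
        with pytest.raises(ValidationError, match="empty"):
            cl.build_profiles(norm, samples, [])


class TestTwoStageCluster:
    def fit(self, rng, **kw):
        norm, samples, truth = profile_fixture(rng)
        prof = cl.build_profiles(norm, samples, norm.values.index)
        model = cl.two_stage_cluster(prof, k1=kw.pop("k1", 20),
                                     k_final=kw.pop("k_final", 5),
                                     seed=kw.pop("seed", 0), **kw)
        return prof, model, truth

    def test_planted_patterns_recovered_exactly(self, rng):
        _prof, model, truth = self.fit(rng)
        assert adjusted_rand_score(truth, model.merged) == pytest.approx(1.0)

    def test_stage1_refines_merged(self, rng):
        _prof, model, _ = self.fit(rng)
        mapping = {}
        for el, s1 in model.stage1.items():
            m = model.merged[el]
            assert mapping.setdefault(s1, m) == m

    def test_k1_equals_kfinal_keeps_stage1_partition(self, rng):
        _prof, model, _ = self.fit(rng, k1=5, k_final=5)
        assert sorted(model.stage1_to_merged) == [1, 2, 3, 4, 5]
        # stage-2 is the identity partition: same co-membership
        s1 = pd.factorize(model.stage1)[0]
        mg = pd.factorize(model.merged)[0]
        assert adjusted_rand_score(s1, mg) == pytest.approx(1.0)

    def test_duplicate_rows_always_co_clustered(self, rng):
        norm, samples, _ = profile_fixture(rng)
        dup = norm.values.iloc[[0]].rename(index={"e0": "dup"})
        vals = pd.concat([norm.values, dup])
        norm2 = NormalizedMatrix(vals, pd.Series(1.0, index=vals.columns))
        prof = cl.build_profiles(norm2, samples, vals.index)
        model = cl.two_stage_cluster(prof, k1=20, k_final=5, seed=0)
        assert model.merged["dup"] == model.merged["e0"]

    def test_permutation_invariance_of_partition(self, rng):
        norm, samples, _ = profile_fixture(rng)
        prof = cl.build_profiles(norm, samples, norm.values.index)
        perm = rng.permutation(len(prof.values))
        prof2 = cl.ProfileMatrix(values=prof.values.iloc[perm],
                                 raw_means=prof.raw_means.iloc[perm])
        m1 = cl.two_stage_cluster(prof, k1=20, k_final=5, seed=0)
        m2 = cl.two_stage_cluster(prof2, k1=20, k_final=5, seed=0)
        common = prof.values.index
        assert adjusted_rand_score(m1.merged.loc[common],
                                   m2.merged.loc[common]) == pytest.approx(1.0)

    def test_parameter_errors(self, rng):
        norm, samples, _ = profile_fixture(rng)
        prof = cl.build_profiles(norm, samples, norm.values.index)
        with pytest.raises(ParameterError, match="k_final"):
            cl.two_stage_cluster(prof, k1=5, k_final=6)
        with pytest.raises(ParameterError, match="k1"):
            cl.two_stage_cluster(prof, k1=10_000, k_final=5)


class TestOrderElements:
    def test_descending_mean_with_stable_ties(self, rng):
        norm, samples, _ = profile_fixture(rng)
        prof = cl.build_profiles(norm, samples, norm.values.index)
        model = cl.two_stage_cluster(prof, k1=20, k_final=5, seed=0)
        order = cl.order_elements(model, prof)
        assert set(order) == set(prof.values.index)
        raw_mean = prof.raw_means.mean(axis=1)
        # brute-force oracle within each cluster
        pos = {el: i for i, el in enumerate(order)}
        for m in model.centroids.index:
            members = list(model.merged.index[model.merged == m])
            expect = sorted(members, key=lambda e: (-raw_mean[e], e))
            got = sorted(members, key=lambda e: pos[e])
            assert got == expect


class TestPca:
    def test_matches_eigendecomposition_oracle(self, rng):
        samples = sample_table([("p2", d, 10) for d in range(3, 6)])
        x = rng.normal(size=(50, 6))
        norm = norm_from(x, samples)
        coords, ve = cl.pca(norm)
        xc = (x - x.mean(axis=1, keepdims=True)).T
        w, v = linalg.eigh(xc @ xc.T)
        w, v = w[::-1], v[:, ::-1]
        oracle = v * np.sqrt(np.clip(w, 0, None))
        for k in range(coords.shape[1] - 1):  # skip the null direction
            c = coords.iloc[:, k].to_numpy()
            o = oracle[:, k]
            assert np.allclose(c, o, atol=1e-8) or np.allclose(c, -o,
                                                               atol=1e-8)
        assert ve.sum() <= 1.0 + 1e-12

    def test_duplicated_sample_groups_separate_on_pc1(self, rng):
        samples = sample_table([("p2", 5, 10), ("p3", 5, 500)])
        a = rng.normal(size=30)
        b = a + 4.0
        norm = norm_from(np.column_stack([a, a, b, b]), samples)
        coords, _ = cl.pca(norm)
        pc1 = coords["PC1"]
        assert pc1.iloc[0] == pytest.approx(pc1.iloc[1], abs=1e-9)
        assert pc1.iloc[2] == pytest.approx(pc1.iloc[3], abs=1e-9)
        assert abs(pc1.iloc[0] - pc1.iloc[2]) > 1.0

    def test_top_n_one_uses_single_element(self, rng):
        samples = sample_table([("p2", 5, 10), ("p3", 5, 500)])
        x = rng.normal(size=(20, 4))
        x[7] *= 50  # dominant-variance element
        norm = norm_from(x, samples)
        coords, _ = cl.pca(norm, top_n=1)
        centered = x[7] - x[7].mean()
        ratio = coords["PC1"].to_numpy() / centered
        assert np.allclose(ratio, ratio[0])

    def test_too_few_samples_errors(self, rng):
        samples = sample_table([("p2", 5, 10)], n_rep=1)
        norm = norm_from(rng.normal(size=(10, 1)), samples)
        with pytest.raises(ValidationError):
            cl.pca(norm)


class TestLabelClusters:
    def model_with_centroids(self, centroids, samples):
        n = len(centroids)
        idx = [f"e{i}" for i in range(n)]
        return cl.ClusterModel(
            stage1=pd.Series(range(1, n + 1), index=idx),
            merged=pd.Series(range(1, n + 1), index=idx),
            stage1_to_merged=pd.Series(range(1, n + 1),
                                       index=range(1, n + 1)),
            centroids=centroids, seed=0)

    def build(self, rows):
        samples = sample_table(CONDS)
        cols = pd.MultiIndex.from_tuples(CONDS,
                                         names=["cell_type", "day", "sag_nM"])
        cent = pd.DataFrame(rows, index=range(1, len(rows) + 1),
                            columns=cols)
        model = self.model_with_centroids(cent, samples)
        prof = cl.ProfileMatrix(values=cent.copy(), raw_means=cent.copy())
        return model, prof, samples

    def test_rule_firing(self):
        model, prof, samples = self.build([
            [2.0, -0.5, -0.5, -0.5, -0.5],   # high only in origin -> NMP
            [-1.0, 1.0, 1.0, 1.0, 1.0],      # low origin, high neural
            [-0.6, -0.6, -0.6, 1.0, 1.0],    # one cell type, low outside
            [-0.4, 0.2, 0.2, 1.0, 1.0],      # one cell type, moderate outside
            [0.0, 0.0, 0.0, 0.0, 0.0],       # nothing high -> other
        ])
        labels = cl.label_clusters(model, prof, samples)
        assert labels == {1: "NMP", 2: "pan-neural", 3: "p3-specific",
                          4: "p3-enriched", 5: "other"}


class TestStabilityAndRegime:
    def test_stability_needs_two_seeds(self, rng):
        norm, samples, _ = profile_fixture(rng)
        prof = cl.build_profiles(norm, samples, norm.values.index)
        with pytest.raises(ParameterError):
            cl.cluster_stability(prof, k1=20, k_final=5, seeds=[0])

    def test_stability_on_planted_data(self, rng):
        norm, samples, _ = profile_fixture(rng)
        prof = cl.build_profiles(norm, samples, norm.values.index)
        ari = cl.cluster_stability(prof, k1=20, k_final=5, seeds=[0, 1, 2])
        assert ari >= 0.95

    def test_regime_requires_labels(self, rng):
        norm, samples, _ = profile_fixture(rng)
        prof = cl.build_profiles(norm, samples, norm.values.index)
        model = cl.two_stage_cluster(prof, k1=20, k_final=5, seed=0)
        with pytest.raises(ValidationError, match="label"):
            cl.classify_regime(model, prof, samples)

    def test_regime_calls_on_crafted_labels(self, rng):
        norm, samples, _ = profile_fixture(rng)
        prof = cl.build_profiles(norm, samples, norm.values.index)
        model = cl.two_stage_cluster(prof, k1=20, k_final=5, seed=0)
        cl.label_clusters(model, prof, samples)
        report = cl.classify_regime(model, prof, samples)
        # pattern 3 is open only in p3 conditions -> p3 owns specific
        # elements; p2's accessible elements sit in shared clusters
        assert report.table.loc["p3", "regime"] == "differential_accessibility"
        assert report.table.loc["p2", "regime"] == "differential_binding"
        assert ((report.table["specificity_fraction"] >= 0)
                & (report.table["specificity_fraction"] <= 1)).all()
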