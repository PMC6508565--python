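"""Responder classification: ANOVA decomposition, BH step-up oracle,
Canberra/Ward clustering, onset labeling, growth-rate and end-size ranks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from phenogxe import synthetic as syn
from phenogxe import timing as T


def bh_stepup_oracle(p):
    """Closed-form BH: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestOneWayAnova:
    def test_hand_decomposition(self):
        # {1,2,3} vs {4,5,6}: SSB 13.5, MSW 1, df (1,4) -> F 13.5
        f, p = T.one_way_anova_F([[1, 2, 3], [4, 5, 6]])
        assert f == pytest.approx(13.5)
        assert p == pytest.approx(stats.f.sf(13.5, 1, 4))

    def test_equal_groups_give_zero_F(self):
        f, p = T.one_way_anova_F([[2.0, 3.0, 4.0], [4.0, 3.0, 2.0]])
        assert f == 0.0 and p == 1.0

    def test_zero_within_variance_limit(self):
        f, p = T.one_way_anova_F([[1.0, 1.0], [2.0, 2.0]])
        assert np.isinf(f) and p == 0.0

    def test_agrees_with_scipy(self, rng):
        groups = [rng.normal(size=7), rng.normal(0.4, 1.2, 5), rng.normal(size=6)]
        f, p = T.one_way_anova_F(groups)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_null_p_values_uniform(self, rng):
        pooled = rng.normal(size=12)
        ps = []
        for _ in range(300):
            perm = rng.permutation(pooled)
            ps.append(T.one_way_anova_F([perm[:6], perm[6:]])[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBhQvalues:
    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(1, 200))
    def test_matches_stepup_closed_form(self, seed, m):
        p = np.random.default_rng(seed).random(m)
        assert np.allclose(T.bh_qvalues(p), bh_stepup_oracle(p))

    def test_single_pvalue_unchanged(self):
        assert T.bh_qvalues([0.123])[0] == pytest.approx(0.123)

    def test_q_at_least_p_and_nan_passthrough(self, rng):
        p = rng.random(50)
        p[7] = np.nan
        q = T.bh_qvalues(p)
        assert np.isnan(q[7])
        ok = ~np.isnan(p)
        assert (q[ok] >= p[ok] - 1e-12).all()


class TestQvalueMatrix:
    def test_effect_genotype_significant_from_onset(self):
        cfg = syn.ExperimentConfig(n_genotypes=4, reps_per_treatment=(9, 9, 6),
                                   early_onset_range=(12, 12),
                                   late_onset_range=(20, 20), seed=77)
        traits, _, _, _ = syn.generate_experiment(
            cfg, with_histograms=False, with_ionome=False)
        qmat = T.qvalue_matrix(traits)
        assert qmat.p.shape == (4, 19)
        # invariants: q >= p, -log10 q >= 0
        assert (qmat.q.to_numpy() >= qmat.p.to_numpy() - 1e-12).all()
        assert (qmat.neglog10_q.to_numpy() >= 0).all()
        early = qmat.q.iloc[0]  # onset day 12 genotype
        assert (early.loc[16:] < 0.05).all()
        # pre-onset days are null; allow at most one chance discovery
        assert (early.loc[:10] < 0.05).sum() <= 1

    def test_single_cell_q_equals_p(self, rng):
        traits = pd.DataFrame({
            "plant_id": [f"p{i}" for i in range(8)],
            "genotype": "g", "day": 8,
            "treatment": ["100/100"] * 4 + ["10/10"] * 4,
            "area": rng.lognormal(6, 0.2, 8),
        })
        qmat = T.qvalue_matrix(traits)
        assert qmat.q.iloc[0, 0] == pytest.approx(qmat.p.iloc[0, 0])


class TestCanberra:
    def test_hand_example(self):
        assert T.canberra_distance([1, 2], [3, 2]) == pytest.approx(0.5)

    def test_metric_axioms_on_random_vectors(self, rng):
        for _ in range(20):
            u, v = rng.normal(size=6), rng.normal(size=6)
            assert T.canberra_distance(u, u) == 0.0
            d = T.canberra_distance(u, v)
            assert d >= 0
            assert d == pytest.approx(T.canberra_distance(v, u))

    def test_zero_zero_terms_contribute_nothing(self):
        assert T.canberra_distance([0, 1], [0, 3]) == pytest.approx(0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            T.canberra_distance([1, 2], [1, 2, 3])


class TestWardDendrogram:
    def test_closest_pair_merges_first(self):
        d = np.array([[0.0, 0.1, 5.0],
                      [0.1, 0.0, 5.0],
                      [5.0, 5.0, 0.0]])
        dend = T.ward_dendrogram(d, labels=["a", "b", "c"])
        assert set(dend.merges[0, :2].astype(int)) == {0, 1}
        assert len(dend.merges) == 2
        assert (np.diff(dend.merges[:, 2]) >= 0).all()

    def test_four_point_lance_williams_oracle(self):
        # hand-computed Ward agglomeration on 4 points: merge (0,1) at d=1;
        # Lance-Williams update d(01,2) = sqrt(4/3*4 - 1/3) etc.
        d = np.array([[0.0, 1.0, 2.0, 9.0],
                      [1.0, 0.0, 2.0, 9.0],
                      [2.0, 2.0, 0.0, 9.0],
                      [9.0, 9.0, 9.0, 0.0]])
        dend = T.ward_dendrogram(d)
        assert set(dend.merges[0, :2].astype(int)) == {0, 1}
        assert dend.merges[0, 2] == pytest.approx(1.0)
        d2 = np.sqrt((2 * 4.0 + 2 * 4.0 - 1.0) / 3.0)  # ward update to point 2
        assert dend.merges[1, 2] == pytest.approx(d2)

    def test_two_blob_construction_recovered_at_k2(self, rng):
        from scipy.cluster.hierarchy import fcluster
        x = np.concatenate([rng.normal(0, 0.1, (5, 3)),
                            rng.normal(4, 0.1, (5, 3))])
        dend = T.ward_dendrogram(T.canberra_matrix(x))
        assign = fcluster(dend.merges, 2, criterion="maxclust")
        assert len(set(assign[:5])) == 1
        assert len(set(assign[5:])) == 1
        assert assign[0] != assign[9]

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            T.ward_dendrogram(np.array([[0.0, 1.0], [2.0, 0.0]]))


@pytest.fixture(scope="module")
def experiment():
    cfg = syn.ExperimentConfig(seed=55)
    traits, _, _, truth = syn.generate_experiment(
        cfg, with_histograms=False, with_ionome=False)
    return traits, truth


class TestSplitEarlyLate:
    def test_recovers_ground_truth_partition(self, experiment):
        traits, truth = experiment
        labels, qmat, dend = T.classify_responders(traits)
        acc = np.mean([labels.labels[g] == truth.responder_labels[g]
                       for g in truth.responder_labels])
        assert acc == 1.0

    def test_onset_days_near_truth(self, experiment):
        traits, truth = experiment
        labels, _, _ = T.classify_responders(traits)
        diffs = [abs(labels.onset_day[g] - truth.onset_days[g])
                 for g in truth.onset_days if labels.onset_day[g] is not None]
        assert np.median(diffs) <= 3

    def test_relabeling_preserves_partition(self, experiment):
        traits, _ = experiment
        labels1, _, _ = T.classify_responders(traits)
        renamed = traits.copy()
        renamed["genotype"] = "x_" + renamed["genotype"]
        labels2, _, _ = T.classify_responders(renamed)
        for g, lab in labels1.labels.items():
            assert labels2.labels["x_" + g] == lab


class TestGrowthRate:
    def test_exact_linear_growth(self):
        days = np.arange(10, 23)
        traits = pd.DataFrame({
            "plant_id": "p0", "genotype": "g", "treatment": "10/10",
            "day": days, "area": 5.0 * days,
        })
        rates = T.growth_rate(traits)
        assert rates.loc["g", "rate"] == pytest.approx(5.0)

    def test_constant_area_zero_rate(self):
        days = np.arange(8, 27)
        traits = pd.DataFrame({
            "plant_id": "p0", "genotype": "g", "treatment": "10/10",
            "day": days, "area": 123.0,
        })
        assert T.growth_rate(traits).loc["g", "rate"] == pytest.approx(0.0)

    def test_ci_covers_true_slope(self, rng):
        # noisy linear truth: CI over replicate plants covers b ~95%
        b = 40.0
        covered = 0
        for rep in range(100):
            frames = []
            for i in range(8):
                days = np.arange(10, 23)
                frames.append(pd.DataFrame({
                    "plant_id": f"p{i}", "genotype": "g", "treatment": "x",
                    "day": days,
                    "area": 200 + b * days + rng.normal(0, 60, len(days)),
                }))
            res = T.growth_rate(pd.concat(frames))
            covered += res.loc["g", "ci_low"] <= b <= res.loc["g", "ci_high"]
        assert covered >= 85


class TestEndSizeOutperformers:
    def test_shifted_genotype_starred(self, rng):
        rows = []
        for i in range(8):
            mu = 1000.0 + (5000.0 if i == 0 else 0.0)  # +5 sd shift
            for r in range(6):
                rows.append({"plant_id": f"g{i}r{r}", "genotype": f"g{i}",
                             "treatment": "10/10", "day": 26,
                             "area": mu + rng.normal(0, 1000)})
        res = T.end_size_outperformers(pd.DataFrame(rows))
        assert res.loc["g0", "star"]
        assert res.index[0] == "g0"  # largest mean first

    def test_exchangeable_genotypes_rarely_starred(self, rng):
        stars = 0
        for rep in range(30):
            rows = []
            for i in range(6):
                for r in range(6):
                    rows.append({"plant_id": f"g{i}r{r}", "genotype": f"g{i}",
                                 "treatment": "10/10", "day": 26,
                                 "area": rng.normal(1000, 100)})
            stars += T.end_size_outperformers(pd.DataFrame(rows))["star"].sum()
        assert stars <= 2

    def test_single_genotype_errors(self):
        df = pd.DataFrame({"plant_id": ["a", "b"], "genotype": "g",
                           "treatment": "10/10", "day": 26,
                           "area": [1.0, 2.0]})
        with pytest.raises(ValueError):
            T.end_size_outperformers(df)
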