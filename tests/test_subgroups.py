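"""K-means subgrouping, Calinski-Harabasz selection and the permutation null."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ipvcooc import (
    cluster,
    generate_regime_cohort,
    heterogeneity,
    permutation_null,
    select_k,
    subgroup_profiles,
)


def two_clouds(n=60, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n, 5))
    b = rng.normal(sep, 1, size=(n, 5))
    return np.vstack([a, b]), np.repeat([0, 1], n)


class TestCluster:
    def test_well_separated_clouds_split_perfectly(self):
        x, truth = two_clouds()
        res = cluster(x, 2, restarts=10, seed=0)
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_identical_rows_have_zero_inertia(self):
        x = np.ones((20, 4))
        res = cluster(x, 3, restarts=5, seed=0)
        assert res.inertia == pytest.approx(0.0)

    def test_seeded_determinism(self):
        x, _ = two_clouds(seed=3)
        a = cluster(x, 4, restarts=10, seed=7)
        b = cluster(x, 4, restarts=10, seed=7)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_k_out_of_range_rejected(self):
        x, _ = two_clouds(n=5)
        with pytest.raises(ValueError, match="k must"):
            cluster(x, 10, seed=0)

    def test_labels_canonicalized_by_descending_size(self):
        rng = np.random.default_rng(2)
        x = np.vstack([rng.normal(0, 0.5, (80, 3)), rng.normal(8, 0.5, (20, 3))])
        res = cluster(x, 2, restarts=5, seed=1)
        sizes = res.sizes()
        assert sizes[0] >= sizes[1]
        assert sizes[0] == 80

    def test_more_restarts_never_worse(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(150, 8))
        inertias = [cluster(x, 6, restarts=r, seed=5).inertia for r in (1, 5, 25)]
        assert inertias[0] >= inertias[1] >= inertias[2]


class TestSelectK:
    def test_three_planted_blobs(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.normal(c, 0.5, (50, 4)) for c in (0, 6, 12)])
        sel = select_k(x, range(2, 7), restarts=10, seed=0)
        assert sel.k_star == 3
        assert len(sel.table) == 5

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            select_k(np.ones((30, 3)), range(2, 5), seed=0)


class TestHeterogeneity:
    def test_identical_profiles_have_zero_heterogeneity(self):
        assert heterogeneity(np.ones((5, 39))) == 0.0

    def test_three_four_five_triangle(self):
        x = np.zeros((2, 39))
        x[1, 0], x[1, 1] = 3.0, 4.0
        assert heterogeneity(x) == pytest.approx(5.0)

    def test_group_of_one_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            heterogeneity(np.ones((5, 3)), member_idx=[0])


class TestPermutationNull:
    def test_full_cohort_sample_has_zero_variance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 6))
        null = permutation_null(x, [30], n_perm=20, seed=1)
        row = null.band.loc[30]
        assert row["lo"] == pytest.approx(row["hi"])
        assert row["mean"] == pytest.approx(heterogeneity(x))

    def test_band_is_deterministic_in_seed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(60, 6))
        a = permutation_null(x, [5, 10], n_perm=50, seed=3).band
        b = permutation_null(x, [5, 10], n_perm=50, seed=3).band
        pd.testing.assert_frame_equal(a, b)

    def test_oversized_group_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            permutation_null(np.ones((10, 3)), [11], seed=0)

    def test_planted_tight_cluster_below_band(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 3, size=(200, 10))
        x[:40] = rng.normal(0, 0.2, size=(40, 10))  # planted tight subgroup
        null = permutation_null(x, [40], n_perm=100, seed=2)
        obs = heterogeneity(x, member_idx=np.arange(40))
        assert null.flag(40, obs) == "below"


class TestSubgroupProfiles:
    def test_single_cluster_equals_cohort_summary(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame(rng.uniform(0, 4, size=(50, 4)),
                              columns=["PV", "PA", "SV", "MA"])
        res = cluster(scores.to_numpy(), 1, restarts=2, seed=0)
        prof = subgroup_profiles(scores, res)
        pv = prof[(prof.cluster == 0) & (prof.type == "PV")].iloc[0]
        assert pv["median"] == pytest.approx(scores["PV"].median())
        assert pv["n"] == 50

    def test_planted_high_pa_cluster_has_top_pa_median(self):
        means = {
            "baseline": (-1.0, -1.0, -1.0, -1.0),
            "high_pa": (-1.0, 3.0, -1.0, -1.0),
            "high_pv": (3.0, -1.0, -1.0, -1.0),
        }
        coh = generate_regime_cohort(n_per_regime=60, regime_means=means, seed=1)
        from ipvcooc import ItemCatalog, compute_type_scores

        scores = compute_type_scores(coh.responses, ItemCatalog.default())
        res = cluster(coh.responses, 3, restarts=25, seed=1)
        prof = subgroup_profiles(scores, res)
        pa = prof[prof.type == "PA"].set_index("cluster")["median"]
        top = pa.idxmax()
        regime = np.bincount(coh.truth.regime_labels[res.labels == top]).argmax()
        assert list(means)[regime] == "high_pa"
        assert (pa.drop(top) < pa[top]).all()

    def test_constant_scores_have_zero_iqr(self):
        scores = pd.DataFrame({"PV": [2.0] * 10, "PA": [1.0] * 10,
                               "SV": [0.0] * 10, "MA": [0.0] * 10})
        res = cluster(np.arange(10, dtype=float).reshape(-1, 1), 2, restarts=2, seed=0)
        prof = subgroup_profiles(scores, res)
        assert (prof["q3"] - prof["q1"] == 0).all()


def test_recovered_type_orderings_match_planted_regimes():
    """Cluster score orderings agree with the planted regime mean orderings."""
    from ipvcooc import ItemCatalog, compute_type_scores
    from ipvcooc.synthetic_data import DEFAULT_REGIME_MEANS

    coh = generate_regime_cohort(n_per_regime=100, seed=2)
    res = cluster(coh.responses, 5, restarts=50, seed=2)
    assert adjusted_rand_score(coh.truth.regime_labels, res.labels) > 0.9
    scores = compute_type_scores(coh.responses, ItemCatalog.default())
    mu = np.array(list(DEFAULT_REGIME_MEANS.values()))
    # map each cluster to its majority planted regime
    for c in range(5):
        members = res.labels == c
        regime = np.bincount(coh.truth.regime_labels[members]).argmax()
        cluster_means = scores.loc[members].mean().to_numpy()  # PV, PA, SV, MA
        planted = mu[regime]
        # types planted "on" score higher than types planted "off"
        for i in range(4):
            for j in range(4):
                if planted[i] - planted[j] > 1.0:
                    assert cluster_means[i] > cluster_means[j]
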