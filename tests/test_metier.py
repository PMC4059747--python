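import itertools

import numpy as np
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from vmstrack.metier import (MetierModel, asw, bray_curtis, clara, classify,
                             discover_metiers, label_medoids, pam,
                             pairwise_distance, profiles_matrix)
from vmstrack.synthetic import LLD_SPEC, OTB_SPEC, PS_SPEC, planted_logbook
from vmstrack.vms_io import LogbookRecord, utc


class TestBrayCurtis:
    def test_worked_pair_is_exactly_half(self):
        # C = min(6,2)+min(2,6) = 4; S = 8, 8 -> 1 - 2*4/16 = 0.5
        assert bray_curtis([6, 2], [2, 6]) == 0.5

    def test_identity_and_disjoint_supports(self):
        assert bray_curtis([3, 1, 0], [3, 1, 0]) == 0.0
        assert bray_curtis([5, 0], [0, 7]) == 1.0

    def test_all_zero_pair_raises(self):
        with pytest.raises(ValueError):
            bray_curtis([0.0, 0.0], [0.0, 0.0])

    def test_algebraic_properties_on_random_profiles(self, rng):
        X = rng.gamma(1.0, 5.0, size=(200, 6)) * (rng.random((200, 6)) > 0.3)
        X[X.sum(axis=1) == 0, 0] = 1.0
        for _ in range(500):
            i, j = rng.integers(0, 200, 2)
            d = bray_curtis(X[i], X[j])
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(bray_curtis(X[j], X[i]), abs=1e-12)
            lam = float(rng.uniform(0.1, 10))
            assert d == pytest.approx(bray_curtis(lam * X[i], lam * X[j]), abs=1e-9)
            if np.array_equal(X[i], X[j]):
                assert d == 0.0

    def test_agrees_with_scipy_on_nonnegative_data(self, rng):
        for _ in range(200):
            x = rng.gamma(1, 5, 5)
            y = rng.gamma(1, 5, 5)
            assert bray_curtis(x, y) == pytest.approx(scipy_braycurtis(x, y), abs=1e-12)

    def test_pairwise_matrix_matches_scalar(self, rng):
        X = rng.gamma(1, 5, size=(20, 4))
        D = pairwise_distance(X, distance="bray_curtis")
        for i, j in itertools.combinations(range(20), 2):
            assert D[i, j] == pytest.approx(bray_curtis(X[i], X[j]), abs=1e-12)


def brute_force_cost(D, k):
    return min(D[:, list(c)].min(axis=1).sum()
               for c in itertools.combinations(range(D.shape[0]), k))


class TestPam:
    def test_k1_medoid_minimises_summed_distance(self, rng):
        X = rng.uniform(0, 10, size=(9, 3))
        D = pairwise_distance(X, distance="manhattan")
        medoids, labels, cost = pam(X, 1, "manhattan")
        assert medoids == [int(np.argmin(D.sum(axis=1)))]
        assert cost == pytest.approx(D.sum(axis=1).min())

    def test_two_separated_blobs_one_medoid_each(self, rng):
        X = np.vstack([rng.normal(0, 0.3, size=(6, 2)),
                       rng.normal(10, 0.3, size=(6, 2)) ])
        medoids, labels, cost = pam(np.abs(X), 2, "euclidean")
        sides = sorted(m // 6 for m in medoids)
        assert sides == [0, 1]
        assert cost == pytest.approx(brute_force_cost(
            pairwise_distance(np.abs(X), distance="euclidean"), 2))

    def test_duplicated_dataset_same_medoid_positions(self, rng):
        X = rng.uniform(0.5, 10, size=(7, 3))
        m1, _, c1 = pam(X, 2, "euclidean")
        m2, _, c2 = pam(np.vstack([X, X]), 2, "euclidean")
        assert c2 == pytest.approx(2 * c1)
        assert {tuple(X[m]) for m in m1} == {tuple(np.vstack([X, X])[m]) for m in m2}

    def test_swap_path_reaches_swap_local_optimum(self, rng):
        # large enough to bypass exact enumeration
        X = rng.uniform(0.1, 10, size=(60, 4))
        medoids, labels, cost = pam(X, 4, "euclidean")
        D = pairwise_distance(X, distance="euclidean")
        assert cost == pytest.approx(D[:, medoids].min(axis=1).sum())
        for i in range(4):
            for h in range(60):
                if h in medoids:
                    continue
                trial = list(medoids)
                trial[i] = h
                assert D[:, trial].min(axis=1).sum() >= cost - 1e-9

    def test_invalid_k_raises(self, rng):
        X = rng.uniform(0, 1, size=(5, 2))
        with pytest.raises(ValueError):
            pam(X, 5, "euclidean")


class TestClara:
    def test_small_n_degenerates_to_pam(self, rng):
        X = rng.gamma(1, 5, size=(40, 5))
        pm, pl, pc = pam(X, 3, "bray_curtis")
        cm, cl, avg = clara(X, 3, n_samples=5, sample_size=100, distance="bray_curtis", seed=1)
        assert cm == pm and np.array_equal(cl, pl)
        assert avg == pytest.approx(pc / 40)

    def test_fixed_seed_is_deterministic(self, rng):
        X = rng.gamma(1, 5, size=(400, 5))
        r1 = clara(X, 3, n_samples=4, sample_size=80, seed=9)
        r2 = clara(X, 3, n_samples=4, sample_size=80, seed=9)
        assert r1[0] == r2[0] and np.array_equal(r1[1], r2[1]) and r1[2] == r2[2]

    def test_full_data_cost_close_to_direct_pam_subsample(self):
        records, _ = planted_logbook([OTB_SPEC, PS_SPEC, LLD_SPEC], 2000, seed=5)
        X, _ = profiles_matrix(records)
        _, _, avg_clara = clara(X, 3, n_samples=5, sample_size=300,
                                distance="bray_curtis", seed=5)
        sub = X[::2][:700]
        _, _, cost = pam(sub, 3, "bray_curtis")
        assert avg_clara <= (cost / len(sub)) * 1.05


class TestAsw:
    def test_two_distant_tight_blobs_near_one(self, rng):
        X = np.vstack([rng.normal(1, 0.05, size=(20, 3)),
                       rng.normal(50, 0.05, size=(20, 3))])
        labels = np.array([0] * 20 + [1] * 20)
        assert asw(np.abs(X), labels, "euclidean") > 0.9

    def test_identical_points_arbitrary_split_scores_zero(self):
        X = np.ones((10, 3))
        labels = np.array([0, 1] * 5)
        assert asw(X, labels, "euclidean") == 0.0

    def test_random_labels_on_one_blob_near_zero(self, rng):
        X = rng.normal(5, 1, size=(300, 4))
        labels = rng.integers(0, 3, 300)
        assert abs(asw(np.abs(X), labels, "euclidean")) < 0.1

    def test_matches_sklearn_silhouette(self, rng):
        from sklearn.metrics import silhouette_score
        X = rng.uniform(0.1, 10, size=(80, 4))
        labels = rng.integers(0, 4, 80)
        ours = asw(X, labels, "euclidean")
        theirs = silhouette_score(X, labels, metric="euclidean")
        assert ours == pytest.approx(float(theirs), abs=1e-9)

    def test_single_cluster_raises(self, rng):
        X = rng.uniform(0, 1, size=(10, 2))
        with pytest.raises(ValueError):
            asw(X, np.zeros(10, dtype=int), "euclidean")


class TestDiscover:
    def test_three_planted_profiles_recovered(self):
        records, labels = planted_logbook([OTB_SPEC, PS_SPEC, LLD_SPEC], 400, seed=2)
        model, profile = discover_metiers(records, range(2, 6), n_samples=3,
                                          sample_size=200, seed=2)
        assert model.k == 3
        # medoid compositions within BCD 0.1 of the planted (normalised) profiles
        species = model.species
        for spec in (OTB_SPEC, PS_SPEC, LLD_SPEC):
            ref = np.array([spec.mean_profile().get(s, 0.0) for s in species])
            dists = [bray_curtis(m / m.sum(), ref) for m in model.medoids]
            assert min(dists) < 0.1

    def test_single_k_range_returned_unconditionally(self):
        records, _ = planted_logbook([OTB_SPEC, PS_SPEC], 60, seed=3)
        model, profile = discover_metiers(records, [2], n_samples=2,
                                          sample_size=50, seed=3)
        assert model.k == 2 and len(profile) == 1

    def test_duplicated_identical_records_do_not_crash(self):
        rec = LogbookRecord("V1", utc(2012, 6, 1), utc(2012, 6, 2), {"HKE": 10.0})
        model, profile = discover_metiers([rec] * 12, [2, 3], n_samples=2,
                                          sample_size=50, seed=0)
        assert model.k in (2, 3)

    def test_empty_k_range_raises(self):
        records, _ = planted_logbook([OTB_SPEC, PS_SPEC], 10, seed=0)
        with pytest.raises(ValueError):
            discover_metiers(records, [])


class TestClassify:
    def _model(self):
        medoids = np.array([[10.0, 0.0, 0.0],
                            [0.0, 10.0, 0.0],
                            [0.0, 0.0, 10.0]])
        return MetierModel(species=["AAA", "BBB", "CCC"], medoids=medoids,
                           labels=["m1", "m2", "m3"])

    def _rec(self, catches):
        return LogbookRecord("V1", utc(2012, 6, 1), utc(2012, 6, 2), catches)

    def test_record_equal_to_medoid_gets_full_membership(self):
        U, hard, bad = classify([self._rec({"BBB": 10.0})], self._model())
        assert np.allclose(U[0], [0, 1, 0]) and hard == ["m2"]

    def test_equidistant_record_splits_membership_and_takes_lower_index(self):
        U, hard, _ = classify([self._rec({"AAA": 5.0, "BBB": 5.0})], self._model())
        assert U[0][0] == pytest.approx(U[0][1])
        assert hard == ["m1"]

    def test_memberships_sum_to_one(self, rng):
        records = [self._rec({"AAA": float(rng.uniform(0, 9) + 0.1),
                              "BBB": float(rng.uniform(0, 9)),
                              "CCC": float(rng.uniform(0, 9))}) for _ in range(50)]
        U, hard, bad = classify(records, self._model())
        assert np.allclose(U.sum(axis=1), 1.0)

    def test_fuzzy_limit_is_crisp_nearest_medoid(self, rng):
        model = self._model()
        model.fuzziness = 1.0001
        records = [self._rec({"AAA": float(rng.uniform(0.1, 9)),
                              "BBB": float(rng.uniform(0, 9)),
                              "CCC": float(rng.uniform(0, 9))}) for _ in range(200)]
        X, _ = profiles_matrix(records, species=list(model.species))
        D = pairwise_distance(X, model.medoids, "bray_curtis")
        nearest = [model.labels[int(i)] for i in np.argmin(D, axis=1)]
        _, hard, _ = classify(records, model)
        assert hard == nearest

    def test_all_zero_record_unclassifiable(self):
        U, hard, bad = classify([self._rec({"AAA": 0.0})], self._model())
        assert bad == 1 and hard == [None] and np.all(np.isnan(U[0]))

    def test_new_species_extend_universe_as_zeros(self):
        U, hard, _ = classify([self._rec({"AAA": 9.0, "ZZZ": 1.0})], self._model())
        assert hard == ["m1"]

    def test_model_csv_round_trip(self, tmp_path):
        model = self._model()
        model.save(tmp_path / "m.csv")
        back = MetierModel.load(tmp_path / "m.csv")
        assert back.species == model.species
        assert back.labels == model.labels
        assert np.allclose(back.medoids, model.medoids)


def test_label_medoids_greedy_reference_matching():
    records, _ = planted_logbook([OTB_SPEC, PS_SPEC], 200, seed=4)
    model, _ = discover_metiers(records, [2], n_samples=2, sample_size=100, seed=4)
    refs = {m.name: m.alpha for m in (OTB_SPEC, PS_SPEC)}
    relabelled = label_medoids(model, refs)
    assert sorted(relabelled.labels) == sorted(refs)
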