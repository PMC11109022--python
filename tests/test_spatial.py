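"""Seat distances, proximity permutation inference and pair characteristics."""

import numpy as np
import pandas as pd
import pytest

from audiencesync import (
    ParticipantInfo,
    feature_association,
    group_contrast,
    pair_features,
    permutation_test_proximity,
    proximity_correlation,
    seat_distance,
)


def pair_table(z, dist, expression="happy", extra=None):
    n = len(z)
    df = pd.DataFrame(
        {
            "participant_a": [f"a{i}" for i in range(n)],
            "participant_b": [f"b{i}" for i in range(n)],
            "expression": expression,
            "r": np.tanh(np.asarray(z, float)),
            "z": np.asarray(z, float),
            "seat_distance": np.asarray(dist, float),
        }
    )
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df


def info(age=30.0, gender="female", empathy=20.0):
    return ParticipantInfo(age=age, gender=gender, empathy_total=empathy,
                           questionnaires_complete=True)


class TestSeatDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [((0, 0), (0, 1), 1.0), ((0, 0), (1, 1), np.sqrt(2)),
         ((2, 3), (2, 3), 0.0), ((0, 0), (3, 4), 5.0)],
    )
    def test_euclidean(self, a, b, expected):
        assert seat_distance(a, b) == pytest.approx(expected)

    def test_metric_properties(self, rng):
        pts = [tuple(map(int, rng.integers(0, 10, 2))) for _ in range(30)]
        for a, b, c in zip(pts, pts[1:], pts[2:]):
            assert seat_distance(a, b) == seat_distance(b, a)
            assert seat_distance(a, c) <= seat_distance(a, b) + seat_distance(b, c)
            assert (seat_distance(a, b) == 0) == (a == b)


class TestProximityCorrelation:
    def test_exact_negative_relation(self):
        d = np.array([1.0, 2.0, 4.0, 9.0, 16.0])
        tab = pair_table(-np.sqrt(d), d)
        assert proximity_correlation(tab, "happy") == pytest.approx(-1.0)

    def test_constant_z_undefined(self):
        tab = pair_table(np.full(6, 0.2), np.arange(1, 7))
        with pytest.warns(UserWarning, match="zero variance"):
            assert np.isnan(proximity_correlation(tab, "happy"))

    def test_too_few_pairs(self):
        tab = pair_table([0.1, 0.2], [1, 2])
        with pytest.raises(ValueError):
            proximity_correlation(tab, "happy")


class TestPermutationTest:
    def _structured(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        d = rng.uniform(1, 10, n)
        return pair_table(-0.5 * np.sqrt(d) + 0.01 * rng.standard_normal(n), d)

    def test_extreme_observation_p_zero_k_over_n(self):
        tab = self._structured()
        res = permutation_test_proximity(tab, "happy", n_perm=200, seed=1)
        assert res.p == 0.0

    def test_add_one_rule(self):
        tab = self._structured()
        res = permutation_test_proximity(tab, "happy", n_perm=200, seed=1,
                                         p_rule="add_one")
        assert res.p == pytest.approx(1 / 201)

    def test_paper_literal_rule_counts_upper_tail(self):
        tab = self._structured()
        res = permutation_test_proximity(tab, "happy", n_perm=200, seed=1,
                                         p_rule="paper_literal")
        assert res.p == 1.0  # every permuted r exceeds the extreme negative

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        tab = pair_table(rng.standard_normal(30), rng.uniform(1, 9, 30))
        a = permutation_test_proximity(tab, "happy", n_perm=500, seed=42)
        b = permutation_test_proximity(tab, "happy", n_perm=500, seed=42)
        assert a.p == b.p and a.observed_r == b.observed_r

    def test_small_n_perm_warns(self):
        tab = self._structured()
        with pytest.warns(UserWarning, match="small"):
            permutation_test_proximity(tab, "happy", n_perm=50, seed=0)


class TestPairFeatures:
    def test_total_age_and_group(self):
        f = pair_features(info(age=20.0), info(age=30.0))
        assert f.total_age == 50.0
        assert f.age_group == "different"

    def test_young_female_pair(self):
        f = pair_features(info(age=20.0), info(age=22.0))
        assert f.gender_group == "female" and f.age_group == "young"

    def test_old_male_pair(self):
        f = pair_features(info(age=40.0, gender="male"),
                          info(age=30.0, gender="male"))
        assert f.gender_group == "male" and f.age_group == "old"

    def test_unknown_gender_excluded(self):
        f = pair_features(info(gender="other"), info())
        assert f.gender_group == "excluded"

    def test_age_exactly_25_makes_pair_different(self):
        f = pair_features(info(age=25.0), info(age=20.0))
        assert f.age_group == "different"
        f = pair_features(info(age=25.0), info(age=30.0))
        assert f.age_group == "different"

    def test_missing_age_propagates(self):
        f = pair_features(info(age=None), info(age=30.0))
        assert f.total_age is None and f.age_group == "different"


class TestFeatureAssociation:
    def test_exact_negative_age_relation(self, rng):
        age = rng.uniform(40, 120, 20)
        tab = pair_table(-0.01 * age, np.arange(1, 21),
                         extra={"total_age": age, "total_empathy": age * 0 + 40})
        out = feature_association(tab, "total_age", "happy")
        assert out["r"] == pytest.approx(-1.0)
        assert out["models"].iloc[0]["model"] == "age"

    def test_constant_feature_missing(self, rng):
        tab = pair_table(rng.standard_normal(10), np.arange(1, 11),
                         extra={"total_age": np.full(10, 60.0),
                                "total_empathy": np.full(10, 40.0)})
        with pytest.warns(UserWarning, match="constant"):
            out = feature_association(tab, "total_age", "happy")
        assert np.isnan(out["r"])

    def test_invalid_feature_name(self, rng):
        tab = pair_table(rng.standard_normal(10), np.arange(1, 11))
        with pytest.raises(ValueError):
            feature_association(tab, "height", "happy")


class TestGroupContrast:
    def _table(self, z_by_group, age_groups=None, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, zs in z_by_group.items():
            for i, z in enumerate(zs):
                rows.append({"participant_a": f"{g}{i}a",
                             "participant_b": f"{g}{i}b",
                             "expression": "happy", "r": np.tanh(z), "z": z,
                             "seat_distance": 1.0, "gender_group": g,
                             "age_group": (age_groups or {}).get(g, "young")})
        return pd.DataFrame(rows)

    def test_single_gender_rejected(self, rng):
        tab = self._table({"female": rng.standard_normal(10)})
        with pytest.raises(ValueError, match="2 gender groups"):
            group_contrast(tab, "happy")

    def test_shifted_female_pairs_detected(self):
        rng = np.random.default_rng(3)
        tab = self._table({
            "female": rng.standard_normal(40) * 0.1 + 0.2,
            "male": rng.standard_normal(40) * 0.1,
            "different": rng.standard_normal(40) * 0.1,
        })
        out = group_contrast(tab, "happy")
        ranks = list(out["models"].model)
        assert ranks.index("age+gender") < ranks.index("age")
        means = out["cell_means"].set_index("gender_group")["mean"]
        assert means["female"] > means["male"]

    def test_null_groups_prefer_null_model(self):
        rng = np.random.default_rng(17)
        wins = 0
        for _ in range(50):
            tab = self._table(
                {"female": rng.standard_normal(50) * 0.1,
                 "male": rng.standard_normal(50) * 0.1,
                 "different": rng.standard_normal(50) * 0.1},
                seed=int(rng.integers(2 ** 31)),
            )
            out = group_contrast(tab, "happy")
            wins += out["models"].iloc[0]["model"] == "age"
        assert wins >= 40

    def test_excluded_pairs_dropped(self):
        rng = np.random.default_rng(4)
        tab = self._table({"female": rng.standard_normal(20),
                           "male": rng.standard_normal(20),
                           "excluded": rng.standard_normal(20) + 5})
        out = group_contrast(tab, "happy")
        assert "excluded" not in set(out["cell_means"].gender_group)
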