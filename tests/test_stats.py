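"""Composition statistics: rates, transforms, PERMANOVA, dispersion, NMDS."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from aphidiet.simulate import simulate_null_composition
from aphidiet.stats import (
    complementary_trap_share,
    composition_matrix,
    dispersion_test,
    euclidean_distances,
    hellinger,
    nmds,
    permanova,
    recovery_rates,
    recovery_ratio,
    taxon_frequencies,
)


class TestRecovery:
    def test_published_counts(self):
        counts = pd.DataFrame(
            {"positives": [167, 19], "total": [330, 289]}, index=["hand", "trap"]
        )
        rates = recovery_rates(counts)["rate_percent"]
        assert rates["hand"] == 50.6 and rates["trap"] == 6.6
        assert recovery_ratio(counts, "hand", "trap") == pytest.approx(7.7, abs=0.1)

    def test_zero_positives_and_zero_total(self):
        counts = pd.DataFrame(
            {"positives": [0, 0], "total": [50, 0]}, index=["a", "b"]
        )
        rates = recovery_rates(counts)["rate_percent"]
        assert rates["a"] == 0.0 and math.isnan(rates["b"])

    def test_positives_cannot_exceed_total(self):
        counts = pd.DataFrame({"positives": [5], "total": [4]}, index=["a"])
        with pytest.raises(ValueError):
            recovery_rates(counts)

    def test_trap_share_arithmetic(self):
        assert complementary_trap_share(854, 720, 320, 67.5) == pytest.approx(
            88.6, abs=0.05
        )

    def test_taxon_frequencies_by_group(self):
        presence = pd.DataFrame(
            {"tA": [1, 1, 0, 0], "tB": [0, 1, 1, 0]},
            index=["i1", "i2", "i3", "i4"],
        )
        groups = pd.Series(["Ha", "Ha", "Cs", "Cs"], index=presence.index)
        freq = taxon_frequencies(presence, groups)
        # i4 is aphid-negative and excluded from all denominators
        assert freq.loc["tA", "overall"] == pytest.approx(100 * 2 / 3)
        assert freq.loc["tA", "Ha"] == 100.0
        assert freq.loc["tA", "Cs"] == 0.0


class TestCompositionMatrix:
    def _meta(self, idx):
        return pd.DataFrame(
            {
                "landscape": ["L1"] * len(idx),
                "round": [1] * len(idx),
                "species": ["Ha"] * len(idx),
            },
            index=idx,
        )

    def test_equal_detections_half_half(self):
        presence = pd.DataFrame(
            {"tA": [1, 1, 0, 0], "tB": [0, 0, 1, 1]},
            index=[f"i{k}" for k in range(4)],
        )
        comp = composition_matrix(presence, self._meta(presence.index))
        assert comp.proportions.iloc[0].tolist() == [0.5, 0.5]

    def test_single_taxon_unit(self):
        presence = pd.DataFrame({"tA": [1], "tB": [0]}, index=["i0"])
        comp = composition_matrix(presence, self._meta(presence.index))
        assert comp.proportions.iloc[0].tolist() == [1.0, 0.0]

    def test_missing_metadata_excluded(self):
        presence = pd.DataFrame({"tA": [1, 1]}, index=["i0", "i1"])
        meta = self._meta(["i0"])
        comp = composition_matrix(presence, meta)
        assert comp.excluded == ["i1"]

    def test_row_sums_zero_or_one(self, rng):
        n = 30
        presence = pd.DataFrame(
            rng.integers(0, 2, size=(n, 5)),
            index=[f"i{k}" for k in range(n)],
            columns=[f"t{k}" for k in range(5)],
        )
        meta = pd.DataFrame(
            {
                "landscape": rng.choice(["L1", "L2", "L3"], n),
                "round": rng.integers(1, 4, n),
                "species": rng.choice(["Ha", "Cs"], n),
            },
            index=presence.index,
        )
        comp = composition_matrix(presence, meta)
        sums = comp.proportions.sum(axis=1).round(9)
        assert set(sums.unique()) <= {0.0, 1.0}


class TestTransforms:
    def test_hellinger_hand_values(self):
        out = hellinger(np.array([[1.0, 1.0, 2.0]]))
        assert out[0] == pytest.approx([0.5, 0.5, math.sqrt(0.5)])

    def test_one_hot_row_unchanged_and_zero_rows_stay_zero(self):
        out = hellinger(np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0]]))
        assert out[0].tolist() == [0.0, 1.0, 0.0]
        assert out[1].tolist() == [0.0, 0.0, 0.0]

    def test_unit_sum_of_squares(self, rng):
        m = rng.random((6, 4))
        out = hellinger(m)
        assert np.allclose((out**2).sum(axis=1), 1.0)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            hellinger(np.array([[-1.0, 2.0]]))

    def test_euclidean_three_four_five(self):
        d = euclidean_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d[0, 1] == 5.0 and d[0, 0] == 0.0


def _oracle_pseudo_f(dist, labels):
    """Independent pseudo-F via explicit group-pair double loops."""
    n = len(labels)
    groups = sorted(set(labels))
    a = len(groups)
    sst = sum(dist[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ssw = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ssw += sum(
            dist[i, j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    ssa = sst - ssw
    return (ssa / (a - 1)) / (ssw / (n - a))


def _within_strata_label_arrangements(labels, strata):
    """All distinct label vectors reachable by permuting within strata."""
    idx_by_s = {}
    for i, s in enumerate(strata):
        idx_by_s.setdefault(s, []).append(i)
    pools = []
    for s, idx in idx_by_s.items():
        vals = [labels[i] for i in idx]
        pools.append((idx, sorted(set(itertools.permutations(vals)))))
    out = []

    def rec(k, current):
        if k == len(pools):
            out.append(tuple(current))
            return
        idx, perms = pools[k]
        for perm in perms:
            nxt = list(current)
            for i, v in zip(idx, perm):
                nxt[i] = v
            rec(k + 1, nxt)

    rec(0, [None] * len(labels))
    return sorted(set(out))


class TestPermanova:
    def test_statistic_matches_oracle(self, rng):
        x = rng.normal(size=(6, 3))
        dist = euclidean_distances(x)
        labels = ["A", "A", "B", "B", "A", "B"]
        res = permanova(dist, labels, n_perm=49, seed=1)
        assert res.pseudo_f == pytest.approx(_oracle_pseudo_f(dist, labels))

    def test_statistic_matches_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as skbio_permanova

        x = rng.normal(size=(12, 4))
        dist = euclidean_distances(x)
        labels = list("AABBAB" * 2)
        ours = permanova(dist, labels, n_perm=9, seed=0)
        theirs = skbio_permanova(
            skbio.DistanceMatrix(dist), labels, permutations=9
        )
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"])

    def test_p_matches_exhaustive_enumeration(self, rng):
        """On 6 rows the permutation p converges to the exact enumeration of
        all within-stratum label arrangements."""
        x = rng.normal(size=(6, 2))
        x[:3] += 1.5
        dist = euclidean_distances(x)
        labels = ["A", "A", "B", "A", "B", "B"]
        strata = [0, 0, 0, 1, 1, 1]
        arrangements = _within_strata_label_arrangements(labels, strata)
        f_obs = _oracle_pseudo_f(dist, labels)
        exact = np.mean(
            [_oracle_pseudo_f(dist, list(arr)) >= f_obs - 1e-12
             for arr in arrangements]
        )
        res = permanova(dist, labels, strata, n_perm=1999, seed=3)
        assert res.p_value == pytest.approx(exact, abs=0.05)

    def test_strong_separation_attains_minimum_p(self, rng):
        x = rng.normal(size=(16, 3))
        x[8:] += 50.0
        labels = ["A"] * 8 + ["B"] * 8
        res = permanova(euclidean_distances(x), labels, n_perm=199, seed=5)
        assert res.p_value == pytest.approx(1 / 200)

    def test_stratified_permutations_respect_strata(self, rng):
        """When groups are confounded with strata, within-stratum shuffling
        leaves the labelling invariant and p stays 1."""
        x = rng.normal(size=(8, 2))
        x[4:] += 10.0
        labels = ["A"] * 4 + ["B"] * 4
        strata = [0] * 4 + [1] * 4
        with pytest.warns(UserWarning, match="single group level"):
            res = permanova(euclidean_distances(x), labels, strata,
                            n_perm=99, seed=7)
        assert res.p_value == 1.0

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError):
            permanova(np.zeros((4, 4)), ["A"] * 4)


class TestDispersion:
    def test_null_rarely_rejects(self):
        rejections = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            x = rng.normal(size=(24, 2))
            labels = ["A"] * 12 + ["B"] * 12
            res = dispersion_test(euclidean_distances(x), labels,
                                  n_perm=99, seed=s)
            rejections += res.p_value <= 0.05
        assert rejections <= 2

    def test_doubled_spread_detected_with_power(self):
        """One group's spread doubled, n = 30/group: detected in nearly
        every replicate at alpha = 0.05."""
        rejections = 0
        for s in range(10):
            rng = np.random.default_rng(200 + s)
            x = np.vstack(
                [rng.normal(0, 1, size=(30, 2)), rng.normal(0, 2, size=(30, 2))]
            )
            labels = ["A"] * 30 + ["B"] * 30
            res = dispersion_test(euclidean_distances(x), labels,
                                  n_perm=99, seed=s)
            rejections += res.p_value <= 0.05
        assert rejections >= 8

    def test_p_matches_exhaustive_enumeration(self, rng):
        from aphidiet.stats import _anova_f, centroid_distances

        x = rng.normal(size=(8, 2))
        x[4:] *= 3.0
        dist = euclidean_distances(x)
        labels = ["A"] * 4 + ["B"] * 4
        arrangements = sorted(set(itertools.permutations(labels)))
        f_for = {}
        for arr in arrangements:
            inv = np.array([0 if v == "A" else 1 for v in arr])
            z = centroid_distances(dist, np.array(arr))
            f_for[arr] = _anova_f(z, inv, 2)
        f_obs = f_for[tuple(labels)]
        exact = np.mean([f >= f_obs - 1e-12 for f in f_for.values()])
        res = dispersion_test(dist, labels, n_perm=1999, seed=11)
        assert res.p_value == pytest.approx(exact, abs=0.05)

    def test_centroid_distances_nonnegative(self, rng):
        x = rng.normal(size=(10, 3))
        from aphidiet.stats import centroid_distances

        z = centroid_distances(euclidean_distances(x), ["A", "B"] * 5)
        assert (z >= 0).all()

    def test_singleton_group_excluded(self, rng):
        x = rng.normal(size=(7, 2))
        labels = ["A"] * 3 + ["B"] * 3 + ["C"]
        with pytest.warns(UserWarning, match="single-member"):
            res = dispersion_test(euclidean_distances(x), labels,
                                  n_perm=49, seed=0)
        assert set(res.group_distances) == {"A", "B"}


class TestNmds:
    def test_planar_configuration_zero_stress(self, rng):
        pts = rng.normal(size=(12, 2))
        res = nmds(euclidean_distances(pts), k=2, n_starts=4, seed=1)
        assert res.stress < 1e-4 and res.converged

    def test_rank_order_recovered(self, rng):
        pts = rng.normal(size=(15, 2))
        dist = euclidean_distances(pts)
        res = nmds(dist, k=2, n_starts=4, seed=2)
        iu = np.triu_indices(15, 1)
        emb = euclidean_distances(res.coordinates)
        rho = spearmanr(dist[iu], emb[iu]).statistic
        assert rho > 0.99

    def test_seeded_reproducibility_and_centering(self, rng):
        comp = simulate_null_composition(10, 5, ["A", "B"] * 5, seed=3, shift=0.5)
        dist = euclidean_distances(hellinger(comp))
        a = nmds(dist, k=2, n_starts=6, seed=9)
        b = nmds(dist, k=2, n_starts=6, seed=9)
        assert np.array_equal(a.coordinates, b.coordinates)
        assert np.allclose(a.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_degenerate_distances_flagged(self):
        d = np.ones((5, 5)) - np.eye(5)
        res = nmds(d, k=2, n_starts=2, seed=0)
        assert res.degenerate and res.stress == 0.0
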