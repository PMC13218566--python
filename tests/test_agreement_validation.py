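"""Cohen kappa, partition concordance, and resampling stability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from themecast import (bootstrap_stability, cohen_kappa, holdout_robustness,
                       js_distance, kappa_band, majority_overlap_map,
                       topk_concordance)
from themecast.agreement_validation import read_confusion_csv
from themecast.coword_cluster import ClusterSolution
from themecast.errors import ParameterError, TermUniverseError


class TestCohenKappa:
    def test_identical_sequences(self):
        rep = cohen_kappa(list("aabbc"), list("aabbc"))
        assert rep.kappa == pytest.approx(1.0)
        assert rep.band == "almost perfect"

    def test_chance_level_2x2(self):
        rep = cohen_kappa(confusion=[[1, 1], [1, 1]])
        assert rep.po == pytest.approx(0.5)
        assert rep.pe == pytest.approx(0.5)
        assert rep.kappa == pytest.approx(0.0)

    def test_sequences_match_sklearn(self):
        """Cross-check against an independent implementation."""
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(5)
        a = rng.integers(0, 4, 60).tolist()
        b = rng.integers(0, 4, 60).tolist()
        assert cohen_kappa(a, b).kappa == pytest.approx(cohen_kappa_score(a, b))

    def test_length_mismatch(self):
        with pytest.raises(ParameterError):
            cohen_kappa([1, 2], [1])

    def test_degenerate_single_label(self):
        rep = cohen_kappa(["x", "x"], ["x", "x"])
        assert rep.kappa == 1.0

    def test_label_permutation_invariance(self):
        a = list("abcabcab")
        b = list("abccbaab")
        perm = {"a": "z", "b": "y", "c": "x"}
        rep1 = cohen_kappa(a, b)
        rep2 = cohen_kappa([perm[x] for x in a], [perm[x] for x in b])
        assert rep1.kappa == pytest.approx(rep2.kappa)

    @pytest.mark.parametrize("k,band", [
        (-0.1, "poor"), (0.1, "slight"), (0.3, "fair"), (0.5, "moderate"),
        (0.7, "substantial"), (0.9, "almost perfect"), (0.6, "moderate"),
        (0.8, "substantial"),
    ])
    def test_bands(self, k, band):
        assert kappa_band(k) == band

    @pytest.mark.parametrize("fname,kappa,po", [
        ("table1_taaa_r1.csv", 0.788, 0.842),
        ("table1_taaa_r2.csv", 0.672, 0.754),
        ("table1_r1_r2.csv", 0.597, 0.684),
    ])
    def test_published_interrater_matrices(self, data_dir, fname, kappa, po):
        """The three 9x9 interrater confusion matrices reproduce their
        published kappa and exact-agreement values."""
        matrix, labels = read_confusion_csv(data_dir / fname)
        rep = cohen_kappa(confusion=matrix, labels=labels)
        assert rep.n == 57
        assert rep.kappa == pytest.approx(kappa, abs=1e-3)
        assert rep.po == pytest.approx(po, abs=5e-4)


class TestMajorityOverlap:
    def fine(self):
        return ClusterSolution({"a": 1, "b": 1, "c": 2, "d": 3, "e": 3},
                               {1: "a", 2: "c", 3: "d"}, "flca")

    def coarse(self):
        return ClusterSolution({"a": 1, "b": 1, "c": 1, "d": 2, "e": 2},
                               {1: "a", 2: "d"}, "louvain")

    def test_nested_partition_maps_into_enclosing(self):
        m = majority_overlap_map(self.fine(), self.coarse())
        assert m == {1: 1, 2: 1, 3: 2}

    def test_identity_map_on_self(self):
        sol = self.fine()
        m = majority_overlap_map(sol, sol)
        assert m == {1: 1, 2: 2, 3: 3}
        collapsed_a = [m[sol.membership[t]] for t in sorted(sol.membership)]
        collapsed_b = [sol.membership[t] for t in sorted(sol.membership)]
        assert cohen_kappa(collapsed_a, collapsed_b).kappa == pytest.approx(1.0)

    def test_plurality_with_exhaustive_tally(self):
        # fine cluster of 5 terms split 3/2 across two coarse clusters
        fine = ClusterSolution({t: 1 for t in "abcde"}, {1: "a"}, "flca")
        coarse = ClusterSolution({"a": 1, "b": 1, "c": 1, "d": 2, "e": 2},
                                 {1: "a", 2: "d"}, "louvain")
        assert majority_overlap_map(fine, coarse) == {1: 1}

    def test_tie_takes_smaller_coarse_id(self):
        fine = ClusterSolution({"a": 1, "b": 1}, {1: "a"}, "flca")
        coarse = ClusterSolution({"a": 2, "b": 1}, {1: "b", 2: "a"}, "louvain")
        assert majority_overlap_map(fine, coarse) == {1: 1}

    def test_universe_mismatch(self):
        fine = ClusterSolution({"a": 1}, {1: "a"}, "flca")
        coarse = ClusterSolution({"b": 1}, {1: "b"}, "louvain")
        with pytest.raises(TermUniverseError, match="a"):
            majority_overlap_map(fine, coarse)


class TestTopkConcordance:
    def test_identical_partitions_k1(self):
        themes = {f"d{i}": i % 3 for i in range(12)}
        res = topk_concordance(themes, themes, k=1)
        assert res.fraction == 1.0 and res.denom == 12

    def test_hand_counted_toy(self):
        # one coarse community; fine themes A(1) x3, B(2) x2, C(3) x1
        fine = {"d1": 1, "d2": 1, "d3": 1, "d4": 2, "d5": 2, "d6": 3}
        coarse = {d: 9 for d in fine}
        res = topk_concordance(fine, coarse, k=2)
        assert res.agree == 5 and res.denom == 6
        assert res.fraction == pytest.approx(5 / 6)

    def test_monotone_in_k_and_saturates(self):
        rng = np.random.default_rng(3)
        fine = {f"d{i}": int(rng.integers(1, 7)) for i in range(60)}
        coarse = {f"d{i}": int(rng.integers(1, 3)) for i in range(60)}
        fracs = [topk_concordance(fine, coarse, k).fraction for k in range(1, 8)]
        assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] == pytest.approx(1.0)  # k >= themes per community

    def test_missing_themes_excluded(self):
        fine = {"d1": 1, "d2": None}
        coarse = {"d1": 1, "d2": 1}
        assert topk_concordance(fine, coarse, k=1).denom == 1

    def test_k_validation(self):
        with pytest.raises(ParameterError):
            topk_concordance({"d": 1}, {"d": 1}, k=0)


class TestJsDistance:
    def test_printed_example(self):
        """JS distance between (.5,.5) and (1,0) with base-2 logs."""
        assert js_distance([0.5, 0.5], [1, 0]) == pytest.approx(0.5579, abs=1e-4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1), min_size=2, max_size=6),
           st.lists(st.floats(0.01, 1), min_size=2, max_size=6))
    def test_metric_properties(self, p, q):
        n = min(len(p), len(q))
        p = np.array(p[:n]) / sum(p[:n])
        q = np.array(q[:n]) / sum(q[:n])
        assert js_distance(p, p) == pytest.approx(0.0, abs=1e-9)
        assert js_distance(p, q) == pytest.approx(js_distance(q, p))
        assert 0.0 <= js_distance(p, q) <= 1.0


class TestStability:
    def test_degenerate_corpus_bootstrap(self):
        themes = [1, 2] * 30  # resampling cannot change much but JS>=0
        rep = bootstrap_stability(themes, reps=20, seed=1)
        assert rep.core_theme_count == 2
        assert rep.js_mean >= 0.0

    def test_identical_articles_js_zero(self):
        with pytest.warns(UserWarning):
            rep = bootstrap_stability([1] * 40, reps=10, seed=0)
        assert rep.js_mean == pytest.approx(0.0)

    def test_seed_reproducibility_bootstrap(self):
        themes = list(np.random.default_rng(2).integers(1, 6, 100))
        a = bootstrap_stability(themes, reps=30, seed=42)
        b = bootstrap_stability(themes, reps=30, seed=42)
        assert (a.js_mean, a.js_sd, a.spearman_mean) == \
               (b.js_mean, b.js_sd, b.spearman_mean)

    def test_kappa_percentile_interval(self):
        rng = np.random.default_rng(0)
        themes = rng.integers(1, 4, 80).tolist()
        ref = [t if rng.random() < 0.8 else int(rng.integers(1, 4)) for t in themes]
        rep = bootstrap_stability(themes, reps=40, seed=1, reference_labels=ref)
        lo, hi = rep.kappa_interval
        assert -1 <= lo <= hi <= 1

    def test_holdout_duplicate_corpus_small_js(self):
        themes = [1, 2, 3] * 40
        rep = holdout_robustness(themes, fraction=0.3, reps=20, seed=3)
        assert rep.js_mean < 0.15

    def test_holdout_seed_reproducibility(self):
        themes = list(np.random.default_rng(4).integers(1, 5, 90))
        a = holdout_robustness(themes, reps=25, seed=9)
        b = holdout_robustness(themes, reps=25, seed=9)
        assert (a.js_mean, a.spearman_mean) == (b.js_mean, b.spearman_mean)

    def test_holdout_fraction_validation(self):
        with pytest.raises(ParameterError):
            holdout_robustness([1, 2], fraction=1.5)
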