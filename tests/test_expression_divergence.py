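import numpy as np
import pandas as pd
import pytest

from allokit.expression_divergence import (
    ExpressionPanel,
    classify_functionalization,
    classify_trans_splicing,
    cluster_profiles,
    conservation_and_divergence,
    cotranscription_summary,
    deg_balance_test,
    dominance_analysis,
    kaks_divergence_trend,
    percent,
    pseudo_ancestral_dosage,
)
from allokit.io_formats import GeneLocation
from allokit.subgenome_assignment import ChromosomeAssignment
from allokit.synthetic_data import simulate_expression_panel

CONTEXTS = [f"t{i}" for i in range(9)]


def _panel(a_rows, b_rows, og_rows=None, floor=1.0):
    n = len(a_rows)
    pairs = pd.DataFrame(
        {
            "pair_id": [f"p{i}" for i in range(n)],
            "subA_gene": [f"p{i}_A" for i in range(n)],
            "subB_gene": [f"p{i}_B" for i in range(n)],
        }
    ).set_index("pair_id")
    og = None
    if og_rows is not None:
        pairs["outgroup_gene"] = [f"p{i}_og" for i in range(n)]
        og = pd.DataFrame(og_rows, index=pairs["outgroup_gene"], columns=CONTEXTS)
    return ExpressionPanel(
        subA=pd.DataFrame(a_rows, index=pairs["subA_gene"], columns=CONTEXTS),
        subB=pd.DataFrame(b_rows, index=pairs["subB_gene"], columns=CONTEXTS),
        pairs=pairs,
        outgroup=og,
        floor=floor,
    )


class TestDominance:
    def test_higher_copy_wins_context(self):
        panel = _panel([[5.0] * 9], [[10.0] * 9])
        dom = dominance_analysis(panel)
        assert (dom["subB_dominant"] == 1).all()
        assert (dom["subA_dominant"] == 0).all()

    def test_ties_and_floor_excluded(self):
        panel = _panel([[3.0] * 9, [0.2] * 9], [[3.0] * 9, [0.5] * 9])
        dom = dominance_analysis(panel)
        assert (dom["ties"] == 1).all()
        assert (dom["excluded"] == 1).all()

    def test_chi2_closed_form(self):
        # counts (600, 400): chi2 = 2 * (100^2 / 500) = 40
        a = [[10.0] * 9] * 400 + [[1.0] * 9] * 600
        b = [[1.0] * 9] * 400 + [[10.0] * 9] * 600
        dom = dominance_analysis(_panel(a, b))
        assert dom["chi2"].iloc[0] == pytest.approx(40.0)
        assert dom["p_value"].iloc[0] == pytest.approx(2.5e-10, rel=0.05)

    def test_counts_partition_pairs(self):
        ds = simulate_expression_panel(300, seed=3)
        panel = ExpressionPanel(subA=ds.subA, subB=ds.subB, pairs=ds.pairs)
        dom = dominance_analysis(panel)
        total = dom[["subA_dominant", "subB_dominant", "ties", "excluded"]].sum(axis=1)
        assert (total == 300).all()


class TestConservationDivergence:
    def test_identical_profiles_conserved_nondivergent(self):
        prof = [[1, 5, 2, 8, 3, 9, 4, 7, 6]] * 20
        cons = conservation_and_divergence(_panel(prof, prof, prof))
        assert cons["conserved_subA"].all() and cons["conserved_subB"].all()
        assert (cons["euclidean_distance"] == 0).all()
        assert np.allclose(cons["correlation"], 1.0)

    def test_planted_high_distance_pairs_flagged(self, rng):
        base = rng.uniform(1, 50, size=(100, 9))
        a = base.copy()
        b = base * rng.uniform(0.98, 1.02, size=(100, 9))
        b[:10] = base[:10] * 200.0  # 10 planted high-distance pairs
        cons = conservation_and_divergence(_panel(list(a), list(b)))
        top = set(cons.sort_values("euclidean_distance").index[-10:])
        assert top == {f"p{i}" for i in range(10)}
        assert cons.loc[sorted(top), "divergent"].all()

    def test_constant_profile_flagged_diverged(self):
        prof = [[1, 5, 2, 8, 3, 9, 4, 7, 6]] * 3
        flat = [[2.0] * 9] * 3
        cons = conservation_and_divergence(_panel(prof, flat))
        assert cons["correlation_undefined"].all()
        assert cons["divergent"].all()


class TestClustering:
    def test_two_blobs_split(self, rng):
        low = rng.normal(2, 0.1, size=(20, 9))
        high = rng.normal(500, 5, size=(20, 9))
        m = pd.DataFrame(np.vstack([low, high]), index=[f"g{i}" for i in range(40)],
                         columns=CONTEXTS)
        labels = cluster_profiles(m, k=2)
        assert labels.iloc[:20].nunique() == 1
        assert labels.iloc[20:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_duplicate_rows_share_cluster(self, rng):
        data = rng.uniform(0, 100, size=(10, 9))
        data[7] = data[3]
        m = pd.DataFrame(data, index=[f"g{i}" for i in range(10)], columns=CONTEXTS)
        labels = cluster_profiles(m, k=5)
        assert labels["g3"] == labels["g7"]

    def test_planted_archetypes_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        ds = simulate_expression_panel(400, conserved_fraction=1.0, seed=6)
        m = pd.concat([ds.subA, ds.subB])
        labels = cluster_profiles(m, k=8)
        truth = [ds.truth.archetype_of[g] for g in m.index]
        assert adjusted_rand_score(truth, labels.values) > 0.9

    def test_k_larger_than_rows_rejected(self, rng):
        m = pd.DataFrame(rng.uniform(size=(3, 9)), columns=CONTEXTS)
        with pytest.raises(ValueError):
            cluster_profiles(m, k=5)


class TestFunctionalization:
    def _classify(self, panel, k=2):
        clusters = cluster_profiles(pd.concat([panel.subA, panel.subB]), k=k)
        cons = conservation_and_divergence(panel)
        return classify_functionalization(panel, clusters, cons)

    def test_silent_copy_is_nonF(self):
        prof = [[1, 5, 2, 8, 3, 9, 4, 7, 6]] * 4
        silent = [[0.0] * 9] + prof[:3]
        classes = self._classify(_panel(silent, prof, prof))
        assert classes["p0"] == "non-F"

    def test_coexpressed_when_same_cluster(self):
        prof = [[10, 50, 20, 80, 30, 90, 40, 70, 60]] * 6
        classes = self._classify(_panel(prof, prof, prof))
        assert (classes == "coexpressed").all()

    def test_neoF_rule(self, rng):
        base = np.array([10, 50, 20, 80, 30, 90, 40, 70, 60], dtype=float)
        flipped = base[::-1].copy()
        a = [base * rng.uniform(0.99, 1.01, 9) for _ in range(6)]
        b = [base * rng.uniform(0.99, 1.01, 9) for _ in range(5)] + [flipped]
        og = [base for _ in range(6)]
        classes = self._classify(_panel(a, b, og))
        assert classes["p5"] == "neo-F"

    def test_classes_partition(self):
        ds = simulate_expression_panel(300, conserved_fraction=0.6, seed=9)
        panel = ExpressionPanel(
            subA=ds.subA, subB=ds.subB, outgroup=ds.outgroup, pairs=ds.pairs
        )
        classes = self._classify(panel, k=8)
        assert classes.isin(["non-F", "neo-F", "sub-F", "coexpressed"]).all()
        assert len(classes) == 300

    def test_no_outgroup_unclassifiable(self):
        prof = [[10, 50, 20, 80, 30, 90, 40, 70, 60]] * 4
        classes = self._classify(_panel(prof, prof))
        assert (classes == "unclassifiable").all()


class TestCotranscription:
    def test_printed_percentage_convention(self):
        assert percent(1451, 2096) == 69.2
        assert percent(1916, 2096) == 91.4

    def test_all_expressed(self):
        prof = [[5.0] * 9] * 10
        s = cotranscription_summary(_panel(prof, prof))
        assert s.percent_all_contexts == 100.0 and s.percent_at_least == 100.0

    def test_floor_above_everything(self):
        prof = [[5.0] * 9] * 10
        s = cotranscription_summary(_panel(prof, prof, floor=100.0))
        assert s.percent_all_contexts == 0.0


class TestDosage:
    def test_exact_sum(self):
        a = [[3.0] * 9]
        b = [[4.0] * 9]
        og = [[7.0] * 9]
        res = pseudo_ancestral_dosage(_panel(a, b, og))
        assert (res["mean_difference"] == 0).all()
        assert (res["p_value"] == 1.0).all()

    def test_half_levels_balance(self, rng):
        og = rng.uniform(10, 100, size=(200, 9))
        res = pseudo_ancestral_dosage(_panel(list(og / 2), list(og / 2), list(og)))
        assert (res["p_value"] > 0.05).all()
        assert np.allclose(res["mean_difference"], 0.0)

    def test_silent_copy_sum_equals_other(self):
        a = [[6.0] * 9]
        b = [[0.0] * 9]
        og = [[6.0] * 9]
        res = pseudo_ancestral_dosage(_panel(a, b, og))
        assert (res["mean_difference"] == 0).all()


class TestKaksTrend:
    def test_logistic_relationship_gives_positive_trend(self, rng):
        ratios = rng.uniform(0.01, 1.0, size=500)
        p = 1 / (1 + np.exp(-8 * (ratios - 0.5)))
        flags = rng.random(500) < p
        trend = kaks_divergence_trend(ratios, flags)
        assert trend.rho > 0 and trend.p_value < 0.01
        assert trend.divergent_fraction == sorted(trend.divergent_fraction)

    def test_null_trend_centred(self, rng):
        rhos = []
        for _ in range(50):
            ratios = rng.uniform(0.01, 1.0, size=200)
            flags = rng.random(200) < 0.3
            rhos.append(kaks_divergence_trend(ratios, flags).rho)
        assert abs(np.mean(rhos)) < 0.05

    def test_all_divergent_flat(self, rng):
        ratios = rng.uniform(0.01, 1.0, size=100)
        trend = kaks_divergence_trend(ratios, [True] * 100)
        assert trend.divergent_fraction == [1.0] * 5
        assert trend.rho == 0.0

    def test_undefined_ratios_counted(self, rng):
        ratios = list(rng.uniform(0.01, 1.0, size=100)) + [None] * 7
        trend = kaks_divergence_trend(ratios, [False] * 107)
        assert trend.n_excluded == 7


class TestDEGBalance:
    def test_identical_flags(self):
        flags = [True] * 30 + [False] * 70
        res = deg_balance_test(flags, flags)
        assert res.p_value == 1.0 and res.n_one_de == 0

    def test_fully_asymmetric(self):
        res = deg_balance_test([True] * 50, [False] * 50)
        assert res.percent_one_de == 100.0

    def test_balanced_calibration(self, rng):
        n_reject = 0
        for _ in range(40):
            a = rng.random(2000) < 0.3
            b = rng.random(2000) < 0.3
            if deg_balance_test(a, b).p_value < 0.05:
                n_reject += 1
        assert n_reject <= 5


class TestTransSplicing:
    ASSIGN = [
        ChromosomeAssignment("cc01", "A", 10, 0),
        ChromosomeAssignment("cc26", "B", 0, 10),
    ]
    LOCS = {
        "a1": GeneLocation("cc01", 0, 1000, "+"),
        "a2": GeneLocation("cc01", 5000, 6000, "+"),
        "b1": GeneLocation("cc26", 0, 1000, "+"),
        "b2": GeneLocation("cc26", 5000, 6000, "+"),
        "sc": GeneLocation("scaffold:9", 0, 1000, "+"),
    }

    def test_classes(self):
        res = classify_trans_splicing(
            [("a1", "b1"), ("a1", "a2"), ("b1", "b2")], self.ASSIGN, self.LOCS
        )
        assert res.counts == {"intra-A": 1, "intra-B": 1, "inter-subgenome": 1}

    def test_scaffold_and_unknown_excluded(self):
        res = classify_trans_splicing(
            [("a1", "sc"), ("a1", "nope")], self.ASSIGN, self.LOCS
        )
        assert res.n_scaffold_excluded == 1 and res.n_unknown_skipped == 1
        assert res.counts == {"intra-A": 0, "intra-B": 0, "inter-subgenome": 0}

    def test_planted_mix_recovered(self, rng):
        calls, expected = [], {"intra-A": 0, "intra-B": 0, "inter-subgenome": 0}
        for _ in range(100):
            kind = rng.choice(["inter", "A", "B"], p=[0.5, 0.25, 0.25])
            if kind == "inter":
                calls.append(("a1", "b1")); expected["inter-subgenome"] += 1
            elif kind == "A":
                calls.append(("a1", "a2")); expected["intra-A"] += 1
            else:
                calls.append(("b1", "b2")); expected["intra-B"] += 1
        res = classify_trans_splicing(calls, self.ASSIGN, self.LOCS)
        assert res.counts == expected
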