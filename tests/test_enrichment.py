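import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tfannot.compendium import Compendium
from tfannot.enrichment import (
    DEFAULT_UNIVERSE_POLICY,
    ContingencyTable,
    GeneUniverse,
    ZeroMarginError,
    annotate_tfs,
    bh_fdr,
    build_contingency,
    build_universe,
    fisher_test,
    g_test,
    log2_odds_ratio,
    odds_ratio,
    phi_coefficient,
    roc_auc,
)

tables = st.builds(
    ContingencyTable,
    n11=st.integers(1, 200),
    n10=st.integers(1, 200),
    n01=st.integers(1, 200),
    n00=st.integers(1, 500),
)


class TestUniverse:
    @pytest.fixture()
    def genes(self):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(10)],
                "is_coding": [True] * 6 + [False] * 4,
                # three coding genes annotated, plus one annotated non-coding
                "in_omim": [True, True, True, False, False, False,
                            True, False, False, False],
            }
        )

    def test_coding_universe(self, genes):
        assert len(build_universe(genes, "coding")) == 6

    def test_literature_rich_counts_annotated_coding(self, genes):
        uni = build_universe(genes, "literature_rich")
        assert len(uni) == 3

    def test_annotated_noncoding_purged(self, genes):
        uni = build_universe(genes, "literature_rich")
        assert "g6" not in uni.members  # annotated but non-coding

    def test_literature_rich_subset_of_coding(self, planted_scenario):
        u = planted_scenario["universes"]
        assert u["literature_rich"].members <= u["coding"].members

    def test_empty_universe_errors(self, genes):
        genes = genes.assign(is_coding=False)
        with pytest.raises(ValueError):
            build_universe(genes, "coding")


class TestContingency:
    def test_small_example(self):
        t = build_contingency({"a", "b"}, {"b", "c"}, {"a", "b", "c", "d"})
        assert t == ContingencyTable(1, 1, 1, 1)

    def test_larger_universe_only_grows_n00(self):
        t = build_contingency({"a", "b"}, {"b", "c"},
                              {"a", "b", "c", "d", "e", "f"})
        assert t == ContingencyTable(1, 1, 1, 3)

    def test_tg_disjoint_from_universe(self):
        t = build_contingency({"x", "y"}, {"b", "c"}, {"a", "b", "c", "d"})
        assert t == ContingencyTable(0, 0, 2, 2)

    def test_cells_sum_to_universe(self):
        uni = {f"g{i}" for i in range(50)}
        t = build_contingency({"g1", "g2", "g3"}, {"g2", "g9"}, uni)
        assert t.total == 50


class TestFisher:
    def test_discordance_stratum_table(self):
        # 117/329 vs 11,704/42,373 known-function support
        p = fisher_test(ContingencyTable(117, 212, 11704, 30669), "greater")
        assert p == pytest.approx(0.001, abs=2e-4)

    def test_independence_point_by_enumeration(self):
        # X ~ Hypergeom(N=4, K=2, n=2): P(X >= 1) = 1 - 1/6
        p = fisher_test(ContingencyTable(1, 1, 1, 1), "greater")
        assert p == pytest.approx(5 / 6, abs=1e-12)

    def test_perfect_split_closed_form(self):
        p = fisher_test(ContingencyTable(5, 0, 0, 5), "greater")
        assert p == pytest.approx(1 / math.comb(10, 5), rel=1e-9)


class TestGTest:
    def test_hand_computed_statistic(self):
        g, p = g_test(ContingencyTable(20, 10, 10, 20))
        assert g == pytest.approx(6.80, abs=0.01)
        assert p == pytest.approx(0.0091, abs=5e-4)

    def test_independent_table_gives_zero(self):
        g, p = g_test(ContingencyTable(8, 8, 8, 8))
        assert g == pytest.approx(0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_margin_errors(self):
        with pytest.raises(ZeroMarginError):
            g_test(ContingencyTable(0, 0, 5, 5))

    def test_matches_scipy_loglikelihood_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = ContingencyTable(*rng.integers(1, 100, size=4))
            g, p = g_test(t)
            g_ref, p_ref, _, _ = stats.chi2_contingency(
                t.as_array(), correction=False, lambda_="log-likelihood"
            )
            assert g == pytest.approx(g_ref, rel=1e-10)
            assert p == pytest.approx(p_ref, rel=1e-10)

    def test_approximates_fisher_for_well_filled_tables(self):
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 100:
            t = ContingencyTable(*rng.integers(20, 200, size=4))
            _, p_g = g_test(t)
            p_f = fisher_test(t, "two-sided")
            if p_f < 1e-12:  # both tiny; ratio comparison unstable
                continue
            assert p_g <= 2 * p_f and p_f <= 2 * max(p_g, 1e-300)
            checked += 1


class TestPhi:
    def test_perfect_agreement(self):
        assert phi_coefficient(ContingencyTable(7, 0, 0, 7)) == pytest.approx(1.0)

    def test_independence(self):
        assert phi_coefficient(ContingencyTable(1, 1, 1, 1)) == 0

    def test_tf_pair_sharing_value(self):
        assert phi_coefficient(
            ContingencyTable(5866, 5339, 6568, 55763)
        ) == pytest.approx(0.401, abs=5e-4)

    def test_zero_margin_errors(self):
        with pytest.raises(ZeroMarginError):
            phi_coefficient(ContingencyTable(3, 5, 0, 0))

    def test_matches_pearson_on_indicators(self):
        """phi equals the Pearson correlation of the expanded 0/1 vectors
        (1,000 random tables, |difference| < 1e-12)."""
        rng = np.random.default_rng(2)
        for _ in range(1000):
            t = ContingencyTable(*rng.integers(1, 60, size=4))
            a = np.r_[np.ones(t.n11 + t.n10), np.zeros(t.n01 + t.n00)]
            b = np.r_[np.ones(t.n11), np.zeros(t.n10),
                      np.ones(t.n01), np.zeros(t.n00)]
            expected = stats.pearsonr(a, b)[0]
            assert abs(phi_coefficient(t) - expected) < 1e-12

    @settings(deadline=None, max_examples=200)
    @given(tables)
    def test_symmetric_under_variable_swap(self, t):
        swapped = ContingencyTable(t.n11, t.n01, t.n10, t.n00)
        assert phi_coefficient(t) == pytest.approx(phi_coefficient(swapped),
                                                   rel=1e-12)


class TestOddsRatio:
    @settings(deadline=None, max_examples=200)
    @given(tables, st.integers(1, 100))
    def test_universe_padding_inflates_or(self, t, extra):
        """Adding genes that are neither TGs nor term members (n00 grows)
        strictly increases the odds ratio — the universe-inflation effect."""
        padded = ContingencyTable(t.n11, t.n10, t.n01, t.n00 + extra)
        assert odds_ratio(padded) > odds_ratio(t)

    def test_log2_or_haldane_only_on_zero_cells(self):
        t = ContingencyTable(4, 2, 2, 4)
        assert log2_odds_ratio(t) == pytest.approx(math.log2(4.0))
        tz = ContingencyTable(4, 0, 2, 4)
        assert math.isfinite(log2_odds_ratio(tz))


class TestBH:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5]
        )

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 5), [0.2] * 5)

    def test_q_dominates_p_and_sorted_monotone(self):
        rng = np.random.default_rng(3)
        p = rng.random(200)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestAnnotate:
    def test_planted_link_is_top_record(self):
        from conftest import make_scenario

        s = make_scenario(seed=21, n_planted_links=1,
                          target_rate_in_term=0.9, background_rate=0.02)
        rec = annotate_tfs(s["compendium"], s["collections"], s["universes"])
        top = rec.loc[rec["p_greater"].idxmin()]
        planted = s["truth"].iloc[0]
        assert (top["tf_id"], top["source"], top["term_id"]) == (
            planted["tf_id"], planted["source"], planted["term_id"]
        )

    def test_tiny_terms_skipped(self, planted_scenario):
        s = planted_scenario
        rec = annotate_tfs(s["compendium"], s["collections"], s["universes"],
                           min_term_size=10**6)
        assert rec.empty

    def test_label_equivariance(self):
        """Relabeling genes consistently in the compendium and collections
        leaves every p-value unchanged."""
        from conftest import make_scenario
        from tfannot.io import GeneSetCollection

        s = make_scenario(seed=22, n_genes=300, n_tfs=5)
        rec = annotate_tfs(s["compendium"], s["collections"], s["universes"])

        relabel = {g: f"X{g}" for g in s["genes"]["gene_id"]}
        comp2 = Compendium()
        for (tf, tg), ev in s["compendium"].edges.items():
            for e in ev:
                comp2.add_edge(relabel[tf], relabel[tg], e)
        colls2 = [
            GeneSetCollection(
                name=c.name,
                sets={t: frozenset(relabel[g] for g in m)
                      for t, m in c.sets.items()},
                source_type=c.source_type,
            )
            for c in s["collections"]
        ]
        unis2 = {
            k: GeneUniverse(u.name, frozenset(relabel[g] for g in u.members))
            for k, u in s["universes"].items()
        }
        rec2 = annotate_tfs(comp2, colls2, unis2)
        key = ["source", "term_id"]
        merged = rec.merge(rec2, on=key, suffixes=("_a", "_b"))
        merged = merged[merged["tf_id_b"] == "X" + merged["tf_id_a"]]
        assert len(merged) == len(rec)
        np.testing.assert_allclose(merged["p_greater_a"], merged["p_greater_b"])

    def test_per_source_bh_grouping(self, planted_associations):
        rec = planted_associations
        for _, grp in rec.groupby("source"):
            ok = grp.dropna(subset=["p_two_sided"])
            np.testing.assert_allclose(
                ok.sort_values("p_two_sided")["q_value"],
                bh_fdr(ok.sort_values("p_two_sided")["p_two_sided"]),
            )


class TestPlantedRecovery:
    def test_precision_and_recall_at_fdr_05(self, planted_scenario,
                                            planted_associations):
        s = planted_scenario
        planted = set(map(tuple, s["truth"][["tf_id", "source", "term_id"]]
                          .itertuples(index=False)))
        pred = planted_associations
        hits = pred[pred["significant"] & (pred["direction"] == "positive")]
        predicted = set(map(tuple, hits[["tf_id", "source", "term_id"]]
                            .itertuples(index=False)))
        tp = len(planted & predicted)
        assert tp / len(predicted) >= 0.9   # precision
        assert tp / len(planted) >= 0.8     # recall

    def test_auc_on_planted_scenario(self, planted_scenario,
                                     planted_associations):
        s = planted_scenario
        planted = set(map(tuple, s["truth"][["tf_id", "source", "term_id"]]
                          .itertuples(index=False)))
        rec = planted_associations
        labels = [
            (tf, src, term) in planted
            for tf, src, term in zip(rec["tf_id"], rec["source"], rec["term_id"])
        ]
        assert roc_auc(labels, rec["p_greater"]) > 0.9

    def test_auc_near_half_without_signal(self, null_scenario):
        s = null_scenario
        rec = annotate_tfs(s["compendium"], s["collections"], s["universes"])
        planted = set(map(tuple, s["truth"][["tf_id", "source", "term_id"]]
                          .itertuples(index=False)))
        labels = [
            (tf, src, term) in planted
            for tf, src, term in zip(rec["tf_id"], rec["source"], rec["term_id"])
        ]
        assert roc_auc(labels, rec["p_greater"]) == pytest.approx(0.5, abs=0.05)
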