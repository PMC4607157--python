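"""Differential expression, clustering, correlation and enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from srnapipe.diffstats import (
    bh_adjust,
    capped_log2fc,
    cluster_samples,
    de_table,
    expression_filter,
    hypergeometric_enrichment,
    isomir_de,
    morna_mirna_correlation,
    nb_exact_test,
    summary_report,
)
from srnapipe.quantify import normalize, size_factors, fit_and_select
from srnapipe.simdata import SimConfig, abstract_truth, simulate_counts

SAMPLES = ["A1", "A2", "A3", "B1", "B2", "B3"]
GROUPS = {s: s[0] for s in SAMPLES}
UNIT_SF = pd.Series(1.0, index=SAMPLES)


class TestExpressionFilter:
    def test_strictly_above_median(self):
        norm = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
        assert set(expression_filter(norm)) == {"c", "d"}

    def test_all_equal_totals_retain_nothing(self):
        norm = pd.DataFrame({"x": [2.0, 2.0, 2.0]}, index=list("abc"))
        assert len(expression_filter(norm)) == 0

    def test_single_feature_never_above_its_own_median(self):
        norm = pd.DataFrame({"x": [7.0]}, index=["a"])
        assert len(expression_filter(norm)) == 0


class TestCappedLog2FC:
    def test_zero_in_disease_reports_minus_cap(self):
        assert capped_log2fc(2493, 0) == -15.0

    def test_equal_means_give_zero(self):
        assert capped_log2fc(100, 100) == 0.0

    def test_huge_ratio_clamped(self):
        assert capped_log2fc(1, 2**20) == 15.0

    def test_both_zero_is_nan(self):
        assert np.isnan(capped_log2fc(0, 0))

    @given(
        a=st.floats(0.01, 1e6, allow_nan=False),
        b=st.floats(0.01, 1e6, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric(self, a, b):
        assert capped_log2fc(a, b) == pytest.approx(-capped_log2fc(b, a), abs=1e-9)


class TestNBExactTest:
    def test_zero_dispersion_binomial_reduction(self):
        counts = pd.Series([8, 0, 0, 2, 0, 0], index=SAMPLES)
        p = nb_exact_test(counts, UNIT_SF, GROUPS, 1e-12)
        assert p == pytest.approx(112 / 1024, abs=1e-9)

    def test_equals_exact_binomial_for_all_totals_up_to_30(self):
        """At zero dispersion and equal size-factor sums the conditional law
        is Binomial(K, 1/2): exhaustive oracle over all splits, K <= 30."""
        for K in range(1, 31):
            pmf = stats.binom.pmf(np.arange(K + 1), K, 0.5)
            for ka in range(K + 1):
                counts = pd.Series([ka, 0, 0, K - ka, 0, 0], index=SAMPLES)
                expected = pmf[pmf <= pmf[ka] * (1 + 1e-8)].sum()
                got = nb_exact_test(counts, UNIT_SF, GROUPS, 1e-12)
                assert got == pytest.approx(expected, abs=1e-9)

    def test_balanced_split_with_symmetric_parameters_gives_p_one(self):
        counts = pd.Series([5, 0, 0, 5, 0, 0], index=SAMPLES)
        assert nb_exact_test(counts, UNIT_SF, GROUPS, 1e-12) == pytest.approx(1.0)

    def test_zero_total_is_nan(self):
        counts = pd.Series(0, index=SAMPLES)
        assert np.isnan(nb_exact_test(counts, UNIT_SF, GROUPS, 0.1))

    def test_stronger_evidence_on_average_with_doubled_counts(self):
        """Doubling both groups' counts does not increase the p-value on
        average (Monte-Carlo check)."""
        rng = np.random.default_rng(2)
        diffs = []
        for _ in range(60):
            ka, kb = int(rng.integers(5, 40)), int(rng.integers(5, 40))
            c1 = pd.Series([ka, 0, 0, kb, 0, 0], index=SAMPLES)
            c2 = 2 * c1
            p1 = nb_exact_test(c1, UNIT_SF, GROUPS, 0.05)
            p2 = nb_exact_test(c2, UNIT_SF, GROUPS, 0.05)
            diffs.append(p2 - p1)
        assert np.mean(diffs) <= 0.0


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagates_and_is_excluded_from_m(self):
        adj = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(adj[1])
        assert np.allclose(adj[[0, 2]], bh_adjust([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
    @settings(max_examples=60, deadline=None)
    def test_permutation_invariant_and_monotone(self, ps):
        adj = bh_adjust(ps)
        order = np.argsort(ps, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()
        perm = np.random.default_rng(0).permutation(len(ps))
        adj_perm = bh_adjust([ps[i] for i in perm])
        assert np.allclose(adj_perm, adj[perm])
        assert (adj >= np.asarray(ps) - 1e-12).all()


class TestPlantedDE:
    def test_sensitivity_and_fdr_on_planted_effects(self):
        """|log2FC| = 2 in 10% of features at 1M reads/sample, 3v3:
        sensitivity >= 0.6 among features passing the expression filter and
        empirical FDP <= 0.10 (averaged over seeds 0-4). Uses the fit-only
        dispersion mode, the power-oriented end of the sharing tradeoff."""
        sens, n_false, n_called = [], 0, 0
        for seed in range(5):
            cfg = SimConfig(
                de_fraction=0.1, de_log2fc=2.0, nb_dispersion=0.2,
                mean_depth=1_000_000, seed=seed, control_only_morna=False,
            )
            truth = abstract_truth(cfg, 500)
            counts = simulate_counts(cfg, truth)
            sf = size_factors(counts)
            fit = fit_and_select(counts, sf, truth.groups)
            de = de_table(counts, sf, truth.groups, fit, sharing="fit-only")
            called = set(de.index[de["significant"]])
            true_de = {f for f, (d, _) in truth.de_status.items() if d}
            testable = set(expression_filter(normalize(counts, sf)))
            testable_de = true_de & testable
            sens.append(len(called & testable_de) / len(testable_de))
            n_false += len(called - true_de)
            n_called += len(called)
        assert np.mean(sens) >= 0.6
        assert n_false / max(1, n_called) <= 0.10

    def test_direction_convention_disease_over_control(self):
        counts = pd.DataFrame(
            {s: [100 if s.startswith("A") else 400] for s in SAMPLES}, index=["f"]
        )
        de = de_table(counts, UNIT_SF, GROUPS, dispersion_fit=_const_fit(0.01))
        # B (disease) is 4x A (control): log2fc = +2
        assert de.loc["f", "log2fc"] == pytest.approx(2.0, abs=1e-9)


def _const_fit(alpha):
    from srnapipe.quantify import DispersionFit

    return DispersionFit("parametric", lambda q: np.full_like(np.asarray(q, float), alpha), 0.0, {})


class TestIsomirDE:
    def _iso_frame(self, rows):
        df = pd.DataFrame(rows, columns=["isomir_id", "mature_id"] + SAMPLES)
        return df.set_index("isomir_id")

    def test_identical_groups_not_flagged(self):
        iso = self._iso_frame([["i1", "m1", 50, 52, 48, 50, 52, 48]])
        out = isomir_de(iso, UNIT_SF, GROUPS)
        assert not out["significant"].any()
        assert out.loc["i1", "log2fc"] == pytest.approx(0.0, abs=0.05)

    def test_planted_fourfold_shift_flagged(self):
        rows = [["i0", "m0", 400, 410, 390, 1600, 1650, 1580]]
        rows += [[f"i{k}", f"m{k}", 100, 101, 99, 100, 102, 98] for k in range(1, 8)]
        out = isomir_de(self._iso_frame(rows), UNIT_SF, GROUPS)
        assert bool(out.loc["i0", "significant"])

    def test_low_contribution_isomir_excluded_from_correlation_set(self):
        iso = self._iso_frame(
            [["i1", "m1", 5, 5, 5, 5, 5, 5], ["i2", "m1", 95, 95, 95, 95, 95, 95]]
        )
        totals = pd.DataFrame({s: [100] for s in SAMPLES}, index=["m1"])
        out = isomir_de(iso, UNIT_SF, GROUPS, feature_totals=totals)
        assert not bool(out.loc["i1", "in_correlation_set"])  # 5% < 10%
        assert bool(out.loc["i2", "in_correlation_set"])


class TestClusterSamples:
    def test_identical_samples_merge_at_height_zero(self):
        norm = pd.DataFrame({"A": [3.0, 8.0], "B": [3.0, 8.0], "C": [9.0, 1.0]})
        Z, dist, newick = cluster_samples(norm)
        assert Z[0, 2] == pytest.approx(0.0)
        assert dist.loc["A", "B"] == 0.0

    def test_strong_group_effect_separates_groups_first(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(10, 100, 40)
        data = {}
        for s in SAMPLES:
            shift = 8.0 if s.startswith("B") else 1.0
            data[s] = base * shift * rng.uniform(0.95, 1.05, 40)
        Z, _, newick = cluster_samples(pd.DataFrame(data))
        # the root bipartition must put A* on one side, B* on the other
        from scipy.cluster import hierarchy

        labels = sorted(data)
        cut = hierarchy.fcluster(Z, 2, criterion="maxclust")
        sides = {g: {labels[i][0] for i in range(6) if cut[i] == g} for g in set(cut)}
        assert sorted(map(tuple, sides.values())) == [("A",), ("B",)]
        assert "A1" in newick and "B3" in newick

    def test_third_quartile_filter_keeps_top_two_of_eight(self):
        """Totals 1..8 with a type-7 third quartile of 6.25: only features
        7 and 8 survive the above_q3 filter."""
        norm = pd.DataFrame(
            {"A": np.arange(1.0, 9.0), "B": np.zeros(8), "C": np.zeros(8)},
            index=[f"f{i}" for i in range(1, 9)],
        )
        Z, dist, _ = cluster_samples(norm, filter="above_q3")
        # distance A-B now uses exactly the two retained features
        expected = np.sqrt(np.log2(8.0) ** 2 + np.log2(9.0) ** 2)
        assert dist.loc["A", "B"] == pytest.approx(expected)

    def test_too_few_features_after_filter_rejected(self):
        norm = pd.DataFrame({"A": [1.0], "B": [2.0]})
        with pytest.raises(ValueError):
            cluster_samples(norm)


class TestMornaMirnaCorrelation:
    def _meta(self):
        return pd.DataFrame(
            {
                "class": ["moRNA", "known_miRNA", "known_miRNA"],
                "hairpin_id": ["h1", "h1", "h1"],
                "arm": ["5p", "5p", "3p"],
            },
            index=["moR-1-5p", "miR-1-5p", "miR-1-3p"],
        )

    def test_identical_profiles_correlate_perfectly(self):
        norm = pd.DataFrame(
            [[1, 5, 3, 8, 2, 9]] * 2 + [[4, 4, 4, 4, 4, 4]],
            index=["moR-1-5p", "miR-1-5p", "miR-1-3p"],
            columns=SAMPLES,
            dtype=float,
        )
        pairs = morna_mirna_correlation(norm, self._meta())
        assert len(pairs) == 1  # only the same-arm miRNA is a cognate
        assert pairs.iloc[0]["mirna_id"] == "miR-1-5p"
        assert pairs.iloc[0]["r"] == pytest.approx(1.0)

    def test_exact_antisymmetry_gives_minus_one(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        norm = pd.DataFrame(
            [x, 7 - x, x * 0 + 1],
            index=["moR-1-5p", "miR-1-5p", "miR-1-3p"],
            columns=SAMPLES,
        )
        pairs = morna_mirna_correlation(norm, self._meta())
        assert pairs.iloc[0]["r"] == pytest.approx(-1.0)

    def test_independent_profiles_center_on_zero(self):
        """1000 independent NB profile pairs: mean r within +-0.05 of 0."""
        rng = np.random.default_rng(8)
        rows, names, klass, hairpin, arm = [], [], [], [], []
        for i in range(1000):
            rows.append(rng.negative_binomial(5, 0.1, size=6).astype(float))
            rows.append(rng.negative_binomial(5, 0.1, size=6).astype(float))
            names += [f"moR-{i}-5p", f"miR-{i}-5p"]
            klass += ["moRNA", "known_miRNA"]
            hairpin += [f"h{i}"] * 2
            arm += ["5p"] * 2
        norm = pd.DataFrame(rows, index=names, columns=SAMPLES)
        meta = pd.DataFrame({"class": klass, "hairpin_id": hairpin, "arm": arm}, index=names)
        pairs = morna_mirna_correlation(norm, meta)
        assert abs(pairs["r"].mean()) <= 0.05

    def test_constant_profile_gives_nan(self):
        norm = pd.DataFrame(
            [[2.0] * 6, [1, 5, 3, 8, 2, 9], [0.0] * 6],
            index=["moR-1-5p", "miR-1-5p", "miR-1-3p"],
            columns=SAMPLES,
        )
        pairs = morna_mirna_correlation(norm, self._meta())
        assert np.isnan(pairs.iloc[0]["r"])


class TestEnrichment:
    def test_closed_form_full_overlap(self):
        universe = {f"g{i}" for i in range(20)}
        sets = {"S": set(list(universe)[:5])}
        query = set(sets["S"])
        out = hypergeometric_enrichment(query, sets, universe)
        assert out.iloc[0]["pvalue"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        sets = {"S": set(list(sorted(universe))[:5])}
        query = set(sorted(universe)[10:15])
        out = hypergeometric_enrichment(query, sets, universe)
        assert out.iloc[0]["pvalue"] == pytest.approx(1.0)

    def test_query_equals_universe_forces_full_overlap(self):
        universe = {f"g{i}" for i in range(12)}
        sets = {"S": set(sorted(universe)[:4])}
        out = hypergeometric_enrichment(set(universe), sets, universe)
        assert out.iloc[0]["overlap"] == 4
        assert out.iloc[0]["pvalue"] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(set(), {"S": {"g"}}, set())


class TestSummaryReport:
    def _fake(self, n_known, n_new, n_mor):
        names = (
            [f"k{i}" for i in range(n_known)]
            + [f"n{i}" for i in range(n_new)]
            + [f"m{i}" for i in range(n_mor)]
        )
        klass = ["known_miRNA"] * n_known + ["new_miRNA"] * n_new + ["moRNA"] * n_mor
        meta = pd.DataFrame({"class": klass}, index=names)
        counts = pd.DataFrame(1, index=names, columns=SAMPLES)
        return counts, meta

    def test_grand_total_from_class_counts(self):
        counts, meta = self._fake(784, 34, 99)
        out = summary_report(counts, meta, GROUPS)
        assert out.loc["Total", "Total"] == 917
        assert out.loc["Total new", "Total"] == 133

    def test_group_columns_require_expression_in_group(self):
        counts, meta = self._fake(2, 1, 1)
        counts.loc["m0", ["B1", "B2", "B3"]] = 0
        out = summary_report(counts, meta, GROUPS)
        assert out.loc["moRNAs", "A"] == 1 and out.loc["moRNAs", "B"] == 0
        assert out.loc["moRNAs", "Total"] == 1

    def test_empty_catalogue_is_all_zeros(self):
        counts = pd.DataFrame(columns=SAMPLES, dtype=int)
        meta = pd.DataFrame(columns=["class"])
        out = summary_report(counts, meta, GROUPS)
        assert (out.to_numpy() == 0).all()
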