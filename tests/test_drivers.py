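import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from driverrank import (
    call_personalized_drivers,
    chauvenet_high,
    classify_novel_drivers,
    cnv_to_alterations,
    condorcet_aggregate,
    maxstat_cutoff,
)

from conftest import make_catalog


class TestMaxstatCutoff:
    def test_separating_cutoff_matches_brute_force(self):
        pct = pd.Series({"d1": 95.0, "d2": 90.0, "x1": 10.0, "x2": 20.0, "x3": 30.0})
        gold = {"d1", "d2"}
        result = maxstat_cutoff(pct, gold)
        # any cutoff in (30, 90] separates perfectly; the smallest candidate wins
        assert 30.0 < result.cutoff <= 90.0
        assert not result.low_confidence

        # independent oracle: enumerate every candidate, score with scipy's
        # uncorrected chi-square, keep the smallest maximizer
        values = pct.to_numpy()
        lo, hi = np.quantile(values, [0.10, 0.90])
        best_cut, best_stat = None, -1.0
        for c in np.unique(values[(values >= lo) & (values <= hi)]):
            above = values >= c
            is_gold = np.array([g in gold for g in pct.index])
            table = np.array(
                [
                    [(above & is_gold).sum(), (above & ~is_gold).sum()],
                    [(~above & is_gold).sum(), (~above & ~is_gold).sum()],
                ]
            )
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                stat = 0.0
            else:
                stat = chi2_contingency(table, correction=False)[0]
            if stat > best_stat:
                best_cut, best_stat = c, stat
        assert result.cutoff == pytest.approx(best_cut)
        assert result.statistic == pytest.approx(best_stat)

    def test_flat_signal_flagged_low_confidence(self):
        pct = pd.Series({"a": 50.0, "b": 50.0, "c": 50.0, "d": 50.0})
        result = maxstat_cutoff(pct, {"a", "b"})
        assert result.low_confidence
        assert result.cutoff == 50.0

    def test_no_gold_genes_is_an_error(self):
        pct = pd.Series({"a": 50.0, "b": 60.0})
        with pytest.raises(ValueError, match="explicit cutoff"):
            maxstat_cutoff(pct, {"zz"})


class TestChauvenet:
    def test_closed_form_decision(self):
        # z = 3.5 on n = 10: expected extreme count 10 * P(Z > 3.5) << 0.5
        rng = np.random.default_rng(0)
        values = rng.normal(50, 10, size=10)
        values = (values - values.mean()) / values.std(ddof=1) * 10 + 50
        res = chauvenet_high(values, 85.0)
        assert res.z == pytest.approx(3.5)
        expected = 10 * 0.5 * math.erfc(3.5 / math.sqrt(2))
        assert res.expected_extreme == pytest.approx(expected, rel=1e-9)
        assert res.is_outlier is True

    def test_value_at_mean_not_an_outlier(self):
        values = np.array([10.0, 20.0, 30.0, 40.0])
        res = chauvenet_high(values, values.mean())
        assert res.is_outlier is False

    def test_one_sided_never_flags_low_values(self):
        values = np.arange(20.0)
        res = chauvenet_high(values, -100.0)
        assert res.is_outlier is False

    @pytest.mark.parametrize("values", [[1.0, 2.0], [5.0, 5.0, 5.0]])
    def test_insufficient_data_is_explicit(self, values):
        res = chauvenet_high(np.array(values), 10.0)
        assert res.is_outlier is None
        assert not res.callable

    def test_matches_survival_function_on_random_cases(self):
        """Flag decisions equal the n * P(Z > z) < 0.5 rule computed via erfc."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(3, 60))
            values = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), size=n)
            value = rng.normal(values.mean(), 4 * values.std(ddof=1) + 0.1)
            res = chauvenet_high(values, value)
            z = (value - values.mean()) / values.std(ddof=1)
            expected_flag = n * 0.5 * math.erfc(z / math.sqrt(2)) < 0.5
            assert res.is_outlier == expected_flag


class TestPersonalizedCalls:
    def _cohort(self, patient_pct, cohort_pct, altered, gold=("K1", "K2")):
        """Build a 1 + n_background patient cohort around gene percentiles."""
        patients = ["p0"] + [f"q{i}" for i in range(len(next(iter(cohort_pct.values()))))]
        data = {}
        for gene, background in cohort_pct.items():
            data[gene] = [patient_pct[gene]] + list(background)
        pct = pd.DataFrame(data, index=patients).T
        catalog = make_catalog(
            {"p0": {g: "point_mutation" for g in altered}},
            patients=patients,
        )
        return pct, catalog, set(gold)

    def test_outlier_above_cutoff_is_called(self):
        rng = np.random.default_rng(1)
        background = rng.normal(60, 8, size=30)
        pct, catalog, gold = self._cohort(
            patient_pct={"K1": 95.0, "K2": 90.0, "G": 99.0, "L": 10.0},
            cohort_pct={
                "K1": rng.normal(90, 3, 30),
                "K2": rng.normal(88, 3, 30),
                "G": background,
                "L": rng.normal(12, 3, 30),
            },
            altered=["G", "L"],
        )
        calls = call_personalized_drivers("p0", pct, catalog, gold=gold)
        assert calls.genes() == ["G"]
        call = calls.calls[0]
        assert call.percentile == 99.0
        assert call.frequency == pytest.approx(1 / 31)
        assert call.classification == "personalized"  # 1/31 = 3.2% >= 2%
        assert not call.known

        # with a looser rarity threshold the same call is tagged rare
        rare = call_personalized_drivers(
            "p0", pct, catalog, gold=gold, rare_threshold=0.05
        )
        assert rare.calls[0].classification == "personalized_rare"

    def test_uniformly_high_gene_is_not_an_outlier(self):
        pct, catalog, gold = self._cohort(
            patient_pct={"K1": 95.0, "G": 99.0, "L": 10.0, "M": 20.0},
            cohort_pct={
                "K1": [94.0] * 20,
                "G": [99.0] * 20,  # high in everyone: typical, not personalized
                "L": [11.0] * 20,
                "M": [21.0] * 20,
            },
            altered=["G"],
            gold=("K1",),
        )
        calls = call_personalized_drivers("p0", pct, catalog, gold=gold)
        assert calls.genes() == []

    def test_unaltered_genes_never_called(self):
        rng = np.random.default_rng(2)
        pct, catalog, gold = self._cohort(
            patient_pct={"K1": 95.0, "G": 99.9, "L": 15.0},
            cohort_pct={
                "K1": rng.normal(90, 3, 20),
                "G": rng.normal(55, 6, 20),
                "L": rng.normal(14, 3, 20),
            },
            altered=["L"],  # the spectacular G is not altered in p0
            gold=("K1",),
        )
        calls = call_personalized_drivers("p0", pct, catalog, gold=gold)
        assert "G" not in calls.genes()

    def test_no_alterations_gives_empty_call_set(self):
        rng = np.random.default_rng(3)
        pct = pd.DataFrame(
            rng.uniform(1, 100, (4, 10)),
            index=["K1", "a", "b", "c"],
            columns=[f"p{i}" for i in range(10)],
        )
        catalog = make_catalog(
            {"p1": {"a": "point_mutation"}}, patients=list(pct.columns)
        )
        calls = call_personalized_drivers("p0", pct, catalog, gold={"K1"})
        assert calls.calls == []

    def test_explicit_cutoff_skips_gold_requirement(self):
        rng = np.random.default_rng(4)
        pct, catalog, _ = self._cohort(
            patient_pct={"G": 99.0, "a": 40.0, "b": 30.0, "c": 20.0},
            cohort_pct={
                "G": rng.normal(60, 8, 30),
                "a": rng.normal(40, 5, 30),
                "b": rng.normal(30, 5, 30),
                "c": rng.normal(20, 5, 30),
            },
            altered=["G"],
        )
        calls = call_personalized_drivers("p0", pct, catalog, cutoff=95.0)
        assert calls.genes() == ["G"]
        with pytest.raises(ValueError):
            call_personalized_drivers("p0", pct, catalog)

    def test_rare_tagging_monotone_in_threshold(self, small_cohort, small_cohort_percentiles):
        gold = set(list(small_cohort.driver_union())[:5])
        patient = small_cohort.patients[0]
        n_rare = []
        for threshold in (0.30, 0.15, 0.05, 0.01):
            calls = call_personalized_drivers(
                patient, small_cohort_percentiles, small_cohort.catalog,
                cutoff=80.0, rare_threshold=threshold,
            )
            n_rare.append(
                sum(c.classification == "personalized_rare" for c in calls.calls)
            )
        assert all(a >= b for a, b in zip(n_rare, n_rare[1:]))


class TestNovelDrivers:
    def _aggregate(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(40)]
        patients = [f"p{i}" for i in range(50)]
        pct = pd.DataFrame(
            rng.uniform(1, 100, (40, 50)), index=genes, columns=patients
        )
        # g0 altered in 10 patients (20%), strong ranks; others sporadic
        assignments = {p: {} for p in patients}
        for p in patients[:10]:
            assignments[p]["g0"] = "point_mutation"
            pct.at["g0", p] = 99.0
        for i, p in enumerate(patients):
            assignments[p][f"g{1 + i % 39}"] = "point_mutation"
        catalog = make_catalog(assignments, patients=patients)
        return condorcet_aggregate(pct, catalog), catalog

    def test_three_criteria(self):
        agg, catalog = self._aggregate()
        rank_of = {g: i for i, g in enumerate(agg.order)}
        novel = classify_novel_drivers(agg, catalog, gold=set(), top_n=30, min_freq=0.02)
        assert all(rank_of[g] < 30 for g in novel)
        assert all(catalog.frequency(g) > 0.02 for g in novel)
        assert "g0" in novel

        # a gold gene is excluded no matter how high it ranks
        assert "g0" not in classify_novel_drivers(
            agg, catalog, gold={"g0"}, top_n=30, min_freq=0.02
        )
        # outside the top N it is excluded regardless of frequency
        assert classify_novel_drivers(agg, catalog, gold=set(), top_n=0) == []

    def test_frequency_strictly_above_threshold(self):
        agg, catalog = self._aggregate()
        novel = classify_novel_drivers(agg, catalog, gold=set(), top_n=40, min_freq=0.0199)
        freq_ok = [g for g in novel if catalog.frequency(g) > 0.0199]
        assert novel == freq_ok
        # with min_freq at exactly 1/50, genes at frequency 0.02 drop out
        strict = classify_novel_drivers(agg, catalog, gold=set(), top_n=40, min_freq=0.02)
        assert all(catalog.frequency(g) > 0.02 for g in strict)


class TestCnvConversion:
    def _frames(self):
        cnv = pd.DataFrame(
            {"p1": {"a": 1.2, "b": 1.2, "c": 0.8, "d": -1.5}},
        )
        diff = pd.DataFrame(
            {"p1": {"a": 2.0, "b": -2.0, "c": 3.0, "d": -1.0}},
        )
        return cnv, diff

    def test_two_fold_with_concordant_expression(self):
        cnv, diff = self._frames()
        events = cnv_to_alterations(cnv, diff)
        records = {(r.gene, r.category) for r in events.itertuples()}
        assert ("a", "cnv_amp") in records  # amplified, expression up
        assert ("d", "cnv_del") in records  # deleted, expression down
        assert all(g != "b" for g, _ in records)  # discordant sign excluded
        assert all(g != "c" for g, _ in records)  # below two-fold excluded

    def test_concordance_optional(self):
        cnv, diff = self._frames()
        events = cnv_to_alterations(cnv, diff, expr_sign_required=False)
        assert {(r.gene, r.category) for r in events.itertuples()} == {
            ("a", "cnv_amp"),
            ("b", "cnv_amp"),
            ("d", "cnv_del"),
        }

    def test_fold_threshold_scales(self):
        cnv, diff = self._frames()
        events = cnv_to_alterations(cnv, diff, fold_threshold=1.5)
        genes = set(events["gene"])
        assert "c" in genes  # 0.8 >= log2(1.5)
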