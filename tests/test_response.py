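"""Tests of treatment-level growth statistics (contrasts, Q10, delta-EAF, partitions)."""

import itertools

import numpy as np
import pandas as pd
import pytest

import fieldqsip as fq

from .conftest import fake_eaf_results, true_eaf_series


class TestScalarContrasts:
    def test_percent_increase_examples(self):
        assert round(fq.percent_increase(0.095, 0.070)) == 36
        assert round(fq.percent_increase(0.176, 0.070)) == 151
        assert fq.percent_increase(0.3, 0.3) == 0.0
        assert fq.fold_change(0.176, 0.070) == pytest.approx(2.514, abs=0.001)

    def test_percent_increase_rejects_zero_control(self):
        with pytest.raises(ValueError):
            fq.percent_increase(0.1, 0.0)

    def test_q10_printed_values(self):
        assert fq.q10(1.36, 1.6) == pytest.approx(6.83, abs=0.01)
        assert fq.q10(2.51, 1.6) == pytest.approx(314.8, abs=0.5)

    @pytest.mark.parametrize("r", [0.3, 1.0, 2.7])
    def test_q10_identities(self, r):
        assert fq.q10(r, 10.0) == pytest.approx(r)
        assert fq.q10(1.0, r) == pytest.approx(1.0)
        # log-linearity: log Q10 = (10 / dT) log r
        assert np.log(fq.q10(r, 1.6)) == pytest.approx((10 / 1.6) * np.log(r))

    def test_q10_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fq.q10(0.0, 1.6)
        with pytest.raises(ValueError):
            fq.q10(1.5, 0.0)


class TestAssemblageContrast:
    def test_identical_groups_share_letter(self):
        rows = [(f"t{i}", tr, 0.1) for i in range(4) for tr in ("a", "b")]
        res = fake_eaf_results(rows)
        with pytest.warns(UserWarning, match="zero variance"):
            con = fq.assemblage_mean_contrast(res)
        assert con.anova_f == pytest.approx(0.0)
        assert con.letters["a"] == con.letters["b"]

    def test_disjoint_constant_groups_distinct_letters(self):
        rows = [(f"t{i}", "a", 0.2) for i in range(4)]
        rows += [(f"u{i}", "b", 1.0) for i in range(4)]
        res = fake_eaf_results(rows)
        with pytest.warns(UserWarning, match="zero variance"):
            con = fq.assemblage_mean_contrast(res)
        assert con.anova_p < 1e-6
        assert con.letters["a"] != con.letters["b"]

    def test_tukey_matches_permutation_oracle(self):
        """Tukey rejections agree with a max-|t| permutation contrast."""
        rng = np.random.default_rng(5)
        n = 15
        groups = {"a": rng.normal(0.0, 1, n),
                  "b": rng.normal(0.15, 1, n),   # indistinguishable from a
                  "c": rng.normal(2.5, 1, n)}    # clearly shifted
        rows = [{"taxon_id": f"{g}{i}", "treatment": g, "mean_eaf": v}
                for g, vals in groups.items() for i, v in enumerate(vals)]
        con = fq.assemblage_mean_contrast(fake_eaf_results(rows),
                                          growing_only=False)
        tukey = {frozenset((r.group1, r.group2)): bool(r.reject)
                 for r in con.tukey.itertuples()}

        # oracle: permutation null of the maximum pairwise |mean difference|
        flat = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), n)
        pairs = list(itertools.combinations(groups, 2))

        def max_diff(values):
            means = {g: values[labels == g].mean() for g in groups}
            return max(abs(means[x] - means[y]) for x, y in pairs)

        obs = {frozenset(p): abs(groups[p[0]].mean() - groups[p[1]].mean())
               for p in pairs}
        null = np.empty(10_000)
        for b in range(10_000):
            null[b] = max_diff(rng.permutation(flat))
        for p in pairs:
            p_perm = (1 + np.sum(null >= obs[frozenset(p)])) / (1 + len(null))
            assert tukey[frozenset(p)] == (p_perm < 0.05), p

    def test_requires_two_treatments(self):
        res = fake_eaf_results([("t1", "a", 0.1), ("t2", "a", 0.2)])
        with pytest.raises(ValueError, match="2 treatments"):
            fq.assemblage_mean_contrast(res)


@pytest.fixture(scope="module")
def null_results():
    cfg = fq.SimConfig(n_taxa=30, seed=21, qpcr_cv=0.0,
                       exact_abundances=True, detection_floor=0.0,
                       treatment_effect=(0.0, 0.0, 0.0))
    return fq.EafModel(fq.simulate_experiment(cfg)).fit(n_boot=200, seed=3)


class TestDeltaEaf:
    def test_identical_treatments_all_neutral(self, null_results):
        """Zero treatment effect + zero noise -> delta = 0 and neutral."""
        d = fq.delta_eaf(null_results, "STW", seed=0, n_boot=200)
        np.testing.assert_allclose(d["delta_eaf"], 0.0, atol=1e-12)
        assert (d["classification"] == "neutral").all()

    def test_clean_shift_all_positive(self):
        cfg = fq.SimConfig(n_taxa=20, seed=22, qpcr_cv=0.0,
                           exact_abundances=True, detection_floor=0.0,
                           treatment_effect=(0.0, 0.1, 0.2))
        res = fq.EafModel(fq.simulate_experiment(cfg)).fit(n_boot=200, seed=3)
        d = fq.delta_eaf(res, "STW", seed=0, n_boot=200)
        grew = true_eaf_series(
            fq.simulate_experiment(cfg), "control").loc[d.index] > 0
        assert (d.loc[grew.values, "classification"] == "positive").all()
        assert d.loc[grew.values, "delta_eaf"].min() > 0.05

    def test_antisymmetry(self, results_small):
        a = fq.delta_eaf(results_small, "LTW", control="control", seed=7)
        b = fq.delta_eaf(results_small, "control", control="LTW", seed=7)
        common = a.index.intersection(b.index)
        np.testing.assert_allclose(a.loc[common, "delta_eaf"],
                                   -b.loc[common, "delta_eaf"], atol=1e-12)
        np.testing.assert_allclose(a.loc[common, "ci_lo"],
                                   -b.loc[common, "ci_hi"], atol=1e-12)

    def test_taxa_not_growing_in_both_excluded(self):
        res = fake_eaf_results([
            ("t1", "control", 0.1), ("t1", "LTW", 0.2),
            ("t2", "control", 0.0), ("t2", "LTW", 0.3),  # warming-only
        ])
        # block_table empty -> no bootstrap values, but membership logic applies
        d = fq.delta_eaf(res, "LTW", n_boot=10, seed=0)
        assert "t2" not in d.index and "t1" in d.index

    def test_same_treatment_rejected(self, results_small):
        with pytest.raises(ValueError):
            fq.delta_eaf(results_small, "control", control="control")


class TestOccurrencePartition:
    def test_membership_categories(self):
        res = fake_eaf_results([
            ("t1", "control", 0.1), ("t1", "STW", 0.1), ("t1", "LTW", 0.1),
            ("t2", "control", 0.0), ("t2", "STW", 0.2), ("t2", "LTW", 0.0),
            ("t3", "control", 0.1), ("t3", "STW", 0.0), ("t3", "LTW", 0.2),
        ])
        part = fq.occurrence_partition(res, treatments=("control", "STW", "LTW"))
        assert part.membership["t1"] == ("control", "STW", "LTW")
        assert part.membership["t2"] == ("STW",)
        assert part.membership["t3"] == ("control", "LTW")
        assert part.counts.sum() == 3

    def test_partition_completeness(self, results_small):
        part = fq.occurrence_partition(results_small)
        growing_total = len(
            set().union(*(set(results_small.growing_taxa(tr))
                          for tr in results_small.treatments)))
        assert part.counts.sum() == growing_total
        assert part.membership.index.is_unique

    def test_zero_noise_partition_matches_truth(self, dataset_clean,
                                                results_clean):
        part = fq.occurrence_partition(results_clean)
        truth_member = {}
        for t in dataset_clean.truth["taxa"]:
            cats = tuple(tr for tr in results_clean.treatments
                         if true_eaf_series(dataset_clean, tr)[t] > 0)
            if cats:
                truth_member[t] = cats
        # restrict to taxa the estimator retained (filter survivors); a true
        # EAF of exactly 0 may estimate as ~1e-15, so membership is compared
        # above numerical zero
        for t, cats in part.membership.to_dict().items():
            est_cats = tuple(
                tr for tr in cats
                if results_clean.treatment_table(tr).loc[t, "mean_eaf"] > 1e-9)
            assert truth_member.get(t, ()) == est_cats

    def test_disjoint_sets_all_singletons(self):
        res = fake_eaf_results([
            ("t1", "a", 0.1), ("t1", "b", 0.0),
            ("t2", "a", 0.0), ("t2", "b", 0.2),
        ])
        part = fq.occurrence_partition(res, treatments=("a", "b"))
        assert set(part.counts.index) == {("a",), ("b",)}
        assert part.tests.empty


class TestAggregateByRank:
    @staticmethod
    def _toy():
        rows = []
        for i in range(4):
            rows += [(f"x{i}", "control", 0.10), (f"x{i}", "LTW", 0.30)]
        for i in range(2):  # order with only 2 growing representatives
            rows += [(f"y{i}", "control", 0.10), (f"y{i}", "LTW", 0.20)]
        tax = pd.DataFrame({
            "order": ["o__Big"] * 4 + ["o__Small"] * 2,
        }, index=[f"x{i}" for i in range(4)] + [f"y{i}" for i in range(2)])
        return fake_eaf_results(rows), tax

    def test_min_representation_rule(self):
        res, tax = self._toy()
        out = fq.aggregate_by_rank(res, tax, "order", treatment="LTW")
        assert list(out["group"]) == ["o__Big"]
        assert out.iloc[0]["delta_eaf"] == pytest.approx(0.20)
        out2 = fq.aggregate_by_rank(res, tax, "order", treatment="LTW",
                                    min_taxa=2)
        assert set(out2["group"]) == {"o__Big", "o__Small"}

    def test_single_order_equals_assemblage_contrast(self):
        res, tax = self._toy()
        tax["order"] = "o__All"
        out = fq.aggregate_by_rank(res, tax, "order", treatment="LTW")
        assert len(out) == 1
        mean_t = res.eaf_series("LTW").mean()
        mean_c = res.eaf_series("control").mean()
        assert out.iloc[0]["delta_eaf"] == pytest.approx(mean_t - mean_c)

    def test_zero_noise_rank_means_match_truth(self, dataset_clean,
                                               results_clean):
        out = fq.aggregate_by_rank(results_clean, dataset_clean.taxonomy,
                                   "order", treatment="LTW")
        truth = true_eaf_series(dataset_clean, "LTW")
        for row in out.itertuples():
            members = dataset_clean.taxonomy.index[
                dataset_clean.taxonomy["order"] == row.group]
            grow = truth.loc[members][lambda s: s > 0]
            est_members = results_clean.eaf_series("LTW").index.intersection(
                grow.index)
            assert row.mean_eaf_treatment == pytest.approx(
                truth.loc[est_members].mean(), abs=0.01)

    def test_unknown_rank_rejected(self, results_small, dataset_small):
        with pytest.raises(KeyError):
            fq.aggregate_by_rank(results_small, dataset_small.taxonomy,
                                 "kingdom")
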