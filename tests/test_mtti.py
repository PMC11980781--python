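import numpy as np
import pandas as pd
import pytest

from streamtherm.io import CommunityDataset, TaxonNode
from streamtherm.mtti import (
    MTTIModel,
    MTTIResults,
    build_otu_table,
    performance,
    stratified_split,
)
from tests.conftest import make_sample


def wa_two_step_oracle(counts, mwmt):
    """Textbook two-step WA (no downweighting, no deshrinking), nested loops."""
    samples = list(counts.index)
    otus = list(counts.columns)
    rel = {}
    for s in samples:
        tot = counts.loc[s].sum()
        rel[s] = {k: counts.loc[s, k] / tot for k in otus}
    optima = {}
    for k in otus:
        num = den = 0.0
        for s in samples:
            num += rel[s][k] * mwmt[s]
            den += rel[s][k]
        optima[k] = num / den if den > 0 else np.nan
    scores = {}
    for s in samples:
        num = den = 0.0
        for k in otus:
            if not np.isnan(optima[k]):
                num += rel[s][k] * optima[k]
                den += rel[s][k]
        scores[s] = num / den
    return optima, scores


def _linked(sample_id, counts, mwmt, unit="U"):
    s = make_sample(sample_id, counts, unit=unit)
    s.mwmt = mwmt
    return s


class TestBuildOtuTable:
    def _dataset(self):
        taxa = {
            "Baetis": TaxonNode("Baetis", "Baetis", None, "genus"),
            "B_tri": TaxonNode("B_tri", "B. tricaudatus", "Baetis", "species"),
            "B_fla": TaxonNode("B_fla", "B. flavistriga", "Baetis", "species"),
            "Other": TaxonNode("Other", "Other", None, "genus"),
        }
        return CommunityDataset(taxa=taxa, samples=[], temperatures={})

    def test_nondistinct_parent_removed_then_children_aggregated(self):
        otu_map = {"Baetis": "OTU_Baetis", "B_tri": "OTU_Baetis", "B_fla": "OTU_Baetis",
                   "Other": "OTU_Other"}
        s = _linked("s1", {"Baetis": 10, "B_tri": 5, "Other": 150}, 15.0)
        table = build_otu_table([s], otu_map, self._dataset(), min_count=100)
        assert table.counts.loc["s1", "OTU_Baetis"] == 5  # genus record dropped
        assert table.counts.loc["s1", "OTU_Other"] == 150

    def test_two_species_one_otu_sum(self):
        otu_map = {"B_tri": "OTU_Baetis", "B_fla": "OTU_Baetis", "Other": "OTU_Other"}
        s = _linked("s1", {"B_tri": 3, "B_fla": 4, "Other": 150}, 15.0)
        table = build_otu_table([s], otu_map, self._dataset(), min_count=100)
        assert table.counts.loc["s1", "OTU_Baetis"] == 7

    def test_low_count_sample_dropped_after_removal(self):
        otu_map = {"B_tri": "OTU_Baetis"}
        # 160 individuals but only 140 remain after dropping unmapped taxa
        s = _linked("s1", {"B_tri": 140, "Other": 20}, 15.0)
        table = build_otu_table([s], otu_map, self._dataset(), min_count=150)
        assert len(table.counts) == 0
        assert table.n_dropped_low_count == 1
        assert table.n_unmapped_taxa == 1


class TestStratifiedSplit:
    def _series(self, n, unit="A", seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"{unit}{i}" for i in range(n)]
        return (
            pd.Series(rng.uniform(5, 30, n), index=idx),
            pd.Series(unit, index=idx),
        )

    def test_exact_val_counts_per_stratum(self):
        mwmt, unit = self._series(100)
        labels = stratified_split(mwmt, unit, frac=0.10, n_bins=5, seed=1)
        assert (labels == "VAL").sum() == 10
        bins = pd.qcut(mwmt, 5, labels=False)
        for b in range(5):
            assert (labels[bins == b] == "VAL").sum() == 2

    def test_frac_zero_all_cal(self):
        mwmt, unit = self._series(50)
        labels = stratified_split(mwmt, unit, frac=0.0, seed=1)
        assert (labels == "CAL").all()

    def test_same_seed_identical_different_seed_differs(self):
        mwmt, unit = self._series(200)
        a = stratified_split(mwmt, unit, seed=5)
        b = stratified_split(mwmt, unit, seed=5)
        c = stratified_split(mwmt, unit, seed=6)
        assert a.equals(b)
        assert not a.equals(c)

    def test_small_unit_single_bin(self):
        from streamtherm.synthetic import generate_edge_cases

        sizes = generate_edge_cases()["small_unit_split"]
        parts = []
        for u, n in sizes.items():
            m, un = self._series(n, unit=u, seed=3)
            parts.append((m, un))
        mwmt = pd.concat([p[0] for p in parts])
        unit = pd.concat([p[1] for p in parts])
        labels = stratified_split(mwmt, unit, frac=0.10, n_bins=5, seed=2)
        # small unit (3 samples) forms one stratum: round(0.3) = 0 in VAL
        assert (labels[unit == "unitB"] == "CAL").all()
        assert set(labels.unique()) <= {"CAL", "VAL"}

    def test_partition_property_over_seeds(self):
        for seed in range(20):
            mwmt, unit = self._series(80, seed=seed)
            labels = stratified_split(mwmt, unit, seed=seed)
            assert set(labels.index) == set(mwmt.index)
            bins = pd.qcut(mwmt, 5, labels=False)
            for b in range(5):
                n = (bins == b).sum()
                expect = int(np.floor(0.1 * n + 0.5))
                assert ((labels[bins == b]) == "VAL").sum() == expect


class TestWAFit:
    def _toy_model(self, downweight=True, deshrink="none"):
        # 10 samples, 2 OTUs with known optima/tolerances cannot be fixed
        # directly; tests below use analytic cases instead
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(1, 50, size=(12, 3)).astype(float),
            index=[f"s{i}" for i in range(12)],
            columns=["o1", "o2", "o3"],
        )
        mwmt = pd.Series(rng.uniform(8, 25, 12), index=counts.index)
        return MTTIModel(counts, mwmt, downweight=downweight, deshrink=deshrink)

    def test_downweighted_score_closed_form(self):
        """Sample with equal shares of two OTUs (u=[10,20], t=[1,2])."""
        res = self._toy_model().fit()
        res.optima[:] = np.nan
        res.optima["o1"], res.optima["o2"] = 10.0, 20.0
        res.tolerances["o1"], res.tolerances["o2"] = 1.0, 2.0
        pred = res.predict(pd.DataFrame({"o1": [5.0], "o2": [5.0]}, index=["new"]))
        # (0.5*10/1 + 0.5*20/4) / (0.5/1 + 0.5/4) = 12.0 ; deshrink none
        assert pred.loc["new", "mtti"] == pytest.approx(12.0)

    def test_unweighted_score_is_mean_of_optima(self):
        res = self._toy_model(downweight=False).fit()
        res.optima[:] = np.nan
        res.optima["o1"], res.optima["o2"] = 10.0, 20.0
        res.tolerances["o1"], res.tolerances["o2"] = 1.0, 2.0
        pred = res.predict(pd.DataFrame({"o1": [5.0], "o2": [5.0]}, index=["new"]))
        assert pred.loc["new", "mtti"] == pytest.approx(15.0)

    def test_single_otu_samples_score_equals_optimum(self):
        counts = pd.DataFrame(
            np.kron(np.eye(2), np.ones((5, 1))).reshape(10, 2) * 20,
            index=[f"s{i}" for i in range(10)],
            columns=["o1", "o2"],
        )
        mwmt = pd.Series(
            [10, 11, 12, 13, 14, 20, 21, 22, 23, 24.0], index=counts.index
        )
        res = MTTIModel(counts, mwmt, deshrink="none").fit()
        # each sample contains exactly one OTU: raw score == that OTU's optimum
        for sid in counts.index:
            otu = counts.columns[counts.loc[sid] > 0][0]
            assert res.raw_scores[sid] == pytest.approx(res.optima[otu])

    def test_matches_nested_loop_wa_oracle(self):
        """No downweighting, no deshrinking == textbook two-step WA."""
        rng = np.random.default_rng(13)
        counts = pd.DataFrame(
            rng.integers(0, 40, size=(15, 6)).astype(float) + 0.0,
            index=[f"s{i}" for i in range(15)],
            columns=[f"o{k}" for k in range(6)],
        )
        counts.iloc[:, 0] += 1  # no empty samples
        mwmt = pd.Series(rng.uniform(5, 30, 15), index=counts.index)
        res = MTTIModel(counts, mwmt, downweight=False, deshrink="none",
                        tol_floor_quantile=0.0).fit()
        optima, scores = wa_two_step_oracle(counts, mwmt)
        for k, v in optima.items():
            assert res.optima[k] == pytest.approx(v, abs=1e-10)
        for s, v in scores.items():
            assert res.raw_scores[s] == pytest.approx(v, abs=1e-10)

    def test_classical_deshrinking_identity(self, prepped):
        """OLS of deshrunk CAL predictions on observed MWMT: slope 1, intercept 0."""
        dataset, _, otu_map, prep = prepped
        table = build_otu_table(prep.samples, otu_map, dataset)
        res = MTTIModel.from_otu_table(table, deshrink="classical").fit()
        b, a = np.polyfit(res.model.mwmt, res.fittedvalues, 1)
        assert b == pytest.approx(1.0, abs=1e-8)
        assert a == pytest.approx(0.0, abs=1e-8)

    def test_scale_invariance_of_prediction(self):
        res = self._toy_model().fit()
        new = pd.DataFrame({"o1": [3.0], "o2": [7.0], "o3": [1.0]}, index=["n"])
        p1 = res.predict(new)
        p2 = res.predict(new * 10)
        assert p1.loc["n", "mtti"] == pytest.approx(p2.loc["n", "mtti"])

    def test_classical_final_prediction_formula(self):
        res = self._toy_model(deshrink="classical").fit()
        res.deshrink_a, res.deshrink_b = 2.0, 0.5
        res.optima[:] = np.nan
        res.optima["o1"], res.optima["o2"] = 10.0, 20.0
        res.tolerances["o1"], res.tolerances["o2"] = 1.0, 2.0
        pred = res.predict(pd.DataFrame({"o1": [5.0], "o2": [5.0]}, index=["n"]))
        assert pred.loc["n", "mtti"] == pytest.approx((12.0 - 2.0) / 0.5)  # 20.0

    def test_no_shared_otus_missing_with_coverage_zero(self):
        res = self._toy_model().fit()
        pred = res.predict(pd.DataFrame({"zz": [5.0]}, index=["n"]))
        assert np.isnan(pred.loc["n", "mtti"])
        assert pred.loc["n", "coverage"] == 0.0

    def test_json_round_trip_predicts_identically(self):
        res = self._toy_model(deshrink="classical").fit()
        new = pd.DataFrame({"o1": [3.0], "o2": [7.0], "o3": [1.0]}, index=["n"])
        back = MTTIResults.from_json_dict(res.to_json_dict())
        assert back.predict(new).loc["n", "mtti"] == pytest.approx(
            res.predict(new).loc["n", "mtti"]
        )


class TestPerformance:
    def test_perfect_predictions(self):
        obs = np.linspace(5, 25, 30)
        p = performance(obs, obs)
        assert (p.rmsep, p.r2, p.max_bias) == (0.0, pytest.approx(1.0), 0.0)

    def test_constant_offset(self):
        obs = np.linspace(0, 10, 50)
        p = performance(obs + 1.0, obs)
        assert p.rmsep == pytest.approx(1.0)
        assert p.max_bias == pytest.approx(1.0)

    def test_localized_bias_detected(self):
        obs = np.linspace(0, 10, 100)
        pred = obs.copy()
        seg = (obs >= 0) & (obs < 1)  # only the first of 10 segments
        pred[seg] += 1.0
        p = performance(pred, obs)
        assert p.max_bias == pytest.approx(1.0)
        assert p.rmsep < 0.5

    def test_zero_variance_observed_errors(self):
        with pytest.raises(ValueError, match="variance"):
            performance(np.arange(10.0), np.full(10, 3.0))


class TestBootstrapCV:
    def _fitted(self, prepped):
        dataset, _, otu_map, prep = prepped
        table = build_otu_table(prep.samples, otu_map, dataset)
        return MTTIModel.from_otu_table(table).fit()

    def test_same_seed_reproducible(self, prepped):
        res = self._fitted(prepped)
        a = res.bootstrap_cv(n_boot=10, seed=3)
        b = res.bootstrap_cv(n_boot=10, seed=3)
        assert a.as_dict() == b.as_dict()

    def test_single_replicate_is_one_oob_evaluation(self, prepped):
        res = self._fitted(prepped)
        p = res.bootstrap_cv(n_boot=1, seed=0)
        assert 0 < p.n < len(res.model.counts)  # only OOB samples scored

    def test_bootstrap_rmsep_not_better_than_apparent(self, prepped):
        """Out-of-bag error >= apparent error (optimism) on synthetic data."""
        res = self._fitted(prepped)
        apparent = res.apparent_performance().rmsep
        worse = 0
        for seed in range(10):
            boot = res.bootstrap_cv(n_boot=20, seed=seed)
            worse += boot.rmsep >= apparent
        assert worse >= 9  # allow one sampling fluke

    def test_residual_trend_absent_after_classical_deshrinking(self, prepped):
        import scipy.stats as stats

        res = self._fitted(prepped)
        resid = res.fittedvalues - res.model.mwmt
        reg = stats.linregress(res.model.mwmt, resid)
        assert reg.pvalue > 0.01
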