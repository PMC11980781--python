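import numpy as np
import pytest

from streamtherm.io import CommunityDataset, SegmentTemperature, TaxonNode
from streamtherm.prep import (
    DemingFit,
    TemperatureLinkError,
    dedupe_segments,
    filter_min_count,
    fit_deming,
    link_mwmt,
    rollup_abundances,
)
from tests.conftest import make_flat_taxa, make_sample


class TestDeming:
    def test_noiseless_line_recovered_exactly(self):
        fit = fit_deming([(1, 2), (2, 4), (3, 6)])
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_reciprocal_slope_symmetry(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(5, 25, 50)
        y = 1.3 * x + 2 + rng.normal(0, 1.0, 50)
        fwd = fit_deming(list(zip(x, y)), delta=1.0)
        rev = fit_deming(list(zip(y, x)), delta=1.0)
        assert fwd.slope == pytest.approx(1.0 / rev.slope, abs=1e-9)

    def test_slope_between_the_two_ols_slopes(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 10, 200)
        y = 0.9 * x + 1 + rng.normal(0, 0.8, 200)
        b1 = np.polyfit(x, y, 1)[0]
        b2 = np.polyfit(y, x, 1)[0]
        fit = fit_deming(list(zip(x, y)))
        assert b1 <= fit.slope <= 1.0 / b2

    def test_matches_perpendicular_distance_grid_minimizer(self):
        """With delta=1 the fit minimizes summed squared perpendicular distance."""
        rng = np.random.default_rng(21)
        x = rng.uniform(0, 10, 60)
        y = 1.4 * x - 2 + rng.normal(0, 0.7, 60)
        fit = fit_deming(list(zip(x, y)))

        def perp_ss(slope):
            inter = np.mean(y) - slope * np.mean(x)
            return np.sum((y - slope * x - inter) ** 2 / (1 + slope**2))

        grid = np.linspace(fit.slope - 0.5, fit.slope + 0.5, 20001)
        best = grid[np.argmin([perp_ss(s) for s in grid])]
        assert fit.slope == pytest.approx(best, abs=1e-4)

    def test_orthogonal_regression_cross_check(self):
        """Agreement with scipy.odr orthogonal regression as external oracle."""
        import scipy.odr as odr

        rng = np.random.default_rng(8)
        x = rng.uniform(0, 10, 80)
        y = 2.2 * x + 3 + rng.normal(0, 1.0, 80)
        fit = fit_deming(list(zip(x, y)))
        data = odr.RealData(x, y)
        out = odr.ODR(data, odr.unilinear, beta0=[1.0, 0.0]).run()
        assert fit.slope == pytest.approx(out.beta[0], rel=1e-4)
        assert fit.intercept == pytest.approx(out.beta[1], abs=1e-3)

    def test_zero_covariance_errors(self):
        with pytest.raises(ValueError, match="covariance"):
            fit_deming([(1, 5), (2, 5), (3, 5)])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_deming([(1, 2), (2, 4)])


class TestLinkMwmt:
    temps = {
        "segA": SegmentTemperature("segA", annual_mwmt={2010: 18.2}, mean_mwmt=17.0),
        "segB": SegmentTemperature("segB", annual_mwmt={}, mean_mwmt=15.0),
        "segC": SegmentTemperature("segC", annual_mwmt={}, mean_mwmt=None, mean_august=14.0),
        "segD": SegmentTemperature("segD"),
    }

    def test_annual_preferred(self):
        s = make_sample("s", {"t1": 5}, segment_id="segA", year=2010)
        linked = link_mwmt(s, self.temps)
        assert (linked.mwmt, linked.mwmt_source) == (18.2, "annual")

    def test_long_term_mean_fallback(self):
        s = make_sample("s", {"t1": 5}, segment_id="segB", year=2010)
        linked = link_mwmt(s, self.temps)
        assert (linked.mwmt, linked.mwmt_source) == (15.0, "long_term_mean")

    def test_deming_imputation(self):
        s = make_sample("s", {"t1": 5}, segment_id="segC", year=2010)
        deming = DemingFit(slope=1.2, intercept=1.0, delta=1.0, n=10)
        linked = link_mwmt(s, self.temps, deming)
        assert linked.mwmt == pytest.approx(1.2 * 14.0 + 1.0)  # 17.8
        assert linked.mwmt_source == "imputed"

    def test_no_temperature_derivable(self):
        s = make_sample("s", {"t1": 5}, segment_id="segD", year=2010)
        with pytest.raises(TemperatureLinkError):
            link_mwmt(s, self.temps)

    def test_rel_abund_sums_to_one(self):
        s = make_sample("s", {"t1": 5, "t2": 15}, segment_id="segA", year=2010)
        linked = link_mwmt(s, self.temps)
        assert sum(linked.rel_abund.values()) == pytest.approx(1.0, abs=1e-9)
        assert linked.presence == {"t1", "t2"}


class TestDedupe:
    def test_highest_richness_wins(self):
        a = make_sample("a", {f"t{i}": 1 for i in range(10)}, segment_id="g")
        b = make_sample("b", {f"t{i}": 1 for i in range(12)}, segment_id="g")
        assert [s.sample_id for s in dedupe_segments([a, b])] == ["b"]

    def test_richness_tie_most_recent_wins(self):
        a = make_sample("a", {f"t{i}": 1 for i in range(12)}, segment_id="g", year=2015)
        b = make_sample("b", {f"t{i}": 1 for i in range(12)}, segment_id="g", year=2018)
        assert [s.sample_id for s in dedupe_segments([a, b])] == ["b"]

    def test_full_tie_smallest_id_wins(self):
        a = make_sample("zz", {"t1": 1}, segment_id="g", year=2015)
        b = make_sample("aa", {"t2": 1}, segment_id="g", year=2015)
        assert [s.sample_id for s in dedupe_segments([a, b])] == ["aa"]

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(0)
        samples = [
            make_sample(
                f"s{i}",
                {f"t{j}": 1 for j in range(rng.integers(1, 8))},
                segment_id=f"g{i % 3}",
                year=int(rng.integers(2000, 2020)),
            )
            for i in range(12)
        ]
        ref = [s.sample_id for s in dedupe_segments(samples)]
        for _ in range(5):
            rng.shuffle(samples)
            assert [s.sample_id for s in dedupe_segments(samples)] == ref
        once = dedupe_segments(samples)
        assert [s.sample_id for s in dedupe_segments(once)] == ref


class TestFilterMinCount:
    @pytest.mark.parametrize("total,kept", [(149, False), (150, True)])
    def test_boundary(self, total, kept):
        s = make_sample("s", {"t1": total})
        assert (len(filter_min_count([s])) == 1) is kept

    def test_counts_retained(self):
        samples = [make_sample(f"s{i}", {"t1": c}) for i, c in enumerate([100, 149, 150, 151, 500])]
        assert len(filter_min_count(samples)) == 3


class TestRollup:
    taxa = {
        "F": TaxonNode("F", "Fam", None, "family"),
        "G": TaxonNode("G", "Gen", "F", "genus"),
        "S": TaxonNode("S", "Sp", "G", "species"),
        "S2": TaxonNode("S2", "Sp2", "G", "species"),
        "H": TaxonNode("H", "Gen2", "F", "genus"),
    }

    def _ds(self):
        return CommunityDataset(taxa=dict(self.taxa), samples=[], temperatures={})

    def test_genus_receives_child_counts(self):
        eff = rollup_abundances(make_sample("s", {"G": 2, "S": 5}), self._ds())
        assert eff["G"] == 7
        assert eff["S"] == 5

    def test_absent_family_appears_with_descendant_sum(self):
        eff = rollup_abundances(make_sample("s", {"S": 5, "H": 7}), self._ds())
        assert eff["F"] == 12

    def test_no_children_identity(self):
        eff = rollup_abundances(make_sample("s", {"H": 4}), self._ds())
        assert eff["H"] == 4

    def test_ancestor_monotone_property(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            counts = {
                t: int(rng.integers(1, 50))
                for t in self.taxa
                if rng.uniform() < 0.7
            }
            if not counts:
                continue
            ds = self._ds()
            eff = rollup_abundances(make_sample("s", counts), ds)
            for t in eff:
                desc_effs = [eff[d] for d in ds.descendants(t) if d in eff]
                if desc_effs and ds.taxa[t].rank in ("genus", "family"):
                    assert eff[t] >= max(desc_effs)
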