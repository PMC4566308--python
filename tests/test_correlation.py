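"""Transcript-trait PCC, tail quantiles, permutation thresholds, set selection."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import leafcorr as lc
from leafcorr.correlation import TranscriptTraitPCC, analytic_null_quantile


def _expr(arr, samples):
    genes = [f"g{i+1}" for i in range(arr.shape[0])]
    return lc.ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


def _traits_1(values, samples, name="LL"):
    df = pd.DataFrame({name: values}, index=samples)
    return lc.TraitTable(
        df, {name: lc.TraitInfo("mm", "leaf_size")}, pd.Series("RIL", index=samples)
    )


class TestTranscriptTraitPcc:
    def test_exact_and_negated_trait(self):
        samples = [f"s{i}" for i in range(70)]
        t = np.linspace(0, 1, 70)
        expr = _expr(np.vstack([t, -t, np.full(70, 3.0)]), samples)
        pcc = lc.transcript_trait_pcc(expr, _traits_1(t, samples), min_lines=10)
        assert pcc.r.loc["g1", "LL"] == pytest.approx(1.0)
        assert pcc.r.loc["g2", "LL"] == pytest.approx(-1.0)
        assert np.isnan(pcc.r.loc["g3", "LL"])  # constant gene flagged

    def test_planted_gene_within_fisher_interval(self, planted_dataset, planted_catalog):
        # planted rho = 0.6 at n = 105: a +-3 SD Fisher-z interval is ~[0.4, 0.8]
        pcc = planted_catalog["pcc"]
        planted = sorted(planted_dataset["truth"].associations)
        rs = pcc.r.loc[planted, "LL"]
        assert ((rs > 0.4) & (rs < 0.8)).mean() >= 0.9

    def test_partial_trait_excluded_by_min_lines(self, planted_dataset, planted_catalog):
        pcc = planted_catalog["pcc"]
        assert "LN" in pcc.excluded_traits and "V-stage" in pcc.excluded_traits
        assert "LL" in pcc.r.columns
        assert pcc.n_samples["LL"] == 105

    def test_no_common_samples_is_error(self):
        expr = _expr(np.ones((2, 3)), ["a", "b", "c"])
        with pytest.raises(ValueError, match="overlap"):
            lc.transcript_trait_pcc(expr, _traits_1([1.0, 2.0], ["x", "y"]))


class TestTailQuantiles:
    def _pcc(self, vals):
        r = pd.DataFrame({"LL": vals}, index=[f"g{i}" for i in range(len(vals))])
        return TranscriptTraitPCC(r, pd.Series({"LL": 10}))

    def test_type7_interpolation(self):
        q = lc.tail_quantiles(self._pcc([-1.0, -0.5, 0.0, 0.5, 1.0]))
        assert q.observed.loc["LL", "q_high"] == pytest.approx(0.98)
        assert q.observed.loc["LL", "q_low"] == pytest.approx(-0.98)

    def test_extreme_quantiles_are_min_max(self):
        q = lc.tail_quantiles(self._pcc([-0.3, 0.1, 0.7]), q_low=0.0, q_high=1.0)
        assert q.observed.loc["LL", "q_low"] == -0.3
        assert q.observed.loc["LL", "q_high"] == 0.7

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.001, max_value=0.999), min_size=5, max_size=40
        )
    )
    def test_symmetric_values_give_symmetric_quantiles(self, vals):
        sym = np.array(vals + [-v for v in vals])
        q = lc.tail_quantiles(self._pcc(sym))
        assert q.observed.loc["LL", "q_low"] == pytest.approx(
            -q.observed.loc["LL", "q_high"], abs=1e-12
        )


@pytest.fixture(scope="module")
def null_data():
    rng = np.random.default_rng(3)
    samples = [f"s{i}" for i in range(100)]
    expr = _expr(rng.normal(size=(2000, 100)), samples)
    traits = _traits_1(rng.normal(size=100), samples)
    return expr, traits


class TestPermutationThresholds:
    def test_mean_permuted_q99_matches_analytic_null(self, null_data):
        expr, traits = null_data
        thr = lc.permutation_thresholds(expr, traits, n_perm=200, seed=3, min_lines=10)
        expected = analytic_null_quantile(0.99, 100)  # ~0.232
        assert expected == pytest.approx(0.232, abs=0.001)
        assert thr.permuted.loc["LL", "q_high"] == pytest.approx(expected, abs=0.01)
        assert thr.permuted.loc["LL", "q_low"] == pytest.approx(
            -thr.permuted.loc["LL", "q_high"], abs=0.01
        )

    def test_reproducible_and_relabeling_invariant(self, null_data):
        expr, traits = null_data
        a = lc.permutation_thresholds(expr, traits, n_perm=50, seed=7, min_lines=10)
        b = lc.permutation_thresholds(expr, traits, n_perm=50, seed=7, min_lines=10)
        assert a.permuted.equals(b.permuted)
        # monotone relabeling of sample ids changes nothing
        mapping = {s: f"z{idx:03d}" for idx, s in enumerate(expr.values.columns)}
        expr2 = lc.ExpressionMatrix(expr.values.rename(columns=mapping))
        tv = traits.values.rename(index=mapping)
        traits2 = lc.TraitTable(tv, traits.traits, pd.Series("RIL", index=tv.index))
        c = lc.permutation_thresholds(expr2, traits2, n_perm=50, seed=7, min_lines=10)
        assert np.allclose(a.permuted, c.permuted)

    def test_constant_trait_and_small_nperm_rejected(self, null_data):
        expr, traits = null_data
        const = _traits_1(np.ones(100), list(expr.values.columns))
        with pytest.raises(ValueError, match="constant"):
            lc.permutation_thresholds(expr, const, n_perm=10, min_lines=10)
        with pytest.raises(ValueError, match="2 permutations"):
            lc.permutation_thresholds(expr, traits, n_perm=1, min_lines=10)


class TestSelectSets:
    def _catalog_from_values(self, vals, obs_low, obs_high, perm_low, perm_high):
        r = pd.DataFrame({"LL": vals}, index=[f"g{i+1}" for i in range(len(vals))])
        pcc = TranscriptTraitPCC(r, pd.Series({"LL": 10}))
        obs = lc.QuantileThresholds(
            pd.DataFrame({"q_low": [obs_low], "q_high": [obs_high]}, index=["LL"])
        )
        perm = lc.QuantileThresholds(
            pd.DataFrame({"q_low": [perm_low], "q_high": [perm_high]}, index=["LL"]),
            permuted=pd.DataFrame(
                {"q_low": [perm_low], "q_high": [perm_high]}, index=["LL"]
            ),
        )
        return lc.select_sets(pcc, obs, perm)

    def test_threshold_semantics(self):
        cat = self._catalog_from_values([0.6, 0.4, -0.7], -0.9, 0.9, -0.5, 0.5)
        qr_pos = cat.get("LL", "positive", "q_random").genes
        qr_neg = cat.get("LL", "negative", "q_random").genes
        assert qr_pos == {"g1"} and qr_neg == {"g3"}

    def test_top1pct_set_size(self, rng):
        vals = rng.normal(size=10000) / 3
        r = pd.DataFrame({"LL": vals}, index=[f"g{i}" for i in range(10000)])
        pcc = TranscriptTraitPCC(r, pd.Series({"LL": 105}))
        obs = lc.tail_quantiles(pcc)
        perm = lc.QuantileThresholds(
            obs.observed, permuted=obs.observed.assign(sd_low=0, sd_high=0)
        )
        cat = lc.select_sets(pcc, obs, perm)
        for sign in ("positive", "negative"):
            assert len(cat.get("LL", sign, "top1pct").genes) == pytest.approx(100, abs=1)

    def test_top1pct_subset_of_q_random(self, planted_catalog):
        cat = planted_catalog["catalog"]
        obs = planted_catalog["observed"].observed
        perm = planted_catalog["permuted"].permuted
        for trait in cat.traits():
            if obs.loc[trait, "q_high"] > perm.loc[trait, "q_high"]:
                assert (
                    cat.get(trait, "positive", "top1pct").genes
                    <= cat.get(trait, "positive", "q_random").genes
                )
            if obs.loc[trait, "q_low"] < perm.loc[trait, "q_low"]:
                assert (
                    cat.get(trait, "negative", "top1pct").genes
                    <= cat.get(trait, "negative", "q_random").genes
                )

    def test_positive_negative_disjoint(self, planted_catalog):
        cat = planted_catalog["catalog"]
        for trait in cat.traits():
            for strg in ("top1pct", "q_random"):
                assert not (
                    cat.get(trait, "positive", strg).genes
                    & cat.get(trait, "negative", strg).genes
                )


class TestCountTableAndHeatmap:
    def test_count_table_totals(self, planted_catalog):
        cat = planted_catalog["catalog"]
        tab = lc.correlation_count_table(cat, "q_random")
        for trait in tab.index:
            assert tab.loc[trait, "total"] == (
                tab.loc[trait, "positive"] + tab.loc[trait, "negative"]
            )
        G = len(cat.universe)
        assert (
            tab["pct"] == (100 * tab["total"] / G).round().astype(int)
        ).all()

    def test_planted_trait_exceeds_null_counts(self, planted_catalog):
        tab = lc.correlation_count_table(planted_catalog["catalog"], "q_random")
        # 20 genes planted on LL at rho=0.6 push LL far above the ~2 % null
        assert tab.loc["LL", "positive"] >= 18

    def test_heatmap_normalization_and_order(self, planted_dataset, planted_catalog):
        expr, traits = planted_dataset["expr"], planted_dataset["traits"]
        hm = lc.heatmap_matrix(expr, traits, "LL", planted_catalog["catalog"])
        vals = hm.to_numpy()
        assert vals.min() >= -3.0 and vals.max() <= 3.0
        # unclipped rows have mean ~0 and SD 1
        raw = expr.values.loc[hm.index, hm.columns].to_numpy()
        z = (raw - raw.mean(1, keepdims=True)) / raw.std(1, ddof=1, keepdims=True)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-10)
        trait_vals = traits.values.loc[hm.columns, "LL"].to_numpy()
        assert (np.diff(trait_vals) >= 0).all()
        pos = planted_catalog["catalog"].get("LL", "positive", "top1pct").genes
        n_pos = len(pos)
        assert set(hm.index[:n_pos]) == pos  # correlated block on top
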