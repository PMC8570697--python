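"""The negative-binomial Wald engine: normalization, dispersion, test, BH."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from intergen.de import (
    DEGCall,
    DEResult,
    bh_adjust,
    call_degs,
    compute_size_factors,
    estimate_dispersions,
    nb_wald_contrast,
)
from intergen.errors import EstimationError, NormalizationError, ValidationError

from conftest import nb_draw, two_group_counts


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        y = np.array([[10, 10], [3, 3], [50, 50]])
        np.testing.assert_allclose(compute_size_factors(y), [1.0, 1.0])

    def test_doubled_column_hand_computation(self):
        # gene ratios to the geometric-mean reference are (1/sqrt2, sqrt2)
        y = np.array([[10, 20], [20, 40]])
        sf = compute_size_factors(y)
        np.testing.assert_allclose(sf, [1 / math.sqrt(2), math.sqrt(2)])
        assert sf[1] / sf[0] == pytest.approx(2.0)

    def test_single_reference_gene(self):
        # only the all-positive gene is used; its ratios are (1, 1)
        y = np.array([[0, 5], [10, 10]])
        np.testing.assert_allclose(compute_size_factors(y), [1.0, 1.0])

    def test_no_reference_gene_raises(self):
        y = np.array([[0, 5], [10, 0]])
        with pytest.raises(NormalizationError, match="pseudocount"):
            compute_size_factors(y)


class TestDispersions:
    def test_zero_variance_shrinks_to_near_floor(self):
        y = np.tile([[7], [13]], (1, 4))
        alphas = estimate_dispersions(y, np.ones(4))
        assert np.all(alphas < 1e-3)

    def test_poisson_counts_estimate_near_zero(self):
        rng = np.random.default_rng(5)
        y = rng.poisson(100, size=(2000, 50))
        alphas = estimate_dispersions(y, np.ones(50))
        assert np.median(alphas) < 0.02

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(6)
        y = nb_draw(rng, 100.0, 0.2, (2000, 50))
        alphas = estimate_dispersions(y, np.ones(50))
        assert 0.15 < np.median(alphas) < 0.25

    def test_condition_pooling_ignores_real_effects(self):
        # a strong condition effect must not inflate the estimate
        rng = np.random.default_rng(7)
        ya = nb_draw(rng, 100.0, 0.05, (1000, 25))
        yb = nb_draw(rng, 400.0, 0.05, (1000, 25))
        y = np.hstack([ya, yb])
        cond = np.array([0] * 25 + [1] * 25)
        pooled = estimate_dispersions(y, np.ones(50), conditions=cond)
        naive = estimate_dispersions(y, np.ones(50))
        assert np.median(pooled) < 0.1 < np.median(naive)

    def test_single_sample_rejected(self):
        with pytest.raises(EstimationError):
            estimate_dispersions(np.array([[1], [2]]), np.ones(1))


class TestWaldContrast:
    def test_all_zero_gene_untested(self):
        rng = np.random.default_rng(0)
        y = nb_draw(rng, 50.0, 0.05, (20, 6))
        y[3] = 0
        cm, sheet = two_group_counts(y, 3, 3)
        res = nb_wald_contrast(cm, sheet, ("control", "stress"))
        row = res.table.loc["g3"]
        assert not row["tested"]
        assert np.isnan(row["p"]) and np.isnan(row["padj"])

    def test_log2fc_unbiased_at_planted_effect(self):
        rng = np.random.default_rng(42)
        mu, lfc, alpha, n, G = 100.0, 2.0, 0.05, 3, 1000
        ya = nb_draw(rng, mu, alpha, (G, n))
        yb = nb_draw(rng, mu * 2**lfc, alpha, (G, n))
        cm, sheet = two_group_counts(np.hstack([ya, yb]), n, n)
        res = nb_wald_contrast(
            cm, sheet, ("control", "stress"),
            size_factors=np.ones(2 * n), dispersions=np.full(G, alpha),
        )
        assert res.table["log2fc"].mean() == pytest.approx(lfc, abs=0.1)

    def test_power_at_twofold_planted_fourfold_effect(self):
        # |log2fc| = 2 at mu = 100, alpha = 0.05, n = 3: essentially full power
        rng = np.random.default_rng(43)
        ya = nb_draw(rng, 100.0, 0.05, (500, 3))
        yb = nb_draw(rng, 400.0, 0.05, (500, 3))
        cm, sheet = two_group_counts(np.hstack([ya, yb]), 3, 3)
        res = nb_wald_contrast(
            cm, sheet, ("control", "stress"),
            size_factors=np.ones(6), dispersions=np.full(500, 0.05),
        )
        power = len(call_degs(res).up) / 500
        assert power >= 0.9

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(44)
        y = nb_draw(rng, 100.0, 0.1, (10000, 10))
        cm, sheet = two_group_counts(y, 5, 5)
        res = nb_wald_contrast(
            cm, sheet, ("control", "stress"),
            size_factors=np.ones(10), dispersions=np.full(10000, 0.1),
        )
        frac = (res.table["p"] < 0.05).mean()
        assert 0.04 <= frac <= 0.06

    def test_too_few_replicates_rejected(self):
        y = np.array([[5, 6, 7]])
        samples = ["s0", "s1", "s2"]
        import pandas as pd
        from intergen.io import CountMatrix, SampleSheet

        cm = CountMatrix(["g0"], samples, y, "sp")
        sheet = SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": samples,
                    "species": "sp",
                    "generation": "F1",
                    "parental_condition": ["control", "control", "stress"],
                    "replicate": [1, 2, 1],
                }
            )
        )
        with pytest.raises(EstimationError, match="replicates"):
            nb_wald_contrast(cm, sheet, ("control", "stress"))

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(45)
        y = nb_draw(rng, 80.0, 0.1, (300, 6))
        cm, sheet = two_group_counts(y, 3, 3)
        call = call_degs(nb_wald_contrast(cm, sheet, ("control", "stress")))
        perm = [4, 1, 5, 0, 3, 2]
        cm2, _ = two_group_counts(y[:, perm], 3, 3)
        sheet2 = sheet  # re-label so sample s<j> keeps its original condition
        frame = sheet.frame.copy()
        frame["parental_condition"] = [
            ["control"] * 3 + ["stress"] * 3
        ][0]
        frame["parental_condition"] = [
            ("control" if perm[j] < 3 else "stress") for j in range(6)
        ]
        from intergen.io import SampleSheet as SS

        call2 = call_degs(nb_wald_contrast(cm2, SS(frame), ("control", "stress")))
        assert call.up == call2.up and call.down == call2.down


def brute_force_bh(p):
    """Literal step-up definition: padj_i = min over j with p_j >= p_i of p_(j) m/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [None] * m
    best = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, p[i] * m / rank)
        out[i] = min(best, 1.0)
    return out


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_brute_force_step_up(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), brute_force_bh(pvals), rtol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(100):
            p = rng.random(rng.integers(1, 50))
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(bh_adjust(p), ref, rtol=1e-12)

    def test_output_at_least_input_and_monotone(self):
        rng = np.random.default_rng(2)
        p = rng.random(200)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_nan_excluded_from_m(self):
        adj = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(adj[1])
        np.testing.assert_allclose(adj[[0, 2]], [0.02, 0.04])


class TestCallDegs:
    def _result(self, rows):
        table = pd.DataFrame(
            rows, columns=["log2fc", "padj"],
            index=[f"g{i}" for i in range(len(rows))],
        )
        table["base_mean"] = 10.0
        table["se_log2fc"] = 0.1
        table["wald_stat"] = 1.0
        table["p"] = table["padj"] / 2
        table["tested"] = True
        return DEResult(("control", "stress"), table, "sp")

    def test_threshold_rule(self):
        res = self._result([(1.1, 0.005), (0.9, 1e-6), (-3.0, 0.5), (-1.5, 0.001)])
        call = call_degs(res)
        assert call.up == {"g0"}
        assert call.down == {"g3"}

    def test_strict_inequalities(self):
        res = self._result([(1.0, 0.005), (1.1, 0.01)])
        call = call_degs(res)
        assert call.up == set() and call.down == set()

    def test_gene_order_invariance(self):
        res = self._result([(2.0, 0.001), (-2.5, 0.002), (0.1, 0.9)])
        shuffled = DEResult(
            res.contrast, res.table.iloc[[2, 0, 1]], res.species
        )
        a, b = call_degs(res), call_degs(shuffled)
        assert a.up == b.up and a.down == b.down

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValidationError):
            DEGCall("c", 2.0, 0.01, frozenset({"g"}), frozenset({"g"}))
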