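import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mcpsc.score_model import ScalingParams, ScoreTable
from mcpsc.psc_engine import PSCMethodSpec
from mcpsc.consensus import (
    ConsensusWeights,
    fit_scaling_params,
    impute_local_average,
    logistic_scale,
    m1_generalized_mean,
    m2_coverage_weights,
    m3_expert_weights,
    m4_divergence_weights,
    m5_user_weights,
    median_mcpsc,
    run_consensus,
    to_dissimilarity,
    weighted_consensus,
)
from _oracles import naive_consensus
from conftest import random_half_table, make_records


class TestDissimilarityConversion:
    def test_polarity_handling(self):
        assert to_dissimilarity(0.9, "similarity") == -0.9
        assert to_dissimilarity(2.5, "dissimilarity") == 2.5

    def test_similarity_ordering_reversed(self):
        assert to_dissimilarity(0.9, "similarity") < to_dissimilarity(0.1, "similarity")


class TestScaling:
    def test_population_moments(self):
        p = fit_scaling_params([0.0, 2.0])
        assert p.mu == 1.0 and p.sigma == 1.0  # population SD, not sample
        p = fit_scaling_params([1.0, 1.0, 1.0])
        assert p.mu == 1.0 and p.sigma == 0.0

    def test_missing_values_excluded(self):
        p = fit_scaling_params([1.0, np.nan, 3.0])
        assert p.mu == 2.0

    def test_all_missing_is_error(self):
        with pytest.raises(ValueError, match="no scores"):
            fit_scaling_params([np.nan], "m")

    def test_sigmoid_midpoint_and_one_sigma(self):
        p = ScalingParams("m", 3.0, 2.0)
        assert logistic_scale(3.0, p) == pytest.approx(0.5, abs=1e-15)
        expected = 1.0 - 1.0 / (1.0 + math.exp(-1.0))
        assert logistic_scale(5.0, p) == pytest.approx(expected, abs=1e-15)

    def test_strictly_decreasing_with_asymptotes(self):
        p = ScalingParams("m", 0.0, 1.0)
        xs = np.linspace(-20, 20, 81)
        s = logistic_scale(xs, p)
        assert np.all(np.diff(s) < 0)
        assert s[-1] < 1e-8 and s[0] > 1 - 1e-8

    def test_sigma_zero_degenerates_to_half(self):
        p = ScalingParams("m", 1.0, 0.0)
        assert logistic_scale(99.0, p) == 0.5

    @given(
        slope=st.floats(0.1, 10),
        offset=st.floats(-5, 5),
        seed=st.integers(0, 100),
    )
    def test_invariant_to_positive_affine_transform(self, slope, offset, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        s0 = logistic_scale(x, fit_scaling_params(x))
        x2 = slope * x + offset
        s1 = logistic_scale(x2, fit_scaling_params(x2))
        assert np.allclose(s0, s1, atol=1e-9)


class TestImputation:
    def _scaled_table(self, rows, domains):
        df = pd.DataFrame(rows, columns=["domain1", "domain2", "method", "scaled"])
        df["raw"] = df["scaled"]
        df["imputed"] = False
        return ScoreTable(df, ["m"], domains)

    def test_directed_union_example(self):
        # missing (a,c): first-domain set for a = {0.8}; second-domain set for c = {}
        t = self._scaled_table(
            [("a", "b", "m", 0.8), ("c", "a", "m", 0.4), ("a", "c", "m", np.nan)],
            ["a", "b", "c"],
        )
        out = impute_local_average(t, "m")
        val = out.df.loc[
            (out.df["domain1"] == "a") & (out.df["domain2"] == "c"), "scaled"
        ].iloc[0]
        assert val == pytest.approx(0.8)

    def test_global_mean_fallback(self):
        t = self._scaled_table(
            [("a", "b", "m", 0.8), ("b", "a", "m", 0.2), ("e", "f", "m", np.nan)],
            ["a", "b", "e", "f"],
        )
        out = impute_local_average(t, "m")
        val = out.df.loc[out.df["domain1"] == "e", "scaled"].iloc[0]
        assert val == pytest.approx(0.5)

    def test_fully_covered_method_unchanged(self):
        t = self._scaled_table(
            [("a", "b", "m", 0.8), ("b", "a", "m", 0.8)], ["a", "b"]
        )
        out = impute_local_average(t, "m")
        pd.testing.assert_frame_equal(out.df, t.df)

    def test_present_values_untouched_and_flagged(self):
        t = self._scaled_table(
            [("a", "b", "m", 0.8), ("b", "c", "m", 0.4), ("a", "c", "m", np.nan)],
            ["a", "b", "c"],
        )
        out = impute_local_average(t, "m")
        present = out.df.dropna(subset=["raw"])
        assert not present["imputed"].any()
        assert out.df.loc[out.df["raw"].isna(), "imputed"].all()
        assert not out.df["scaled"].isna().any()


class TestSchemes:
    def test_m1_is_arithmetic_mean_at_q1(self):
        assert m1_generalized_mean([0.2, 0.4, 0.6]) == pytest.approx(0.4)
        assert m1_generalized_mean([0.5], q=3) == pytest.approx(0.5)

    def test_m1_general_q(self):
        assert m1_generalized_mean([0.25, 1.0], q=2) == pytest.approx(
            math.sqrt((0.0625 + 1) / 2)
        )

    def test_m2_is_coverage_fraction(self):
        df = pd.DataFrame(
            [
                ("a", "b", "x", 1.0), ("b", "a", "x", 1.0),
                ("a", "b", "y", 1.0), ("b", "a", "y", np.nan),
            ],
            columns=["domain1", "domain2", "method", "raw"],
        )
        w = m2_coverage_weights(ScoreTable(df, ["x", "y"], ["a", "b"]))
        assert w.weights == {"x": 1.0, "y": 0.5}

    def test_coverage_weights_match_published_style_counts(self):
        # 64964 and 72630 of P = 72630 pairs
        assert 64964 / 72630 == pytest.approx(0.8944, abs=5e-4)

    def test_m3_multiplies_expert_priors(self):
        df = pd.DataFrame(
            [("a", "b", "x", 1.0), ("b", "a", "x", 1.0),
             ("a", "b", "u", 1.0), ("b", "a", "u", 1.0)],
            columns=["domain1", "domain2", "method", "raw"],
        )
        t = ScoreTable(df, ["u", "x"], ["a", "b"])
        specs = [
            PSCMethodSpec("x", expert_weight=1.0),
            PSCMethodSpec("u", expert_weight=0.5),
        ]
        w = m3_expert_weights(t, specs)
        assert w.weights == {"u": 0.5, "x": 1.0}
        # per-pair normalization of {1, 0.5} -> {2/3, 1/3}
        eff = weighted_consensus({"x": 1.0, "u": 0.0}, w)
        assert eff == pytest.approx(2 / 3)

    def test_m4_identical_methods_fall_back_to_equal_weights(self):
        wide = pd.DataFrame({"x": [0.1, 0.5], "y": [0.1, 0.5]})
        w = m4_divergence_weights(wide, ["x", "y"])
        assert w.weights == {"x": 1.0, "y": 1.0}

    def test_m4_hand_instance_matches_direct_formulas(self):
        wide = pd.DataFrame(
            {"x": [0.1, 0.9], "y": [0.2, 0.6], "z": [0.8, 0.1]}
        )
        w = m4_divergence_weights(wide, ["x", "y", "z"])
        rxy = math.sqrt(((0.1 - 0.2) ** 2 + (0.9 - 0.6) ** 2) / 2)
        rxz = math.sqrt(((0.1 - 0.8) ** 2 + (0.9 - 0.1) ** 2) / 2)
        ryz = math.sqrt(((0.2 - 0.8) ** 2 + (0.6 - 0.1) ** 2) / 2)
        r = {"x": (rxy + rxz) / 3, "y": (rxy + ryz) / 3, "z": (rxz + ryz) / 3}
        rmax = max(r.values())
        for m in "xyz":
            assert w.weights[m] == pytest.approx(r[m] / rmax, abs=1e-12)
        assert max(w.weights.values()) == 1.0

    def test_m4_no_shared_pairs_is_error(self):
        wide = pd.DataFrame({"x": [0.1, np.nan], "y": [np.nan, 0.5]})
        with pytest.raises(ValueError, match="share no scored pairs"):
            m4_divergence_weights(wide, ["x", "y"])

    def test_m5_explicit_weights_normalize_per_pair(self):
        w = m5_user_weights(["A", "B"], weights={"A": 1.0, "B": 3.0})
        assert weighted_consensus({"A": 0.2, "B": 0.8}, w) == pytest.approx(0.65)

    def test_m5_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            m5_user_weights(["A"], weights={"A": -1.0})

    def test_m5_learns_to_prefer_informative_method(self, planted_noisy):
        cfg, records, table, specs = planted_noisy
        labels = {r.domain_id: r.label for r in records}
        noise_cfg = dict(cfg.method_noise)
        res = run_consensus(table, specs)
        wide = res.imputed
        pairs = list(zip(wide["domain1"], wide["domain2"]))
        # add a pure-noise column next to the informative ones
        rng = np.random.default_rng(0)
        wide = wide.copy()
        wide["noise"] = rng.random(len(wide))
        w = m5_user_weights(
            ["alpha", "noise"],
            learn={
                "scaled_wide": wide, "labels": labels, "pairs": pairs,
                "level": 1, "train_fraction": 0.5, "seed": 1,
            },
        )
        assert w.weights["alpha"] > w.weights["noise"]

    def test_m5_single_class_training_sample_is_error(self):
        recs = make_records({"a": "a.1.1.1", "b": "a.1.1.1"})
        labels = {r.domain_id: r.label for r in recs}
        wide = pd.DataFrame({"domain1": ["a"], "domain2": ["b"], "x": [0.5]})
        with pytest.raises(ValueError, match="single class"):
            m5_user_weights(
                ["x"],
                learn={
                    "scaled_wide": wide, "labels": labels,
                    "pairs": [("a", "b")], "train_fraction": 1.0,
                },
            )

    def test_weighted_consensus_single_method_ignores_weight(self):
        w = ConsensusWeights("m5", {"A": 0.123, "B": 5.0})
        assert weighted_consensus({"A": 0.7, "B": np.nan}, w) == 0.7

    def test_median_is_third_order_statistic(self):
        assert median_mcpsc([0.1, 0.2, 0.3, 0.4, 0.9]) == 0.3
        assert median_mcpsc([0.5] * 5) == 0.5


class TestRunConsensusPipeline:
    def test_matches_bruteforce_transcription(self):
        """Pipeline M1-M5 + median equal a naive re-implementation to 1e-12."""
        rng = np.random.default_rng(42)
        for _ in range(40):
            n_dom = int(rng.integers(3, 6))
            n_meth = int(rng.integers(1, 4))
            table, specs = random_half_table(rng, n_dom, n_meth)
            m5w = {s.name: float(rng.uniform(0.1, 2.0)) for s in specs}
            res = run_consensus(table, specs, m5_weights=m5w)
            rows = [
                (r.domain1, r.domain2, r.method, r.raw)
                for r in table.df.itertuples(index=False)
            ]
            pol = {s.name: s.polarity for s in specs}
            experts = {s.name: s.expert_weight for s in specs}
            oracle_imp, oracle_orig, oracle_post = naive_consensus(rows, pol, experts, m5w)
            got = res.imputed.set_index(["domain1", "domain2"])
            for (a, b), expected in oracle_imp.items():
                actual = got.loc[(a, b), ["m1", "m2", "m3", "m4", "m5", "median"]]
                assert np.allclose(actual.to_numpy(dtype=float), expected, atol=1e-12)
            got_orig = res.original.set_index(["domain1", "domain2"])
            for (a, b), expected in oracle_orig.items():
                actual = got_orig.loc[(a, b), ["m1", "m2", "m3", "m4", "m5", "median"]]
                assert np.allclose(actual.to_numpy(dtype=float), expected, atol=1e-12)

    def test_identical_methods_degenerate_to_common_score(self):
        rng = np.random.default_rng(1)
        domains = [f"d{i}" for i in range(4)]
        pairs = [(a, b) for i, a in enumerate(domains) for b in domains[i + 1:]]
        vals = rng.random(len(pairs))
        rows = [
            {"domain1": a, "domain2": b, "method": m, "raw": v}
            for m in ("x", "y", "z")
            for (a, b), v in zip(pairs, vals)
        ]
        table = ScoreTable(pd.DataFrame(rows), ["x", "y", "z"], domains)
        specs = [PSCMethodSpec(m, polarity="dissimilarity") for m in ("x", "y", "z")]
        res = run_consensus(table, specs)
        wide = res.imputed
        for col in ("m1", "m2", "m3", "m4", "m5", "median"):
            assert np.allclose(wide[col], wide["x"], atol=1e-12)

    def test_consensus_is_convex_combination_of_scaled_scores(self, planted_noisy):
        _, _, table, specs = planted_noisy
        res = run_consensus(table, specs)
        wide = res.imputed
        S = wide[res.methods].to_numpy(dtype=float)
        lo, hi = S.min(axis=1), S.max(axis=1)
        for col in ("m1", "m2", "m3", "m4", "m5", "median"):
            v = wide[col].to_numpy(dtype=float)
            assert np.all(v >= lo - 1e-12) and np.all(v <= hi + 1e-12)
            assert np.all(v >= 0) and np.all(v <= 1)

    def test_no_missing_after_imputation(self, planted_noisy):
        _, _, table, specs = planted_noisy
        res = run_consensus(table, specs)
        cols = res.methods + ["m1", "m2", "m3", "m4", "m5", "median"]
        assert not res.imputed[cols].isna().any().any()
        n = len(res.domains)
        assert len(res.imputed) == n * n - n

    def test_common_view_counts_fully_covered_pairs(self):
        rng = np.random.default_rng(3)
        table, specs = random_half_table(rng, 5, 3, keep_prob=0.6)
        res = run_consensus(table, specs)
        pre = res.original[res.methods]
        expected = int(pre.notna().all(axis=1).sum())
        assert len(res.common) == expected

    def test_single_method_equals_all_schemes(self):
        rng = np.random.default_rng(4)
        table, specs = random_half_table(rng, 4, 1, keep_prob=1.0)
        res = run_consensus(table, specs)
        wide = res.imputed
        m = res.methods[0]
        for col in ("m1", "m2", "m3", "m4", "m5", "median"):
            assert np.allclose(wide[col], wide[m], atol=1e-15)

    def test_m4_weights_independent_of_method_order(self):
        rng = np.random.default_rng(5)
        table, specs = random_half_table(rng, 5, 3)
        res_fwd = run_consensus(table, specs)
        rev_table = ScoreTable(table.df.copy(), list(reversed(table.methods)), table.domains)
        res_rev = run_consensus(rev_table, list(reversed(specs)))
        for m in table.methods:
            assert res_fwd.weights["m4"].weights[m] == pytest.approx(
                res_rev.weights["m4"].weights[m], abs=1e-12
            )
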