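"""Normalization, the internal DE test, the five-stage cascade and ΔΔCT."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phosphorescue.rnaseq_cascade import (
    CascadeThresholds,
    DeTable,
    NormalizationError,
    ddct,
    ddct_summary,
    log2_expression_ratio,
    median_of_ratios_size_factors,
    run_cascade,
    simple_de,
)
from phosphorescue.synthetic_data import (
    RnaseqSimConfig,
    simulate_qpcr,
    simulate_rnaseq_dataset,
)

from cascade_fixture import brute_force_cascade as _brute_force_cascade
from cascade_fixture import toy_inputs as _toy_inputs


class TestSizeFactors:
    def test_identical_samples(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        factors = median_of_ratios_size_factors(counts)
        assert list(factors) == pytest.approx([1.0, 1.0])

    def test_doubled_sample(self):
        counts = pd.DataFrame({"a": [10, 20, 30, 40], "b": [20, 40, 60, 80]})
        factors = median_of_ratios_size_factors(counts)
        assert factors["b"] / factors["a"] == pytest.approx(2.0)

    def test_recovers_planted_library_factors(self, default_rnaseq):
        """Within one condition (same composition) size-factor ratios track
        the simulated library-size ratios to within 5%."""
        _, counts, sheet, truth = default_rnaseq
        samples = list(
            sheet.index[(sheet["genotype"] == "WT") & (sheet["treatment"] == "vehicle")]
        )
        factors = median_of_ratios_size_factors(counts[samples])
        planted = np.array([truth.library_factors[s] for s in samples])
        ratio = factors.to_numpy() / planted
        ratio /= ratio.mean()
        assert np.all(np.abs(ratio - 1.0) < 0.05)

    def test_no_common_nonzero_gene_is_an_error(self):
        counts = pd.DataFrame({"a": [5, 0], "b": [0, 5]})
        with pytest.raises(NormalizationError):
            median_of_ratios_size_factors(counts)


class TestSimpleDe:
    def test_identical_groups_zero_fc(self):
        rng = np.random.default_rng(0)
        base = rng.integers(50, 500, size=30)
        counts = pd.DataFrame({f"s{i}": base for i in range(4)})
        de = simple_de(counts, ["s0", "s1"], ["s2", "s3"])
        assert np.allclose(de.table["log2fc"], 0.0)

    def test_planted_eightfold_change(self):
        rng = np.random.default_rng(1)
        n = 200
        base = rng.integers(200, 2000, size=n).astype(float)
        a = {f"a{i}": rng.poisson(base) for i in range(6)}
        hot = base.copy()
        hot[0] *= 8
        b = {f"b{i}": rng.poisson(hot) for i in range(6)}
        counts = pd.DataFrame({**b, **a})
        de = simple_de(counts, list(b), list(a))
        assert de.table["log2fc"].iloc[0] == pytest.approx(3.0, abs=0.3)

    def test_bh_matches_hand_computation(self):
        from statsmodels.stats.multitest import multipletests

        p = [0.01, 0.04, 0.5]
        # step-up by hand: m=3 -> [0.03, 0.06, 0.5] -> monotone [0.03, 0.06, 0.5]
        hand = [0.03, 0.06, 0.5]
        assert list(multipletests(p, method="fdr_bh")[1]) == pytest.approx(hand)

    def test_permuted_null_type_one_error(self, default_rnaseq):
        """DE on label-permuted replicates of the same condition: the
        fraction of genes with p < 0.05 stays near nominal."""
        _, counts, sheet, _ = default_rnaseq
        samples = list(
            sheet.index[(sheet["genotype"] == "WT") & (sheet["treatment"] == "vehicle")]
        )
        rates = []
        rng = np.random.default_rng(5)
        for _ in range(5):
            perm = list(rng.permutation(samples))
            de = simple_de(counts, perm[:3], perm[3:])
            rates.append(float((de.table["p"] < 0.05).mean()))
        assert np.mean(rates) <= 0.07


class TestExpressionRatio:
    @staticmethod
    def _panel():
        counts = pd.DataFrame(
            {
                "wt1": [100, 400],
                "wt2": [100, 400],
                "d1": [100, 1600],
                "d2": [100, 1600],
            },
            index=["g0", "g1"],
        )
        sheet = pd.DataFrame(
            {
                "genotype": ["WT", "WT", "S473D", "S473D"],
                "treatment": ["TSZ"] * 4,
                "replicate": [1, 2, 1, 2],
            },
            index=["wt1", "wt2", "d1", "d2"],
        )
        return counts, sheet

    def test_equal_means_zero(self):
        counts, sheet = self._panel()
        ratio = log2_expression_ratio(
            counts, sheet, "S473D", "WT", "TSZ", size_factors=pd.Series(1.0, index=counts.columns)
        )
        assert ratio["g0"] == pytest.approx(0.0)

    def test_fourfold_is_two(self):
        counts, sheet = self._panel()
        ratio = log2_expression_ratio(
            counts, sheet, "S473D", "WT", "TSZ", size_factors=pd.Series(1.0, index=counts.columns)
        )
        assert ratio["g1"] == pytest.approx(2.0, abs=0.01)

    def test_agrees_with_raw_recomputation(self, default_rnaseq):
        _, counts, sheet, _ = default_rnaseq
        factors = median_of_ratios_size_factors(counts)
        ratio = log2_expression_ratio(
            counts, sheet, "KO", "WT", "TSZ", size_factors=factors
        )
        norm = counts / factors
        ko = [s for s in counts.columns if s.startswith("KO_TSZ")]
        wt = [s for s in counts.columns if s.startswith("WT_TSZ")]
        expected = np.log2(norm[ko].mean(axis=1) + 0.5) - np.log2(
            norm[wt].mean(axis=1) + 0.5
        )
        assert np.allclose(ratio, expected, atol=1e-9)

    def test_missing_condition_is_contract_error(self):
        counts, sheet = self._panel()
        with pytest.raises(ValueError):
            log2_expression_ratio(counts, sheet, "KO", "WT", "TSZ")


class TestCascade:
    def test_empty_table(self):
        de = DeTable(
            pd.DataFrame(columns=["log2fc", "p", "p_adjusted"], index=pd.Index([], name="gene"))
        )
        result = run_cascade(de, {}, {}, {})
        assert all(v == 0 for v in result.counts.values())

    def test_toy_fixture_matches_exhaustive_oracle(self):
        de, (r2, r3, r4) = _toy_inputs()
        result = run_cascade(de, r2, r3, r4)
        expected = _brute_force_cascade()
        assert (
            result.s1_up,
            result.s1_down,
            result.s2,
            result.s3,
            result.s4,
            result.s5,
        ) == tuple(frozenset(s) for s in expected)

    def test_nesting_invariant_on_toy(self):
        de, (r2, r3, r4) = _toy_inputs()
        result = run_cascade(de, r2, r3, r4)
        assert result.s5 <= result.s4 <= result.s3 <= result.s2 <= result.s1_up

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6))
    def test_nesting_invariant_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        genes = [f"g{i}" for i in range(n)]
        de = DeTable(
            pd.DataFrame(
                {
                    "log2fc": rng.normal(0, 2.5, n),
                    "p": rng.uniform(0, 1, n),
                    "p_adjusted": rng.uniform(0, 1, n),
                },
                index=genes,
            )
        )
        # ratio maps with random holes
        maps = []
        for _ in range(3):
            keep = rng.random(n) > 0.1
            maps.append(
                {g: float(rng.normal(0, 1)) for g, k in zip(genes, keep) if k}
            )
        result = run_cascade(de, *maps)
        assert result.s5 <= result.s4 <= result.s3 <= result.s2 <= result.s1_up
        counts = result.counts
        assert (
            counts["s1_up"] >= counts["s2"] >= counts["s3"]
            >= counts["s4"] >= counts["s5"]
        )

    def test_raising_thresholds_is_monotone(self):
        de, (r2, r3, r4) = _toy_inputs()
        loose = run_cascade(de, r2, r3, r4, CascadeThresholds())
        tight = run_cascade(
            de, r2, r3, r4,
            CascadeThresholds(stage1_min_abs_log2fc=2.4, stage5_min_log2ratio=0.5),
        )
        assert tight.s1_up <= loose.s1_up
        assert tight.s5 <= loose.s5

    def test_disjoint_namespaces_rejected(self):
        de, _ = _toy_inputs()
        with pytest.raises(ValueError):
            run_cascade(de, {"zzz": 1.0}, {"zzz": 1.0}, {"zzz": 1.0})

    def test_planted_stage_sizes_recovered(self, default_rnaseq):
        """End-to-end on simulated counts: internal DE + panel ratios
        reproduce the planted stage sizes within 10%."""
        config, counts, sheet, truth = default_rnaseq
        factors = median_of_ratios_size_factors(counts)

        def samples(gt, tr):
            return list(
                sheet.index[(sheet["genotype"] == gt) & (sheet["treatment"] == tr)]
            )

        de = simple_de(counts, samples("WT", "TSZ"), samples("WT", "vehicle"))
        ratios = [
            log2_expression_ratio(counts, sheet, a, b, "TSZ", size_factors=factors).to_dict()
            for a, b in (("KO", "WT"), ("S473D", "WT"), ("S473D", "S473A"))
        ]
        result = run_cascade(de, *ratios)
        planted = dict(zip(("s1_up", "s2", "s3", "s4", "s5"), config.stage_sizes))
        for stage, size in planted.items():
            assert abs(result.counts[stage] - size) <= max(1, 0.1 * size)


class TestDdct:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(
            rows, columns=["gene", "condition", "replicate", "ct_target", "ct_reference"]
        )

    def test_closed_form_fold_four(self):
        table = self._table(
            [
                ["G", "treated", 1, 20.0, 15.0],
                ["G", "control", 1, 22.0, 15.0],
            ]
        )
        out = ddct(table)
        treated = out[out["condition"] == "treated"].iloc[0]
        assert treated["delta_delta_ct"] == pytest.approx(-2.0)
        assert treated["fold"] == pytest.approx(4.0)

    def test_identical_conditions_fold_one(self):
        table = self._table(
            [
                ["G", "treated", 1, 21.0, 15.0],
                ["G", "control", 1, 21.0, 15.0],
            ]
        )
        out = ddct(table)
        assert np.allclose(out["fold"], 1.0)

    def test_invariant_to_constant_ct_shift(self):
        base = self._table(
            [
                ["G", "treated", r, 20.0 + 0.1 * r, 15.0] for r in range(3)
            ]
            + [["G", "control", r, 22.0, 15.0 + 0.05 * r] for r in range(3)]
        )
        shifted = base.copy()
        shifted["ct_target"] += 3.7
        shifted["ct_reference"] += 3.7
        assert np.allclose(ddct(base)["fold"], ddct(shifted)["fold"])

    def test_missing_reference_is_contract_error(self):
        table = self._table([["G", "treated", 1, 20.0, np.nan]])
        with pytest.raises(ValueError):
            ddct(table)

    def test_simulated_fold_recovery(self):
        table = simulate_qpcr({"G8": 8.0}, noise_sd=0.1, seed=7, n_replicates=100)
        out = ddct(table)
        summary = ddct_summary(out)
        treated = summary[
            (summary["gene"] == "G8") & (summary["condition"] == "treated")
        ]
        assert float(treated["fold_mean"].iloc[0]) == pytest.approx(8.0, rel=0.1)
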