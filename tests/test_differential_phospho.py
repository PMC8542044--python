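"""Regulation calling, rescue classification, temporal patterns and PCA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from phosphorescue.differential_phospho import (
    RegulationThresholds,
    assign_temporal_pattern,
    call_sites,
    classify_dependence,
    export_calls,
    pca_profiles,
    rescue_fraction,
)
from phosphorescue.differential_phospho import test_regulation as regulation_test
from phosphorescue.phospho_io import SiteQuant, compute_site_quant
from phosphorescue.synthetic_data import PhosphoSimConfig, simulate_phospho_dataset

TIMEPOINTS = ("15min", "0.5h", "2h", "4h")


def _quant(log2r_T, timepoint="15min", log2r_TN=None):
    quant = SiteQuant(site_id="s")
    for r, val in enumerate(log2r_T, start=1):
        quant.log2r_T[(timepoint, r)] = val
    for r, val in enumerate(log2r_TN or [], start=1):
        quant.log2r_TN[(timepoint, r)] = val
    quant.mean_log2r_T[timepoint] = float(np.mean(log2r_T))
    if log2r_TN:
        quant.mean_log2r_TN[timepoint] = float(np.mean(log2r_TN))
    return quant


class TestRegulationTest:
    def test_flat_replicates_are_ns(self):
        call = regulation_test(_quant([0.0] * 6), "15min")
        assert call.direction == "ns"

    def test_ratio_gate_blocks_small_effects(self):
        # tight replicates around 0.40: p tiny but below the 0.485 gate
        call = regulation_test(_quant([0.39, 0.40, 0.41, 0.40, 0.40, 0.40]), "15min")
        assert call.p_value < 0.001
        assert call.direction == "ns"

    def test_p_matches_textbook_t_statistic(self):
        ratios = [0.6, 0.5, 0.7, 0.55, 0.65, 0.5]
        call = regulation_test(_quant(ratios), "15min")
        mean = np.mean(ratios)
        sd = np.std(ratios, ddof=1)
        t = mean / (sd / math.sqrt(len(ratios)))
        expected = 2.0 * stats.t.sf(abs(t), df=5)
        assert call.p_value == pytest.approx(expected, abs=1e-9)
        assert call.direction == "up"

    def test_insufficient_replicates_is_ns_with_reason(self):
        call = regulation_test(_quant([1.0]), "15min")
        assert call.direction == "ns"
        assert call.reason == "insufficient replicates"

    def test_zero_variance_nonzero_mean_has_finite_p(self):
        call = regulation_test(_quant([1.0] * 6), "15min")
        assert call.direction == "up"
        assert 0.0 <= call.p_value < 1e-6

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_direction_gate_symmetry(self, seed):
        """Negating all log2 ratios swaps up<->down and preserves p and |f|."""
        rng = np.random.default_rng(seed)
        ratios = rng.normal(0.6, 0.2, size=6)
        tn = rng.normal(0.1, 0.2, size=6)
        pos = regulation_test(_quant(list(ratios), log2r_TN=list(tn)), "15min")
        neg = regulation_test(_quant(list(-ratios), log2r_TN=list(-tn)), "15min")
        assert pos.p_value == pytest.approx(neg.p_value, abs=1e-12)
        swap = {"up": "down", "down": "up", "ns": "ns"}
        assert neg.direction == swap[pos.direction]
        if pos.direction != "ns":
            f_pos = rescue_fraction(pos.mean_log2r_T, pos.mean_log2r_TN)
            f_neg = rescue_fraction(neg.mean_log2r_T, neg.mean_log2r_TN)
            assert f_pos == pytest.approx(f_neg, abs=1e-12)


class TestRescue:
    @pytest.mark.parametrize(
        "t, tn, expected",
        [(1.0, 0.0, 1.0), (1.0, 1.0, 0.0), (-1.0, -0.3, 0.7), (1.0, 1.5, -0.5)],
    )
    def test_closed_forms(self, t, tn, expected):
        assert rescue_fraction(t, tn) == pytest.approx(expected)

    def test_zero_stimulus_ratio_is_undefined(self):
        with pytest.raises(ValueError):
            rescue_fraction(0.0, 0.5)

    @pytest.mark.parametrize(
        "direction, t, tn, expected",
        [
            ("up", 1.0, 0.5, "inhibited"),  # f = 0.5 exactly: boundary inclusive
            ("up", 1.0, 0.8, "independent"),  # f = 0.2
            ("down", -1.0, -0.2, "rescued"),  # f = 0.8
        ],
    )
    def test_dependence_classes(self, direction, t, tn, expected):
        from phosphorescue.differential_phospho import RegulationCall

        call = RegulationCall(
            site_id="s",
            timepoint="2h",
            direction=direction,
            p_value=0.01,
            mean_log2r_T=t,
            mean_log2r_TN=tn,
        )
        assert classify_dependence(call).dependence == expected

    def test_ns_call_is_a_contract_error(self):
        from phosphorescue.differential_phospho import RegulationCall

        with pytest.raises(ValueError):
            classify_dependence(RegulationCall(site_id="s", timepoint="2h"))

    def test_monotone_in_f(self):
        """At fixed direction, increasing f never flips dependent->independent."""
        from phosphorescue.differential_phospho import RegulationCall

        classes = []
        for tn in np.linspace(1.0, -0.5, 16):  # f from 0 to 1.5
            call = RegulationCall(
                site_id="s",
                timepoint="2h",
                direction="up",
                p_value=0.01,
                mean_log2r_T=1.0,
                mean_log2r_TN=float(tn),
            )
            classes.append(classify_dependence(call).dependence == "inhibited")
        first_true = classes.index(True)
        assert all(classes[first_true:])


class TestTemporalPattern:
    def _call(self, tp, direction="ns", dependence="not_applicable"):
        from phosphorescue.differential_phospho import RegulationCall

        return RegulationCall(
            site_id="s", timepoint=tp, direction=direction, dependence=dependence
        )

    def test_early_only(self):
        calls = [self._call("15min", "up", "independent")] + [
            self._call(tp) for tp in TIMEPOINTS[1:]
        ]
        assert assign_temporal_pattern(calls, TIMEPOINTS).label == "early_only"

    def test_late_dependent_archetype(self):
        """Up at all four timepoints, inhibitor-dependent only at 2 h and 4 h."""
        calls = [
            self._call("15min", "up", "independent"),
            self._call("0.5h", "up", "independent"),
            self._call("2h", "up", "inhibited"),
            self._call("4h", "up", "inhibited"),
        ]
        assert assign_temporal_pattern(calls, TIMEPOINTS).label == "late_dependent"

    def test_sustained_without_dependence(self):
        calls = [self._call(tp, "up", "independent") for tp in TIMEPOINTS]
        assert assign_temporal_pattern(calls, TIMEPOINTS).label == "sustained"

    def test_single_timepoint_insufficient(self):
        assert (
            assign_temporal_pattern([self._call("15min", "up")], TIMEPOINTS).label
            == "insufficient"
        )

    def test_planted_late_dependent_recovery(self, default_phospho, default_phospho_calls):
        _, _, truth = default_phospho
        _, by_site = default_phospho_calls
        dep = truth.sites_of_class("dependent_late_up") + truth.sites_of_class(
            "dependent_late_down"
        )
        hits = [
            assign_temporal_pattern(by_site[s], TIMEPOINTS).label == "late_dependent"
            for s in dep
        ]
        assert np.mean(hits) >= 0.9


class TestTypeIError:
    def test_null_only_false_call_rate(self):
        """On data with no planted effects the up/down call rate stays near
        the nominal p gate, attenuated by the ratio gate."""
        rates = []
        for seed in range(5):
            config = PhosphoSimConfig(
                n_sites=400, class_fractions={"null": 1.0}, seed=100 + seed
            )
            records, _ = simulate_phospho_dataset(config)
            quants = [compute_site_quant(r) for r in records]
            calls = call_sites(quants, config.timepoints)
            rates.append(np.mean([c.direction != "ns" for c in calls]))
        assert np.mean(rates) <= 0.07


class TestPca:
    def test_identical_samples_identical_coordinates(self):
        rng = np.random.default_rng(1)
        row = rng.normal(size=20)
        X = np.vstack([row, row, rng.normal(size=20)])
        coords, _ = pca_profiles(X)
        assert np.allclose(coords[0], coords[1])

    def test_explained_variance_matches_eigen_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 30))
        X[:, 0] += np.linspace(0, 10, 10)  # dominant direction
        _, explained = pca_profiles(X)
        Xc = X - X.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(Xc @ Xc.T))[::-1]
        assert explained[0] == pytest.approx(eigvals[0] / eigvals.sum(), abs=1e-8)

    def test_group_separation_on_planted_effects(self, default_phospho):
        config, records, _ = default_phospho
        quants = [compute_site_quant(r) for r in records[:500]]
        rows = []
        for attr in ("mean_log2r_T", "mean_log2r_TN"):
            for tp in config.timepoints:
                rows.append([getattr(q, attr).get(tp, 0.0) for q in quants])
        coords, _ = pca_profiles(np.array(rows))
        t_pts, tn_pts = coords[:4], coords[4:]

        def mean_dist(a, b):
            return np.mean([np.linalg.norm(x - y) for x in a for y in b if not np.array_equal(x, y)])

        within = (mean_dist(t_pts, t_pts) + mean_dist(tn_pts, tn_pts)) / 2
        between = mean_dist(t_pts, tn_pts)
        assert within < between

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca_profiles(np.ones((4, 5)))


class TestExport:
    def test_empty_calls_gives_header_only(self, tmp_path):
        path = tmp_path / "calls.tsv"
        df = export_calls([], path=path)
        assert len(df) == 0
        assert path.read_text().count("\n") == 1

    def test_round_trip(self, tmp_path):
        import pandas as pd

        quant = _quant([0.6, 0.5, 0.7, 0.55, 0.65, 0.5], log2r_TN=[0.1] * 6)
        call = regulation_test(quant, "15min")
        classify_dependence(call)
        path = tmp_path / "calls.tsv"
        df = export_calls([call], path=path)
        back = pd.read_csv(path, sep="\t")
        assert back.loc[0, "direction"] == "up"
        assert back.loc[0, "p_value"] == pytest.approx(df.loc[0, "p_value"])
        assert back.loc[0, "dependence"] == "inhibited"
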