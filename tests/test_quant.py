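"""Cp normalization, fold changes, delta-delta-Cp, and the correlation screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chromodisp.quant import (
    CpTable,
    aggregate_and_compare,
    correlate_dispersion_expression,
    fold_change,
    fold_changes,
    normalize_cp,
    qpcr_expression_fold_change,
)
from chromodisp.synthetic import generate_cp_table, generate_expression_matrix


def _table(cps, origin="L1", sample="s", replicate=1):
    rows = [
        {"sample": sample, "replicate": replicate, "locus": f"L{i + 1}", "cp": cp}
        for i, cp in enumerate(cps)
    ]
    return CpTable(data=pd.DataFrame(rows), origin_locus=origin)


class TestNormalize:
    def test_mean_centering(self):
        out = normalize_cp(_table([20.0, 22.0]))
        assert sorted(out.data["cp"]) == [-1.0, 1.0]

    def test_shift_invariance(self):
        a = normalize_cp(_table([20.0, 22.0, 25.0]))
        b = normalize_cp(_table([23.0, 25.0, 28.0]))
        assert np.allclose(a.data["cp"], b.data["cp"])

    def test_matches_direct_subtraction(self):
        rng = np.random.default_rng(1)
        cps = rng.uniform(18, 30, 5)
        out = normalize_cp(_table(list(cps)))
        assert np.allclose(np.sort(out.data["cp"]), np.sort(cps - cps.mean()))

    def test_single_locus_errors(self):
        with pytest.raises(ValueError):
            normalize_cp(_table([20.0]))


class TestFoldChange:
    @pytest.mark.parametrize("delta,expected", [(0.0, 1.0), (1.0, 2.0), (-2.0, 0.25)])
    def test_closed_form(self, delta, expected):
        assert fold_change(20.0 + delta, 20.0) == pytest.approx(expected)

    def test_non_finite_errors(self):
        with pytest.raises(ValueError):
            fold_change(float("nan"), 20.0)

    def test_origin_exactly_one_in_every_replicate(self):
        table = generate_cp_table(
            ["ori", "a", "b"], "ori", {"a": 0.7, "b": -1.3},
            replicate_sd=0.2, n_replicates=5, seed=3,
        )
        fc = fold_changes(table)
        origin = fc.table.loc[fc.table["locus"] == "ori", "fold_change"]
        assert (origin == 1.0).all()

    @given(shift=st.floats(min_value=-5, max_value=5, allow_nan=False))
    @settings(derandomize=True, deadline=None)
    def test_fold_changes_shift_invariant(self, shift):
        base = generate_cp_table(
            ["ori", "a", "b"], "ori", {"a": 1.0, "b": -0.5},
            replicate_sd=0.1, n_replicates=3, seed=9,
        )
        shifted = CpTable(
            data=base.data.assign(cp=base.data["cp"] + shift),
            origin_locus="ori",
        )
        a = fold_changes(base).table["fold_change"].to_numpy()
        b = fold_changes(shifted).table["fold_change"].to_numpy()
        assert np.allclose(a, b)


class TestAggregateCompare:
    def _result(self, deltas, seed, sd=0.05):
        return fold_changes(
            generate_cp_table(["ori", "a", "b"], "ori", deltas,
                              replicate_sd=sd, n_replicates=3, seed=seed)
        )

    def test_identical_conditions_p_one(self):
        r = self._result({"a": 1.0}, seed=1)
        out = aggregate_and_compare({"wt": r, "mut": r}, correction="none")
        assert np.allclose(out["p_value"], 1.0)

    def test_shifted_locus_flagged(self):
        wt = self._result({"a": 0.0}, seed=2)
        mut = self._result({"a": 1.0}, seed=3)
        out = aggregate_and_compare({"wt": wt, "mut": mut}, correction="holm_sidak")
        assert bool(out.loc["a", "significant"])
        assert not bool(out.loc["ori", "significant"])

    def test_means_are_replicate_means(self):
        wt = self._result({"a": 0.5}, seed=4)
        mut = self._result({"a": 0.5}, seed=5)
        out = aggregate_and_compare({"wt": wt, "mut": mut})
        by_hand = wt.table.loc[wt.table["locus"] == "a", "fold_change"].mean()
        assert out.loc["a", "mean_wt"] == pytest.approx(by_hand)

    def test_single_replicate_errors(self):
        r1 = fold_changes(
            generate_cp_table(["ori", "a"], "ori", {}, replicate_sd=0.1,
                              n_replicates=1, seed=6)
        )
        with pytest.raises(ValueError, match="replicate"):
            aggregate_and_compare({"wt": r1, "mut": r1})


class TestDeltaDeltaCp:
    def test_flat_series_gives_unit_fold(self):
        target = {"0h": 25.0, "24h": 25.0, "48h": 25.0}
        control = {"0h": 18.0, "24h": 18.0, "48h": 18.0}
        fc = qpcr_expression_fold_change(target, control, "0h")
        assert np.allclose(fc, 1.0)

    def test_one_cycle_drop_doubles(self):
        target = {"0h": 25.0, "24h": 24.0}
        control = {"0h": 18.0, "24h": 18.0}
        fc = qpcr_expression_fold_change(target, control, "0h")
        assert fc["24h"] == pytest.approx(2.0)
        assert fc["0h"] == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        tps = [f"t{i}" for i in range(5)]
        target = pd.Series(rng.uniform(20, 30, 5), index=tps)
        control = pd.Series(rng.uniform(15, 20, 5), index=tps)
        fc = qpcr_expression_fold_change(target, control, "t0")
        for t in tps:
            dd = (target[t] - control[t]) - (target["t0"] - control["t0"])
            assert fc[t] == pytest.approx(2.0 ** (-dd))

    def test_missing_control_errors(self):
        with pytest.raises(ValueError, match="control"):
            qpcr_expression_fold_change({"0h": 25.0, "24h": 24.0}, {"0h": 18.0}, "0h")


class TestCorrelationScreen:
    def test_self_and_negated_covariate(self):
        cov = pd.Series(np.arange(1.0, 6.0), index=list("abcde"))
        expr = pd.DataFrame(
            [cov.to_numpy(), -cov.to_numpy(), np.full(5, 3.0)],
            index=["same", "neg", "flat"], columns=cov.index,
        )
        hits = {h.transcript: h for h in correlate_dispersion_expression(cov, expr)}
        assert hits["same"].r == pytest.approx(1.0) and hits["same"].passes
        assert hits["neg"].r == pytest.approx(-1.0) and hits["neg"].direction == "negative"
        assert np.isnan(hits["flat"].r) and not hits["flat"].passes

    def test_allele_mismatch_lists_difference(self):
        cov = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        expr = pd.DataFrame(np.ones((1, 3)), index=["t"], columns=["a", "b", "z"])
        with pytest.raises(ValueError, match="z"):
            correlate_dispersion_expression(cov, expr)

    def test_planted_recovery(self):
        cov = pd.Series(np.arange(1.0, 16.0),
                        index=[f"al{i}" for i in range(15)])
        matrix, truth = generate_expression_matrix(
            cov, n_planted_pos=50, n_planted_neg=3, n_noise=500,
            target_abs_r=0.9, seed=17,
        )
        hits = correlate_dispersion_expression(cov, matrix)
        by_name = {h.transcript: h for h in hits}
        pos = truth[truth == "planted_pos"].index
        neg = truth[truth == "planted_neg"].index
        noise = truth[truth == "noise"].index
        recall = np.mean([by_name[t].passes and by_name[t].direction == "positive" for t in pos])
        fpr = np.mean([by_name[t].passes for t in noise])
        assert recall >= 0.9
        assert fpr <= 0.05
        assert all(by_name[t].passes and by_name[t].direction == "negative" for t in neg)

    def test_all_finite_r_bounded(self):
        cov = pd.Series(np.arange(1.0, 16.0), index=[f"al{i}" for i in range(15)])
        matrix, _ = generate_expression_matrix(cov, 5, 5, 50, seed=2)
        hits = correlate_dispersion_expression(cov, matrix)
        rs = np.array([h.r for h in hits])
        assert np.all(np.abs(rs[np.isfinite(rs)]) <= 1.0)
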