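"""Intron-retention scoring: filters, Q-test, collapsing, permutation tests."""

import numpy as np
import pandas as pd
import pytest

from splicestate.ir import (
    collapse_nested,
    delta_ir_z,
    filter_introns,
    gel_psi,
    q_test_score,
    transcript_significance,
)


def _intron_table(n=4, **overrides):
    samples = ("control", "treat1", "treat2", "treat3")
    df = pd.DataFrame({
        "transcript_id": [f"t{i}" for i in range(n)],
        "chrom": "c", "start": np.arange(n) * 1_000, "end": np.arange(n) * 1_000 + 200,
        "ir_control": 0.3, "ir_treat1": 0.2, "ir_treat2": 0.25, "ir_treat3": 0.22,
    })
    for s in samples:
        df[f"cpm_{s}"] = 2.0
        df[f"flank5_{s}"] = 12
        df[f"flank3_{s}"] = 12
    for col, vals in overrides.items():
        df[col] = vals
    return df


class TestFilter:
    def test_all_criteria_met_retained(self):
        kept, log = filter_introns(_intron_table())
        assert len(kept) == 4 and len(log) == 0

    def test_boundary_flank_exactly_ten_rejected(self):
        df = _intron_table(flank5_treat2=[12, 10, 12, 12])
        kept, log = filter_introns(df)
        assert len(kept) == 3
        assert log["reason"].iloc[0] == "flank5"

    def test_low_cpm_in_one_sample_rejected_with_reason(self):
        df = _intron_table(cpm_control=[2, 2, 0.9, 2])
        kept, log = filter_introns(df)
        assert len(kept) == 3
        assert log["reason"].iloc[0] == "CPM"

    def test_cpm_exactly_one_rejected(self):
        df = _intron_table(cpm_treat1=[1.0, 2, 2, 2])
        kept, _ = filter_introns(df)
        assert len(kept) == 3


class TestQTest:
    def test_separated_control_significant(self):
        q, p, score = q_test_score(0.5, [0.10, 0.12, 0.14], mc_reps=50_000, seed=1)
        assert q == pytest.approx(0.36 / 0.40)
        assert p < 0.05
        assert score == pytest.approx(-np.log10(p))

    def test_control_inside_treatment_range_is_null(self):
        q, p, score = q_test_score(0.12, [0.10, 0.12, 0.14], mc_reps=10_000, seed=1)
        assert (q, p, score) == (0.0, 1.0, 0.0)

    def test_degenerate_equal_values(self):
        q, p, score = q_test_score(0.4, [0.4, 0.4, 0.4], mc_reps=10_000, seed=1)
        assert (p, score) == (1.0, 0.0)

    def test_mc_convergence_on_doubling(self):
        _, p1, _ = q_test_score(0.5, [0.1, 0.15, 0.2], mc_reps=50_000, seed=2)
        _, p2, _ = q_test_score(0.5, [0.1, 0.15, 0.2], mc_reps=100_000, seed=2)
        assert abs(p1 - p2) < 2 / np.sqrt(50_000)

    def test_critical_value_cross_check(self):
        # with the control-designated suspect the Dixon alpha=0.05 critical
        # ratio (0.829 at n=4) must be comfortably significant
        _, p, _ = q_test_score(0.929, [0.0, 0.05, 0.1], mc_reps=100_000, seed=3)
        assert p < 0.05

    def test_arity_error(self):
        with pytest.raises(ValueError):
            q_test_score(0.5, [0.1, 0.2], mc_reps=1_000, seed=1)


class TestCollapse:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["transcript_id", "chrom", "start", "end", "score"])

    def test_two_overlapping_introns_median(self):
        out = collapse_nested(self._df([("t", "c", 100, 200, 2.0), ("t", "c", 150, 250, 4.0)]))
        assert len(out) == 1
        assert out["score"].iloc[0] == pytest.approx(3.0)
        assert out["n_members"].iloc[0] == 2

    def test_three_member_component_median(self):
        out = collapse_nested(self._df([
            ("t", "c", 0, 300, 1.0), ("t", "c", 100, 200, 3.0), ("t", "c", 250, 400, 10.0)]))
        assert len(out) == 1
        assert out["score"].iloc[0] == pytest.approx(3.0)

    def test_disjoint_pass_through(self):
        rows = [("t", "c", 0, 100, 1.0), ("t", "c", 200, 300, 2.0)]
        out = collapse_nested(self._df(rows))
        assert len(out) == 2
        assert list(out["score"]) == [1.0, 2.0]

    def test_order_invariance(self):
        rows = [("t", "c", 100, 200, 2.0), ("t", "c", 150, 250, 4.0),
                ("t", "c", 500, 600, 1.0), ("u", "c", 120, 180, 9.0)]
        a = collapse_nested(self._df(rows)).sort_values("entity_id").reset_index(drop=True)
        b = collapse_nested(self._df(rows[::-1])).sort_values("entity_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_different_transcripts_not_merged(self):
        out = collapse_nested(self._df([("t", "c", 100, 200, 2.0), ("u", "c", 150, 250, 4.0)]))
        assert len(out) == 2


class TestTranscriptSignificance:
    def _entities(self, scores_by_tx):
        rows = []
        for tid, scores in scores_by_tx.items():
            for i, s in enumerate(scores):
                rows.append({"transcript_id": tid, "score": s})
        return pd.DataFrame(rows)

    def test_extreme_transcript_hits_p_floor(self):
        rng = np.random.default_rng(0)
        d = {f"n{i}": rng.random(5).tolist() for i in range(200)}
        d["hot"] = [5.0] * 5
        res = transcript_significance(self._entities(d), B=1_000, seed=1)
        hot = res.set_index("transcript_id").loc["hot"]
        assert hot["p_fw1"] == pytest.approx(1 / 1_001)
        assert hot["p_fw2"] == pytest.approx(1 / 1_001)

    def test_add_one_smoothing_upper_bound(self):
        rng = np.random.default_rng(0)
        d = {f"n{i}": (1 + rng.random(5)).tolist() for i in range(50)}
        d["cold"] = [1e-6] * 5  # below every null mean
        res = transcript_significance(self._entities(d), B=1_000, seed=1)
        assert res.set_index("transcript_id").loc["cold", "p_fw2"] == pytest.approx(1.0)

    def test_no_positive_scores_not_evaluable_never_sensitive(self):
        d = {"zero": [0.0] * 4, **{f"n{i}": [0.5, 1.0, 0.0] for i in range(30)}}
        res = transcript_significance(self._entities(d), B=1_000, seed=2)
        row = res.set_index("transcript_id").loc["zero"]
        assert np.isnan(row["p_fw1"])
        assert not row["sensitive"]

    def test_framework2_stat_leq_framework1_with_zeros(self):
        d = {f"t{i}": [0.0, 1.0, 2.0] for i in range(20)}
        res = transcript_significance(self._entities(d), B=1_000, seed=3)
        assert (res["stat_fw2"] <= res["stat_fw1"] + 1e-12).all()

    def test_b_floor_enforced(self):
        with pytest.raises(ValueError):
            transcript_significance(self._entities({"t": [1.0]}), B=10, seed=1)


class TestDeltaIR:
    def test_all_identical_deltas_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            delta_ir_z([0.2, 0.2], [0.3, 0.3], ["t", "t"], B=1_000, seed=1)

    def test_transcript_at_global_mean_z_near_zero(self):
        rng = np.random.default_rng(4)
        n = 400
        ctrl = rng.uniform(0.2, 0.6, n)
        treat = ctrl * rng.uniform(0.8, 1.25, n)
        tx = ["bulk"] * (n - 4) + ["sym"] * 4
        # give 'sym' deltas straddling the pool symmetrically
        res = delta_ir_z(ctrl, treat, tx, B=2_000, seed=5)
        row = res.set_index("transcript_id").loc["sym"]
        assert row["z"] == pytest.approx((row["observed"] - row["null_mean"]) / row["null_sd"])

    def test_planted_negative_shift_strong_negative_z(self):
        rng = np.random.default_rng(6)
        n = 500
        ctrl = rng.uniform(0.3, 0.6, n)
        treat = ctrl + rng.normal(0, 0.02, n)
        treat[:10] = ctrl[:10] - 0.3  # one 10-intron transcript with reduced IR
        tx = ["hot"] * 10 + [f"t{i // 5}" for i in range(n - 10)]
        res = delta_ir_z(ctrl, np.clip(treat, 0.01, 1), tx, B=2_000, seed=7)
        assert res.set_index("transcript_id").loc["hot", "z"] < -3


class TestGelPsi:
    @pytest.mark.parametrize("ret,spl,expect", [(30, 70, 0.30), (0, 50, 0.0), (50, 0, 1.0)])
    def test_ratio(self, ret, spl, expect):
        assert gel_psi(ret, spl) == pytest.approx(expect)

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            gel_psi(0, 0)
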