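import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynapquant import enrichment as E
from dynapquant.tables_io import Pairing, PairingSpec

from _oracles import bh_oracle, fc_oracle, p_oracle, z_oracle


def _pairing(bait="baitX"):
    return PairingSpec([Pairing(bait, ("expt1",), ("ctrl1", "ctrl2"))])


class TestCollapse:
    def test_proteins_sum_within_group(self):
        df = pd.DataFrame(
            [("r1", "b", "A", 3), ("r1", "b", "B", 4)],
            columns=["run_id", "bait_label", "protein_id", "psm_count"],
        )
        out = E.collapse_to_groups(df, {"A": "g1", "B": "g1"})
        assert out["protein_id"].tolist() == ["g1"]
        assert out["psm_count"].tolist() == [7]

    def test_identity_map_preserves_counts(self, small_psm_table):
        idmap = {p: p for p in small_psm_table["protein_id"]}
        out = E.collapse_to_groups(small_psm_table, idmap)
        merged = out.merge(
            small_psm_table, on=["run_id", "protein_id"], suffixes=("_o", "_i")
        )
        assert (merged["psm_count_o"] == merged["psm_count_i"]).all()
        assert len(out) == len(small_psm_table)

    def test_runs_kept_separate(self):
        df = pd.DataFrame(
            [("r1", "b", "A", 2), ("r2", "b", "A", 5)],
            columns=["run_id", "bait_label", "protein_id", "psm_count"],
        )
        out = E.collapse_to_groups(df, {"A": "g1"})
        assert dict(zip(out["run_id"], out["psm_count"])) == {"r1": 2, "r2": 5}


class TestCombineRuns:
    def test_control_replicates_pooled_by_summing(self, small_psm_table):
        cp = E.combine_runs(small_psm_table, _pairing(), "baitX")
        by_group = dict(zip(cp.group_ids, cp.psm_ctrl))
        assert by_group == {"A": 5, "B": 5, "C": 30}
        assert cp.total_ctrl == 40
        assert cp.total_expt == 40

    def test_group_seen_only_in_expt_gets_zero_ctrl(self, small_psm_table):
        extra = pd.DataFrame(
            [("expt1", "baitX", "D", 7)], columns=small_psm_table.columns
        )
        table = pd.concat([small_psm_table, extra], ignore_index=True)
        cp = E.combine_runs(table, _pairing(), "baitX")
        i = cp.group_ids.index("D")
        assert cp.psm_expt[i] == 7 and cp.psm_ctrl[i] == 0
        assert cp.universe_size_n == 4

    def test_group_absent_everywhere_excluded(self, small_psm_table):
        cp = E.combine_runs(small_psm_table, _pairing(), "baitX")
        assert set(cp.group_ids) == {"A", "B", "C"}

    def test_unknown_run_id_raises(self, small_psm_table):
        spec = PairingSpec([Pairing("baitX", ("nope",), ("ctrl1",))])
        with pytest.raises(KeyError, match="nope"):
            E.combine_runs(small_psm_table, spec, "baitX")


class TestFoldChange:
    @pytest.mark.parametrize(
        "expt, ctrl, expected",
        [
            ((5, 5), (5, 5), (0.0, 0.0)),
            ((9, 0, 1), (0, 9, 1), (np.log2(10), -np.log2(10), 0.0)),
            ((0, 7), (0, 7), (0.0, 0.0)),
        ],
    )
    def test_hand_examples(self, expt, ctrl, expected):
        # the (0, 7) case probes the pseudocount identity for a group absent
        # on both sides, which the CountPair universe invariant excludes, so
        # the kernel is exercised directly
        np.testing.assert_allclose(
            E.log2_fc_from_counts(expt, ctrl), expected, atol=1e-12
        )

    def test_always_finite(self, rng):
        e = rng.integers(0, 50, size=30)
        c = rng.integers(0, 50, size=30)
        keep = (e + c) >= 1
        cp = E.CountPair.from_counts(
            [f"g{i}" for i in range(int(keep.sum()))], e[keep], c[keep]
        )
        assert np.isfinite(E.fold_change(cp)).all()


class TestZScore:
    def test_equal_frequencies_give_zero(self):
        cp = E.CountPair.from_counts(["a", "b"], (10, 90), (10, 90))
        np.testing.assert_allclose(E.z_score(cp), 0.0, atol=1e-12)

    def test_ten_vs_one_percent_example(self):
        # group at 10% of a 100-PSM pulldown vs 1% of a 100-PSM control
        cp = E.CountPair.from_counts(["a", "b"], (10, 90), (1, 99))
        assert E.z_score(cp)[0] == pytest.approx(2.7915, abs=5e-5)

    def test_single_group_universe_is_degenerate(self):
        cp = E.CountPair.from_counts(["a"], (7,), (3,))
        assert E.z_score(cp)[0] == 0.0

    def test_zero_total_raises(self):
        with pytest.raises(ValueError, match="total"):
            E.z_from_counts((0, 0), (1, 2))


class TestPValue:
    @pytest.mark.parametrize(
        "z, expected, tol",
        [(0.0, 0.5, 1e-12), (1.645, 0.05, 5e-4), (2.7915, 0.00262, 5e-6)],
    )
    def test_upper_tail_values(self, z, expected, tol):
        assert E.p_value(z) == pytest.approx(expected, abs=tol)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            E.p_value(np.inf)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(E.bh_adjust([0.03]), [0.03])

    def test_four_value_hand_example(self):
        np.testing.assert_allclose(
            E.bh_adjust([0.01, 0.04, 0.03, 0.005]), [0.02, 0.04, 0.04, 0.02]
        )

    def test_ties_map_to_common_value(self):
        np.testing.assert_allclose(E.bh_adjust([0.2] * 7), [0.2] * 7)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            E.bh_adjust([0.1, 1.2])

    def test_matches_statsmodels_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(
                E.bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    def test_batch_axis_matches_rowwise(self, rng):
        p = rng.uniform(size=(20, 7))
        batch = E.bh_adjust(p, axis=-1)
        for i in range(20):
            np.testing.assert_allclose(batch[i], E.bh_adjust(p[i]), atol=1e-12)


class TestScoreExperiment:
    def test_enriched_group_ranked_first_with_expected_stats(self, small_psm_table):
        res = E.score_experiment(
            small_psm_table, {p: p for p in "ABC"}, _pairing(), "baitX", "A"
        )
        top = res.iloc[0]
        assert top["group_id"] == "A"
        assert top["log2_fc"] == pytest.approx(np.log2(31 / 6), abs=1e-9)
        assert top["z"] == pytest.approx(5.634, abs=5e-4)
        assert bool(top["is_bait"]) and bool(top["significant"])
        assert res["z"].is_monotonic_decreasing

    def test_null_experiment_has_no_significant_rows(self):
        rows = [("e", "b", p, 5) for p in "ABC"] + [("c", "GFP", p, 5) for p in "ABC"]
        df = pd.DataFrame(
            rows, columns=["run_id", "bait_label", "protein_id", "psm_count"]
        )
        spec = PairingSpec([Pairing("b", ("e",), ("c",))])
        res = E.score_experiment(df, {}, spec, "b", "A")
        assert res["significant"].sum() == 0
        np.testing.assert_allclose(res["z"], 0.0, atol=1e-12)

    def test_degenerate_single_group_gets_p_one(self):
        df = pd.DataFrame(
            [("e", "b", "A", 9), ("c", "GFP", "A", 2)],
            columns=["run_id", "bait_label", "protein_id", "psm_count"],
        )
        spec = PairingSpec([Pairing("b", ("e",), ("c",))])
        res = E.score_experiment(df, {}, spec, "b", "A")
        assert res["z"].iloc[0] == 0.0 and res["p"].iloc[0] == 1.0

    def test_frequency_columns_are_consistent(self, small_psm_table):
        res = E.score_experiment(small_psm_table, {}, _pairing(), "baitX", "A")
        np.testing.assert_allclose(res["f_expt"].sum(), 1.0, atol=1e-12)
        np.testing.assert_allclose(res["f_ctrl"].sum(), 1.0, atol=1e-12)
        np.testing.assert_allclose(
            res["f_comb"],
            (res["psm_expt"] + res["psm_ctrl"]) / 80.0,
            atol=1e-12,
        )


def _random_count_pairs(rng, n_pairs):
    for _ in range(n_pairs):
        n = int(rng.integers(2, 40))
        e = rng.integers(0, 30, size=n)
        c = rng.integers(0, 30, size=n)
        e[rng.integers(n)] += 1  # guarantee a non-empty universe
        keep = (e + c) >= 1
        yield E.CountPair.from_counts(
            [f"g{i}" for i in range(int(keep.sum()))], e[keep], c[keep]
        )


class TestInvariants:
    def test_antisymmetry_and_normalization(self, rng):
        """Swapping bait and control negates FC and Z; pseudocounted
        frequencies stay normalized."""
        for cp in _random_count_pairs(rng, 300):
            swapped = E.CountPair.from_counts(cp.group_ids, cp.psm_ctrl, cp.psm_expt)
            np.testing.assert_allclose(
                E.fold_change(cp), -E.fold_change(swapped), atol=1e-12
            )
            np.testing.assert_allclose(
                E.z_score(cp), -E.z_score(swapped), atol=1e-9
            )
            fe = (cp.psm_expt + 1) / (cp.psm_expt + 1).sum()
            assert abs(fe.sum() - 1.0) < 1e-12

    @given(
        te=st.integers(5, 200),
        tc=st.integers(5, 200),
        ci=st.integers(0, 100),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_z_strictly_increasing_in_expt_count(self, te, tc, ci):
        """With totals and the control count fixed, Z rises with the bait
        count of the group (up to the degenerate all-of-total corner)."""
        ci = min(ci, tc)
        rest_c = tc - ci
        zs = []
        for ei in range(0, te):  # ei == te can be degenerate (f_comb == 1)
            if rest_c == 0 and ei == te:
                continue
            e = np.array([ei, te - ei], dtype=float)
            c = np.array([ci, rest_c], dtype=float)
            zs.append(E.z_from_counts(e, c)[0])
        assert (np.diff(zs) > 0).all()

    def test_matches_oracles_on_random_universes(self, rng):
        for cp in _random_count_pairs(rng, 100):
            e, c = cp.psm_expt.tolist(), cp.psm_ctrl.tolist()
            np.testing.assert_allclose(E.fold_change(cp), fc_oracle(e, c), atol=1e-9)
            z = E.z_score(cp)
            np.testing.assert_allclose(z, z_oracle(e, c), atol=1e-9)
            np.testing.assert_allclose(
                E.p_value(z), [p_oracle(v) for v in z], atol=1e-9
            )
            p = E.p_value(z)
            np.testing.assert_allclose(E.bh_adjust(p), bh_oracle(list(p)), atol=1e-9)
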