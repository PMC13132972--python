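"""Top-k-mean final binding score, anti-target exclusion, ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lysoscreen.docking import ScoreMatrix
from lysoscreen.prioritize import (
    PrioritizationConfig,
    anti_target_filter,
    final_binding_score,
    prioritize,
    rank_and_select,
    score_matrix_records,
)
from lysoscreen.synthetic import FixtureSpec, gen_receptor_manifest, gen_score_matrix


def matrix_from(values, ligs=None, recs=None, **kw):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ligs = ligs or [f"l{i}" for i in range(values.shape[0])]
    recs = recs or [f"r{j}" for j in range(values.shape[1])]
    return ScoreMatrix(pd.DataFrame(values, index=ligs, columns=recs))


class TestFinalBindingScore:
    def test_hand_mean_of_three_largest_magnitudes(self):
        row = pd.Series({"r1": -10.1, "r2": -10.3, "r3": -10.2, "r4": -5.0, "r5": -4.0})
        score, ids = final_binding_score(row, k=3)
        assert score == pytest.approx(10.2)
        assert ids == ["r2", "r3", "r1"]

    def test_constant_row(self):
        row = pd.Series({f"r{j}": -6.0 for j in range(30)})
        score, _ = final_binding_score(row, k=20)
        assert score == pytest.approx(6.0)

    def test_default_k_is_20(self):
        cfg = PrioritizationConfig()
        assert cfg.k == 20

    def test_short_row_averages_all(self):
        row = pd.Series({"r1": -4.0, "r2": -8.0})
        score, ids = final_binding_score(row, k=20)
        assert score == pytest.approx(6.0)
        assert ids == ["r2", "r1"]

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            final_binding_score(pd.Series(dtype=float), k=3)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_oracle_equivalence_random_matrices(self, seed):
        """Top-k mean equals brute-force sort-and-average exactly."""
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(1, 21)), int(rng.integers(1, 31))
        k = int(rng.integers(1, 25))
        mat = matrix_from(-rng.uniform(0, 12, size=(n, m)))
        for lig in mat.ligand_ids:
            score, _ = final_binding_score(mat.row(lig), k=k)
            mags = np.sort(-mat.row(lig).to_numpy())[::-1]
            assert score == np.mean(mags[:k])

    def test_monotonicity(self):
        row = pd.Series({"r1": -9.0, "r2": -8.0, "r3": -7.0, "r4": -2.0})
        base, _ = final_binding_score(row, k=3)
        improved = row.copy(); improved["r1"] = -9.5
        assert final_binding_score(improved, k=3)[0] >= base
        worse_nontop = row.copy(); worse_nontop["r4"] = -1.0
        assert final_binding_score(worse_nontop, k=3)[0] == base


class TestAntiTargetFilter:
    def test_default_threshold(self):
        assert PrioritizationConfig().antitarget_threshold == 8.5

    def test_strong_antitarget_binder_excluded(self):
        mat = matrix_from([[-6.0, -9.2], [-6.0, -4.0]], recs=["r", "anti"])
        cfg = PrioritizationConfig(antitarget_receptor_ids=("anti",))
        out = anti_target_filter(mat, cfg)
        assert out.loc["l0", "excluded"] and out.loc["l0", "antitarget_affinity"] == 9.2
        assert not out.loc["l1", "excluded"]

    def test_literal_rule_flips_direction(self):
        mat = matrix_from([[-6.0, -9.2], [-6.0, -4.0]], recs=["r", "anti"])
        cfg = PrioritizationConfig(antitarget_receptor_ids=("anti",), literal_antitarget_rule=True)
        out = anti_target_filter(mat, cfg)
        assert not out.loc["l0", "excluded"] and out.loc["l1", "excluded"]

    def test_no_antitarget_columns_excludes_nothing(self):
        mat = matrix_from([[-12.0, -11.0]])
        out = anti_target_filter(mat, PrioritizationConfig())
        assert not out["excluded"].any()

    def test_unknown_antitarget_id_rejected(self):
        mat = matrix_from([[-6.0]])
        with pytest.raises(ValueError, match="ghost"):
            anti_target_filter(mat, PrioritizationConfig(antitarget_receptor_ids=("ghost",)))

    def test_filter_idempotent_and_order_independent(self):
        rng = np.random.default_rng(0)
        vals = -rng.uniform(0, 12, size=(8, 5))
        mat = matrix_from(vals, recs=["r0", "r1", "r2", "r3", "anti"])
        cfg = PrioritizationConfig(antitarget_receptor_ids=("anti",))
        out1 = anti_target_filter(mat, cfg)
        out2 = anti_target_filter(mat, cfg)
        pd.testing.assert_frame_equal(out1, out2)
        perm = matrix_from(vals[::-1], ligs=[f"l{i}" for i in range(7, -1, -1)],
                           recs=["r0", "r1", "r2", "r3", "anti"])
        out3 = anti_target_filter(perm, cfg)
        assert set(out3.index[out3["excluded"]]) == set(out1.index[out1["excluded"]])


class TestRankAndSelect:
    def test_default_n_select_is_20(self):
        assert PrioritizationConfig().n_select == 20

    def test_tie_broken_by_ligand_id(self):
        records = pd.DataFrame(
            {"ligand_id": ["lb", "la"], "final_binding_score": [7.0, 7.0],
             "excluded": [False, False]}
        )
        out = rank_and_select(records, n_select=2)
        assert out["ligand_id"].tolist() == ["la", "lb"]
        assert out["rank"].tolist() == [1, 2]

    def test_single_survivor_rank_one(self):
        records = pd.DataFrame(
            {"ligand_id": ["la", "lb"], "final_binding_score": [7.0, 9.0],
             "excluded": [False, True]}
        )
        out = rank_and_select(records, n_select=20)
        assert out["ligand_id"].tolist() == ["la"] and out["rank"].tolist() == [1]

    def test_excluded_records_carry_no_rank(self):
        mat = matrix_from([[-6.0, -9.2], [-6.0, -4.0]], recs=["r", "anti"])
        cfg = PrioritizationConfig(antitarget_receptor_ids=("anti",), k=1, n_select=5)
        records = score_matrix_records(mat, cfg)
        assert records.loc[records["excluded"], "rank"].isna().all()
        assert records.loc[~records["excluded"], "rank"].notna().all()


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", range(10))
    def test_hits_selected_binders_excluded(self, seed):
        """Planted multi-target hits are all selected; planted anti-target
        binders never are, across seeds."""
        spec = FixtureSpec(
            seed=seed, n_ligands=60, n_references=5,
            planted_hit_ids=("LIG00001", "LIG00002", "LIG00003", "LIG00004"),
            planted_antitarget_binder_ids=("LIG00010", "LIG00011"),
            n_receptors_total=60, n_missing_structure=4,
            n_pocketless=5, n_antitarget_receptors=3,
        )
        receptors, _ = gen_receptor_manifest(spec)
        matrix, truth = gen_score_matrix(spec, spec.ligand_ids(), receptors)
        cfg = PrioritizationConfig(
            antitarget_receptor_ids=tuple(truth["antitarget_receptor_ids"])
        )
        records, selected = prioritize(matrix, cfg)
        chosen = set(selected["ligand_id"])
        assert set(truth["planted_hit_ids"]) <= chosen
        assert not set(truth["planted_antitarget_binder_ids"]) & chosen
        assert records.loc[
            records["ligand_id"].isin(truth["planted_antitarget_binder_ids"]), "excluded"
        ].all()
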