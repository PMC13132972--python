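"""Generator contracts: determinism, preconditions, planted-truth closure,
and noise-zero limits."""

import numpy as np
import pandas as pd
import pytest

from lysoscreen.kinetics import mm_rate
from lysoscreen.synthetic import (
    FixtureSpec,
    gen_dose_response,
    gen_itc,
    gen_kinetics,
    gen_library,
    gen_melt_curves,
    gen_receptor_manifest,
    gen_score_matrix,
)


class TestFixtureSpec:
    def test_zero_references_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            FixtureSpec(n_references=0)

    def test_planted_sets_must_be_disjoint(self):
        with pytest.raises(ValueError, match="disjoint"):
            FixtureSpec(n_ligands=10, planted_hit_ids=("LIG00001",),
                        planted_antitarget_binder_ids=("LIG00001",))

    def test_flag_counts_exceeding_total_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            FixtureSpec(n_receptors_total=10, n_missing_structure=5,
                        n_pocketless=4, n_antitarget_receptors=3)

    def test_unknown_planted_id_rejected(self):
        with pytest.raises(ValueError, match="not in the ligand id set"):
            FixtureSpec(n_ligands=5, planted_hit_ids=("LIG09999",))


class TestDeterminism:
    def test_library_identical_for_same_seed(self):
        spec = FixtureSpec(seed=7, n_ligands=12, n_references=3,
                           planted_hit_ids=("LIG00003",),
                           n_receptors_total=10, n_missing_structure=1,
                           n_pocketless=1, n_antitarget_receptors=1)
        lib1, refs1, _ = gen_library(spec)
        lib2, refs2, _ = gen_library(spec)
        for a, b in zip(lib1 + refs1, lib2 + refs2):
            assert a.ligand_id == b.ligand_id
            np.testing.assert_array_equal(a.level1, b.level1)
            np.testing.assert_array_equal(a.level2, b.level2)
            np.testing.assert_array_equal(a.level3, b.level3)

    def test_manifest_and_matrix_identical_for_same_seed(self, desk_spec):
        r1, t1 = gen_receptor_manifest(desk_spec)
        r2, t2 = gen_receptor_manifest(desk_spec)
        assert r1 == r2 and t1 == t2
        m1, mt1 = gen_score_matrix(desk_spec, desk_spec.ligand_ids(), r1)
        m2, mt2 = gen_score_matrix(desk_spec, desk_spec.ligand_ids(), r2)
        pd.testing.assert_frame_equal(m1.affinity, m2.affinity)
        assert mt1 == mt2

    def test_assay_tables_identical_for_same_seed(self):
        for gen in (lambda s: gen_melt_curves(5, seed=s)[0],
                    lambda s: gen_itc(seed=s)[0],
                    lambda s: gen_kinetics(seed=s)[0],
                    lambda s: gen_dose_response(seed=s)[0]):
            pd.testing.assert_frame_equal(gen(42), gen(42))

    def test_different_seeds_differ(self):
        a = gen_itc(seed=1)[0]["heat_ucal"]
        b = gen_itc(seed=2)[0]["heat_ucal"]
        assert not np.allclose(a, b)


class TestManifestGeneration:
    def test_planted_flag_counts(self, desk_spec):
        records, truth = gen_receptor_manifest(desk_spec)
        assert sum(not r.has_structure for r in records) == desk_spec.n_missing_structure
        assert len(truth["pocketless_ids"]) == desk_spec.n_pocketless
        assert len(truth["antitarget_receptor_ids"]) == desk_spec.n_antitarget_receptors
        # planted subsets are disjoint
        sets = [set(truth["missing_structure_ids"]), set(truth["pocketless_ids"]),
                set(truth["antitarget_receptor_ids"])]
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])

    def test_survivor_pockets_ranked(self, desk_spec):
        records, _ = gen_receptor_manifest(desk_spec)
        for r in records:
            if r.pockets:
                assert [p.rank for p in r.pockets] == list(range(1, len(r.pockets) + 1))


class TestScoreMatrix:
    def test_dimensions_match_inputs(self, desk_spec, desk_matrix):
        matrix, truth = desk_matrix
        n_ready = 60 - 4 - 5 - 3
        assert matrix.shape == (60, n_ready + len(truth["antitarget_receptor_ids"]))

    def test_planted_hit_final_score_hand_value(self):
        """Planted favorable scores {-10.1, -10.3, -10.2}: top-3 mean magnitude 10.2."""
        from lysoscreen.docking import MockDockingBackend, assemble_matrix
        from lysoscreen.prioritize import final_binding_score

        plants = {("l0", "r0"): -10.1, ("l0", "r1"): -10.3, ("l0", "r2"): -10.2}
        m = assemble_matrix(["l0"], ["r0", "r1", "r2", "r3"], MockDockingBackend(seed=0, plants=plants))
        score, _ = final_binding_score(m.row("l0"), k=3)
        assert score == pytest.approx(10.2)

    def test_planted_cells_match_sidecar(self, desk_matrix):
        matrix, truth = desk_matrix
        for key, val in truth["plants"].items():
            lig, rec = key.split("|")
            assert matrix.affinity.loc[lig, rec] == pytest.approx(val, abs=5e-4)

    def test_empty_axes_rejected(self, desk_spec):
        with pytest.raises(ValueError, match="nonempty"):
            gen_score_matrix(desk_spec, [], [])


class TestMeltGeneration:
    def test_default_grid_ten_temperatures(self):
        curves, _ = gen_melt_curves(2, seed=0)
        temps = curves.loc[
            (curves["protein_id"] == "PROT001") & (curves["condition"] == "vehicle"),
            "temperature_c",
        ]
        assert len(temps) == 10
        assert temps.min() == 37.0 and temps.max() == 67.0

    def test_zero_shift_gives_zero_expected_delta(self):
        curves, _ = gen_melt_curves(4, delta_tm=0.0, noise=0.0, seed=1)
        wide = curves.pivot_table(index=["protein_id", "temperature_c"],
                                  columns="condition", values="fold_change")
        np.testing.assert_allclose(wide["vehicle"], wide["treated"])

    def test_too_few_temperatures_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            gen_melt_curves(2, temps=(37.0, 50.0, 67.0), seed=0)


class TestAssayNoiseZeroLimits:
    def test_kinetics_rate_law_identity(self):
        km, vmax, ki, i = 25.0, 100.0, 8.5, 10.0
        s = km * (1 + i / ki)
        rates, _ = gen_kinetics(km, vmax, ki, "competitive", s_grid=(s,), i_grid=(i,),
                                noise=0.0, replicates=1, seed=0)
        assert rates["rate"].iloc[0] == pytest.approx(vmax / 2.0)

    def test_itc_no_binding_limit(self):
        df, _ = gen_itc(kd_um=1e9, noise=0.0, dilution_offset_ucal=0.5, seed=0)
        assert np.allclose(df["heat_ucal"].iloc[1:], 0.5, atol=1e-3)

    def test_itc_emits_twenty_injections(self):
        df, _ = gen_itc(seed=0)
        assert len(df) == 20
        assert df["volume_uL"].iloc[0] == 0.2

    def test_dose_response_matches_logistic_at_zero_noise(self):
        from lysoscreen.kinetics import four_parameter_logistic

        df, truth = gen_dose_response(noise=0.0, replicates=1, seed=0)
        expected = four_parameter_logistic(
            df["dose_uM"].to_numpy(), truth["ic50_um"], truth["hill"],
            truth["top"], truth["bottom"],
        )
        np.testing.assert_allclose(df["response"], expected)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            gen_kinetics(mode="mixed", seed=0)
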