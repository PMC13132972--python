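"""Receptor triage, cross-docking, and final-binding-score prioritization.

Runs the structure-based half of the screen at two scales: the desk-scale
fixture written by 01_simulate_fixtures.py (read back from disk, scored
and ranked), and the full study-scale funnel (1745 ligands, 1028-receptor
manifest -> 1006 analyzable -> 908 docking-ready) with the deterministic
mock backend.  Writes ranked candidates and triage ledgers under results/.
"""

import dataclasses
import json
from pathlib import Path

from lysoscreen import io as lio
from lysoscreen.prioritize import PrioritizationConfig, prioritize
from lysoscreen.synthetic import FixtureSpec, gen_receptor_manifest, gen_score_matrix
from lysoscreen.triage import triage

ROOT = Path(__file__).resolve().parents[1] / "results"
FIX = ROOT / "fixtures"


def desk_scale() -> None:
    truth = json.loads((FIX / "ground_truth.json").read_text())
    records = lio.read_receptor_manifest(FIX / "receptor_manifest.tsv", FIX / "pockets.csv")
    survivors, ledger = triage(records)
    matrix = lio.read_score_matrix(FIX / "score_matrix.tsv")
    config = PrioritizationConfig(
        antitarget_receptor_ids=tuple(truth["matrix"]["antitarget_receptor_ids"])
    )
    prio_records, selected = prioritize(matrix, config)
    lio.write_ranked_candidates(selected, ROOT / "ranked_candidates_desk.tsv")
    lio.write_json_report(dataclasses.asdict(ledger), ROOT / "triage_ledger_desk.json")

    hits = set(truth["matrix"]["planted_hit_ids"])
    binders = set(truth["matrix"]["planted_antitarget_binder_ids"])
    chosen = set(selected["ligand_id"])
    print(f"[desk] triage: {ledger.n_collected} -> {ledger.n_analyzable} analyzable "
          f"-> {ledger.n_docking_ready} docking-ready")
    print(f"[desk] matrix {matrix.shape[0]} x {matrix.shape[1]}; "
          f"selected {len(selected)}; planted hits in selection: "
          f"{len(hits & chosen)}/{len(hits)}; anti-target binders selected: "
          f"{len(binders & chosen)} (excluded: "
          f"{int(prio_records.loc[prio_records['ligand_id'].isin(binders), 'excluded'].sum())})")


def study_scale() -> None:
    spec = FixtureSpec(
        seed=0,
        planted_hit_ids=tuple(f"LIG{i:05d}" for i in range(1, 6)),
        planted_antitarget_binder_ids=("LIG00010", "LIG00011"),
    )
    manifest, _ = gen_receptor_manifest(spec)
    survivors, ledger = triage(manifest)
    matrix, truth = gen_score_matrix(spec, spec.ligand_ids(), manifest)
    config = PrioritizationConfig(
        antitarget_receptor_ids=tuple(truth["antitarget_receptor_ids"])
    )
    _, selected = prioritize(matrix, config)
    lio.write_ranked_candidates(selected, ROOT / "ranked_candidates_full.tsv")
    lio.write_json_report(dataclasses.asdict(ledger), ROOT / "triage_ledger_full.json")
    print(f"[full] funnel: {ledger.n_collected} collected -> {ledger.n_analyzable} "
          f"analyzable -> {ledger.n_docking_ready} docking-ready")
    print(f"[full] cross-docking matrix over the ready panel: "
          f"{matrix.shape[0]} x {len(survivors)}; selected top {len(selected)}")
    print(f"[full] rank 1: {selected['ligand_id'].iloc[0]} "
          f"(final binding score {selected['final_binding_score'].iloc[0]:.3f})")


def main() -> None:
    desk_scale()
    study_scale()


if __name__ == "__main__":
    main()
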