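"""Generate the desk-scale synthetic study inputs.

Writes a complete fixture bundle — descriptor library with planted
reference-similar ligands, receptor manifest with planted triage subsets,
two-condition melt curves with planted thermal shifts, an ITC isotherm,
inhibition rate tables and a dose–response table — plus ground-truth
sidecars, under results/fixtures/.
"""

import dataclasses
import sys
from pathlib import Path

from lysoscreen import io as lio
from lysoscreen import synthetic

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 11
OUT = Path(__file__).resolve().parents[1] / "results" / "fixtures"

SPEC = synthetic.FixtureSpec(
    seed=SEED,
    n_ligands=120,
    n_references=15,
    planted_hit_ids=tuple(f"LIG{i:05d}" for i in range(1, 7)),
    planted_antitarget_binder_ids=("LIG00008", "LIG00009"),
    n_receptors_total=80,
    n_missing_structure=5,
    n_pocketless=7,
    n_antitarget_receptors=4,
)
SHIFTED_PROTEINS = tuple(f"PROT{i:03d}" for i in (3, 10, 22, 31, 44))
PREDICTED_TARGETS = ["PROT003", "PROT049", "PROT050"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    library, references, lib_truth = synthetic.gen_library(SPEC)
    lio.write_profiles(library, OUT / "library_profiles.csv")
    lio.write_profiles(references, OUT / "reference_profiles.csv")
    records, rec_truth = synthetic.gen_receptor_manifest(SPEC)
    lio.write_receptor_manifest(records, OUT / "receptor_manifest.tsv", OUT / "pockets.csv")
    matrix, mat_truth = synthetic.gen_score_matrix(SPEC, SPEC.ligand_ids(), records)
    lio.write_score_matrix(matrix, OUT / "score_matrix.tsv")
    lio.write_json_report(
        {"spec": dataclasses.asdict(SPEC), "library": lib_truth,
         "receptors": rec_truth, "matrix": mat_truth},
        OUT / "ground_truth.json",
    )

    melt, melt_truth = synthetic.gen_melt_curves(50, SHIFTED_PROTEINS, seed=SEED)
    melt.to_csv(OUT / "melt_curves.csv", index=False, float_format="%.6f")
    (OUT / "predicted_targets.txt").write_text("\n".join(PREDICTED_TARGETS) + "\n")
    itc, itc_truth = synthetic.gen_itc(seed=SEED)
    itc.to_csv(OUT / "itc_heats.csv", index=False, float_format="%.6f")
    rates, kin_truth = synthetic.gen_kinetics(i_grid=(0.0, 10.0, 15.0), seed=SEED)
    rates.to_csv(OUT / "rate_table.csv", index=False, float_format="%.6f")
    doses, dose_truth = synthetic.gen_dose_response(seed=SEED)
    doses.to_csv(OUT / "dose_response.csv", index=False, float_format="%.6f")
    lio.write_json_report(
        {"melt": melt_truth, "itc": itc_truth, "kinetics": kin_truth, "dose": dose_truth},
        OUT / "assay_ground_truth.json",
    )
    print(f"seed {SEED}: wrote fixture bundle to {OUT}")
    print(f"  library: {SPEC.n_ligands} ligands, {SPEC.n_references} references, "
          f"{len(SPEC.planted_similar_ids)} planted similar")
    print(f"  receptors: {SPEC.n_receptors_total} total "
          f"({SPEC.n_missing_structure} missing structure, {SPEC.n_pocketless} pocketless, "
          f"{SPEC.n_antitarget_receptors} anti-target)")
    print(f"  matrix: {matrix.shape[0]} x {matrix.shape[1]}; melt: 50 proteins "
          f"({len(SHIFTED_PROTEINS)} shifted by {melt_truth['delta_tm']} °C)")


if __name__ == "__main__":
    main()
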