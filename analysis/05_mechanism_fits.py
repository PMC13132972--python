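"""Mechanism-of-action fits on the fixture assay tables.

One-site ITC fit (K_D, N, ΔH), inhibition-mode classification with the
Lineweaver–Burk common-intercept diagnostic, 4PL IC50, and the
Cheng–Prusoff consistency check between the dose–response potency and the
kinetic K_i.
"""

import dataclasses
import json
from pathlib import Path

from lysoscreen import io as lio
from lysoscreen.kinetics import cheng_prusoff, fit_ic50, fit_inhibition, fit_itc

ROOT = Path(__file__).resolve().parents[1] / "results"
FIX = ROOT / "fixtures"


def main() -> None:
    truth = json.loads((FIX / "assay_ground_truth.json").read_text())

    heats = lio.read_itc_table(FIX / "itc_heats.csv").sort_values("injection_index")
    itc = fit_itc(heats["heat_ucal"].to_numpy())
    print(f"ITC one-site fit: K_D = {itc.kd_um:.2f} μM (truth {truth['itc']['kd_um']}), "
          f"N = {itc.n_sites:.2f}, ΔH = {itc.dh_kcal_mol:.1f} kcal/mol, "
          f"offset = {itc.dilution_offset_ucal:.2f} μcal")

    rates = lio.read_rate_table(FIX / "rate_table.csv")
    inh = fit_inhibition(rates)
    ints = ", ".join(f"[I]={k:g}: {v:.4f}" for k, v in sorted(inh.lb_intercepts.items()))
    print(f"inhibition mode: {inh.mode} (truth {truth['kinetics']['mode']}); "
          f"Km = {inh.km_um:.1f} μM, Vmax = {inh.vmax:.1f}, Ki = {inh.ki_um:.1f} μM")
    print(f"  AICc: " + ", ".join(f"{m}: {s:.1f}" for m, s in inh.model_scores.items()))
    print(f"  Lineweaver–Burk 1/v-axis intercepts: {ints}")

    doses = lio.read_dose_table(FIX / "dose_response.csv")
    dr = fit_ic50(doses["dose_uM"].to_numpy(), doses["response"].to_numpy())
    ki_cp = cheng_prusoff(dr.ic50_um, s_um=inh.km_um, km_um=inh.km_um)
    print(f"IC50 = {dr.ic50_um:.2f} μM (truth {truth['dose']['ic50_um']}), "
          f"Hill = {dr.hill:.2f}")
    print(f"Cheng–Prusoff Ki at [S] = Km: {ki_cp:.2f} μM (kinetic Ki {inh.ki_um:.1f} μM)")

    lio.write_json_report(
        {
            "itc": dataclasses.asdict(itc),
            "inhibition": {
                "mode": inh.mode, "km_um": inh.km_um, "vmax": inh.vmax,
                "ki_um": inh.ki_um, "model_scores": dict(inh.model_scores),
                "lb_intercepts": {str(k): v for k, v in inh.lb_intercepts.items()},
            },
            "dose_response": dataclasses.asdict(dr),
            "cheng_prusoff_ki_um": ki_cp,
        },
        ROOT / "mechanism_fits.json",
    )


if __name__ == "__main__":
    main()
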