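"""Synthetic fixture generation with planted ground truth.

Every input the pipeline consumes can be generated here at desk scale with
seeded randomness: a descriptor-profile library with a planted fraction
similar to the reference agonists, a receptor manifest with planted
missing-structure / pocketless / anti-target subsets, a cross-docking
score matrix with planted multi-target hits and planted anti-target
binders, two-condition melt curves with planted thermal shifts, one-site
binding isotherms, competitive-inhibition rate tables and dose–response
tables.  Each generator returns its data together with a ground-truth
sidecar dict; sidecars are written as separate JSON files so analysis
stages stay blind to the plants.

Default counts mirror the study conditions: a 1745-ligand candidate set
against a 1028-receptor manifest (22 lacking structures, 98 pooled
pocketless-or-anti-target exclusions, 908 docking-ready).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .deconvolution import DEFAULT_TPP_TEMPS_C, melt_model, params_for_tm
from .docking import MockDockingBackend, ScoreMatrix, assemble_matrix
from .kinetics import (
    DEFAULT_DOSE_GRID,
    DEFAULT_S_GRID,
    INHIBITION_MODES,
    ITCProtocol,
    four_parameter_logistic,
    itc_isotherm,
    mm_rate,
)
from .similarity import DescriptorProfile
from .triage import Pocket, ReceptorRecord

PROFILE_DIM = 16
FP_BITS = 128
FP_ON_BITS = 32
#: paper-scale inhibitor grid for rate-table generation (two inhibitor doses)
DEFAULT_GEN_I_GRID = (10.0, 15.0)

# fixed per-stage offsets so each generator has an independent substream
_STAGE = {"library": 11, "receptors": 23, "matrix": 37, "melt": 53, "itc": 67,
          "kinetics": 79, "dose": 97}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STAGE[stage]])


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic screening fixture.

    Defaults reproduce the study-scale funnel counts; tests shrink them.
    """

    seed: int = 0
    n_ligands: int = 1745
    n_references: int = 15
    planted_hit_ids: tuple[str, ...] = ()
    planted_antitarget_binder_ids: tuple[str, ...] = ()
    n_receptors_total: int = 1028
    n_missing_structure: int = 22
    n_pocketless: int = 60
    n_antitarget_receptors: int = 38
    noise_levels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_references < 1:
            raise ValueError("need at least one reference ligand")
        if self.n_ligands < 1 or self.n_receptors_total < 1:
            raise ValueError("ligand and receptor counts must be positive")
        flagged = self.n_missing_structure + self.n_pocketless + self.n_antitarget_receptors
        if flagged > self.n_receptors_total:
            raise ValueError(
                f"flagged receptor subsets ({flagged}) exceed total ({self.n_receptors_total})"
            )
        hits = set(self.planted_hit_ids)
        binders = set(self.planted_antitarget_binder_ids)
        if len(hits) != len(self.planted_hit_ids) or len(binders) != len(
            self.planted_antitarget_binder_ids
        ):
            raise ValueError("duplicate ids in a planted set")
        if hits & binders:
            raise ValueError("planted hit and anti-target-binder sets must be disjoint")
        valid = set(self.ligand_ids())
        unknown = (hits | binders) - valid
        if unknown:
            raise ValueError(f"planted ids not in the ligand id set: {sorted(unknown)}")

    def ligand_ids(self) -> list[str]:
        return [f"LIG{i:05d}" for i in range(1, self.n_ligands + 1)]

    def reference_ids(self) -> list[str]:
        return [f"REF{i:02d}" for i in range(1, self.n_references + 1)]

    def receptor_ids(self) -> list[str]:
        return [f"RCPT{i:04d}" for i in range(1, self.n_receptors_total + 1)]

    @property
    def planted_similar_ids(self) -> tuple[str, ...]:
        """Ligands generated similar to a reference (hits and anti-target binders)."""
        return tuple(sorted(set(self.planted_hit_ids) | set(self.planted_antitarget_binder_ids)))


def _random_profile(lid: str, rng: np.random.Generator) -> DescriptorProfile:
    fp = np.zeros(FP_BITS, dtype=bool)
    fp[rng.choice(FP_BITS, size=FP_ON_BITS, replace=False)] = True
    return DescriptorProfile(
        lid, rng.standard_normal(PROFILE_DIM), fp, rng.standard_normal(PROFILE_DIM)
    )


def _perturbed_profile(
    lid: str, ref: DescriptorProfile, rng: np.random.Generator,
    n_bit_flips: int = 8, vec_noise: float = 0.15,
) -> DescriptorProfile:
    fp = ref.level2.copy()
    fp[rng.choice(FP_BITS, size=n_bit_flips, replace=False)] ^= True
    return DescriptorProfile(
        lid,
        ref.level1 + vec_noise * rng.standard_normal(PROFILE_DIM),
        fp,
        ref.level3 + vec_noise * rng.standard_normal(PROFILE_DIM),
    )


def gen_library(spec: FixtureSpec) -> tuple[list[DescriptorProfile], list[DescriptorProfile], dict]:
    """Generate the ligand library and reference profiles.

    Planted-similar ligands (the planted hits and planted anti-target
    binders) are perturbations of a reference profile, so their fused
    similarity exceeds the default screen threshold; all other ligands get
    independent random profiles whose expected similarity sits well below
    it.  Returns (library, references, truth).
    """
    rng = _rng(spec.seed, "library")
    references = [_random_profile(rid, rng) for rid in spec.reference_ids()]
    planted = set(spec.planted_similar_ids)
    library: list[DescriptorProfile] = []
    ref_cycle = 0
    for lid in spec.ligand_ids():
        if lid in planted:
            library.append(_perturbed_profile(lid, references[ref_cycle % len(references)], rng))
            ref_cycle += 1
        else:
            library.append(_random_profile(lid, rng))
    truth = {"planted_similar_ids": sorted(planted)}
    return library, references, truth


def gen_receptor_manifest(spec: FixtureSpec) -> tuple[list[ReceptorRecord], dict]:
    """Generate the receptor manifest with planted triage subsets.

    Missing-structure records carry no structure (and no pockets);
    pocketless records have a structure but no predicted pocket;
    anti-target records are fully dockable but flagged.  Remaining records
    carry 1–3 ranked pockets.  The planted subsets are disjoint and
    scattered across the manifest.
    """
    rng = _rng(spec.seed, "receptors")
    ids = spec.receptor_ids()
    order = rng.permutation(spec.n_receptors_total)
    missing = {ids[j] for j in order[: spec.n_missing_structure]}
    lo = spec.n_missing_structure
    pocketless = {ids[j] for j in order[lo : lo + spec.n_pocketless]}
    lo += spec.n_pocketless
    antitarget = {ids[j] for j in order[lo : lo + spec.n_antitarget_receptors]}

    records = []
    for rid in ids:
        uid = f"UP{rid[4:]}"
        if rid in missing:
            records.append(ReceptorRecord(rid, uid, has_structure=False, pockets=()))
            continue
        if rid in pocketless:
            records.append(ReceptorRecord(rid, uid, has_structure=True, pockets=()))
            continue
        n_pockets = int(rng.integers(1, 4))
        base_score = float(rng.uniform(5.0, 20.0))
        pockets = tuple(
            Pocket(
                center=tuple(np.round(rng.uniform(-30.0, 30.0, size=3), 2)),
                rank=r,
                predictor_score=round(base_score / r, 3),
            )
            for r in range(1, n_pockets + 1)
        )
        records.append(
            ReceptorRecord(rid, uid, has_structure=True, pockets=pockets,
                           antitarget_flag=rid in antitarget)
        )
    truth = {
        "missing_structure_ids": sorted(missing),
        "pocketless_ids": sorted(pocketless),
        "antitarget_receptor_ids": sorted(antitarget),
    }
    return records, truth


def gen_score_matrix(
    spec: FixtureSpec,
    ligand_ids: Sequence[str],
    receptors: Sequence[ReceptorRecord],
    n_strong: int = 25,
) -> tuple[ScoreMatrix, dict]:
    """Assemble the mock cross-docking matrix with planted structure.

    Columns are the docking-ready receptors plus any dockable anti-target
    receptors (docked only to feed the anti-target exclusion filter).
    Planted hits receive strongly favorable scores (≈ −10.5 kcal/mol) on
    ``n_strong`` docking-ready receptors and weak anti-target scores;
    planted anti-target binders receive the same strong profile plus
    anti-target scores beyond the 8.5 exclusion threshold.  Background
    cells follow the declared truncated-normal distribution.
    """
    ligand_ids = list(ligand_ids)
    if not ligand_ids or not receptors:
        raise ValueError("ligand and receptor lists must be nonempty")
    rng = _rng(spec.seed, "matrix")
    ready = [r.receptor_id for r in receptors if r.docking_ready]
    antitarget_cols = [
        r.receptor_id for r in receptors
        if r.antitarget_flag and r.has_structure and r.pockets
    ]
    columns = ready + antitarget_cols
    if not columns:
        raise ValueError("no dockable receptors")

    plants: dict[tuple[str, str], float] = {}
    n_strong_eff = min(n_strong, len(ready))
    for lid in sorted(set(spec.planted_hit_ids) | set(spec.planted_antitarget_binder_ids)):
        if lid not in ligand_ids:
            continue
        strong = rng.choice(len(ready), size=n_strong_eff, replace=False)
        for j in strong:
            plants[(lid, ready[j])] = -(10.0 + rng.uniform(0.0, 1.0))
        for rec in antitarget_cols:
            if lid in spec.planted_antitarget_binder_ids:
                plants[(lid, rec)] = -(9.0 + rng.uniform(0.0, 1.0))
            else:
                plants[(lid, rec)] = -(3.0 + rng.uniform(0.0, 1.0))

    backend = MockDockingBackend(seed=spec.seed, plants=plants)
    matrix = assemble_matrix(ligand_ids, columns, backend)
    truth = {
        "planted_hit_ids": sorted(set(spec.planted_hit_ids) & set(ligand_ids)),
        "planted_antitarget_binder_ids": sorted(
            set(spec.planted_antitarget_binder_ids) & set(ligand_ids)
        ),
        "antitarget_receptor_ids": antitarget_cols,
        "plants": {f"{l}|{r}": round(s, 3) for (l, r), s in sorted(plants.items())},
    }
    return matrix, truth


def gen_melt_curves(
    n_proteins: int,
    planted_shift_ids: Sequence[str] = (),
    delta_tm: float = 4.0,
    noise: float = 0.02,
    temps: Sequence[float] = DEFAULT_TPP_TEMPS_C,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Two-condition melt curves with planted thermal shifts.

    Vehicle curves come from the plateau sigmoid at a drawn Tm (46–56 °C);
    treated curves are identical except the planted proteins, whose Tm is
    shifted by ``delta_tm`` °C.  Multiplicative noise at relative SD
    ``noise`` is applied and curves re-anchored to 1 at the lowest
    temperature.  Fewer than 4 temperature points is unfittable and an
    error.
    """
    temps = np.asarray(list(temps), dtype=float)
    if temps.size < 4:
        raise ValueError("need >= 4 temperature points for fittable curves")
    if np.any(np.diff(temps) <= 0):
        raise ValueError("temperatures must be strictly increasing")
    rng = _rng(seed, "melt")
    ids = [f"PROT{i:03d}" for i in range(1, n_proteins + 1)]
    unknown = set(planted_shift_ids) - set(ids)
    if unknown:
        raise ValueError(f"planted shift ids not in protein set: {sorted(unknown)}")
    rows = []
    tm_true: dict[str, float] = {}
    for pid in ids:
        tm = float(rng.uniform(46.0, 56.0))
        a = float(rng.uniform(4.0e4, 6.5e4))
        p = float(rng.uniform(0.02, 0.12))
        tm_true[pid] = tm
        for cond in ("vehicle", "treated"):
            tm_c = tm + (delta_tm if pid in set(planted_shift_ids) and cond == "treated" else 0.0)
            b = params_for_tm(tm_c, a, p)
            fc = melt_model(temps, a, b, p)
            fc = fc * (1.0 + noise * rng.standard_normal(temps.size))
            fc = np.maximum(fc / fc[0], 1e-6)
            for t, y in zip(temps, fc):
                rows.append({"protein_id": pid, "condition": cond,
                             "temperature_c": float(t), "fold_change": float(y)})
    df = pd.DataFrame(rows)
    truth = {"tm_true": tm_true, "shifted_ids": sorted(set(planted_shift_ids)),
             "delta_tm": float(delta_tm)}
    return df, truth


def gen_itc(
    kd_um: float = 2.30,
    n_sites: float = 1.0,
    dh_kcal_mol: float = -10.0,
    protocol: ITCProtocol = ITCProtocol(),
    noise: float = 0.03,
    dilution_offset_ucal: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """One-site injection heat series under the default titration protocol.

    Additive gaussian noise whose per-injection SD is ``noise`` × that
    injection's binding-heat magnitude, plus a baseline floor of ``noise``
    × 10% of the largest binding heat (instrument noise does not vanish at
    saturation).  A constant dilution-heat offset (default 0.5 μcal) is
    included so fitters must handle baseline subtraction.
    """
    if kd_um <= 0 or n_sites <= 0:
        raise ValueError("kd and stoichiometry must be positive")
    rng = _rng(seed, "itc")
    clean = itc_isotherm(kd_um, n_sites, dh_kcal_mol, protocol, dilution_offset_ucal)
    binding = clean - dilution_offset_ucal
    scale = np.abs(binding) + 0.1 * float(np.max(np.abs(binding)))
    sigma = noise * scale if noise > 0 else np.zeros_like(clean)
    heats = clean + sigma * rng.standard_normal(clean.size)
    df = pd.DataFrame(
        {
            "injection_index": np.arange(1, protocol.n_injections + 1),
            "volume_uL": list(protocol.injection_volumes_ul),
            "heat_ucal": heats,
        }
    )
    truth = {"kd_um": kd_um, "n_sites": n_sites, "dh_kcal_mol": dh_kcal_mol,
             "dilution_offset_ucal": dilution_offset_ucal,
             "noise_sd_ucal": float(np.mean(sigma))}
    return df, truth


def gen_kinetics(
    km_um: float = 25.0,
    vmax: float = 100.0,
    ki_um: float = 8.5,
    mode: str = "competitive",
    s_grid: Sequence[float] = DEFAULT_S_GRID,
    i_grid: Sequence[float] = DEFAULT_GEN_I_GRID,
    noise: float = 0.03,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Rate table from the selected inhibition rate law with multiplicative noise."""
    if mode not in INHIBITION_MODES:
        raise ValueError(f"unknown inhibition mode {mode!r}")
    s_grid = list(s_grid)
    i_grid = list(i_grid)
    if not s_grid or not i_grid:
        raise ValueError("substrate and inhibitor grids must be nonempty")
    rng = _rng(seed, "kinetics")
    rows = []
    for i_conc in i_grid:
        for s_conc in s_grid:
            v = float(mm_rate(s_conc, i_conc, km_um, vmax, ki_um, mode))
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "S_uM": float(s_conc),
                        "I_uM": float(i_conc),
                        "replicate": rep,
                        "rate": v * (1.0 + noise * float(rng.standard_normal())),
                    }
                )
    df = pd.DataFrame(rows)
    truth = {"km_um": km_um, "vmax": vmax, "ki_um": ki_um, "mode": mode}
    return df, truth


def gen_dose_response(
    ic50_um: float = 16.97,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    conc_grid: Sequence[float] = DEFAULT_DOSE_GRID,
    noise: float = 0.05,
    replicates: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Activity table from a four-parameter logistic with multiplicative noise."""
    conc_grid = list(conc_grid)
    if not conc_grid:
        raise ValueError("dose grid must be nonempty")
    rng = _rng(seed, "dose")
    rows = []
    for dose in conc_grid:
        resp = float(four_parameter_logistic(np.asarray([dose]), ic50_um, hill, top, bottom)[0])
        for rep in range(1, replicates + 1):
            rows.append(
                {
                    "dose_uM": float(dose),
                    "replicate": rep,
                    "response": resp * (1.0 + noise * float(rng.standard_normal())),
                }
            )
    df = pd.DataFrame(rows)
    truth = {"ic50_um": ic50_um, "hill": hill, "top": top, "bottom": bottom}
    return df, truth
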