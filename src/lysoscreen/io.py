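"""Readers and writers for the pipeline's tabular dialects.

All formats are plain text (TSV/CSV/JSON) at declared decimal precision so
artifacts diff cleanly and round-trip losslessly: score matrices at 3
decimals, descriptor vectors at 6.  Malformed inputs raise
:class:`DataError` with the path and, where meaningful, the line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .docking import SCORE_DECIMALS, ScoreMatrix
from .similarity import DescriptorProfile
from .triage import Pocket, ReceptorRecord


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def _require_nonempty(path: Path) -> None:
    if not path.exists():
        raise DataError(f"{path}: input file does not exist")
    if path.stat().st_size == 0:
        raise DataError(f"{path}: input file is empty")


# --------------------------------------------------------------------------
# ligands
# --------------------------------------------------------------------------

def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a one-record-per-line ligand file: ``SMILES<ws>ligand_id``."""
    path = Path(path)
    _require_nonempty(path)
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise DataError(f"{path}:{lineno}: expected 'SMILES ligand_id'")
        smiles, lid = parts[0], parts[1]
        if lid in seen:
            raise DataError(f"{path}:{lineno}: duplicate ligand id {lid!r}")
        seen.add(lid)
        out.append((lid, smiles))
    if not out:
        raise DataError(f"{path}: no ligand records found")
    return out


def read_sdf_file(path: str | Path) -> list[tuple[str, str]]:
    """Read ligands from an SDF file; returns (id, SMILES) pairs."""
    from rdkit import Chem

    path = Path(path)
    _require_nonempty(path)
    out = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            raise DataError(f"{path}: unparseable record at index {i}")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"SDF{i:05d}"
        out.append((name or f"SDF{i:05d}", Chem.MolToSmiles(mol)))
    if not out:
        raise DataError(f"{path}: no ligand records found")
    return out


def write_profiles(profiles: Sequence[DescriptorProfile], path: str | Path) -> None:
    """Cache descriptor profiles as CSV (fingerprint hex-packed)."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "ligand_id": p.ligand_id,
                "fp_bits": p.level2.size,
                "fp_hex": np.packbits(p.level2).tobytes().hex(),
                "level1": ";".join(f"{x:.6f}" for x in p.level1),
                "level3": ";".join(f"{x:.6f}" for x in p.level3),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profiles(path: str | Path) -> list[DescriptorProfile]:
    path = Path(path)
    _require_nonempty(path)
    df = pd.read_csv(path, dtype={"ligand_id": str})
    required = {"ligand_id", "fp_bits", "fp_hex", "level1", "level3"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: profile CSV must have columns {sorted(required)}")
    dup = df["ligand_id"].duplicated()
    if dup.any():
        lineno = int(dup.idxmax()) + 2  # header + 1-based
        raise DataError(f"{path}:{lineno}: duplicate ligand id {df['ligand_id'][dup].iloc[0]!r}")
    out = []
    for _, row in df.iterrows():
        nbits = int(row["fp_bits"])
        fp = np.unpackbits(np.frombuffer(bytes.fromhex(row["fp_hex"]), dtype=np.uint8))[:nbits]
        out.append(
            DescriptorProfile(
                str(row["ligand_id"]),
                np.array([float(x) for x in str(row["level1"]).split(";")]),
                fp.astype(bool),
                np.array([float(x) for x in str(row["level3"]).split(";")]),
            )
        )
    return out


# --------------------------------------------------------------------------
# receptors
# --------------------------------------------------------------------------

def write_receptor_manifest(
    records: Sequence[ReceptorRecord], manifest_path: str | Path, pockets_path: str | Path
) -> None:
    """Write the manifest TSV and companion pocket CSV."""
    man_rows, pocket_rows = [], []
    for r in records:
        man_rows.append(
            {
                "receptor_id": r.receptor_id,
                "uniprot_id": r.uniprot_id,
                "structure_path": f"structures/{r.receptor_id}.pdb" if r.has_structure else "",
                "antitarget": int(r.antitarget_flag),
            }
        )
        for p in r.pockets:
            pocket_rows.append(
                {
                    "name": r.receptor_id,
                    "rank": p.rank,
                    "score": p.predictor_score,
                    "center_x": p.center[0],
                    "center_y": p.center[1],
                    "center_z": p.center[2],
                }
            )
    pd.DataFrame(man_rows).to_csv(manifest_path, sep="\t", index=False)
    pd.DataFrame(
        pocket_rows, columns=["name", "rank", "score", "center_x", "center_y", "center_z"]
    ).to_csv(pockets_path, index=False)


def read_receptor_manifest(
    manifest_path: str | Path,
    pockets_path: str | Path | None = None,
    blocklist_path: str | Path | None = None,
) -> list[ReceptorRecord]:
    """Read the manifest TSV (+ optional pockets CSV and anti-target blocklist).

    The blocklist holds one UniProt id per line; matching records get the
    anti-target flag in addition to any flag in the manifest itself.
    """
    manifest_path = Path(manifest_path)
    _require_nonempty(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t", dtype=str).fillna("")
    required = {"receptor_id", "uniprot_id", "structure_path", "antitarget"}
    if not required.issubset(df.columns):
        raise DataError(f"{manifest_path}: manifest must have columns {sorted(required)}")
    dup = df["receptor_id"].duplicated()
    if dup.any():
        lineno = int(dup.idxmax()) + 2
        raise DataError(
            f"{manifest_path}:{lineno}: duplicate receptor id {df['receptor_id'][dup].iloc[0]!r}"
        )
    pockets_by_rec: dict[str, list[Pocket]] = {}
    if pockets_path is not None:
        ppath = Path(pockets_path)
        _require_nonempty(ppath)
        pdf = pd.read_csv(ppath, dtype={"name": str})
        preq = {"name", "rank", "score", "center_x", "center_y", "center_z"}
        if not preq.issubset(pdf.columns):
            raise DataError(f"{ppath}: pocket CSV must have columns {sorted(preq)}")
        for _, row in pdf.iterrows():
            pockets_by_rec.setdefault(str(row["name"]), []).append(
                Pocket(
                    center=(float(row["center_x"]), float(row["center_y"]), float(row["center_z"])),
                    rank=int(row["rank"]),
                    predictor_score=float(row["score"]),
                )
            )
    blocked: set[str] = set()
    if blocklist_path is not None:
        bpath = Path(blocklist_path)
        _require_nonempty(bpath)
        blocked = {
            ln.strip() for ln in bpath.read_text().splitlines() if ln.strip()
        }
    records = []
    for _, row in df.iterrows():
        rid = str(row["receptor_id"])
        records.append(
            ReceptorRecord(
                receptor_id=rid,
                uniprot_id=str(row["uniprot_id"]),
                has_structure=bool(str(row["structure_path"]).strip()),
                pockets=tuple(pockets_by_rec.get(rid, ())),
                antitarget_flag=str(row["antitarget"]).strip() in {"1", "true", "True"}
                or str(row["uniprot_id"]) in blocked,
            )
        )
    return records


# --------------------------------------------------------------------------
# score matrix
# --------------------------------------------------------------------------

def write_score_matrix(matrix: ScoreMatrix, path: str | Path) -> None:
    """Matrix TSV (3-decimal scores) with a provenance JSON sidecar."""
    path = Path(path)
    df = matrix.affinity.copy()
    df.index.name = "ligand_id"
    df.to_csv(path, sep="\t", float_format=f"%.{SCORE_DECIMALS}f")
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    sidecar.write_text(json.dumps(matrix.provenance, indent=2, sort_keys=True) + "\n")


def read_score_matrix(path: str | Path) -> ScoreMatrix:
    path = Path(path)
    _require_nonempty(path)
    df = pd.read_csv(path, sep="\t", index_col="ligand_id")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        lineno = int(np.nonzero(df.index.duplicated())[0][0]) + 2
        raise DataError(f"{path}:{lineno}: duplicate ligand id {dup!r}")
    df.index = df.index.astype(str)
    provenance = {}
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text())
    return ScoreMatrix(df.astype(float), provenance)


# --------------------------------------------------------------------------
# assay tables and reports
# --------------------------------------------------------------------------

def _read_csv_checked(path: str | Path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    _require_nonempty(path)
    df = pd.read_csv(path)
    if not required.issubset(df.columns):
        raise DataError(f"{path}: expected columns {sorted(required)}, found {list(df.columns)}")
    return df


def read_melt_table(path: str | Path) -> pd.DataFrame:
    """Long-form fold-change CSV: protein_id, condition, temperature_c, fold_change."""
    df = _read_csv_checked(path, {"protein_id", "condition", "temperature_c", "fold_change"})
    df["protein_id"] = df["protein_id"].astype(str)
    return df


def read_itc_table(path: str | Path) -> pd.DataFrame:
    return _read_csv_checked(path, {"injection_index", "volume_uL", "heat_ucal"})


def read_rate_table(path: str | Path) -> pd.DataFrame:
    return _read_csv_checked(path, {"S_uM", "I_uM", "rate"})


def read_dose_table(path: str | Path) -> pd.DataFrame:
    return _read_csv_checked(path, {"dose_uM", "response"})


def read_id_list(path: str | Path) -> list[str]:
    """One id per line (e.g. the predicted-target list)."""
    path = Path(path)
    _require_nonempty(path)
    ids = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not ids:
        raise DataError(f"{path}: no ids found")
    return ids


def write_ranked_candidates(selected: pd.DataFrame, path: str | Path) -> None:
    cols = ["rank", "ligand_id", "final_binding_score", "antitarget_affinity",
            "excluded", "reason"]
    out = selected[[c for c in cols if c in selected.columns]].copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_json_report(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
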