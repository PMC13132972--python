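"""Cross-docking score matrix assembly behind a pluggable backend.

Scores follow the docking-engine convention: kcal/mol, negative =
favorable.  The deterministic mock backend maps a keyed hash of
(ligand_id, receptor_id, seed) onto a declared background distribution
(normal, mean −6.0, SD 1.0, truncated above at 0) so matrix cells are
reproducible and independent of assembly order; fixture sidecars can plant
specific pair scores on top.  A thin adapter contract is provided for an
external engine; the engine itself is out of scope.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .triage import DockingBox, ReceptorRecord

SCORE_DECIMALS = 3  # declared text round-trip precision, kcal/mol
BACKGROUND_MEAN = -6.0
BACKGROUND_SD = 1.0


class DockingBackend(Protocol):
    name: str

    def score(self, ligand_id: str, receptor_id: str) -> float: ...

    def config_hash(self) -> str: ...


def _hash_uniform(ligand_id: str, receptor_id: str, seed: int) -> float:
    key = f"{ligand_id}\x1f{receptor_id}\x1f{seed}".encode()
    h = hashlib.blake2b(key, digest_size=8).digest()
    u = int.from_bytes(h, "big") / 2.0**64
    return min(max(u, 1e-12), 1.0 - 1e-12)


class MockDockingBackend:
    """Deterministic stand-in docking engine.

    Each (ligand, receptor) pair hashes to a uniform deviate that is mapped
    through the inverse CDF of the truncated-normal background; planted
    pair scores from a fixture sidecar override the background.  Never
    fails; quantizes to 0.001 kcal/mol.
    """

    name = "mock"

    def __init__(
        self,
        seed: int = 0,
        mean: float = BACKGROUND_MEAN,
        sd: float = BACKGROUND_SD,
        plants: Mapping[tuple[str, str], float] | None = None,
    ):
        self.seed = int(seed)
        self.mean = float(mean)
        self.sd = float(sd)
        self.plants = dict(plants or {})
        self._b = (0.0 - self.mean) / self.sd  # upper truncation at 0 in z units

    def score(self, ligand_id: str, receptor_id: str) -> float:
        planted = self.plants.get((ligand_id, receptor_id))
        if planted is not None:
            return round(float(planted), SCORE_DECIMALS)
        u = _hash_uniform(ligand_id, receptor_id, self.seed)
        x = stats.truncnorm.ppf(u, -np.inf, self._b, loc=self.mean, scale=self.sd)
        return round(float(x), SCORE_DECIMALS)

    def score_block(self, ligand_ids: Sequence[str], receptor_ids: Sequence[str]) -> np.ndarray:
        """Vectorized scoring of the full cross product (same values as score())."""
        u = np.fromiter(
            (
                _hash_uniform(lig, rec, self.seed)
                for lig in ligand_ids
                for rec in receptor_ids
            ),
            dtype=float,
            count=len(ligand_ids) * len(receptor_ids),
        ).reshape(len(ligand_ids), len(receptor_ids))
        x = stats.truncnorm.ppf(u, -np.inf, self._b, loc=self.mean, scale=self.sd)
        x = np.round(x, SCORE_DECIMALS)
        for (lig, rec), s in self.plants.items():
            try:
                i = ligand_ids.index(lig)  # type: ignore[union-attr]
                j = receptor_ids.index(rec)  # type: ignore[union-attr]
            except (ValueError, AttributeError):
                continue
            x[i, j] = round(float(s), SCORE_DECIMALS)
        return x

    def config_hash(self) -> str:
        cfg = {"seed": self.seed, "mean": self.mean, "sd": self.sd,
               "n_plants": len(self.plants)}
        return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


class ExternalEngineAdapter:
    """Adapter contract for a real docking engine.

    ``runner(structure_path, box, ligand_id) -> best-pose affinity`` is
    supplied by the caller; engine configuration is passed through
    verbatim.  Failures surface the offending ligand/receptor ids.
    """

    def __init__(
        self,
        runner: Callable[[str, DockingBox, str], float],
        structure_paths: Mapping[str, str],
        boxes: Mapping[str, DockingBox],
        name: str = "external",
        config: Mapping | None = None,
    ):
        self.runner = runner
        self.structure_paths = dict(structure_paths)
        self.boxes = dict(boxes)
        self.name = name
        self.config = dict(config or {})

    def score(self, ligand_id: str, receptor_id: str) -> float:
        path = self.structure_paths.get(receptor_id)
        if not path:
            raise ValueError(f"receptor {receptor_id!r}: no structure path for docking")
        box = self.boxes.get(receptor_id)
        if box is None:
            raise ValueError(f"receptor {receptor_id!r}: no docking box defined")
        try:
            return float(self.runner(path, box, ligand_id))
        except Exception as exc:  # surface ids on engine failure
            raise RuntimeError(
                f"docking backend failed for ligand {ligand_id!r} on receptor {receptor_id!r}: {exc}"
            ) from exc

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ScoreMatrix:
    """Ligand × receptor affinity table (kcal/mol, negative = favorable)."""

    affinity: pd.DataFrame  # index: ligand ids, columns: receptor ids
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx, cols = self.affinity.index, self.affinity.columns
        if idx.has_duplicates or cols.has_duplicates:
            raise ValueError("score matrix has duplicate ligand or receptor ids")
        if self.affinity.isna().any().any():
            raise ValueError("score matrix has missing cells (strict completeness)")

    @property
    def ligand_ids(self) -> list[str]:
        return list(self.affinity.index)

    @property
    def receptor_ids(self) -> list[str]:
        return list(self.affinity.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.affinity.shape

    def row(self, ligand_id: str) -> pd.Series:
        return self.affinity.loc[ligand_id]


def dock(
    ligand_id: str,
    receptor: ReceptorRecord,
    box: DockingBox,
    backend: DockingBackend,
) -> float:
    """Dock one ligand into one receptor's box; return the best-pose affinity."""
    if not receptor.has_structure:
        raise ValueError(f"receptor {receptor.receptor_id!r} has no structure; not docking-ready")
    if box is None:
        raise ValueError(f"receptor {receptor.receptor_id!r}: docking box required")
    return backend.score(ligand_id, receptor.receptor_id)


def assemble_matrix(
    ligand_ids: Sequence[str],
    receptor_ids: Sequence[str],
    backend: DockingBackend,
) -> ScoreMatrix:
    """Fill the complete cross-docking matrix, row/column order = input order.

    Cells are independent of assembly order (the mock hashes each pair
    independently), so a parallel assembly must produce the same matrix.
    """
    ligand_ids = list(ligand_ids)
    receptor_ids = list(receptor_ids)
    if not ligand_ids or not receptor_ids:
        raise ValueError("ligand and receptor id lists must be nonempty")
    if len(set(ligand_ids)) != len(ligand_ids):
        raise ValueError("duplicate ligand ids")
    if len(set(receptor_ids)) != len(receptor_ids):
        raise ValueError("duplicate receptor ids")
    if hasattr(backend, "score_block"):
        values = backend.score_block(ligand_ids, receptor_ids)
    else:
        values = np.array(
            [[backend.score(lig, rec) for rec in receptor_ids] for lig in ligand_ids]
        )
    df = pd.DataFrame(values, index=ligand_ids, columns=receptor_ids)
    provenance = {"backend": backend.name, "config_hash": backend.config_hash()}
    return ScoreMatrix(df, provenance)
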