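"""Multi-level ligand similarity screen.

Each ligand is summarised by a three-level descriptor profile — scalar
physicochemical properties (level 1), a binary substructure fingerprint
(level 2), and a 3D-shape proxy vector (level 3) — and compared to a panel
of reference agonists.  Level 2 similarity is the Tanimoto coefficient;
levels 1 and 3 use cosine similarity rescaled to [0, 1] via (1 + cos)/2.
The fused score is a weighted mean of the three levels (equal weights by
default) and a library ligand is retained when its best fused similarity
over the references is strictly greater than the threshold (default 0.65).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_SIMILARITY_THRESHOLD = 0.65
DEFAULT_FUSION_WEIGHTS = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)

#: scalar physicochemical descriptors used for level 1 and their rough
#: dynamic ranges, used as fixed scaling constants so cosine similarity is
#: not dominated by molecular weight.
_LEVEL1_DESCRIPTORS = (
    ("MolWt", 500.0),
    ("MolLogP", 5.0),
    ("TPSA", 140.0),
    ("NumHDonors", 5.0),
    ("NumHAcceptors", 10.0),
    ("NumRotatableBonds", 10.0),
    ("RingCount", 6.0),
    ("FractionCSP3", 1.0),
)

#: 2D topological shape/complexity descriptors standing in for conformer-
#: derived 3D features when no conformer is available.
_LEVEL3_DESCRIPTORS = (
    ("Kappa1", 30.0),
    ("Kappa2", 15.0),
    ("Kappa3", 10.0),
    ("Chi0v", 25.0),
    ("Chi1v", 15.0),
    ("LabuteASA", 250.0),
    ("BalabanJ", 3.0),
    ("BertzCT", 1500.0),
)

FINGERPRINT_BITS = 1024


@dataclass(frozen=True)
class DescriptorProfile:
    """Three-level descriptor profile of one ligand."""

    ligand_id: str
    level1: np.ndarray
    level2: np.ndarray  # boolean fingerprint
    level3: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "level1", np.asarray(self.level1, dtype=float))
        object.__setattr__(self, "level2", np.asarray(self.level2, dtype=bool))
        object.__setattr__(self, "level3", np.asarray(self.level3, dtype=float))
        if self.level2.size == 0:
            raise ValueError(f"ligand {self.ligand_id!r}: empty fingerprint")
        if not np.all(np.isfinite(self.level1)) or not np.all(np.isfinite(self.level3)):
            raise ValueError(f"ligand {self.ligand_id!r}: non-finite descriptor values")


@dataclass(frozen=True)
class SimilarityResult:
    """Per-level and fused similarity of one ligand against one reference."""

    ligand_id: str
    best_reference_id: str
    level1: float
    level2: float
    level3: float
    fused: float

    @property
    def per_level(self) -> tuple[float, float, float]:
        return (self.level1, self.level2, self.level3)


def compute_descriptor_profile(ligand_id: str, smiles: str) -> DescriptorProfile:
    """Compute a :class:`DescriptorProfile` from a SMILES string.

    Deterministic: the same input always yields the same profile.  Raises
    ``ValueError`` naming the record when the SMILES cannot be parsed.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors, rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"ligand {ligand_id!r}: unparseable SMILES {smiles!r}")
    level1 = np.array(
        [getattr(Descriptors, name)(mol) / scale for name, scale in _LEVEL1_DESCRIPTORS]
    )
    level3 = np.array(
        [getattr(Descriptors, name)(mol) / scale for name, scale in _LEVEL3_DESCRIPTORS]
    )
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=FINGERPRINT_BITS)
    fp = gen.GetFingerprint(mol)
    level2 = np.zeros(FINGERPRINT_BITS, dtype=bool)
    level2[list(fp.GetOnBits())] = True
    return DescriptorProfile(ligand_id, level1, level2, level3)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient of two boolean fingerprints."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0  # two empty bit sets are indistinguishable
    return float(np.count_nonzero(a & b) / union)


def cosine01(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity rescaled to [0, 1]; zero-norm vectors map to 0.5."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"descriptor dimension mismatch: {a.size} vs {b.size}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        cos = 0.0
    else:
        cos = float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))
    return 0.5 * (1.0 + cos)


def pairwise_similarity(
    a: DescriptorProfile,
    b: DescriptorProfile,
    weights: Sequence[float] = DEFAULT_FUSION_WEIGHTS,
) -> SimilarityResult:
    """Per-level and fused similarity of profile ``a`` against ``b``.

    Symmetric in (a, b) by construction of all three level metrics.
    """
    w = np.asarray(weights, dtype=float)
    if w.size != 3 or np.any(w < 0) or w.sum() == 0:
        raise ValueError("fusion weights must be three non-negative values, not all zero")
    w = w / w.sum()
    s1 = cosine01(a.level1, b.level1)
    s2 = tanimoto(a.level2, b.level2)
    s3 = cosine01(a.level3, b.level3)
    fused = float(w[0] * s1 + w[1] * s2 + w[2] * s3)
    return SimilarityResult(a.ligand_id, b.ligand_id, s1, s2, s3, fused)


def screen_library(
    library: Iterable[DescriptorProfile],
    references: Sequence[DescriptorProfile],
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    weights: Sequence[float] = DEFAULT_FUSION_WEIGHTS,
) -> tuple[list[str], pd.DataFrame]:
    """Screen a ligand library against reference agonist profiles.

    A ligand is retained iff its maximum fused similarity over the
    references is strictly greater than ``threshold``.  Ties for the best
    reference are broken by lexicographic reference id.

    Returns ``(retained_ids, report)`` where the report has one row per
    library ligand: ligand_id, best_reference, level1..level3, fused,
    retained.
    """
    references = list(references)
    if not references:
        raise ValueError("reference set is empty")
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    rows = []
    retained: list[str] = []
    for prof in library:
        best: SimilarityResult | None = None
        for ref in sorted(references, key=lambda r: r.ligand_id):
            res = pairwise_similarity(prof, ref, weights)
            if best is None or res.fused > best.fused:
                best = res
        assert best is not None
        # strict inequality at the cut; the degenerate threshold 1.0 keeps
        # exact-profile duplicates (fused can never exceed 1, up to rounding)
        keep = best.fused > threshold or (threshold == 1.0 and best.fused >= 1.0 - 1e-9)
        if keep:
            retained.append(prof.ligand_id)
        rows.append(
            {
                "ligand_id": prof.ligand_id,
                "best_reference": best.best_reference_id,
                "level1": best.level1,
                "level2": best.level2,
                "level3": best.level3,
                "fused": best.fused,
                "retained": keep,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=["ligand_id", "best_reference", "level1", "level2", "level3", "fused", "retained"],
    )
    logger.info("similarity screen: retained %d of %d ligands at threshold %.2f",
                len(retained), len(report), threshold)
    return retained, report
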