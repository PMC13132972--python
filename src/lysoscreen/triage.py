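"""Receptor triage: from a raw structure manifest to a docking-ready panel.

The funnel mirrors a reverse virtual-screening preparation: records lacking
a structural model are dropped first, then records without any predicted
binding pocket and records flagged as members of the excluded anti-target
signaling pathway (pooled into one exclusion count).  Survivors carry their
ranked pocket lists; the top-ranked pocket centers a cubic docking box
(default edge 25 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence


@dataclass(frozen=True)
class Pocket:
    """One predicted binding pocket: center in Å, predictor rank and score."""

    center: tuple[float, float, float]
    rank: int
    predictor_score: float = 0.0

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError(f"pocket rank must be positive, got {self.rank}")


@dataclass(frozen=True)
class DockingBox:
    """Axis-aligned cubic search box for docking, in Å."""

    center: tuple[float, float, float]
    edges: tuple[float, float, float] = (25.0, 25.0, 25.0)

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.edges):
            raise ValueError(f"box edges must be positive, got {self.edges}")


@dataclass(frozen=True)
class ReceptorRecord:
    receptor_id: str
    uniprot_id: str = ""
    has_structure: bool = True
    pockets: tuple[Pocket, ...] = ()
    antitarget_flag: bool = False

    def __post_init__(self) -> None:
        pockets = tuple(sorted(self.pockets, key=lambda p: p.rank))
        ranks = [p.rank for p in pockets]
        if len(set(ranks)) != len(ranks):
            raise ValueError(f"receptor {self.receptor_id!r}: duplicate pocket ranks")
        object.__setattr__(self, "pockets", pockets)

    @property
    def docking_ready(self) -> bool:
        return self.has_structure and bool(self.pockets) and not self.antitarget_flag


@dataclass(frozen=True)
class TriageLedger:
    """Count trail of the triage funnel; identities are enforced."""

    n_collected: int
    n_missing_structure: int
    n_analyzable: int
    n_excluded_pocketless_or_antitarget: int
    n_docking_ready: int
    n_pocketless: int = 0
    n_antitarget: int = 0

    def __post_init__(self) -> None:
        if self.n_analyzable != self.n_collected - self.n_missing_structure:
            raise ValueError("ledger identity violated: analyzable != collected - missing")
        if self.n_docking_ready != self.n_analyzable - self.n_excluded_pocketless_or_antitarget:
            raise ValueError("ledger identity violated: ready != analyzable - excluded")


def triage(manifest: Sequence[ReceptorRecord]) -> tuple[list[ReceptorRecord], TriageLedger]:
    """Drop missing-structure, then pocketless-or-anti-target records.

    Returns the docking-ready survivor list (manifest order preserved) and
    the :class:`TriageLedger`.  Pocketless and anti-target exclusions are
    pooled in the ledger but also reported separately.  A record that is
    both pocketless and anti-target is counted once in the pooled figure
    (and once in each verbose figure).
    """
    manifest = list(manifest)
    if not manifest:
        raise ValueError("receptor manifest is empty")
    ids = [r.receptor_id for r in manifest]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate receptor ids in manifest: {dupes}")

    with_structure = [r for r in manifest if r.has_structure]
    n_missing = len(manifest) - len(with_structure)
    survivors = [r for r in with_structure if r.pockets and not r.antitarget_flag]
    n_pocketless = sum(1 for r in with_structure if not r.pockets)
    n_antitarget = sum(1 for r in with_structure if r.antitarget_flag)
    n_excluded = len(with_structure) - len(survivors)
    ledger = TriageLedger(
        n_collected=len(manifest),
        n_missing_structure=n_missing,
        n_analyzable=len(with_structure),
        n_excluded_pocketless_or_antitarget=n_excluded,
        n_docking_ready=len(survivors),
        n_pocketless=n_pocketless,
        n_antitarget=n_antitarget,
    )
    return survivors, ledger


def select_pocket(record: ReceptorRecord) -> Pocket:
    """Return the top-ranked pocket of a record.

    Ties on predictor score are broken by lower rank index (the record's
    pockets are stored rank-sorted, so the first pocket is the selection).
    """
    if not record.pockets:
        raise ValueError(f"receptor {record.receptor_id!r} has no predicted pockets")
    return record.pockets[0]


def make_box(pocket: Pocket, edge: float = 25.0) -> DockingBox:
    """Build the cubic docking box centered on a pocket (default 25 Å edge)."""
    if edge <= 0:
        raise ValueError(f"box edge must be positive, got {edge}")
    return DockingBox(center=pocket.center, edges=(edge, edge, edge))
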