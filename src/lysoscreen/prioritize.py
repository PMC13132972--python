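"""Final-binding-score prioritization with anti-target exclusion.

For each ligand row of the cross-docking matrix the *final binding score*
is the mean of its top-k affinity magnitudes (A = −score, so larger =
stronger; k = 20 by default) across the receptor panel.  Ligands whose
affinity magnitude for any configured anti-target receptor reaches the
exclusion threshold (default 8.5) are removed so the selected candidates
do not engage the avoided pathway, then survivors are ranked by final
binding score and the top n (default 20) are selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .docking import ScoreMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrioritizationConfig:
    """Workflow constants of the prioritization stage.

    ``literal_antitarget_rule`` flips the exclusion to the literal reading
    (exclude magnitude < threshold); the default removes strong anti-target
    binders.  ``antitarget_in_topk`` controls whether anti-target columns
    also contribute to the top-k mean (default: they do not).
    """

    k: int = 20
    antitarget_threshold: float = 8.5
    n_select: int = 20
    antitarget_receptor_ids: tuple[str, ...] = ()
    literal_antitarget_rule: bool = False
    antitarget_in_topk: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.antitarget_threshold <= 0:
            raise ValueError("antitarget_threshold must be positive")
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")


def final_binding_score(row: pd.Series, k: int = 20) -> tuple[float, list[str]]:
    """Mean of the k largest affinity magnitudes of one ligand row.

    Scores are converted to magnitudes A = −score.  Returns the score and
    the contributing receptor ids in descending magnitude (ties broken by
    receptor id ascending).  Rows shorter than k average all available
    values with a logged warning.
    """
    if len(row) == 0:
        raise ValueError("empty affinity row")
    mags = -row.astype(float)
    order = sorted(zip(mags.index, mags.values), key=lambda t: (-t[1], t[0]))
    if len(order) < k:
        logger.warning("row has %d receptors < k=%d; averaging all", len(order), k)
    top = order[: min(k, len(order))]
    score = float(np.mean([v for _, v in top]))
    return score, [rid for rid, _ in top]


def anti_target_filter(matrix: ScoreMatrix, config: PrioritizationConfig) -> pd.DataFrame:
    """Per-ligand anti-target exclusion decisions.

    Default rule: a ligand is excluded iff its maximum affinity magnitude
    over the anti-target columns is >= the threshold (strong anti-target
    binders are removed).  The literal rule excludes magnitudes below the
    threshold instead.  Returns a frame indexed by ligand id with columns
    antitarget_affinity, antitarget_receptor, excluded, reason.
    """
    at_ids = list(config.antitarget_receptor_ids)
    missing = [r for r in at_ids if r not in matrix.affinity.columns]
    if missing:
        raise ValueError(f"anti-target receptor ids not in matrix columns: {missing}")
    n = len(matrix.ligand_ids)
    if not at_ids:
        return pd.DataFrame(
            {
                "antitarget_affinity": np.zeros(n),
                "antitarget_receptor": [""] * n,
                "excluded": [False] * n,
                "reason": [""] * n,
            },
            index=matrix.ligand_ids,
        )
    sub = -matrix.affinity[at_ids].astype(float)  # magnitudes
    # offending receptor = largest magnitude, ties by receptor id ascending
    ordered = sub[sorted(at_ids)]
    best_rec = ordered.idxmax(axis=1)
    best_mag = ordered.max(axis=1)
    if config.literal_antitarget_rule:
        excluded = best_mag < config.antitarget_threshold
        reason_tpl = "anti-target affinity {mag:.3f} < {thr}"
    else:
        excluded = best_mag >= config.antitarget_threshold
        reason_tpl = "anti-target affinity {mag:.3f} >= {thr} on {rec}"
    reasons = [
        reason_tpl.format(mag=m, thr=config.antitarget_threshold, rec=r) if e else ""
        for m, r, e in zip(best_mag, best_rec, excluded)
    ]
    return pd.DataFrame(
        {
            "antitarget_affinity": best_mag,
            "antitarget_receptor": best_rec,
            "excluded": excluded,
            "reason": reasons,
        },
        index=matrix.ligand_ids,
    )


def score_matrix_records(matrix: ScoreMatrix, config: PrioritizationConfig) -> pd.DataFrame:
    """Score every ligand and apply the anti-target filter.

    Returns one row per ligand: final_binding_score, topk_receptor_ids
    (';'-joined), antitarget_affinity, antitarget_receptor, excluded,
    reason, rank (NA for excluded ligands; 1..N over survivors).
    """
    filt = anti_target_filter(matrix, config)
    panel_cols = [
        c for c in matrix.affinity.columns
        if config.antitarget_in_topk or c not in set(config.antitarget_receptor_ids)
    ]
    if not panel_cols:
        raise ValueError("no receptor columns left for top-k averaging")
    panel = matrix.affinity[panel_cols]
    scores, topk = [], []
    for lig in matrix.ligand_ids:
        s, ids = final_binding_score(panel.loc[lig], config.k)
        scores.append(s)
        topk.append(";".join(ids))
    records = pd.DataFrame(
        {
            "ligand_id": matrix.ligand_ids,
            "final_binding_score": scores,
            "topk_receptor_ids": topk,
            "antitarget_affinity": filt["antitarget_affinity"].values,
            "antitarget_receptor": filt["antitarget_receptor"].values,
            "excluded": filt["excluded"].values,
            "reason": filt["reason"].values,
        }
    )
    survivors = records.loc[~records["excluded"]].sort_values(
        ["final_binding_score", "ligand_id"], ascending=[False, True]
    )
    records["rank"] = pd.Series(dtype="Int64")
    records.loc[survivors.index, "rank"] = np.arange(1, len(survivors) + 1)
    records["rank"] = records["rank"].astype("Int64")
    return records


def rank_and_select(records: pd.DataFrame, n_select: int = 20) -> pd.DataFrame:
    """Top-n non-excluded records, ranked 1..n.

    Sorted by final binding score descending, ties by ligand id ascending.
    Fewer than ``n_select`` survivors returns all of them (logged).
    """
    survivors = records.loc[~records["excluded"]].sort_values(
        ["final_binding_score", "ligand_id"], ascending=[False, True]
    ).reset_index(drop=True)
    if len(survivors) < n_select:
        logger.warning("only %d survivors for n_select=%d", len(survivors), n_select)
    out = survivors.head(n_select).copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def prioritize(matrix: ScoreMatrix, config: PrioritizationConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full prioritization: score, filter, rank, select.

    Returns ``(records, selected)``: the per-ligand record table and the
    ranked top-n selection.
    """
    config = config or PrioritizationConfig()
    records = score_matrix_records(matrix, config)
    selected = rank_and_select(records, config.n_select)
    return records, selected
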