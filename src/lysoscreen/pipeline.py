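"""End-to-end screening pipeline: screen → triage → dock → prioritize.

The pipeline reads cached descriptor profiles and a receptor manifest,
runs the similarity screen, triages the receptor panel, assembles the
cross-docking matrix with the configured backend (the deterministic mock
by default), prioritizes by the top-k-mean final binding score with
anti-target exclusion, and writes the ranked candidates plus a triage
ledger and a run manifest sufficient to reproduce the run (config hash,
seed, package versions, input file hashes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as lio
from .docking import MockDockingBackend, assemble_matrix
from .prioritize import PrioritizationConfig, prioritize
from .similarity import screen_library
from .triage import make_box, select_pocket, triage

logger = logging.getLogger(__name__)

_CONFIG_FIELDS = {
    "similarity_threshold", "k_top", "antitarget_threshold", "n_select",
    "box_edge", "delta_tm_threshold", "seed", "paths",
}


@dataclass
class PipelineConfig:
    """Workflow constants plus input/output paths.

    ``paths`` keys: library_profiles, reference_profiles, receptor_manifest,
    pockets, outdir; optional: blocklist, plants (sidecar JSON of planted
    pair scores for the mock backend).
    """

    similarity_threshold: float = 0.65
    k_top: int = 20
    antitarget_threshold: float = 8.5
    n_select: int = 20
    box_edge: float = 25.0
    delta_tm_threshold: float = 2.0
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.similarity_threshold <= 1.0):
            raise ValueError("similarity_threshold must be in (0, 1]")
        if self.k_top < 1 or self.n_select < 1:
            raise ValueError("k_top and n_select must be >= 1")
        if self.antitarget_threshold <= 0 or self.box_edge <= 0:
            raise ValueError("antitarget_threshold and box_edge must be positive")
        if self.delta_tm_threshold < 0:
            raise ValueError("delta_tm_threshold must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from YAML or JSON; unknown keys are rejected."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise lio.DataError(f"{path}: config must be a mapping")
        unknown = set(raw) - _CONFIG_FIELDS
        if unknown:
            raise lio.DataError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full screen on file inputs; returns a result summary.

    Writes into ``paths['outdir']``: ranked_candidates.tsv, score_matrix.tsv
    (+ provenance sidecar), triage_ledger.json, screen_report.tsv and
    run_manifest.json.  Reruns with the same config and inputs are
    byte-identical.  Any stage error aborts naming the stage.
    """
    paths = {k: Path(v) for k, v in config.paths.items()}
    for key in ("library_profiles", "reference_profiles", "receptor_manifest", "pockets", "outdir"):
        if key not in paths:
            raise lio.DataError(f"pipeline config: missing required path {key!r}")
    outdir = paths["outdir"]
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "screen"
    try:
        library = lio.read_profiles(paths["library_profiles"])
        references = lio.read_profiles(paths["reference_profiles"])
        retained, screen_report = screen_library(
            library, references, threshold=config.similarity_threshold
        )
        screen_report.to_csv(outdir / "screen_report.tsv", sep="\t", index=False,
                             float_format="%.6f")
        if not retained:
            raise ValueError("similarity screen retained no ligands")

        stage = "triage"
        manifest = lio.read_receptor_manifest(
            paths["receptor_manifest"], paths["pockets"], paths.get("blocklist")
        )
        survivors, ledger = triage(manifest)
        boxes = {
            r.receptor_id: make_box(select_pocket(r), edge=config.box_edge) for r in survivors
        }
        lio.write_json_report(dataclasses.asdict(ledger), outdir / "triage_ledger.json")

        stage = "dock"
        antitarget_recs = [
            r for r in manifest if r.antitarget_flag and r.has_structure and r.pockets
        ]
        columns = [r.receptor_id for r in survivors] + [r.receptor_id for r in antitarget_recs]
        plants = {}
        if "plants" in paths:
            raw = json.loads(paths["plants"].read_text()).get("plants", {})
            plants = {tuple(k.split("|", 1)): float(v) for k, v in raw.items()}
        backend = MockDockingBackend(seed=config.seed, plants=plants)
        matrix = assemble_matrix(retained, columns, backend)
        lio.write_score_matrix(matrix, outdir / "score_matrix.tsv")

        stage = "prioritize"
        pconfig = PrioritizationConfig(
            k=config.k_top,
            antitarget_threshold=config.antitarget_threshold,
            n_select=config.n_select,
            antitarget_receptor_ids=tuple(r.receptor_id for r in antitarget_recs),
        )
        records, selected = prioritize(matrix, pconfig)
        lio.write_ranked_candidates(selected, outdir / "ranked_candidates.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    import numpy, scipy  # noqa: PLC0415

    from . import __version__

    run_manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "lysoscreen": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "input_hashes": {
            k: _file_hash(p) for k, p in paths.items() if p.is_file()
        },
        "funnel": {
            "n_library": len(library),
            "n_retained": len(retained),
            "n_collected": ledger.n_collected,
            "n_analyzable": ledger.n_analyzable,
            "n_docking_ready": ledger.n_docking_ready,
            "n_selected": len(selected),
        },
        "n_boxes": len(boxes),
    }
    lio.write_json_report(run_manifest, outdir / "run_manifest.json")
    logger.info(
        "funnel: %d library -> %d retained; %d collected -> %d analyzable -> %d ready; %d selected",
        len(library), len(retained), ledger.n_collected, ledger.n_analyzable,
        ledger.n_docking_ready, len(selected),
    )
    return {
        "retained": retained,
        "ledger": ledger,
        "matrix_shape": matrix.shape,
        "records": records,
        "selected": selected,
        "outdir": str(outdir),
    }
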