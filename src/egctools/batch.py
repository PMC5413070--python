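"""Batch orchestration: load -> normalize -> viability filter -> detect ->
two-pass correct -> certify -> report, over one or many models.

Per-model failures are isolated into the row's ``solver_status``; a batch
never aborts because one model is broken.  Rows mirror the per-model summary
table layout: growth/EGC flags, one ``generates.<label>`` column per energy
metabolite, and the removal sets of the unrestricted ("simple") and
ATP-synthase-protected ("synthase") correction passes.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import correct as _correct
from . import dissipation as _dissipation
from .detect import DetectionSettings, detect_egc
from .dissipation import LABELS, DissipationCatalog
from .model_core import MetabolicModel, check_viability, load_model, \
    normalize_model

log = logging.getLogger(__name__)


@dataclass
class BatchConfig:
    namespace: str | None = None
    viability_threshold: float = 1e-6
    catalog: DissipationCatalog | None = None
    detection: DetectionSettings = field(default_factory=DetectionSettings)
    correction: _correct.CorrectionSettings = field(
        default_factory=_correct.CorrectionSettings)
    run_correction: bool = True
    protected_patterns: tuple = ()
    weights: dict | None = None


@dataclass
class BatchSummary:
    rows: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        cols = ["model_id", "hasGrowth", "hasEGCs"]
        cols += [f"generates.{lab}" for lab in LABELS]
        cols += ["removals_simple", "removals_synthase", "biomass_ratio",
                 "wall_time", "solver_status"]
        return pd.DataFrame(self.rows, columns=cols)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _fmt_removals(solution) -> str:
    return ";".join(f"{rid}:{d}" for rid, d in sorted(solution.removals))


def process_model(model: MetabolicModel, config: BatchConfig):
    """Run the full pipeline on one loaded model; returns (row, outputs).

    ``outputs`` maps 'corrected' to the constrained model (when correction
    ran and succeeded) so callers can serialize it.
    """
    row: dict = {"model_id": model.id, "solver_status": "ok"}
    outputs: dict = {}
    t0 = time.perf_counter()
    model, _ = normalize_model(model)
    viable, optimum = check_viability(
        model, config.viability_threshold,
        rich_bound=config.correction.rich_bound)
    row["hasGrowth"] = bool(viable)
    if not viable:
        row["hasEGCs"] = None
        row["wall_time"] = time.perf_counter() - t0
        return row, outputs
    attached = _dissipation.attach_default(model, config.catalog)
    report = detect_egc(attached, config.detection)
    row.update({k: v for k, v in report.to_row().items()
                if k != "model_id"})
    if report.has_egcs and config.run_correction:
        try:
            simple, synthase = _correct.run_two_pass(
                attached, config.correction,
                protected_patterns=config.protected_patterns,
                weights=config.weights)
            row["removals_simple"] = _fmt_removals(simple)
            row["removals_synthase"] = _fmt_removals(synthase)
            row["biomass_ratio"] = _correct.biomass_impact(attached, synthase)
            outputs["corrected"] = _correct.apply_removals(
                model, synthase.removals)
        except (_correct.InfeasibleCorrectionError,
                _correct.CertificationError,
                _correct.ConfigurationError) as exc:
            row["solver_status"] = f"correction_failed: {exc}"
    row["wall_time"] = time.perf_counter() - t0
    return row, outputs


def run_batch(inputs, config: BatchConfig | None = None,
              out_dir=None) -> BatchSummary:
    """Process a sequence of model paths (or loaded models).

    With ``out_dir`` set, corrected models are written there as
    ``<model_id>.corrected.xml``.
    """
    config = config or BatchConfig()
    summary = BatchSummary()
    for item in inputs:
        try:
            model = item if isinstance(item, MetabolicModel) else \
                load_model(item, config.namespace)
        except Exception as exc:   # malformed input must not kill the batch
            summary.rows.append({
                "model_id": str(item), "hasGrowth": None, "hasEGCs": None,
                "solver_status": f"load_failed: {exc}", "wall_time": 0.0})
            continue
        try:
            row, outputs = process_model(model, config)
        except Exception as exc:
            row, outputs = {"model_id": model.id, "hasGrowth": None,
                            "hasEGCs": None,
                            "solver_status": f"error: {exc}",
                            "wall_time": 0.0}, {}
        if out_dir and "corrected" in outputs:
            from .model_core import save_sbml
            save_sbml(outputs["corrected"],
                      Path(out_dir) / f"{model.id}.corrected.xml")
        summary.rows.append(row)
    return summary
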