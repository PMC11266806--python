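"""End-to-end orchestration: virtual sample -> sorting -> signals -> DSP ->
classification -> sample-level counts and diagnosis.

All stage seeds derive deterministically from one master seed, so a run is
fully reproducible: same config + seed -> byte-identical report JSON
(timestamps live only in the log file).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from cytosim import dsp
from cytosim.cytonet import CLASS_NAMES, CytoNetModel, gating_baseline
from cytosim.dielectrics import get_medium, get_preset
from cytosim.signal_sim import (
    ElectrodeConfig,
    NoiseModel,
    TransitEvent,
    simulate_event,
)
from cytosim.virtual_lab import (
    PopulationSpec,
    apply_stage_chain,
    build_spikein_scenario,
    default_stage_chain,
    simulate_cells,
)

REPORT_SCHEMA_VERSION = 1

logger = logging.getLogger("cytosim.pipeline")


@dataclass
class RunConfig:
    """Configuration of one virtual sample run."""

    background: PopulationSpec = field(
        default_factory=lambda: PopulationSpec(preset="WBC", count=5000)
    )
    spike_count: int = 0
    spike_preset: str = "MCF-7"
    max_background: int | None = 20000
    electrode: ElectrodeConfig = field(default_factory=ElectrodeConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    stages: list = field(default_factory=default_stage_chain)
    # classifier: "gating", a checkpoint path, or a CytoNetModel instance
    classifier: object = "gating"
    gating_diameter_cut_um: float = 13.0
    gating_opacity_cut: float = 0.875
    theta_ctc: float = 10.0
    theta_total: float = 1e9
    master_seed: int = 0
    speed: float = 0.15
    gap_samples: int = 200
    chunk_events: int = 500

    def __post_init__(self) -> None:
        if self.theta_ctc < 0 or self.theta_total < 0:
            raise ValueError("diagnosis thresholds must be >= 0")
        if self.noise.amplitude_noise_sd <= 0:
            raise ValueError(
                "pipeline runs need amplitude noise > 0 (event detection "
                "thresholds are scaled from the noise floor)"
            )


@dataclass
class SampleReport:
    """Sample-level outcome of one pipeline run (schema v1)."""

    total_detected: int
    accepted: int
    rejected: int
    rejected_reasons: dict
    predicted_wbc: int
    predicted_ctc: int
    diagnosis_positive: bool
    theta_ctc: float
    theta_total: float
    n_input_cells: int
    n_sorted_product: int
    n_sorted_waste: int
    background_scale: float
    spike_count: int
    stage_reports: list
    master_seed: int
    schema_version: int = REPORT_SCHEMA_VERSION
    software_version: str = ""

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "software_version": self.software_version,
            "master_seed": self.master_seed,
            "counts": {
                "total_detected": self.total_detected,
                "accepted": self.accepted,
                "rejected": self.rejected,
                "predicted_wbc": self.predicted_wbc,
                "predicted_ctc": self.predicted_ctc,
                "n_input_cells": self.n_input_cells,
                "n_sorted_product": self.n_sorted_product,
                "n_sorted_waste": self.n_sorted_waste,
            },
            "rejected_reasons": self.rejected_reasons,
            "diagnosis": {
                "positive": self.diagnosis_positive,
                "theta_ctc": self.theta_ctc,
                "theta_total": self.theta_total,
            },
            "sample": {
                "background_scale": self.background_scale,
                "spike_count": self.spike_count,
            },
            "stage_reports": self.stage_reports,
        }


def diagnose(predicted_ctc: float, total_cells: float,
             theta_ctc: float, theta_total: float) -> bool:
    """Positive iff predicted CTC count >= theta_ctc OR total >= theta_total."""
    if theta_ctc < 0 or theta_total < 0:
        raise ValueError("thresholds must be >= 0")
    return bool(predicted_ctc >= theta_ctc or total_cells >= theta_total)


def default_size_calibration(
    config: ElectrodeConfig,
    bead_diameters_um=(7.0, 10.0, 15.0, 20.0),
    speed: float = 0.15,
) -> dsp.SizeCalibration:
    """Noiseless simulated-bead calibration of the electrical diameter."""
    medium = get_medium("PBS")
    bead = get_preset("polystyrene")
    peak_sets = []
    for d in bead_diameters_um:
        ev = TransitEvent(particle=bead.with_diameter(d), trajectory="T1", speed=speed)
        sig = simulate_event(ev, config, medium)
        peak_sets.append(dsp.extract_peaks(sig))
    return dsp.fit_size_calibration(peak_sets, bead_diameters_um)


def _classify(cfg: RunConfig, fragments, features_frame) -> np.ndarray:
    if isinstance(cfg.classifier, CytoNetModel):
        model = cfg.classifier
    elif cfg.classifier == "gating":
        return gating_baseline(
            features_frame, cfg.gating_diameter_cut_um, cfg.gating_opacity_cut
        )
    else:
        model = CytoNetModel.load(cfg.classifier)
    x = np.stack([f.values for f in fragments]).astype(np.float32)
    return model.predict(x)


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> SampleReport:
    """Execute all stages; optionally export report/features/log to outdir."""
    from cytosim import __version__

    seeds = np.random.SeedSequence(cfg.master_seed).spawn(4)
    s_sample, s_sort, s_sim, s_stream = (s.generate_state(1)[0] for s in seeds)

    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    stage_name = "setup"
    try:
        # 1. virtual sample -------------------------------------------------
        stage_name = "sample-generation"
        sample = build_spikein_scenario(
            cfg.background, [cfg.spike_count], seed=s_sample,
            spike_preset=cfg.spike_preset, max_background=cfg.max_background,
        )[0]
        cells = sample.cells
        log(f"sample: {len(cells)} cells ({sample.background_count} background, "
            f"{sample.spike_count} spiked, scale {sample.background_scale:g})")

        # 2. sorting --------------------------------------------------------
        stage_name = "sorting"
        product, waste, stage_reports = apply_stage_chain(cells, cfg.stages, seed=s_sort)
        assert len(product) + len(waste) == len(cells)
        for rep in stage_reports:
            log(f"stage {rep.stage}: in={rep.n_in} product={rep.n_product} "
                f"waste={rep.n_waste} purity={rep.purity:.3f}")

        # 3-5. detection module: signals -> DSP -> features ----------------
        stage_name = "detection"
        calibration = default_size_calibration(cfg.electrode, speed=cfg.speed)
        medium = get_medium("PBS")
        stream_rng = np.random.default_rng(s_stream)
        detected = 0
        accepted_features: list[dsp.EventFeatures] = []
        accepted_fragments: list[dsp.FragmentTensor] = []
        rejected_reasons: dict[str, int] = {}

        for start in range(0, len(product), cfg.chunk_events):
            chunk = product[start : start + cfg.chunk_events]
            events = simulate_cells(
                chunk, config=cfg.electrode, medium=medium, noise=cfg.noise,
                seed=s_sim + start, speed=cfg.speed,
            )
            result = dsp.process_event_stream(
                events, calibration, cfg.noise.amplitude_noise_sd,
                rng=stream_rng, gap_samples=cfg.gap_samples,
            )
            detected += result.n_detected
            for reason, count in result.rejected_reasons.items():
                rejected_reasons[reason] = rejected_reasons.get(reason, 0) + count
            for pe in result.processed:
                accepted_features.append(pe.features)
                accepted_fragments.append(pe.fragment)

        rejected = detected - len(accepted_features)
        log(f"detection: {detected} events, {len(accepted_features)} accepted, "
            f"{rejected} rejected")

        # 6. classification -------------------------------------------------
        stage_name = "classification"
        if accepted_features:
            features_frame = dsp.features_table(accepted_features)
            pred = _classify(cfg, accepted_fragments, features_frame)
            features_frame["predicted_label"] = [CLASS_NAMES[i] for i in pred]
        else:
            features_frame = pd.DataFrame(columns=list(dsp.FEATURE_COLUMNS))
            pred = np.zeros(0, dtype=int)
        n_ctc = int((pred == 1).sum())
        n_wbc = int((pred == 0).sum())
        log(f"classification: {n_wbc} WBC, {n_ctc} CTC")

        # 7. report ---------------------------------------------------------
        stage_name = "reporting"
        flag = diagnose(n_ctc, len(accepted_features), cfg.theta_ctc, cfg.theta_total)
        report = SampleReport(
            total_detected=detected,
            accepted=len(accepted_features),
            rejected=rejected,
            rejected_reasons=rejected_reasons,
            predicted_wbc=n_wbc,
            predicted_ctc=n_ctc,
            diagnosis_positive=flag,
            theta_ctc=cfg.theta_ctc,
            theta_total=cfg.theta_total,
            n_input_cells=len(cells),
            n_sorted_product=len(product),
            n_sorted_waste=len(waste),
            background_scale=sample.background_scale,
            spike_count=sample.spike_count,
            stage_reports=[r.to_dict() for r in stage_reports],
            master_seed=cfg.master_seed,
            software_version=__version__,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage_name}' failed: {exc}") from exc

    if outdir is not None:
        export_report(report, outdir, features_frame=features_frame, log_lines=log_lines)
    return report


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def export_report(
    report: SampleReport,
    outdir: str | Path,
    features_frame: pd.DataFrame | None = None,
    log_lines: list[str] | None = None,
) -> dict:
    """Write report.json (+ features.csv, run.log); returns written paths."""
    outdir = Path(outdir)
    if not outdir.exists():
        raise FileNotFoundError(f"output directory does not exist: {outdir}")
    paths = {}
    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["report"] = report_path
    if features_frame is not None:
        features_path = outdir / "features.csv"
        features_frame.to_csv(features_path, index=False)
        paths["features"] = features_path
    if log_lines is not None:
        import datetime

        log_path = outdir / "run.log"
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        log_path.write_text(f"# run completed {stamp}\n" + "\n".join(log_lines) + "\n")
        paths["log"] = log_path
    return paths


def read_report(path: str | Path) -> dict:
    """Read and validate a report.json written by export_report."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"report not found: {path}")
    with open(path) as fh:
        data = json.load(fh)
    version = data.get("schema_version")
    if version != REPORT_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported report schema version {version} "
            f"(expected {REPORT_SCHEMA_VERSION})"
        )
    return data


# ---------------------------------------------------------------------------
# Analytic spike-recovery interval
# ---------------------------------------------------------------------------

def spike_recovery_interval(
    n_spike: int,
    sorting_recovery: float,
    classifier_tpr: float,
    confidence: float = 0.95,
    expected_false_positives: float = 0.0,
) -> tuple[float, float]:
    """Predicted-CTC count interval from two Bernoulli stages.

    A spiked tumor cell is counted iff it survives sorting (prob RE) and is
    classified as tumor (prob TPR); the product is one Bernoulli trial per
    spiked cell.  The interval is the central ``confidence`` mass of
    Binomial(n_spike, RE * TPR), shifted by the expected number of WBC
    false positives.
    """
    p = sorting_recovery * classifier_tpr
    if not (0.0 <= p <= 1.0):
        raise ValueError("RE * TPR must be a probability")
    lo, hi = stats.binom.interval(confidence, n_spike, p)
    return (float(lo) + expected_false_positives, float(hi) + expected_false_positives)
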