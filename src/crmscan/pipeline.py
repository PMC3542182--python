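"""End-to-end orchestration: simulate -> scan/features -> bolasso -> final
model -> positional profile -> annotation, with a full parameter echo in the
run report so every run is reproducible from its report alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import annotate, classify, location, simulate
from .motifs import scan_consensus
from .seqio import PathLike

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters with their conventional defaults."""

    seed: int = 0
    # study design
    n_positive: int = 24
    n_negative: int = 37
    positive_density: float = simulate.DEFAULT_POSITIVE_DENSITY
    negative_density: float = simulate.DEFAULT_NEGATIVE_DENSITY
    n_noise_motifs: int = 30
    # scanning
    scan_threshold: float = 4.6
    location_threshold: float = 4.5
    bg_order: int = 2
    kmer_bg_order: int = 3
    k: int = 6
    # classifier
    n_bootstrap: int = 1000
    max_features: int = 50
    confidence_start: float = 0.95
    confidence_step: float = 0.05
    # location / annotation
    loess_span: float = 0.75
    promoter_span: int = 2000


def validate_config(config: RunConfig) -> list[str]:
    """Every invariant violation, as human-readable issues; empty iff runnable."""
    issues = []

    def check_number(name, value, minimum=None, strict=False):
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            issues.append(f"{name} must be a number, got {type(value).__name__}")
            return
        if minimum is not None and (value <= minimum if strict else value < minimum):
            op = ">" if strict else ">="
            issues.append(f"{name} must be {op} {minimum}, got {value}")

    check_number("seed", config.seed, 0)
    check_number("n_positive", config.n_positive, 2)
    check_number("n_negative", config.n_negative, 2)
    check_number("positive_density", config.positive_density, 0)
    check_number("negative_density", config.negative_density, 0)
    check_number("n_bootstrap", config.n_bootstrap, 0, strict=True)
    check_number("max_features", config.max_features, 0)
    check_number("bg_order", config.bg_order, 0)
    check_number("kmer_bg_order", config.kmer_bg_order, 0)
    check_number("k", config.k, 1)
    check_number("scan_threshold", config.scan_threshold)
    check_number("location_threshold", config.location_threshold)
    check_number("promoter_span", config.promoter_span, 0)
    if isinstance(config.confidence_start, (int, float)) and not (0 < config.confidence_start <= 1):
        issues.append(f"confidence_start must be in (0, 1], got {config.confidence_start}")
    if isinstance(config.loess_span, (int, float)) and not (0 < config.loess_span <= 1):
        issues.append(f"loess_span must be in (0, 1], got {config.loess_span}")
    if isinstance(config.kmer_bg_order, int) and isinstance(config.k, int) \
            and config.kmer_bg_order >= config.k:
        issues.append("kmer_bg_order must be smaller than k")
    return issues


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig, out_dir: Optional[PathLike] = None) -> dict:
    """Run every stage on a generated study and return the run report.

    The report echoes the full configuration and carries each stage's key
    outputs (selection frequencies, the final motif panel, LOOCV AUC, the
    positional profile, annotation accuracy on the landscape fixture).
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid configuration: " + "; ".join(issues))
    report: dict = {"config": asdict(config), "stages": {}}
    timer = time.perf_counter

    def stage(name):
        logger.info("stage %s ...", name)
        return timer()

    try:
        t = stage("simulate")
        design = simulate.cardiac_design(
            seed=config.seed,
            n_positive=config.n_positive,
            n_negative=config.n_negative,
            n_noise_motifs=config.n_noise_motifs,
            bg_order=config.bg_order,
        )
        design.planted[0].density_positive = config.positive_density
        design.planted[0].density_negative = config.negative_density
        study = simulate.generate_study(design)
        if out_dir is not None:
            simulate.write_study(study, out_dir)
        report["stages"]["simulate"] = {
            "n_sequences": len(study.enhancers.records),
            "n_positive": int((study.enhancers.labels > 0).sum()),
            "n_motifs": len(study.motifs),
            "seconds": timer() - t,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc

    try:
        t = stage("features")
        fm = classify.build_features(
            study.enhancers, consensi=study.motifs,
            bg_order=config.bg_order, threshold=config.scan_threshold,
        )
        fm_std = classify.standardize(fm)
        labels = study.enhancers.labels
        pos_density = float(fm.values.loc[labels > 0, "CEE"].mean())
        neg_density = float(fm.values.loc[labels < 0, "CEE"].mean())
        report["stages"]["features"] = {
            "shape": list(fm.values.shape),
            "cee_density_positive": pos_density,
            "cee_density_negative": neg_density,
            "seconds": timer() - t,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("features", exc) from exc

    try:
        t = stage("bolasso")
        bres = classify.bolasso(
            fm_std, labels, n_bootstrap=config.n_bootstrap,
            seed=config.seed, max_features=config.max_features,
        )
        top = sorted(bres.selection_freq.items(), key=lambda kv: -kv[1])[:5]
        report["stages"]["bolasso"] = {
            "top_selection_freq": {m: f for m, f in top},
            "seconds": timer() - t,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("bolasso", exc) from exc

    try:
        t = stage("select_final")
        clf = classify.select_final(
            bres, fm_std, labels,
            start_threshold=config.confidence_start, step=config.confidence_step,
        )
        report["stages"]["select_final"] = {
            "motifs": clf.motifs if clf else [],
            "coefficients": clf.coefficients if clf else {},
            "confidence_threshold": clf.confidence_threshold if clf else None,
            "loocv_auc": clf.loocv_auc if clf else None,
            "seconds": timer() - t,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("select_final", exc) from exc

    try:
        t = stage("locate")
        hits = []
        for rec in study.enhancers.sequences:
            hits.extend(scan_consensus(rec, simulate.CEE))
        positions = location.relative_positions(hits, study.enhancers.sequences)
        prof = location.profile(positions, loess_span=config.loess_span)
        report["stages"]["locate"] = {
            "n_hits": prof.n_hits,
            "scaled_density": [round(v, 4) for v in prof.scaled_density.tolist()],
            "seconds": timer() - t,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("locate", exc) from exc

    try:
        t = stage("annotate")
        genes, peaks, truth = simulate.generate_gene_landscape(seed=config.seed)
        correct = 0
        for peak, (_, row) in zip(peaks, truth.iterrows()):
            ann = annotate.assign_gene(peak, genes, promoter_span=config.promoter_span)
            correct += ann.category == row["category"] and ann.gene_id == row["gene_id"]
        report["stages"]["annotate"] = {
            "n_peaks": len(peaks),
            "truth_agreement": correct / len(peaks),
            "seconds": timer() - t,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("annotate", exc) from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
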