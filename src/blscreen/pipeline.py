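"""End-to-end orchestration: preprocess -> train ensemble -> infer -> report.

The flagship entry point is the fully synthetic demo: generate a labeled
pseudo-WSI cohort, tile it across magnification levels, run the four-stage
QC, normalize stains, build MIL bags, split 6:2:2 at slide level, train all
six ensemble variants, and score the held-out test slides with the
consensus/indecision rule.  Every artifact is written with the config hash
and seed for provenance, and each stage logs its counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import ensemble as ens
from . import mil, qc, stain, synthetic, tiling

logger = logging.getLogger(__name__)

MODES = ("train", "infer", "full-synthetic-demo")


def default_model_configs(
    seed: int = 0, input_size_px: int = 64, sample_size: int = 20, batch_size: int = 4
) -> list[mil.ModelConfig]:
    """The six ensemble variants: three backbones, each plain and attention.

    Attention head widths follow the grid used for each backbone family
    (10/50 for the efficientnet-like variant, 16/64 for the others).
    """
    configs = []
    heads = {"resnet50-like": 64, "efficientnet-like": 50, "googlenet-like": 16}
    for i, backbone in enumerate(("resnet50-like", "efficientnet-like", "googlenet-like")):
        for j, attention in enumerate((False, True)):
            configs.append(
                mil.ModelConfig(
                    backbone=backbone,
                    attention=attention,
                    attention_head_size=heads[backbone],
                    batch_size=batch_size,
                    sample_size=sample_size,
                    input_size_px=input_size_px,
                    seed=seed * 1000 + i * 10 + j,
                )
            )
    return configs


@dataclasses.dataclass
class PipelineConfig:
    work_dir: str = "blscreen_run"
    cohort_dir: str | None = None  # existing cohort manifest dir; None -> synthesize
    n_positive: int = 20
    n_negative: int = 20
    slide_width_px: int = 320
    slide_height_px: int = 320
    levels: tuple[str, ...] = ("20x", "10x")
    tile_size_px: int = 64
    overlap_px: int = 8
    thresholds: qc.QCThresholds = dataclasses.field(default_factory=qc.QCThresholds)
    reference_path: str | None = None  # JSON ReferenceStats; None -> package default
    model_configs: list[mil.ModelConfig] | None = None
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("work_dir", None)  # provenance hash covers the science, not paths
        payload["thresholds"].pop("pen_hsv_ranges", None)
        if self.model_configs is not None:
            payload["model_configs"] = [dataclasses.asdict(c) for c in self.model_configs]
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _stage(name: str):
    logger.info("stage %s", name)
    return time.time()


def _load_cohort(config: PipelineConfig):
    """Synthesize or load the slide cohort; returns (slides, labels)."""
    if config.cohort_dir is not None:
        from PIL import Image

        manifest = pd.read_csv(Path(config.cohort_dir) / "cohort.csv")
        slides = []
        labels = {}
        for row in manifest.itertuples():
            raster = np.asarray(Image.open(row.path).convert("RGB"))
            spec = synthetic.SyntheticSlideSpec(
                slide_id=row.slide_id, label=int(row.label),
                width_px=raster.shape[1], height_px=raster.shape[0],
                seed=int(getattr(row, "seed", 0)),
            )
            slides.append(synthetic.SyntheticSlide(spec=spec, raster=raster,
                                                   truth_mask=np.zeros(raster.shape[:2], np.uint8)))
            labels[row.slide_id] = int(row.label)
        return slides, labels
    slides = synthetic.generate_cohort(
        config.n_positive, config.n_negative, base_seed=config.seed,
        width_px=config.slide_width_px, height_px=config.slide_height_px,
    )
    labels = {s.spec.slide_id: s.spec.label for s in slides}
    return slides, labels


def _preprocess(config: PipelineConfig, slides, labels, work: Path):
    """Tile -> QC -> stain-normalize; returns (records, qc manifest path)."""
    t0 = _stage("tile+qc+normalize")
    ref = (
        stain.ReferenceStats.from_json(config.reference_path)
        if config.reference_path
        else stain.default_reference()
    )
    records = []
    qc_rows = []
    stage_counts: dict[str, int] = {}
    for slide in slides:
        recs = tiling.tile_slide(
            slide.raster, slide.spec.slide_id, levels=config.levels,
            tile_size_px=config.tile_size_px, overlap_px=config.overlap_px,
        )
        for rec in recs:
            rec.qc = qc.run_qc(rec.raster, config.thresholds)
            if rec.qc.passed:
                rec.raster = stain.normalize_tile(rec.raster, ref)
            else:
                stage = rec.qc.fail_stage
                stage_counts[stage] = stage_counts.get(stage, 0) + 1
            qc_rows.append(
                {
                    "slide_id": rec.slide_id, "x": rec.x, "y": rec.y,
                    "magnification": rec.magnification,
                    "passed": rec.qc.passed, "fail_stage": rec.qc.fail_stage or "",
                    **{k: rec.qc.scores.get(k, np.nan) for k in
                       ("bg_std", "pen_fraction", "pp_ratio", "tissue_fraction")},
                }
            )
        records.extend(recs)
    manifest = work / "tiles_qc.csv"
    pd.DataFrame(qc_rows).to_csv(manifest, index=False)
    n_pass = sum(r.qc.passed for r in records)
    logger.info(
        "tiled %d slides -> %d tiles, %d passed QC (rejects by stage: %s) in %.1fs",
        len(slides), len(records), n_pass, stage_counts, time.time() - t0,
    )
    return records, manifest


def run_pipeline(config: PipelineConfig, mode: str = "full-synthetic-demo") -> dict:
    """Execute the pipeline; returns a summary dict (also written to JSON).

    Modes: "full-synthetic-demo" runs everything from cohort synthesis to
    the ensemble report with zero external inputs; "train" stops after
    training and checkpointing; "infer" loads checkpoints from a previous
    run and only scores.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    work = Path(config.work_dir)
    work.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": config.config_hash(), "seed": config.seed}

    slides, labels = _load_cohort(config)
    records, _ = _preprocess(config, slides, labels, work)

    bags, rejects = mil.build_bags(records, labels)
    split = mil.split_slides(
        [b.slide_id for b in bags], ratios=config.ratios, seed=config.seed, labels=labels
    )
    (work / "split.json").write_text(
        json.dumps({"ratios": split.ratios, "seed": split.seed,
                    "assignment": split.assignment, **provenance}, indent=2)
    )
    by_part = {p: [b for b in bags if split.assignment[b.slide_id] == p]
               for p in ("train", "val", "test")}
    logger.info("bags: %d (rejected slides: %s); split %s", len(bags), rejects,
                {p: len(v) for p, v in by_part.items()})

    configs = config.model_configs or default_model_configs(seed=config.seed,
                                                            input_size_px=config.tile_size_px)
    ckpt_dir = work / "ckpt"
    models: list[mil.TrainedModel] = []
    if mode == "infer":
        paths = sorted(ckpt_dir.glob("*.npz"))
        if not paths:
            raise FileNotFoundError(f"no checkpoints found under {ckpt_dir}")
        models = [mil.TrainedModel.load(p) for p in paths]
    else:
        for i, mc in enumerate(configs):
            t0 = _stage(f"train {mc.name}")
            tm = mil.train_model(mc, by_part["train"], by_part["val"])
            tm.save(ckpt_dir / f"model_{i + 1}_{mc.name}.npz")
            pd.DataFrame(tm.history).to_csv(ckpt_dir / f"model_{i + 1}_{mc.name}_log.csv", index=False)
            models.append(tm)
            logger.info("trained %s: %d epochs, best %d (val loss %.3f) in %.1fs",
                        mc.name, len(tm.history), tm.best_epoch,
                        tm.history[tm.best_epoch - 1]["val_loss"], time.time() - t0)
    if mode == "train":
        summary = {**provenance, "mode": mode, "n_models": len(models)}
        (work / "summary.json").write_text(json.dumps(summary, indent=2))
        return summary

    test_bags = by_part["test"] if mode != "infer" else bags
    predictions = [ens.predict_slide(models, bag) for bag in test_bags]
    pred_rows = []
    for p in predictions:
        row = {"slide_id": p.slide_id}
        row.update({f"vote_{k}": v for k, v in p.votes.items()})
        row.update({f"prob_{k}": v for k, v in p.probabilities.items()})
        row["confidence"] = p.confidence
        row["decision"] = p.decision
        pred_rows.append(row)
    pd.DataFrame(pred_rows).to_csv(work / "predictions.csv", index=False)

    report, binary = ens.evaluate_ensemble(predictions, labels)
    per_model = _per_model_metrics(models, test_bags)
    summary = {
        **provenance,
        "mode": mode,
        "n_slides": len(slides),
        "n_test_slides": len(test_bags),
        "ensemble": {
            "percent_correct": report.percent_correct,
            "percent_indecision": report.percent_indecision,
            "percent_incorrect": report.percent_incorrect,
        },
        "ensemble_decided_metrics": binary.to_dict() if binary else None,
        "per_model_test_metrics": per_model,
    }
    (work / "metrics.json").write_text(json.dumps(summary, indent=2))
    logger.info("ensemble report: %s", summary["ensemble"])
    return summary


def _per_model_metrics(models, test_bags) -> dict:
    out = {}
    for i, model in enumerate(models):
        probs, truths = [], []
        for bag in test_bags:
            p, _ = mil.forward_bag(model, bag.instances)
            probs.append(p)
            truths.append(bag.label)
        hard = [int(p >= ens.VOTE_THRESHOLD) for p in probs]
        rep = ens.binary_metrics(hard, truths)
        if len(set(truths)) == 2:
            rep.auc = ens.auc_score(probs, truths)
        out[f"m{i + 1}_{model.config.name}"] = rep.to_dict()
    return out
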