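"""Pipeline orchestration: simulate/load -> align -> signal -> discriminate.

``run_pipeline`` ties the modules into the four analyses — multivariate
phylogenetic signal on species mean shapes, landmark-based PCA-CVA, pixel-
matrix PCA-CVA, and the contrast-CNN discriminator — writing per-stage
result files and a combined JSON report.  Every stochastic stage has its own
named seed recorded in the output, so a rerun with the same configuration is
numerically identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnn as cnn_mod
from .discriminant import (ConfusionSummary, classify_and_summarize,
                           fit_pca_cva, hotelling_t2_boot, jackknife_loo,
                           sma_regression)
from .images import flatten_to_matrix
from .phylosignal import kmult_test, phylomorphospace
from .procrustes import gpa_align, species_means
from .simulate import SimulationConfig, simulate_dataset


class StageError(RuntimeError):
    """A pipeline stage failed; partial results are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    wings: tuple[str, ...] = ("forewing", "hindwing")
    run_phylosignal: bool = True
    run_landmark_cva: bool = True
    run_image_cva: bool = True
    run_cnn: bool = False
    var_threshold: float = 0.95
    permutations: int = 1000
    cnn_epochs: int = 1
    cnn_iterations: int = 200
    cnn_targets: int = 6
    seeds: dict = field(default_factory=lambda: {
        "kmult": 11, "t2": 12, "sma": 13, "cnn": 14, "cnn_jackknife": 15})

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        sim = SimulationConfig(**raw.pop("simulation", {}))
        cfg = cls(simulation=sim)
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown pipeline option {k!r}")
            setattr(cfg, k, tuple(v) if k == "wings" else v)
        return cfg


def _confusions_record(name: str, post: ConfusionSummary,
                       jack: ConfusionSummary) -> dict:
    return {
        "analysis": name,
        "groups": list(post.groups),
        "post_hoc": {"counts": post.counts.tolist(),
                     "accuracy": post.accuracy, "mcc": post.mcc},
        "jackknife": {"counts": jack.counts.tolist(),
                      "accuracy": jack.accuracy, "mcc": jack.mcc},
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the enabled stages in dependency order and return (and
    optionally write) the combined result bundle."""
    results: dict = {"config": {"simulation": asdict(config.simulation),
                                "seeds": dict(config.seeds)},
                     "timings": {}, "confusions": []}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _save(name: str, payload) -> None:
        if out is None:
            return
        if isinstance(payload, pd.DataFrame):
            payload.to_csv(out / f"{name}.csv")
        else:
            (out / f"{name}.json").write_text(json.dumps(payload, indent=1))

    t0 = time.time()
    try:
        need_images = config.run_image_cva or config.run_cnn
        ds = simulate_dataset(config.simulation, config.wings, render=need_images)
    except Exception as e:                     # pragma: no cover - defensive
        raise StageError("simulate", e)
    results["timings"]["simulate"] = time.time() - t0
    results["habitats"] = {sp: [ds.habitats.landscape(sp), ds.habitats.water_body(sp)]
                           for sp in ds.phylogeny.tip_names}

    for wing in config.wings:
        configs = ds.configurations[wing]
        labels = ds.labels[wing]
        t0 = time.time()
        try:
            aligned = gpa_align(configs)
        except Exception as e:
            raise StageError(f"align/{wing}", e)
        results["timings"][f"align/{wing}"] = time.time() - t0

        if config.run_phylosignal:
            t0 = time.time()
            try:
                means, order = species_means(aligned, tip_order=ds.phylogeny.tip_names)
                kr = kmult_test(means.reshape(len(means), -1), ds.phylogeny,
                                B=config.permutations, seed=config.seeds["kmult"])
                pm = phylomorphospace(means.reshape(len(means), -1), ds.phylogeny)
                rec = {"wing": wing, "K": kr.K_observed, "p": kr.p_value,
                       "percentiles": [kr.percentile_low, kr.percentile_high],
                       "significant": kr.significant,
                       "n_crossings": pm.n_crossings,
                       "seed": config.seeds["kmult"]}
                results.setdefault("phylosignal", []).append(rec)
                _save(f"phylosignal_{wing}", rec)
            except Exception as e:
                raise StageError(f"phylosignal/{wing}", e)
            results["timings"][f"phylosignal/{wing}"] = time.time() - t0

        if config.run_landmark_cva:
            X = aligned.flat()
            for factor in ("landscape", "water_body"):
                y = labels[factor].to_numpy()
                name = f"landmark/{wing}/{factor}"
                t0 = time.time()
                try:
                    model = fit_pca_cva(X, y, config.var_threshold)
                    post = classify_and_summarize(
                        model, model.pc_model.transform(X), y)
                    jack = jackknife_loo(X, y, config.var_threshold)
                    t2 = hotelling_t2_boot(model.pc_model.transform(X), y,
                                           B=config.permutations,
                                           seed=config.seeds["t2"])
                    results["confusions"].append(_confusions_record(name, post, jack))
                    results.setdefault("t2", []).append(
                        {"analysis": name, "T2": t2.T2_observed, "p": t2.p_value})
                    results.setdefault("_ld_scores", {})[name] = model.scores
                except Exception as e:
                    raise StageError(name, e)
                results["timings"][name] = time.time() - t0
            # conjugate-selection check: SMA between the two factors' axes
            sA = results["_ld_scores"][f"landmark/{wing}/landscape"]
            sB = results["_ld_scores"][f"landmark/{wing}/water_body"]
            sma = sma_regression(sA, sB, B=config.permutations,
                                 seed=config.seeds["sma"])
            results.setdefault("sma", []).append(
                {"wing": wing, "slope": sma.slope, "intercept": sma.intercept,
                 "r": sma.r, "p": sma.p_value})

        if config.run_image_cva:
            Xi, _frame = flatten_to_matrix(ds.images[wing])
            for factor in ("landscape", "water_body"):
                y = labels[factor].to_numpy()
                name = f"image/{wing}/{factor}"
                t0 = time.time()
                try:
                    model = fit_pca_cva(Xi, y, config.var_threshold)
                    post = classify_and_summarize(
                        model, model.pc_model.transform(Xi), y)
                    jack = jackknife_loo(Xi, y, config.var_threshold)
                    results["confusions"].append(_confusions_record(name, post, jack))
                except Exception as e:
                    raise StageError(name, e)
                results["timings"][name] = time.time() - t0

        if config.run_cnn:
            y = labels["landscape"].to_numpy()
            name = f"cnn/{wing}/landscape"
            t0 = time.time()
            try:
                schedule = cnn_mod.TrainingSchedule(
                    epochs=config.cnn_epochs,
                    iterations_per_epoch=config.cnn_iterations,
                    seed=config.seeds["cnn"])
                contrasts = cnn_mod.enumerate_contrasts(y)
                model = cnn_mod.train(contrasts, ds.images[wing], schedule)
                post_acc = cnn_mod.contrast_accuracy(model, contrasts, ds.images[wing])
                jack = cnn_mod.cnn_jackknife(
                    ds.images[wing], y, schedule,
                    n_targets=min(config.cnn_targets, len(y)),
                    seed=config.seeds["cnn_jackknife"])
                results.setdefault("cnn", []).append(
                    {"analysis": name, "contrast_accuracy": post_acc,
                     "loss_trace": model.loss_trace,
                     "jackknife_accuracy": jack.accuracy,
                     "jackknife_mcc": jack.mcc})
            except Exception as e:
                raise StageError(name, e)
            results["timings"][name] = time.time() - t0

    results.pop("_ld_scores", None)
    if out is not None:
        _save("confusions", results["confusions"])
        _save("report", {k: v for k, v in results.items()
                         if k not in ("confusions",)})
    return results


def summarize_confusions(results: dict | list) -> pd.DataFrame:
    """Comparison table of post-hoc and jackknife performance; the rendered
    column shows jackknife values in parentheses after the post-hoc value."""
    records = results.get("confusions", []) if isinstance(results, dict) else results
    rows = []
    for rec in records:
        post, jack = rec.get("post_hoc"), rec.get("jackknife")
        row = {"analysis": rec["analysis"]}
        if post:
            row["accuracy"] = post["accuracy"]
            row["mcc"] = post["mcc"]
        if jack:
            row["jackknife_accuracy"] = jack["accuracy"]
            row["jackknife_mcc"] = jack["mcc"]
        if post and jack:
            row["rendered"] = (f"{post['accuracy']:.2f} ({jack['accuracy']:.2f}) / "
                               f"MCC {post['mcc']:.2f} ({jack['mcc']:.2f})")
        elif post:
            row["rendered"] = f"{post['accuracy']:.2f} / MCC {post['mcc']:.2f}"
        rows.append(row)
    return pd.DataFrame(rows)
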