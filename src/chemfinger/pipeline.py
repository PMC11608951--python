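"""End-to-end experiment runner: synth -> tokenize -> prior -> evaluate -> grade.

`run_all` chains the whole benchmark for the three base data types (HPLC,
FTIR, low-level fused) and their augmented counterparts, writing CSV
artifacts: stage-1 loss traces, generation-quality reports, projection
coordinates, per-grade metric tables, confusion matrices and a JSON
manifest of seeds, sizes and the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import quality
from .fingerprints import (DEFAULT_CLASS_SIZES, DEFAULT_GENERATED_COUNTS, GRADES,
                           Fingerprint, default_profiles, fuse_low_level,
                           generate_ftir, generate_hplc, make_split,
                           save_fingerprints, values_matrix)
from .model import TimeVqvae
from .plsda import results_to_frame, run_experiment
from .prior import PriorConfig
from .quality import FcnConfig, evaluate_generation, projection_panels, train_fcn
from .vq import Stage1Config


@dataclass
class RunConfig:
    """Configuration of a full benchmark run.

    ``profile`` presets: "smoke" (minutes on one CPU) and "full"
    (full signal lengths and iteration counts).
    """

    seed: int = 0
    hplc_length: int = 512
    ftir_length: int = 256
    class_sizes: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    generated_counts: dict = field(
        default_factory=lambda: dict(DEFAULT_GENERATED_COUNTS))
    test_fraction: float = 0.3
    real_test_size: int | None = 35
    mixed_test: bool = True
    effect: float = 1.0
    noise_sd: float = 0.01
    stage1_iterations: int = 400
    prior_steps: int = 300
    fcn_iterations: int = 250
    n_lv: int | None = 6
    max_lv: int = 15
    folds: int = 10
    outdir: str = "chemfinger_run"

    @classmethod
    def profile(cls, name: str, **overrides) -> "RunConfig":
        if name == "smoke":
            base = cls(hplc_length=256, ftir_length=128,
                       class_sizes={"H": 12, "M": 12, "L": 12},
                       generated_counts={"H": 12, "M": 12, "L": 12},
                       real_test_size=None, stage1_iterations=60,
                       prior_steps=60, fcn_iterations=60, n_lv=3, folds=4)
        elif name == "full":
            base = cls(hplc_length=9000, ftir_length=1869,
                       stage1_iterations=5000, prior_steps=5000,
                       fcn_iterations=2000, n_lv=None)
        elif name == "desk":
            base = cls()
        else:
            raise ValueError(f"unknown profile {name!r}")
        return replace(base, **overrides)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        profile = raw.pop("profile", "desk")
        return cls.profile(profile, **raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _seed(config: RunConfig, offset: int) -> int:
    # single global seed fanned out per stage by fixed offsets
    return (config.seed * 1000 + offset) % (2 ** 31 - 1)


def synthesize_cohort(config: RunConfig) -> dict[str, list[Fingerprint]]:
    """Real-standing synthetic cohort for the three base data types."""
    profiles = default_profiles(effect=config.effect, noise_sd=config.noise_sd)
    hplc: list[Fingerprint] = []
    ftir: list[Fingerprint] = []
    for k, g in enumerate(GRADES):
        n = config.class_sizes[g]
        hplc += generate_hplc(profiles[g], n, seed=_seed(config, k),
                              length=config.hplc_length)
        ftir += generate_ftir(profiles[g], n, seed=_seed(config, 10 + k),
                              length=config.ftir_length)
    # paired measurements of the same batch share one sample id
    for i, (h, f) in enumerate(zip(hplc, ftir)):
        h.sample_id = f"HPLC-{h.grade}-{i:04d}"
        f.sample_id = f"FTIR-{f.grade}-{i:04d}"
    fused = [fuse_low_level(h, f) for h, f in zip(hplc, ftir)]
    return {"HPLC": hplc, "FTIR": ftir, "HPLC-FTIR": fused}


def run_all(config: RunConfig) -> dict:
    """Run the full benchmark; returns the artifact bundle and writes CSVs."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    datasets = synthesize_cohort(config)
    artifacts: dict = {"config": config, "datasets": datasets}
    manifest = {"seed": config.seed, "config": asdict(config),
                "config_hash": config.config_hash(), "stages": {}}
    eval_reports = []
    experiment_results = []
    for j, base in enumerate(["HPLC", "FTIR", "HPLC-FTIR"]):
        real = datasets[base]
        split = make_split(real, [], test_fraction=config.test_fraction,
                           seed=_seed(config, 40 + j),
                           real_test_size=config.real_test_size)
        train_real = [real[i] for i in split.train_real]
        # stage 1 + stage 2 on the training portion only (no leakage)
        gen_model = TimeVqvae(
            train_real,
            stage1_config=Stage1Config(iterations=config.stage1_iterations,
                                       seed=_seed(config, 100 + j)),
            prior_config=PriorConfig(steps=config.prior_steps,
                                     seed=_seed(config, 200 + j)))
        fitted = gen_model.fit()
        fitted.stage1.loss_trace.to_csv(out / f"loss_trace_{base}.csv", index=False)
        generated = fitted.generate_counts(config.generated_counts,
                                           seed=_seed(config, 300 + j))
        save_fingerprints(generated, str(out / f"generated_{base}.csv"))
        # quality scoring with a real-trained FCN
        X_real, y_real = values_matrix(real)
        Xg, _ = values_matrix(generated)
        fcn = train_fcn(X_real, y_real,
                        FcnConfig(iterations=config.fcn_iterations,
                                  seed=_seed(config, 400 + j)))
        eval_reports.append(evaluate_generation(fcn, X_real, Xg, base))
        ids = [f.sample_id for f in real] + [f.sample_id for f in generated]
        sources = ["real"] * len(real) + ["generated"] * len(generated)
        stackX = np.vstack([X_real, Xg])
        panels = projection_panels(stackX, fcn.features(stackX), ids, sources,
                                   seed=_seed(config, 500 + j))
        panels.to_csv(out / f"projections_{base}.csv", index=False)
        # classification: plain and augmented
        split_aug = make_split(real, generated,
                               test_fraction=config.test_fraction,
                               seed=_seed(config, 40 + j),
                               real_test_size=config.real_test_size,
                               mixed_test=config.mixed_test)
        for data_type, gen_list, sp in ((base, [], split),
                                        (f"{base}-TimeVQVAE", generated, split_aug)):
            res = run_experiment(data_type, real, gen_list, sp,
                                 n_lv=config.n_lv, max_lv=config.max_lv,
                                 folds=config.folds,
                                 seed=_seed(config, 600 + j))
            experiment_results.append(res)
            np.savetxt(out / f"confusion_{data_type}.csv",
                       res.test_metrics.confusion, fmt="%d", delimiter=",")
        manifest["stages"][base] = {
            "stage1_hash": fitted.stage1.state_hash(),
            "n_generated": len(generated),
            "train_real": int(split.train_real.size),
            "test_real": int(split.test_real.size)}
    eval_frame = quality.reports_to_frame(eval_reports)
    eval_frame.to_csv(out / "generation_quality.csv", index=False)
    metrics_frame = results_to_frame(experiment_results)
    metrics_frame.to_csv(out / "classification_metrics.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    artifacts.update(eval_reports=eval_frame, metrics=metrics_frame,
                     results=experiment_results, manifest=manifest)
    return artifacts
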