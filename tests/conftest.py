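"""Shared fixtures.

The expensive session fixtures train real models once and are reused by
several tests: `small_generator` is a tiny fitted two-stage generator for
contract checks, and `augmentation_study` runs the scarce-data
augmentation comparison (5 seeds, signal length 512, 20 real samples per
grade, 200 generated per grade) that several end-to-end properties read.
"""

from __future__ import annotations

import numpy as np
import pytest

from chemfinger import (FcnConfig, PriorConfig, Stage1Config, TimeVqvae,
                        default_profiles, generate_hplc, make_split,
                        run_experiment, train_fcn, values_matrix)


def cohort(profiles, n_per_grade, seed, length):
    out = []
    for k, g in enumerate("HML"):
        out += generate_hplc(profiles[g], n_per_grade, seed=seed * 100 + k,
                             length=length)
    return out


@pytest.fixture(scope="session")
def well_separated_profiles():
    return default_profiles(effect=1.5, noise_sd=0.01, height_jitter_sd=0.1)


@pytest.fixture(scope="session")
def small_cohort(well_separated_profiles):
    """12 samples of length 128, well separated grades."""
    return cohort(well_separated_profiles, 4, seed=3, length=128)


@pytest.fixture(scope="session")
def small_generator(small_cohort):
    """Tiny fitted two-stage generator (fast; used for contract checks)."""
    model = TimeVqvae(small_cohort,
                      stage1_config=Stage1Config(iterations=100, seed=5),
                      prior_config=PriorConfig(steps=120, seed=5))
    return model.fit()


@pytest.fixture(scope="session")
def augmentation_study():
    """Scarce-data augmentation comparison under moderate class overlap.

    Per seed: 20 real chromatograms per grade (length 512), a two-stage
    generator fitted on the real training split, 200 generated samples per
    grade, PLS-DA evaluated on the real-only test split with and without
    augmentation, and conditional fidelity of the generated samples under
    an FCN trained on all real data.
    """
    profiles = default_profiles(effect=0.6, noise_sd=0.05, height_jitter_sd=0.3)
    records = []
    for seed in range(5):
        real = cohort(profiles, 20, seed=seed, length=512)
        split0 = make_split(real, [], test_fraction=0.3, seed=seed)
        train_real = [real[i] for i in split0.train_real]
        fitted = TimeVqvae(
            train_real,
            stage1_config=Stage1Config(iterations=400, seed=seed),
            prior_config=PriorConfig(steps=300, seed=seed)).fit()
        generated = fitted.generate_counts({"H": 200, "M": 200, "L": 200},
                                           seed=seed)
        split = make_split(real, generated, test_fraction=0.3, seed=seed,
                           mixed_test=False)
        unaug = run_experiment("HPLC", real, [], split, n_lv=6)
        aug = run_experiment("HPLC-TimeVQVAE", real, generated, split, n_lv=6)
        X, y = values_matrix(real)
        Xg, yg = values_matrix(generated)
        fcn = train_fcn(X, y, FcnConfig(iterations=250, seed=seed))
        records.append({
            "seed": seed,
            "unaug_acc": unaug.test_metrics.overall_accuracy,
            "aug_acc": aug.test_metrics.overall_accuracy,
            "fidelity": float(np.mean(fcn.predict(Xg) == yg)),
            "real": real,
            "generated": generated,
        })
    return records
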