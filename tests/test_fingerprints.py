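"""Synthetic fingerprint generator, fusion and split bookkeeping."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from chemfinger.fingerprints import (FTIR_GRADE_WINDOW, FusionError,
                                     GradeProfile, ProfileError,
                                     StratificationError, default_profiles,
                                     fingerprints_to_frame,
                                     frame_to_fingerprints, fuse_low_level,
                                     generate_ftir, generate_hplc, make_split)


def noiseless(profile, **kw):
    from dataclasses import replace
    return replace(profile, noise_sd=0.0, baseline_drift_amplitude=0.0,
                   height_jitter_sd=0.0, **kw)


def test_single_noiseless_peak_has_unit_maximum_at_center():
    p = GradeProfile(grade="H", peak_centers=[30.0], peak_heights=[1.0],
                     peak_widths=[0.5], noise_sd=0.0,
                     baseline_drift_amplitude=0.0, height_jitter_sd=0.0)
    (fp,) = generate_hplc(p, 1, seed=0, length=601)
    assert fp.values.max() == pytest.approx(1.0)
    assert fp.axis[np.argmax(fp.values)] == pytest.approx(30.0)


def test_detected_peak_counts_follow_grade_order():
    profiles = default_profiles()
    mean_peaks = {}
    for g in "HML":
        fps = generate_hplc(profiles[g], 10, seed=11, length=2000)
        counts = [len(find_peaks(f.values, height=0.1 * f.values.max())[0])
                  for f in fps]
        mean_peaks[g] = np.mean(counts)
    assert mean_peaks["H"] > mean_peaks["M"] > mean_peaks["L"]


def test_generation_is_deterministic_per_seed():
    p = default_profiles()["M"]
    a = generate_hplc(p, 3, seed=9, length=256)
    b = generate_hplc(p, 3, seed=9, length=256)
    for fa, fb in zip(a, b):
        np.testing.assert_array_equal(fa.values, fb.values)
    c = generate_hplc(p, 3, seed=10, length=256)
    assert not np.array_equal(a[0].values, c[0].values)


def test_invalid_generation_arguments_raise():
    p = default_profiles()["L"]
    with pytest.raises(ValueError):
        generate_hplc(p, 0, seed=0)
    with pytest.raises(ProfileError):
        GradeProfile(grade="H", peak_centers=[1.0], peak_heights=[1.0],
                     peak_widths=[0.0])


def test_ftir_grade_signal_confined_to_fingerprint_window():
    profiles = default_profiles()
    lo, hi = FTIR_GRADE_WINDOW
    specs = {g: generate_ftir(noiseless(profiles[g]), 1, seed=0, length=1869)[0]
             for g in "HL"}
    diff = np.abs(specs["H"].values - specs["L"].values)
    axis = specs["H"].axis
    outside = (axis < lo - 100) | (axis > hi + 100)  # allow band tails
    assert diff[outside].max() < 1e-4
    inside = (axis >= lo) & (axis <= hi)
    assert diff[inside].max() > 0.05


def test_default_cohort_class_sizes():
    profiles = default_profiles()
    sizes = {"H": 44, "M": 60, "L": 33}
    fps = []
    for g, n in sizes.items():
        fps += generate_ftir(profiles[g], n, seed=1, length=64)
    labels = [f.grade for f in fps]
    assert [labels.count(g) for g in "HML"] == [44, 60, 33]


def test_zero_band_profile_yields_zero_spectrum():
    p = GradeProfile(grade="M", band_centers=[1200.0], band_heights=[0.0],
                     band_widths=[10.0], noise_sd=0.0,
                     baseline_drift_amplitude=0.0, height_jitter_sd=0.0)
    (fp,) = generate_ftir(p, 1, seed=0, length=128)
    np.testing.assert_allclose(fp.values, 0.0)


class TestFusion:
    def test_full_length_fusion(self):
        p = noiseless(default_profiles()["H"])
        (h,) = generate_hplc(p, 1, seed=0, length=9000)
        (f,) = generate_ftir(p, 1, seed=0, length=1869)
        f.sample_id = h.sample_id = "S-0"
        fused = fuse_low_level(h, f)
        assert len(fused) == 10869
        assert fused.modality == "FUSED"

    def test_toy_concatenation_order(self):
        from chemfinger.fingerprints import Fingerprint
        h = Fingerprint("s", "H", "HPLC", [1, 2, 3, 4], [0, 1, 2, 3])
        f = Fingerprint("s", "H", "FTIR", [5, 6, 7], [9, 8, 7])
        np.testing.assert_array_equal(fuse_low_level(h, f).values,
                                      [1, 2, 3, 4, 5, 6, 7])

    def test_modality_and_grade_mismatches_raise(self):
        from chemfinger.fingerprints import Fingerprint
        h = Fingerprint("s", "H", "HPLC", [1.0], [0.0])
        with pytest.raises(FusionError):
            fuse_low_level(h, h)  # fusing with itself: not an FTIR partner
        f = Fingerprint("s", "L", "FTIR", [1.0], [0.0])
        with pytest.raises(FusionError):
            fuse_low_level(h, f)


class TestMakeSplit:
    def cohort(self, sizes):
        from chemfinger.fingerprints import Fingerprint
        return [Fingerprint(f"s{i}-{g}", g, "HPLC", [0.0], [0.0])
                for g, n in sizes.items() for i in range(n)]

    def test_benchmark_arithmetic_with_generation(self):
        real = self.cohort({"H": 44, "M": 60, "L": 33})
        gen = self.cohort({"H": 298, "M": 311, "L": 291})
        plan = make_split(real, gen, test_fraction=0.3, seed=0,
                          real_test_size=35)
        assert (plan.n_train, plan.n_test) == (732, 305)

    def test_benchmark_arithmetic_real_only(self):
        real = self.cohort({"H": 44, "M": 60, "L": 33})
        plan = make_split(real, [], test_fraction=0.3, seed=0,
                          real_test_size=35)
        assert (plan.n_train, plan.n_test) == (102, 35)

    def test_same_seed_reproduces_indices(self):
        real = self.cohort({"H": 10, "M": 12, "L": 9})
        gen = self.cohort({"H": 20, "M": 20, "L": 20})
        a = make_split(real, gen, 0.3, seed=4)
        b = make_split(real, gen, 0.3, seed=4)
        np.testing.assert_array_equal(a.train_real, b.train_real)
        np.testing.assert_array_equal(a.test_generated, b.test_generated)

    def test_partition_is_disjoint_and_stratified(self):
        real = self.cohort({"H": 21, "M": 34, "L": 13})
        plan = make_split(real, [], test_fraction=0.25, seed=2)
        train, test = set(plan.train_real), set(plan.test_real)
        assert not train & test
        assert train | test == set(range(len(real)))
        labels = np.array([f.grade for f in real])
        global_frac = plan.test_real.size / len(real)
        for g in "HML":
            members = np.flatnonzero(labels == g)
            got = np.isin(members, plan.test_real).sum()
            assert abs(got - global_frac * members.size) <= 1.0

    def test_missing_grade_raises(self):
        real = self.cohort({"H": 5, "M": 5})
        with pytest.raises(StratificationError):
            make_split(real, [], 0.3, seed=0)


def test_csv_frame_round_trip():
    fps = generate_hplc(default_profiles()["M"], 3, seed=2, length=64)
    df = fingerprints_to_frame(fps)
    assert list(df.columns[:3]) == ["sample_id", "grade", "modality"]
    back = frame_to_fingerprints(df, fps[0].axis)
    for a, b in zip(fps, back):
        assert a.sample_id == b.sample_id and a.grade == b.grade
        np.testing.assert_allclose(a.values, b.values)
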