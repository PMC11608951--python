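"""Grade-structured synthetic HPLC / FTIR fingerprints and dataset splits.

The generator emulates a three-grade (H / M / L) herbal-material cohort:
chromatograms are sums of Gaussian peaks on a retention-time axis where
the high grade carries the most peaks, infrared spectra are sums of
absorption bands on a wavenumber axis whose grade-discriminating bands
sit only inside the 1,000-1,500 cm^-1 fingerprint region.  Per-sample
multiplicative peak-height jitter, a smooth quadratic baseline drift and
additive Gaussian noise stand in for instrument and preparation
variability.  Low-level data fusion is plain concatenation of the two
modalities, and `make_split` reproduces the stratified real/generated
train-test bookkeeping used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GRADES = ("H", "M", "L")
MODALITIES = ("HPLC", "FTIR", "FUSED")

#: default cohort sizes per grade (H, M, L)
DEFAULT_CLASS_SIZES = {"H": 44, "M": 60, "L": 33}
#: default generated-batch counts per grade
DEFAULT_GENERATED_COUNTS = {"H": 298, "M": 311, "L": 291}

HPLC_LENGTH = 9000
FTIR_LENGTH = 1869
HPLC_TIME_RANGE = (0.0, 60.0)       # minutes
FTIR_WAVENUMBER_RANGE = (4000.0, 400.0)  # cm^-1, descending
FTIR_GRADE_WINDOW = (1000.0, 1500.0)     # cm^-1 region carrying grade signal


class ProfileError(ValueError):
    pass


class FusionError(ValueError):
    pass


class StratificationError(ValueError):
    pass


@dataclass
class Fingerprint:
    """One sample's 1-D instrument trace with its grade label."""

    sample_id: str
    grade: str
    modality: str
    values: np.ndarray
    axis: np.ndarray

    def __post_init__(self):
        if self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        self.axis = np.asarray(self.axis, dtype=np.float64)
        if self.values.shape != self.axis.shape or self.values.ndim != 1:
            raise ValueError("values and axis must be 1-D and equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in fingerprint")

    def __len__(self):
        return self.values.size


@dataclass
class GradeProfile:
    """Ground-truth peak/band layout for one grade.

    Chromatographic peaks are parameterised on the retention-time axis
    (minutes), infrared bands on the wavenumber axis (cm^-1).  Heights are
    jittered per sample by a log-normal factor of spread
    ``height_jitter_sd``; ``noise_sd`` is additive white noise and
    ``baseline_drift_amplitude`` scales a random quadratic baseline.
    """

    grade: str
    peak_centers: np.ndarray = field(default_factory=lambda: np.empty(0))
    peak_heights: np.ndarray = field(default_factory=lambda: np.empty(0))
    peak_widths: np.ndarray = field(default_factory=lambda: np.empty(0))
    band_centers: np.ndarray = field(default_factory=lambda: np.empty(0))
    band_heights: np.ndarray = field(default_factory=lambda: np.empty(0))
    band_widths: np.ndarray = field(default_factory=lambda: np.empty(0))
    noise_sd: float = 0.01
    baseline_drift_amplitude: float = 0.02
    height_jitter_sd: float = 0.15

    def __post_init__(self):
        for name in ("peak_centers", "peak_heights", "peak_widths",
                     "band_centers", "band_heights", "band_widths"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name),
                                                         dtype=np.float64)))
        if self.peak_centers.size and not (
                self.peak_centers.size == self.peak_heights.size == self.peak_widths.size):
            raise ProfileError("peak arrays must share a length")
        if self.band_centers.size and not (
                self.band_centers.size == self.band_heights.size == self.band_widths.size):
            raise ProfileError("band arrays must share a length")
        if np.any(self.peak_widths <= 0) or np.any(self.band_widths <= 0):
            raise ProfileError("widths must be positive")
        if self.noise_sd < 0 or self.baseline_drift_amplitude < 0:
            raise ProfileError("noise parameters must be non-negative")

    @property
    def peak_count(self) -> int:
        return int(self.peak_centers.size)


# deterministic default layouts -------------------------------------------

# ten peaks common to all grades; M adds four, H adds eight (18/14/10 total)
_BASE_PEAKS = np.array([4.0, 9.5, 14.0, 19.5, 25.0, 31.0, 36.5, 42.0, 48.5, 55.0])
_M_EXTRA = np.array([7.0, 22.5, 33.5, 51.5])
_H_EXTRA = np.array([6.0, 12.0, 17.0, 27.5, 34.5, 40.0, 46.0, 53.0])

# grade-invariant infrared bands (outside the discriminating window)
_SHARED_BANDS = np.array([3400.0, 2920.0, 2850.0, 1710.0, 1620.0, 870.0, 720.0, 580.0])
_SHARED_BAND_H = np.array([0.55, 0.40, 0.30, 0.65, 0.80, 0.25, 0.30, 0.20])
_SHARED_BAND_W = np.array([120.0, 45.0, 40.0, 35.0, 40.0, 25.0, 22.0, 30.0])

# discriminating bands, all inside 1,000-1,500 cm^-1
_GRADE_BANDS = np.array([1050.0, 1160.0, 1270.0, 1380.0, 1460.0])
_GRADE_BAND_W = np.array([28.0, 32.0, 30.0, 26.0, 30.0])
_GRADE_BAND_BASE = np.array([0.45, 0.40, 0.50, 0.35, 0.40])
# per-grade multiplicative offsets on the discriminating bands
_GRADE_BAND_DELTA = {
    "H": np.array([0.9, 0.5, -0.3, 0.7, 0.2]),
    "M": np.array([0.2, -0.2, 0.4, -0.1, -0.4]),
    "L": np.array([-0.6, 0.6, -0.5, -0.5, 0.5]),
}


def default_profiles(effect: float = 1.0, noise_sd: float = 0.01,
                     baseline_drift_amplitude: float = 0.02,
                     height_jitter_sd: float = 0.15) -> dict[str, GradeProfile]:
    """Default H/M/L ground truth.

    ``effect`` scales the between-grade differences (extra HPLC peak
    heights and infrared band-height offsets); at 0 the three grades are
    identical in expectation, larger values make them easier to separate.
    """
    profiles = {}
    for grade in GRADES:
        extra = {"H": np.concatenate([_M_EXTRA, _H_EXTRA]),
                 "M": _M_EXTRA, "L": np.empty(0)}[grade]
        centers = np.concatenate([_BASE_PEAKS, extra])
        n_base = _BASE_PEAKS.size
        heights = np.concatenate([
            0.6 + 0.4 * np.cos(np.arange(n_base)),  # shared, grade-invariant
            np.clip(effect, 0.0, None) * (0.45 + 0.25 * np.sin(np.arange(extra.size))),
        ])
        widths = np.full(centers.size, 0.35)
        band_heights = np.concatenate([
            _SHARED_BAND_H,
            np.clip(_GRADE_BAND_BASE * (1.0 + effect * _GRADE_BAND_DELTA[grade]),
                    0.02, None),
        ])
        profiles[grade] = GradeProfile(
            grade=grade,
            peak_centers=centers,
            peak_heights=heights,
            peak_widths=widths,
            band_centers=np.concatenate([_SHARED_BANDS, _GRADE_BANDS]),
            band_heights=band_heights,
            band_widths=np.concatenate([_SHARED_BAND_W, _GRADE_BAND_W]),
            noise_sd=noise_sd,
            baseline_drift_amplitude=baseline_drift_amplitude,
            height_jitter_sd=height_jitter_sd,
        )
    return profiles


def _gaussian_mixture(axis: np.ndarray, centers: np.ndarray, heights: np.ndarray,
                      widths: np.ndarray) -> np.ndarray:
    out = np.zeros_like(axis)
    for c, h, w in zip(centers, heights, widths):
        out += h * np.exp(-0.5 * ((axis - c) / w) ** 2)
    return out


def _instrument_effects(rng: np.random.Generator, axis: np.ndarray,
                        profile: GradeProfile) -> np.ndarray:
    t = np.linspace(-1.0, 1.0, axis.size)
    coeffs = rng.normal(size=3)
    baseline = profile.baseline_drift_amplitude * (
        coeffs[0] + coeffs[1] * t + coeffs[2] * t ** 2)
    noise = rng.normal(0.0, profile.noise_sd, size=axis.size) if profile.noise_sd else 0.0
    return baseline + noise


def _generate(profile: GradeProfile, n: int, seed: int, axis: np.ndarray,
              centers, heights, widths, modality: str) -> list[Fingerprint]:
    if n < 1:
        raise ValueError("n must be a positive integer")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        jitter = (rng.lognormal(0.0, profile.height_jitter_sd, size=heights.size)
                  if profile.height_jitter_sd > 0 else np.ones(heights.size))
        values = _gaussian_mixture(axis, centers, heights * jitter, widths)
        values = values + _instrument_effects(rng, axis, profile)
        out.append(Fingerprint(
            sample_id=f"{modality}-{profile.grade}-{seed}-{i:04d}",
            grade=profile.grade, modality=modality, values=values, axis=axis))
    return out


def generate_hplc(profile: GradeProfile, n: int, seed: int,
                  length: int = HPLC_LENGTH,
                  time_range: tuple[float, float] = HPLC_TIME_RANGE) -> list[Fingerprint]:
    """Simulate `n` chromatograms for one grade; deterministic per seed."""
    axis = np.linspace(*time_range, length)
    return _generate(profile, n, seed, axis, profile.peak_centers,
                     profile.peak_heights, profile.peak_widths, "HPLC")


def generate_ftir(profile: GradeProfile, n: int, seed: int,
                  length: int = FTIR_LENGTH,
                  wavenumber_range: tuple[float, float] = FTIR_WAVENUMBER_RANGE
                  ) -> list[Fingerprint]:
    """Simulate `n` infrared spectra for one grade; deterministic per seed."""
    axis = np.linspace(*wavenumber_range, length)
    return _generate(profile, n, seed, axis, profile.band_centers,
                     profile.band_heights, profile.band_widths, "FTIR")


def generate_cohort(profiles: dict[str, GradeProfile] | None = None,
                    class_sizes: dict[str, int] | None = None,
                    seed: int = 0, modality: str = "HPLC",
                    length: int | None = None) -> list[Fingerprint]:
    """Generate a full graded cohort (default sizes 44/60/33 for H/M/L)."""
    profiles = profiles or default_profiles()
    class_sizes = class_sizes or dict(DEFAULT_CLASS_SIZES)
    gen = generate_hplc if modality == "HPLC" else generate_ftir
    kwargs = {} if length is None else {"length": length}
    out: list[Fingerprint] = []
    for k, grade in enumerate(GRADES):
        out.extend(gen(profiles[grade], class_sizes[grade],
                       seed=seed * 7919 + k, **kwargs))
    return out


def fuse_low_level(hplc: Fingerprint, ftir: Fingerprint,
                   standardize: bool = False) -> Fingerprint:
    """Low-level data fusion: concatenate the two raw traces.

    With ``standardize`` each block is centred and scaled to unit overall
    standard deviation before concatenation (off by default: the raw
    concatenation is the reference protocol).
    """
    if hplc.modality != "HPLC" or ftir.modality != "FTIR":
        raise FusionError("fusion requires one HPLC and one FTIR fingerprint")

    def core(fp):  # sample identity with any modality prefix stripped
        prefix = fp.modality + "-"
        return fp.sample_id[len(prefix):] if fp.sample_id.startswith(prefix) \
            else fp.sample_id

    if core(hplc) != core(ftir):
        raise FusionError("sample_id mismatch")
    if hplc.grade != ftir.grade:
        raise FusionError("grade mismatch")
    a, b = hplc.values, ftir.values
    if standardize:
        a = (a - a.mean()) / (a.std() or 1.0)
        b = (b - b.mean()) / (b.std() or 1.0)
    return Fingerprint(
        sample_id=f"FUSED-{hplc.sample_id.split('-', 1)[-1]}",
        grade=hplc.grade, modality="FUSED",
        values=np.concatenate([a, b]),
        axis=np.concatenate([hplc.axis, ftir.axis]))


# ---------------------------------------------------------------------------
# train/test partitioning


@dataclass
class SplitPlan:
    """Index bookkeeping for a real + generated train/test partition."""

    train_real: np.ndarray
    test_real: np.ndarray
    train_generated: np.ndarray
    test_generated: np.ndarray
    mixed_test: bool = True

    @property
    def n_train(self) -> int:
        return self.train_real.size + self.train_generated.size

    @property
    def n_test(self) -> int:
        if self.mixed_test:
            return self.test_real.size + self.test_generated.size
        return self.test_real.size


def _largest_remainder(counts: np.ndarray, total: int) -> np.ndarray:
    """Allocate `total` across strata proportionally to `counts`."""
    if total > counts.sum():
        raise StratificationError("requested test size exceeds population")
    quota = counts * total / counts.sum()
    alloc = np.floor(quota).astype(int)
    rem = quota - alloc
    for i in np.argsort(-rem)[: total - alloc.sum()]:
        alloc[i] += 1
    return alloc


def _stratified_pick(labels: list[str], n_test: int,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    grades = [g for g in GRADES if g in labels]
    counts = np.array([(labels == g).sum() for g in grades])
    alloc = _largest_remainder(counts, n_test)
    test_idx = []
    for g, k in zip(grades, alloc):
        members = np.flatnonzero(labels == g)
        test_idx.extend(rng.permutation(members)[:k])
    test_idx = np.sort(np.array(test_idx, dtype=int))
    train_idx = np.setdiff1d(np.arange(labels.size), test_idx)
    return train_idx, test_idx


def make_split(real: list[Fingerprint], generated: list[Fingerprint],
               test_fraction: float = 0.3, seed: int = 0,
               real_test_size: int | None = None,
               mixed_test: bool = True) -> SplitPlan:
    """Stratified-by-grade partition of real and generated samples.

    The real cohort is split with ``real_test_size`` held-out samples
    (default: ``round(n_real * test_fraction)``); generated samples are
    allocated train/test at ``test_fraction``.  Per-grade counts follow a
    largest-remainder rule so each grade's proportion is within one sample
    of the global one.  ``mixed_test`` selects whether evaluation uses the
    real+generated test pool or the real samples only.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    real_labels = [f.grade for f in real]
    missing = [g for g in GRADES if g not in real_labels]
    if missing:
        raise StratificationError(f"grades absent from real data: {missing}")
    rng = np.random.default_rng(seed)
    n_test_real = (real_test_size if real_test_size is not None
                   else int(round(len(real) * test_fraction)))
    train_r, test_r = _stratified_pick(real_labels, n_test_real, rng)
    if generated:
        n_test_gen = int(round(len(generated) * test_fraction))
        train_g, test_g = _stratified_pick([f.grade for f in generated],
                                           n_test_gen, rng)
    else:
        train_g = test_g = np.empty(0, dtype=int)
    return SplitPlan(train_real=train_r, test_real=test_r,
                     train_generated=train_g, test_generated=test_g,
                     mixed_test=mixed_test)


# ---------------------------------------------------------------------------
# CSV interchange: one row per sample, wide value columns, axis in a sidecar


def fingerprints_to_frame(fps: list[Fingerprint]) -> pd.DataFrame:
    if not fps:
        return pd.DataFrame(columns=["sample_id", "grade", "modality"])
    L = len(fps[0])
    if any(len(f) != L for f in fps):
        raise ValueError("all fingerprints must share a length")
    meta = pd.DataFrame({"sample_id": [f.sample_id for f in fps],
                         "grade": [f.grade for f in fps],
                         "modality": [f.modality for f in fps]})
    vals = pd.DataFrame(np.stack([f.values for f in fps]),
                        columns=[f"v{i}" for i in range(L)])
    return pd.concat([meta, vals], axis=1)


def frame_to_fingerprints(df: pd.DataFrame, axis: np.ndarray) -> list[Fingerprint]:
    value_cols = [c for c in df.columns if c.startswith("v")]
    return [Fingerprint(sample_id=row.sample_id, grade=row.grade,
                        modality=row.modality,
                        values=df.loc[row.Index, value_cols].to_numpy(float),
                        axis=axis)
            for row in df.itertuples()]


def save_fingerprints(fps: list[Fingerprint], path: str):
    fingerprints_to_frame(fps).to_csv(path, index=False)
    if fps:
        pd.DataFrame({"axis": fps[0].axis}).to_csv(
            str(path).replace(".csv", "") + ".axis.csv", index=False)


def load_fingerprints(path: str) -> list[Fingerprint]:
    df = pd.read_csv(path)
    axis_path = str(path).replace(".csv", "") + ".axis.csv"
    axis = pd.read_csv(axis_path)["axis"].to_numpy(float)
    return frame_to_fingerprints(df, axis)


def values_matrix(fps: list[Fingerprint]) -> tuple[np.ndarray, np.ndarray]:
    """Stack fingerprints into (n_samples, n_channels) X plus grade labels."""
    X = np.stack([f.values for f in fps])
    y = np.array([f.grade for f in fps])
    return X, y
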