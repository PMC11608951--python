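"""Time-frequency representation: invertible STFT, inverse, band split.

The transform is a one-sided short-time Fourier transform with a periodic
Hann window and centred zero-padding; inversion is synthesis-windowed
overlap-add normalised by the window-square envelope, which is exact for
consistent spectrograms.  The same analysis/synthesis matrices drive a
differentiable inverse used inside the tokenizer's reconstruction loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autodiff import Tensor


def default_window_length(signal_length: int) -> int:
    return 64 if signal_length >= 1024 else 16


@dataclass
class Spectrogram:
    """One-sided STFT of a real signal: u is complex (F, T)."""

    u: np.ndarray
    window_length: int
    hop: int
    original_length: int

    @property
    def n_bins(self) -> int:
        return self.u.shape[0]

    @property
    def n_frames(self) -> int:
        return self.u.shape[1]

    def energy(self) -> float:
        return float(np.sum(np.abs(self.u) ** 2))


@dataclass
class BandPair:
    """Exact low/high-band partition of a spectrogram (zero-padded halves)."""

    u_LF: np.ndarray
    u_HF: np.ndarray
    cutoff_bin: int
    window_length: int
    hop: int
    original_length: int

    def as_spectrograms(self) -> tuple[Spectrogram, Spectrogram]:
        mk = lambda u: Spectrogram(u, self.window_length, self.hop,
                                   self.original_length)
        return mk(self.u_LF), mk(self.u_HF)


def _hann(n: int) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))


def _geometry(length: int, win: int, hop: int) -> tuple[int, int, int]:
    """(pad_left, padded_length, n_frames) for centred framing."""
    pad = win // 2
    lp = length + 2 * pad
    if (lp - win) % hop:
        lp += hop - (lp - win) % hop
    n_frames = (lp - win) // hop + 1
    return pad, lp, n_frames


def _frame(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    """(..., L) -> (..., T, win) centred frames."""
    pad, lp, T = _geometry(x.shape[-1], win, hop)
    widths = [(0, 0)] * (x.ndim - 1) + [(pad, lp - pad - x.shape[-1])]
    xp = np.pad(x, widths)
    s = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, shape=(*xp.shape[:-1], T, win),
        strides=(*s[:-1], s[-1] * hop, s[-1])).copy()


def stft(x: np.ndarray, window_length: int | None = None,
         hop: int | None = None) -> Spectrogram:
    """One-sided Hann STFT of a real 1-D signal."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("stft expects a 1-D signal")
    win = window_length or default_window_length(x.size)
    if win % 2 or win > x.size:
        raise ValueError("window_length must be even and no longer than the signal")
    hop = hop or win // 2
    if hop > win:
        raise ValueError("hop must not exceed window_length")
    frames = _frame(x, win, hop) * _hann(win)
    u = np.fft.rfft(frames, axis=-1).T  # (F, T)
    return Spectrogram(u=u, window_length=win, hop=hop, original_length=x.size)


def _window_square_envelope(win: int, hop: int, n_frames: int, lp: int) -> np.ndarray:
    w2 = _hann(win) ** 2
    env = np.zeros(lp)
    for t in range(n_frames):
        env[t * hop:t * hop + win] += w2
    return np.maximum(env, 1e-12)


def istft(s: Spectrogram) -> np.ndarray:
    """Inverse STFT; exact round-trip for spectrograms produced by `stft`."""
    win, hop = s.window_length, s.hop
    pad, lp, T = _geometry(s.original_length, win, hop)
    if s.n_frames != T:
        raise ValueError("frame count inconsistent with original_length")
    frames = np.fft.irfft(s.u.T, n=win, axis=-1) * _hann(win)
    y = np.zeros(lp)
    for t in range(T):
        y[t * hop:t * hop + win] += frames[t]
    y /= _window_square_envelope(win, hop, T, lp)
    return y[pad:pad + s.original_length]


def stft_batch(X: np.ndarray, window_length: int, hop: int) -> np.ndarray:
    """Batched STFT: (B, L) -> complex (B, F, T)."""
    frames = _frame(X, window_length, hop) * _hann(window_length)
    return np.fft.rfft(frames, axis=-1).transpose(0, 2, 1)


def band_split(s: Spectrogram, cutoff_bin: int) -> BandPair:
    """Split into complementary zero-padded low/high-frequency spectrograms."""
    F = s.n_bins
    if not 0 < cutoff_bin < F:
        raise ValueError(f"cutoff_bin must lie in (0, {F})")
    u_LF = s.u.copy()
    u_LF[cutoff_bin:, :] = 0.0
    u_HF = s.u.copy()
    u_HF[:cutoff_bin, :] = 0.0
    return BandPair(u_LF=u_LF, u_HF=u_HF, cutoff_bin=cutoff_bin,
                    window_length=s.window_length, hop=s.hop,
                    original_length=s.original_length)


def band_masks(n_bins: int, cutoff_bin: int) -> tuple[np.ndarray, np.ndarray]:
    lf = np.zeros(n_bins)
    lf[:cutoff_bin] = 1.0
    return lf, 1.0 - lf


# ---------------------------------------------------------------------------
# differentiable inverse for the tokenizer's time-domain reconstruction loss


class DifferentiableISTFT:
    """Linear inverse-STFT operator acting on autodiff tensors.

    Input layout: (B, 2F, T) with real parts in the first F channels and
    imaginary parts in the last F.  Numerically identical to `istft`.
    """

    def __init__(self, window_length: int, hop: int, original_length: int):
        self.win, self.hop, self.length = window_length, hop, original_length
        self.pad, self.lp, self.T = _geometry(original_length, window_length, hop)
        N = window_length
        F = N // 2 + 1
        f = np.arange(F)[:, None]
        n = np.arange(N)[None, :]
        scale = np.full((F, 1), 2.0 / N)
        scale[0] = 1.0 / N
        if N % 2 == 0:
            scale[-1] = 1.0 / N
        ang = 2.0 * np.pi * f * n / N
        self.Mr = scale * np.cos(ang)          # (F, N)
        self.Mi = -scale * np.sin(ang)
        self.window = _hann(N)
        self.inv_env = 1.0 / _window_square_envelope(N, hop, self.T, self.lp)

    def __call__(self, u: Tensor) -> Tensor:
        F = self.Mr.shape[0]
        re = u[:, :F, :].transpose(0, 2, 1)    # (B, T, F)
        im = u[:, F:, :].transpose(0, 2, 1)
        frames = re @ Tensor(self.Mr) + im @ Tensor(self.Mi)   # (B, T, N)
        frames = frames * Tensor(self.window)
        y = frames.overlap_add(self.hop, self.lp) * Tensor(self.inv_env)
        return y[:, self.pad:self.pad + self.length]


def complex_to_channels(u: np.ndarray) -> np.ndarray:
    """(B, F, T) complex -> (B, 2F, T) real channel stack."""
    return np.concatenate([u.real, u.imag], axis=1)


def channels_to_complex(c: np.ndarray) -> np.ndarray:
    F = c.shape[1] // 2
    return c[:, :F, :] + 1j * c[:, F:, :]
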