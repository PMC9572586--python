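"""Frequency-domain feature extraction for the four classifier branches.

From one standardized waveform (10 kHz, 30,000 samples by default) we compute:

* a mel power spectrogram in dB (59 frames x 128 bands),
* MFCC: a 32-coefficient cosine-transform cepstrum of the mel dB matrix,
* LFCC: the same cepstrum computed over a *linearly* spaced triangular
  filter bank (better high-frequency resolution than the mel bank),
* a time-averaged 128-coefficient mel cepstrum (the 1-D branch input).

The filter banks are triangular in the FFT-bin variable: filter m rises
linearly from its lower breakpoint o(m) to 1.0 at its center c(m) and falls
to 0 at h(m), with c(m) = o(m+1) so adjacent filters overlap 50%.  The
breakpoints are equally spaced on the mel axis (HTK convention,
mel = 2595*log10(1 + f/700)) or on the Hz axis, then snapped to FFT bins so
every triangle attains exactly 1 at its center bin.

The cepstra use the plain (unnormalised) DCT-II kernel
``sum_m X(t, m) * cos(c*pi*(m - 0.5) / M)``; an orthonormal variant is
available for cross-checks against standard toolkits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

from .audio_io import Waveform

__all__ = [
    "STFTConfig",
    "FeatureConfig",
    "PowerSpectrogram",
    "FilterBank",
    "BandedSpectrogram",
    "CepstralMatrix",
    "FeatureSet",
    "stft_power",
    "hz_to_mel",
    "mel_to_hz",
    "make_filterbank",
    "apply_filterbank",
    "power_to_db",
    "dct_cepstra",
    "extract_feature_set",
    "to_branch_input",
]


# ---------------------------------------------------------------------------
# configuration and containers


@dataclass(frozen=True)
class STFTConfig:
    frame_len: int = 1024
    hop: int = 512
    window: str = "hann"
    periodic: bool = True  # periodic (DFT-even) taper; symmetric tapers make
    # the spectrogram exactly time-reversal symmetric
    centered: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.frame_len):
            raise ValueError(f"need 0 < hop <= frame_len, got hop={self.hop}, frame_len={self.frame_len}")


@dataclass(frozen=True)
class FeatureConfig:
    stft: STFTConfig = field(default_factory=STFTConfig)
    n_filters: int = 128
    n_cepstra: int = 32
    f_lo: float = 0.0
    f_hi: float | None = None  # None -> Nyquist
    db_floor: float = 1e-10

    def __post_init__(self) -> None:
        if self.n_filters < 1:
            raise ValueError("n_filters must be >= 1")
        if not (1 <= self.n_cepstra <= self.n_filters):
            raise ValueError("need 1 <= n_cepstra <= n_filters")


@dataclass(frozen=True)
class PowerSpectrogram:
    """|STFT|^2 matrix, frames x one-sided frequency bins (linear power)."""

    values: np.ndarray  # (L, K)
    frame_times: np.ndarray  # (L,) seconds
    bin_freqs: np.ndarray  # (K,) Hz

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FilterBank:
    """Triangular filters as a (bins x filters) weight matrix."""

    weights: np.ndarray  # (K, M)
    lo_hz: np.ndarray  # o(m)
    center_hz: np.ndarray  # c(m)
    hi_hz: np.ndarray  # h(m)
    scale: str  # "mel" | "linear"

    @property
    def n_filters(self) -> int:
        return self.weights.shape[1]

    @property
    def n_bins(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class BandedSpectrogram:
    values: np.ndarray  # (L, M)
    scale: str  # "power" | "db"


@dataclass(frozen=True)
class CepstralMatrix:
    values: np.ndarray  # (L, C)


@dataclass(frozen=True)
class FeatureSet:
    """The four per-clip branch inputs, all from one standardized waveform."""

    mel: BandedSpectrogram  # dB, (L, n_filters)
    mfcc: CepstralMatrix  # (L, n_cepstra)
    lfcc: CepstralMatrix  # (L, n_cepstra)
    mean_mfcc: np.ndarray  # (n_filters,)


# ---------------------------------------------------------------------------
# STFT


def stft_power(w: Waveform, cfg: STFTConfig = STFTConfig()) -> PowerSpectrogram:
    """Power spectrogram of a waveform.

    With centered frames (reflection padding by frame_len//2) the frame count
    is ``1 + len // hop`` — 59 frames for the default 30,000-sample clip at
    hop 512 — and K = frame_len//2 + 1 = 513 one-sided bins.
    """
    x = w.samples
    n, flen, hop = x.size, cfg.frame_len, cfg.hop
    if cfg.centered:
        pad = flen // 2
        x = np.pad(x, pad, mode="reflect")
        n_frames = 1 + n // hop
        t0 = 0.0
    else:
        if n < flen:
            raise ValueError(f"clip of {n} samples shorter than frame_len={flen} with centered=False")
        n_frames = 1 + (n - flen) // hop
        t0 = flen / 2 / w.sample_rate
    frames = sliding_window_view(x, flen)[:: hop][:n_frames]
    win = get_window(cfg.window, flen, fftbins=cfg.periodic)
    spec = np.fft.rfft(frames * win, axis=1)
    power = spec.real**2 + spec.imag**2
    times = t0 + np.arange(n_frames) * hop / w.sample_rate
    freqs = np.fft.rfftfreq(flen, 1.0 / w.sample_rate)
    return PowerSpectrogram(values=power, frame_times=times, bin_freqs=freqs)


# ---------------------------------------------------------------------------
# filter banks


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def make_filterbank(
    n_bins: int,
    n_filters: int,
    f_lo: float,
    f_hi: float,
    scale: str,
    sample_rate: int,
) -> FilterBank:
    """Build a triangular filter bank as a (n_bins x n_filters) matrix.

    M + 2 breakpoints are placed equally on the mel or Hz axis between f_lo
    and f_hi and snapped to the nearest FFT bin; filter m spans
    [o(m), h(m)] with apex exactly 1 at c(m) and shares its endpoints with
    its neighbours (o(m+1) = c(m), h(m) = c(m+1)).
    """
    if scale not in ("mel", "linear"):
        raise ValueError(f"unknown filter-bank scale {scale!r}")
    if n_filters < 1:
        raise ValueError("need at least one filter")
    if not (0 <= f_lo < f_hi <= sample_rate / 2):
        raise ValueError(f"need 0 <= f_lo < f_hi <= Nyquist, got [{f_lo}, {f_hi}] at rate {sample_rate}")
    n_fft = 2 * (n_bins - 1)
    df = sample_rate / n_fft
    if scale == "mel":
        pts_hz = mel_to_hz(np.linspace(hz_to_mel(f_lo), hz_to_mel(f_hi), n_filters + 2))
    else:
        pts_hz = np.linspace(f_lo, f_hi, n_filters + 2)
    bins = np.round(pts_hz / df).astype(int)
    bins = np.clip(bins, 0, n_bins - 1)
    weights = np.zeros((n_bins, n_filters))
    k = np.arange(n_bins, dtype=np.float64)
    for m in range(n_filters):
        o, c, h = bins[m], bins[m + 1], bins[m + 2]
        if not (o < c < h):
            raise ValueError(
                f"filter {m} narrower than one FFT bin (breakpoints {o}, {c}, {h}); "
                f"reduce n_filters or increase FFT size"
            )
        rise = (k - o) / (c - o)
        fall = (h - k) / (h - c)
        weights[:, m] = np.maximum(0.0, np.minimum(rise, fall))
    return FilterBank(
        weights=weights,
        lo_hz=bins[:-2] * df,
        center_hz=bins[1:-1] * df,
        hi_hz=bins[2:] * df,
        scale=scale,
    )


@lru_cache(maxsize=8)
def _cached_filterbank(n_bins, n_filters, f_lo, f_hi, scale, sample_rate) -> FilterBank:
    return make_filterbank(n_bins, n_filters, f_lo, f_hi, scale, sample_rate)


def apply_filterbank(P: PowerSpectrogram, B: FilterBank) -> BandedSpectrogram:
    """Project a power spectrogram through a filter bank (linear in P)."""
    if P.n_bins != B.n_bins:
        raise ValueError(f"spectrogram has {P.n_bins} bins but filter bank expects {B.n_bins}")
    return BandedSpectrogram(values=P.values @ B.weights, scale="power")


def power_to_db(X: BandedSpectrogram, floor_eps: float = 1e-10) -> BandedSpectrogram:
    """Convert linear band powers to decibels with a floor at ``floor_eps``."""
    if floor_eps <= 0:
        raise ValueError("floor_eps must be positive")
    if X.scale != "power":
        raise ValueError(f"expected linear power input, got scale {X.scale!r}")
    return BandedSpectrogram(values=10.0 * np.log10(np.maximum(X.values, floor_eps)), scale="db")


# ---------------------------------------------------------------------------
# cepstra


def dct_kernel(n_bands: int, n_cepstra: int, orthonormal: bool = False) -> np.ndarray:
    """Cosine kernel ``k[c, m] = cos(c*pi*(m + 0.5)/M)``, c = 0..C-1."""
    c = np.arange(n_cepstra)[:, None]
    m = np.arange(n_bands)[None, :]
    kern = np.cos(c * np.pi * (m + 0.5) / n_bands)
    if orthonormal:
        kern = kern * np.sqrt(2.0 / n_bands)
        kern[0] *= np.sqrt(0.5)
    return kern


def dct_cepstra(Xdb: BandedSpectrogram, n_cepstra: int, orthonormal: bool = False) -> CepstralMatrix:
    """Cepstrum of a dB-scale banded spectrogram.

    ``values[t, c] = sum_{m=1..M} Xdb[t, m] * cos(c*pi*(m - 0.5)/M)`` —
    the plain DCT-II sum, no normalisation unless ``orthonormal``.
    """
    M = Xdb.values.shape[1]
    if not (1 <= n_cepstra <= M):
        raise ValueError(f"need 1 <= n_cepstra <= {M}, got {n_cepstra}")
    kern = dct_kernel(M, n_cepstra, orthonormal=orthonormal)
    return CepstralMatrix(values=Xdb.values @ kern.T)


# ---------------------------------------------------------------------------
# full pipeline


def extract_feature_set(w: Waveform, cfg: FeatureConfig = FeatureConfig()) -> FeatureSet:
    """Compute the four branch features from one standardized waveform.

    mel  : dB mel-bank spectrogram, (L, n_filters)
    mfcc : n_cepstra-coefficient cepstrum of mel, (L, n_cepstra)
    lfcc : same but over a linear bank, (L, n_cepstra)
    mean_mfcc : full n_filters-coefficient mel cepstrum averaged over
                frames, (n_filters,)
    """
    P = stft_power(w, cfg.stft)
    f_hi = cfg.f_hi if cfg.f_hi is not None else w.sample_rate / 2
    mel_bank = _cached_filterbank(P.n_bins, cfg.n_filters, cfg.f_lo, f_hi, "mel", w.sample_rate)
    lin_bank = _cached_filterbank(P.n_bins, cfg.n_filters, cfg.f_lo, f_hi, "linear", w.sample_rate)
    mel_db = power_to_db(apply_filterbank(P, mel_bank), cfg.db_floor)
    lin_db = power_to_db(apply_filterbank(P, lin_bank), cfg.db_floor)
    mfcc = dct_cepstra(mel_db, cfg.n_cepstra)
    lfcc = dct_cepstra(lin_db, cfg.n_cepstra)
    full_mel_cepstrum = dct_cepstra(mel_db, cfg.n_filters)
    return FeatureSet(
        mel=mel_db,
        mfcc=mfcc,
        lfcc=lfcc,
        mean_mfcc=full_mel_cepstrum.values.mean(axis=0),
    )


def _resize_bilinear(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Separable bilinear resize with corner alignment (identity when the
    target matches the input shape)."""
    h_out, w_out = shape
    h_in, w_in = a.shape
    if h_out != h_in:
        coords = np.linspace(0.0, h_in - 1.0, h_out) if h_out > 1 else np.array([(h_in - 1) / 2.0])
        src = np.arange(h_in, dtype=np.float64)
        a = np.stack([np.interp(coords, src, a[:, j]) for j in range(a.shape[1])], axis=1)
    if w_out != w_in:
        coords = np.linspace(0.0, w_in - 1.0, w_out) if w_out > 1 else np.array([(w_in - 1) / 2.0])
        src = np.arange(w_in, dtype=np.float64)
        a = np.stack([np.interp(coords, src, a[i]) for i in range(a.shape[0])], axis=0)
    return a


def to_branch_input(F: np.ndarray, target_shape: tuple[int, int] | None = None, channels: int = 3) -> np.ndarray:
    """Turn a (time x frequency) feature matrix into a CNN branch input.

    Transposes to frequency x time, min-max scales each clip to [0, 1]
    (constant inputs map to zeros), bilinearly resizes to ``target_shape``
    (native shape if None), and replicates to ``channels`` identical planes.
    Returns (channels, H, W).
    """
    F = np.asarray(F, dtype=np.float64)
    if F.ndim != 2:
        raise ValueError(f"expected a 2-D feature matrix, got shape {F.shape}")
    if not np.all(np.isfinite(F)):
        raise ValueError("feature matrix contains non-finite values")
    G = F.T
    lo, hi = G.min(), G.max()
    G = np.zeros_like(G) if hi == lo else (G - lo) / (hi - lo)
    if target_shape is not None:
        G = _resize_bilinear(G, tuple(target_shape))
    return np.broadcast_to(G, (channels, *G.shape)).copy()
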