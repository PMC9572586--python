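"""Standardising clips to a fixed rate and length.

Every clip is resampled to a common rate (10 kHz by default) and then
cropped or zero-padded to a fixed number of samples (30,000 = 3 s), so the
feature extractors downstream see one constant shape.  Long clips keep a
contiguous random window; short clips get the deficit split randomly between
leading and trailing zeros.  Evaluation-time standardisation is deterministic
(center crop / symmetric pad) so that metrics are reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

from .audio_io import Waveform

__all__ = ["PreprocessConfig", "resample", "fix_length", "standardize"]


@dataclass(frozen=True)
class PreprocessConfig:
    target_rate: int = 10_000
    target_len: int = 30_000
    seed: int = 0
    eval_deterministic: bool = True

    def __post_init__(self) -> None:
        if self.target_rate <= 0:
            raise ValueError("target_rate must be positive")
        if self.target_len <= 0:
            raise ValueError("target_len must be positive")


def resample(w: Waveform, target_rate: int) -> Waveform:
    """Band-limited (polyphase) resampling to ``target_rate`` Hz.

    Duration is preserved to within one output sample.  Identity when the
    rate already matches.
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == w.sample_rate:
        return w
    frac = Fraction(int(target_rate), int(w.sample_rate))
    out = resample_poly(w.samples, frac.numerator, frac.denominator)
    return Waveform(out, target_rate)


def _derive_rng(seed: int, key: str | None) -> np.random.Generator:
    """Seeded generator, optionally keyed by a clip identifier.

    Keying by e.g. the clip path lets each clip draw its own crop offset
    while the whole corpus stays reproducible under one seed.
    """
    if key is None:
        return np.random.default_rng(seed)
    mix = zlib.crc32(key.encode("utf-8"))
    return np.random.default_rng((int(seed) * 2654435761 + mix) % (2**31))


def fix_length(
    w: Waveform,
    target_len: int,
    rng_seed: int = 0,
    *,
    key: str | None = None,
    deterministic: bool = False,
) -> Waveform:
    """Crop or zero-pad to exactly ``target_len`` samples.

    Longer inputs keep a contiguous window at a uniform-random offset; shorter
    inputs have the deficit D split as (d, D-d) zeros with d uniform on
    {0..D}.  With ``deterministic=True`` the window is centered and the pad
    symmetric.
    """
    if target_len <= 0:
        raise ValueError("target_len must be positive")
    n = len(w)
    if n == target_len:
        return w
    if n > target_len:
        max_off = n - target_len
        if deterministic:
            off = max_off // 2
        else:
            off = int(_derive_rng(rng_seed, key).integers(0, max_off + 1))
        return Waveform(w.samples[off : off + target_len], w.sample_rate)
    deficit = target_len - n
    if deterministic:
        left = deficit // 2
    else:
        left = int(_derive_rng(rng_seed, key).integers(0, deficit + 1))
    out = np.zeros(target_len, dtype=w.samples.dtype)
    out[left : left + n] = w.samples
    return Waveform(out, w.sample_rate)


def standardize(
    w: Waveform,
    cfg: PreprocessConfig,
    *,
    key: str | None = None,
    train: bool = False,
) -> Waveform:
    """Resample then fix length: the two-step standardisation.

    ``train=False`` with ``cfg.eval_deterministic`` gives center-crop /
    symmetric-pad; ``train=True`` draws a seeded random window per clip key.
    """
    w = resample(w, cfg.target_rate)
    deterministic = cfg.eval_deterministic and not train
    return fix_length(
        w, cfg.target_len, rng_seed=cfg.seed, key=key, deterministic=deterministic
    )
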