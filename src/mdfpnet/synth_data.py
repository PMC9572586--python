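"""Synthetic marine-mammal-like call generator.

Builds labeled WAV datasets from three parametric call families that caricature
the broad sound types of cetaceans:

* ``fm_whistle``     — a tonal with a sinusoidal frequency contour
  (dolphin-like whistles),
* ``click_train``    — periodic exponentially decaying resonant impulses
  (odontocete echolocation clicks),
* ``harmonic_moan``  — a low-fundamental harmonic stack with slow amplitude
  modulation (baleen-whale-like moans).

Six default classes are drawn from these families with disjoint parameter
ranges (two recipes per family), intentionally imbalanced per-class counts
(60/120/100/140/70/55 = 545 clips) to exercise the flip augmentation, mixed
sample rates and durations to exercise resampling and crop/pad, and additive
white Gaussian noise at a controlled SNR.  Everything is deterministic given
the config seed.  All spectral content sits below 4.8 kHz so it survives
resampling to the 10 kHz analysis rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .audio_io import ManifestRecord, Waveform, write_manifest, write_wav

__all__ = ["ClassRecipe", "SynthConfig", "default_recipes", "gen_call", "add_noise", "gen_dataset"]


@dataclass(frozen=True)
class ClassRecipe:
    """Parameter ranges for one synthetic species class."""

    name: str
    family: str  # fm_whistle | click_train | harmonic_moan
    count: int
    amplitude: float = 0.9
    # fm_whistle
    carrier_hz: tuple[float, float] = (1000.0, 1000.0)
    fm_depth_hz: tuple[float, float] = (0.0, 0.0)
    fm_rate_hz: tuple[float, float] = (3.0, 3.0)
    # click_train
    click_rate_hz: tuple[float, float] = (10.0, 10.0)
    resonance_hz: tuple[float, float] = (1500.0, 1500.0)
    decay_s: tuple[float, float] = (0.005, 0.005)
    # harmonic_moan
    f0_hz: tuple[float, float] = (150.0, 150.0)
    n_harmonics: int = 5
    am_rate_hz: tuple[float, float] = (1.5, 1.5)

    def __post_init__(self) -> None:
        if self.family not in ("fm_whistle", "click_train", "harmonic_moan"):
            raise ValueError(f"unknown call family {self.family!r}")
        if self.count < 1:
            raise ValueError("count must be >= 1")

    def max_frequency(self) -> float:
        """Highest spectral content the recipe can produce, in Hz."""
        if self.family == "fm_whistle":
            return self.carrier_hz[1] + self.fm_depth_hz[1]
        if self.family == "click_train":
            return self.resonance_hz[1]
        return self.f0_hz[1] * self.n_harmonics


def default_recipes() -> tuple[ClassRecipe, ...]:
    """Six classes, two per family, with disjoint spectral occupancy.

    A decaying resonant click train is spectrally narrow (a Lorentzian line
    at its resonance), so each class is also given its own frequency band to
    keep the classes identifiable from the spectral envelope alone:
    moans sit lowest (fundamental 120-480 Hz), whistles sweep the 500-1500
    and 2450-3850 Hz bands, click resonances occupy 2000-2400 and
    4100-4600 Hz.  Everything stays below 4.8 kHz, inside the analysis-rate
    Nyquist band.
    """
    return (
        ClassRecipe(
            name="whistle_low", family="fm_whistle", count=60,
            carrier_hz=(800.0, 1200.0), fm_depth_hz=(150.0, 300.0), fm_rate_hz=(2.0, 4.0),
        ),
        ClassRecipe(
            name="whistle_high", family="fm_whistle", count=120,
            carrier_hz=(2900.0, 3400.0), fm_depth_hz=(300.0, 450.0), fm_rate_hz=(6.0, 10.0),
        ),
        ClassRecipe(
            name="clicks_slow", family="click_train", count=100,
            click_rate_hz=(8.0, 15.0), resonance_hz=(2000.0, 2400.0), decay_s=(0.004, 0.008),
        ),
        ClassRecipe(
            name="clicks_fast", family="click_train", count=140,
            click_rate_hz=(45.0, 80.0), resonance_hz=(4100.0, 4600.0), decay_s=(0.002, 0.004),
        ),
        ClassRecipe(
            name="moan_low", family="harmonic_moan", count=70,
            f0_hz=(120.0, 180.0), n_harmonics=6, am_rate_hz=(1.0, 2.0),
        ),
        ClassRecipe(
            name="moan_high", family="harmonic_moan", count=55,
            f0_hz=(300.0, 480.0), n_harmonics=4, am_rate_hz=(3.0, 5.0),
        ),
    )


@dataclass(frozen=True)
class SynthConfig:
    recipes: tuple[ClassRecipe, ...] = field(default_factory=default_recipes)
    sample_rate_pool: tuple[int, ...] = (16_000, 22_050, 44_100)
    duration_range: tuple[float, float] = (1.0, 6.0)
    snr_db_range: tuple[float, float] = (20.0, 20.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_range[0] <= 0:
            raise ValueError("durations must be positive")
        if not np.all(np.isfinite(self.snr_db_range)):
            raise ValueError("SNR range must be finite")


def _uniform(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    return lo if lo == hi else float(rng.uniform(lo, hi))


def gen_call(recipe: ClassRecipe, duration: float, rate: int, rng: np.random.Generator) -> Waveform:
    """One clean synthetic call, peak-normalised to the recipe amplitude."""
    if recipe.max_frequency() >= rate / 2:
        raise ValueError(
            f"recipe {recipe.name!r} reaches {recipe.max_frequency():.0f} Hz, "
            f"beyond Nyquist of {rate} Hz"
        )
    n = max(1, int(round(duration * rate)))
    t = np.arange(n) / rate
    if recipe.family == "fm_whistle":
        carrier = _uniform(rng, recipe.carrier_hz)
        depth = _uniform(rng, recipe.fm_depth_hz)
        fm_rate = _uniform(rng, recipe.fm_rate_hz)
        phase0 = rng.uniform(0, 2 * np.pi)
        # instantaneous frequency carrier + depth*sin(2 pi fm_rate t)
        phase = 2 * np.pi * carrier * t + phase0
        if depth > 0:
            phase = phase - depth / fm_rate * (np.cos(2 * np.pi * fm_rate * t) - 1.0)
        x = np.sin(phase)
    elif recipe.family == "click_train":
        click_rate = _uniform(rng, recipe.click_rate_hz)
        resonance = _uniform(rng, recipe.resonance_hz)
        decay = _uniform(rng, recipe.decay_s)
        period = max(1, int(round(rate / click_rate)))
        x = np.zeros(n)
        click_len = min(n, max(8, int(round(5 * decay * rate))))
        tc = np.arange(click_len) / rate
        click = np.exp(-tc / decay) * np.sin(2 * np.pi * resonance * tc)
        for start in range(0, n, period):
            seg = min(click_len, n - start)
            x[start : start + seg] += click[:seg]
    else:  # harmonic_moan
        f0 = _uniform(rng, recipe.f0_hz)
        am_rate = _uniform(rng, recipe.am_rate_hz)
        phases = rng.uniform(0, 2 * np.pi, size=recipe.n_harmonics)
        x = np.zeros(n)
        for h in range(1, recipe.n_harmonics + 1):
            x += np.sin(2 * np.pi * h * f0 * t + phases[h - 1]) / h
        x *= (1.0 + 0.5 * np.sin(2 * np.pi * am_rate * t + rng.uniform(0, 2 * np.pi))) / 1.5
    peak = np.abs(x).max()
    if peak > 0 and recipe.amplitude > 0:
        x = x * (recipe.amplitude / peak)
    else:
        x = np.zeros(n)
    return Waveform(x, rate)


def add_noise(w: Waveform, snr_db: float, rng: np.random.Generator) -> Waveform:
    """Add white Gaussian noise at an exact realised signal-to-noise ratio."""
    p_sig = float(np.mean(w.samples**2))
    if p_sig == 0.0:
        raise ValueError("cannot set a finite SNR on a silent clip")
    noise = rng.standard_normal(len(w))
    p_noise = float(np.mean(noise**2))
    scale = np.sqrt(p_sig / (10.0 ** (snr_db / 10.0) * p_noise))
    return Waveform(w.samples + scale * noise, w.sample_rate)


def gen_dataset(cfg: SynthConfig, out_dir) -> list[ManifestRecord]:
    """Write the WAV tree and manifest for a full synthetic dataset.

    One directory per class under ``out_dir``; clips are peak-normalised to
    0.9 after noise so 16-bit encoding never clips.  A ``manifest.csv`` is
    written alongside.  Byte-identical output for identical seeds.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(cfg.seed)
    streams = master.spawn(len(cfg.recipes))
    records: list[ManifestRecord] = []
    for recipe, rng in zip(cfg.recipes, streams):
        cdir = out_dir / recipe.name
        cdir.mkdir(exist_ok=True)
        for i in range(recipe.count):
            rate = int(rng.choice(np.asarray(cfg.sample_rate_pool)))
            duration = _uniform(rng, cfg.duration_range)
            w = gen_call(recipe, duration, rate, rng)
            snr = _uniform(rng, cfg.snr_db_range)
            if np.any(w.samples != 0.0):
                w = add_noise(w, snr, rng)
            peak = np.abs(w.samples).max()
            if peak > 0:
                w = Waveform(w.samples * (0.9 / peak), w.sample_rate)
            path = cdir / f"{recipe.name}_{i:04d}.wav"
            write_wav(w, path)
            records.append(
                ManifestRecord(
                    path=str(path),
                    label=recipe.name,
                    duration_s=w.duration_s,
                    sample_rate=rate,
                    augmented=False,
                )
            )
    write_manifest(records, out_dir / "manifest.csv")
    return records
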