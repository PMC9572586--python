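import numpy as np
import pytest
from dataclasses import replace

from mdfpnet.audio_io import Waveform, write_wav
from mdfpnet.synth_data import SynthConfig, default_recipes, gen_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_wave():
    """1 s of a 1 kHz tone at 10 kHz."""
    t = np.arange(10_000) / 10_000
    return Waveform(0.5 * np.sin(2 * np.pi * 1000 * t), 10_000)


@pytest.fixture
def standard_clip(rng):
    """A 30,000-sample, 10 kHz noise clip (the standardized shape)."""
    return Waveform(0.1 * rng.normal(size=30_000), 10_000)


@pytest.fixture
def wav_tree(tmp_path, rng):
    """Directory tree with 3 classes x 2 clips, plus one non-WAV distractor."""
    root = tmp_path / "tree"
    for cls in ("alpha", "beta", "gamma"):
        d = root / cls
        d.mkdir(parents=True)
        for i in range(2):
            w = Waveform(0.3 * rng.normal(size=4000), 8000)
            write_wav(w, d / f"{cls}_{i}.wav")
    (root / "alpha" / "notes.txt").write_text("not audio")
    return root


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A reduced synthetic dataset (12 clips/class) shared across tests."""
    out = tmp_path_factory.mktemp("synthdata")
    recipes = tuple(replace(r, count=12) for r in default_recipes())
    cfg = SynthConfig(recipes=recipes, duration_range=(1.0, 4.0), seed=7)
    records = gen_dataset(cfg, out)
    return cfg, records
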