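"""Reading, writing and cataloguing single-channel WAV clips.

Passive-acoustic-monitoring archives are heterogeneous: clips arrive at
anything from 5.12 kHz to 192 kHz, in integer PCM or float encodings, with
wildly different durations.  This module normalises every clip into a single
in-memory representation (:class:`Waveform`, float samples in [-1, 1] plus a
sample rate) and builds the CSV manifest that the rest of the pipeline uses
for reproducible splits and augmentation bookkeeping.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.io import wavfile

logger = logging.getLogger(__name__)

__all__ = [
    "Waveform",
    "ManifestRecord",
    "LabelMap",
    "read_wav",
    "write_wav",
    "build_manifest",
    "read_manifest",
    "write_manifest",
]

MANIFEST_FIELDS = ("path", "label", "duration_s", "sample_rate", "augmented")

#: full-scale divisors for integer PCM encodings
_PCM_SCALE = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,
}


@dataclass(frozen=True)
class Waveform:
    """A single-channel sampled signal.

    samples are dimensionless amplitudes, nominally in [-1, 1];
    ``sample_rate`` is in Hz.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"waveform must be single-channel, got shape {samples.shape}")
        if samples.size == 0:
            raise ValueError("waveform must be non-empty")
        if int(self.sample_rate) <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class ManifestRecord:
    path: str
    label: str
    duration_s: float
    sample_rate: int
    augmented: bool = False

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s} for {self.path}")

    def with_flags(self, **kwargs) -> "ManifestRecord":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LabelMap:
    """Bijective mapping between class names and indices 0..N-1.

    Ordering is alphabetical by class name unless an explicit order is given,
    so two runs over the same corpus agree on the encoding.
    """

    names: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate class names in label map")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "LabelMap":
        return cls(tuple(sorted(set(labels))))

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown class label {name!r}; known: {list(self.names)}") from None

    def name(self, idx: int) -> str:
        return self.names[idx]

    def encode(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self.index(l) for l in labels], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.names)


def read_wav(path) -> Waveform:
    """Read a WAV file into a :class:`Waveform` with samples in [-1, 1].

    Integer PCM is divided by full scale; float data is taken as-is.
    Multichannel files are reduced to channel 0 with a warning.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalise scipy's varied errors
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"zero-length audio in {path}")
    if data.ndim == 2:
        logger.warning("%s has %d channels; keeping channel 0", path, data.shape[1])
        data = data[:, 0]
    if data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.uint8:  # 8-bit WAV is unsigned with midpoint 128
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise IOError(f"unsupported WAV sample format {data.dtype} in {path}")
    return Waveform(samples, int(rate))


def write_wav(w: Waveform, path) -> None:
    """Write a waveform as 16-bit PCM RIFF WAV.

    Samples outside [-1, 1] are clipped with a warning.
    """
    path = Path(path)
    samples = w.samples
    if np.any(np.abs(samples) > 1.0):
        logger.warning(
            "clipping %d sample(s) outside [-1, 1] while writing %s",
            int(np.sum(np.abs(samples) > 1.0)),
            path,
        )
        samples = np.clip(samples, -1.0, 1.0)
    # encode against the same full scale read_wav divides by, so a round
    # trip stays within half an LSB (one LSB at exactly +1.0)
    pcm = np.clip(np.round(samples * 32768.0), -32768, 32767).astype(np.int16)
    try:
        wavfile.write(path, w.sample_rate, pcm)
    except OSError as exc:
        raise IOError(f"cannot write WAV file {path}: {exc}") from exc


def build_manifest(
    root,
    label_rule: Callable[[str], str] | None = None,
) -> list[ManifestRecord]:
    """Scan a ``root/<class>/<clip>.wav`` tree into manifest records.

    ``label_rule`` maps a subdirectory name to a class label (identity by
    default).  Records are ordered lexicographically by path; non-WAV files
    are skipped with a log message; empty class directories warn but do not
    fail.  Clips whose stem ends in ``__flip`` are flagged as augmented.
    """
    root = Path(root)
    if not root.is_dir():
        raise ValueError(f"manifest root {root} is not a directory")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories found under {root}")
    rule = label_rule or (lambda name: name)

    records: list[ManifestRecord] = []
    for cdir in class_dirs:
        label = rule(cdir.name)
        n_before = len(records)
        for f in sorted(cdir.iterdir()):
            if f.suffix.lower() != ".wav":
                if f.is_file():
                    logger.info("skipping non-WAV file %s", f)
                continue
            w = read_wav(f)
            records.append(
                ManifestRecord(
                    path=str(f),
                    label=label,
                    duration_s=w.duration_s,
                    sample_rate=w.sample_rate,
                    augmented=f.stem.endswith("__flip"),
                )
            )
        n_class = len(records) - n_before
        if n_class == 0:
            logger.warning("class directory %s contains no WAV files", cdir)
        logger.info("class %s: %d clips", label, n_class)
    return records


def write_manifest(records: Sequence[ManifestRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_FIELDS)
        for r in records:
            # repr gives the shortest decimal that round-trips exactly
            writer.writerow([r.path, r.label, repr(r.duration_s), r.sample_rate, int(r.augmented)])


def read_manifest(path) -> list[ManifestRecord]:
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != MANIFEST_FIELDS:
            raise ValueError(f"manifest {path} has unexpected header {reader.fieldnames}")
        for row in reader:
            records.append(
                ManifestRecord(
                    path=row["path"],
                    label=row["label"],
                    duration_s=float(row["duration_s"]),
                    sample_rate=int(row["sample_rate"]),
                    augmented=bool(int(row["augmented"])),
                )
            )
    return records
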