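"""Class balancing by waveform time reversal.

Archival call collections are imbalanced across species, which hurts the
generalisation of the minority classes.  Reversing a clip in time yields a
legitimate new training sample whose spectrogram is mirrored along the time
axis, so under-represented classes are doubled by writing one flipped copy of
every original clip.  The default selection rule doubles every class whose
count falls below the mean class count.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .audio_io import ManifestRecord, Waveform, read_wav, write_wav

logger = logging.getLogger(__name__)

__all__ = ["AugmentPlan", "flip_waveform", "plan_augmentation", "apply_augmentation", "FLIP_SUFFIX"]

FLIP_SUFFIX = "__flip"


@dataclass(frozen=True)
class AugmentPlan:
    original: dict[str, int]
    target: dict[str, int]
    rule: str
    threshold: float

    @property
    def doubled_classes(self) -> list[str]:
        return sorted(c for c in self.original if self.target[c] == 2 * self.original[c] and self.original[c] > 0)

    @property
    def total_before(self) -> int:
        return sum(self.original.values())

    @property
    def total_after(self) -> int:
        return sum(self.target.values())


def flip_waveform(w: Waveform) -> Waveform:
    """Reverse the samples in time (exact involution; rate and length kept)."""
    return Waveform(w.samples[::-1].copy(), w.sample_rate)


def plan_augmentation(
    counts: Mapping[str, int],
    rule: str = "below_mean",
    threshold: float | None = None,
    classes: Sequence[str] | None = None,
) -> AugmentPlan:
    """Decide which classes get doubled by flipping.

    rules:
      below_mean       — double classes with count < mean(counts) (default)
      below_threshold  — double classes with count < ``threshold``
      explicit         — double exactly the classes in ``classes``
    """
    if not counts:
        raise ValueError("counts must be non-empty")
    if any(c <= 0 for c in counts.values()):
        raise ValueError(f"class counts must be positive, got {dict(counts)}")
    if rule == "below_mean":
        cut = float(np.mean(list(counts.values())))
        selected = {c for c, n in counts.items() if n < cut}
    elif rule == "below_threshold":
        if threshold is None:
            raise ValueError("below_threshold rule requires a threshold")
        cut = float(threshold)
        selected = {c for c, n in counts.items() if n < cut}
    elif rule == "explicit":
        if classes is None:
            raise ValueError("explicit rule requires a class list")
        unknown = set(classes) - set(counts)
        if unknown:
            raise ValueError(f"explicit classes not in counts: {sorted(unknown)}")
        cut = float("nan")
        selected = set(classes)
    else:
        raise ValueError(f"unknown augmentation rule {rule!r}")
    target = {c: (2 * n if c in selected else n) for c, n in counts.items()}
    return AugmentPlan(original=dict(counts), target=target, rule=rule, threshold=cut)


def _flip_path(record: ManifestRecord, out_dir: Path) -> Path:
    src = Path(record.path)
    return out_dir / record.label / f"{src.stem}{FLIP_SUFFIX}.wav"


def apply_augmentation(
    manifest: Sequence[ManifestRecord],
    plan: AugmentPlan,
    out_dir,
) -> list[ManifestRecord]:
    """Write flipped copies per the plan and return the extended manifest.

    Original records are untouched; each doubled class gains one flipped WAV
    per source clip, written to ``out_dir/<label>/<stem>__flip.wav`` and
    flagged ``augmented=True``.  Idempotent: flips already present in the
    manifest are not re-created.
    """
    out_dir = Path(out_dir)
    originals = [r for r in manifest if not r.augmented]
    counts = Counter(r.label for r in originals)
    if dict(counts) != plan.original:
        raise ValueError(
            f"manifest original counts {dict(counts)} do not match plan counts {plan.original}"
        )
    existing_aug = {r.path for r in manifest if r.augmented}
    result = list(manifest)
    for record in originals:
        if record.label not in plan.doubled_classes:
            continue
        dst = _flip_path(record, out_dir)
        if str(dst) in existing_aug:
            continue
        dst.parent.mkdir(parents=True, exist_ok=True)
        write_wav(flip_waveform(read_wav(record.path)), dst)
        result.append(
            ManifestRecord(
                path=str(dst),
                label=record.label,
                duration_s=record.duration_s,
                sample_rate=record.sample_rate,
                augmented=True,
            )
        )
    final = Counter(r.label for r in result)
    for label, want in plan.target.items():
        if final[label] != want:
            raise ValueError(f"class {label}: expected {want} records after augmentation, got {final[label]}")
    logger.info("augmentation: %d -> %d records", len(manifest), len(result))
    return result
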