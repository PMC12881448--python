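"""Training-set assembly: windows, labels, and the event-basis split.

Every window generated from one event carries that event's split tag, so no
event ever contributes to both training and validation ("split on an event
basis"). Windows never straddle movie boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from edamic.detector.config import DetectorConfig
from edamic.detector.labels import labeled_frames, render_labels
from edamic.detector.normalize import normalize_stack

TRAIN_FRACTION = 0.75
_HASH_MULT = 2654435761  # Knuth multiplicative hash


def event_split(event_id: int, train_fraction: float = TRAIN_FRACTION) -> str:
    """Deterministic train/validation tag from an event id."""
    u = ((event_id + 1) * _HASH_MULT % (2 ** 32)) / 2 ** 32
    return "train" if u < train_fraction else "validation"


@dataclass
class TrainingExample:
    window: np.ndarray        # (n_time_points, H, W), normalized
    label: np.ndarray         # (H, W)
    event_id: int
    split: str
    movie_id: int = 0
    t: int = 0


@dataclass
class TrainingSet:
    examples: list = field(default_factory=list)
    n_time_points: int = 1

    def subset(self, split: str) -> list:
        return [ex for ex in self.examples if ex.split == split]

    @property
    def train(self) -> list:
        return self.subset("train")

    @property
    def validation(self) -> list:
        return self.subset("validation")

    def __len__(self) -> int:
        return len(self.examples)


def build_training_set(movies, config: DetectorConfig,
                       sigma_label: float | None = None) -> TrainingSet:
    """Assemble windows + last-frame labels from (frames, events) pairs.

    ``movies`` is a list of ``(frames, events)`` with ``frames`` a (T, H, W)
    stack. Positive events contribute their labeled last-five frames;
    negative events contribute the same window positions with all-zero
    labels. Event ids are assigned in encounter order across movies.
    """
    tp = config.n_time_points + getattr(config, "warmup_frames", 0)
    sigma = config.sigma_label if sigma_label is None else sigma_label
    ts = TrainingSet(n_time_points=tp)
    event_id = 0
    for movie_id, (frames, events) in enumerate(movies):
        frames = np.asarray(frames, float)
        norm = normalize_stack(frames)
        shape = frames.shape[1:]
        positives = [e for e in events if e.polarity == "positive"]
        for ev in events:
            split = event_split(event_id)
            for t in labeled_frames(ev):
                if t - (config.n_time_points - 1) < 0 or t >= len(frames):
                    continue  # core window would straddle the movie start/end
                idx = [max(0, t - tp + 1 + i) for i in range(tp)]
                window = norm[idx]
                if ev.polarity == "positive":
                    label = render_labels(positives, t, shape, sigma).map
                else:
                    label = np.zeros(shape)
                ts.examples.append(TrainingExample(
                    window=window, label=label, event_id=event_id,
                    split=split, movie_id=movie_id, t=t))
            event_id += 1
    return ts
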