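"""Training loop: Adam on BCE or soft focal loss, deterministic per seed."""

from __future__ import annotations

import numpy as np

from edamic.detector.autodiff import Adam, Tensor
from edamic.detector.config import DetectorConfig
from edamic.detector.losses import soft_focal_loss_node
from edamic.detector.models import Detector


def _clip_global_norm(params, max_norm: float) -> None:
    total = np.sqrt(sum(float((p.grad ** 2).sum())
                        for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def train_detector(detector: Detector, training_set,
                   config: DetectorConfig | None = None):
    """Train in place on the training split; returns (detector, history).

    ``history`` is the per-epoch mean training loss. Validation events are
    never touched. Deterministic given ``config.seed``.
    """
    cfg = config or detector.config
    examples = training_set.train
    if not examples:
        raise ValueError("empty training split")
    expected = (detector.config.n_time_points
                + getattr(detector.config, "warmup_frames", 0))
    if training_set.n_time_points != expected:
        raise ValueError("training set window length mismatch")
    gamma = cfg.gamma if cfg.loss == "soft_focal" else 0.0
    opt = Adam(detector.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng([cfg.seed, 13])
    history = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(examples))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [examples[i] for i in order[start:start + cfg.batch_size]]
            x = np.stack([ex.window for ex in batch])
            y = np.stack([ex.label for ex in batch])[:, None]
            opt.zero_grad()
            pred = detector.forward(Tensor(x))
            loss = soft_focal_loss_node(pred, y, gamma=gamma)
            loss.backward()
            if cfg.grad_clip > 0:
                _clip_global_norm(detector.parameters(), cfg.grad_clip)
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    return detector, history
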