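"""Detector architectures.

Two families share a fully convolutional encoder-decoder core with skip
connections (depth 2, 16 initial filters doubling per level by default):

* non-stateful: the ``n_time_points`` input frames are stacked as image
  channels; the output is a single-channel score map in [0, 1] for the last
  frame. A pure function of the input window.
* stateful: the same encoder is applied identically to every frame of the
  window (time-distributed); a convolutional LSTM at the bottleneck consumes
  the encoded sequence and carries memory; the decoder combines the LSTM
  hidden state with the last frame's skip features.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from edamic.detector import autodiff as ad
from edamic.detector.autodiff import Tensor
from edamic.detector.config import DetectorConfig
from edamic.detector.normalize import normalize_stack


def _he(rng, shape):
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)


class Detector:
    """A (possibly stateful) heatmap event detector."""

    def __init__(self, config: DetectorConfig):
        self.config = config
        self.params: dict = {}
        self.hidden = None  # (h, c) numpy arrays for the stateful variant
        self._init_params()

    # -- construction --

    def _filters(self):
        f = self.config.initial_filters
        return [f * 2 ** l for l in range(self.config.depth + 1)]

    def _init_params(self) -> None:
        cfg = self.config
        rng = np.random.default_rng([cfg.seed, 11])
        filters = self._filters()
        c_in = 1 if cfg.stateful else cfg.n_time_points
        p = {}
        for l, f in enumerate(filters[:-1]):
            p[f"enc{l}_w"] = _he(rng, (f, c_in, 3, 3))
            p[f"enc{l}_b"] = np.zeros(f)
            c_in = f
        f_bot = filters[-1]
        if cfg.stateful:
            p["lstm_w"] = _he(rng, (4 * f_bot, filters[-2] + f_bot, 3, 3)) * 0.5
            b = np.zeros(4 * f_bot)
            b[f_bot:2 * f_bot] = 1.0  # forget-gate bias
            p["lstm_b"] = b
        else:
            p["bott_w"] = _he(rng, (f_bot, filters[-2], 3, 3))
            p["bott_b"] = np.zeros(f_bot)
        c = f_bot
        for l in reversed(range(cfg.depth)):
            f = filters[l]
            p[f"dec{l}_w"] = _he(rng, (f, c + f, 3, 3))
            p[f"dec{l}_b"] = np.zeros(f)
            c = f
        p["head_w"] = _he(rng, (1, c, 1, 1))
        p["head_b"] = np.zeros(1)
        self.params = {k: Tensor(v, requires_grad=True) for k, v in p.items()}

    def parameters(self):
        return list(self.params.values())

    # -- graph builders --

    def _encode(self, x: Tensor):
        skips = []
        h = x
        for l in range(self.config.depth):
            h = ad.relu(ad.conv2d(h, self.params[f"enc{l}_w"],
                                  self.params[f"enc{l}_b"]))
            skips.append(h)
            h = ad.maxpool2(h)
        return skips, h

    def _decode(self, bottom: Tensor, skips) -> Tensor:
        h = bottom
        for l in reversed(range(self.config.depth)):
            h = ad.upsample2(h)
            h = ad.concat_channels([h, skips[l]])
            h = ad.relu(ad.conv2d(h, self.params[f"dec{l}_w"],
                                  self.params[f"dec{l}_b"]))
        return ad.sigmoid(ad.conv2d(h, self.params["head_w"],
                                    self.params["head_b"]))

    def _lstm_step(self, x: Tensor, h: Tensor, c: Tensor):
        f_bot = self._filters()[-1]
        gates = ad.conv2d(ad.concat_channels([x, h]),
                          self.params["lstm_w"], self.params["lstm_b"])
        i = ad.sigmoid(ad.narrow_channels(gates, 0, f_bot))
        f = ad.sigmoid(ad.narrow_channels(gates, f_bot, 2 * f_bot))
        o = ad.sigmoid(ad.narrow_channels(gates, 2 * f_bot, 3 * f_bot))
        g = ad.tanh(ad.narrow_channels(gates, 3 * f_bot, 4 * f_bot))
        c_new = ad.add(ad.mul(f, c), ad.mul(i, g))
        h_new = ad.mul(o, ad.tanh(c_new))
        return h_new, c_new

    def _zero_state(self, n: int, hw) -> tuple:
        f_bot = self._filters()[-1]
        factor = 2 ** self.config.depth
        shape = (n, f_bot, hw[0] // factor, hw[1] // factor)
        return Tensor(np.zeros(shape)), Tensor(np.zeros(shape))

    def forward(self, x: Tensor) -> Tensor:
        """Build the score-map graph for a batch.

        Input is (N, T, H, W); output (N, 1, H, W) in [0, 1] for the last
        frame of each window. The stateful variant starts from a zero state.
        """
        n, t, hh, ww = x.shape
        tp = self.config.n_time_points
        if not self.config.stateful:
            if t != tp:
                raise ValueError(f"window length {t} != n_time_points {tp}")
            skips, bottom = self._encode(x)
            bott = ad.relu(ad.conv2d(bottom, self.params["bott_w"],
                                     self.params["bott_b"]))
            return self._decode(bott, skips)
        if t < tp:
            raise ValueError(f"window length {t} < n_time_points {tp}")
        # frames beyond n_time_points are a state warm-up: they advance the
        # memory but carry no gradient, so backprop stays truncated to the
        # core window while the LSTM still sees longer history
        h, c = self._zero_state(n, (hh, ww))
        skips = None
        for i in range(t):
            frame = ad.narrow_channels(x, i, i + 1)
            skips, bottom = self._encode(frame)
            h, c = self._lstm_step(bottom, h, c)
            if i < t - tp:
                h, c = Tensor(h.data), Tensor(c.data)
        return self._decode(h, skips)

    # -- inference API --

    def infer(self, window: np.ndarray, normalize: bool = True) -> np.ndarray:
        """Score map for one window of ``n_time_points`` frames (T, H, W)."""
        window = np.asarray(window, float)
        if window.ndim != 3 or window.shape[0] != self.config.n_time_points:
            raise ValueError(
                f"expected window of {self.config.n_time_points} frames")
        if normalize:
            window = normalize_stack(window)
        out = self.forward(Tensor(window[None]))
        return out.data[0, 0]

    def reset_state(self) -> None:
        """Restore the stateful variant's hidden state to its initial value."""
        self.hidden = None

    def step(self, frame: np.ndarray, normalize: bool = True) -> np.ndarray:
        """Advance the persistent hidden state by one frame (stateful only)."""
        if not self.config.stateful:
            raise ValueError("step() is only defined for stateful detectors")
        frame = np.asarray(frame, float)
        if normalize:
            frame = normalize_stack(frame[None])[0]
        x = Tensor(frame[None, None])
        if self.hidden is None:
            h, c = self._zero_state(1, frame.shape)
        else:
            h, c = Tensor(self.hidden[0]), Tensor(self.hidden[1])
        skips, bottom = self._encode(x)
        h, c = self._lstm_step(bottom, h, c)
        self.hidden = (h.data, c.data)
        return self._decode(h, skips).data[0, 0]

    def infer_sequence(self, frames: np.ndarray,
                       normalize: bool = True) -> list:
        """One score map per movie frame.

        Non-stateful: each frame is scored from its trailing window, with the
        first frames left-padded by repeating the first frame. Stateful: the
        hidden state is reset and then carried frame-to-frame.
        """
        frames = np.asarray(frames, float)
        tp = self.config.n_time_points
        if self.config.stateful:
            self.reset_state()
            return [self.step(f, normalize=normalize) for f in frames]
        if normalize:
            frames = normalize_stack(frames)
        windows = np.stack([
            frames[[max(0, t - (tp - 1) + i) for i in range(tp)]]
            for t in range(len(frames))
        ])
        maps = []
        for c0 in range(0, len(windows), 16):  # batch for matmul efficiency
            out = self.forward(Tensor(windows[c0:c0 + 16]))
            maps.extend(out.data[:, 0])
        return maps

    # -- persistence --

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {k: v.data for k, v in self.params.items()}
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(
            json.dumps(self.config.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "Detector":
        path = Path(path)
        config = DetectorConfig.from_dict(
            json.loads(path.with_suffix(".json").read_text()))
        det = cls(config)
        with np.load(path.with_suffix(".npz")) as data:
            for k in det.params:
                det.params[k].data = data[k]
        return det


def build_detector(config: DetectorConfig) -> Detector:
    """Construct an untrained detector; deterministic given ``config.seed``."""
    return Detector(config)
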