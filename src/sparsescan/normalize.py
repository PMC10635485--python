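"""Real-time signal normalization and dynamic threshold adjustment.

During a long raster scan the incident flux is not constant: the
storage-ring current decays between top-ups and the beam can drift in
position, which the four-blade beam position monitor (BPM) senses. A
threshold fixed before the scan therefore stops selecting the intended
region unless either the signal is normalized on the fly or the
threshold itself is adjusted in step with the beam.

Five methods are provided:

``identity``     no correction;
``ring``         divide out the ring-current ratio (raw * I_ref/I_now);
``window``       subtract a floating-window average of the last N pixels
                 (N defaults to twice the number of pixels per row);
``ring_window``  the window rule applied to ring-normalized values;
``bpm``          divide out the blade-current-sum ratio;
``window_div``   divisive variant of the floating window.

For the multiplicative methods (``ring``, ``bpm``) the central
algebraic contract is: comparing the *raw* signal against the adjusted
threshold from :func:`adjust_threshold` is exactly equivalent to
comparing the *normalized* signal against the base threshold.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NormalizerState",
    "default_window_length",
    "normalize_value",
    "normalize_image",
    "adjust_threshold",
]

METHODS = ("identity", "ring", "window", "ring_window", "bpm", "window_div")
MULTIPLICATIVE = ("ring", "bpm")


def default_window_length(cols: int) -> int:
    """Floating-window length rule: twice the number of pixels per row."""
    if cols < 1:
        raise ValueError("cols must be >= 1")
    return 2 * cols


@dataclass
class NormalizerState:
    """Online normalizer; one instance per scan, updated pixel by pixel.

    The window buffer holds the last ``window_length`` values of the
    stream the window operates on (raw values for ``window``,
    ring-normalized values for ``ring_window``). The mean is always
    taken *before* the current value is inserted, so the first pixel's
    window output is the raw value itself (empty-buffer mean defined
    as 0 for subtraction, 1 for division).
    """

    method: str = "identity"
    window_length: int = 1
    reference_current: float = 300.0
    blade_reference: np.ndarray | None = None
    _buffer: deque = field(default_factory=deque, repr=False)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown normalization method {self.method!r}")
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if self.reference_current <= 0:
            raise ValueError("reference_current must be > 0")
        self._buffer = deque(maxlen=self.window_length)

    def reset(self) -> None:
        self._buffer.clear()

    # -- core update -------------------------------------------------
    def normalize(self, raw: float, ring_current_now: float, blades_now=None) -> float:
        if ring_current_now <= 0:
            raise ValueError("ring current must be > 0")

        if self.method == "identity":
            return float(raw)
        if self.method == "ring":
            return float(raw) * (self.reference_current / ring_current_now)
        if self.method == "bpm":
            if blades_now is None:
                raise ValueError("bpm method requires blade currents")
            if self.blade_reference is None:
                self.blade_reference = np.asarray(blades_now, float).copy()
            s = float(np.sum(blades_now))
            if s == 0:
                raise ValueError("blade current sum is zero")
            return float(raw) * (float(np.sum(self.blade_reference)) / s)

        # window variants
        if self.method == "ring_window":
            v = float(raw) * (self.reference_current / ring_current_now)
        else:
            v = float(raw)
        if self.method == "window_div":
            out = v / (float(np.mean(self._buffer)) if self._buffer else 1.0)
        else:
            out = v - (float(np.mean(self._buffer)) if self._buffer else 0.0)
        self._buffer.append(v)
        return out


def normalize_value(
    state: NormalizerState, raw: float, ring_current_now: float, blades_now=None
) -> float:
    """Normalize one value, updating ``state`` in place."""
    return state.normalize(raw, ring_current_now, blades_now)


def normalize_image(
    image: np.ndarray,
    ring_current: np.ndarray,
    blades: np.ndarray | None = None,
    method: str = "ring",
    window_length: int | None = None,
    reference_current: float | None = None,
) -> np.ndarray:
    """Offline replay of the online normalization over a recorded scan.

    ``ring_current`` has one entry per pixel in row-major scan order;
    ``blades`` is (P, 4). The replay applies :func:`normalize_value`
    over the same row-major stream, so it is bit-identical to the
    values an online scan with the same method would have logged.
    """
    image = np.asarray(image, float)
    rc = np.asarray(ring_current, float).ravel()
    if rc.size != image.size:
        raise ValueError("diagnostics log length does not match image size")
    if blades is not None:
        blades = np.asarray(blades, float).reshape(image.size, 4)
    if window_length is None:
        window_length = default_window_length(image.shape[1])
    if reference_current is None:
        reference_current = float(rc[0])
    state = NormalizerState(
        method=method,
        window_length=window_length,
        reference_current=reference_current,
        blade_reference=None if blades is None else blades[0].copy(),
    )
    out = np.empty(image.size)
    flat = image.ravel()
    for p in range(image.size):
        out[p] = state.normalize(flat[p], rc[p], None if blades is None else blades[p])
    return out.reshape(image.shape)


def adjust_threshold(
    base_threshold: float,
    state: NormalizerState,
    ring_current_now: float,
    blades_now=None,
) -> float:
    """Scale a threshold to be applied to the *raw* signal.

    Only meaningful for the multiplicative methods: ``raw > adjusted``
    iff ``normalized(raw) > base``. The subtractive window methods
    adjust the signal, not the threshold, and raise here.
    """
    if state.method == "ring":
        if ring_current_now <= 0:
            raise ValueError("ring current must be > 0")
        return base_threshold * (ring_current_now / state.reference_current)
    if state.method == "bpm":
        if blades_now is None:
            raise ValueError("bpm method requires blade currents")
        if state.blade_reference is None:
            raise ValueError("bpm reference not initialized")
        ref = float(np.sum(state.blade_reference))
        if ref == 0:
            raise ValueError("blade reference sum is zero")
        return base_threshold * (float(np.sum(blades_now)) / ref)
    raise ValueError(
        f"threshold adjustment is multiplicative-only; method {state.method!r} "
        "adjusts the signal, not the threshold"
    )
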