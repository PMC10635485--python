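"""Per-pixel trigger strategies deciding where to spend the long XRF dwell.

Four bases are available, mirroring the acquisition modes of a
compressive-sensing multimodal scan:

``mask``          static: acquire where a precomputed mask (plus a few
                  seeded spare points outside it) says so;
``absorption``    dynamic: acquire where the absorption derived from the
                  fast transmitted signal exceeds a threshold, with
                  optional beam normalization / threshold adjustment;
``xrf_fast``      dynamic, XRF-only: probe each pixel with a short XRF
                  dwell and acquire the long dwell where the fast ROI
                  counts exceed a threshold (for opaque samples);
``ml``            acquire where a trained oracle's predicted XRF-like
                  map exceeds a threshold.

All comparisons are strictly greater-than: a value exactly equal to the
threshold does not trigger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .normalize import NormalizerState, adjust_threshold, normalize_value

__all__ = [
    "TriggerDecision",
    "StrategySpec",
    "AlwaysAcquire",
    "NeverAcquire",
    "StaticMaskStrategy",
    "AbsorptionThresholdStrategy",
    "XRFFastStrategy",
    "MLTriggerStrategy",
    "draw_spare_points",
    "static_mask_decide",
    "absorption_threshold_decide",
    "xrf_fast_decide",
    "choose_fast_dwell",
    "make_strategy",
]


@dataclass
class TriggerDecision:
    """Outcome of consulting a strategy at one pixel, fully logged."""

    acquire_long: bool
    value_compared: float
    threshold_in_force: float
    basis: str


@dataclass
class StrategySpec:
    """Declarative description of a strategy, as it appears in configs."""

    basis: str  # mask | absorption | xrf_fast | ml
    threshold: float = 0.0
    normalizer: str = "identity"
    window_length: int | None = None
    mask: np.ndarray | None = None
    spare_fraction: float = 0.0
    roi_element: str | None = None
    t_fast: float = 0.0
    t_long: float = 0.0
    adjust_threshold: bool = False
    predicted_map: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 <= self.spare_fraction <= 0.2:
            raise ValueError("spare_fraction must be in [0, 0.2]")
        if self.basis == "mask" and self.mask is None:
            raise ValueError("mask basis requires a mask")
        if self.basis == "xrf_fast":
            if self.roi_element is None:
                raise ValueError("xrf_fast basis requires roi_element")
            if self.t_long and not self.t_fast < self.t_long:
                raise ValueError("xrf_fast basis requires t_fast < t_long")


def draw_spare_points(mask: np.ndarray, spare_fraction: float, seed: int) -> np.ndarray:
    """Seeded spare points: a fixed fraction of the outside-mask pixels,
    drawn once per scan, uniformly without replacement."""
    mask = np.asarray(mask, bool)
    outside = np.flatnonzero(~mask.ravel())
    n = int(round(spare_fraction * outside.size))
    spare = np.zeros(mask.size, bool)
    if n > 0:
        rng = np.random.default_rng(seed)
        spare[rng.choice(outside, size=n, replace=False)] = True
    return spare.reshape(mask.shape)


class TriggerStrategy:
    """Base class; subclasses set ``basis`` and ``needs``.

    ``needs`` names the fast modality the engine must acquire before
    consulting the strategy: ``"stxm"`` or ``"xrf_fast"``.
    """

    basis = "mask"
    needs = "stxm"
    name = "base"

    def begin(self, config, beam, seed: int) -> None:  # pragma: no cover - trivial
        pass

    def decide(self, pixel_index, measurement) -> TriggerDecision:
        raise NotImplementedError


class AlwaysAcquire(TriggerStrategy):
    name = "always"

    def decide(self, pixel_index, measurement) -> TriggerDecision:
        return TriggerDecision(True, 1.0, 0.0, "mask")


class NeverAcquire(TriggerStrategy):
    name = "never"

    def decide(self, pixel_index, measurement) -> TriggerDecision:
        return TriggerDecision(False, 0.0, 1.0, "mask")


class StaticMaskStrategy(TriggerStrategy):
    """Acquire where the precomputed mask (or a spare point) is set.

    The decision is independent of any measurement; spare points are
    drawn once, at scan start, from the strategy seed.
    """

    basis = "mask"
    name = "mask"

    def __init__(self, mask: np.ndarray, spare_fraction: float = 0.0):
        self.mask = np.asarray(mask, bool)
        if not 0.0 <= spare_fraction <= 0.2:
            raise ValueError("spare_fraction must be in [0, 0.2]")
        self.spare_fraction = spare_fraction
        self.effective = self.mask.copy()

    def begin(self, config, beam, seed: int) -> None:
        if self.mask.shape != (config.rows, config.cols):
            raise ValueError(
                f"mask shape {self.mask.shape} does not match scan shape "
                f"{(config.rows, config.cols)}"
            )
        spare = draw_spare_points(self.mask, self.spare_fraction, seed)
        self.effective = self.mask | spare

    def decide(self, pixel_index, measurement) -> TriggerDecision:
        hit = bool(self.effective[pixel_index])
        return TriggerDecision(hit, 1.0 if hit else 0.0, 0.5, "mask")


class AbsorptionThresholdStrategy(TriggerStrategy):
    """Trigger on the absorption derived from the fast transmitted signal.

    Absorption is defined as (reference flat-field signal - normalized
    transmitted intensity), the flat-field reference being the
    noiseless open-beam intensity at reference ring current
    (``nominal_flux * t_stxm``). Acquire where absorption strictly
    exceeds the threshold.

    Two equivalent real-time implementations are provided: normalize
    the signal and compare with the base threshold
    (``adjust=False``), or leave the signal raw and adjust an
    intensity threshold with the beam (``adjust=True``; multiplicative
    normalizers only). For the subtractive window methods the
    threshold applies to the deviation signal (local-mean minus
    current value).
    """

    basis = "absorption"
    needs = "stxm"
    name = "abs_threshold"

    def __init__(
        self,
        threshold: float,
        normalizer: str = "identity",
        window_length: int | None = None,
        adjust: bool = False,
    ):
        self.threshold = float(threshold)
        self.normalizer_method = normalizer
        self.window_length = window_length
        self.adjust = adjust
        if adjust and normalizer not in ("ring", "bpm"):
            raise ValueError("threshold adjustment requires a multiplicative normalizer")
        self.state: NormalizerState | None = None
        self.reference_signal = 0.0

    def begin(self, config, beam, seed: int) -> None:
        n = self.window_length or (2 * config.cols)
        self.state = NormalizerState(
            method=self.normalizer_method,
            window_length=n,
            reference_current=beam.reference_current,
        )
        self.reference_signal = beam.nominal_flux * config.t_stxm

    def decide(self, pixel_index, measurement) -> TriggerDecision:
        if measurement is None or measurement.stxm_intensity is None:
            raise ValueError("absorption strategy requires an STXM measurement")
        raw = measurement.stxm_intensity
        rc = measurement.ring_current
        blades = measurement.blade_currents
        if self.adjust:
            # raw-signal path: intensity threshold scaled with the beam
            raw_intensity_thr = adjust_threshold(
                self.reference_signal - self.threshold, self.state, rc, blades
            )
            acquire = raw < raw_intensity_thr
            return TriggerDecision(acquire, raw_intensity_thr - raw, 0.0, self.basis)
        norm = normalize_value(self.state, raw, rc, blades)
        if self.normalizer_method in ("window", "ring_window"):
            absorption = -norm  # deviation below the floating-window mean
        else:
            absorption = self.reference_signal - norm
        return TriggerDecision(absorption > self.threshold, absorption, self.threshold, self.basis)


class XRFFastStrategy(TriggerStrategy):
    """Trigger on ROI counts from a short probing XRF dwell."""

    basis = "xrf_fast"
    needs = "xrf_fast"
    name = "xrf_threshold"

    def __init__(self, threshold: float, roi_element: str):
        self.threshold = float(threshold)
        self.roi_element = roi_element

    def decide(self, pixel_index, measurement) -> TriggerDecision:
        if self.roi_element not in measurement.xrf_counts:
            raise KeyError(f"ROI element {self.roi_element!r} not in fast measurement")
        c = measurement.xrf_counts[self.roi_element]
        return TriggerDecision(c > self.threshold, float(c), self.threshold, self.basis)


class MLTriggerStrategy(TriggerStrategy):
    """Acquire where a trained oracle's predicted map exceeds a threshold."""

    basis = "ml"
    needs = "stxm"
    name = "ml"

    def __init__(self, predicted: np.ndarray, threshold: float):
        self.predicted = np.asarray(predicted, float)
        self.threshold = float(threshold)

    def begin(self, config, beam, seed: int) -> None:
        if self.predicted.shape != (config.rows, config.cols):
            raise ValueError("predicted map shape does not match scan shape")

    def decide(self, pixel_index, measurement) -> TriggerDecision:
        v = float(self.predicted[pixel_index])
        return TriggerDecision(v > self.threshold, v, self.threshold, self.basis)


# ----------------------------------------------------------------------
# functional wrappers matching the declarative StrategySpec surface
# ----------------------------------------------------------------------

def static_mask_decide(spec: StrategySpec, pixel_index, *, seed: int = 0, _cache={}) -> TriggerDecision:
    key = (id(spec.mask), spec.spare_fraction, seed)
    if key not in _cache:
        _cache[key] = spec.mask | draw_spare_points(spec.mask, spec.spare_fraction, seed)
    eff = _cache[key]
    hit = bool(eff[pixel_index])
    return TriggerDecision(hit, 1.0 if hit else 0.0, 0.5, "mask")


def absorption_threshold_decide(
    spec: StrategySpec, measurement, normalizer_state: NormalizerState,
    reference_signal: float,
) -> TriggerDecision:
    if measurement is None or measurement.stxm_intensity is None:
        raise ValueError("absorption decision requires an STXM measurement")
    norm = normalize_value(
        normalizer_state, measurement.stxm_intensity,
        measurement.ring_current, measurement.blade_currents,
    )
    if normalizer_state.method in ("window", "ring_window"):
        absorption = -norm
    else:
        absorption = reference_signal - norm
    return TriggerDecision(absorption > spec.threshold, absorption, spec.threshold, "absorption")


def xrf_fast_decide(spec: StrategySpec, fast_counts: int) -> TriggerDecision:
    return TriggerDecision(fast_counts > spec.threshold, float(fast_counts), spec.threshold, "xrf_fast")


def make_strategy(spec: StrategySpec) -> TriggerStrategy:
    """Instantiate the engine-facing strategy object for a spec."""
    if spec.basis == "mask":
        return StaticMaskStrategy(spec.mask, spec.spare_fraction)
    if spec.basis == "absorption":
        return AbsorptionThresholdStrategy(
            spec.threshold, spec.normalizer, spec.window_length, spec.adjust_threshold
        )
    if spec.basis == "xrf_fast":
        return XRFFastStrategy(spec.threshold, spec.roi_element)
    if spec.basis == "ml":
        if spec.predicted_map is None:
            raise ValueError("ml basis requires a predicted map")
        return MLTriggerStrategy(spec.predicted_map, spec.threshold)
    raise ValueError(f"unknown strategy basis {spec.basis!r}")


# ----------------------------------------------------------------------
# fast-dwell selection under Poisson counting statistics
# ----------------------------------------------------------------------

def choose_fast_dwell(
    rate_present: float,
    rate_absent: float,
    dwell_grid,
    target_sensitivity: float,
    target_specificity: float,
    max_k: int | None = None,
):
    """Smallest probing dwell that separates presence from absence.

    For each candidate dwell (ascending) the discriminator is an
    integer count threshold k: trigger if counts > k. Sensitivity is
    P(counts > k | element present) and specificity
    P(counts <= k | element absent) under Poisson counting. Returns
    ``(dwell, k)`` for the first dwell admitting a k that meets both
    targets, or ``None`` if no dwell in the grid suffices.
    """
    dwell_grid = list(dwell_grid)
    if not dwell_grid:
        raise ValueError("dwell grid must not be empty")
    if rate_present < rate_absent or rate_absent < 0:
        raise ValueError("need rate_present >= rate_absent >= 0")
    for dwell in dwell_grid:
        mu_p = rate_present * dwell
        mu_a = rate_absent * dwell
        # Specificity is non-decreasing in k and sensitivity non-increasing,
        # so the smallest k meeting the specificity target is optimal.
        k = 0 if mu_a == 0 else int(stats.poisson.ppf(target_specificity, mu_a))
        while (stats.poisson.cdf(k, mu_a) if mu_a > 0 else 1.0) < target_specificity:
            k += 1
        if max_k is not None and k > max_k:
            continue
        if stats.poisson.sf(k, mu_p) >= target_sensitivity:
            return dwell, k
    return None
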