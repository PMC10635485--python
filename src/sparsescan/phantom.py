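"""Synthetic specimens and a virtual beam for sparse-scanning experiments.

The phantoms emulate the three specimen classes a soft X-ray
STXM + low-energy-XRF instrument typically meets:

``filaments``
    sparse curvilinear structures (a fungal mycelium) on an otherwise
    empty Si3N4-like support window;
``leaf``
    one connected, irregularly shaped biological section with internal
    holes (a plant leaf section);
``stone``
    a thick, non-transmitting mineral sample with surface holes, mapped
    by XRF only, carrying a major matrix element and a trace element.

The beam model captures the storage-ring environment: an exponentially
decaying ring current restored by periodic top-up, a four-blade beam
position monitor (blades at 0/90/180/270 degrees) whose photocurrents
encode both intensity and positional drift, and a linear motor-stage
drift that displaces the actually illuminated position over time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "GroundTruthSample",
    "BeamModel",
    "PixelMeasurement",
    "make_phantom",
    "simulate_beam",
    "measure_pixel",
    "synthesize_spectrum",
]

#: attenuation coefficient used to derive transmission from thickness,
#: in 1/(thickness unit); transmission = exp(-MU * thickness)
DEFAULT_MU = 1.0

#: thickness above which a pixel counts as real sample rather than bare support
SUPPORT_THRESHOLD = 0.05

BLADE_ANGLES_DEG = (0.0, 90.0, 180.0, 270.0)


@dataclass
class GroundTruthSample:
    """Noiseless multimodal ground truth on a pixel grid.

    ``transmission`` is the fraction of incident photons transmitted at
    each pixel, ``xrf_rate`` maps element labels to expected emission
    count rates (counts/second at nominal incident flux), and the phase
    gradients ``dpc_x``/``dpc_y`` are discrete derivatives of thickness.
    """

    thickness: np.ndarray
    transmission: np.ndarray
    dpc_x: np.ndarray
    dpc_y: np.ndarray
    xrf_rate: dict[str, np.ndarray]
    support_mask: np.ndarray
    pixel_size: float
    mu: float = DEFAULT_MU
    kind: str = "custom"

    @property
    def shape(self) -> tuple[int, int]:
        return self.thickness.shape

    def element_labels(self) -> list[str]:
        return list(self.xrf_rate)


def _derive_fields(thickness: np.ndarray, mu: float) -> tuple[np.ndarray, ...]:
    transmission = np.exp(-mu * thickness)
    # central differences, one-sided at the boundary
    dpc_y, dpc_x = np.gradient(thickness)
    support = thickness > SUPPORT_THRESHOLD
    return transmission, dpc_x, dpc_y, support


# default per-kind element layouts: label -> (region, rate in counts/s)
_DEFAULT_ELEMENTS = {
    "filaments": {"C": ("body", 30.0), "O": ("body", 40.0), "Se": ("body", 8.0)},
    "leaf": {"C": ("body", 40.0), "O": ("body", 50.0), "Mg": ("body", 10.0), "Al": ("inclusions", 15.0)},
    "stone": {"Si": ("body", 60.0), "Al": ("body", 20.0), "Na": ("trace", 2.0)},
}


def _resolve_elements(kind: str, elements) -> dict[str, tuple[str, float]]:
    if elements is None or len(elements) == 0:
        raise ValueError("element list must not be empty")
    defaults = _DEFAULT_ELEMENTS[kind]
    resolved: dict[str, tuple[str, float]] = {}
    for entry in elements:
        if isinstance(entry, str):
            label = entry
            profile = defaults.get(label, ("body", 20.0))
        else:
            label, profile = entry[0], (entry[1], float(entry[2]))
        resolved[label] = profile
    return resolved


def _filament_thickness(rows: int, cols: int, rng: np.random.Generator) -> np.ndarray:
    """Random-walk curvilinear filaments, dilated and smoothed."""
    canvas = np.zeros((rows, cols), bool)
    n_fil = max(3, (rows * cols) // 600)
    for _ in range(n_fil):
        r = rng.uniform(0, rows)
        c = rng.uniform(0, cols)
        ang = rng.uniform(0, 2 * math.pi)
        length = int(rng.uniform(0.5, 1.5) * max(rows, cols))
        for _ in range(length):
            ri, ci = int(r), int(c)
            if 0 <= ri < rows and 0 <= ci < cols:
                canvas[ri, ci] = True
            ang += rng.normal(0, 0.25)
            r += math.sin(ang)
            c += math.cos(ang)
            if not (-5 < r < rows + 5 and -5 < c < cols + 5):
                break
    canvas = ndimage.binary_dilation(canvas, iterations=1)
    thick = ndimage.gaussian_filter(canvas.astype(float), 0.8)
    thick = np.where(thick > 0.15, 0.4 + 0.6 * thick, 0.0)
    return thick


def _blob_field(rows: int, cols: int, rng: np.random.Generator, smooth: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.normal(size=(rows, cols)), smooth)
    return (f - f.mean()) / (f.std() + 1e-12)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lbl, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
    return lbl == (1 + int(np.argmax(sizes)))


def _leaf_thickness(rows: int, cols: int, rng: np.random.Generator) -> np.ndarray:
    """One connected irregular blob with internal holes."""
    f = _blob_field(rows, cols, rng, smooth=max(2.0, rows / 12))
    # bias toward the centre so the blob is a single compact object
    yy, xx = np.mgrid[0:rows, 0:cols]
    r2 = ((yy - rows / 2) / (0.55 * rows)) ** 2 + ((xx - cols / 2) / (0.55 * cols)) ** 2
    body = (f - f.min()) / (np.ptp(f) + 1e-12) + 0.55 - r2 > 0.55
    body = _largest_component(body)
    body = ndimage.binary_fill_holes(body)
    holes = _blob_field(rows, cols, rng, smooth=max(1.5, rows / 24)) > 1.0
    body &= ~holes
    body = _largest_component(body)  # hole carving must not disconnect the blob
    thick = ndimage.gaussian_filter(body.astype(float), 1.0) * 1.2
    return np.where(body, np.maximum(thick, 0.3), 0.0)


def _stone_fields(rows: int, cols: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Very thick matrix (no transmission) with hole regions of zero emission."""
    holes = _blob_field(rows, cols, rng, smooth=max(1.5, rows / 16)) > 0.9
    thick = np.full((rows, cols), 20.0)  # exp(-20) ~ 2e-9: effectively opaque
    thick[holes] = 15.0  # holes are still opaque; only XRF distinguishes them
    return thick, ~holes


def make_phantom(
    kind: str,
    rows: int,
    cols: int,
    pixel_size: float,
    elements=None,
    seed: int = 0,
    mu: float = DEFAULT_MU,
    halo: int = 1,
) -> GroundTruthSample:
    """Generate a synthetic ground-truth sample.

    Parameters
    ----------
    kind : {"filaments", "leaf", "stone"}
        Specimen class, see module docstring.
    rows, cols : int
        Grid size (>= 8 each).
    pixel_size : float
        Pixel pitch in micrometres.
    elements : sequence, optional
        Element labels (strings) or ``(label, region, rate)`` triples,
        where region is one of ``support, body, inclusions, trace`` and
        rate is the emission rate in counts/s at nominal flux. Plain
        labels take per-kind defaults. ``None`` uses the full per-kind
        default set.
    seed : int
        Deterministic generator seed.
    halo : int
        Dilation (pixels) of the support mask outside which sample-only
        element rates are exactly zero.
    """
    if kind not in ("filaments", "leaf", "stone"):
        raise ValueError(f"unknown phantom kind {kind!r}")
    if rows < 8 or cols < 8:
        raise ValueError("rows and cols must both be >= 8")
    if elements is None:
        elements = list(_DEFAULT_ELEMENTS[kind])
    profiles = _resolve_elements(kind, elements)
    rng = np.random.default_rng(seed)

    if kind == "filaments":
        thickness = _filament_thickness(rows, cols, rng)
        body = thickness > SUPPORT_THRESHOLD
    elif kind == "leaf":
        thickness = _leaf_thickness(rows, cols, rng)
        body = thickness > SUPPORT_THRESHOLD
    else:
        thickness, body = _stone_fields(rows, cols, rng)

    transmission, dpc_x, dpc_y, support = _derive_fields(thickness, mu)
    if kind == "stone":
        support = body  # opacity hides thickness; support = non-hole matrix

    halo_mask = ndimage.binary_dilation(support, iterations=max(halo, 1))
    inclusions = _blob_field(rows, cols, rng, smooth=max(1.0, rows / 20)) > 1.2

    xrf_rate: dict[str, np.ndarray] = {}
    for label, (region, rate) in profiles.items():
        grid = np.zeros((rows, cols))
        if region == "support":
            grid[:] = rate
        elif region == "body":
            grid[support] = rate
        elif region == "inclusions":
            grid[support & inclusions] = rate
        elif region == "trace":
            grid[support] = rate
        else:
            raise ValueError(f"unknown abundance region {region!r}")
        if region != "support":
            grid[~halo_mask] = 0.0
        xrf_rate[label] = grid

    return GroundTruthSample(
        thickness=thickness,
        transmission=transmission,
        dpc_x=dpc_x,
        dpc_y=dpc_y,
        xrf_rate=xrf_rate,
        support_mask=support,
        pixel_size=pixel_size,
        mu=mu,
        kind=kind,
    )


@dataclass
class BeamModel:
    """Storage-ring and diagnostics model, evaluated at elapsed seconds.

    Ring current decays exponentially from ``reference_current`` with a
    characteristic ``decay_time`` and is restored instantaneously every
    ``topup_period`` (sawtooth). Positional drift is a slow biperiodic
    wander of amplitude ``position_amp``; it couples into the four BPM
    blade currents with opposite signs on opposing blades and (weakly)
    into the delivered intensity.
    """

    reference_current: float = 300.0  # mA
    decay_time: float = 36_000.0  # s
    topup_period: float = 1_200.0  # s
    position_amp: float = 0.0  # um
    drift_period: float = 900.0  # s
    blade_gains: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    position_coupling: float = 0.1  # blade response per um of drift
    intensity_coupling: float = 0.05  # fractional flux loss at full drift
    motor_drift_rate: float = 0.0  # um/s
    nominal_flux: float = 20_000.0  # incident counts/s at reference current
    seed: int = 0
    _phases: tuple[float, float] = field(default=(0.0, 0.0), repr=False)

    def __post_init__(self):
        if self.decay_time <= 0:
            raise ValueError("decay_time must be > 0")
        if self.topup_period <= 0:
            raise ValueError("topup_period must be > 0")
        rng = np.random.default_rng(self.seed)
        self._phases = tuple(rng.uniform(0, 2 * math.pi, size=2))

    def ring_current(self, t: float) -> float:
        return self.reference_current * math.exp(-(t % self.topup_period) / self.decay_time)

    def position_drift(self, t: float) -> tuple[float, float]:
        if self.position_amp == 0.0:
            return (0.0, 0.0)
        w = 2 * math.pi / self.drift_period
        dx = self.position_amp * math.sin(w * t + self._phases[0])
        dy = self.position_amp * math.sin(w * t / 1.618 + self._phases[1])
        return (dx, dy)

    def intensity_factor(self, t: float) -> float:
        if self.position_amp == 0.0:
            return 1.0
        dx, dy = self.position_drift(t)
        frac = (dx * dx + dy * dy) / (2 * self.position_amp**2)
        return 1.0 - self.intensity_coupling * frac

    def blade_currents(self, t: float) -> np.ndarray:
        rc = self.ring_current(t)
        f = self.intensity_factor(t)
        dx, dy = self.position_drift(t)
        out = np.empty(4)
        for k, ang in enumerate(BLADE_ANGLES_DEG):
            proj = dx * math.cos(math.radians(ang)) + dy * math.sin(math.radians(ang))
            out[k] = self.blade_gains[k] * f * rc * (1.0 + self.position_coupling * proj)
        return out

    def flux(self, t: float) -> float:
        """Delivered incident flux (counts/s) at elapsed time t."""
        return self.nominal_flux * self.intensity_factor(t) * self.ring_current(t) / self.reference_current


def simulate_beam(
    duration: float,
    decay_time: float,
    topup_period: float,
    position_amp: float = 0.0,
    blade_gains=(1.0, 1.0, 1.0, 1.0),
    motor_drift_rate: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> BeamModel:
    """Construct a :class:`BeamModel` for a scan of the given duration.

    ``duration`` is validated but the model itself is analytic and can
    be evaluated at any elapsed time.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    return BeamModel(
        decay_time=decay_time,
        topup_period=topup_period,
        position_amp=position_amp,
        blade_gains=tuple(blade_gains),
        motor_drift_rate=motor_drift_rate,
        seed=seed,
        **kwargs,
    )


@dataclass
class PixelMeasurement:
    """Everything recorded at one scan point."""

    stxm_intensity: float | None
    dpc_x_meas: float | None
    dpc_y_meas: float | None
    xrf_counts: dict[str, int]
    dwell_stxm: float
    dwell_xrf: float
    ring_current: float
    blade_currents: np.ndarray
    nominal_position: tuple[float, float]
    actual_position: tuple[float, float]
    timestamp: float


def _drifted_index(
    sample: GroundTruthSample, nominal_ij: tuple[int, int], drift_um: float
) -> tuple[int, int]:
    i, j = nominal_ij
    shift = drift_um / sample.pixel_size
    ii = min(max(int(round(i + shift)), 0), sample.shape[0] - 1)
    jj = min(max(int(round(j + shift)), 0), sample.shape[1] - 1)
    return ii, jj


def measure_pixel(
    sample: GroundTruthSample,
    beam: BeamModel,
    nominal_position: tuple[int, int],
    t_elapsed: float,
    dwell_stxm: float,
    dwell_xrf: float,
    elements=(),
    rng: np.random.Generator | None = None,
    noise_sigma: float = 0.0,
) -> PixelMeasurement:
    """Simulate acquiring one pixel.

    A zero dwell means the corresponding modality is not acquired. The
    transmitted signal is ``flux(t) * transmission * dwell`` plus
    Gaussian readout noise; each requested element's counts are Poisson
    with mean ``rate * dwell * flux(t)/nominal_flux``. Under motor
    drift, the position actually illuminated is the nominal one plus
    ``motor_drift_rate * t_elapsed`` (clamped to the grid).
    """
    if dwell_stxm < 0 or dwell_xrf < 0:
        raise ValueError("dwell times must be >= 0")
    for el in elements:
        if el not in sample.xrf_rate:
            raise KeyError(f"unknown element label {el!r}")
    rng = np.random.default_rng() if rng is None else rng

    drift_um = beam.motor_drift_rate * t_elapsed
    ii, jj = _drifted_index(sample, nominal_position, drift_um)
    flux = beam.flux(t_elapsed)
    rel_flux = flux / beam.nominal_flux

    stxm = dpx = dpy = None
    if dwell_stxm > 0:
        stxm = flux * sample.transmission[ii, jj] * dwell_stxm
        dpx = sample.dpc_x[ii, jj] * rel_flux
        dpy = sample.dpc_y[ii, jj] * rel_flux
        if noise_sigma > 0:
            stxm += rng.normal(0.0, noise_sigma)
            dpx += rng.normal(0.0, noise_sigma * 1e-3)
            dpy += rng.normal(0.0, noise_sigma * 1e-3)

    counts: dict[str, int] = {}
    if dwell_xrf > 0:
        for el in elements:
            mean = sample.xrf_rate[el][ii, jj] * dwell_xrf * rel_flux
            counts[el] = int(rng.poisson(mean))

    x0 = nominal_position[1] * sample.pixel_size
    y0 = nominal_position[0] * sample.pixel_size
    return PixelMeasurement(
        stxm_intensity=stxm,
        dpc_x_meas=dpx,
        dpc_y_meas=dpy,
        xrf_counts=counts,
        dwell_stxm=dwell_stxm,
        dwell_xrf=dwell_xrf,
        ring_current=beam.ring_current(t_elapsed),
        blade_currents=beam.blade_currents(t_elapsed),
        nominal_position=(x0, y0),
        actual_position=(x0 + drift_um, y0 + drift_um),
        timestamp=t_elapsed,
    )


# spectral line energies (keV) for the rendering-only spectrum synthesizer
_LINE_ENERGY = {
    "C": 0.277, "N": 0.392, "O": 0.525, "Na": 1.041, "Mg": 1.254,
    "Al": 1.487, "Si": 1.740, "Se": 1.379,
}


def synthesize_spectrum(
    counts: dict[str, float],
    energy_axis: np.ndarray | None = None,
    fwhm: float = 0.08,
) -> tuple[np.ndarray, np.ndarray]:
    """Render an average XRF spectrum as a sum of Gaussian peaks.

    Presentation-only helper: trigger logic operates on per-element ROI
    count streams, never on this synthetic spectrum.
    """
    if energy_axis is None:
        energy_axis = np.linspace(0.2, 2.2, 600)
    sigma = fwhm / 2.3548
    spec = np.zeros_like(energy_axis)
    for el, c in counts.items():
        e0 = _LINE_ENERGY.get(el)
        if e0 is None:
            continue
        spec += c * np.exp(-0.5 * ((energy_axis - e0) / sigma) ** 2)
    return energy_axis, spec
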