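"""Ground-truthed synthetic voltage-clamp traces and synapse images.

The generators here emulate the two kinds of raw data the analysis consumes:

* whole-cell voltage-clamp current traces containing Poisson trains of
  postsynaptic currents (PSCs) from two kinetic populations (fast "Type 1",
  putative sensory, and slow "Type 2", putative corticothalamic) riding on
  Gaussian instrument noise with RMS ~ 1.4 pA at 20 kHz sampling;

* four-channel (homer / bassoon / VGLUT1 / VGLUT2) single-z-plane
  fluorescence images at 27 nm pixel size, with small pre/postsynaptic
  puncta, large bright VGLUT2 sensory terminals, diffuse somatic VGLUT2
  background, and planted colocalizations recorded as ground truth.

Every generator takes an explicit seed and is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traceio import Polarity, Trace

# --------------------------------------------------------------------------
# traces
# --------------------------------------------------------------------------

DEFAULT_SAMPLING_RATE = 20_000.0  # Hz
DEFAULT_RMS_NOISE = 1.4  # pA; 5 x RMS = 7 pA, the automated detection anchor
DEFAULT_TAU_RISE = 0.5  # ms


@dataclass
class TraceGroundTruth:
    """Planted events for one simulated trace."""

    event_times: np.ndarray  # s, sorted
    event_amplitudes: np.ndarray  # pA, magnitudes > 0
    event_types: np.ndarray  # 1 or 2 per event
    tau_decay_per_event: np.ndarray  # ms
    duration: float
    seed: int

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.event_amplitudes = np.asarray(self.event_amplitudes, dtype=float)
        self.event_types = np.asarray(self.event_types, dtype=int)
        self.tau_decay_per_event = np.asarray(self.tau_decay_per_event, dtype=float)
        n = self.event_times.size
        if not (self.event_amplitudes.size == self.event_types.size == self.tau_decay_per_event.size == n):
            raise ValueError("per-event arrays must have equal length")
        if n and (self.event_times.min() < 0 or self.event_times.max() >= self.duration):
            raise ValueError("event times must lie within [0, duration)")
        if np.any(np.diff(self.event_times) < 0):
            raise ValueError("event times must be sorted")
        if np.any(self.event_amplitudes <= 0):
            raise ValueError("amplitudes must be positive magnitudes")

    @property
    def n_events(self) -> int:
        return self.event_times.size


def psc_kernel(t_ms: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Peak-normalized biexponential PSC waveform.

    ``(exp(-t/tau_decay) - exp(-t/tau_rise))`` scaled so the maximum is 1;
    ``t_ms`` in milliseconds, zero before ``t = 0``.
    """
    if tau_rise <= 0 or tau_decay <= 0:
        raise ValueError("time constants must be positive")
    if tau_rise >= tau_decay:
        raise ValueError("tau_rise must be smaller than tau_decay")
    t = np.asarray(t_ms, dtype=float)
    y = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_decay) - np.exp(-np.maximum(t, 0) / tau_rise), 0.0)
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    return y / peak


def kernel_peak_time_ms(tau_rise: float, tau_decay: float) -> float:
    """Time of the biexponential kernel maximum after onset, in ms."""
    return tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)


def simulate_trace(
    duration: float = 180.0,
    rate_type1: float = 1.5,
    rate_type2: float = 1.5,
    tau1: float = 2.0,
    tau2: float = 8.0,
    amp_mean: float = 15.0,
    amp_sd: float = 4.0,
    rms_noise: float = DEFAULT_RMS_NOISE,
    polarity: Polarity = "inward",
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    seed: int = 0,
    tau_rise: float = DEFAULT_TAU_RISE,
    tau_jitter: float = 0.0,
    amp_floor: float = 5.0,
) -> tuple[Trace, TraceGroundTruth]:
    """Simulate a voltage-clamp trace with two Poisson PSC populations.

    Type 1 events decay with ``tau1`` (fast), Type 2 with ``tau2`` (slow);
    ``tau1 < tau2`` is required.  Amplitudes are drawn from a normal
    truncated below ``amp_floor`` so every planted event is a real deflection
    (detection-threshold tests stay well-posed).  ``tau_jitter`` is the
    relative SD of per-event decay constants (0.2 = 20% spread).

    Returns the trace (inward polarity gives negative deflections, as for
    EPSCs at -70 mV) together with the planted ground truth.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if sampling_rate < 10_000:
        raise ValueError(f"sampling_rate must be >= 10 kHz, got {sampling_rate}")
    if rate_type1 < 0 or rate_type2 < 0:
        raise ValueError("event rates must be non-negative")
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("decay constants must be positive")
    if tau1 >= tau2:
        raise ValueError(f"tau1 must be smaller than tau2 (Type 1 is the fast population); got {tau1} >= {tau2}")

    rng = np.random.default_rng(seed)
    n1 = rng.poisson(rate_type1 * duration)
    n2 = rng.poisson(rate_type2 * duration)
    times = np.concatenate([rng.uniform(0, duration, n1), rng.uniform(0, duration, n2)])
    types = np.concatenate([np.ones(n1, dtype=int), np.full(n2, 2, dtype=int)])
    order = np.argsort(times, kind="stable")
    times, types = times[order], types[order]
    n = times.size

    # truncated-normal amplitudes (resample below the floor)
    amps = rng.normal(amp_mean, amp_sd, n)
    for _ in range(100):
        bad = amps < amp_floor
        if not bad.any():
            break
        amps[bad] = rng.normal(amp_mean, amp_sd, bad.sum())
    amps = np.maximum(amps, amp_floor)

    taus = np.where(types == 1, tau1, tau2).astype(float)
    if tau_jitter > 0:
        taus = taus * np.exp(rng.normal(0.0, tau_jitter, n) - 0.5 * tau_jitter**2)
        taus = np.maximum(taus, tau_rise * 1.5)

    n_samples = int(round(duration * sampling_rate))
    current = np.zeros(n_samples)
    dt_ms = 1000.0 / sampling_rate
    sign = -1.0 if polarity == "inward" else 1.0
    for t0, a, tau in zip(times, amps, taus):
        i0 = int(np.ceil(t0 * sampling_rate))
        # render until the kernel tail is far below numerical noise
        tail_ms = tau * np.log(max(a, 1.0) * 1e12) + 8 * tau_rise
        length = min(int(np.ceil(tail_ms / dt_ms)) + 1, n_samples - i0)
        if length <= 0:
            continue
        t_rel = (np.arange(length) + (i0 - t0 * sampling_rate)) * dt_ms
        current[i0 : i0 + length] += sign * a * psc_kernel(t_rel, tau_rise, tau)

    if rms_noise > 0:
        current += rng.normal(0.0, rms_noise, n_samples)

    trace = Trace(
        sampling_rate=sampling_rate,
        current=current,
        holding_potential=-70.0 if polarity == "inward" else 0.0,
        polarity=polarity,
        seed=seed,
        meta={"tau_rise_ms": tau_rise},
    )
    truth = TraceGroundTruth(
        event_times=times,
        event_amplitudes=amps,
        event_types=types,
        tau_decay_per_event=taus,
        duration=duration,
        seed=seed,
    )
    return trace, truth


# --------------------------------------------------------------------------
# images
# --------------------------------------------------------------------------

DEFAULT_PIXEL_SIZE = 0.027  # µm, near-super-resolution spinning-disk sampling

CHANNELS = ("homer", "bassoon", "vglut1", "vglut2")

# rendering constants (arbitrary camera units)
_BASE = 50.0  # flat background offset per channel
_PUNCTUM_AMP = 1200.0
_PUNCTUM_SIGMA = 3.0  # px
_VGLUT1_AMP = 2500.0
_VGLUT1_SIGMA = 8.0
_VGLUT2_AMP = 3000.0
_VGLUT2_SIGMA = 12.0
_SPECKLE_VALUE = 1500.0  # single hot pixels in somatic VGLUT2 background
_GAUSS_NOISE_SD = 15.0

# default analysis thresholds matched to the rendering constants; these play
# the role of the per-session "empirically set" intensity thresholds
DEFAULT_MIN_INTENSITY = 400.0
DEFAULT_MAX_INTENSITY = 1000.0  # VGLUT positivity cutoff (upper threshold)


@dataclass
class ImageGroundTruth:
    """Planted object inventory for one simulated field of view."""

    puncta_centroids: dict = field(default_factory=dict)  # channel -> (n, 2) float array (row, col)
    puncta_areas: dict = field(default_factory=dict)  # channel -> areas in µm² (nominal, at threshold)
    planted_colocalizations: dict = field(default_factory=dict)  # homer_bassoon / vglut1_bassoon / vglut2_bassoon
    pixel_size: float = DEFAULT_PIXEL_SIZE
    shape: tuple = (0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for ch, c in self.puncta_centroids.items():
            c = np.asarray(c, dtype=float)
            if c.size and (
                c[:, 0].min() < 0 or c[:, 1].min() < 0 or c[:, 0].max() >= self.shape[0] or c[:, 1].max() >= self.shape[1]
            ):
                raise ValueError(f"{ch} centroids outside image bounds")
        if any(v < 0 for v in self.planted_colocalizations.values()):
            raise ValueError("planted counts must be >= 0")


class _Placer:
    """Rejection-samples blob centers with per-object exclusion radii."""

    def __init__(self, shape, rng, margin=40.0, gap=6.0, max_tries_per_object=400):
        self.shape = shape
        self.rng = rng
        self.margin = margin
        self.gap = gap
        self.max_tries = max_tries_per_object
        self.centers = np.empty((0, 2))
        self.radii = np.empty(0)

    def add(self, radius: float, near: tuple | None = None, near_r: float = 0.0) -> tuple[float, float]:
        h, w = self.shape
        for _ in range(self.max_tries):
            if near is None:
                r = self.rng.uniform(self.margin, h - self.margin)
                c = self.rng.uniform(self.margin, w - self.margin)
            else:
                ang = self.rng.uniform(0, 2 * np.pi)
                rad = self.rng.uniform(0, near_r)
                r = near[0] + rad * np.sin(ang)
                c = near[1] + rad * np.cos(ang)
                if not (self.margin <= r < h - self.margin and self.margin <= c < w - self.margin):
                    continue
            if self.centers.size:
                d = np.hypot(self.centers[:, 0] - r, self.centers[:, 1] - c)
                if np.any(d < self.radii + radius + self.gap):
                    continue
            self.centers = np.vstack([self.centers, [r, c]])
            self.radii = np.append(self.radii, radius)
            return (r, c)
        raise ValueError(
            "image too small to place the requested objects within the retry budget; "
            "increase the image size or reduce object counts"
        )

    def register(self, center: tuple, radius: float) -> None:
        self.centers = np.vstack([self.centers, center])
        self.radii = np.append(self.radii, radius)


def _render_gaussian(img: np.ndarray, center: tuple, amp: float, sigma: float) -> None:
    h, w = img.shape
    r0, c0 = center
    half = int(np.ceil(4 * sigma))
    r_lo, r_hi = max(0, int(r0) - half), min(h, int(r0) + half + 1)
    c_lo, c_hi = max(0, int(c0) - half), min(w, int(c0) + half + 1)
    rr, cc = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi), indexing="ij")
    img[r_lo:r_hi, c_lo:c_hi] += amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))


def _nominal_area(amp: float, sigma: float, threshold: float, pixel_size: float) -> float:
    """Area (µm²) of a Gaussian blob above an intensity threshold."""
    if amp <= threshold:
        return 0.0
    r = sigma * np.sqrt(2 * np.log(amp / threshold))
    return float(np.pi * r**2 * pixel_size**2)


def simulate_synapse_image(
    width: int = 2048,
    height: int = 2048,
    n_bassoon: int = 700,
    n_homer: int = 300,
    frac_homer_paired: float = 200.0 / 300.0,
    n_vglut1_terminals: int = 200,
    n_vglut2_terminals: int = 200,
    soma_background_level: float = 150.0,
    noise_model: str = "gaussian",
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    seed: int = 0,
    n_somas: int = 5,
    n_soma_speckles: int = 25,
) -> tuple[np.ndarray, ImageGroundTruth]:
    """Simulate a four-channel single-z-plane synaptic image.

    Channel order is ``(homer, bassoon, vglut1, vglut2)``.  Planted structure:

    * ``round(frac_homer_paired * n_homer)`` homer puncta are placed a few
      pixels from a partner bassoon punctum so their thresholded masks
      overlap (planted homer∩bassoon synapses);
    * every VGLUT1 / VGLUT2 terminal carries one bassoon punctum (planted
      VGLUT-positive bassoon);
    * remaining bassoon/homer puncta are isolated;
    * VGLUT2 additionally contains diffuse somatic background at
      ``soma_background_level`` plus single-pixel hot speckles beneath
      ``n_soma_speckles`` dedicated bassoon puncta — these emulate somatic
      VGLUT2 signal that a median blur must suppress and are *not* counted
      as planted colocalizations.

    Returns a ``(4, height, width)`` float array and the ground truth.
    """
    if min(width, height) <= 0:
        raise ValueError("image dimensions must be positive")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if not 0 <= frac_homer_paired <= 1:
        raise ValueError("frac_homer_paired must lie in [0, 1]")
    for name, v in [
        ("n_bassoon", n_bassoon),
        ("n_homer", n_homer),
        ("n_vglut1_terminals", n_vglut1_terminals),
        ("n_vglut2_terminals", n_vglut2_terminals),
    ]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0")

    n_paired = int(round(frac_homer_paired * n_homer)) if n_bassoon else 0
    n_paired = min(n_paired, n_bassoon)
    n_speckle_b = min(n_soma_speckles, max(0, n_bassoon - n_paired - n_vglut1_terminals - n_vglut2_terminals))
    n_special = n_paired + n_vglut1_terminals + n_vglut2_terminals + n_speckle_b
    if n_bassoon < n_paired + n_vglut1_terminals + n_vglut2_terminals:
        raise ValueError(
            f"n_bassoon={n_bassoon} too small for {n_paired} homer pairs plus "
            f"{n_vglut1_terminals + n_vglut2_terminals} VGLUT terminals"
        )
    n_free_bassoon = n_bassoon - n_special
    n_free_homer = n_homer - n_paired

    rng = np.random.default_rng(seed)
    shape = (height, width)
    img = np.full((4, height, width), _BASE, dtype=float)
    homer, bassoon, vglut1, vglut2 = img

    placer = _Placer(shape, rng)
    r_small, r_v1, r_v2 = 8.0, 18.0, 27.0

    centroids: dict[str, list] = {ch: [] for ch in CHANNELS}
    areas: dict[str, list] = {ch: [] for ch in CHANNELS}
    punctum_area = _nominal_area(_PUNCTUM_AMP, _PUNCTUM_SIGMA, DEFAULT_MIN_INTENSITY - _BASE, pixel_size)

    def plant_punctum(channel_img, channel, center):
        _render_gaussian(channel_img, center, _PUNCTUM_AMP, _PUNCTUM_SIGMA)
        centroids[channel].append(center)
        areas[channel].append(punctum_area)

    # somata: diffuse VGLUT2 background regions; dim and smooth, so they do
    # not take part in object-placement exclusion (puncta may sit on them)
    soma_centers: list[tuple[float, float]] = []
    soma_margin = min(150.0, height / 3.0, width / 3.0)
    for _ in range(n_somas):
        for _ in range(200):
            c = (rng.uniform(soma_margin, height - soma_margin), rng.uniform(soma_margin, width - soma_margin))
            if all(np.hypot(c[0] - s[0], c[1] - s[1]) >= 250.0 for s in soma_centers):
                break
        soma_centers.append(c)
        _render_gaussian(vglut2, c, soma_background_level, 70.0)

    # VGLUT terminals, each with one bassoon punctum on top
    for _ in range(n_vglut2_terminals):
        c = placer.add(r_v2)
        _render_gaussian(vglut2, c, _VGLUT2_AMP, _VGLUT2_SIGMA)
        centroids["vglut2"].append(c)
        areas["vglut2"].append(_nominal_area(_VGLUT2_AMP, _VGLUT2_SIGMA, DEFAULT_MIN_INTENSITY - _BASE, pixel_size))
        off = rng.uniform(-3, 3, 2)
        plant_punctum(bassoon, "bassoon", (c[0] + off[0], c[1] + off[1]))
    for _ in range(n_vglut1_terminals):
        c = placer.add(r_v1)
        _render_gaussian(vglut1, c, _VGLUT1_AMP, _VGLUT1_SIGMA)
        centroids["vglut1"].append(c)
        areas["vglut1"].append(_nominal_area(_VGLUT1_AMP, _VGLUT1_SIGMA, DEFAULT_MIN_INTENSITY - _BASE, pixel_size))
        off = rng.uniform(-3, 3, 2)
        plant_punctum(bassoon, "bassoon", (c[0] + off[0], c[1] + off[1]))

    # paired homer-bassoon synapses
    for _ in range(n_paired):
        c = placer.add(r_small)
        plant_punctum(bassoon, "bassoon", c)
        ang = rng.uniform(0, 2 * np.pi)
        hc = (c[0] + 3.0 * np.sin(ang), c[1] + 3.0 * np.cos(ang))
        plant_punctum(homer, "homer", hc)

    # bassoon puncta sitting on somatic speckle (hot single pixels in VGLUT2)
    for i in range(n_speckle_b):
        soma = soma_centers[i % len(soma_centers)] if soma_centers else None
        c = placer.add(r_small, near=soma, near_r=60.0) if soma else placer.add(r_small)
        plant_punctum(bassoon, "bassoon", c)
        pr, pc = int(round(c[0])), int(round(c[1]))
        vglut2[pr, pc] = max(vglut2[pr, pc], _SPECKLE_VALUE)

    # isolated puncta
    for _ in range(n_free_bassoon):
        plant_punctum(bassoon, "bassoon", placer.add(r_small))
    for _ in range(n_free_homer):
        plant_punctum(homer, "homer", placer.add(r_small))

    if noise_model == "gaussian":
        img += rng.normal(0.0, _GAUSS_NOISE_SD, img.shape)
    elif noise_model == "poisson":
        img = rng.poisson(np.maximum(img, 0.0)).astype(float)
    else:
        raise ValueError(f"unknown noise_model {noise_model!r}")
    img = np.maximum(img, 0.0)

    truth = ImageGroundTruth(
        puncta_centroids={ch: np.asarray(centroids[ch]).reshape(-1, 2) for ch in CHANNELS},
        puncta_areas={ch: np.asarray(areas[ch]) for ch in CHANNELS},
        planted_colocalizations={
            "homer_bassoon": n_paired,
            "vglut1_bassoon": n_vglut1_terminals,
            "vglut2_bassoon": n_vglut2_terminals,
        },
        pixel_size=pixel_size,
        shape=shape,
        seed=seed,
    )
    return img, truth


def write_image(img: np.ndarray, path, pixel_size: float = DEFAULT_PIXEL_SIZE) -> None:
    """Write a multichannel image as a multipage TIFF (one page per channel)."""
    import tifffile

    res = 1.0 / pixel_size  # pixels per micron
    tifffile.imwrite(
        path,
        np.asarray(img, dtype=np.float32),
        resolution=(res, res),
        metadata={"axes": "CYX", "pixel_size_um": pixel_size, "channels": list(CHANNELS)},
    )


def read_image(path) -> tuple[np.ndarray, float | None]:
    """Read a multipage TIFF; returns (channels-first array, pixel size in µm or None)."""
    import json

    import tifffile

    with tifffile.TiffFile(path) as tf:
        img = tf.asarray().astype(float)
        pixel_size = None
        desc = tf.pages[0].description
        if desc:
            try:
                pixel_size = json.loads(desc).get("pixel_size_um")
            except (ValueError, AttributeError):
                pixel_size = None
    return img, pixel_size
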