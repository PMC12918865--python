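"""Decay-kinetics measurement and bimodal Type 1 / Type 2 separation.

Miniature EPSCs onto thalamocortical relay neurons arise from two synapse
populations with distinct decay kinetics: fast events from ascending sensory
terminals and slow events from corticothalamic terminals.  The procedure
implemented here separates them per cell:

1. each event's decay is summarized by a monoexponential time constant
   fitted between the 70% and 30% of-peak crossings of its decay phase;
2. the per-cell decay distribution is tested for multimodality;
3. the decay histogram is interpolated with an Akima spline, and the
   x-intercept of the spline's first derivative between the two dominant
   modes — the location of the inter-mode minimum — is taken as the
   *critical value*;
4. events with decay below the critical value are labelled Type 1 (fast,
   putative sensory), the rest Type 2 (slow, putative corticothalamic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import Akima1DInterpolator
from scipy.optimize import brentq, curve_fit

from .detect import Event, oriented
from .traceio import Trace

logger = logging.getLogger(__name__)

MIN_EVENTS_FOR_MULTIMODALITY = 30


class SeparationError(RuntimeError):
    """Raised when a decay distribution cannot be split into two modes."""


# --------------------------------------------------------------------------
# per-event decay metric
# --------------------------------------------------------------------------

def _crossing_time(t: np.ndarray, y: np.ndarray, level: float, start: int) -> tuple[float, int] | None:
    """First downward crossing of ``level`` at or after index ``start``
    (linear interpolation between samples)."""
    below = np.flatnonzero(y[start:] <= level)
    if below.size == 0:
        return None
    i = start + below[0]
    if i == start or y[i - 1] <= level:
        return float(t[i]), i
    frac = (y[i - 1] - level) / (y[i - 1] - y[i])
    return float(t[i - 1] + frac * (t[i] - t[i - 1])), i


def _edge_padded_boxcar(y: np.ndarray, k: int) -> np.ndarray:
    """Centered moving average with edge-value padding.

    A boxcar average of a pure exponential is the same exponential up to a
    constant factor, so this smoothing stabilizes the of-peak crossing
    detection without perturbing the fitted time constant.
    """
    if k <= 1:
        return y
    pad = k // 2
    yp = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
    return np.convolve(yp, np.ones(k) / k, mode="valid")


def fit_decay_3070(
    trace: Trace,
    event: Event,
    metric: str = "tau",
    next_onset_index: int | None = None,
    max_window_ms: float = 60.0,
    smooth_ms: float = 0.35,
) -> float | None:
    """Decay metric (ms) fitted over the 30-70% of-peak decay segment.

    ``metric="tau"`` (default) fits a monoexponential time constant to the
    samples between the 70% and 30% of-peak crossings; ``metric="transit"``
    returns the 70-to-30% transit time instead (equal to ``tau * ln(7/3)``
    for a pure exponential).  The decay segment is smoothed with a short
    edge-padded boxcar (``smooth_ms``) before locating the crossings — noisy
    single-sample threshold crossings otherwise bias the fit window — and
    the fit uses the event's measured amplitude as the peak reference when
    available.  Returns ``None`` — the event is flagged unmeasurable and
    excluded from the distribution — when the decay never reaches 30% of
    peak before the next event onset or the window end.
    """
    if metric not in ("tau", "transit"):
        raise ValueError(f"unknown metric {metric!r}")
    rate = trace.sampling_rate
    y = oriented(trace) - event.baseline
    p = event.peak_index
    if p < 0:
        raise ValueError("event must carry a peak_index into the trace")
    end = min(y.size, p + int(max_window_ms / 1000.0 * rate))
    if next_onset_index is not None:
        end = min(end, next_onset_index)
    seg = y[p:end]
    if seg.size < 3:
        logger.debug("event at %.4fs: decay window too short", event.peak_time)
        return None
    k = int(round(smooth_ms / 1000.0 * rate))
    k += 1 - k % 2  # odd
    ys = _edge_padded_boxcar(seg, max(1, k))
    peak_ref = event.amplitude if event.amplitude > 0 else ys[0]
    if ys[0] <= 0.7 * peak_ref:
        peak_ref = ys[0]
    if peak_ref <= 0:
        return None
    t_ms = np.arange(seg.size) / rate * 1000.0

    c70 = _crossing_time(t_ms, ys, 0.7 * peak_ref, 0)
    if c70 is None:
        logger.debug("event at %.4fs: never decays to 70%% of peak", event.peak_time)
        return None
    t70, i70 = c70
    c30 = _crossing_time(t_ms, ys, 0.3 * peak_ref, i70)
    if c30 is None:
        logger.debug("event at %.4fs: never decays to 30%% of peak", event.peak_time)
        return None
    t30, i30 = c30

    if metric == "transit":
        return float(t30 - t70)

    ts, yy = t_ms[i70:i30], ys[i70:i30]
    pos = yy > 0
    ts, yy = ts[pos], yy[pos]
    if ts.size < 2:
        return None
    # log-linear initialization, then exponential least-squares refinement
    slope, intercept = np.polyfit(ts, np.log(yy), 1)
    if slope >= 0:
        return None
    tau0 = -1.0 / slope
    try:
        popt, _ = curve_fit(
            lambda t, a, tau: a * np.exp(-t / tau),
            ts, yy, p0=[np.exp(intercept), tau0], maxfev=400,
        )
        tau = float(popt[1])
    except RuntimeError:
        tau = tau0
    if not np.isfinite(tau) or tau <= 0:
        return None
    return tau


def measure_decays(trace: Trace, events: list[Event], metric: str = "tau") -> list[Event]:
    """Fill ``decay_metric`` for every event in place (None where unmeasurable)."""
    for k, e in enumerate(events):
        nxt = events[k + 1].onset_index if k + 1 < len(events) and events[k + 1].onset_index >= 0 else None
        e.decay_metric = fit_decay_3070(trace, e, metric=metric, next_onset_index=nxt)
    n_bad = sum(e.decay_metric is None for e in events)
    if n_bad:
        logger.info("%d of %d events had unmeasurable decays and were excluded", n_bad, len(events))
    return events


# --------------------------------------------------------------------------
# multimodality test
# --------------------------------------------------------------------------

_NULL_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _gmm_loglik_2(x: np.ndarray, random_state: int = 0) -> float:
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(n_components=2, covariance_type="full", n_init=2,
                         reg_covar=1e-3, random_state=random_state, max_iter=200)
    gm.fit(x.reshape(-1, 1))
    return float(gm.score(x.reshape(-1, 1)) * x.size)


def _lrt_statistic(x: np.ndarray) -> float:
    """2*(log L_2 - log L_1) for two- vs one-component Gaussian fits,
    computed on standardized data (the statistic is affine-invariant)."""
    z = (x - x.mean()) / x.std(ddof=0)
    ll1 = float(np.sum(-0.5 * np.log(2 * np.pi) - 0.5 * np.log(z.std(ddof=0) ** 2) - 0.5 * (z - z.mean()) ** 2 / z.std(ddof=0) ** 2))
    ll2 = _gmm_loglik_2(z)
    return max(0.0, 2.0 * (ll2 - ll1))


def _null_lrt(n: int, n_boot: int) -> np.ndarray:
    """Parametric-bootstrap null LRT distribution for sample size ``n``.

    Because the statistic is invariant to location/scale, the Gaussian null
    distribution depends only on ``n``; it is cached and reused.
    """
    key = (n, n_boot)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(2_000_000 + n)
        _NULL_CACHE[key] = np.array([_lrt_statistic(rng.standard_normal(n)) for _ in range(n_boot)])
    return _NULL_CACHE[key]


def test_multimodality(decay_values: np.ndarray, n_boot: int = 199) -> float:
    """p-value against the null of a unimodal (single-Gaussian) distribution.

    A two- vs one-component Gaussian-mixture likelihood-ratio statistic is
    compared with its parametric-bootstrap null distribution; small p means
    the per-cell decay distribution is multimodal.
    """
    x = np.asarray(decay_values, dtype=float)
    if x.size < MIN_EVENTS_FOR_MULTIMODALITY:
        raise ValueError(
            f"need at least {MIN_EVENTS_FOR_MULTIMODALITY} decay values, got {x.size}"
        )
    if np.ptp(x) == 0:
        return 1.0
    obs = _lrt_statistic(x)
    null = _null_lrt(x.size, n_boot)
    return float((1 + np.sum(null >= obs)) / (n_boot + 1))


# --------------------------------------------------------------------------
# Akima spline and critical value
# --------------------------------------------------------------------------

def akima_spline(nodes) -> Akima1DInterpolator:
    """Akima's piecewise-cubic interpolant through ``(x, y)`` nodes.

    Uses Akima's original slope-weighting rule; the spline passes through
    every node and has a continuous first derivative (available via
    ``.derivative()``).  Requires >= 5 nodes with strictly increasing x.
    """
    nodes = np.asarray(nodes, dtype=float)
    if nodes.ndim != 2 or nodes.shape[1] != 2:
        raise ValueError("nodes must be (n, 2) pairs")
    x, y = nodes[:, 0], nodes[:, 1]
    if x.size < 5:
        raise ValueError(f"need at least 5 nodes, got {x.size}")
    if np.any(np.diff(x) <= 0):
        raise ValueError("node x values must be strictly increasing (no duplicates)")
    return Akima1DInterpolator(x, y, method="akima")


def find_modes(spline: Akima1DInterpolator, min_separation: float, n_grid: int = 2000) -> tuple[float, float]:
    """The two dominant local maxima of the spline.

    Candidates are local maxima of the spline on a dense grid over the node
    range; the two tallest separated by at least ``min_separation`` are
    returned (ties broken toward the wider-separated pair).  Raises
    :class:`SeparationError` when fewer than two such modes exist.
    """
    x0, x1 = spline.x[0], spline.x[-1]
    xs = np.linspace(x0, x1, n_grid)
    ys = spline(xs)
    interior = (ys[1:-1] >= ys[:-2]) & (ys[1:-1] > ys[2:])
    cand_x = xs[1:-1][interior]
    cand_y = ys[1:-1][interior]
    if ys[0] > ys[1]:
        cand_x, cand_y = np.append(cand_x, x0), np.append(cand_y, ys[0])
    if ys[-1] > ys[-2]:
        cand_x, cand_y = np.append(cand_x, x1), np.append(cand_y, ys[-1])
    if cand_x.size < 2:
        raise SeparationError("fewer than two local maxima in the spline")
    order = np.argsort(cand_y)[::-1]
    best: tuple[float, tuple[float, float]] | None = None
    primary = cand_x[order[0]]
    for j in order[1:]:
        sep = abs(cand_x[j] - primary)
        if sep >= min_separation:
            score = cand_y[j]
            if best is None or score > best[0] + 1e-12 or (
                abs(score - best[0]) <= 1e-12 and sep > abs(best[1][1] - best[1][0])
            ):
                best = (score, (primary, cand_x[j]))
    if best is None:
        raise SeparationError("no pair of modes with the required separation")
    m1, m2 = sorted(best[1])
    return float(m1), float(m2)


def find_critical_value(spline: Akima1DInterpolator, mode_locations: tuple[float, float],
                        tol: float = 1e-6, oversample: int = 10) -> float:
    """Derivative x-intercept between the two modes: the decay time at the
    spline's inter-mode minimum.

    Sign changes of the first derivative are bracketed on a grid oversampled
    ``oversample``-fold relative to the node spacing, then refined by root
    bisection to ``tol`` (ms).  Among the derivative zeros strictly between
    the modes, the one where the spline is lowest is returned.  Raises
    :class:`SeparationError` when the derivative never changes sign between
    the modes.
    """
    m1, m2 = sorted(mode_locations)
    if not m2 > m1:
        raise ValueError("mode locations must be distinct")
    deriv = spline.derivative()
    dx = np.median(np.diff(spline.x)) / oversample
    n = max(int(np.ceil((m2 - m1) / dx)), 10)
    xs = np.linspace(m1, m2, n + 1)[1:-1]
    ds = deriv(xs)
    sign_change = np.flatnonzero(np.sign(ds[:-1]) * np.sign(ds[1:]) < 0)
    roots = [float(xs[i]) for i in np.flatnonzero(ds == 0)]
    for i in sign_change:
        roots.append(float(brentq(deriv, xs[i], xs[i + 1], xtol=tol)))
    roots = [r for r in roots if m1 < r < m2]
    if not roots:
        raise SeparationError("first derivative has no x-intercept between the modes")
    values = spline(np.array(roots))
    return float(roots[int(np.argmin(values))])


# --------------------------------------------------------------------------
# distribution container and classification
# --------------------------------------------------------------------------

@dataclass
class DecayDistribution:
    """Per-cell decay histogram with its spline-based split."""

    decay_values: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    multimodality_p: float
    spline_nodes: np.ndarray  # (bin center, count) pairs
    mode_locations: tuple[float, float] | None
    critical_value: float | None
    separable: bool

    def __post_init__(self) -> None:
        if self.counts.sum() != self.decay_values.size:
            raise ValueError("histogram counts must sum to the number of events")
        if not 0 <= self.multimodality_p <= 1:
            raise ValueError("multimodality_p must lie in [0, 1]")
        if self.separable:
            m1, m2 = self.mode_locations
            if not m1 < self.critical_value < m2:
                raise ValueError("critical value must lie strictly between the modes")


def decay_histogram(values: np.ndarray, bins="fd", min_bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of decay values; Freedman-Diaconis binning by default,
    widened to at least ``min_bins`` bins — on a wide two-mode distribution
    the FD rule alone can be too coarse to resolve the fast mode."""
    values = np.asarray(values, dtype=float)
    edges = np.histogram_bin_edges(values, bins=bins)
    if edges.size - 1 < min_bins:
        edges = np.histogram_bin_edges(values, bins=min_bins)
    counts, edges = np.histogram(values, bins=edges)
    return counts, edges


def analyze_decay_distribution(decay_values, bins="fd", n_boot: int = 199,
                               min_mode_separation_bins: int = 2) -> DecayDistribution:
    """Full per-cell separation: histogram, multimodality p, Akima spline,
    two modes and the critical value (``separable=False`` on failure)."""
    values = np.asarray([v for v in np.ravel(decay_values) if v is not None and np.isfinite(v)], dtype=float)
    counts, edges = decay_histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = test_multimodality(values, n_boot=n_boot)
    nodes = np.column_stack([centers, counts])
    bin_width = edges[1] - edges[0]
    try:
        spline = akima_spline(nodes)
        modes = find_modes(spline, min_separation=min_mode_separation_bins * bin_width)
        critical = find_critical_value(spline, modes)
        return DecayDistribution(values, edges, counts, p, nodes, modes, critical, True)
    except (SeparationError, ValueError) as exc:
        logger.info("decay distribution not separable: %s", exc)
        return DecayDistribution(values, edges, counts, p, nodes, None, None, False)


@dataclass
class TypedEventSet:
    """Events partitioned at the critical value, with per-type rates."""

    type1_events: list[Event]
    type2_events: list[Event]
    critical_value: float
    analyzed_duration: float

    @property
    def type1_frequency(self) -> float:
        return len(self.type1_events) / self.analyzed_duration

    @property
    def type2_frequency(self) -> float:
        return len(self.type2_events) / self.analyzed_duration

    def mean_amplitude(self, which: int) -> float:
        evs = self.type1_events if which == 1 else self.type2_events
        return float(np.mean([e.amplitude for e in evs])) if evs else float("nan")


def classify_events(events: list[Event], critical_value: float, analyzed_duration: float) -> TypedEventSet:
    """Split events at the critical value: decay < critical -> Type 1 (fast,
    putative sensory); decay >= critical -> Type 2 (slow, putative
    corticothalamic).  Events without a measured decay are excluded (logged).
    """
    if critical_value <= 0:
        raise ValueError("critical_value must be positive")
    if analyzed_duration <= 0:
        raise ValueError("analyzed_duration must be positive")
    t1: list[Event] = []
    t2: list[Event] = []
    n_skipped = 0
    for e in events:
        if e.decay_metric is None or not np.isfinite(e.decay_metric):
            n_skipped += 1
            continue
        if e.decay_metric < critical_value:
            e.type_label = "Type1"
            t1.append(e)
        else:
            e.type_label = "Type2"
            t2.append(e)
    if n_skipped:
        logger.info("%d events without a decay metric excluded from classification", n_skipped)
    return TypedEventSet(t1, t2, critical_value, analyzed_duration)
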