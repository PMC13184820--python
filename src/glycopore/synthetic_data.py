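"""Synthetic single-channel traces and event populations.

Generates ionic-current recordings with the statistical structure the analysis
pipeline assumes: an open-pore baseline (white noise plus a slow random-walk
drift, low-pass filtered), Poisson blockade-event arrivals, per-class Gaussian
blockade depths, single- or biexponential dwell-time distributions, AR(1)
intra-event fluctuations, and rectangular spike excursions toward the
baseline. An optional background process emulates lysate interference
(collision-like short events of wildly variable amplitude plus extra baseline
noise).

Class presets carry the published per-glycan kinetics for the engineered
α-hemolysin pores: event frequency 45.04 s⁻¹ and a 0.40 ms single-exponential
dwell for GT1c on M113R; biexponential τ_slow = 3.19 ms / τ_fast = 0.08 ms for
GT1c on the M113R/K147Y double mutant; Gaussian ΔI₁/I₀ means 0.97 / 0.92 /
0.92 / 0.95 and dwell constants 0.23 / 0.19 / 0.50 ms for GT1c / GT1b / GT1a /
GT1aα. Fluctuation-spectrum and spike parameters are not published; the preset
values are chosen to make the classes spectrally distinct (see docs/methods.md).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .trace_io import EventBoundaryTable, Trace, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ClassSpec",
    "BackgroundSpec",
    "GeneratorConfig",
    "class_presets",
    "background_preset",
    "simulate_dwell_times",
    "simulate_event_segment",
    "simulate_trace",
    "simulate_labeled_events",
    "SyntheticEvent",
]


@dataclass(frozen=True)
class ClassSpec:
    """Event-generating parameters for one analyte class.

    ``depth_mean``/``depth_sd`` parameterize the Gaussian of normalized
    blockade depth ΔI₁/I₀; ``intra_ar1_rho`` is the lag-1 autocorrelation of
    the stationary AR(1) intra-event fluctuation (its marginal SD is
    ``intra_noise_sd`` pA); spikes are brief rectangular excursions toward the
    open-pore level with Poisson rate ``spike_rate`` per ms.
    """

    name: str
    event_rate: float                 # events/s (Poisson arrival intensity)
    dwell_model: str = "single"       # "single" | "biexponential"
    tau_slow: float = 1.0             # ms
    tau_fast: float = 0.1             # ms (unused if single)
    w_slow: float = 1.0               # mixture weight of slow component
    depth_mean: float = 0.9           # fraction of I0
    depth_sd: float = 0.01
    intra_ar1_rho: float = 0.5
    intra_noise_sd: float = 2.0       # pA
    spike_rate: float = 0.2           # spikes/ms
    spike_amp: float = 8.0            # pA, toward baseline
    spike_width: int = 2              # samples
    non_paper: bool = False           # kinetic parameters not from a printed value

    def __post_init__(self) -> None:
        if self.dwell_model not in ("single", "biexponential"):
            raise ValidationError(f"unknown dwell_model {self.dwell_model!r}")
        if not (self.tau_slow > 0 and self.tau_fast > 0):
            raise ValidationError("time constants must be positive")
        if self.tau_slow < self.tau_fast:
            raise ValidationError("tau_slow must be >= tau_fast")
        if not (0.0 <= self.w_slow <= 1.0):
            raise ValidationError("w_slow must lie in [0, 1]")
        if not (0.0 < self.depth_mean <= 1.0):
            raise ValidationError("depth_mean must lie in (0, 1]")
        if not (0.0 <= self.intra_ar1_rho < 1.0):
            raise ValidationError("intra_ar1_rho must lie in [0, 1)")
        if not (self.event_rate > 0):
            raise ValidationError("event_rate must be positive")


@dataclass(frozen=True)
class BackgroundSpec:
    """Collision-like interference events (lysate-style background)."""

    rate: float = 10.0                # events/s
    dwell_scale: float = 0.1          # ms, single exponential (short)
    depth_low: float = 0.05           # uniform depth range (wide, unstable)
    depth_high: float = 0.95
    extra_baseline_noise_sd: float = 1.0  # pA added to the open-pore noise

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValidationError("background rate must be >= 0")
        if not (0 <= self.depth_low < self.depth_high <= 1):
            raise ValidationError("background depth range must satisfy 0 <= low < high <= 1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full trace-generation recipe.

    Defaults mirror the recording conditions of the emulated experiments:
    50 kHz sampling, 5 kHz low-pass, open-pore current 100 pA (the analyses
    only use ratios, so the absolute level is immaterial).
    """

    classes: tuple = ()               # sequence of (ClassSpec, mixing weight)
    sampling_rate: float = 50_000.0   # Hz
    filter_cutoff: float = 5_000.0    # Hz
    duration: float = 10.0            # s
    open_pore_current: float = 100.0  # pA
    baseline_noise_sd: float = 1.0    # pA
    baseline_drift_sd: float = 0.3    # pA per sqrt(s) random walk
    background: BackgroundSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.filter_cutoff < self.sampling_rate / 2):
            raise ValidationError("filter_cutoff must be below Nyquist")
        if not (self.duration > 0):
            raise ValidationError("duration must be positive")
        if self.classes:
            total = sum(w for _, w in self.classes)
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"mixing weights must sum to 1, got {total}")


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def class_presets() -> dict:
    """Per-glycan generator presets keyed by class name.

    GT1c carries the biexponential dwell kinetics of the double-mutant pore;
    GT1b/GT1a/GT1aα are single-exponential with the published time constants
    and depth Gaussians. GQ1c/GP1c kinetics are not printed in the source
    study and use distinct placeholder values (``non_paper=True``).
    ``"GT1c_M113R"`` is the single-mutant preset (0.40 ms dwell, 45.04 s⁻¹).
    Fluctuation/spike parameters are design choices made for class
    separability; see docs/methods.md.
    """
    presets = {
        "GT1c": ClassSpec(
            name="GT1c", event_rate=45.04, dwell_model="biexponential",
            tau_slow=3.19, tau_fast=0.08, w_slow=0.5,
            depth_mean=0.97, depth_sd=0.005,
            intra_ar1_rho=0.30, intra_noise_sd=1.5,
            spike_rate=0.3, spike_amp=15.0, spike_width=3,
        ),
        "GT1b": ClassSpec(
            name="GT1b", event_rate=30.0, dwell_model="single",
            tau_slow=0.23, tau_fast=0.23,
            depth_mean=0.92, depth_sd=0.005,
            intra_ar1_rho=0.10, intra_noise_sd=0.4,
            spike_rate=0.05, spike_amp=8.0, spike_width=2,
        ),
        "GT1a": ClassSpec(
            name="GT1a", event_rate=30.0, dwell_model="single",
            tau_slow=0.19, tau_fast=0.19,
            depth_mean=0.92, depth_sd=0.008,
            intra_ar1_rho=0.30, intra_noise_sd=2.0,
            spike_rate=3.0, spike_amp=20.0, spike_width=2,
        ),
        "GT1aα": ClassSpec(
            name="GT1aα", event_rate=25.0, dwell_model="single",
            tau_slow=0.50, tau_fast=0.50,
            depth_mean=0.95, depth_sd=0.006,
            intra_ar1_rho=0.85, intra_noise_sd=1.0,
            spike_rate=8.0, spike_amp=30.0, spike_width=2,
        ),
        "GQ1c": ClassSpec(
            name="GQ1c", event_rate=20.0, dwell_model="single",
            tau_slow=1.0, tau_fast=1.0,
            depth_mean=0.98, depth_sd=0.004,
            intra_ar1_rho=0.60, intra_noise_sd=1.0,
            spike_rate=0.5, spike_amp=12.0, spike_width=2,
            non_paper=True,
        ),
        "GP1c": ClassSpec(
            name="GP1c", event_rate=20.0, dwell_model="single",
            tau_slow=2.0, tau_fast=2.0,
            depth_mean=0.99, depth_sd=0.003,
            intra_ar1_rho=0.50, intra_noise_sd=0.8,
            spike_rate=0.1, spike_amp=8.0, spike_width=3,
            non_paper=True,
        ),
        # GT1c on the single mutant M113R: highest capture rate, short dwell.
        "GT1c_M113R": ClassSpec(
            name="GT1c_M113R", event_rate=45.04, dwell_model="single",
            tau_slow=0.40, tau_fast=0.40,
            depth_mean=0.97, depth_sd=0.005,
            intra_ar1_rho=0.30, intra_noise_sd=1.5,
            spike_rate=0.3, spike_amp=15.0, spike_width=3,
        ),
        "background": background_preset(),
    }
    return presets


def background_preset() -> BackgroundSpec:
    return BackgroundSpec(rate=10.0, dwell_scale=0.1, depth_low=0.05,
                          depth_high=0.95, extra_baseline_noise_sd=1.0)


# ---------------------------------------------------------------------------
# Dwell times
# ---------------------------------------------------------------------------

def simulate_dwell_times(spec: ClassSpec, n: int, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. dwell times (ms) from the spec's exponential mixture."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if spec.dwell_model == "single":
        return rng.exponential(spec.tau_slow, size=n)
    slow = rng.random(n) < spec.w_slow
    taus = np.where(slow, spec.tau_slow, spec.tau_fast)
    return rng.exponential(1.0, size=n) * taus


# ---------------------------------------------------------------------------
# Intra-event signal
# ---------------------------------------------------------------------------

def _ar1_noise(rng, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series of length n with lag-1 correlation rho, marginal SD sd."""
    if sd == 0.0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=n)
    innov[0] = rng.normal(0.0, sd)  # stationary start
    if rho == 0.0:
        return innov
    return signal.lfilter([1.0], [1.0, -rho], innov)


def simulate_event_segment(
    spec: ClassSpec,
    I0: float,
    n_samples: int,
    sampling_rate: float,
    seed,
    depth: float | None = None,
) -> np.ndarray:
    """One blockade-event segment (pA): level + AR(1) noise + spikes.

    The mean level is ``I0 * (1 - depth)`` with the depth drawn from the
    class's Gaussian (truncated to (0, 1]) unless supplied. Spikes are
    rectangular excursions of ``spike_width`` samples toward the open-pore
    level.
    """
    if n_samples < 2:
        raise ValidationError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    if depth is None:
        depth = float(np.clip(rng.normal(spec.depth_mean, spec.depth_sd), 1e-6, 1.0))
    level = I0 * (1.0 - depth)
    seg = level + _ar1_noise(rng, n_samples, spec.intra_ar1_rho, spec.intra_noise_sd)
    dwell_ms = n_samples / sampling_rate * 1000.0
    n_spikes = rng.poisson(spec.spike_rate * dwell_ms)
    for _ in range(n_spikes):
        s = rng.integers(0, n_samples)
        seg[s : s + spec.spike_width] += spec.spike_amp
    return seg


# ---------------------------------------------------------------------------
# Full traces
# ---------------------------------------------------------------------------

def simulate_trace(config: GeneratorConfig) -> tuple[Trace, EventBoundaryTable]:
    """Generate a trace and its ground-truth labelled event table.

    Events are placed by merged Poisson arrivals over all classes (arrival
    intensity = Σ weight·event_rate); an arrival that would overlap an ongoing
    event is dropped and counted (logged). Background collision events, if
    configured, are placed by the same occupancy rule. The final trace is
    low-pass filtered (4-pole Butterworth, zero-phase) at ``filter_cutoff``.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    I0 = config.open_pore_current

    noise_sd = config.baseline_noise_sd
    if config.background is not None:
        noise_sd = float(np.hypot(noise_sd, config.background.extra_baseline_noise_sd))
    trace = rng.normal(I0, noise_sd, size=n)
    if config.baseline_drift_sd > 0:
        trace += np.cumsum(rng.normal(0.0, config.baseline_drift_sd / np.sqrt(fs), size=n))

    # Merged arrival process over analyte classes and background.
    sources: list[tuple[object, float]] = [
        (spec, w * spec.event_rate) for spec, w in config.classes
    ]
    if config.background is not None and config.background.rate > 0:
        sources.append((config.background, config.background.rate))
    total_rate = sum(r for _, r in sources)

    starts, ends, labels = [], [], []
    dropped = 0
    if total_rate > 0:
        probs = np.array([r for _, r in sources]) / total_rate
        t = rng.exponential(1.0 / total_rate)
        busy_until = 0.0
        while t < config.duration:
            src = sources[rng.choice(len(sources), p=probs)][0]
            if isinstance(src, BackgroundSpec):
                dwell_ms = rng.exponential(src.dwell_scale)
                depth = rng.uniform(src.depth_low, src.depth_high)
                label = "background"
                spec = ClassSpec(
                    name="background", event_rate=src.rate, depth_mean=max(depth, 1e-3),
                    depth_sd=0.0, intra_ar1_rho=0.2, intra_noise_sd=2.0,
                    spike_rate=1.0, spike_amp=10.0, spike_width=2,
                )
            else:
                spec = src
                dwell_ms = float(simulate_dwell_times(spec, 1, rng.integers(2**31))[0])
                depth = None
                label = spec.name
            start = int(round(t * fs))
            n_seg = max(2, int(round(dwell_ms * fs / 1000.0)))
            end = start + n_seg
            if t < busy_until or end > n:
                dropped += 1
            else:
                seg = simulate_event_segment(
                    spec, I0, n_seg, fs, rng.integers(2**31), depth=depth
                )
                trace[start:end] = seg
                starts.append(start)
                ends.append(end)
                labels.append(label)
                busy_until = end / fs
            t += rng.exponential(1.0 / total_rate)
    if dropped:
        logger.info("dropped %d colliding/truncated arrivals", dropped)
    if not starts:
        warnings.warn("no events placed (duration too short or zero rates)", stacklevel=2)

    sos = signal.butter(4, config.filter_cutoff, fs=fs, output="sos")
    trace = signal.sosfiltfilt(sos, trace)

    meta = {
        "generator": "glycopore.synthetic_data",
        "open_pore_current": I0,
        "filter_cutoff": config.filter_cutoff,
        "n_dropped_arrivals": dropped,
        "classes": [spec.name for spec, _ in config.classes],
    }
    truth = EventBoundaryTable(starts, ends, labels, n_samples=n)
    return Trace(trace, fs, metadata=meta), truth


# ---------------------------------------------------------------------------
# Direct event populations (no full trace)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticEvent:
    """A standalone generated blockade event with known ground truth."""

    segment: np.ndarray
    I0: float
    sampling_rate: float
    label: str
    true_depth: float

    @property
    def dwell_ms(self) -> float:
        return self.segment.size / self.sampling_rate * 1000.0


def simulate_labeled_events(
    specs: Sequence[ClassSpec],
    n_per_class: int,
    seed,
    I0: float = 100.0,
    sampling_rate: float = 50_000.0,
    baseline_noise_sd: float = 1.0,
) -> list[SyntheticEvent]:
    """Generate labelled event populations directly, bypassing trace synthesis.

    This is the fast path for ML-scale datasets: dwell times and segments are
    drawn per event exactly as in :func:`simulate_trace`, but without laying
    them into a full 50 kHz recording. The per-event baseline I0 carries the
    estimation noise a real preceding open-pore window would have.
    """
    rng = np.random.default_rng(seed)
    events: list[SyntheticEvent] = []
    for spec in specs:
        dwells = simulate_dwell_times(spec, n_per_class, rng.integers(2**31))
        for dwell_ms in dwells:
            n_seg = max(2, int(round(dwell_ms * sampling_rate / 1000.0)))
            depth = float(np.clip(rng.normal(spec.depth_mean, spec.depth_sd), 1e-6, 1.0))
            seg = simulate_event_segment(
                spec, I0, n_seg, sampling_rate, rng.integers(2**31), depth=depth
            )
            i0_est = I0 + rng.normal(0.0, baseline_noise_sd / np.sqrt(500))
            events.append(SyntheticEvent(seg, i0_est, sampling_rate, spec.name, depth))
    return events


def background_events(
    spec: BackgroundSpec,
    n: int,
    seed,
    I0: float = 100.0,
    sampling_rate: float = 50_000.0,
) -> list[SyntheticEvent]:
    """Generate collision-like background events (unstable amplitude, short)."""
    rng = np.random.default_rng(seed)
    events = []
    for _ in range(n):
        dwell_ms = rng.exponential(spec.dwell_scale) + 0.04
        n_seg = max(2, int(round(dwell_ms * sampling_rate / 1000.0)))
        depth = rng.uniform(spec.depth_low, spec.depth_high)
        cs = ClassSpec(
            name="background", event_rate=max(spec.rate, 1e-6), depth_mean=depth,
            depth_sd=0.0, intra_ar1_rho=0.2,
            intra_noise_sd=2.0 + spec.extra_baseline_noise_sd,
            spike_rate=1.0, spike_amp=12.0, spike_width=2,
        )
        seg = simulate_event_segment(cs, I0, n_seg, sampling_rate, rng.integers(2**31), depth=depth)
        events.append(SyntheticEvent(seg, I0, sampling_rate, "background", depth))
    return events
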