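"""Per-event feature extraction: the 19-descriptor vector with explicit missingness.

Canonical order (``FEATURE_NAMES``): dwell_time, mean, median, std, skew,
kurt, delta_ratio (ΔI₁/I₀), blockade_charge, rise_time, fall_time, fwhm,
spectral_centroid, bp_low, bp_mid, bp_high, spectral_entropy, approx_entropy,
spike_count, spike_rate.

MISSING is a first-class value (NaN in memory, empty CSV cell): skew/kurt need
≥ 4 samples and non-zero variance; the Welch spectral set needs ≥ 8 samples;
approximate entropy needs ``min_apen_samples`` (50 by default) — short events
therefore carry structurally missing entries, which is itself informative (the
missing rate of approximate entropy collapses to ~0 once dwell times are long
enough, the motivation for the long-residence pore engineering). No silent
zero-filling happens here; imputation is the ML preprocessor's job.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .event_detection import EventRecord
from .trace_io import FEATURE_COLUMNS as FEATURE_NAMES
from .trace_io import ValidationError

__all__ = [
    "FEATURE_NAMES",
    "SpectralConfig",
    "SpikeConfig",
    "ApEnConfig",
    "delta_ratio",
    "time_domain_features",
    "morphological_features",
    "welch_psd",
    "spectral_features",
    "approximate_entropy",
    "detect_spikes_mad",
    "extract_features",
    "extract_feature_table",
    "missing_rate",
]

MISSING = float("nan")


@dataclass(frozen=True)
class SpectralConfig:
    """Welch-PSD parameters and band edges (Hz).

    Band edges default to low (0, 500], mid (500, 2000], high (2000, 5000] Hz
    — the hardware filter cutoff bounds the top band.
    """

    welch_segment: int = 256
    welch_overlap: float = 0.5
    window: str = "hann"
    band_edges: tuple = (0.0, 500.0, 2000.0, 5000.0)

    def __post_init__(self) -> None:
        f = self.band_edges
        if not (len(f) == 4 and f[0] < f[1] < f[2] < f[3]):
            raise ValidationError("band_edges must be 4 increasing frequencies")


@dataclass(frozen=True)
class SpikeConfig:
    """MAD spike-detector parameters."""

    mad_k: float = 5.0
    min_spike_samples: int = 2

    def __post_init__(self) -> None:
        if not (self.mad_k > 0):
            raise ValidationError("mad_k must be positive")


@dataclass(frozen=True)
class ApEnConfig:
    """Approximate-entropy parameters (standard literature defaults)."""

    m: int = 2
    r_factor: float = 0.2
    min_apen_samples: int = 50


# ---------------------------------------------------------------------------
# Scalar features
# ---------------------------------------------------------------------------

def delta_ratio(event: EventRecord, central: str = "median") -> float:
    """Normalized blockade amplitude ΔI₁/I₀ = (I0 − central level) / I0.

    The central level is the segment median by default (robust to intra-event
    spikes); the mean is available via ``central="mean"``. The value is not
    clamped; out-of-[0,1] results are the caller's QC concern.
    """
    if not (event.I0 > 0):
        raise ValidationError("delta_ratio requires a positive baseline I0")
    level = float(np.median(event.segment) if central == "median" else np.mean(event.segment))
    return (event.I0 - level) / event.I0


def time_domain_features(event: EventRecord) -> dict:
    """Sample statistics of the segment amplitudes plus the dwell time.

    Kurtosis is excess kurtosis (0 for a Gaussian). Skew/kurt are MISSING for
    segments shorter than 4 samples or with zero variance.
    """
    x = event.segment
    out = {
        "dwell_time": event.dwell_time,
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "std": float(np.std(x, ddof=1)) if x.size >= 2 else MISSING,
    }
    if x.size >= 4 and np.std(x) > 0:
        out["skew"] = float(stats.skew(x))
        out["kurt"] = float(stats.kurtosis(x))  # excess (Fisher)
    else:
        out["skew"] = MISSING
        out["kurt"] = MISSING
    return out


def morphological_features(event: EventRecord) -> dict:
    """Blockade charge, 10–90% rise time, 90–10% fall time, and FWHM.

    All computed on the depth waveform d(t) = I0 − I(t): charge = Σ d·Δt
    (pA·ms); rise time = time from the first crossing of 0.1·d_max to the
    first crossing of 0.9·d_max; fall time the mirror image at the event end;
    FWHM = total time with d ≥ 0.5·d_max. Rise/fall/FWHM are MISSING when the
    event never blocks (d_max ≤ 0).
    """
    fs_ms = event.segment.size / event.dwell_time  # samples per ms
    d = event.I0 - event.segment
    charge = float(np.sum(d) / fs_ms)
    d_max = float(np.max(d))
    if not (d_max > 0) or np.isnan(event.I0):
        return {
            "blockade_charge": charge if not np.isnan(event.I0) else MISSING,
            "rise_time": MISSING,
            "fall_time": MISSING,
            "fwhm": MISSING,
        }
    above10 = np.nonzero(d >= 0.1 * d_max)[0]
    above90 = np.nonzero(d >= 0.9 * d_max)[0]
    rise = (above90[0] - above10[0]) / fs_ms
    fall = (above10[-1] - above90[-1]) / fs_ms
    fwhm = float(np.count_nonzero(d >= 0.5 * d_max) / fs_ms)
    return {
        "blockade_charge": charge,
        "rise_time": float(rise),
        "fall_time": float(fall),
        "fwhm": fwhm,
    }


def welch_psd(
    segment: np.ndarray, sampling_rate: float, cfg: SpectralConfig = SpectralConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD of the mean-removed segment.

    Segment length must be ≥ 8; the Welch segment length is capped at the
    signal length so short events fall back to a single periodogram.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 8:
        raise ValidationError("welch_psd requires >= 8 samples")
    nperseg = min(cfg.welch_segment, x.size)
    freqs, psd = signal.welch(
        x - np.mean(x),
        fs=sampling_rate,
        window=cfg.window,
        nperseg=nperseg,
        noverlap=int(cfg.welch_overlap * nperseg),
        detrend=False,
    )
    return freqs, psd


def spectral_features(
    freqs: np.ndarray, psd: np.ndarray, cfg: SpectralConfig = SpectralConfig()
) -> dict:
    """Centroid, relative band powers, and normalized spectral entropy.

    All statistics use the positive-frequency bins. Band powers are fractions
    of the total positive-frequency power; entropy is Shannon entropy of the
    normalized PSD divided by ln(N_bins) so it lies in [0, 1]. Everything is
    MISSING when the total power is zero.
    """
    pos = freqs > 0
    f, p = freqs[pos], psd[pos]
    total = float(np.sum(p))
    if not (total > 0) or f.size == 0:
        return {
            "spectral_centroid": MISSING,
            "bp_low": MISSING,
            "bp_mid": MISSING,
            "bp_high": MISSING,
            "spectral_entropy": MISSING,
        }
    centroid = float(np.sum(f * p) / total)
    e = cfg.band_edges
    bands = {}
    for name, lo, hi in (("bp_low", e[0], e[1]), ("bp_mid", e[1], e[2]), ("bp_high", e[2], e[3])):
        bands[name] = float(np.sum(p[(f > lo) & (f <= hi)]) / total)
    q = p / total
    q = q[q > 0]
    entropy = float(-np.sum(q * np.log(q)) / np.log(q.size)) if q.size > 1 else 0.0
    return {"spectral_centroid": centroid, "spectral_entropy": entropy, **bands}


def approximate_entropy(
    segment: np.ndarray, m: int = 2, r_factor: float = 0.2,
    min_samples: int = 50,
) -> float:
    """ApEn(m, r) with r = r_factor · SD(segment), self-match-inclusive counts.

    ApEn = Φ_m(r) − Φ_{m+1}(r) with Φ_k(r) the average log fraction of
    template pairs within Chebyshev distance r. Returns MISSING for segments
    shorter than ``min_samples``; 0 for constant segments.
    """
    x = np.asarray(segment, dtype=float)
    n = x.size
    if n < min_samples:
        return MISSING
    sd = np.std(x)
    if sd == 0:
        return 0.0
    r = r_factor * sd

    def phi(k: int) -> float:
        templates = np.lib.stride_tricks.sliding_window_view(x, k)  # (n-k+1, k)
        # Chebyshev distances between all template pairs, built per lag column.
        nt = templates.shape[0]
        dist = np.zeros((nt, nt))
        for j in range(k):
            col = templates[:, j]
            np.maximum(dist, np.abs(col[:, None] - col[None, :]), out=dist)
        counts = np.count_nonzero(dist <= r, axis=1)  # includes self-match
        return float(np.mean(np.log(counts / nt)))

    return phi(m) - phi(m + 1)


def detect_spikes_mad(
    segment: np.ndarray, dwell_ms: float, cfg: SpikeConfig = SpikeConfig()
) -> tuple[int, float, np.ndarray]:
    """MAD-based intra-event spike detection.

    A sample is a spike sample when its absolute deviation from the segment
    median exceeds ``mad_k`` scaled MADs (σ̂ = 1.4826·MAD); a run of at least
    ``min_spike_samples`` consecutive spike samples counts as one spike.
    Returns (count, rate in spikes/ms, boolean sample mask). A zero MAD yields
    zero spikes.
    """
    x = np.asarray(segment, dtype=float)
    med = np.median(x)
    sigma = 1.4826 * np.median(np.abs(x - med))
    if sigma == 0:
        return 0, 0.0, np.zeros(x.size, dtype=bool)
    mask = np.abs(x - med) > cfg.mad_k * sigma
    edges = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
    run_starts = np.nonzero(edges == 1)[0]
    run_ends = np.nonzero(edges == -1)[0]
    count = int(np.count_nonzero(run_ends - run_starts >= cfg.min_spike_samples))
    return count, count / dwell_ms, mask


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def extract_features(
    event: EventRecord,
    sampling_rate: float,
    spectral_cfg: SpectralConfig = SpectralConfig(),
    spike_cfg: SpikeConfig = SpikeConfig(),
    apen_cfg: ApEnConfig = ApEnConfig(),
) -> dict:
    """The full 19-descriptor vector for one non-excluded event.

    Deterministic; MISSING (NaN) wherever a feature's precondition fails.
    Raises on excluded events — they carry no feature obligations.
    """
    if event.excluded:
        raise ValidationError(
            f"cannot extract features from an excluded event ({event.exclusion_reason})"
        )
    out = dict.fromkeys(FEATURE_NAMES, MISSING)
    out.update(time_domain_features(event))
    out["delta_ratio"] = delta_ratio(event)
    out.update(morphological_features(event))
    if event.segment.size >= 8:
        freqs, psd = welch_psd(event.segment, sampling_rate, spectral_cfg)
        out.update(spectral_features(freqs, psd, spectral_cfg))
    out["approx_entropy"] = approximate_entropy(
        event.segment, apen_cfg.m, apen_cfg.r_factor, apen_cfg.min_apen_samples
    )
    count, rate, _ = detect_spikes_mad(event.segment, event.dwell_time, spike_cfg)
    out["spike_count"] = float(count)
    out["spike_rate"] = rate
    return out


def extract_feature_table(
    events,
    sampling_rate: float | None = None,
    spectral_cfg: SpectralConfig = SpectralConfig(),
    spike_cfg: SpikeConfig = SpikeConfig(),
    apen_cfg: ApEnConfig = ApEnConfig(),
) -> pd.DataFrame:
    """Feature table over a collection of events (EventRecord or SyntheticEvent).

    Excluded EventRecords yield an all-MISSING feature row flagged excluded.
    ``sampling_rate`` may be omitted for SyntheticEvents, which carry it.
    """
    rows = []
    for ev in events:
        fs = getattr(ev, "sampling_rate", sampling_rate)
        if fs is None:
            raise ValidationError("sampling_rate required for EventRecord inputs")
        if isinstance(ev, EventRecord):
            rec, label = ev, ev.label
        else:  # SyntheticEvent duck-type
            rec = EventRecord(
                start=0, end=ev.segment.size, segment=ev.segment, I0=ev.I0,
                dwell_time=ev.dwell_ms, label=ev.label,
            )
            label = ev.label
        if rec.excluded:
            row = dict.fromkeys(FEATURE_NAMES, MISSING)
            row["excluded"] = True
            row["exclusion_reason"] = rec.exclusion_reason.value
        else:
            row = extract_features(rec, fs, spectral_cfg, spike_cfg, apen_cfg)
            row["excluded"] = False
            row["exclusion_reason"] = "none"
        row["label"] = label
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_NAMES + ["label", "excluded", "exclusion_reason"])


def missing_rate(table: pd.DataFrame) -> pd.Series:
    """Per-feature fraction of events with a MISSING value, in [0, 1]."""
    if len(table) == 0:
        raise ValidationError("missing_rate of an empty table is undefined")
    return table[FEATURE_NAMES].isna().mean()
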