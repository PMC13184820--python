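"""Population-level kinetic fits and GHK ion-selectivity computations.

Dwell-time models are fitted by maximum likelihood on the unbinned durations:
the single-exponential MLE is the sample mean (SE = τ/√n); the two-component
exponential mixture is fitted by EM with deterministic multi-start and the
slow/fast components ordered τ_slow ≥ τ_fast. Blockade-amplitude populations
are summarized by a Gaussian MLE. Ion selectivity uses the
Goldman–Hodgkin–Katz zero-current relation for one monovalent cation/anion
pair (K⁺/Cl⁻), with activities approximated by concentrations.

Sign convention: V is the potential of the *trans* chamber with *cis*
grounded. The zero-current condition then reads

    exp(VF/RT) = (r·[K]_cis + [Cl]_trans) / (r·[K]_trans + [Cl]_cis),

with r = P_K⁺/P_Cl⁻, so :func:`ghk_reversal_potential` and
:func:`ghk_permeability_ratio` are mutually inverse by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .trace_io import ValidationError

__all__ = [
    "DwellFit",
    "AmplitudeFit",
    "GHKInputs",
    "fit_gaussian_amplitude",
    "fit_exponential_dwell",
    "fit_biexponential_dwell",
    "voltage_series_summary",
    "ghk_reversal_potential",
    "ghk_permeability_ratio",
]

R_GAS = 8.314462618  # J/(mol K)
FARADAY = 96485.33212  # C/mol


@dataclass
class DwellFit:
    """A fitted dwell-time model."""

    model: str                    # "single" | "biexponential"
    tau: float | None = None      # ms (single)
    tau_slow: float | None = None
    tau_fast: float | None = None
    w_slow: float | None = None
    log_likelihood: float = float("nan")
    n: int = 0
    se: dict = field(default_factory=dict)
    aic: float = float("nan")
    aic_single: float | None = None   # for biexp fits: AIC of the nested single model
    prefers_single: bool | None = None
    em_loglik_path: list = field(default_factory=list)


@dataclass
class AmplitudeFit:
    """Gaussian summary of a ΔI₁/I₀ population."""

    mu: float
    sigma: float
    n: int
    se_mu: float
    dispersion_warning: bool = False  # population inconsistent with one Gaussian


@dataclass(frozen=True)
class GHKInputs:
    """Electrolyte conditions for the GHK relation (mol/L, K, mV)."""

    K_cis: float
    K_trans: float
    Cl_cis: float
    Cl_trans: float
    temperature: float = 298.15
    reversal_potential: float | None = None  # mV at trans, cis grounded

    def __post_init__(self) -> None:
        for name in ("K_cis", "K_trans", "Cl_cis", "Cl_trans"):
            if not (getattr(self, name) > 0):
                raise ValidationError(f"{name} must be positive")
        if not (self.temperature > 0):
            raise ValidationError("temperature must be positive")


# ---------------------------------------------------------------------------
# Amplitude and dwell fits
# ---------------------------------------------------------------------------

def fit_gaussian_amplitude(delta_ratios) -> AmplitudeFit:
    """Maximum-likelihood Gaussian fit of a normalized-blockade population.

    Equivalent to the sample mean and (MLE) SD. A normality test flags
    populations whose dispersion is inconsistent with a single Gaussian
    (e.g. a mixture of two separated amplitude modes).
    """
    x = np.asarray(delta_ratios, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValidationError(f"need >= 10 finite values, got {x.size}")
    mu = float(np.mean(x))
    sigma = float(np.std(x))
    warn = False
    if sigma > 1e-12:
        # D'Agostino K² on a capped subsample; strongly bimodal mixtures fail it.
        sub = x if x.size <= 5000 else x[:: x.size // 5000 + 1]
        try:
            warn = bool(stats.normaltest(sub).pvalue < 1e-6)
        except ValueError:
            warn = False
    return AmplitudeFit(mu=mu, sigma=sigma, n=x.size, se_mu=sigma / math.sqrt(x.size),
                        dispersion_warning=warn)


def _check_dwells(dwells, n_min: int) -> np.ndarray:
    t = np.asarray(dwells, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValidationError("dwell times must be positive and finite")
    if t.size < n_min:
        raise ValidationError(f"need >= {n_min} dwell times, got {t.size}")
    return t


def fit_exponential_dwell(dwells) -> DwellFit:
    """Single-exponential MLE: τ = mean dwell, SE = τ/√n (censoring ignored)."""
    t = _check_dwells(dwells, 10)
    tau = float(np.mean(t))
    n = t.size
    ll = float(-n * math.log(tau) - n)  # Σ log(1/τ e^{-t/τ}) at the MLE
    return DwellFit(
        model="single", tau=tau, log_likelihood=ll, n=n,
        se={"tau": tau / math.sqrt(n)}, aic=2 * 1 - 2 * ll,
    )


def _biexp_loglik(t: np.ndarray, w: float, ts: float, tf: float) -> float:
    dens = w / ts * np.exp(-t / ts) + (1 - w) / tf * np.exp(-t / tf)
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


def _em_biexp(t: np.ndarray, w: float, ts: float, tf: float,
              max_iter: int = 500, tol: float = 1e-10):
    """EM for the two-component exponential mixture; returns params + LL path."""
    path = []
    ll_old = -np.inf
    for _ in range(max_iter):
        a = w / ts * np.exp(-t / ts)
        b = (1 - w) / tf * np.exp(-t / tf)
        denom = np.maximum(a + b, 1e-300)
        resp = a / denom
        w = float(np.mean(resp))
        w = min(max(w, 1e-12), 1 - 1e-12)
        ts = float(np.sum(resp * t) / np.sum(resp))
        tf = float(np.sum((1 - resp) * t) / np.sum(1 - resp))
        ll = _biexp_loglik(t, w, ts, tf)
        path.append(ll)
        if ll - ll_old < tol * (1 + abs(ll)):
            break
        ll_old = ll
    return w, ts, tf, path


def _biexp_se(t: np.ndarray, w: float, ts: float, tf: float) -> dict:
    """Standard errors from the finite-difference observed information."""
    theta = np.array([w, ts, tf])
    h = np.maximum(1e-5, 1e-4 * np.abs(theta))

    def f(p):
        return _biexp_loglik(t, min(max(p[0], 1e-9), 1 - 1e-9), max(p[1], 1e-9), max(p[2], 1e-9))

    hess = np.zeros((3, 3))
    for i in range(3):
        for j in range(i, 3):
            ei = np.eye(3)[i] * h[i]
            ej = np.eye(3)[j] * h[j]
            hess[i, j] = hess[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(-hess)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
        return {"w_slow": float(ses[0]), "tau_slow": float(ses[1]), "tau_fast": float(ses[2])}
    except np.linalg.LinAlgError:
        return {}


def fit_biexponential_dwell(dwells, n_starts: int = 5) -> DwellFit:
    """Two-component exponential-mixture MLE via multi-start EM.

    Starts are deterministic: quantile-split initializations spanning weight
    and scale combinations. Components are ordered τ_slow ≥ τ_fast; the fit
    reports AIC against the nested single-exponential model.
    """
    t = _check_dwells(dwells, 100)
    mean = float(np.mean(t))
    qs = np.quantile(t, [0.1, 0.25, 0.5, 0.75, 0.9])
    starts = [
        (0.5, qs[4], qs[0]),
        (0.3, qs[3] * 2, qs[1] * 0.5),
        (0.7, qs[4] * 2, qs[0] * 0.5),
        (0.5, mean * 3, mean * 0.2),
        (0.2, mean * 5, mean * 0.5),
    ][:n_starts]

    best = None
    for w0, ts0, tf0 in starts:
        ts0, tf0 = max(ts0, tf0), min(ts0, tf0)
        if ts0 <= 0 or tf0 <= 0 or ts0 == tf0:
            continue
        try:
            w, ts, tf, path = _em_biexp(t, w0, ts0, tf0)
        except FloatingPointError:
            continue
        ll = path[-1]
        if best is None or ll > best[3][-1]:
            best = (w, ts, tf, path)
    if best is None:
        raise ValidationError("biexponential EM failed to converge from every start")
    w, ts, tf, path = best
    if ts < tf:  # enforce slow/fast labelling
        ts, tf, w = tf, ts, 1 - w
    ll = path[-1]
    single = fit_exponential_dwell(t)
    aic = 2 * 3 - 2 * ll
    return DwellFit(
        model="biexponential", tau_slow=ts, tau_fast=tf, w_slow=w,
        log_likelihood=ll, n=t.size, se=_biexp_se(t, w, ts, tf),
        aic=aic, aic_single=single.aic, prefers_single=bool(single.aic <= aic),
        em_loglik_path=path,
    )


def voltage_series_summary(fits_by_voltage: dict) -> tuple[float, list]:
    """Voltage at which the fitted dwell time peaks (ties → lower voltage).

    ``fits_by_voltage`` maps voltage (mV) → DwellFit; the characteristic time
    is τ for single fits and τ_slow for biexponential fits. Returns the argmax
    voltage and the full (voltage, tau) table sorted by voltage.
    """
    if len(fits_by_voltage) < 2:
        raise ValidationError("need fits at >= 2 voltages")
    table = []
    for v in sorted(fits_by_voltage):
        fit = fits_by_voltage[v]
        tau = fit.tau if fit.model == "single" else fit.tau_slow
        table.append((float(v), float(tau)))
    best_v = max(table, key=lambda vt: (vt[1], -vt[0]))[0]
    return best_v, table


# ---------------------------------------------------------------------------
# GHK ion selectivity
# ---------------------------------------------------------------------------

def ghk_reversal_potential(p_ratio: float, inputs: GHKInputs) -> float:
    """Zero-current (reversal) potential in mV for a given P_K⁺/P_Cl⁻ ratio."""
    if not (p_ratio > 0):
        raise ValidationError("permeability ratio must be positive")
    rt_f = R_GAS * inputs.temperature / FARADAY  # volts
    arg = (p_ratio * inputs.K_cis + inputs.Cl_trans) / (
        p_ratio * inputs.K_trans + inputs.Cl_cis
    )
    return 1000.0 * rt_f * math.log(arg)


def ghk_permeability_ratio(inputs: GHKInputs) -> float:
    """P_K⁺/P_Cl⁻ solving the zero-current GHK relation at the measured V_rev."""
    if inputs.reversal_potential is None:
        raise ValidationError("GHKInputs.reversal_potential is required")
    rt_f = R_GAS * inputs.temperature / FARADAY
    a = math.exp(inputs.reversal_potential / 1000.0 / rt_f)
    num = inputs.Cl_trans - a * inputs.Cl_cis
    den = a * inputs.K_trans - inputs.K_cis
    if den == 0 or num / den <= 0:
        raise ValidationError(
            "no positive permeability ratio satisfies the GHK relation at this potential"
        )
    return num / den
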