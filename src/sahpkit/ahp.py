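"""Bi-exponential decomposition of the post-step after-hyperpolarization.

The decay of the AHP from its peak, found immediately after the end of the
depolarizing step, is modeled as

    V(t) = V_med·exp(−t/τ_med) + V_slow·exp(−t/τ_slow),

with the medium decay constrained to (0, 400] ms and the slow decay to
(400, 8000] ms; components are labeled by which bound interval their time
constant occupies, never by amplitude.  SSE is minimized by Nelder–Mead
with each τ mapped onto its interval through a logit-style transform and a
3×3 multi-start grid of τ pairs with linear least-squares amplitudes; the
tail is baseline-subtracted and decimated to 1 kHz before fitting.
Goodness of fit is the squared Pearson correlation between fitted curve
and data over the fit window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import pearsonr

from .io import VoltageTrace, CellRecord
from .spikes import smooth

#: Bound intervals for the medium and slow decay constants, ms.
TAU_MED_BOUNDS = (0.0, 400.0)
TAU_SLOW_BOUNDS = (400.0, 8000.0)
#: Search window for the AHP peak after step offset, ms.
PEAK_WINDOW_MS = 100.0
#: Fitting sample rate, Hz.
FIT_RATE = 1000.0
#: τ within this relative distance of a bound raises the at_bound flag.
_BOUND_RTOL = 0.01

_START_TAUS = [(tm, ts) for tm in (50.0, 150.0, 350.0)
               for ts in (1000.0, 3000.0, 6000.0)]


@dataclass
class AHPFit:
    """Medium/slow decomposition of one sweep's AHP tail.

    Amplitudes follow the negative-down convention (hyperpolarization < 0),
    measured relative to the pre-probe baseline at the fit start.
    ``converged`` is ``"ok"``, ``"at_bound"``, ``"ill_conditioned"``,
    ``"absent"`` (no negative excursion, fit skipped) or ``"failed"``.
    """

    v_med: float
    tau_med: float
    v_slow: float
    tau_slow: float
    r2: float
    sse: float
    peak_amp: float     # mV, total AHP peak relative to baseline
    t_fit_start: float  # ms from step offset
    converged: str

    @property
    def ok(self) -> bool:
        return self.converged in ("ok", "at_bound")

    @property
    def flagged(self) -> bool:
        return self.converged in ("at_bound", "ill_conditioned")


def trace_baseline(trace: VoltageTrace) -> float:
    """Mean of the 100 ms preceding the hyperpolarizing probe (shared
    amplitude reference for AHP and spike analysis)."""
    p = trace.protocol
    t0 = max(p.hyper_onset - 100.0, 0.0)
    return trace.window_mean(t0, p.hyper_onset)


def ahp_peak(trace: VoltageTrace, smoothed: VoltageTrace | None = None,
             ) -> tuple[float, float]:
    """AHP peak amplitude (mV, negative) and its time (ms from step offset).

    Most negative excursion relative to the pre-probe baseline within the
    first 100 ms after the end of the depolarizing step, on the smoothed
    trace.  Returns ``(0.0, nan)`` when there is no negative excursion.
    """
    sm = smoothed if smoothed is not None else smooth(trace)
    p = trace.protocol
    base = trace_baseline(sm)
    sl = sm.segment(p.depol_end, min(p.depol_end + PEAK_WINDOW_MS, p.record_dur))
    seg = sm.voltage[sl] - base
    i_min = int(np.argmin(seg))
    if seg[i_min] >= 0:
        return 0.0, float("nan")
    t_peak = sm.time[sl.start + i_min] * 1000.0 - p.depol_end
    return float(seg[i_min]), float(t_peak)


def _tau_transform(z: float, lo: float, hi: float) -> float:
    # clamp far outside the interval to its (open) edges, never exactly lo
    if z < -500:
        return lo + 1e-9 * (hi - lo)
    if z > 500:
        return hi
    return lo + (hi - lo) / (1.0 + math.exp(-z))


def _tau_inverse(tau: float, lo: float, hi: float) -> float:
    f = (tau - lo) / (hi - lo)
    f = min(max(f, 1e-6), 1 - 1e-6)
    return math.log(f / (1.0 - f))


def _ls_amplitudes(t_ms: np.ndarray, y: np.ndarray, tau_med: float,
                   tau_slow: float) -> tuple[float, float, float]:
    """Linear least-squares amplitudes for fixed taus; returns (a_med,
    a_slow, sse)."""
    E = np.column_stack([np.exp(-t_ms / tau_med), np.exp(-t_ms / tau_slow)])
    coef, *_ = np.linalg.lstsq(E, y, rcond=None)
    resid = y - E @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def _fit_window(trace: VoltageTrace, smoothed: VoltageTrace | None,
                ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """(t_ms from fit start, baseline-subtracted decimated tail, peak_amp,
    t_fit_start).

    The tail is decimated by block averaging (local support: no filter
    ringing at the step-offset kink), with time stamps at block centers;
    the last millisecond before the zero-current step is dropped because
    the smoothing kernel straddles that kink.
    """
    sm = smoothed if smoothed is not None else smooth(trace)
    p = trace.protocol
    peak_amp, t_peak = ahp_peak(trace, smoothed=sm)
    if peak_amp == 0.0:
        return np.zeros(0), np.zeros(0), 0.0, float("nan")
    base = trace_baseline(sm)
    t0 = p.depol_end + t_peak
    sl = sm.segment(t0, p.record_dur - 1.0)
    y = sm.voltage[sl] - base
    t_ms = sm.time[sl] * 1000.0 - t0
    q = int(sm.sampling_rate // FIT_RATE)
    if q >= 2:
        n = (len(y) // q) * q
        y = y[:n].reshape(-1, q).mean(axis=1)
        t_ms = t_ms[:n].reshape(-1, q).mean(axis=1)
    return t_ms, y, peak_amp, t_peak


def fit_ahp(trace: VoltageTrace, smoothed: VoltageTrace | None = None,
            ) -> AHPFit:
    """Constrained bi-exponential fit of one sweep's AHP decay."""
    t_ms, y, peak_amp, t_peak = _fit_window(trace, smoothed)
    if len(t_ms) == 0:
        return AHPFit(v_med=0.0, tau_med=100.0, v_slow=0.0, tau_slow=1000.0,
                      r2=float("nan"), sse=0.0, peak_amp=0.0,
                      t_fit_start=float("nan"), converged="absent")

    lo_m, hi_m = TAU_MED_BOUNDS
    lo_s, hi_s = TAU_SLOW_BOUNDS

    def sse_fn(theta):
        am, asl, zm, zs = theta
        tm = _tau_transform(zm, lo_m, hi_m)
        ts = _tau_transform(zs, lo_s, hi_s)
        resid = y - am * np.exp(-t_ms / tm) - asl * np.exp(-t_ms / ts)
        return float(resid @ resid)

    best = None
    best_taus = None
    for tm0, ts0 in _START_TAUS:
        am0, as0, _ = _ls_amplitudes(t_ms, y, tm0, ts0)
        theta0 = np.array([am0, as0, _tau_inverse(tm0, lo_m, hi_m),
                           _tau_inverse(ts0, lo_s, hi_s)])
        res = minimize(sse_fn, theta0, method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-12,
                                "maxiter": 4000, "maxfev": 6000})
        ts_fit = _tau_transform(res.x[3], lo_s, hi_s)
        if (best is None or res.fun < best.fun * (1 - 1e-9)
                or (abs(res.fun - best.fun) <= 1e-9 * max(best.fun, 1e-30)
                    and ts_fit < best_taus[1])):
            best, best_taus = res, (_tau_transform(res.x[2], lo_m, hi_m), ts_fit)

    v_med, v_slow = float(best.x[0]), float(best.x[1])
    tau_med, tau_slow = best_taus
    fitted = v_med * np.exp(-t_ms / tau_med) + v_slow * np.exp(-t_ms / tau_slow)
    r2 = fit_quality(fitted, y)

    status = "ok" if best.success else "failed"
    span_m, span_s = hi_m - lo_m, hi_s - lo_s
    # a tau pinned at a bound only matters when its component carries
    # non-negligible amplitude
    amp_floor = max(0.05 * abs(peak_amp), 0.02)
    at_bound = (
        (abs(v_med) > amp_floor
         and (tau_med > hi_m - _BOUND_RTOL * span_m
              or tau_med < lo_m + 1e-3 * span_m))
        or (abs(v_slow) > amp_floor
            and (tau_slow > hi_s - _BOUND_RTOL * span_s
                 or tau_slow < lo_s + _BOUND_RTOL * span_s))
    )
    if status == "ok" and at_bound:
        status = "at_bound"
    if status == "ok" and tau_slow / max(tau_med, 1e-9) < 1.6:
        status = "ill_conditioned"
    return AHPFit(v_med=v_med, tau_med=float(tau_med), v_slow=v_slow,
                  tau_slow=float(tau_slow), r2=r2, sse=float(best.fun),
                  peak_amp=peak_amp, t_fit_start=float(t_peak),
                  converged=status)


def fit_quality(fitted: np.ndarray, data: np.ndarray) -> float:
    """Squared Pearson correlation between fitted curve and data."""
    if len(fitted) < 3 or np.std(data) == 0 or np.std(fitted) == 0:
        return float("nan")
    r, _ = pearsonr(fitted, data)
    return float(r * r)


def refit_quality(fit: AHPFit, trace: VoltageTrace,
                  smoothed: VoltageTrace | None = None) -> float:
    """Recompute r² of an existing fit against a sweep's (smoothed,
    decimated) tail."""
    t_ms, y, _, _ = _fit_window(trace, smoothed)
    if len(t_ms) == 0:
        return float("nan")
    fitted = (fit.v_med * np.exp(-t_ms / fit.tau_med)
              + fit.v_slow * np.exp(-t_ms / fit.tau_slow))
    return fit_quality(fitted, y)


def ablation_contrast(fits_before: dict[float, AHPFit],
                      fits_after: dict[float, AHPFit],
                      step_range: tuple[float, float] = (325.0, 450.0),
                      ) -> tuple[float, float]:
    """Percent change of mean mAHP and sAHP amplitude across a step range.

    Mirrors the pharmacological sAHP-blockade check: fitted amplitudes are
    averaged over current steps in ``step_range`` (inclusive) before and
    after, and the percent change of each component's mean is returned as
    ``(mahp_change_pct, sahp_change_pct)``.
    """
    lo, hi = step_range
    steps = [s for s in fits_before if lo <= s <= hi and s in fits_after]
    if not steps:
        raise ValueError(f"no common steps in range {lo}-{hi} pA")
    med_b = np.mean([fits_before[s].v_med for s in steps])
    med_a = np.mean([fits_after[s].v_med for s in steps])
    slow_b = np.mean([fits_before[s].v_slow for s in steps])
    slow_a = np.mean([fits_after[s].v_slow for s in steps])
    if med_b == 0 or slow_b == 0:
        raise ValueError("zero baseline component amplitude")
    return (100.0 * float((med_a - med_b) / med_b),
            100.0 * float((slow_a - slow_b) / slow_b))


def ahp_by_step(cell: CellRecord,
                fits: dict[float, AHPFit] | None = None) -> "pd.DataFrame":
    """Long-format per-cell table of AHP fit results, one row per step."""
    import pandas as pd

    if fits is None:
        fits = {step: fit_ahp(tr) for step, tr in cell.sweeps.items()}
    rows = [
        {"cell_id": cell.cell_id, "group": cell.group_label, "step": step,
         "v_med": f.v_med, "v_slow": f.v_slow, "tau_med": f.tau_med,
         "tau_slow": f.tau_slow, "r2": f.r2, "peak_amp": f.peak_amp,
         "converged": f.converged}
        for step, f in sorted(fits.items())
    ]
    return pd.DataFrame(rows)
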