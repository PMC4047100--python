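"""Passive-membrane estimation from the hyperpolarizing probe.

The voltage response to the −20 pA / 200 ms probe is modeled as the sum of
two saturating exponentials,

    V(t) = V_offset + I_inj·R_a·(1 − exp(−t/τ_p)) + I_inj·R_in·(1 − exp(−t/τ_m)),

the fast branch (R_a, τ_p) carrying the pipette/series drop and the slow
branch (R_in, τ_m) the membrane charging.  Components are ordered by time
constant with τ_p constrained below 10 ms, which is the only physically
consistent labeling.  The model is fitted by Nelder–Mead on log-transformed
positive parameters with a method-of-moments multi-start; a direct
measurement from the raw trace serves as an independent cross-check, and
the cell-inclusion filter keeps input resistances between 100 and 450 MΩ
(inclusive on both ends).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .io import MV_PER_PA_MOHM, CellRecord, VoltageTrace
from .spikes import smooth

#: Upper bound keeping the fast branch identifiable as the pipette, ms.
TAU_P_MAX = 10.0
#: Inclusive input-resistance inclusion window, MΩ.
R_IN_QC = (100.0, 450.0)


@dataclass
class PassiveFit:
    """Passive-membrane estimates from one sweep's probe segment."""

    v_offset: float   # mV, pre-step membrane potential offset
    r_a: float        # MΩ, series/access resistance
    tau_p: float      # ms, pipette branch time constant
    r_in: float       # MΩ, input resistance
    tau_m: float      # ms, membrane time constant
    sse: float        # mV²
    converged: bool
    rmp: float = float("nan")  # mV, resting potential at zero current

    def __post_init__(self) -> None:
        if self.r_in <= 0 or self.r_a < 0:
            raise ValueError("resistances must satisfy r_in > 0, r_a >= 0")
        if not 0 < self.tau_p < self.tau_m:
            raise ValueError("component ordering requires tau_m > tau_p > 0")


def resting_potential(trace: VoltageTrace, settle_frac: float = 0.5) -> float:
    """Resting membrane potential from the zero-current check segment.

    Mean voltage over the last ``1 − settle_frac`` of the zero-current step
    appended at the sweep end (the membrane needs a few time constants to
    relax once the holding current is removed).
    """
    p = trace.protocol
    if p.zero_current_dur <= 0:
        raise ValueError("protocol has no zero-current segment")
    t0 = p.record_dur + settle_frac * p.zero_current_dur
    return trace.window_mean(t0, p.total_dur)


def _model(t_ms: np.ndarray, v0: float, i_inj: float, r_a: float, tau_p: float,
           r_in: float, tau_m: float) -> np.ndarray:
    return v0 + i_inj * MV_PER_PA_MOHM * (
        r_a * (1.0 - np.exp(-t_ms / tau_p))
        + r_in * (1.0 - np.exp(-t_ms / tau_m))
    )


def _moment_start(t_ms: np.ndarray, v: np.ndarray, v0: float, i_inj: float,
                  ) -> np.ndarray:
    """Method-of-moments seed for (r_a, tau_p, r_in, tau_m)."""
    defl = v[-max(len(v) // 10, 1):].mean() - v0
    r_tot = max(defl / (i_inj * MV_PER_PA_MOHM), 1.0)
    # rough split: fast branch ~10% of total, tau from 63% crossing
    target = v0 + 0.632 * defl
    crossing = np.nonzero((v - target) * np.sign(defl) >= 0)[0]
    tau_guess = float(t_ms[crossing[0]]) if len(crossing) else t_ms[-1] / 5.0
    tau_guess = min(max(tau_guess, 1.0), t_ms[-1] / 2.0)
    return np.array([0.1 * r_tot, 1.0, 0.9 * r_tot, tau_guess])


def fit_passive(trace: VoltageTrace, i_inj: float | None = None,
                smooth_window_ms: float = 1.0, n_starts: int = 3,
                ) -> PassiveFit:
    """Fit the two-branch passive charging model to the probe segment.

    The trace is smoothed (1 ms local linear window) first; SSE is minimized
    by Nelder–Mead over log-transformed (r_a, τ_p', r_in, τ_m) and V_offset,
    with τ_p mapped onto (0, 10] ms through a sigmoid.  Three starts
    (method-of-moments seed ± perturbation); non-convergence is flagged,
    not raised.
    """
    p = trace.protocol
    if i_inj is None:
        i_inj = p.hyper_step_amp
    sm = smooth(trace, smooth_window_ms)
    fs = sm.sampling_rate
    w = int(round(smooth_window_ms / 1000.0 * fs)) | 1  # filter length used
    half_ms = 0.5 * w / fs * 1000.0
    # exclude the half-window at each step edge, where the smoothing kernel
    # straddles the current kink and the filtered model is not exponential
    sl = sm.segment(p.hyper_onset + half_ms, p.hyper_end - half_ms)
    v = sm.voltage[sl]
    t_ms = (sm.time[sl] - p.hyper_onset / 1000.0) * 1000.0
    if t_ms[-1] < 5.0:
        raise ValueError("hyperpolarizing step segment too short to fit")
    # subsample for speed; the smoothing already band-limited the data
    stride = max(int(fs // 10_000), 1)
    v, t_ms = v[::stride], t_ms[::stride]
    v0_seed = sm.window_mean(max(p.hyper_onset - 100.0, 0.0), p.hyper_onset)

    # Inside the step the boxcar-averaged model stays a sum of exponentials
    # with amplitude scale c(tau) = sinh(w·dt/2tau) / (w·sinh(dt/2tau)).
    dt_ms = 1000.0 / fs

    def _cscale(tau: float) -> float:
        x = dt_ms / (2.0 * tau)
        return math.sinh(w * x) / (w * math.sinh(x))

    # V_offset and the two amplitudes enter the model linearly, so the
    # simplex only searches (tau_p, tau_m); amplitudes are profiled out by
    # ordinary least squares at every simplex vertex.
    scale = i_inj * MV_PER_PA_MOHM
    ones = np.ones_like(t_ms)

    def profile(theta):
        zp, ltm = theta
        tau_p = TAU_P_MAX / (1.0 + math.exp(-zp))
        tau_m = math.exp(ltm)
        if tau_m <= tau_p:
            return 1e12, None
        E = np.column_stack([
            ones,
            scale * (1.0 - _cscale(tau_p) * np.exp(-t_ms / tau_p)),
            scale * (1.0 - _cscale(tau_m) * np.exp(-t_ms / tau_m)),
        ])
        coef, *_ = np.linalg.lstsq(E, v, rcond=None)
        resid = v - E @ coef
        return float(resid @ resid), (coef[0], coef[1], tau_p, coef[2], tau_m)

    seed = _moment_start(t_ms, v, v0_seed, i_inj)
    best_fun, best_sol, best_ok = np.inf, None, False
    rng = np.random.default_rng(0)
    for k in range(n_starts):
        pert = np.ones(2) if k == 0 else np.exp(rng.normal(0.0, 0.4, size=2))
        tau_p0 = min(max(seed[1] * pert[0], 0.05), TAU_P_MAX * 0.95)
        tau_m0 = max(seed[3] * pert[1], 2.0)
        theta0 = np.array([
            math.log(tau_p0 / (TAU_P_MAX - tau_p0)),
            math.log(tau_m0),
        ])
        sse0 = profile(theta0)[0]
        res = minimize(lambda th: profile(th)[0], theta0,
                       method="Nelder-Mead",
                       options={"xatol": 1e-8,
                                "fatol": 1e-10 * max(sse0, 1e-9),
                                "maxiter": 2000, "maxfev": 3000})
        if res.fun < best_fun:
            best_fun = res.fun
            best_sol = profile(res.x)[1]
            best_ok = bool(res.success)
    v0, r_a, tau_p, r_in, tau_m = best_sol
    if tau_m <= tau_p:  # degenerate; swap labels to honor ordering
        (r_a, tau_p), (r_in, tau_m) = (r_in, tau_m), (r_a, tau_p)
    r_a = max(float(r_a), 0.0)
    rmp = float("nan")
    try:
        rmp = resting_potential(trace)
    except ValueError:
        pass
    return PassiveFit(v_offset=float(v0), r_a=r_a, tau_p=float(tau_p),
                      r_in=float(r_in), tau_m=float(tau_m),
                      sse=float(best_fun), converged=best_ok, rmp=rmp)


def direct_resistance_estimate(trace: VoltageTrace, i_inj: float | None = None,
                               smooth_window_ms: float = 1.0,
                               ) -> tuple[float, float]:
    """(r_in, r_a) measured directly from the probe, no model fit.

    The slow branch is isolated by log-linear regression on the late phase
    of the charging curve (t > 5 ms, fast branch settled), giving R_in and
    τ_m; R_a is the steady-state total resistance minus R_in.  Agrees with
    :func:`fit_passive` within a few percent whenever τ_p ≪ τ_m and the
    step reaches steady state.
    """
    p = trace.protocol
    if i_inj is None:
        i_inj = p.hyper_step_amp
    sm = smooth(trace, smooth_window_ms)
    sl = sm.segment(p.hyper_onset, p.hyper_end)
    v = sm.voltage[sl]
    t_ms = (sm.time[sl] - sm.time[sl.start]) * 1000.0
    v0 = sm.window_mean(max(p.hyper_onset - 100.0, 0.0), p.hyper_onset)
    n_ss = max(len(v) // 10, 1)
    v_ss = v[-n_ss:].mean()
    r_tot = (v_ss - v0) / (i_inj * MV_PER_PA_MOHM)
    # late phase: ln(v_ss − v) = ln(I·R_in·1e-3) − t/τ_m
    resid = (v_ss - v) * np.sign(i_inj * MV_PER_PA_MOHM)
    m = (t_ms > 5.0) & (t_ms < 0.6 * t_ms[-1]) & (resid > 1e-6)
    if m.sum() < 10:
        raise ValueError("probe segment too short for the direct estimate")
    # weights ∝ residual magnitude stabilize the log-transformed noise
    slope, intercept = np.polyfit(t_ms[m], np.log(resid[m]), 1, w=resid[m])
    r_in = math.exp(intercept) / abs(i_inj * MV_PER_PA_MOHM)
    r_a = max(r_tot - r_in, 0.0)
    return float(r_in), float(r_a)


def qc_filter(cells: list[CellRecord], fits: dict[str, PassiveFit] | None = None,
              ) -> tuple[list[CellRecord], list[dict]]:
    """Apply the input-resistance inclusion filter (100–450 MΩ, inclusive).

    *fits* maps cell_id → PassiveFit; when omitted each cell must carry a
    ``passive`` entry in ``cell.features``.  Returns the retained cells and
    an exclusion report (one dict per excluded cell with the reason).
    """
    lo, hi = R_IN_QC
    kept, report = [], []
    for cell in cells:
        fit = fits.get(cell.cell_id) if fits else cell.features.get("passive")
        if fit is None:
            report.append({"cell_id": cell.cell_id, "r_in": None,
                           "reason": "no passive fit"})
            continue
        if lo <= fit.r_in <= hi:
            kept.append(cell)
        else:
            side = "below" if fit.r_in < lo else "above"
            report.append({
                "cell_id": cell.cell_id, "r_in": fit.r_in,
                "reason": f"input resistance {fit.r_in:.1f} MΩ {side} "
                          f"the {lo:g}–{hi:g} MΩ inclusion window",
            })
    return kept, report
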