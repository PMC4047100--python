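"""Independent reference implementations used only by the test suite.

Each oracle recomputes a quantity by brute force (dense grid search,
per-sample scans, leave-one-out refits) without sharing code paths with
the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def grid_biexp(t_ms: np.ndarray, y: np.ndarray,
               med_range=(5.0, 400.0), slow_range=(401.0, 8000.0),
               n_coarse: int = 80, n_fine: int = 41,
               ) -> tuple[float, float, float, float]:
    """Dense two-stage grid search over (tau_med, tau_slow) with linear
    least-squares amplitudes; returns (v_med, tau_med, v_slow, tau_slow)."""

    def sweep(med_grid, slow_grid):
        E1 = np.exp(-t_ms[None, :] / med_grid[:, None])    # (M, n)
        E2 = np.exp(-t_ms[None, :] / slow_grid[:, None])   # (S, n)
        s11 = (E1 * E1).sum(axis=1)                        # (M,)
        s22 = (E2 * E2).sum(axis=1)                        # (S,)
        s12 = E1 @ E2.T                                    # (M, S)
        b1 = E1 @ y                                        # (M,)
        b2 = E2 @ y                                        # (S,)
        det = s11[:, None] * s22[None, :] - s12 ** 2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        a1 = (b1[:, None] * s22[None, :] - s12 * b2[None, :]) / det
        a2 = (s11[:, None] * b2[None, :] - s12 * b1[:, None]) / det
        sse = (y @ y
               - a1 * b1[:, None] - a2 * b2[None, :])
        sse = np.where(np.isnan(sse), np.inf, sse)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        return i, j, float(a1[i, j]), float(a2[i, j])

    med = np.geomspace(*med_range, n_coarse)
    slow = np.geomspace(*slow_range, n_coarse)
    i, j, a1, a2 = sweep(med, slow)
    # iterative local refinement: shallow SSE valleys put the coarse argmin
    # a few grid steps from the continuous optimum
    for span in (3, 1, 1):
        lo_m = med[max(i - span, 0)]
        hi_m = med[min(i + span, len(med) - 1)]
        lo_s = slow[max(j - span, 0)]
        hi_s = slow[min(j + span, len(slow) - 1)]
        med = np.linspace(lo_m, hi_m, n_fine)
        slow = np.linspace(lo_s, hi_s, n_fine)
        i, j, a1, a2 = sweep(med, slow)
    return a1, float(med[i]), a2, float(slow[j])


def grid_passive(t_ms: np.ndarray, v: np.ndarray, i_inj: float,
                 tau_p_range=(0.1, 10.0), tau_m_range=(5.0, 120.0),
                 n: int = 120) -> tuple[float, float, float, float, float]:
    """Dense grid over (tau_p, tau_m) with linear (v0, r_a, r_in);
    returns (v0, r_a, tau_p, r_in, tau_m)."""
    scale = i_inj * 1e-3
    ones = np.ones_like(t_ms)

    def sweep(taus_p, taus_m):
        best = (np.inf, None, 0, 0)
        for ip, tp in enumerate(taus_p):
            c1 = scale * (1.0 - np.exp(-t_ms / tp))
            for im, tm in enumerate(taus_m):
                if tm <= tp:
                    continue
                c2 = scale * (1.0 - np.exp(-t_ms / tm))
                E = np.column_stack([ones, c1, c2])
                coef, *_ = np.linalg.lstsq(E, v, rcond=None)
                sse = float(((v - E @ coef) ** 2).sum())
                if sse < best[0]:
                    best = (sse, (coef[0], coef[1], tp, coef[2], tm), ip, im)
        return best

    taus_p = np.geomspace(*tau_p_range, n)
    taus_m = np.geomspace(*tau_m_range, n)
    _, sol, ip, im = sweep(taus_p, taus_m)
    fine_p = np.linspace(taus_p[max(ip - 1, 0)], taus_p[min(ip + 1, n - 1)], 41)
    fine_m = np.linspace(taus_m[max(im - 1, 0)], taus_m[min(im + 1, n - 1)], 41)
    _, sol, *_ = sweep(fine_p, fine_m)
    return sol


def scan_spike_features(t_ms: np.ndarray, v: np.ndarray, i_peak: int,
                        slope_crit: float = 20.0,
                        ) -> dict:
    """Brute-force per-sample scan of one spike's waveform features.

    Threshold: walking backward sample by sample from the peak, the
    earliest sample of the contiguous run where the centered-difference
    slope stays >= *slope_crit* mV/ms.  Crossing times are whole samples
    (no interpolation), so agreement with the implementation is expected
    within one sample interval.
    """
    dt = t_ms[1] - t_ms[0]
    out: dict = {}
    slopes = np.empty_like(v)
    slopes[1:-1] = (v[2:] - v[:-2]) / (2 * dt)
    slopes[0] = slopes[1]
    slopes[-1] = slopes[-2]
    i = i_peak
    lo = max(i_peak - int(round(10.0 / dt)), 1)
    while i > lo and slopes[i] < slope_crit:
        i -= 1
    if slopes[i] < slope_crit:
        return {"threshold_v": np.nan}
    while i > lo and slopes[i - 1] >= slope_crit:
        i -= 1
    th_v, th_t = v[i], t_ms[i]
    out["threshold_v"] = th_v
    out["threshold_t"] = th_t
    v_peak = v[i_peak]
    amp = v_peak - th_v
    out["v_peak"] = v_peak
    out["amplitude"] = amp

    def first_cross(seg_idx, level, rising):
        for k in seg_idx:
            if rising and v[k] >= level:
                return k
            if not rising and v[k] < level:
                return k
        return None

    rise_idx = range(i, i_peak + 1)
    k20 = first_cross(rise_idx, th_v + 0.2 * amp, True)
    k80 = first_cross(rise_idx, th_v + 0.8 * amp, True)
    if k20 is not None and k80 is not None and k80 > k20:
        out["rise_time_20_80"] = (t_ms[k80] - t_ms[k20]) * 1000.0
        out["rising_slope"] = 0.6 * amp / (t_ms[k80] - t_ms[k20])
    half = th_v + 0.5 * amp
    kup = first_cross(rise_idx, half, True)
    end = min(i_peak + int(round(20.0 / dt)), len(v))
    kdn = first_cross(range(i_peak, end), half, False)
    if kup is not None and kdn is not None:
        out["half_width"] = t_ms[kdn] - t_ms[kup]
    return out


def smooth_midpoint_ols(v: np.ndarray, w: int) -> np.ndarray:
    """Per-window OLS line evaluated at the window midpoint (interior
    samples only; edges returned unchanged)."""
    out = v.astype(float).copy()
    half = w // 2
    x = np.arange(w) - half
    for i in range(half, len(v) - half):
        seg = v[i - half:i + half + 1]
        b, a = np.polyfit(x, seg, 1)
        out[i] = a
    return out


def loo_cooks(table, fit_fn, p: int) -> np.ndarray:
    """Leave-one-observation-out Cook's distances by full mixed-model
    refits: D_i = (β − β_(i))' Cov(β)^{-1} (β − β_(i)) / p."""
    import pandas as pd

    full = fit_fn(table)
    beta = full.params.to_numpy()
    covinv = np.linalg.inv(full.cov_params.to_numpy())
    used = table.index[~table["missing"]]
    out = np.full(len(used), np.nan)
    for k, idx in enumerate(used):
        sub = table.drop(index=idx)
        try:
            fit_i = fit_fn(sub)
        except Exception:
            continue
        d = beta - fit_i.params.to_numpy()
        out[k] = float(d @ covinv @ d) / p
    return out
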