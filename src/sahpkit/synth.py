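"""Synthetic current-clamp sweep and cohort generator.

Every downstream stage of the pipeline is exercised against traces built
here, with exact ground truth returned alongside.  The generator emulates
whole-cell recordings from pyramidal neurons: resting potential near
−70 mV, a −20 pA/200 ms hyperpolarizing probe whose response follows the
two-component passive charging model (series/pipette branch plus membrane
branch), a 600 ms depolarizing step evoking an accommodating spike train
of stereotyped template spikes, a post-step after-hyperpolarization decaying
as the sum of a medium (<400 ms) and a slow (0.4–8 s) exponential, and
band-limited Gaussian noise mimicking 0–2 kHz acquisition.

Spikes are stereotyped piecewise templates (sub-threshold approach ramp,
exponential upstroke from the threshold kink, exponential repolarization),
not a conductance-based model: the analysis under test only needs realistic
spike geometry, and templates keep the ground truth exact.  During the
depolarizing step the membrane charges toward a sub-threshold plateau just
below spike threshold rather than toward the linear passive prediction,
because spiking clamps a real neuron's membrane near threshold; the linear
passive equation applies exactly to the small-signal hyperpolarizing probe
and the zero-current step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np
from scipy import signal

from .io import (
    MV_PER_PA_MOHM,
    DEPOL_STEP_GRID,
    CellRecord,
    CurrentProtocol,
    VoltageTrace,
)

__all__ = [
    "SpikeShape",
    "TraceGenParams",
    "CohortGenParams",
    "TraceGroundTruth",
    "CohortGroundTruth",
    "generate_trace",
    "generate_ablation_pair",
    "generate_cohort",
]


@dataclass(frozen=True)
class SpikeShape:
    """Stereotyped action-potential template geometry (absolute mV / ms)."""

    peak_height: float = 80.0   # mV above resting potential
    rise_tau: float = 0.12      # ms, upstroke exponential
    fall_tau: float = 1.1       # ms, repolarization exponential
    threshold: float = -50.0    # mV, absolute potential of the upstroke kink
    approach_dur: float = 2.0   # ms of sub-threshold ramp before the kink


@dataclass(frozen=True)
class TraceGenParams:
    """Ground-truth parameters for one synthetic sweep."""

    rmp: float = -70.0          # mV, true resting potential at zero current
    r_in_true: float = 230.0    # MΩ, input resistance
    tau_m_true: float = 30.0    # ms, membrane time constant
    r_a_true: float = 28.0      # MΩ, series (access) resistance
    tau_p_true: float = 1.0     # ms, pipette/series time constant
    v_med_true: float = -3.5    # mV (<=0), medium-AHP amplitude
    tau_med_true: float = 150.0   # ms in (0, 400]
    v_slow_true: float = -1.4   # mV (<=0), slow-AHP amplitude
    tau_slow_true: float = 6000.0  # ms in (400, 8000]
    spike_gain: float = 0.05    # spikes per pA above 125 pA
    isi_adaptation: float = 2.0  # generative last-ISI / first-ISI, >= 1
    spike_shape: SpikeShape = field(default_factory=SpikeShape)
    noise_sd: float = 0.2       # mV, band-limited noise sd
    noise_bandwidth: float = 2000.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tau_m_true", "tau_p_true", "tau_med_true", "tau_slow_true"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.tau_med_true <= 400:
            raise ValueError("tau_med_true must lie in (0, 400] ms")
        if not 400 < self.tau_slow_true <= 8000:
            raise ValueError("tau_slow_true must lie in (400, 8000] ms")
        if self.v_med_true > 0 or self.v_slow_true > 0:
            raise ValueError("AHP amplitudes are <= 0 by convention")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.isi_adaptation < 1:
            raise ValueError("isi_adaptation must be >= 1")
        if self.spike_shape.peak_height <= 40.0:
            raise ValueError(
                "spike peak_height must exceed 40 mV above rmp so generated "
                "spikes satisfy the detection criterion by design"
            )


@dataclass
class TraceGroundTruth:
    """Exact decomposition of a generated sweep.

    ``voltage == baseline + passive + spikes + ahp + noise`` sample by
    sample, where *baseline* is the constant holding level.
    """

    params: TraceGenParams
    protocol: CurrentProtocol
    baseline: float              # mV, holding level before the probe
    passive: np.ndarray          # mV deflection
    spikes: np.ndarray           # mV deflection
    ahp: np.ndarray              # mV deflection
    noise: np.ndarray            # mV
    spike_times: np.ndarray      # s, template peak times
    n_spikes: int


def _rect_response(t: np.ndarray, t_on: float, t_off: float, amp_pa: float,
                   rs: Sequence[float], taus_ms: Sequence[float]) -> np.ndarray:
    """Linear passive response (mV) to a rectangular current pulse.

    Superposition of saturating exponentials for the on-step minus the same
    for the off-step; exact for the two-branch passive model.
    """
    out = np.zeros_like(t)
    for r, tau in zip(rs, taus_ms):
        tau_s = tau / 1000.0
        on = np.clip(t - t_on, 0.0, None)
        off = np.clip(t - t_off, 0.0, None)
        out += amp_pa * r * MV_PER_PA_MOHM * (
            (1.0 - np.exp(-on / tau_s)) * (t >= t_on)
            - (1.0 - np.exp(-off / tau_s)) * (t >= t_off)
        )
    return out


def _spike_times_s(protocol: CurrentProtocol, params: TraceGenParams) -> np.ndarray:
    """Template peak times for one sweep, seconds from sweep start.

    Spike count is ``round(spike_gain * (depol_step_amp − 125 pA))``;
    inter-spike intervals stretch geometrically so that the last/first ISI
    ratio equals ``isi_adaptation``, filling the step window with the first
    peak 10 ms after onset and the last peak 30 ms before offset (so the
    repolarization never overlaps the AHP analysis window).
    """
    n = int(round(params.spike_gain * (protocol.depol_step_amp - 125.0)))
    if n <= 0:
        return np.zeros(0)
    latency = 10.0  # ms from step onset to first peak
    t_first = protocol.depol_onset + latency
    if n == 1:
        return np.array([t_first]) / 1000.0
    avail = protocol.depol_step_dur - latency - 30.0
    if avail <= 0:
        raise ValueError("depolarizing step too short for the spike train")
    n_isi = n - 1
    if n_isi == 1:
        isis = np.array([avail])
    else:
        q = params.isi_adaptation ** (1.0 / (n_isi - 1))
        w = q ** np.arange(n_isi)
        isis = avail * w / w.sum()
    if isis.min() < 4.0:
        raise ValueError(
            f"spike train of {n} spikes does not fit the depolarizing window "
            f"(min ISI {isis.min():.2f} ms < 4 ms)"
        )
    times_ms = t_first + np.concatenate([[0.0], np.cumsum(isis)])
    return times_ms / 1000.0


def _spike_component(t: np.ndarray, protocol: CurrentProtocol,
                     params: TraceGenParams, plateau_defl: np.ndarray,
                     baseline: float, peak_times_s: np.ndarray) -> np.ndarray:
    """Additive spike-template deflection (mV) on top of the plateau."""
    shape = params.spike_shape
    out = np.zeros_like(t)
    if len(peak_times_s) == 0:
        return out
    fs = protocol.sampling_rate
    t_a = shape.approach_dur / 1000.0
    t_r = 5.0 * shape.rise_tau / 1000.0
    t_f = 8.0 * shape.fall_tau / 1000.0
    th = shape.threshold
    pk = params.rmp + shape.peak_height
    pk_actual = th + (pk - th) * (1.0 - np.exp(-5.0))
    for tp in peak_times_s:
        t_on = tp - t_r - t_a
        i0 = int(np.floor(t_on * fs))
        i1 = min(int(np.ceil((tp + t_f) * fs)) + 1, len(t))
        tw = t[i0:i1]
        base = baseline + plateau_defl[i0:i1]  # local sub-threshold level
        tau_loc = (tw - t_on) * 1000.0  # ms since template onset
        v = np.zeros_like(tw)
        # approach ramp: base -> threshold
        m_app = (tau_loc >= 0) & (tau_loc < shape.approach_dur)
        v[m_app] = (th - base[m_app]) * tau_loc[m_app] / shape.approach_dur
        # upstroke: threshold -> peak, exponential approach
        tau_up = tau_loc - shape.approach_dur
        m_up = (tau_up >= 0) & (tau_up < 5.0 * shape.rise_tau)
        v[m_up] = (th - base[m_up]) + (pk - th) * (
            1.0 - np.exp(-tau_up[m_up] / shape.rise_tau)
        )
        # repolarization: peak -> base, exponential decay
        tau_dn = tau_up - 5.0 * shape.rise_tau
        m_dn = tau_dn >= 0
        v[m_dn] = (pk_actual - base[m_dn]) * np.exp(-tau_dn[m_dn] / shape.fall_tau)
        out[i0:i1] += v
    return out


def _bandlimited_noise(n: int, fs: float, sd: float, bandwidth: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Zero-phase low-passed white Gaussian noise, rescaled to sd exactly."""
    if sd == 0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    if bandwidth < fs / 2:
        sos = signal.butter(4, bandwidth, fs=fs, output="sos")
        w = signal.sosfiltfilt(sos, w)
    s = w.std()
    if s > 0:
        w *= sd / s
    return w


def generate_trace(protocol: CurrentProtocol, params: TraceGenParams,
                   ) -> tuple[VoltageTrace, TraceGroundTruth]:
    """Generate one synthetic sweep and its exact ground-truth decomposition."""
    t = protocol.time_grid()
    rs = (params.r_a_true, params.r_in_true)
    taus = (params.tau_p_true, params.tau_m_true)
    r_tot = sum(rs)

    # holding current positions the baseline at −70 mV given the true rmp
    holding = (-70.0 - params.rmp) / (r_tot * MV_PER_PA_MOHM) if r_tot > 0 else 0.0
    protocol = replace(protocol, holding_current=holding)
    baseline = params.rmp + holding * r_tot * MV_PER_PA_MOHM  # == −70 exactly

    passive = np.zeros_like(t)
    # hyperpolarizing probe: exact two-branch passive response
    passive += _rect_response(
        t, protocol.hyper_onset / 1000.0, protocol.hyper_end / 1000.0,
        protocol.hyper_step_amp, rs, taus,
    )
    # zero-current step at sweep end: holding switched off
    passive += _rect_response(
        t, protocol.record_dur / 1000.0, protocol.total_dur / 1000.0 + 1.0,
        -holding, rs, taus,
    )

    # depolarizing step: charge toward a sub-threshold plateau with tau_m,
    # instant reset at offset (active repolarization ends the depolarization)
    t_on = protocol.depol_onset / 1000.0
    t_off = protocol.depol_end / 1000.0
    plateau = params.spike_shape.threshold - 5.0 - baseline  # mV deflection
    in_step = (t >= t_on) & (t < t_off)
    depol = np.zeros_like(t)
    depol[in_step] = plateau * (
        1.0 - np.exp(-(t[in_step] - t_on) / (params.tau_m_true / 1000.0))
    )
    passive_with_depol = passive + depol

    peak_times = _spike_times_s(protocol, params)
    spikes = _spike_component(t, protocol, params, passive_with_depol,
                              baseline, peak_times)

    # AHP tail relative to baseline, from the first sample after step offset
    # to the end of the record (the zero-current check segment is excluded)
    ahp = np.zeros_like(t)
    m_tail = (t >= t_off) & (t < protocol.record_dur / 1000.0)
    tau_rel = (t[m_tail] - t_off) * 1000.0  # ms since step offset
    ahp[m_tail] = (
        params.v_med_true * np.exp(-tau_rel / params.tau_med_true)
        + params.v_slow_true * np.exp(-tau_rel / params.tau_slow_true)
    )

    rng = np.random.default_rng(params.seed)
    noise = _bandlimited_noise(len(t), protocol.sampling_rate, params.noise_sd,
                               params.noise_bandwidth, rng)

    voltage = baseline + passive_with_depol + spikes + ahp + noise
    trace = VoltageTrace(time=t, voltage=voltage, protocol=protocol)
    gt = TraceGroundTruth(
        params=params, protocol=protocol, baseline=baseline,
        passive=passive_with_depol, spikes=spikes, ahp=ahp, noise=noise,
        spike_times=peak_times, n_spikes=len(peak_times),
    )
    return trace, gt


def generate_ablation_pair(protocol: CurrentProtocol, params: TraceGenParams,
                           sahp_scale: float, mahp_scale: float,
                           noise_seed_after: int | None = None,
                           ) -> tuple[tuple[VoltageTrace, TraceGroundTruth],
                                      tuple[VoltageTrace, TraceGroundTruth]]:
    """Before/after sweep pair emulating pharmacological sAHP blockade.

    The second sweep is identical except that the slow and medium AHP
    amplitudes are scaled by ``sahp_scale`` and ``mahp_scale``.  By default
    the same seed (hence the same noise draw) is used for both sweeps, so
    unit scales reproduce the first sweep exactly; pass ``noise_seed_after``
    for an independent noise realization.
    """
    if not (0 <= sahp_scale <= 1 and 0 <= mahp_scale <= 1):
        raise ValueError("ablation scales must lie in [0, 1]")
    before = generate_trace(protocol, params)
    params_after = replace(
        params,
        v_slow_true=params.v_slow_true * sahp_scale,
        v_med_true=params.v_med_true * mahp_scale,
        seed=params.seed if noise_seed_after is None else noise_seed_after,
    )
    after = generate_trace(protocol, params_after)
    return before, after


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortGenParams:
    """Two-group cohort structure with a treatment × current interaction.

    The generative slow-AHP amplitude of cell *i* at current step *s* (pA) is

    ``v_slow(i, s) = −[a0 + u0_i + (b + u1_i + γ·T_i)·(s − 300)]``

    with ``T_i`` the treated indicator, ``u0_i ~ N(0, random_intercept_sd²)``
    and ``u1_i ~ N(0, random_slope_sd²)`` per-cell random effects, and
    ``γ = sahp_interaction_slope`` the treated group's extra per-pA growth —
    the generative analogue of the treatment × current-step interaction.
    Table-level observations add N(0, residual_sd²) measurement noise; a
    fraction of observations is deleted completely at random or displaced
    into outliers.
    """

    n_cells_per_group: tuple[int, int] = (20, 15)   # (vehicle, treated)
    group_labels: tuple[str, str] = ("vehicle", "treated")
    sahp_interaction_slope: float = 0.003   # mV/pA extra |sAHP| growth, treated
    sahp_base_amp: float = 1.6              # mV, |v_slow| at 300 pA, vehicle
    sahp_step_slope: float = 0.004          # mV/pA, |v_slow| growth, vehicle
    mahp_base_amp: float = 3.0              # mV, |v_med| at 300 pA
    mahp_step_slope: float = 0.004          # mV/pA, |v_med| growth
    random_intercept_sd: float = 0.3        # mV
    random_slope_sd: float = 0.001          # mV/pA
    residual_sd: float = 0.3                # mV
    missing_frac: float = 0.0
    outlier_frac: float = 0.0
    outlier_scale: float = 8.0              # multiples of residual_sd
    r_in_cv: float = 0.0                    # per-cell input-resistance spread
    rmp_sd: float = 0.0                     # mV, per-cell resting-potential spread
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.random_intercept_sd, self.random_slope_sd,
               self.residual_sd) < 0:
            raise ValueError("all sds must be >= 0")
        if not 0 <= self.missing_frac <= 0.5:
            raise ValueError("missing_frac must lie in [0, 0.5]")
        if self.missing_frac + self.outlier_frac >= 1:
            raise ValueError("missing_frac + outlier_frac must be < 1")


@dataclass
class CohortGroundTruth:
    params: CohortGenParams
    cell_effects: "pd.DataFrame"        # cell_id, group, u0, u1
    true_values: "pd.DataFrame"         # cell_id, step, v_slow_true, v_med_true
    n_missing: int
    n_outliers: int


def generate_cohort(protocol: CurrentProtocol, trace_params_base: TraceGenParams,
                    cohort: CohortGenParams, make_traces: bool = False,
                    ) -> tuple["pd.DataFrame", list[CellRecord], CohortGroundTruth]:
    """Generate a two-group cohort.

    Returns a long-format cohort table of slow-AHP observations (one row per
    cell × current step; missing rows flagged, not dropped), the per-cell
    sweep families (empty unless ``make_traces``), and the ground truth.
    The table-level ``response`` column carries generative amplitude plus
    residual noise; when traces are generated the same generative amplitudes
    parameterize each sweep so the measured pipeline response can be compared
    against truth.
    """
    import pandas as pd

    rng = np.random.default_rng(cohort.seed)
    steps = np.array(DEPOL_STEP_GRID, dtype=float)
    rows, eff_rows, true_rows = [], [], []
    cells: list[CellRecord] = []
    n_veh, n_trt = cohort.n_cells_per_group
    groups = [cohort.group_labels[0]] * n_veh + [cohort.group_labels[1]] * n_trt

    for i, group in enumerate(groups):
        cell_id = f"c{i:03d}"
        treated = 1.0 if group == cohort.group_labels[1] else 0.0
        u0 = rng.normal(0.0, cohort.random_intercept_sd)
        u1 = rng.normal(0.0, cohort.random_slope_sd)
        eff_rows.append((cell_id, group, u0, u1))
        slope = (cohort.sahp_step_slope + u1
                 + cohort.sahp_interaction_slope * treated)
        amp_slow = cohort.sahp_base_amp + u0 + slope * (steps - 300.0)
        amp_slow = np.clip(amp_slow, 0.0, None)
        amp_med = np.clip(
            cohort.mahp_base_amp + cohort.mahp_step_slope * (steps - 300.0),
            0.0, None,
        )
        eps = rng.normal(0.0, cohort.residual_sd, size=len(steps))
        resp = -(amp_slow) + eps

        if make_traces:
            if trace_params_base is None or protocol is None:
                raise ValueError("make_traces requires a protocol and base "
                                 "trace parameters")
            r_in_i = trace_params_base.r_in_true
            rmp_i = trace_params_base.rmp
            if cohort.r_in_cv > 0:
                r_in_i *= rng.lognormal(0.0, cohort.r_in_cv)
            if cohort.rmp_sd > 0:
                rmp_i += rng.normal(0.0, cohort.rmp_sd)

        cell = CellRecord(cell_id=cell_id, group_label=group)
        for j, step in enumerate(steps):
            true_rows.append((cell_id, step, -amp_slow[j], -amp_med[j]))
            rows.append({
                "cell_id": cell_id, "group": group, "step": step,
                "response": resp[j], "response_name": "v_slow",
                "missing": False, "outlier": False,
            })
            if make_traces:
                p = replace(
                    trace_params_base,
                    r_in_true=r_in_i, rmp=rmp_i,
                    v_slow_true=-float(amp_slow[j]),
                    v_med_true=-float(amp_med[j]),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                proto = replace(protocol, depol_step_amp=float(step))
                tr, _ = generate_trace(proto, p)
                tr.cell_id = cell_id
                tr.sweep_id = f"{cell_id}_s{int(step)}"
                tr.group_label = group
                cell.add_sweep(tr)
        if make_traces:
            cells.append(cell)

    table = pd.DataFrame(rows)
    n_obs = len(table)
    n_miss = 0
    n_out = 0
    u = rng.random(n_obs)
    miss_mask = u < cohort.missing_frac
    out_mask = (~miss_mask) & (u < cohort.missing_frac + cohort.outlier_frac)
    n_miss = int(miss_mask.sum())
    n_out = int(out_mask.sum())
    table.loc[miss_mask, "response"] = np.nan
    table.loc[miss_mask, "missing"] = True
    if n_out:
        signs = rng.choice([-1.0, 1.0], size=n_out)
        table.loc[out_mask, "response"] += (
            signs * cohort.outlier_scale * cohort.residual_sd
        )
        table.loc[out_mask, "outlier"] = True

    gt = CohortGroundTruth(
        params=cohort,
        cell_effects=pd.DataFrame(eff_rows,
                                  columns=["cell_id", "group", "u0", "u1"]),
        true_values=pd.DataFrame(
            true_rows, columns=["cell_id", "step", "v_slow_true", "v_med_true"]),
        n_missing=n_miss, n_outliers=n_out,
    )
    return table, cells, gt
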