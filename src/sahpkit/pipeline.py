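"""End-to-end orchestration: simulate → features → QC → stats → report.

`run_pipeline` drives the whole chain from a single config object (or YAML
mapping), writes one CSV/JSON artifact per stage plus a manifest recording
config hash, seeds and package versions, and is bit-reproducible under a
fixed seed.  The numbered scripts under ``analysis/`` are thin drivers over
these functions.
"""

from __future__ import annotations

import hashlib
import json
import platform
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CurrentProtocol, CellRecord, write_sweeps
from .synth import TraceGenParams, CohortGenParams, generate_cohort
from .passive import fit_passive, qc_filter
from .spikes import sweep_spike_analysis, first_spike_cell_average, SpikeFeatures
from .ahp import fit_ahp, ahp_by_step
from . import stats as cstats

_STAGES = ("simulate", "passive", "spikes", "ahp", "stats", "power", "report")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "run_out"
    seed: int = 0
    stages: tuple = _STAGES[:5] + ("report",)
    response: str = "v_slow"
    sampling_rate: float = 50_000.0
    protocol: dict = field(default_factory=dict)
    trace_params: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    input_traces: str = ""   # read cells from this container when the
                             # simulate stage is not run
    n_imputations: int = 20
    screen_influence: bool = True
    power_grid: tuple = (30, 50, 70, 90)
    power_n_sim: int = 200
    alpha: float = 0.05
    save_traces: bool = False

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in _STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; valid: {_STAGES}")
        order = [s for s in _STAGES if s in self.stages]
        self.stages = tuple(order)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Cells are processed one at a time (each 13-sweep family is released
    after feature extraction) so memory stays flat in cohort size.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "sahpkit": "0.1.0",
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
        "outputs": {},
        "stage_seconds": {},
    }
    stages = config.stages

    protocol = CurrentProtocol(
        sampling_rate=config.sampling_rate, **config.protocol)
    base = TraceGenParams(**config.trace_params)
    cohort = CohortGenParams(seed=config.seed, **config.cohort)

    cells: list[CellRecord] = []
    table = None
    if "simulate" in stages:
        t0 = time.time()
        table, cells, gt = generate_cohort(protocol, base, cohort,
                                           make_traces=True)
        table.to_csv(out / "cohort_generative.csv", index=False)
        gt.true_values.to_csv(out / "ground_truth.csv", index=False)
        if config.save_traces:
            write_sweeps(cells, out / "cohort.h5")
            manifest["outputs"]["traces"] = "cohort.h5"
        manifest["outputs"]["cohort_generative"] = "cohort_generative.csv"
        manifest["stage_seconds"]["simulate"] = round(time.time() - t0, 2)
    elif config.input_traces:
        from .io import read_sweeps

        cells = read_sweeps(config.input_traces)

    passive_rows, spike_rows, cellavg_rows, ahp_frames = [], [], [], []
    feature_stages = {"passive", "spikes", "ahp"} & set(stages)
    if feature_stages:
        t0 = time.time()
        for cell in cells:
            ref_step = min(cell.sweeps)
            if "passive" in stages:
                pf = fit_passive(cell.sweeps[ref_step])
                cell.features["passive"] = pf
                passive_rows.append({
                    "cell_id": cell.cell_id, "group": cell.group_label,
                    "rmp": pf.rmp, "v_offset": pf.v_offset, "r_a": pf.r_a,
                    "tau_p": pf.tau_p, "r_in": pf.r_in, "tau_m": pf.tau_m,
                    "sse": pf.sse, "converged": pf.converged,
                })
            if "spikes" in stages:
                per_step_feats = {}
                trains = {}
                for step, tr in cell.sweeps.items():
                    feats, ts = sweep_spike_analysis(tr)
                    per_step_feats[step] = feats
                    trains[step] = ts
                    for k, f in enumerate(feats):
                        row = {"cell_id": cell.cell_id,
                               "group": cell.group_label, "step": step,
                               "spike_idx": k}
                        row.update({n: getattr(f, n)
                                    for n in SpikeFeatures._FIELDS})
                        spike_rows.append(row)
                cell.features["trains"] = trains
                avg = first_spike_cell_average(cell, per_step=per_step_feats)
                row = {"cell_id": cell.cell_id, "group": cell.group_label}
                row.update({n: getattr(avg, n) for n in SpikeFeatures._FIELDS})
                cellavg_rows.append(row)
            if "ahp" in stages:
                fits = {step: fit_ahp(tr) for step, tr in cell.sweeps.items()}
                cell.features["ahp"] = fits
                ahp_frames.append(ahp_by_step(cell, fits=fits))
            cell.sweeps.clear()  # free the raw traces
        if passive_rows:
            pd.DataFrame(passive_rows).to_csv(out / "passive.csv", index=False)
            manifest["outputs"]["passive"] = "passive.csv"
        if spike_rows:
            pd.DataFrame(spike_rows).to_csv(out / "spikes.csv", index=False)
            pd.DataFrame(cellavg_rows).to_csv(out / "spikes_cell_avg.csv",
                                              index=False)
            manifest["outputs"]["spikes"] = "spikes.csv"
        if ahp_frames:
            pd.concat(ahp_frames).to_csv(out / "ahp.csv", index=False)
            manifest["outputs"]["ahp"] = "ahp.csv"
        manifest["stage_seconds"]["features"] = round(time.time() - t0, 2)

    # QC: input-resistance inclusion window
    if "passive" in stages and cells:
        fits = {c.cell_id: c.features["passive"] for c in cells
                if "passive" in c.features}
        kept, excl = qc_filter(cells, fits)
        with open(out / "qc_report.json", "w") as fh:
            json.dump({"n_in": len(cells), "n_kept": len(kept),
                       "excluded": excl}, fh, indent=1)
        manifest["outputs"]["qc"] = "qc_report.json"
        cells = kept

    stats_out = {}
    if "stats" in stages and cells:
        t0 = time.time()
        measured = cstats.build_long_table(cells, config.response)
        # carry over generative MCAR deletions so imputation has work to do
        if table is not None:
            gen_missing = table.loc[table["missing"],
                                    ["cell_id", "step"]]
            key = set(map(tuple, gen_missing.to_numpy()))
            mask = [
                (r.cell_id, r.step) in key for r in measured.itertuples()
            ]
            measured.loc[mask, "response"] = np.nan
            measured.loc[mask, "missing"] = True
        measured.to_csv(out / "cohort_table.csv", index=False)
        stats_out = _stats_stage(measured, config)
        with open(out / "stats.json", "w") as fh:
            json.dump(stats_out, fh, indent=1, default=float)
        manifest["outputs"]["stats"] = "stats.json"
        manifest["stage_seconds"]["stats"] = round(time.time() - t0, 2)

    if "power" in stages:
        t0 = time.time()
        effect = replace(cohort, missing_frac=0.0, outlier_frac=0.0)
        pc = cstats.power_curve(effect, config.power_grid,
                                alpha=config.alpha,
                                n_sim=config.power_n_sim, seed=config.seed)
        pcurve = {
            "n_total": pc.n_total.tolist(), "power": pc.power.tolist(),
            "mc_se": pc.mc_se.tolist(), "alpha": pc.alpha,
            "n_sim": pc.n_sim,
        }
        with open(out / "power.json", "w") as fh:
            json.dump(pcurve, fh, indent=1)
        manifest["outputs"]["power"] = "power.json"
        manifest["stage_seconds"]["power"] = round(time.time() - t0, 2)

    manifest["elapsed_seconds"] = round(time.time() - t_start, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)

    if "report" in stages:
        report(out)
        manifest["outputs"]["report"] = "report.txt"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _stats_stage(measured: pd.DataFrame, config: RunConfig) -> dict:
    out: dict = {"response": config.response}
    work = measured
    res_full = None
    if config.screen_influence and (~work["missing"]).sum() > 10:
        base_fit = cstats.fit_lme(work)
        rep = cstats.cooks_screen(work, base_fit)
        out["influence"] = {
            "cutoff": rep.cutoff, "n_flagged": rep.n_flagged,
            "flagged_rows": [int(i) for i in rep.flagged],
        }
        work = cstats.screen_and_mask(work, base_fit)
    if work["missing"].any():
        completed = cstats.impute(work, m=config.n_imputations,
                                  seed=config.seed + 1)
        lrts, fulls = [], []
        for comp in completed:
            r, full, _ = cstats.interaction_lrt(comp)
            lrts.append(r)
            fulls.append(full)
        pooled_lrt = cstats.pool(lrts)
        pooled_fe = cstats.pool(fulls)
        out["interaction"] = {
            "pooled": True, "m": pooled_lrt.m,
            "mean_chi_square": pooled_lrt.mean_chi_square,
            "statistic_d2": pooled_lrt.statistic,
            "p_value": pooled_lrt.p_value,
        }
        out["fixed_effects"] = json.loads(pooled_fe.to_json(orient="index"))
        res_full = fulls[0]
    else:
        lrt_res, full, _ = cstats.interaction_lrt(work)
        main_res, _, _ = cstats.main_effect_lrt(work)
        out["interaction"] = {
            "pooled": False, "chi_square": lrt_res.chi_square,
            "df": lrt_res.df, "p_value": lrt_res.p_value,
        }
        out["main_effect"] = {
            "chi_square": main_res.chi_square, "df": main_res.df,
            "p_value": main_res.p_value,
        }
        out["fixed_effects"] = {
            n: {"estimate": float(full.params[n]), "se": float(full.bse[n])}
            for n in full.params.index
        }
        res_full = full
    if res_full is not None:
        out["random_effects"] = {
            "intercept_var": float(res_full.cov_re[0, 0]),
            "slope_var": float(res_full.cov_re[1, 1]),
            "residual_var": res_full.scale,
            "diagonal_re": res_full.diagonal_re,
        }
    return out


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run (written to report.txt)."""
    run_dir = Path(run_dir)
    lines = ["sahpkit run report", "=" * 60]
    man_path = run_dir / "manifest.json"
    if not man_path.exists():
        raise FileNotFoundError(f"{run_dir} has no manifest.json")
    with open(man_path) as fh:
        manifest = json.load(fh)
    lines.append(f"config hash {manifest['config_hash']}  "
                 f"seed {manifest['seed']}")

    def _groupwise(df: pd.DataFrame, cols: list[str]) -> list[str]:
        rows = []
        g = df.groupby("group")
        for col in cols:
            mean = g[col].mean()
            sem = g[col].sem()
            entry = "  ".join(
                f"{grp}: {mean[grp]:.2f}±{sem[grp]:.2f}" for grp in mean.index
            )
            rows.append(f"  {col:<18} {entry}")
        return rows

    p_csv = run_dir / "passive.csv"
    if p_csv.exists():
        df = pd.read_csv(p_csv)
        lines.append("\nPassive membrane properties (mean±SEM per group)")
        lines += _groupwise(df, ["rmp", "r_in", "tau_m", "r_a"])
    s_csv = run_dir / "spikes_cell_avg.csv"
    if s_csv.exists():
        df = pd.read_csv(s_csv)
        lines.append("\nFirst-spike waveform (cell averages, mean±SEM)")
        lines += _groupwise(df, ["v_peak", "amplitude", "threshold_v",
                                 "rise_time_20_80", "rising_slope",
                                 "half_width"])
    a_csv = run_dir / "ahp.csv"
    if a_csv.exists():
        df = pd.read_csv(a_csv)
        lines.append("\nAHP components per current step (group means, mV)")
        piv = df.groupby(["group", "step"])[["v_med", "v_slow"]].mean().round(2)
        lines.append(piv.to_string())
    st = run_dir / "stats.json"
    if st.exists():
        with open(st) as fh:
            stats_out = json.load(fh)
        inter = stats_out.get("interaction", {})
        lines.append("\nTreatment × current-step interaction "
                     f"({stats_out.get('response')})")
        if inter.get("pooled"):
            lines.append(
                f"  pooled over m={inter['m']} imputations: "
                f"D2={inter['statistic_d2']:.2f}, p={inter['p_value']:.4g}")
        elif inter:
            lines.append(
                f"  chi-square={inter['chi_square']:.2f} "
                f"(df={inter['df']}), p={inter['p_value']:.4g}")
    pw = run_dir / "power.json"
    if pw.exists():
        with open(pw) as fh:
            pc = json.load(fh)
        lines.append("\nPower of the interaction test vs total cell count")
        for n, p, se in zip(pc["n_total"], pc["power"], pc["mc_se"]):
            lines.append(f"  N={n:>4}: power {p:.2f} ± {se:.2f}")
    text = "\n".join(lines) + "\n"
    with open(run_dir / "report.txt", "w") as fh:
        fh.write(text)
    return text
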