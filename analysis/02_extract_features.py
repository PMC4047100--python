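"""Extract per-sweep features from the simulated cohort.

For every cell: passive membrane properties from the −20 pA probe
(input/series resistance, time constants, resting potential), spike
detection and first-spike waveform features, interval statistics with the
accommodation ratio, and the bi-exponential medium/slow AHP decomposition
of each sweep's tail.  Applies the 100–450 MΩ input-resistance inclusion
filter and writes one CSV per feature family under results/cohort/.

Run after 01:  python analysis/02_extract_features.py
"""

from pathlib import Path

import pandas as pd

from sahpkit.pipeline import RunConfig, run_pipeline

RESULTS = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    cfg = RunConfig(
        out_dir=str(RESULTS),
        stages=("passive", "spikes", "ahp"),
        input_traces=str(RESULTS / "cohort.h5"),
    )
    run_pipeline(cfg)
    passive = pd.read_csv(RESULTS / "passive.csv")
    ahp = pd.read_csv(RESULTS / "ahp.csv")
    print(f"{len(passive)} cells fitted; input resistance "
          f"{passive['r_in'].mean():.0f} ± {passive['r_in'].sem():.0f} MΩ "
          "(mean ± SEM)")
    by_group = ahp.groupby("group")[["v_med", "v_slow"]].mean().round(2)
    print("mean AHP component amplitudes (mV):")
    print(by_group.to_string())
    print(f"mean bi-exponential fit r² = {ahp['r2'].mean():.2f}")


if __name__ == "__main__":
    main()
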