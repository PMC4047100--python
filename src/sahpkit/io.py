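"""Trace containers and on-disk formats.

Canonical units: time in seconds on the in-memory grid, milliseconds in
protocol metadata and report surfaces; voltage mV; current pA; resistance
MΩ.  With these units Ohm's law reads ``V[mV] = I[pA] * R[MΩ] * 1e-3``;
the conversion constant lives here and nowhere else.

On-disk formats:

* per-cell TSV sweep table (columns ``sweep_id``, ``step_pA``, ``time_s``,
  ``voltage_mV``) plus a JSON sidecar carrying the protocol and labels;
* an HDF5 container for whole cohorts (one group per cell, one dataset per
  sweep, protocol serialized as JSON attributes).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np

#: mV produced by 1 pA flowing through 1 MΩ.
MV_PER_PA_MOHM = 1e-3

#: The 13-value depolarizing current grid, pA.
DEPOL_STEP_GRID = tuple(range(150, 451, 25))

GROUP_LABELS = ("vehicle", "treated", "unknown")


@dataclass(frozen=True)
class CurrentProtocol:
    """Timing and amplitudes of one current-clamp sweep.

    A sweep holds the cell near −70 mV, applies a −20 pA / 200 ms
    hyperpolarizing probe, a 600 ms depolarizing step from the 150–450 pA
    grid, records the after-hyperpolarization tail out to ``record_dur``,
    and ends with a 200 ms absolute-zero-current segment.
    """

    holding_current: float = 0.0      # pA
    hyper_step_amp: float = -20.0     # pA, relative to holding
    hyper_step_dur: float = 200.0     # ms
    depol_step_amp: float = 300.0     # pA, relative to holding
    depol_step_dur: float = 600.0     # ms
    record_dur: float = 8000.0        # ms
    zero_current_dur: float = 200.0   # ms, appended after record_dur
    inter_sweep_interval: float = 30.0  # s, metadata only
    sampling_rate: float = 50_000.0   # Hz
    hyper_onset: float = 200.0        # ms
    depol_onset: float = 700.0        # ms

    def __post_init__(self) -> None:
        if self.depol_step_amp not in DEPOL_STEP_GRID:
            raise ValueError(
                f"depol_step_amp must be one of {DEPOL_STEP_GRID} pA, "
                f"got {self.depol_step_amp}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        segs = [
            (self.hyper_onset, self.hyper_onset + self.hyper_step_dur),
            (self.depol_onset, self.depol_onset + self.depol_step_dur),
            (self.record_dur, self.record_dur + self.zero_current_dur),
        ]
        for (a0, a1), (b0, b1) in zip(segs, segs[1:]):
            if a1 > b0:
                raise ValueError("protocol segments overlap or are out of order")
        if self.hyper_onset < 0:
            raise ValueError("hyper_onset must be >= 0")

    # -- segment boundaries, all in ms ------------------------------------
    @property
    def hyper_end(self) -> float:
        return self.hyper_onset + self.hyper_step_dur

    @property
    def depol_end(self) -> float:
        return self.depol_onset + self.depol_step_dur

    @property
    def total_dur(self) -> float:
        return self.record_dur + self.zero_current_dur

    @property
    def n_samples(self) -> int:
        return int(round(self.total_dur / 1000.0 * self.sampling_rate))

    def time_grid(self) -> np.ndarray:
        """Sweep time base in seconds, 0-based at sweep start."""
        return np.arange(self.n_samples) / self.sampling_rate

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CurrentProtocol":
        return cls(**d)

    def family(self) -> list["CurrentProtocol"]:
        """The 13-sweep protocol family spanning 150–450 pA."""
        return [replace(self, depol_step_amp=float(a)) for a in DEPOL_STEP_GRID]


@dataclass
class VoltageTrace:
    """One sweep: uniformly sampled membrane potential plus its protocol."""

    time: np.ndarray          # s
    voltage: np.ndarray       # mV
    protocol: CurrentProtocol
    cell_id: str = "cell0"
    sweep_id: str = "sweep0"
    group_label: str = "unknown"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.time.shape != self.voltage.shape or self.time.ndim != 1:
            raise ValueError("time and voltage must be 1-D arrays of equal length")
        if len(self.time) < 2:
            raise ValueError("trace must contain at least two samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        dt0 = dt.mean()
        if np.max(np.abs(dt - dt0)) > 1e-6 * dt0:
            raise ValueError("time grid is not uniform to within 1 ppm")
        fs_grid = 1.0 / dt0
        if not math.isclose(fs_grid, self.protocol.sampling_rate, rel_tol=1e-6):
            raise ValueError(
                f"protocol sampling_rate {self.protocol.sampling_rate} Hz does not "
                f"match the time grid ({fs_grid:.6g} Hz)"
            )
        if self.group_label not in GROUP_LABELS:
            raise ValueError(f"group_label must be one of {GROUP_LABELS}")

    @property
    def sampling_rate(self) -> float:
        return self.protocol.sampling_rate

    def segment(self, t0_ms: float, t1_ms: float) -> slice:
        """Index slice covering [t0, t1) ms of sweep time."""
        fs = self.sampling_rate
        i0 = int(np.ceil(t0_ms / 1000.0 * fs - 1e-9))
        i1 = int(np.ceil(t1_ms / 1000.0 * fs - 1e-9))
        return slice(max(i0, 0), min(i1, len(self.time)))

    def window_mean(self, t0_ms: float, t1_ms: float) -> float:
        sl = self.segment(t0_ms, t1_ms)
        if sl.stop <= sl.start:
            raise ValueError(f"empty window [{t0_ms}, {t1_ms}) ms")
        return float(self.voltage[sl].mean())


@dataclass
class CellRecord:
    """All sweeps of one cell, keyed by depolarizing-step amplitude (pA)."""

    cell_id: str
    group_label: str = "unknown"
    sweeps: dict[float, VoltageTrace] = field(default_factory=dict)
    features: dict = field(default_factory=dict)

    def add_sweep(self, trace: VoltageTrace) -> None:
        step = float(trace.protocol.depol_step_amp)
        if step in self.sweeps:
            raise ValueError(
                f"duplicate sweep at {step:g} pA for cell {self.cell_id!r}"
            )
        if step not in DEPOL_STEP_GRID:
            raise ValueError(f"step {step:g} pA not on the 13-value grid")
        self.sweeps[step] = trace

    @property
    def steps(self) -> list[float]:
        return sorted(self.sweeps)


# ---------------------------------------------------------------------------
# TSV + JSON sidecar (per cell)
# ---------------------------------------------------------------------------

def _cell_sidecar(cell: CellRecord) -> dict:
    return {
        "cell_id": cell.cell_id,
        "group_label": cell.group_label,
        "sweeps": {
            f"{step:g}": {
                "sweep_id": tr.sweep_id,
                "protocol": tr.protocol.to_dict(),
            }
            for step, tr in sorted(cell.sweeps.items())
        },
    }


def write_sweeps(cells: Iterable[CellRecord], path: str | Path) -> Path:
    """Write cell records to *path*.

    ``*.h5`` → HDF5 cohort container; otherwise *path* is a directory that
    receives one ``<cell_id>.tsv`` sweep table and ``<cell_id>.json``
    sidecar per cell.  Field ordering is deterministic.
    """
    path = Path(path)
    cells = list(cells)
    ids = [c.cell_id for c in cells]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cell_id in cohort")
    if path.suffix == ".h5":
        return _write_h5(cells, path)
    path.mkdir(parents=True, exist_ok=True)
    for cell in cells:
        tsv = path / f"{cell.cell_id}.tsv"
        with open(tsv, "w") as fh:
            fh.write("sweep_id\tstep_pA\ttime_s\tvoltage_mV\n")
            for step, tr in sorted(cell.sweeps.items()):
                for t, v in zip(tr.time, tr.voltage):
                    fh.write(f"{tr.sweep_id}\t{step:g}\t{float(t)!r}\t"
                             f"{float(v)!r}\n")
        with open(path / f"{cell.cell_id}.json", "w") as fh:
            json.dump(_cell_sidecar(cell), fh, indent=1, sort_keys=True)
    return path


def read_sweeps(path: str | Path) -> list[CellRecord]:
    """Read cell records written by :func:`write_sweeps`."""
    path = Path(path)
    if path.suffix == ".h5":
        return _read_h5(path)
    if not path.is_dir():
        raise FileNotFoundError(f"{path} is not a sweep directory or .h5 file")
    cells = []
    for sidecar in sorted(path.glob("*.json")):
        with open(sidecar) as fh:
            meta = json.load(fh)
        for key in ("cell_id", "group_label", "sweeps"):
            if key not in meta:
                raise ValueError(f"{sidecar}: missing metadata key {key!r}")
        cell = CellRecord(cell_id=meta["cell_id"], group_label=meta["group_label"])
        tsv = path / f"{meta['cell_id']}.tsv"
        if not tsv.exists():
            raise FileNotFoundError(f"sweep table {tsv} missing for {sidecar}")
        data = np.genfromtxt(
            tsv, delimiter="\t", skip_header=1,
            dtype=None, encoding="utf-8",
            names=("sweep_id", "step_pA", "time_s", "voltage_mV"),
        )
        data = np.atleast_1d(data)
        for skey, smeta in meta["sweeps"].items():
            step = float(skey)
            mask = data["step_pA"] == step
            if not mask.any():
                raise ValueError(f"{tsv}: no samples for step {skey} pA")
            proto = CurrentProtocol.from_dict(smeta["protocol"])
            tr = VoltageTrace(
                time=data["time_s"][mask],
                voltage=data["voltage_mV"][mask],
                protocol=proto,
                cell_id=meta["cell_id"],
                sweep_id=smeta["sweep_id"],
                group_label=meta["group_label"],
            )
            cell.add_sweep(tr)
        cells.append(cell)
    return cells


# ---------------------------------------------------------------------------
# HDF5 cohort container
# ---------------------------------------------------------------------------

def _write_h5(cells: list[CellRecord], path: Path) -> Path:
    with h5py.File(path, "w") as h5:
        root = h5.create_group("cells")
        for cell in cells:
            g = root.create_group(cell.cell_id)
            g.attrs["group_label"] = cell.group_label
            for step, tr in sorted(cell.sweeps.items()):
                ds = g.create_dataset(f"step_{step:g}", data=tr.voltage)
                ds.attrs["sweep_id"] = tr.sweep_id
                ds.attrs["protocol"] = json.dumps(tr.protocol.to_dict(),
                                                  sort_keys=True)
                ds.attrs["t0_s"] = float(tr.time[0])
    return path


def _read_h5(path: Path) -> list[CellRecord]:
    cells = []
    with h5py.File(path, "r") as h5:
        if "cells" not in h5:
            raise ValueError(f"{path}: not a cohort container (no /cells group)")
        for cell_id in sorted(h5["cells"]):
            g = h5["cells"][cell_id]
            if "group_label" not in g.attrs:
                raise ValueError(f"{path}:/cells/{cell_id}: missing group_label")
            cell = CellRecord(cell_id=cell_id, group_label=str(g.attrs["group_label"]))
            for name in sorted(g):
                ds = g[name]
                for key in ("sweep_id", "protocol", "t0_s"):
                    if key not in ds.attrs:
                        raise ValueError(f"{path}:{name}: missing attribute {key!r}")
                proto = CurrentProtocol.from_dict(json.loads(ds.attrs["protocol"]))
                t0 = float(ds.attrs["t0_s"])
                v = ds[()]
                tr = VoltageTrace(
                    time=t0 + np.arange(len(v)) / proto.sampling_rate,
                    voltage=v,
                    protocol=proto,
                    cell_id=cell_id,
                    sweep_id=str(ds.attrs["sweep_id"]),
                    group_label=cell.group_label,
                )
                cell.add_sweep(tr)
            cells.append(cell)
    return cells


# ---------------------------------------------------------------------------
# Decimation
# ---------------------------------------------------------------------------

def decimate(trace: VoltageTrace, target_rate: float) -> VoltageTrace:
    """Anti-aliased decimation of a trace to *target_rate* (must divide fs)."""
    from scipy import signal

    fs = trace.sampling_rate
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    ratio = fs / target_rate
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 * ratio:
        raise ValueError(
            f"target_rate {target_rate:g} Hz does not divide the sampling "
            f"rate {fs:g} Hz"
        )
    if q == 1:
        return trace
    v = trace.voltage
    # cascade in factors <= 10 as recommended for large decimation ratios
    for f in _factor_chain(q):
        v = signal.decimate(v, f, ftype="fir", zero_phase=True)
    proto = replace(trace.protocol, sampling_rate=target_rate)
    return VoltageTrace(
        time=trace.time[0] + np.arange(len(v)) / target_rate,
        voltage=v,
        protocol=proto,
        cell_id=trace.cell_id,
        sweep_id=trace.sweep_id,
        group_label=trace.group_label,
    )


def _factor_chain(q: int) -> list[int]:
    chain = []
    while q > 10:
        for f in (10, 9, 8, 7, 6, 5, 4, 3, 2):
            if q % f == 0:
                chain.append(f)
                q //= f
                break
        else:  # prime > 10
            chain.append(q)
            return chain
    chain.append(q)
    return chain
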