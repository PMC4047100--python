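import numpy as np
import pytest

import sahpkit as sk

#: short-record protocol (probe + step + short tail) for tests that do not
#: need the full 8-s AHP tail; keeps trace generation cheap
SHORT = dict(record_dur=1600.0)


@pytest.fixture(scope="session")
def proto():
    return sk.CurrentProtocol(depol_step_amp=300.0)


@pytest.fixture(scope="session")
def proto_short():
    return sk.CurrentProtocol(depol_step_amp=300.0, **SHORT)


@pytest.fixture(scope="session")
def proto_10k():
    return sk.CurrentProtocol(depol_step_amp=300.0, sampling_rate=10_000.0)


@pytest.fixture(scope="session")
def clean_params():
    """Noiseless, spike-free, AHP-free sweep parameters."""
    return sk.TraceGenParams(noise_sd=0.0, spike_gain=0.0,
                             v_med_true=0.0, v_slow_true=0.0)


@pytest.fixture(scope="session")
def default_trace(proto):
    tr, gt = sk.generate_trace(proto, sk.TraceGenParams(seed=11))
    return tr, gt


def make_cell(proto, params, cell_id="c0", group="vehicle", steps=None):
    cell = sk.CellRecord(cell_id=cell_id, group_label=group)
    from dataclasses import replace
    for step in steps or sk.DEPOL_STEP_GRID:
        p = replace(proto, depol_step_amp=float(step))
        tr, _ = sk.generate_trace(p, params)
        tr.cell_id, tr.group_label = cell_id, group
        tr.sweep_id = f"{cell_id}_{step}"
        cell.add_sweep(tr)
    return cell
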