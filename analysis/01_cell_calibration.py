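"""Resting properties and intrinsic signatures of the two model cells.

Relaxes the calibrated thalamocortical (TC) and cortical presets, measures
their resting potential and input conductance, fires the TC rebound-burst
protocol (release from a 500 ms hyperpolarizing step), and bisects the
cortical single-AMPA-event spike threshold. Writes
results/cell_calibration.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from rtcnet import cell_models as cm
from rtcnet.circuit_sim import CircuitSpec, simulate_cortical_cell
from rtcnet.stimuli import SpikeTrain

OUT = Path("results")
OUT.mkdir(exist_ok=True)


def ctx_event_threshold(lo=10.0, hi=300.0, tol=0.05) -> float:
    """Smallest single alpha-AMPA amplitude evoking a cortical spike."""
    ctx = cm.ctx_default()
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        circ = CircuitSpec(n_ret=0, n_tc=1, w_tc=np.array([mid]),
                           tc_params=[], ctx_params=ctx)
        _, sp = simulate_cortical_cell(
            circ, [SpikeTrain(np.array([50.0]), 200.0)], 200.0)
        if len(sp) >= 1:
            hi = mid
        else:
            lo = mid
    return hi


def main():
    rows = []
    for name, preset in (("tc", cm.tc_default), ("ctx", cm.ctx_default)):
        p = preset()
        v_rest, g_in = cm.rest_properties(p)
        rows.append(dict(cell=name, v_rest_mv=v_rest, g_in_ns=g_in))
        print(f"{name}: V_rest = {v_rest:.2f} mV, g_in = {g_in:.2f} nS")

    rebound = cm.rebound_response(cm.tc_default())
    burst = rebound[rebound < 150.0]
    print(f"TC rebound burst: {burst.size} spikes in the first 150 ms "
          f"after release (first at {rebound[0]:.1f} ms)" if rebound.size
          else "no rebound spikes")
    rows.append(dict(cell="tc", rebound_spikes_150ms=float(burst.size),
                     rebound_latency_ms=float(rebound[0]) if rebound.size
                     else np.nan))

    thr = ctx_event_threshold()
    print(f"cortical single-AMPA-event spike threshold: {thr:.1f} nS")
    rows.append(dict(cell="ctx", event_threshold_ns=thr))

    pd.DataFrame(rows).to_csv(OUT / "cell_calibration.csv", index=False)
    print(f"wrote {OUT / 'cell_calibration.csv'}")


if __name__ == "__main__":
    sys.exit(main())
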