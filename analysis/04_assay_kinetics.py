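#!/usr/bin/env python
"""Liposome tandem-assay influx kinetics.

Simulates fluorescence turn-on curves for peptide influx through a single
channel into 100 nm liposomes carrying the CX4/LCG reporter pair, at outside
concentrations 0.1-1.0 uM in the exit-limited transport regime.  Shows the
assay's key signature — initial rates independent of concentration — and
closes the loop by converting the initial rate back into a per-channel flux,
recovering the simulator's exit rate.  Writes results/assay_kinetics.json
and one curve CSV.
"""

import json
from pathlib import Path

import numpy as np

from porethru import liposome_assay as la
from porethru import workflows

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rep = workflows.run_assay_recovery(
        k_entry=1000.0, k_exit=2.0, concentrations_uM=(0.1, 0.5, 1.0)
    )
    OUT.mkdir(exist_ok=True)
    (OUT / "assay_kinetics.json").write_text(
        json.dumps(rep, indent=2, default=float) + "\n"
    )
    curve = la.simulate_influx(
        la.AssayConfig(), la.TransportModel(1000.0, 2.0), 1e-6,
        np.linspace(0.0, 2.0, 2001),
    )
    la.curve_to_csv(curve, OUT / "assay_curve_1uM.csv")

    print("c_out (uM)  initial rate (1/s)  flux (molecules/s/channel)")
    for c, r in rep["initial_rates_per_s"].items():
        print(f"{float(c):10.1f} {r:19.2e} {rep['flux_per_channel_per_s'][c]:16.2f}")
    print(f"rate spread over 10x concentration range: "
          f"{rep['rate_spread_fraction']:.1%} (exit-limited transport)")
    print(f"recovered k_exit = {rep['k_exit_recovered_per_s']:.2f} /s "
          f"(true {rep['k_exit_true_per_s']:.1f} /s, "
          f"error {rep['k_exit_relative_error']:.1%})")


if __name__ == "__main__":
    main()
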