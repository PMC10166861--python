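#!/usr/bin/env python
"""Spike-detection oracle: recover known spike times from a synthetic trace.

Builds a 60-s, 4-channel, 30-kHz trace with 10-sigma biphasic templates at
5 Hz, runs the full preprocessing chain (common-median reference, 300-6,000 Hz
zero-phase Butterworth, 9xMAD thresholding) and reports recall, the
false-event rate and the MAD-based noise estimate.
"""

from pathlib import Path

import pandas as pd

from engramephys import experiments

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    res = experiments.detection_experiment(
        duration=60.0, n_channels=4, rate_hz=5.0, amplitude_sigma=10.0, seed=seed
    )
    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([res]).to_csv(OUT / "detection_oracle.csv", index=False)
    print(
        f"detected {res['n_true_spikes']} true spikes: recall {res['recall_pct']:.1f}% "
        f"(threshold 9xMAD ~ 6.1 sigma), false events {res['false_event_rate_hz']:.3f} Hz, "
        f"MAD sigma error {res['mad_sigma_error_pct']:.2f}%"
    )
    print(f"-> {OUT / 'detection_oracle.csv'}")


if __name__ == "__main__":
    main()
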