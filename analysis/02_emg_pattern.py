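#!/usr/bin/env python
"""Derive the EMG stimulation pattern from the volitional-cycling EMG
recording written by 01_simulate_session.py.

Band-pass filters each quadriceps head's EMG ([10, 30] Hz, 4th order,
zero-phase), extracts the moving-RMS envelope, normalizes per revolution,
averages onto the crank-angle grid, thresholds at 25% of the peak, and takes
the union over the heads; the left leg is the 180-degree rotation of the
dominant (right) leg. Writes the per-muscle intervals to
results/emg_intervals.csv.
"""
import argparse
from pathlib import Path

import pandas as pd

from fescycling import derive_emg_pattern, read_recording


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--recording", type=Path, default=Path("results/session/emg_session.txt")
    )
    parser.add_argument("--out", type=Path, default=Path("results/emg_intervals.csv"))
    parser.add_argument("--threshold", type=float, default=0.25)
    args = parser.parse_args()

    rec = read_recording(args.recording)
    pattern, intervals = derive_emg_pattern(rec, threshold_fraction=args.threshold)

    rows = [
        {"muscle": m, "start_deg": round(iv.start, 2), "stop_deg": round(iv.stop, 2),
         "length_deg": round(iv.length, 2)}
        for m, iv in intervals.items()
    ]
    for ch, iv in pattern.channels.items():
        rows.append(
            {"muscle": f"{ch} (pattern)", "start_deg": round(iv.start, 2),
             "stop_deg": round(iv.stop, 2), "length_deg": round(iv.length, 2)}
        )
    table = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)
    print(f"activation intervals at the {args.threshold:.0%} threshold:")
    print(table.to_string(index=False))
    print(f"\nwrote {args.out}")


if __name__ == "__main__":
    main()
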