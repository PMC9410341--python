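#!/usr/bin/env python
"""Generate the synthetic telemetry cohort.

Emulates 24-h post-infarction telemetry at desk scale: 12 hypokalemic-MI
("STORM"-like) mice, each a 10-minute single-lead ECG at 2 kHz with a
550 bpm sinus baseline, several planted VT runs (900–1200 bpm, 2–8 s),
occasional extrasystoles, and a Vfib segment in roughly a third of the
animals.  Traces are written as two-column CSV with JSON metadata and a
ground-truth sidecar under scratch/telemetry/.

Run:  python analysis/01_simulate_telemetry.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

from stormquant.io import write_ecg_csv, write_ground_truth
from stormquant.simulate import random_telemetry_spec, simulate_ecg

OUT = Path("scratch/telemetry")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-mice", type=int, default=12)
    args = ap.parse_args()

    OUT.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i in range(args.n_mice):
        spec = random_telemetry_spec(args.seed * 1000 + i, duration_s=600.0,
                                     p_vfib=0.33)
        trace, truth = simulate_ecg(spec)
        stem = OUT / f"mouse{i:02d}"
        write_ecg_csv(trace, stem)
        write_ground_truth(truth, stem.with_suffix(".truth.json"))
        n_vt = sum(1 for k, *_ in truth.episodes if k == "VT")
        n_vf = sum(1 for k, *_ in truth.episodes if k == "Vfib")
        manifest.append({"subject": stem.name, "n_vt": n_vt, "n_vfib": n_vf})
        print(f"{stem.name}: {n_vt} VT runs, {n_vf} Vfib segments")
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=1))
    print(f"\nwrote {len(manifest)} traces to {OUT}/")


if __name__ == "__main__":
    main()
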