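#!/usr/bin/env python
"""Simulate the study-scale synthetic cohort.

22 patients of minute-sampled multichannel vitals, ~220 analysis segments
at a ~10:1 control:case imbalance, with planted pre-event physiology,
BP artifacts and missingness.  Writes the long-format cohort and its
ground-truth sidecar under results/analysis/.
"""

import sys
from pathlib import Path

from icp_horizon.records import write_cohort
from icp_horizon.synthgen import CohortConfig, generate_cohort

OUT = Path("results/analysis")
SEED = 0


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else SEED
    records, truths = generate_cohort(22, CohortConfig(), seed=seed)
    OUT.mkdir(parents=True, exist_ok=True)
    write_cohort(OUT / "cohort.csv", records, truths)
    n_cases = sum(len(t.event_onsets) for t in truths)
    n_controls = sum(len(t.control_intervals) for t in truths)
    total_h = sum(r.n_minutes for r in records) / 60
    print(f"simulated 22 patients, {total_h:.0f} monitor-hours")
    print(f"  {n_cases} elevated-ICP events, {n_controls} control periods "
          f"({n_controls / n_cases:.1f}:1)")
    print(f"wrote {OUT/'cohort.csv'} (+ truth sidecar)")


if __name__ == "__main__":
    main()
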