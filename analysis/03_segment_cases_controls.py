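#!/usr/bin/env python
"""Cut corrected records into labeled case and control analysis records.

Cases anchor 4-h spans at elevated-ICP event onsets (>=20 cm H2O for
10 min, independent at 5 h, washout-respecting); controls are the final
4 h of 6-h quiet periods.  Segment-level QC (10% poor-quality/missing
rule) is applied per span.  Writes the segment data and a manifest.
"""

from pathlib import Path

import pandas as pd

from icp_horizon import qc
from icp_horizon.records import read_cohort
from icp_horizon.segmentation import segment_record

OUT = Path("results/analysis")


def main() -> None:
    corrected, _ = read_cohort(OUT / "cohort_corrected.csv")
    raw, _ = read_cohort(OUT / "cohort.csv")
    raw_by_id = {r.record_id: r for r in raw}
    rows, frames, dropped = [], [], 0
    for rec in corrected:
        mask = qc.detect_artifacts(raw_by_id[rec.record_id])
        segs, rejs = segment_record(rec)
        dropped += len(rejs)
        for s in segs:
            rep = qc.adjudicate(raw_by_id[rec.record_id], mask, span=s.span)
            if rep.verdict != "pass":
                dropped += 1
                continue
            rows.append({"segment_id": s.segment_id,
                         "patient_id": s.patient_id, "label": s.label,
                         "anchor": s.anchor, "span_start": s.span[0],
                         "span_end": s.span[1]})
            for ch, vals in s.data.items():
                frames.append(pd.DataFrame({
                    "segment_id": s.segment_id, "minute": range(len(vals)),
                    "channel": ch, "value": vals}))
    pd.concat(frames, ignore_index=True).to_csv(OUT / "segments.csv",
                                                index=False)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(OUT / "segments_manifest.csv", index=False)
    counts = manifest.label.value_counts()
    print(f"kept {len(manifest)} segments "
          f"({counts.get('case', 0)} cases, {counts.get('control', 0)} "
          f"controls), rejected {dropped}")


if __name__ == "__main__":
    main()
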