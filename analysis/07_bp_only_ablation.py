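#!/usr/bin/env python
"""Blood-pressure-only ablation.

Re-runs the XGB benchmark on feature tables restricted to the SBP/DBP/MAP
streams (54 statistic columns) and compares the 30-min-horizon metrics
with the full eight-channel run, quantifying how much of the predictive
signal survives without ICP-linked channels.
"""

from pathlib import Path

import pandas as pd

from icp_horizon.features import build_tables
from icp_horizon.modeling import benchmark

import importlib.util as _ilu

OUT = Path("results/analysis")
SEED = 202

_spec = _ilu.spec_from_file_location(
    "extract", Path(__file__).parent / "04_extract_features.py")
_mod = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_mod)


def main() -> None:
    segs = _mod.load_segments()
    tables = build_tables(segs, channels="bp_only")
    res = benchmark({2: tables[2]}, families=("xgb",), n_iter=10, budget=16,
                    seed=SEED, keep_bundles=False)
    res.summary.to_csv(OUT / "benchmark_bp_only_w2.csv", index=False)
    bp = res.summary.query("window == 2").set_index("metric")

    full_path = OUT / "benchmark_summary.csv"
    print("BP-only (SBP/DBP/MAP) XGB at the 30-min horizon:")
    for m in ("auroc", "auprc", "sensitivity", "specificity"):
        print(f"  {m}: {bp.loc[m, 'mean']:.2f} "
              f"[{bp.loc[m, 'ci_lo']:.2f},{bp.loc[m, 'ci_hi']:.2f}]")
    if full_path.exists():
        full = pd.read_csv(full_path).query(
            "window == 2 and family == 'xgb'").set_index("metric")
        d_auroc = full.loc["auroc", "mean"] - bp.loc["auroc", "mean"]
        print(f"drop vs full channel set: AUROC -{d_auroc:.2f}")


if __name__ == "__main__":
    main()
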