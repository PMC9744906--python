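"""Shared fixtures: one default synthetic cohort carried through QC,
segmentation, featurization and an XGB benchmark, reused session-wide."""

from __future__ import annotations

import numpy as np
import pytest

from icp_horizon import qc
from icp_horizon.features import build_tables
from icp_horizon.modeling import benchmark
from icp_horizon.segmentation import segment_record
from icp_horizon.synthgen import generate_cohort

COHORT_SEED = 11


@pytest.fixture(scope="session")
def cohort():
    """Default-config cohort: 22 patients, ~220 segments, ~10:1 imbalance."""
    return generate_cohort(22, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def corrected(cohort):
    records, truths = cohort
    out = []
    for rec in records:
        corr, mask = qc.correct_record(rec)
        out.append((corr, mask))
    return out


@pytest.fixture(scope="session")
def segments(corrected):
    segs = []
    for corr, _mask in corrected:
        s, _rej = segment_record(corr)
        segs.extend(s)
    return segs


@pytest.fixture(scope="session")
def tables(segments):
    return build_tables(segments, channels="full")


@pytest.fixture(scope="session")
def xgb_benchmark(tables):
    """All 8 windows, 10 Monte-Carlo iterations, default XGB parameters."""
    return benchmark(tables, families=("xgb",), n_iter=10, budget=1, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
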