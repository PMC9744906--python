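"""Generator contracts: determinism, physiologic invariants, imbalance,
planted-signature directions, artifact/missingness plumbing."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from icp_horizon.features import extract_features, sample_entropy
from icp_horizon.records import EffectConfig, VitalsRecord
from icp_horizon.segmentation import AnalysisWindow, segment_record
from icp_horizon.synthgen import (ArtifactConfig, CohortConfig,
                                  ConfigurationError, MissingnessConfig,
                                  add_narrow_spike, generate_cohort,
                                  inject_artifacts, plant_prodrome)


def _clean_mask(rec, truth):
    art = np.any(list(truth.artifact_mask_true.values()), axis=0)
    return ~art


def test_fixed_seed_reproduces_cohort_bitwise(cohort):
    records, truths = cohort
    records2, truths2 = generate_cohort(22, seed=11)
    for a, b in zip(records, records2):
        for ch in a.channels:
            assert np.array_equal(a.channels[ch], b.channels[ch],
                                  equal_nan=True)
            assert np.array_equal(a.missing[ch], b.missing[ch])
    for t, u in zip(truths, truths2):
        assert t.event_onsets == u.event_onsets
        assert t.control_intervals == u.control_intervals


def test_configuration_errors():
    with pytest.raises(ConfigurationError):
        CohortConfig(record_len=120)
    with pytest.raises(ConfigurationError):
        CohortConfig(control_duration=200)
    with pytest.raises(ConfigurationError):
        generate_cohort(0)


def test_physiologic_invariants_on_clean_minutes(cohort):
    """DBP<MAP<SBP ordering and CPP=MAP-0.7355*ICP hold at >=99% of
    non-artifact, non-missing minutes; SpO2 and pressures in range."""
    records, truths = cohort
    for rec, truth in zip(records, truths):
        viol = rec.check_physiology(exclude=~_clean_mask(rec, truth))
        assert viol["ordering"] <= 0.01
        assert viol["cpp_consistency"] <= 0.01
        assert viol["range"] == 0.0


def test_time_grid_one_minute(cohort):
    rec = cohort[0][0]
    assert np.array_equal(np.diff(rec.t), np.ones(rec.n_minutes - 1))


def test_imbalance_near_ten_to_one(cohort):
    _, truths = cohort
    n_cases = sum(len(t.event_onsets) for t in truths)
    n_controls = sum(len(t.control_intervals) for t in truths)
    assert 8 <= n_cases <= 34          # binomial spread around 20
    assert n_cases + n_controls == 220
    assert 5 <= n_controls / n_cases <= 18


def test_event_onsets_start_qualifying_runs(cohort):
    records, truths = cohort
    for rec, truth in zip(records, truths):
        icp = rec.channels["ICP"]
        for onset in truth.event_onsets:
            run = icp[onset:onset + 10]
            assert np.all(run >= 20.0)
            assert onset == 0 or not icp[onset - 1] >= 20.0


def test_artifact_mask_disjoint_from_missing(cohort):
    records, truths = cohort
    for rec, truth in zip(records, truths):
        for ch, m in truth.artifact_mask_true.items():
            assert not np.any(m & rec.missing[ch])


# -- prodrome planting ------------------------------------------------------


def _quiet_record(n=600, seed=0):
    from icp_horizon.synthgen import _baselines, _base_channels
    rng = np.random.default_rng(seed)
    ch = _base_channels(n, _baselines(rng), rng)
    return VitalsRecord("r", "p", ch), rng


def test_icp_mean_effect_is_additive():
    """A flat +5 cm H2O ICP effect over the last hour raises the window
    mean by about 5 relative to the unplanted record."""
    rec, rng = _quiet_record()
    eff = EffectConfig(ramp=False, span_min=60, icp_mean_delta=5.0,
                       icp_entropy_noise=0.0, hr_swing=0.0, dbp_drift=0.0,
                       sbp_sd_shrink=0.0, map_smooth=0.0)
    planted = plant_prodrome(rec, 400, eff, rng)
    diff = (planted.channels["ICP"][340:400].mean()
            - rec.channels["ICP"][340:400].mean())
    assert diff == pytest.approx(5.0, abs=0.2)
    # outside the span the record is untouched
    assert np.array_equal(planted.channels["ICP"][:340],
                          rec.channels["ICP"][:340])


def test_sbp_sd_reduction_effect():
    rec, rng = _quiet_record(seed=1)
    eff = EffectConfig(ramp=False, span_min=240, icp_mean_delta=0.0,
                       icp_entropy_noise=0.0, hr_swing=0.0, dbp_drift=0.0,
                       sbp_sd_shrink=0.6, map_smooth=0.0)
    planted = plant_prodrome(rec, 400, eff, rng)
    sd_aff = planted.channels["SBP"][370:400].std()
    sd_unaff = rec.channels["SBP"][370:400].std()
    assert sd_aff < sd_unaff


def test_map_smoothing_lowers_sample_entropy():
    rec, rng = _quiet_record(seed=3)
    eff = EffectConfig(ramp=False, span_min=240, icp_mean_delta=0.0,
                       icp_entropy_noise=0.0, hr_swing=0.0, dbp_drift=0.0,
                       sbp_sd_shrink=0.0, map_smooth=1.0)
    planted = plant_prodrome(rec, 400, eff, rng)
    se_aff = sample_entropy(planted.channels["MAP"][370:400])
    se_unaff = sample_entropy(rec.channels["MAP"][370:400])
    assert np.isfinite(se_aff) and np.isfinite(se_unaff)
    assert se_aff < se_unaff


def test_prodrome_requires_four_hours_history():
    rec, rng = _quiet_record()
    with pytest.raises(ValueError):
        plant_prodrome(rec, 120, EffectConfig(), rng)


def test_prodrome_preserves_invariants():
    rec, rng = _quiet_record(seed=4)
    planted = plant_prodrome(rec, 400, EffectConfig(), rng)
    viol = planted.check_physiology()
    assert viol["ordering"] == 0.0
    assert viol["cpp_consistency"] == 0.0


def test_all_six_signatures_shift_in_stated_directions(corrected):
    """Case windows at the 30-min horizon show higher ICP mean and sample
    entropy, higher HR binned entropy, lower DBP trend, lower SBP SD and
    lower MAP sample entropy than control windows (cohort medians)."""
    w2 = AnalysisWindow(2)
    vals = {"case": [], "control": []}
    for corr, _ in corrected:
        segs, _ = segment_record(corr)
        for s in segs:
            row = {}
            for ch, stat in [("ICP", "mean"), ("ICP", "sample_entropy"),
                             ("HR_ekg", "binned_entropy"),
                             ("DBP", "mean_change"), ("SBP", "sd"),
                             ("MAP", "sample_entropy")]:
                row[f"{ch}.{stat}"] = extract_features(
                    s.window_values(ch, w2))[stat]
            vals[s.label].append(row)
    import pandas as pd
    case = pd.DataFrame(vals["case"]).median()
    ctrl = pd.DataFrame(vals["control"]).median()
    assert case["ICP.mean"] > ctrl["ICP.mean"]
    assert case["ICP.sample_entropy"] > ctrl["ICP.sample_entropy"]
    assert case["HR_ekg.binned_entropy"] > ctrl["HR_ekg.binned_entropy"]
    assert case["DBP.mean_change"] < ctrl["DBP.mean_change"]
    assert case["SBP.sd"] < ctrl["SBP.sd"]
    assert case["MAP.sample_entropy"] < ctrl["MAP.sample_entropy"]


def test_null_effect_case_control_exchangeable():
    """With zero effect magnitude, case and control pre-anchor windows are
    drawn from the same process: KS tests across feature columns reject
    at about the nominal rate, not en masse."""
    cfg = CohortConfig(effect=EffectConfig.null())
    records, _ = generate_cohort(30, cfg, seed=21)
    from icp_horizon.features import build_tables
    segs = []
    for r in records:
        s, _ = segment_record(r)
        segs.extend(s)
    table = build_tables(segs, channels="full")[2]
    case = table[table.label == "case"]
    ctrl = table[table.label == "control"]
    assert len(case) >= 10
    pvals = []
    for col in table.columns[3:]:
        a = case[col].dropna()
        b = ctrl[col].dropna()
        if len(a) > 5 and len(b) > 5:
            pvals.append(ks_2samp(a, b).pvalue)
    pvals = np.array(pvals)
    assert (pvals < 0.05).mean() <= 0.15
    assert np.median(pvals) > 0.15


# -- artifacts --------------------------------------------------------------


def test_zero_artifact_rate_leaves_record_unchanged():
    rec, _ = _quiet_record()
    cfg = ArtifactConfig(wide_rate_per_4h=0.0, narrow_rate_per_4h=0.0)
    out, mask = inject_artifacts(rec, cfg, seed=0)
    for ch in rec.channels:
        assert np.array_equal(out.channels[ch], rec.channels[ch])
    assert all(m.sum() == 0 for m in mask.values())


def test_single_narrow_spike_mask():
    rec, _ = _quiet_record()
    mask = add_narrow_spike(rec, 100, 0.5)
    assert np.flatnonzero(mask).tolist() == [100]


def test_mean_corrupted_minutes_matches_default_rate():
    """Default artifact config corrupts about 2.8 minutes per 4-h record."""
    cfg = CohortConfig(segments_per_patient=1, case_fraction=0.0,
                       missingness=MissingnessConfig(gap_rate_per_4h=0.0))
    base, _ = generate_cohort(5, cfg, seed=4)
    rng = np.random.default_rng(3)
    total = 0
    n = 250
    for i in range(n):
        r = base[i % 5]
        sub = VitalsRecord("x", "p",
                           {ch: v[:240].copy()
                            for ch, v in r.channels.items()})
        _, tm = inject_artifacts(sub, ArtifactConfig(), rng)
        total += tm["SBP"].sum()
    assert total / n == pytest.approx(2.8, abs=0.4)
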