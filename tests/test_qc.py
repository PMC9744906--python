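"""Artifact-detection hand traces, fill semantics, adjudication rules,
and detector performance against the simulator's injected truth."""

import numpy as np
import pytest

from icp_horizon import qc
from icp_horizon.records import BP_CHANNELS, VitalsRecord
from icp_horizon.synthgen import generate_cohort, CohortConfig, \
    ArtifactConfig, MissingnessConfig


def _record(sbp, **extra):
    n = len(sbp)
    ch = {c: np.full(n, v, dtype=float) for c, v in
          {"DBP": 60.0, "MAP": 75.0, "ICP": 10.0, "CPP": 67.6,
           "HR_ekg": 100.0, "PR_pleth": 100.0, "SpO2": 98.0}.items()}
    ch["SBP"] = np.asarray(sbp, dtype=float)
    ch.update(extra)
    return VitalsRecord("r", "p", ch)


class TestDetectWide:
    def test_constant_series_empty_mask(self):
        mask, _ = qc.detect_wide(np.full(30, 100.0), 5.0)
        assert mask.n_flagged == 0

    def test_excursion_beyond_two_sd_flagged_and_filled(self):
        """Anchor 100, sd 5: a value of 115 three minutes later deviates by
        15 > 2*5 and is forward-filled to the anchor level."""
        x = np.array([100., 100, 100, 115, 100, 100, 100])
        mask, corrected = qc.detect_wide(x, 5.0)
        assert np.flatnonzero(mask.flags).tolist() == [3]
        assert corrected[3] == 100.0

    def test_step_excursion_fully_flagged(self):
        """An 8-min step of +2.5 sd is flagged in full: forward-filling
        keeps block anchors at the pre-excursion level."""
        x = np.full(30, 100.0)
        x[10:18] += 12.5
        mask, corrected = qc.detect_wide(x, 5.0)
        assert np.flatnonzero(mask.flags).tolist() == list(range(10, 18))
        assert np.all(corrected == 100.0)

    def test_tie_at_exactly_two_sd_not_flagged(self):
        x = np.array([100., 100, 110, 100, 100])
        mask, _ = qc.detect_wide(x, 5.0)          # |10| == 2*5, strict
        assert mask.n_flagged == 0

    def test_zero_sd_nonconstant_is_internal_error(self):
        with pytest.raises(RuntimeError):
            qc.detect_wide(np.array([100., 120, 100, 100, 100]), 0.0)

    def test_all_missing_series_empty_mask(self):
        mask, _ = qc.detect_wide(np.full(10, np.nan), 5.0)
        assert mask.n_flagged == 0


class TestDetectNarrow:
    def test_gentle_ramp_unflagged(self):
        x = 100.0 * 1.05 ** np.arange(10)     # 5% steps
        mask, _ = qc.detect_narrow(x)
        assert mask.n_flagged == 0

    def test_spike_flagged_once_return_not_flagged(self):
        """[100, 150, 100]: only the 150 is flagged; after the causal fill
        the next change is 0%."""
        mask, corrected = qc.detect_narrow(np.array([100., 150, 100, 100]))
        assert np.flatnonzero(mask.flags).tolist() == [1]
        assert corrected.tolist() == [100, 100, 100, 100]

    def test_twenty_nine_percent_change_unflagged(self):
        mask, _ = qc.detect_narrow(np.array([100., 129, 100]))
        # 29% up is below threshold; the way back down 129->100 is 22.5%
        assert mask.n_flagged == 0

    def test_zero_previous_value_is_artifact(self):
        mask, _ = qc.detect_narrow(np.array([0., 80, 80]))
        assert bool(mask.flags[1])


class TestRemoveAndFill:
    def test_empty_mask_identity(self):
        rec = _record(np.linspace(100, 110, 20))
        mask = qc.ArtifactMask(np.zeros(20, dtype=bool))
        out = qc.remove_and_fill(rec, mask)
        for ch in rec.channels:
            assert np.array_equal(out.channels[ch], rec.channels[ch])

    def test_bp_channels_filled_others_untouched(self):
        rec = _record(np.full(10, 100.0))
        for ch in BP_CHANNELS:
            rec.channels[ch][4] = 999.0
        rec.channels["HR_ekg"][4] = 180.0
        flags = np.zeros(10, dtype=bool)
        flags[4] = True
        out = qc.remove_and_fill(rec, qc.ArtifactMask(flags))
        for ch in BP_CHANNELS:
            assert out.channels[ch][4] == out.channels[ch][3]
        assert out.channels["HR_ekg"][4] == 180.0

    def test_mask_at_minute_zero_backfilled(self):
        rec = _record(np.array([500., 100, 100, 100]))
        flags = np.array([True, False, False, False])
        out = qc.remove_and_fill(rec, qc.ArtifactMask(flags))
        assert out.channels["SBP"][0] == 100.0

    def test_idempotent(self):
        rec = _record(np.array([100., 150, 100, 100, 100]))
        mask = qc.detect_artifacts(rec)
        once = qc.remove_and_fill(rec, mask)
        twice = qc.remove_and_fill(once, mask)
        for ch in rec.channels:
            assert np.array_equal(once.channels[ch], twice.channels[ch])


class TestAdjudicate:
    def test_clean_record_passes(self):
        rec = _record(np.full(240, 100.0))
        mask = qc.ArtifactMask(np.zeros(240, dtype=bool))
        rep = qc.adjudicate(rec, mask)
        assert rep.verdict == "pass"
        assert rep.replaced_fraction == 0.0
        assert rep.concurrent_hours == 4.0

    def test_over_ten_percent_missing_excluded(self):
        rec = _record(np.full(240, 100.0))
        rec.channels["SBP"][:25] = np.nan
        rec.missing["SBP"][:25] = True
        rep = qc.adjudicate(rec, qc.ArtifactMask(np.zeros(240, dtype=bool)))
        assert rep.verdict == "exclude_missing"

    def test_short_concurrency_excluded(self):
        rec = _record(np.full(240, 100.0))
        rec.channels["ICP"][:60] = np.nan
        rec.missing["ICP"][:60] = True
        rep = qc.adjudicate(rec, qc.ArtifactMask(np.zeros(240, dtype=bool)))
        assert rep.concurrent_hours == 3.0
        assert rep.verdict == "exclude_concurrency"

    def test_replacement_fraction_arithmetic(self):
        """2.8 replaced minutes per 240-min record is a 1.2% replacement
        fraction (reported to one decimal)."""
        reps = []
        for k in (2, 3, 3, 3, 3):                     # mean 2.8
            flags = np.zeros(240, dtype=bool)
            flags[:k] = True
            rec = _record(np.full(240, 100.0))
            reps.append(qc.adjudicate(rec, qc.ArtifactMask(flags)))
        mean_frac = np.mean([r.replaced_fraction for r in reps])
        assert round(100 * mean_frac, 1) == 1.2


class TestDetectorPerformance:
    def test_recall_and_false_flags_on_default_cohort(self, cohort):
        """>=90% recall of injected wide/narrow artifacts, <=2% false
        flags on uncorrupted minutes."""
        records, truths = cohort
        tp = fn = fp = clean = 0
        for rec, truth in zip(records, truths):
            mask = qc.detect_artifacts(rec)
            true = truth.artifact_mask_true["SBP"]
            tp += int((mask.flags & true).sum())
            fn += int((~mask.flags & true).sum())
            fp += int((mask.flags & ~true).sum())
            clean += int((~true).sum())
        assert tp + fn > 100
        assert tp / (tp + fn) >= 0.90
        assert fp / clean <= 0.02

    def test_no_flags_on_artifact_free_records(self):
        cfg = CohortConfig(artifact=ArtifactConfig(wide_rate_per_4h=0.0,
                                                   narrow_rate_per_4h=0.0))
        records, _ = generate_cohort(8, cfg, seed=31)
        flagged = total = 0
        for rec in records:
            mask = qc.detect_artifacts(rec)
            flagged += mask.n_flagged
            total += rec.n_minutes
        assert flagged / total <= 0.02

    def test_full_pass_idempotent_with_record_sd(self, cohort):
        records, _ = cohort
        for rec in records[:8]:
            c1, m1 = qc.correct_record(rec)
            c2, m2 = qc.correct_record(c1, record_sd=m1.record_sd)
            assert m2.n_flagged == 0
            for ch in c1.channels:
                assert np.array_equal(c1.channels[ch], c2.channels[ch],
                                      equal_nan=True)

    def test_mask_never_touches_non_bp_channels(self, cohort):
        records, _ = cohort
        rec = records[0]
        corr, mask = qc.correct_record(rec)
        for ch in ("HR_ekg", "PR_pleth", "SpO2", "ICP"):
            assert np.array_equal(corr.channels[ch], rec.channels[ch],
                                  equal_nan=True)

    def test_wide_and_narrow_labels_disjoint(self, cohort):
        records, _ = cohort
        for rec in records[:8]:
            mask = qc.detect_artifacts(rec)
            assert not np.any(mask.labels[qc.WIDE] & mask.labels[qc.NARROW])
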