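import math

import numpy as np
import pytest

from prebotpy.burst_detection import Burst, BurstTable
from prebotpy.epoch_analysis import (
    assign_epochs,
    normalize_to_baseline,
    summaries_to_frame,
    summarize_epoch,
)
from prebotpy.io_traces import default_epoch_plan


def burst_at(t, period=None, height=1.0, width=1.0, area=1.0):
    return Burst(t, t - width / 2, t + width / 2, height, width, area, period)


def table_from_times(times):
    bursts = [
        burst_at(t, period=(times[i + 1] - t if i + 1 < len(times) else None))
        for i, t in enumerate(times)
    ]
    return BurstTable(slice_id="s", bursts=bursts)


class TestAssign:
    def setup_method(self):
        self.plan = default_epoch_plan(["drug"])  # baseline [0,600), drug window [1200,1800)

    def test_peak_in_drug_window(self):
        out = assign_epochs(table_from_times([100.0, 1300.0, 1320.0]), self.plan)
        assert [b.peak_t_s for b in out["drug"].bursts] == [1300.0, 1320.0]

    def test_peak_before_analysis_window_unassigned(self):
        out = assign_epochs(table_from_times([900.0]), self.plan)
        assert all(len(t) == 0 for t in out.values())

    def test_boundary_straddling_period_dropped(self):
        # burst at 1195 s sits outside the drug analysis window; its period
        # to the 1210 s burst must not survive into any epoch
        out = assign_epochs(table_from_times([1195.0, 1210.0, 1225.0]), self.plan)
        drug = out["drug"]
        assert [b.peak_t_s for b in drug.bursts] == [1210.0, 1225.0]
        assert list(drug.periods_s) == [15.0]

    def test_partition_property(self):
        times = [50.0, 300.0, 599.0, 700.0, 1250.0, 1400.0, 1900.0]
        out = assign_epochs(table_from_times(times), self.plan)
        assigned = sum(len(t) for t in out.values())
        assert assigned == 5  # 700 s and 1900 s fall outside all windows


class TestSummarize:
    def test_constant_periods(self):
        s = summarize_epoch(table_from_times([0, 2, 4, 6, 8]))
        assert s.mean_period_s == 2.0 and s.cv_period == 0.0

    def test_two_periods_hand_arithmetic(self):
        s = summarize_epoch(table_from_times([0.0, 1.0, 4.0]))  # periods {1, 3}
        assert s.mean_period_s == 2.0
        assert abs(s.cv_period - math.sqrt(2) / 2) < 1e-12

    def test_mean_height(self):
        t = BurstTable(bursts=[burst_at(i * 10.0, height=h) for i, h in enumerate([1, 2, 3])])
        assert summarize_epoch(t).mean_height == 2.0

    def test_too_few_bursts_gives_nan_period_stats(self):
        s = summarize_epoch(table_from_times([5.0]))
        assert s.n_bursts == 1
        assert math.isnan(s.mean_period_s) and math.isnan(s.cv_period)


class TestNormalize:
    def summaries(self, base_times, drug_times):
        plan = default_epoch_plan(["drug"])
        tables = assign_epochs(table_from_times(base_times + drug_times), plan)
        return [summarize_epoch(t) for t in tables.values()]

    def test_plus_25_percent_recovery(self):
        base = list(np.arange(0.0, 600.0, 2.0))
        drug = list(np.arange(1200.0, 1800.0, 2.5))
        out = normalize_to_baseline(self.summaries(base, drug))
        drug_s = next(s for s in out if s.epoch_label == "drug")
        assert abs(drug_s.normalized_period - 1.25) < 1e-12

    def test_baseline_normalizes_to_one(self):
        base = list(np.arange(0.0, 600.0, 2.0))
        drug = list(np.arange(1200.0, 1800.0, 2.0))
        out = normalize_to_baseline(self.summaries(base, drug))
        for s in out:
            assert abs(s.normalized_period - 1.0) < 1e-12
            assert abs(s.delta_cv) < 1e-12

    def test_delta_cv_is_difference(self):
        rng = np.random.default_rng(0)
        base = list(np.cumsum(rng.gamma(100, 2 / 100, 200)))
        base = [t for t in base if t < 600]
        drug = list(1200 + np.cumsum(rng.gamma(25, 2 / 25, 200)))
        drug = [t for t in drug if t < 1800]
        out = normalize_to_baseline(self.summaries(base, drug))
        b = next(s for s in out if s.epoch_label == "baseline")
        d = next(s for s in out if s.epoch_label == "drug")
        assert abs(d.delta_cv - (d.cv_period - b.cv_period)) < 1e-12
        assert d.delta_cv > 0  # drug epoch was generated more irregular

    def test_scale_invariance_of_normalization(self):
        base = list(np.arange(0.0, 600.0, 2.0))
        drug = list(np.arange(1200.0, 1800.0, 3.0))
        out1 = normalize_to_baseline(self.summaries(base, drug))
        out2 = normalize_to_baseline(
            self.summaries([t for t in base], [t for t in drug])
        )
        # rescaling all raw features by a > 0 leaves normalized values alone
        plan = default_epoch_plan(["drug"])
        tables = assign_epochs(table_from_times(base + drug), plan)
        scaled = []
        for t in tables.values():
            bursts = [
                Burst(b.peak_t_s, b.onset_t_s, b.offset_t_s, 7 * b.height,
                      b.width_s, 7 * b.area, b.period_to_next_s)
                for b in t.bursts
            ]
            scaled.append(summarize_epoch(BurstTable(t.slice_id, t.epoch_label, bursts)))
        out3 = normalize_to_baseline(scaled)
        for a, b in zip(out1, out3):
            assert abs(a.normalized_height - b.normalized_height) < 1e-12
            assert abs(a.normalized_area - b.normalized_area) < 1e-12
        assert out1[0].normalized_period == out2[0].normalized_period

    def test_missing_baseline_errors(self):
        s = summarize_epoch(table_from_times([0, 2, 4]))
        s.epoch_label = "drug"
        with pytest.raises(ValueError, match="baseline"):
            normalize_to_baseline([s])

    def test_frame_schema(self):
        base = list(np.arange(0.0, 600.0, 2.0))
        drug = list(np.arange(1200.0, 1800.0, 2.5))
        df = summaries_to_frame(normalize_to_baseline(self.summaries(base, drug)))
        assert {"slice_id", "epoch_label", "normalized_period", "cv_period", "delta_cv"} <= set(df.columns)
        assert len(df) == 2
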