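import itertools

import numpy as np
import pandas as pd
import pytest

from urobiome.io import CountMatrix
from urobiome.qc import (
    QCConfig,
    apply_qc,
    crosstalk_filter,
    nc_read_fraction_filter,
    prevalence_contaminant_test,
    _independence_p,
)

from oracles import chi2_independence_naive, fisher_exact_naive


def _matrix(gu_rows, nc_rows, columns):
    frame = pd.DataFrame(
        gu_rows + nc_rows,
        index=[f"GU{i}" for i in range(len(gu_rows))] + [f"NC{i}" for i in range(len(nc_rows))],
        columns=columns,
    )
    types = pd.Series(["GU"] * len(gu_rows) + ["NC"] * len(nc_rows), index=frame.index)
    return CountMatrix(frame, types)


class TestPrevalenceRule:
    def test_direction_condition_blocks_gu_dominant_asv(self):
        # present in 50/100 GUs but 0/10 NCs: never a contaminant
        gu = [[1] if i < 50 else [0] for i in range(100)]
        nc = [[0]] * 10
        result = prevalence_contaminant_test(_matrix(gu, nc, ["A"]))
        assert not result["rule1"]["A"]

    def test_nc_dominant_asv_flagged_with_exact_p(self):
        # 5/100 GUs vs 9/10 NCs; p must equal the Fisher enumeration oracle
        gu = [[1] if i < 5 else [0] for i in range(100)]
        nc = [[1]] * 9 + [[0]]
        result = prevalence_contaminant_test(_matrix(gu, nc, ["A"]))
        assert result["rule1"]["A"]
        expected = fisher_exact_naive([[5, 95], [9, 1]])
        assert result["prevalence_p"]["A"] == pytest.approx(expected, abs=1e-9)

    def test_exact_p_matches_oracle_on_small_margins(self):
        # every 2x2 table with margins <= 12 routed through Fisher
        for a, b, c, d in itertools.product(range(0, 7, 2), repeat=4):
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            p = _independence_p(np.array([[a, b], [c, d]]))
            expected = np.outer([a + b, c + d], [a + c, b + d]) / (a + b + c + d)
            if expected.min() < 5:
                assert p == pytest.approx(fisher_exact_naive([[a, b], [c, d]]), abs=1e-9)
            else:
                assert p == pytest.approx(chi2_independence_naive([[a, b], [c, d]])[1], abs=1e-9)

    def test_requires_negative_controls(self, toy_counts):
        gu_only = toy_counts.subset(samples=["GU1", "GU2", "GU3"])
        with pytest.raises(ValueError, match="NC"):
            prevalence_contaminant_test(gu_only)

    def test_alpha_bounds(self, toy_counts):
        with pytest.raises(ValueError):
            prevalence_contaminant_test(toy_counts, alpha=1.5)


class TestReadFractionRule:
    def test_six_percent_of_reads_flags(self):
        gu = [[94]]
        nc = [[6]]
        result = nc_read_fraction_filter(_matrix(gu, nc, ["A"]))
        assert result["nc_read_fraction"]["A"] == pytest.approx(0.06)
        assert result["rule2"]["A"]

    def test_zero_nc_reads_never_flags(self):
        result = nc_read_fraction_filter(_matrix([[100]], [[0]], ["A"]))
        assert not result["rule2"]["A"]

    def test_nc_sample_count_clause(self):
        # ASV present in 2 NCs of 12 total samples: 2 > 0.06*12 -> flagged
        gu = [[1000, 10]] * 10
        nc = [[0, 1]] * 2
        result = nc_read_fraction_filter(_matrix(gu, nc, ["A", "B"]))
        assert result["rule2"]["B"]
        assert not result["rule2"]["A"]


class TestCrosstalkRule:
    def test_rare_low_abundance_flagged(self):
        # present in 2 GU samples at 0.1% and 0.3%
        gu = [[1, 999], [3, 997], [0, 1000]]
        result = crosstalk_filter(_matrix(gu, [[0, 10]], ["A", "B"]))
        assert result["rule3"]["A"]

    def test_abundant_occurrence_blocks_flag(self):
        # one of the two occurrences reaches 1%
        gu = [[10, 990], [3, 997], [0, 1000]]
        result = crosstalk_filter(_matrix(gu, [[0, 10]], ["A", "B"]))
        assert not result["rule3"]["A"]


class TestApplyQC:
    def test_clean_input_passes_through(self):
        gu = [[50, 50], [60, 40], [55, 45]]
        nc = [[0, 0]]
        cm = _matrix(gu, nc, ["A", "B"])
        filtered, report = apply_qc(cm)
        assert filtered.counts.equals(cm.gu().counts)
        assert (report.per_sample.loc[filtered.sample_ids, "retained_fraction"] == 1).all()
        assert report.reads_retained_overall == 1.0

    def test_rules_commute(self, desk_pipeline):
        cm = desk_pipeline(1)["counts"]
        config = QCConfig()
        r1 = prevalence_contaminant_test(cm, config.alpha)["rule1"]
        r2 = nc_read_fraction_filter(cm)["rule2"]
        r3 = crosstalk_filter(cm)["rule3"]
        _, report = apply_qc(cm, config)
        # flags are computed on the unfiltered matrix, so the union is
        # identical regardless of application order
        assert report.per_asv["removed"].equals(r1 | r2 | r3)

    def test_threshold_monotonicity(self, desk_pipeline):
        cm = desk_pipeline(1)["counts"]
        loose = crosstalk_filter(cm, min_gu_samples=3)["rule3"]
        strict = crosstalk_filter(cm, min_gu_samples=5)["rule3"]
        assert (strict | loose).equals(strict)  # raising threshold only adds
        low = nc_read_fraction_filter(cm, max_frac=0.05)["rule2"]
        lower = nc_read_fraction_filter(cm, max_frac=0.01)["rule2"]
        assert (lower | low).equals(lower)

    def test_retention_boundary_is_strict(self):
        # sample retaining exactly 50% must be dropped
        gu = [[50, 50], [1, 99]]
        nc = [[30, 0]]  # drives ASV "A" removal via rule 2
        cm = _matrix(gu, nc, ["A", "B"])
        filtered, report = apply_qc(cm)
        assert report.per_asv["removed"]["A"]
        assert not report.per_sample["sample_kept"]["GU0"]
        assert filtered.sample_ids == ["GU1"]

    def test_all_samples_dropped_raises(self):
        gu = [[100, 1], [100, 1]]
        nc = [[50, 0]]
        with pytest.raises(ValueError, match="all GU samples"):
            apply_qc(_matrix(gu, nc, ["A", "B"]))
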