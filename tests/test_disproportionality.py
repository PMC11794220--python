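"""IC, credible bounds, ROR and screening against small oracles."""

import math

import numpy as np
import pytest

from icsr_signal import (
    ContingencyTable,
    build_table,
    comparative_ror,
    disproportionality,
    expected_count,
    ic_credible_bounds,
    information_component,
    ror,
    run_screen,
    signal_flag,
)

from conftest import make_report


class TestExpectedCount:
    def test_full_exposure_limit(self):
        assert expected_count(1000, 50, 1000) == 50.0

    def test_arithmetic(self):
        assert expected_count(100, 50, 1000) == 5.0

    def test_zero_margin_degenerate(self):
        assert expected_count(0, 50, 1000) == 0.0

    def test_invalid_margins(self):
        with pytest.raises(ValueError):
            expected_count(2000, 50, 1000)
        with pytest.raises(ValueError):
            expected_count(10, 5, 0)

    def test_independent_assignment_converges_to_unity(self):
        """Law of large numbers: O/E -> 1 under independence."""
        rng = np.random.default_rng(42)
        for n in (10_000, 100_000):
            drug = rng.random(n) < 0.05
            event = rng.random(n) < 0.02
            observed = int((drug & event).sum())
            e = expected_count(int(drug.sum()), int(event.sum()), n)
            assert observed / e == pytest.approx(1.0, abs=4.0 / math.sqrt(n * 0.001))


class TestInformationComponent:
    def test_identity_at_equality(self):
        assert information_component(7, 7.0) == 0.0

    def test_shrinkage_keeps_zero_counts_finite(self):
        assert information_component(0, 0) == 0.0
        assert information_component(3, 0.5) == pytest.approx(math.log2(3.5))

    def test_monotonic_in_observed_and_expected(self):
        ics = [information_component(o, 10.0) for o in range(0, 50, 5)]
        assert all(x < y for x, y in zip(ics, ics[1:]))
        ics = [information_component(20, e) for e in (1.0, 5.0, 20.0, 80.0)]
        assert all(x > y for x, y in zip(ics, ics[1:]))


class TestCredibleBounds:
    def test_bounds_bracket_point_estimate(self):
        for o, e in [(0, 9.0), (1, 9.0), (18, 9.0), (159, 50.0), (1000, 1000.0)]:
            lo, hi = ic_credible_bounds(o, e)
            assert lo < information_component(o, e) < hi

    def test_large_equal_counts_bracket_zero_symmetrically(self):
        o = 1000
        lo, hi = ic_credible_bounds(o, float(o))
        scale = 1.0 / math.sqrt(o)
        assert -3 * scale < lo < 0 < hi < 3 * scale
        assert abs(lo + hi) < scale / 2

    def test_interval_widens_at_lower_counts(self):
        narrow = ic_credible_bounds(100, 100.0)
        wide = ic_credible_bounds(4, 4.0)
        assert wide[1] - wide[0] > narrow[1] - narrow[0]

    def test_signal_rule_is_strict(self):
        assert not signal_flag(0.0)
        assert signal_flag(1e-9)
        assert not signal_flag(-6.4)

    def test_signal_implies_positive_ic(self):
        for o, e in [(18, 9.0), (159, 50.0), (5, 1.0), (2, 1.0)]:
            res = disproportionality(o, e)
            if res.signal:
                assert res.ic > 0
            assert res.ic025 < res.ic < res.ic975


class TestRor:
    def test_small_table_arithmetic(self):
        res = ror(ContingencyTable(2, 8, 1, 9))
        assert res.ror == pytest.approx(2.25)
        assert not res.correction_applied
        assert res.ci_low < 2.25 < res.ci_high

    def test_null_table(self):
        res = ror(ContingencyTable(5, 10, 10, 20))
        assert res.ror == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_cell_triggers_haldane_correction(self):
        res = ror(ContingencyTable(5, 10, 0, 20))
        assert res.correction_applied
        assert math.isfinite(res.ror) and res.ror > 0

    def test_empty_margin_is_undefined(self):
        with pytest.raises(ValueError, match="margin"):
            ror(ContingencyTable(0, 0, 5, 10))

    def test_swap_gives_reciprocal(self):
        direct = ror(ContingencyTable(12, 40, 7, 90))
        swapped = ror(ContingencyTable(7, 90, 12, 40))
        assert swapped.ror == pytest.approx(1.0 / direct.ror)
        assert swapped.ci_low == pytest.approx(1.0 / direct.ci_high)
        assert swapped.ci_high == pytest.approx(1.0 / direct.ci_low)
        assert swapped.p == pytest.approx(direct.p)

    def test_interval_narrows_as_cells_grow(self):
        small = ror(ContingencyTable(5, 10, 7, 20))
        big = ror(ContingencyTable(50, 100, 70, 200))
        assert (math.log(big.ci_high) - math.log(big.ci_low)) < (
            math.log(small.ci_high) - math.log(small.ci_low)
        )

    def test_matches_statsmodels_woolf_interval(self):
        sm_stats = pytest.importorskip("statsmodels.stats.api")
        table = ContingencyTable(12, 40, 7, 90)
        res = ror(table)
        t22 = sm_stats.Table2x2(
            np.array([[table.a, table.b], [table.c, table.d]]), shift_zeros=False
        )
        assert res.ror == pytest.approx(t22.oddsratio)
        lo, hi = t22.oddsratio_confint(0.05)
        assert res.ci_low == pytest.approx(lo, rel=1e-4)
        assert res.ci_high == pytest.approx(hi, rel=1e-4)


class TestComparativeRor:
    def _universe(self):
        reports = []
        # 40 PD1-exposed (8 cases), 40 PDL1-exposed (8 cases): identical rates
        for i in range(40):
            reports.append(
                make_report(
                    f"A{i}",
                    ingredients=("nivolumab",),
                    pts=("Kidney transplant rejection",) if i < 8 else ("Rash",),
                )
            )
            reports.append(
                make_report(
                    f"B{i}",
                    ingredients=("avelumab",),
                    pts=("Kidney transplant rejection",) if i < 8 else ("Rash",),
                )
            )
        return reports

    def test_identical_rates_give_unity(self, transplant_case):
        res = comparative_ror(self._universe(), "PD1i", "PDL1i", transplant_case)
        assert res.ror == pytest.approx(1.0)

    def test_swap_classes_gives_reciprocal(self, transplant_case):
        reports = self._universe()[:60]
        ab = comparative_ror(reports, "PD1i", "PDL1i", transplant_case)
        ba = comparative_ror(reports, "PDL1i", "PD1i", transplant_case)
        assert ba.ror == pytest.approx(1.0 / ab.ror)
        assert ba.ci_low == pytest.approx(1.0 / ab.ci_high)

    def test_dual_exposed_reports_excluded(self, transplant_case):
        reports = self._universe()
        dual = [
            make_report(
                f"D{i}",
                ingredients=("nivolumab", "avelumab"),
                pts=("Kidney transplant rejection",),
            )
            for i in range(10)
        ]
        with_dual = comparative_ror(reports + dual, "PD1i", "PDL1i", transplant_case)
        without = comparative_ror(reports, "PD1i", "PDL1i", transplant_case)
        assert with_dual.table == without.table

    def test_empty_comparator_arm_raises(self, transplant_case):
        reports = [make_report(f"A{i}", ingredients=("nivolumab",)) for i in range(5)]
        with pytest.raises(ValueError, match="comparator"):
            comparative_ror(reports, "PD1i", "PDL1i", transplant_case)


class TestRunScreen:
    def test_empty_exposure_list(self, small_cohort, transplant_case):
        table = run_screen(small_cohort, [], transplant_case)
        assert len(table) == 0
        assert list(table.columns) == [
            "exposure", "O", "E", "IC", "IC025", "IC975", "signal",
        ]

    def test_invariant_to_report_order(
        self, small_cohort, transplant_case, screen_exposures
    ):
        reports = small_cohort * 1  # copy
        forward = run_screen(reports, screen_exposures, transplant_case)
        backward = run_screen(reports[::-1], screen_exposures, transplant_case)
        assert forward.equals(backward)

    def test_observed_counts_match_build_table(
        self, small_cohort, transplant_case, screen_exposures
    ):
        screen = run_screen(small_cohort, screen_exposures, transplant_case)
        for exp_def, (_, row) in zip(screen_exposures, screen.iterrows()):
            table = build_table(small_cohort, exp_def, transplant_case)
            assert row["O"] == table.a
            assert row["E"] == pytest.approx(table.expected)
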